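"""Separable temporal ERGM: formation/dissolution decomposition and fitting.

A transition from y_t to y_{t+1} is decomposed into two conditionally
independent processes on disjoint dyad sets:

* the formation network Y+ = y_t | y_{t+1} (ties present at t plus newly
  formed ties), modeled as an ERGM over the dyads EMPTY at t with the ties
  of y_t frozen on;
* the dissolution network Y- = y_t & y_{t+1} (surviving ties), modeled as
  an ERGM over the dyads PRESENT at t with all other dyads frozen off.

The next network is reconstructed as y_{t+1} = Y- | (Y+ \\ y_t), which
round-trips exactly with the decomposition. In the dissolution model a
positive coefficient means ties are more likely to be preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .graph import Network, NetworkError
from .terms import ModelSpec
from .ergm import (
    EstimationError,
    FitResult,
    SamplerControl,
    _component_from_network,
    _fit_components,
    _pooled_mple,
    sample_networks,
)

__all__ = [
    "TransitionPair",
    "Panel",
    "decompose_transition",
    "reconstruct",
    "fit_stergm",
    "simulate_panel",
]


def _check_same_nodes(a: Network, b: Network) -> None:
    if a.node_labels != b.node_labels:
        raise NetworkError("networks are defined on different node sets")


@dataclass(frozen=True)
class TransitionPair:
    """Base network y_t with its formation (Y+) and dissolution (Y-) networks."""

    base: Network
    formation: Network
    dissolution: Network

    def __post_init__(self):
        _check_same_nodes(self.base, self.formation)
        _check_same_nodes(self.base, self.dissolution)
        b, f, d = (set(x.edges()) for x in (self.base, self.formation, self.dissolution))
        if not b <= f:
            raise NetworkError("formation network must contain every tie of the base")
        if not d <= b:
            raise NetworkError("dissolution network must be a subset of the base ties")


@dataclass(frozen=True)
class Panel:
    """An ordered sequence of networks on an identical node set."""

    networks: tuple
    times: tuple = None

    def __post_init__(self):
        nets = tuple(self.networks)
        if len(nets) < 2:
            raise NetworkError("a panel needs at least two networks")
        for y in nets[1:]:
            _check_same_nodes(nets[0], y)
        times = tuple(self.times) if self.times is not None else tuple(range(len(nets)))
        if len(times) != len(nets):
            raise NetworkError("times must match the number of networks")
        object.__setattr__(self, "networks", nets)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.networks)

    def transitions(self) -> list[TransitionPair]:
        return [
            decompose_transition(a, b)
            for a, b in zip(self.networks[:-1], self.networks[1:])
        ]


def decompose_transition(y_t: Network, y_t1: Network) -> TransitionPair:
    """Split a transition into formation (union) and dissolution (intersection)."""
    _check_same_nodes(y_t, y_t1)
    e_t = set(y_t.edges())
    e_t1 = set(y_t1.edges())
    return TransitionPair(
        base=y_t,
        formation=y_t.with_edges(e_t | e_t1),
        dissolution=y_t.with_edges(e_t & e_t1),
    )


def reconstruct(y_t: Network, y_plus: Network, y_minus: Network) -> Network:
    """y_{t+1} = Y- union (Y+ minus y_t); exact inverse of decompose_transition."""
    pair = TransitionPair(base=y_t, formation=y_plus, dissolution=y_minus)
    e_t = set(y_t.edges())
    formed = set(y_plus.edges()) - e_t
    surviving = set(y_minus.edges())
    return y_t.with_edges(surviving | formed)


def _formation_component(spec, pair: TransitionPair, attrs):
    base_edges = set(pair.base.edges())
    free = [d for d in _all_dyads(pair.base) if d not in base_edges]
    if not free:
        raise EstimationError(
            "formation model has no free dyads (base network is complete)"
        )
    return _component_from_network(spec, pair.formation, attrs, free_pairs=free)


def _dissolution_component(spec, pair: TransitionPair, attrs):
    free = pair.base.edges()
    if not free:
        raise EstimationError(
            "dissolution model has no free dyads (base network is empty)"
        )
    return _component_from_network(spec, pair.dissolution, attrs, free_pairs=free)


def _all_dyads(net: Network):
    from .terms import all_dyads

    return all_dyads(net.n)


def fit_stergm(
    panel: Panel | Sequence[Network],
    formation_spec: ModelSpec,
    dissolution_spec: ModelSpec,
    attrs=None,
    control: SamplerControl | None = None,
    method: str = "mcmc",
    pooled: bool = True,
    **fit_kwargs,
):
    """Fit formation and dissolution coefficients (theta+, theta-) to a panel.

    Each of the T-1 observed transitions contributes an independent
    conditional likelihood factor; by default coefficients are pooled
    (homogeneous across transitions). Estimation is conditional MPLE
    followed by conditional MCMC-MLE with toggles restricted to the free
    dyads of each component (``method="mple"`` stops after the first
    stage). The formation and dissolution fits never share dyads.

    Returns ``(formation_fit, dissolution_fit)``; with ``pooled=False``, a
    list of such pairs, one per transition.
    """
    if not isinstance(panel, Panel):
        panel = Panel(tuple(panel))
    control = control if control is not None else SamplerControl()
    pairs = panel.transitions()
    if not pooled:
        return [
            fit_stergm(
                Panel((a, b)), formation_spec, dissolution_spec, attrs=attrs,
                control=control, method=method, pooled=True, **fit_kwargs,
            )
            for a, b in zip(panel.networks[:-1], panel.networks[1:])
        ]
    form_comps = [_formation_component(formation_spec, p, attrs) for p in pairs]
    diss_comps = [_dissolution_component(dissolution_spec, p, attrs) for p in pairs]
    fits = []
    for comps, tag in ((form_comps, "formation"), (diss_comps, "dissolution")):
        if method == "mple":
            theta, se = _pooled_mple(comps)
            fits.append(
                FitResult(
                    names=comps[0].bound.names, theta=theta, se=se,
                    method=f"mple/{tag}", converged=True,
                )
            )
        elif method == "mcmc":
            fr = _fit_components(comps, control, **fit_kwargs)
            fr.method = f"mcmc-mle/{tag}"
            fits.append(fr)
        else:
            raise ValueError(f"unknown method {method!r}")
    return fits[0], fits[1]


def simulate_panel(
    y_0: Network,
    formation_spec: ModelSpec,
    theta_plus,
    dissolution_spec: ModelSpec,
    theta_minus,
    T: int,
    attrs=None,
    control: SamplerControl | None = None,
) -> Panel:
    """Simulate a panel of T transitions forward from ``y_0``.

    At each step a formation network is drawn with toggles restricted to
    the dyads empty at t (ties of y_t frozen on), a dissolution network
    with toggles restricted to the ties of y_t, and the two are
    recombined. Deterministic under a fixed control seed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    control = control if control is not None else SamplerControl()
    nets = [y_0]
    dyads = _all_dyads(y_0)
    for t in range(T):
        y_t = nets[-1]
        ties = set(y_t.edges())
        empty = [d for d in dyads if d not in ties]
        if not empty or not ties:
            raise EstimationError(
                f"transition {t}: base network is empty or complete; "
                "formation/dissolution draws are undefined"
            )
        f_draw = sample_networks(
            formation_spec, theta_plus, attrs=attrs,
            control=replace(control, samples=1, seed=control.seed + 2 * t + 1),
            start=y_t, free_dyads=empty,
        )
        d_draw = sample_networks(
            dissolution_spec, theta_minus, attrs=attrs,
            control=replace(control, samples=1, seed=control.seed + 2 * t + 2),
            start=y_t, free_dyads=sorted(ties),
        )
        nets.append(reconstruct(y_t, f_draw.networks[0], d_draw.networks[0]))
    return Panel(tuple(nets))
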