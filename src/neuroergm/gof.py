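"""Simulation-based goodness of fit.

Networks are simulated at the fitted coefficients and four families of
summaries are compared with the observed network: the degree distribution,
the edgewise shared-partner distribution, the minimum geodesic distance
distribution (with a separate bucket for disconnected pairs), and the model
statistics themselves. For each bin the 2.5/25/50/75/97.5% simulation
quantiles form the envelope; an observed value is flagged when it escapes
the outer (95%) band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Network, esp_counts, geodesic_distribution
from .terms import ModelSpec
from .ergm import FitResult, SamplerControl, sample_networks

__all__ = ["GofReport", "run_gof", "plot_gof"]

_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class GofMetric:
    """Observed values and simulation envelopes for one summary family."""

    name: str
    bins: list  # bin labels (degree, shared-partner count, distance, stat name)
    observed: np.ndarray
    sims: np.ndarray  # n_sims x n_bins
    quantiles: np.ndarray  # 5 x n_bins, rows follow _QUANTILES

    @property
    def inside(self) -> np.ndarray:
        return (self.observed >= self.quantiles[0]) & (self.observed <= self.quantiles[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"observed": self.observed}, index=[str(b) for b in self.bins])
        for q, row in zip(_QUANTILES, self.quantiles):
            df[f"q{q * 100:g}"] = row
        df["inside"] = self.inside
        return df


@dataclass
class GofReport:
    """Goodness-of-fit summaries for the four metric families."""

    metrics: dict[str, GofMetric]
    n_sims: int
    seed: int

    def __getitem__(self, name: str) -> GofMetric:
        return self.metrics[name]

    @property
    def all_inside(self) -> bool:
        return all(bool(m.inside.all()) for m in self.metrics.values())

    def to_dict(self) -> dict:
        out = {"n_sims": self.n_sims, "seed": self.seed, "metrics": {}}
        for name, m in self.metrics.items():
            out["metrics"][name] = {
                "bins": [str(b) for b in m.bins],
                "observed": m.observed.tolist(),
                "quantile_levels": list(_QUANTILES),
                "quantiles": m.quantiles.tolist(),
                "inside": m.inside.tolist(),
            }
        return out

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _degree_hist(net: Network) -> np.ndarray:
    return np.bincount(net.degrees(), minlength=net.n).astype(float)


def _esp_hist(net: Network) -> np.ndarray:
    return esp_counts(net).counts.astype(float)


def _geodesic_hist(net: Network, max_d: int) -> np.ndarray:
    """Counts for distances 1..max_d plus a final infinity bucket."""
    out = np.zeros(max_d + 1)
    for d, c in geodesic_distribution(net).items():
        if d is math.inf or d == math.inf:
            out[-1] = c
        else:
            out[min(int(d), max_d) - 1] += c  # distances beyond max_d pooled
    return out


def _metric(name, bins, observed, sims) -> GofMetric:
    sims = np.asarray(sims, dtype=float)
    q = np.quantile(sims, _QUANTILES, axis=0)
    return GofMetric(name=name, bins=list(bins), observed=np.asarray(observed, float),
                     sims=sims, quantiles=q)


def run_gof(
    fit: FitResult,
    spec: ModelSpec,
    net: Network,
    attrs=None,
    n_sims: int = 1000,
    seed: int | None = None,
    control: SamplerControl | None = None,
) -> GofReport:
    """Simulate ``n_sims`` networks at the fitted coefficients and compare.

    The chain starts at the observed network. Counting invariants (degree
    counts sum to n, shared-partner counts to the edge count, geodesic
    counts to the dyad count) are asserted for every simulated network.
    """
    if not fit.converged:
        raise ValueError("refusing to run GOF on a non-converged fit")
    base = control if control is not None else (fit.control or SamplerControl())
    if seed is None:
        seed = base.seed + 7919
    ctl = SamplerControl(
        burn_in=base.burn_in, interval=base.interval, samples=n_sims,
        proposal=base.proposal, tnt_prob=base.tnt_prob, seed=seed,
    )
    draw = sample_networks(spec, fit.theta, attrs=attrs, control=ctl, start=net)
    n, D = net.n, net.dyad_count
    obs_geo = geodesic_distribution(net)
    finite_obs = [d for d in obs_geo if d is not math.inf and d != math.inf]
    max_d = max(finite_obs, default=1)
    for y in draw.networks:
        finite = [d for d in geodesic_distribution(y) if d != math.inf]
        max_d = max(max_d, max(finite, default=1))

    deg_sims, esp_sims, geo_sims = [], [], []
    for y in draw.networks:
        dh, eh, gh = _degree_hist(y), _esp_hist(y), _geodesic_hist(y, max_d)
        assert dh.sum() == n and eh.sum() == y.edge_count and gh.sum() == D
        deg_sims.append(dh)
        esp_sims.append(eh)
        geo_sims.append(gh)
    deg_obs, esp_obs, geo_obs = _degree_hist(net), _esp_hist(net), _geodesic_hist(net, max_d)
    assert deg_obs.sum() == n and esp_obs.sum() == net.edge_count and geo_obs.sum() == D

    from .terms import BoundModel, GraphState

    bound = BoundModel(spec, net, attrs)
    g_obs = bound.stats(GraphState.from_network(net))

    metrics = {
        "degree": _metric("degree", list(range(n)), deg_obs, deg_sims),
        "esp": _metric("esp", list(range(len(esp_obs))), esp_obs, esp_sims),
        "geodesic": _metric(
            "geodesic", [*range(1, max_d + 1), "inf"], geo_obs, geo_sims
        ),
        "model": _metric("model", bound.names, g_obs, draw.stats.to_numpy()),
    }
    return GofReport(metrics=metrics, n_sims=n_sims, seed=seed)


def plot_gof(report: GofReport, path) -> Path:
    """Write the four-panel observed-vs-envelope figure.

    Each panel shows box-and-whisker simulation summaries (boxes at the
    quartiles, whiskers at the 2.5/97.5% quantiles) with the observed
    values drawn as a line, in the style of standard ERGM GOF plots.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, axes = plt.subplots(1, 4, figsize=(18, 4.2))
    titles = {
        "degree": "degree distribution",
        "esp": "edgewise shared partners",
        "geodesic": "minimum geodesic distance",
        "model": "model statistics",
    }
    for ax, name in zip(axes, ("degree", "esp", "geodesic", "model")):
        m = report[name]
        pos = np.arange(len(m.bins))
        boxes = [
            {
                "whislo": m.quantiles[0, b],
                "q1": m.quantiles[1, b],
                "med": m.quantiles[2, b],
                "q3": m.quantiles[3, b],
                "whishi": m.quantiles[4, b],
                "fliers": [],
            }
            for b in pos
        ]
        ax.bxp(boxes, positions=pos, showfliers=False)
        ax.plot(pos, m.observed, color="black", lw=2, marker="o", ms=3)
        ax.set_title(titles[name])
        step = max(1, len(m.bins) // 12)
        ax.set_xticks(pos[::step])
        ax.set_xticklabels([str(m.bins[b]) for b in pos[::step]], rotation=45, fontsize=7)
    fig.tight_layout()
    try:
        fig.savefig(path)
    except OSError as e:
        raise OSError(f"cannot write GOF figure to {path}: {e}") from None
    finally:
        plt.close(fig)
    return path
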