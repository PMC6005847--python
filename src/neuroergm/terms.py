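"""ERGM model statistics g(y) and their change statistics.

Supported terms: ``edges`` (edge count), ``nodecov(attr)`` (sum of endpoint
covariate values over edges), ``nodemix(attr)`` (edge counts per unordered
label pair), and ``gwesp(decay)`` (geometrically weighted edgewise shared
partners with fixed decay).

Each bound term exposes three views used by the estimation engine:

* ``stat(state)`` -- the statistic on the full graph;
* ``delta(state, i, j)`` -- the term-wise change from toggling dyad (i, j)
  ON, i.e. g(y + ij) - g(y - ij);
* ``score(state, i, j, theta)`` -- the scalar contribution theta_t' delta_t,
  the only quantity the Metropolis sampler needs per proposal.

The delta implementations are incremental; tests verify them against the
brute-force toggle difference on exhaustively sampled small graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import AttrTable, Network, NetworkError

__all__ = [
    "Edges",
    "NodeCov",
    "NodeMix",
    "Gwesp",
    "ModelSpec",
    "ModelSpecError",
    "model_statistics",
    "change_statistics",
]


class ModelSpecError(ValueError):
    """Invalid model specification (unknown attribute, bad cell, rank issue)."""


@dataclass(frozen=True)
class Edges:
    """Total edge count; the density 'intercept' of the model."""

    kind: str = "edges"


@dataclass(frozen=True)
class NodeCov:
    """Sum over edges of the endpoint values of a quantitative attribute."""

    attr: str
    kind: str = "nodecov"


@dataclass(frozen=True)
class NodeMix:
    """Edge counts per unordered category pair of a categorical attribute.

    ``include`` restricts the reported cells; ``exclude`` drops cells from
    the default full set. Cells are unordered ``(level_a, level_b)`` pairs.
    When an ``edges`` term is present in the same model, at least one cell
    must be excluded or the design matrix is rank deficient; by default the
    first between-level cell in level order is dropped.
    """

    attr: str
    include: tuple | None = None
    exclude: tuple | None = None
    kind: str = "nodemix"

    def __post_init__(self):
        if self.include is not None and self.exclude is not None:
            raise ModelSpecError("nodemix: give include or exclude, not both")
        for fld in ("include", "exclude"):
            v = getattr(self, fld)
            if v is not None:
                object.__setattr__(
                    self, fld, tuple(tuple(sorted((str(a), str(b)))) for a, b in v)
                )


@dataclass(frozen=True)
class Gwesp:
    """Geometrically weighted edgewise shared partners with fixed decay.

    The statistic is ``e^tau * sum_i [1 - (1 - e^-tau)^i] EP_i(y)`` where
    EP_i counts edges with exactly i shared partners. The decay tau is held
    fixed (no curved estimation).
    """

    decay: float
    kind: str = "gwesp"

    def __post_init__(self):
        if self.decay < 0:
            raise ModelSpecError(f"gwesp decay must be >= 0, got {self.decay}")


Term = Edges | NodeCov | NodeMix | Gwesp


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of model terms."""

    terms: tuple

    def __init__(self, terms: Sequence[Term]):
        terms = tuple(terms)
        keys = []
        for t in terms:
            if not isinstance(t, (Edges, NodeCov, NodeMix, Gwesp)):
                raise ModelSpecError(f"unknown term {t!r}")
            keys.append(
                (t.kind, getattr(t, "attr", None), getattr(t, "decay", None),
                 getattr(t, "include", None), getattr(t, "exclude", None))
            )
        if len(set(keys)) != len(keys):
            raise ModelSpecError("duplicate terms in model specification")
        object.__setattr__(self, "terms", terms)

    @property
    def has_edges(self) -> bool:
        return any(isinstance(t, Edges) for t in self.terms)

    def with_gwesp_decay(self, decay: float) -> "ModelSpec":
        """Copy of the spec with every gwesp term's decay replaced."""
        return ModelSpec(
            tuple(Gwesp(decay) if isinstance(t, Gwesp) else t for t in self.terms)
        )

    @classmethod
    def from_config(cls, cfg) -> "ModelSpec":
        """Parse the YAML/JSON term-array form, e.g.

        ``[edges, {nodecov: degree}, {nodemix: {attr: resting}},
        {gwesp: {decay: 0.45}}]``
        """
        if isinstance(cfg, dict) and "terms" in cfg:
            cfg = cfg["terms"]
        terms: list[Term] = []
        for item in cfg:
            if item == "edges":
                terms.append(Edges())
            elif isinstance(item, dict) and len(item) == 1:
                (kind, val), = item.items()
                if kind == "nodecov":
                    terms.append(NodeCov(str(val)))
                elif kind == "nodemix":
                    if isinstance(val, str):
                        terms.append(NodeMix(val))
                    else:
                        terms.append(
                            NodeMix(
                                str(val["attr"]),
                                include=tuple(map(tuple, val["include"])) if "include" in val else None,
                                exclude=tuple(map(tuple, val["exclude"])) if "exclude" in val else None,
                            )
                        )
                elif kind == "gwesp":
                    decay = val["decay"] if isinstance(val, dict) else val
                    terms.append(Gwesp(float(decay)))
                else:
                    raise ModelSpecError(f"unknown term kind {kind!r}")
            else:
                raise ModelSpecError(f"cannot parse term entry {item!r}")
        return cls(terms)


# ---------------------------------------------------------------------------
# graph state shared by evaluators and the sampler


class GraphState:
    """Mutable neighbor-set view of a graph used during sampling."""

    __slots__ = ("n", "nbrs", "edge_count")

    def __init__(self, n: int, nbrs: list[set]):
        self.n = n
        self.nbrs = nbrs
        self.edge_count = sum(len(s) for s in nbrs) // 2

    @classmethod
    def from_network(cls, net: Network) -> "GraphState":
        return cls(net.n, net.neighbor_sets())

    def add(self, i: int, j: int) -> None:
        self.nbrs[i].add(j)
        self.nbrs[j].add(i)
        self.edge_count += 1

    def remove(self, i: int, j: int) -> None:
        self.nbrs[i].discard(j)
        self.nbrs[j].discard(i)
        self.edge_count -= 1

    def has(self, i: int, j: int) -> bool:
        return j in self.nbrs[i]

    def to_network(self, labels) -> Network:
        a = np.zeros((self.n, self.n), dtype=bool)
        for i, s in enumerate(self.nbrs):
            for j in s:
                a[i, j] = True
        return Network(labels, a)


# ---------------------------------------------------------------------------
# bound evaluators


class _BoundEdges:
    width = 1

    def __init__(self):
        self.names = ["edges"]

    def stat(self, st: GraphState) -> list[float]:
        return [float(st.edge_count)]

    def delta(self, st: GraphState, i: int, j: int) -> list[float]:
        return [1.0]

    def score(self, st: GraphState, i: int, j: int, theta) -> float:
        return theta[0]


class _BoundNodeCov:
    width = 1

    def __init__(self, attr: str, x: np.ndarray):
        self.names = [f"nodecov.{attr}"]
        self.x = x.tolist()

    def stat(self, st: GraphState) -> list[float]:
        x = self.x
        return [sum(len(st.nbrs[i]) * x[i] for i in range(st.n))]

    def delta(self, st: GraphState, i: int, j: int) -> list[float]:
        return [self.x[i] + self.x[j]]

    def score(self, st: GraphState, i: int, j: int, theta) -> float:
        return theta[0] * (self.x[i] + self.x[j])


class _BoundNodeMix:
    def __init__(self, term: NodeMix, attrs: AttrTable, net: Network):
        levels = attrs.levels(term.attr)
        codes = attrs.codes(term.attr, net)
        all_cells = [
            (levels[a], levels[b])
            for a in range(len(levels))
            for b in range(a, len(levels))
        ]
        norm = lambda c: tuple(sorted((str(c[0]), str(c[1]))))
        known = {norm(c): c for c in all_cells}
        if term.include is not None:
            cells = []
            for c in term.include:
                if norm(c) not in known:
                    raise ModelSpecError(f"nodemix cell {c} references unknown level")
                cells.append(known[norm(c)])
        else:
            drop = set()
            for c in term.exclude or ():
                if norm(c) not in known:
                    raise ModelSpecError(f"nodemix cell {c} references unknown level")
                drop.add(norm(c))
            cells = [c for c in all_cells if norm(c) not in drop]
        self.cells = cells
        self.names = [f"mix.{term.attr}.{a}.{b}" for a, b in cells]
        self.width = len(cells)
        L = len(levels)
        lvl_idx = {lv: k for k, lv in enumerate(levels)}
        cell_of = np.full((L, L), -1, dtype=np.int64)
        for k, (a, b) in enumerate(cells):
            ia, ib = lvl_idx[a], lvl_idx[b]
            cell_of[ia, ib] = cell_of[ib, ia] = k
        self.codes = codes.tolist()
        self.cell_of = cell_of

    def stat(self, st: GraphState) -> list[float]:
        out = [0.0] * self.width
        codes, cell_of = self.codes, self.cell_of
        for i in range(st.n):
            ci = codes[i]
            for j in st.nbrs[i]:
                if j > i:
                    k = cell_of[ci, codes[j]]
                    if k >= 0:
                        out[k] += 1.0
        return out

    def delta(self, st: GraphState, i: int, j: int) -> list[float]:
        out = [0.0] * self.width
        k = self.cell_of[self.codes[i], self.codes[j]]
        if k >= 0:
            out[k] = 1.0
        return out

    def score(self, st: GraphState, i: int, j: int, theta) -> float:
        k = self.cell_of[self.codes[i], self.codes[j]]
        return theta[k] if k >= 0 else 0.0


class _BoundGwesp:
    width = 1

    def __init__(self, decay: float):
        self.names = [f"gwesp.fixed.{decay:g}"]
        self.decay = decay
        self.etau = float(np.exp(decay))
        self.r = 1.0 - float(np.exp(-decay))

    def stat(self, st: GraphState) -> list[float]:
        etau, r = self.etau, self.r
        total = 0.0
        nbrs = st.nbrs
        for i in range(st.n):
            si = nbrs[i]
            for j in si:
                if j > i:
                    c = len(si & nbrs[j])
                    if c:
                        total += etau * (1.0 - r**c)
        return [total]

    def delta(self, st: GraphState, i: int, j: int) -> list[float]:
        # change from adding (i, j) to a state in which it is absent:
        # the new edge contributes its own weight, and each edge to a common
        # neighbor k gains one shared partner, contributing r^esp(i,k).
        nbrs = st.nbrs
        common = nbrs[i] & nbrs[j]
        r = self.r
        d = self.etau * (1.0 - r ** len(common))
        si, sj = nbrs[i], nbrs[j]
        for k in common:
            sk = nbrs[k]
            d += r ** len(si & sk) + r ** len(sj & sk)
        return [d]

    def score(self, st: GraphState, i: int, j: int, theta) -> float:
        return theta[0] * self.delta(st, i, j)[0]


class BoundModel:
    """A ModelSpec bound to a node set and attribute table."""

    def __init__(self, spec: ModelSpec, net: Network, attrs: AttrTable | None):
        self.spec = spec
        self.labels = net.node_labels
        bound = []
        for t in spec.terms:
            if isinstance(t, Edges):
                bound.append(_BoundEdges())
            elif isinstance(t, NodeCov):
                if attrs is None:
                    raise ModelSpecError(f"nodecov({t.attr}) requires an attribute table")
                bound.append(_BoundNodeCov(t.attr, attrs.quantitative(t.attr, net)))
            elif isinstance(t, NodeMix):
                if attrs is None:
                    raise ModelSpecError(f"nodemix({t.attr}) requires an attribute table")
                bt = _BoundNodeMix(t, attrs, net)
                if (
                    spec.has_edges
                    and t.include is None
                    and not t.exclude
                    and bt.width > 1
                ):
                    # default reference cell: first between-level cell in order
                    levels = attrs.levels(t.attr)
                    if len(levels) > 1:
                        bt = _BoundNodeMix(
                            NodeMix(t.attr, exclude=((levels[0], levels[1]),)),
                            attrs,
                            net,
                        )
                bound.append(bt)
            elif isinstance(t, Gwesp):
                bound.append(_BoundGwesp(t.decay))
        self.terms = bound
        self.offsets = np.cumsum([0] + [b.width for b in bound])
        self.names: list[str] = [n for b in bound for n in b.names]
        self.k = len(self.names)
        if spec.has_edges:
            for b in bound:
                if isinstance(b, _BoundNodeMix) and b.cell_of.size and (b.cell_of >= 0).all():
                    raise ModelSpecError(
                        "nodemix includes every cell while an edges term is present; "
                        "exclude at least one cell to keep the design full rank"
                    )

    def stats(self, st: GraphState) -> np.ndarray:
        return np.array([v for b in self.terms for v in b.stat(st)])

    def delta(self, st: GraphState, i: int, j: int) -> np.ndarray:
        """Change vector for toggling (i, j) ON; (i, j) must be absent."""
        return np.array([v for b in self.terms for v in b.delta(st, i, j)])

    def split_theta(self, theta: np.ndarray) -> list:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ModelSpecError(
                f"theta has length {theta.size}, model has {self.k} statistics"
            )
        return [
            theta[self.offsets[t]: self.offsets[t + 1]].tolist()
            for t in range(len(self.terms))
        ]


# ---------------------------------------------------------------------------
# public helpers


def term_edges(net: Network) -> int:
    return net.edge_count


def term_nodecov(net: Network, attrs: AttrTable, attr: str) -> float:
    x = attrs.quantitative(attr, net)
    return float(sum(x[i] + x[j] for i, j in net.edges()))


def term_nodemix(
    net: Network, attrs: AttrTable, attr: str, cells=None
) -> pd.Series:
    term = NodeMix(attr, include=tuple(map(tuple, cells)) if cells is not None else None)
    bt = _BoundNodeMix(term, attrs, net)
    st = GraphState.from_network(net)
    return pd.Series(bt.stat(st), index=bt.names)


def term_gwesp(net: Network, decay: float) -> float:
    if decay < 0:
        raise ModelSpecError(f"gwesp decay must be >= 0, got {decay}")
    st = GraphState.from_network(net)
    return _BoundGwesp(decay).stat(st)[0]


def model_statistics(
    spec: ModelSpec, net: Network, attrs: AttrTable | None = None
) -> pd.Series:
    """Named statistic vector g(y) in term order."""
    bound = BoundModel(spec, net, attrs)
    return pd.Series(bound.stats(GraphState.from_network(net)), index=bound.names)


def change_statistics(
    spec: ModelSpec, net: Network, dyad: tuple, attrs: AttrTable | None = None
) -> pd.Series:
    """Change statistics for toggling ``dyad`` ON: g(y+ij) - g(y-ij).

    Equals the brute-force toggle difference regardless of the dyad's
    current state in ``net``.
    """
    bound = BoundModel(spec, net, attrs)
    u, v = dyad
    try:
        i, j = net.index_of(u), net.index_of(v)
    except KeyError as e:
        raise NetworkError(f"unknown node in dyad: {e}") from None
    if i == j:
        raise NetworkError("self-dyad has no change statistic")
    st = GraphState.from_network(net)
    present = st.has(i, j)
    if present:
        st.remove(i, j)
    d = bound.delta(st, i, j)
    return pd.Series(d, index=bound.names)


def all_dyads(n: int) -> list[tuple[int, int]]:
    """All unordered index pairs (i < j)."""
    return list(itertools.combinations(range(n), 2))
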