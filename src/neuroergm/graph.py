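"""Binary undirected network container, structural node metrics, and file I/O.

The container is deliberately minimal: a symmetric boolean adjacency matrix
over an ordered list of node labels, with no self-loops and no weights.
Brain graphs produced by sparsifying partial-correlation matrices are binary,
so weighted input is rejected rather than silently thresholded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Network",
    "AttrTable",
    "EspCounts",
    "NetworkError",
    "load_network",
    "save_network",
    "density",
    "structural_node_covariates",
    "esp_counts",
    "geodesic_distribution",
]


class NetworkError(ValueError):
    """Raised for invalid graph input (asymmetry, weights, bad labels)."""


class Network:
    """A simple undirected binary graph on labeled nodes.

    Parameters
    ----------
    node_labels:
        Ordered node identifiers. Order is authoritative: attribute tables
        and adjacency files are aligned by this order. Internally nodes are
        addressed by 0-based index.
    adjacency:
        Square array-like; must be symmetric, hollow (zero diagonal) and
        contain only 0/1 values.
    """

    __slots__ = ("_labels", "_adj", "_index")

    def __init__(self, node_labels: Sequence, adjacency) -> None:
        labels = tuple(str(x) for x in node_labels)
        if len(set(labels)) != len(labels):
            raise NetworkError("duplicate node labels")
        a = np.asarray(adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkError(f"adjacency must be square, got shape {a.shape}")
        if a.shape[0] != len(labels):
            raise NetworkError(
                f"{len(labels)} labels but adjacency is {a.shape[0]}x{a.shape[1]}"
            )
        if a.dtype != bool:
            vals = np.unique(a)
            if not np.all(np.isin(vals, (0, 1))):
                raise NetworkError(
                    "non-binary adjacency values found "
                    f"(e.g. {vals[~np.isin(vals, (0, 1))][0]!r}); "
                    "binarize the matrix before constructing a Network"
                )
            a = a.astype(bool)
        if np.any(a != a.T):
            raise NetworkError("adjacency is not symmetric (directed input rejected)")
        a = a.copy()
        np.fill_diagonal(a, False)
        self._labels = labels
        self._adj = a
        self._adj.setflags(write=False)
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(cls, node_labels: Sequence, edges: Iterable[tuple]) -> "Network":
        """Build from an iterable of (u, v) label pairs; isolates preserved."""
        labels = [str(x) for x in node_labels]
        index = {lab: i for i, lab in enumerate(labels)}
        a = np.zeros((len(labels), len(labels)), dtype=bool)
        for u, v in edges:
            u, v = str(u), str(v)
            if u not in index or v not in index:
                missing = u if u not in index else v
                raise NetworkError(f"edge references undeclared node {missing!r}")
            if u == v:
                raise NetworkError(f"self-loop on node {u!r} not allowed")
            a[index[u], index[v]] = a[index[v], index[u]] = True
        return cls(labels, a)

    @classmethod
    def empty(cls, node_labels: Sequence) -> "Network":
        n = len(tuple(node_labels))
        return cls(node_labels, np.zeros((n, n), dtype=bool))

    # -- basic accessors ---------------------------------------------------

    @property
    def node_labels(self) -> tuple:
        return self._labels

    @property
    def n(self) -> int:
        return len(self._labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Read-only boolean adjacency matrix."""
        return self._adj

    @property
    def edge_count(self) -> int:
        return int(self._adj.sum()) // 2

    @property
    def dyad_count(self) -> int:
        return self.n * (self.n - 1) // 2

    def index_of(self, label) -> int:
        return self._index[str(label)]

    def has_edge(self, u, v) -> bool:
        return bool(self._adj[self.index_of(u), self.index_of(v)])

    def edges(self, labels: bool = False) -> list[tuple]:
        """Edge list as index pairs (i < j), or as label pairs."""
        ii, jj = np.nonzero(np.triu(self._adj, k=1))
        if labels:
            return [(self._labels[i], self._labels[j]) for i, j in zip(ii, jj)]
        return list(zip(ii.tolist(), jj.tolist()))

    def neighbor_sets(self) -> list[set]:
        return [set(np.nonzero(row)[0].tolist()) for row in self._adj]

    def degrees(self) -> np.ndarray:
        return self._adj.sum(axis=0).astype(np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    def with_edges(self, edges: Iterable[tuple[int, int]]) -> "Network":
        """New Network on the same labels with the given index-pair edge set."""
        a = np.zeros((self.n, self.n), dtype=bool)
        for i, j in edges:
            a[i, j] = a[j, i] = True
        return Network(self._labels, a)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Network)
            and self._labels == other._labels
            and bool(np.array_equal(self._adj, other._adj))
        )

    def __hash__(self):  # pragma: no cover - identity semantics suffice
        return id(self)

    def __repr__(self) -> str:
        return f"Network(n={self.n}, edges={self.edge_count})"


class AttrTable:
    """Per-node categorical and quantitative attributes.

    Wraps a :class:`pandas.DataFrame` indexed by node label. Categorical
    columns keep a fixed, recorded level order (the order of first
    appearance unless given explicitly), which downstream mixing terms rely
    on for cell ordering.
    """

    def __init__(
        self,
        table: pd.DataFrame | Mapping,
        categorical: Sequence[str] | Mapping[str, Sequence] | None = None,
    ) -> None:
        df = pd.DataFrame(table).copy()
        df.index = df.index.map(str)
        if categorical is None:
            categorical = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if isinstance(categorical, Mapping):
            cat_levels = {c: list(v) for c, v in categorical.items()}
        else:
            cat_levels = {c: None for c in categorical}
        for col, levels in cat_levels.items():
            if col not in df.columns:
                raise NetworkError(f"categorical column {col!r} not in table")
            if levels is None:
                seen = list(dict.fromkeys(df[col].astype(str)))
                levels = seen
            df[col] = pd.Categorical(df[col].astype(str), categories=[str(x) for x in levels])
            if df[col].isna().any():
                raise NetworkError(f"column {col!r} has values outside declared levels")
        self._df = df
        self._categorical = set(cat_levels)

    @property
    def table(self) -> pd.DataFrame:
        return self._df

    @property
    def columns(self) -> list[str]:
        return list(self._df.columns)

    def is_categorical(self, name: str) -> bool:
        return name in self._categorical

    def levels(self, name: str) -> list[str]:
        if name not in self._categorical:
            raise NetworkError(f"{name!r} is not a categorical attribute")
        return list(self._df[name].cat.categories)

    def quantitative(self, name: str, net: Network) -> np.ndarray:
        """Real-valued column aligned to the network's node order."""
        if name not in self._df.columns:
            raise NetworkError(f"attribute {name!r} not found")
        if name in self._categorical:
            raise NetworkError(f"{name!r} is categorical, not quantitative")
        return self._aligned(name, net).to_numpy(dtype=float)

    def codes(self, name: str, net: Network) -> np.ndarray:
        """Integer level codes of a categorical column, in node order."""
        col = self._aligned(name, net)
        if name not in self._categorical:
            raise NetworkError(f"{name!r} is not a categorical attribute")
        return col.cat.codes.to_numpy()

    def _aligned(self, name: str, net: Network) -> pd.Series:
        missing = [lab for lab in net.node_labels if lab not in self._df.index]
        if missing:
            raise NetworkError(f"nodes missing from attribute table: {missing[:5]}")
        return self._df.loc[list(net.node_labels), name]

    def validate_against(self, net: Network) -> None:
        unknown = [lab for lab in self._df.index if lab not in net._index]
        if unknown:
            raise NetworkError(f"attribute table names unknown nodes: {unknown[:5]}")
        missing = [lab for lab in net.node_labels if lab not in self._df.index]
        if missing:
            raise NetworkError(f"nodes missing from attribute table: {missing[:5]}")

    def merged_with(self, other: "AttrTable") -> "AttrTable":
        df = self._df.join(other._df, how="outer")
        cats: dict[str, Sequence] = {}
        for src in (self, other):
            for c in src._categorical:
                cats[c] = src.levels(c)
        return AttrTable(df, categorical=cats)

    def __repr__(self) -> str:
        return f"AttrTable(nodes={len(self._df)}, columns={self.columns})"


@dataclass(frozen=True)
class EspCounts:
    """Histogram EP_i: number of edges whose endpoints share exactly i partners.

    ``counts[i]`` holds EP_i for i = 0..n-2; the counts sum to the number of
    edges in the graph.
    """

    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))

    @property
    def n_edges(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        """Nonzero entries only, mapping shared-partner count -> edge count."""
        return {int(i): int(c) for i, c in enumerate(self.counts) if c}

    def __getitem__(self, i: int) -> int:
        if 0 <= i < len(self.counts):
            return int(self.counts[i])
        return 0


# ---------------------------------------------------------------------------
# metrics


def density(net: Network) -> float:
    """Fraction of realized edges among the n(n-1)/2 possible dyads."""
    if net.n < 2:
        raise NetworkError("density undefined for fewer than 2 nodes")
    return net.edge_count / net.dyad_count


def structural_node_covariates(net: Network) -> AttrTable:
    """Degree, clustering coefficient, and local efficiency per node.

    These are the quantitative covariates computed on a structural
    (tractography-derived) graph and fed into a functional-network model as
    ``nodecov`` terms. Degenerate nodes (degree < 2) get clustering and
    efficiency 0. Local efficiency is the mean inverse shortest-path length
    within each node's neighbor-induced subgraph (Rubinov-Sporns form);
    unreachable neighbor pairs contribute 0.
    """
    g = net.to_networkx()
    deg = net.degrees().astype(float)
    clust = nx.clustering(g)
    eff = np.zeros(net.n)
    for v in range(net.n):
        nbrs = list(g[v])
        if len(nbrs) >= 2:
            eff[v] = nx.global_efficiency(g.subgraph(nbrs))
    df = pd.DataFrame(
        {
            "degree": deg,
            "cluster": [clust[v] for v in range(net.n)],
            "efficiency": eff,
        },
        index=list(net.node_labels),
    )
    return AttrTable(df, categorical=[])


def esp_counts(net: Network) -> EspCounts:
    """Edgewise shared-partner histogram over all edges."""
    a = net.adjacency.astype(np.int64)
    counts = np.zeros(max(net.n - 1, 1), dtype=np.int64)
    if net.edge_count:
        common = a @ a
        ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
        for i, j in zip(ii, jj):
            counts[common[i, j]] += 1
    return EspCounts(counts)


def geodesic_distribution(net: Network) -> dict:
    """Counts of unordered dyads at each minimum geodesic distance.

    Disconnected pairs are reported under the key ``math.inf``. Counts sum
    to the dyad universe size n(n-1)/2.
    """
    d = shortest_path(csr_matrix(net.adjacency), method="D", unweighted=True)
    iu = np.triu_indices(net.n, k=1)
    vals = d[iu]
    out: dict = {}
    finite = vals[np.isfinite(vals)].astype(int)
    for dist, cnt in zip(*np.unique(finite, return_counts=True)):
        out[int(dist)] = int(cnt)
    n_inf = int(np.sum(~np.isfinite(vals)))
    if n_inf:
        out[math.inf] = n_inf
    return out


# ---------------------------------------------------------------------------
# file I/O


def _read_attr_table(path) -> AttrTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AttrTable(df)


def load_network(
    path,
    format: str = "edgelist",
    nodes=None,
    attrs=None,
    sep: str | None = None,
) -> tuple[Network, AttrTable | None]:
    """Read a network from disk, with optional node attributes.

    ``format="edgelist"`` expects one ``u<TAB>v`` pair per line (a header
    line is skipped if present); pass ``nodes`` (path to a one-label-per-line
    manifest, or a sequence of labels) to preserve isolated nodes.
    ``format="adjacency"`` expects a square numeric CSV/TSV with labels in
    the header row and first column. ``attrs`` is a TSV with one row per
    node (first column = label).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        edges = []
        with open(path) as fh:
            for ln, line in enumerate(fh):
                parts = line.strip().split(sep)
                if not parts or parts == [""]:
                    continue
                if len(parts) != 2:
                    raise NetworkError(f"{path}:{ln + 1}: expected two fields, got {parts}")
                edges.append((parts[0], parts[1]))
        # tolerate a header line such as "from  to"
        if edges and edges[0][0].lower() in {"from", "source", "u", "node1"}:
            edges = edges[1:]
        if nodes is None:
            labels = list(dict.fromkeys([x for e in edges for x in e]))
        elif isinstance(nodes, (str, Path)):
            labels = [ln.strip() for ln in open(nodes) if ln.strip()]
        else:
            labels = list(nodes)
        net = Network.from_edges(labels, edges)
    elif format == "adjacency":
        df = pd.read_csv(path, sep=sep if sep is not None else None, index_col=0, engine="python")
        if list(df.index.map(str)) != [str(c) for c in df.columns]:
            raise NetworkError("adjacency row labels do not match column labels")
        net = Network(list(df.columns.map(str)), df.to_numpy())
    else:
        raise ValueError(f"unknown format {format!r}")
    table = None
    if attrs is not None:
        table = _read_attr_table(attrs)
        table.validate_against(net)
    return net, table


def save_network(net: Network, path, format: str = "edgelist") -> None:
    """Write a network to disk in one of the formats read by load_network."""
    path = Path(path)
    if format == "edgelist":
        with open(path, "w") as fh:
            for u, v in net.edges(labels=True):
                fh.write(f"{u}\t{v}\n")
        manifest = path.with_suffix(path.suffix + ".nodes")
        with open(manifest, "w") as fh:
            fh.write("\n".join(net.node_labels) + "\n")
    elif format == "adjacency":
        df = pd.DataFrame(
            net.adjacency.astype(int), index=list(net.node_labels), columns=list(net.node_labels)
        )
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
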