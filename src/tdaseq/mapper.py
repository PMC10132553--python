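"""Mapper graphs on subject score matrices.

Mapper summarizes a cohort as a graph: a scalar filter (here the mean,
max, or min pairwise Pearson correlation of each subject against the
rest) maps subjects to the real line; the filter range is covered by
``b`` equal-length overlapping intervals (adjacent overlap = ``p``
percent of the interval length); subjects within each interval are
clustered (agglomerative, Euclidean metric, merges stopped at scale
``epsilon``); each cluster becomes a node, and two nodes are joined by an
edge weighted by the number of subjects they share.

Cover convention: with filter range R = max - min, the interval length is
``l = R / (1 + (b-1)(1 - p/100))`` and interval i starts at
``min + i*l*(1 - p/100)``, so the union covers the range exactly and
every adjacent pair overlaps by ``l*p/100``. Interval membership is
closed at both endpoints: boundary subjects join both bins, which is
precisely what creates edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "MapperParams",
    "Cover",
    "MapperNode",
    "MapperGraph",
    "compute_filter",
    "build_cover",
    "cluster_within_bin",
    "build_mapper",
]

FILTER_KINDS = ("mean_corr", "max_corr", "min_corr")
LINKAGES = ("single", "complete", "average")


@dataclass(frozen=True)
class MapperParams:
    b: int = 80
    p: float = 50.0
    epsilon: float = 600.0
    filter_kind: str = "mean_corr"
    linkage: str = "single"

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("b (number of bins) must be >= 1")
        if not 0 < self.p < 100:
            raise ValueError("p (percent overlap) must be in (0, 100)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.filter_kind not in FILTER_KINDS:
            raise ValueError(f"filter_kind must be one of {FILTER_KINDS}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")


@dataclass(frozen=True)
class Cover:
    """Ordered equal-length overlapping intervals spanning the filter range."""

    intervals: np.ndarray  # shape (b, 2)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def membership(self, values) -> list[np.ndarray]:
        """Indices of ``values`` falling in each interval (closed ends)."""
        v = np.asarray(values, dtype=float)
        span = max(float(self.intervals[-1, 1] - self.intervals[0, 0]), 1.0)
        tol = 1e-9 * span
        return [
            np.flatnonzero((v >= lo - tol) & (v <= hi + tol))
            for lo, hi in self.intervals
        ]


@dataclass(frozen=True)
class MapperNode:
    node_id: int
    bin_index: int
    members: tuple[str, ...]


@dataclass(frozen=True)
class MapperGraph:
    nodes: tuple[MapperNode, ...]
    edges: tuple[tuple[int, int, int], ...]  # (node_id, node_id, weight)
    params: MapperParams
    filter_values: dict[str, float]
    subject_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def members_of(self, node_id: int) -> tuple[str, ...]:
        return self.nodes[node_id].members

    def subjects(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes:
            out.update(node.members)
        return out

    def to_networkx(self, labels=None) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {
                "bin": node.bin_index,
                "members": ",".join(node.members),
                "size": len(node.members),
            }
            if labels is not None:
                n_tumor = sum(labels[m] == "tumor" for m in node.members)
                attrs["n_tumor"] = n_tumor
                attrs["n_healthy"] = len(node.members) - n_tumor
            g.add_node(node.node_id, **attrs)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=int(w))
        return g

    def to_json_dict(self, labels=None) -> dict:
        nodes = []
        for node in self.nodes:
            entry = {
                "id": node.node_id,
                "bin": node.bin_index,
                "members": list(node.members),
            }
            if labels is not None:
                n_tumor = sum(labels[m] == "tumor" for m in node.members)
                entry["n_tumor"] = n_tumor
                entry["n_healthy"] = len(node.members) - n_tumor
            nodes.append(entry)
        edges = [
            {"source": u, "target": v, "weight": int(w)} for u, v, w in self.edges
        ]
        return {"nodes": nodes, "edges": edges}

    def write_json(self, path, labels=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(labels), fh, indent=1)

    def write_graphml(self, path, labels=None) -> None:
        nx.write_graphml(self.to_networkx(labels), path)


def compute_filter(matrix, filter_kind: str = "mean_corr", subject_ids=None):
    """Per-subject correlation filter.

    ``matrix`` is subjects x genes. For each subject the Pearson
    correlation against every *other* subject is computed; the filter is
    the mean, max, or min of those n-1 values.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    if filter_kind not in FILTER_KINDS:
        raise ValueError(f"filter_kind must be one of {FILTER_KINDS}")
    variances = X.var(axis=1)
    if np.any(variances <= 0):
        bad = int(np.argmax(variances <= 0))
        name = subject_ids[bad] if subject_ids is not None else f"row {bad}"
        raise ValueError(
            f"subject {name} has zero variance; correlation filter undefined"
        )
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, np.nan)
    if filter_kind == "mean_corr":
        return np.nanmean(corr, axis=1)
    if filter_kind == "max_corr":
        return np.nanmax(corr, axis=1)
    return np.nanmin(corr, axis=1)


def build_cover(filter_values, b: int, p: float) -> Cover:
    """Equal-length cover of [min f, max f] with b bins and p% overlap."""
    if b < 1:
        raise ValueError("b must be >= 1")
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    f = np.asarray(filter_values, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("filter values must be finite")
    lo, hi = float(f.min()), float(f.max())
    r = hi - lo
    if r == 0:
        return Cover(np.array([[lo, hi]]))
    step_frac = 1.0 - p / 100.0
    length = r / (1.0 + (b - 1) * step_frac)
    starts = lo + np.arange(b) * length * step_frac
    return Cover(np.column_stack([starts, starts + length]))


def cluster_within_bin(
    bin_rows, epsilon: float, linkage: str = "single"
) -> list[np.ndarray]:
    """Partition one bin's subject rows by agglomerative clustering.

    Merging stops at Euclidean distance ``epsilon``: clusters are groups
    whose merge heights are strictly below epsilon (for single linkage
    this equals the connected components of the epsilon-threshold
    distance graph). Returns index arrays into ``bin_rows``, ordered by
    their smallest member index.
    """
    X = np.atleast_2d(np.asarray(bin_rows, dtype=float))
    n = X.shape[0]
    if n == 0:
        return []
    if n == 1:
        return [np.array([0])]
    model = AgglomerativeClustering(
        n_clusters=None,
        distance_threshold=float(epsilon),
        linkage=linkage,
        metric="euclidean",
    )
    labels = model.fit_predict(X)
    clusters = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    clusters.sort(key=lambda idx: int(idx[0]))
    return clusters


def build_mapper(
    score_matrix,
    params: MapperParams,
    subject_ids=None,
    filter_values=None,
) -> MapperGraph:
    """Build a Mapper graph from a subjects x genes score matrix.

    The filter and the clustering both operate on the rows of
    ``score_matrix``. Precomputed ``filter_values`` can be supplied to
    reuse across parameter sweeps. Nodes are ordered by
    (bin_index, smallest member index) so identical inputs produce
    identical graphs.
    """
    X = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    n = X.shape[0]
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n)]
    subject_ids = [str(s) for s in subject_ids]
    if len(subject_ids) != n:
        raise ValueError("subject_ids length does not match matrix rows")
    if filter_values is None:
        filter_values = compute_filter(X, params.filter_kind, subject_ids)
    f = np.asarray(filter_values, dtype=float)

    cover = build_cover(f, params.b, params.p)
    nodes: list[MapperNode] = []
    member_sets: list[frozenset[int]] = []
    for bin_index, members in enumerate(cover.membership(f)):
        if members.size == 0:
            continue
        for cluster in cluster_within_bin(
            X[members], params.epsilon, params.linkage
        ):
            idx = members[cluster]
            nodes.append(
                MapperNode(
                    node_id=len(nodes),
                    bin_index=bin_index,
                    members=tuple(subject_ids[i] for i in idx),
                )
            )
            member_sets.append(frozenset(int(i) for i in idx))

    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            shared = len(member_sets[i] & member_sets[j])
            if shared >= 1:
                edges.append((i, j, shared))

    return MapperGraph(
        nodes=tuple(nodes),
        edges=tuple(edges),
        params=params,
        filter_values={sid: float(v) for sid, v in zip(subject_ids, f)},
        subject_ids=tuple(subject_ids),
    )
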