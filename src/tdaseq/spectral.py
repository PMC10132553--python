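"""Heat kernel signatures and graphical subject scores on Mapper graphs.

A Mapper graph becomes a *doubly-weighted graph* G = (V, M, W): vertex
weights M = diag(m_1..m_n) encode each node's tumor/healthy composition,
and edge weights W_ij count the subjects shared by nodes i and j. The
weighted Laplacian is

    L = M^(-1/2) (D - W) M^(-1/2),     d_i = sum_j W_ij,

symmetric and positive semi-definite (M = I gives the unnormalized, and
M = D the normalized, graph Laplacian). With eigenpairs {lambda_k,
phi_k}, the heat kernel signature of node i at diffusion time t is

    nu_i(t) = sum_k exp(-t lambda_k) phi_k(i)^2,

the amount of heat retained at i at time t from a unit initial
condition. A subject's graphical subject score (GSS) is the sum of
nu_i(t) over all nodes containing it.

Node weights: a literal healthy:tumor ratio is 0 or infinite on pure
nodes, which breaks M^(-1/2). The default is therefore the smoothed
tumor fraction m_i = (n_tumor + alpha) / (n_total + 2 alpha), positive
and bounded for any composition; the smoothed healthy fraction and a
floored literal ratio are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh

from tdaseq.mapper import MapperGraph

__all__ = [
    "DoublyWeightedGraph",
    "SpectralDecomposition",
    "HKSTable",
    "GSSVector",
    "to_weighted_graph",
    "weighted_laplacian",
    "spectral_decomposition",
    "heat_kernel_signature",
    "graphical_subject_scores",
    "compute_gss",
]

EIG_CLAMP = 1e-12


@dataclass(frozen=True)
class DoublyWeightedGraph:
    """Vertex weights m, symmetric edge weights W, degrees d_i = sum_j W_ij."""

    m: np.ndarray
    W: np.ndarray
    node_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        W = np.asarray(self.W, dtype=float)
        if W.shape != (m.size, m.size):
            raise ValueError("W must be square and match the vertex count")
        if np.any(m <= 0):
            raise ValueError("vertex weights must be positive")
        if np.max(np.abs(W - W.T)) > 1e-12:
            raise ValueError("edge-weight matrix must be symmetric")
        if np.any(W < 0) or np.any(np.diag(W) != 0):
            raise ValueError("edge weights must be nonnegative with zero diagonal")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "W", (W + W.T) / 2.0)
        if not self.node_ids:
            object.__setattr__(self, "node_ids", tuple(range(m.size)))

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.m.size)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Ascending eigenvalues and orthonormal eigenvectors (columns)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def lambda2(self) -> float | None:
        """Smallest nonzero eigenvalue (None if all are zero)."""
        pos = self.eigenvalues[self.eigenvalues > EIG_CLAMP]
        return float(pos[0]) if pos.size else None


@dataclass(frozen=True)
class HKSTable:
    """nu_i(t) for each node i (rows) and diffusion time t (columns)."""

    times: np.ndarray
    values: np.ndarray  # (n_nodes, n_times)
    node_ids: tuple[int, ...] = ()

    def at(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise ValueError(f"time {t} not in the HKS table")
        return self.values[:, idx[0]]


@dataclass(frozen=True)
class GSSVector:
    scores: pd.Series
    t: float | dict
    provenance: dict


def to_weighted_graph(
    graph: MapperGraph,
    labels,
    smoothing_alpha: float = 1.0,
    weight_rule: str = "tumor_fraction",
    ratio_floor: float = 1e-3,
) -> DoublyWeightedGraph:
    """Convert a Mapper graph into a doubly-weighted graph.

    ``labels`` maps subject id -> {healthy, tumor}. Rules for m_i:
    ``tumor_fraction`` (default) (n_tumor + a)/(n_total + 2a),
    ``healthy_fraction`` its complement, ``ratio`` the literal
    healthy:tumor ratio clipped below at ``ratio_floor``. Edge weights
    are shared-subject counts.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("cannot weight an empty graph")
    a = float(smoothing_alpha)
    m = np.empty(n)
    for i, node in enumerate(graph.nodes):
        total = len(node.members)
        if total == 0:
            raise ValueError(f"node {node.node_id} has no members")
        tumor = sum(labels[s] == "tumor" for s in node.members)
        if weight_rule == "tumor_fraction":
            m[i] = (tumor + a) / (total + 2 * a)
        elif weight_rule == "healthy_fraction":
            m[i] = (total - tumor + a) / (total + 2 * a)
        elif weight_rule == "ratio":
            healthy = total - tumor
            m[i] = max(healthy / max(tumor, ratio_floor), ratio_floor)
        else:
            raise ValueError(f"unknown weight_rule {weight_rule!r}")
    W = np.zeros((n, n))
    for u, v, w in graph.edges:
        W[u, v] = W[v, u] = float(w)
    return DoublyWeightedGraph(m, W, tuple(nd.node_id for nd in graph.nodes))


def weighted_laplacian(g: DoublyWeightedGraph) -> np.ndarray:
    """L = M^(-1/2) (D - W) M^(-1/2); symmetric PSD."""
    inv_sqrt_m = 1.0 / np.sqrt(g.m)
    lap = np.diag(g.degrees) - g.W
    L = inv_sqrt_m[:, None] * lap * inv_sqrt_m[None, :]
    return (L + L.T) / 2.0


def spectral_decomposition(L: np.ndarray) -> SpectralDecomposition:
    """Full symmetric eigendecomposition with near-zero eigenvalues
    clamped to exactly zero."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("L must be square")
    if np.max(np.abs(L - L.T)) > 1e-10:
        raise ValueError("L must be symmetric")
    eigenvalues, eigenvectors = eigh(L)
    eigenvalues = eigenvalues.copy()
    eigenvalues[np.abs(eigenvalues) < EIG_CLAMP] = 0.0
    return SpectralDecomposition(eigenvalues, eigenvectors)


def heat_kernel_signature(
    decomp: SpectralDecomposition, times
) -> HKSTable:
    """nu_i(t) = sum_k exp(-t lambda_k) phi_k(i)^2."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("diffusion times must be nonnegative")
    phi_sq = decomp.eigenvectors ** 2  # (i, k)
    heat = np.exp(-np.outer(t, decomp.eigenvalues))  # (t, k)
    values = phi_sq @ heat.T  # (i, t)
    return HKSTable(t, values)


def graphical_subject_scores(
    graph: MapperGraph, hks: HKSTable, t: float
) -> pd.Series:
    """GSS(subject) = sum of nu_i(t) over the nodes containing it."""
    if len(hks.values) != graph.n_nodes:
        raise ValueError("HKS table does not match the graph's node set")
    nu = hks.at(t)
    scores: dict[str, float] = {}
    for i, node in enumerate(graph.nodes):
        for s in node.members:
            scores[s] = scores.get(s, 0.0) + float(nu[i])
    missing = graph.subjects() - set(scores)
    if missing:
        raise ValueError(f"subjects in no node: {sorted(missing)[:5]}")
    out = pd.Series(scores, name="gss").sort_index()
    out.index.name = "subject_id"
    return out


def compute_gss(
    graph: MapperGraph,
    labels,
    t: float | str = "auto",
    smoothing_alpha: float = 1.0,
    weight_rule: str = "tumor_fraction",
) -> GSSVector:
    """End-to-end GSS: weight the graph, decompose per connected
    component, evaluate the HKS, and aggregate per subject.

    ``t='auto'`` uses t* = 1/lambda_2 within each connected component
    (the reciprocal of its spectral gap), the scale at which signatures
    discriminate between positions; isolated nodes have nu = 1 at any t.
    A fixed float applies the same t everywhere.
    """
    g = to_weighted_graph(graph, labels, smoothing_alpha, weight_rule)
    adj = nx.from_numpy_array(g.W)
    scores: dict[str, float] = {}
    t_used: dict[int, float] = {}
    for comp in nx.connected_components(adj):
        idx = np.array(sorted(comp))
        sub = DoublyWeightedGraph(g.m[idx], g.W[np.ix_(idx, idx)])
        decomp = spectral_decomposition(weighted_laplacian(sub))
        if t == "auto":
            lam2 = decomp.lambda2
            t_comp = 1.0 / lam2 if lam2 else 1.0
        else:
            t_comp = float(t)
        nu = heat_kernel_signature(decomp, [t_comp]).values[:, 0]
        for local_i, node_i in enumerate(idx):
            for s in graph.nodes[node_i].members:
                scores[s] = scores.get(s, 0.0) + float(nu[local_i])
            t_used[int(node_i)] = t_comp
    series = pd.Series(scores, name="gss").sort_index()
    series.index.name = "subject_id"
    prm = graph.params
    provenance = {
        "b": prm.b, "p": prm.p, "epsilon": prm.epsilon,
        "filter_kind": prm.filter_kind, "linkage": prm.linkage,
        "weight_rule": weight_rule, "smoothing_alpha": smoothing_alpha,
        "t_rule": t,
    }
    t_values = sorted(set(t_used.values()))
    t_out: float | dict = t_values[0] if len(t_values) == 1 else t_used
    return GSSVector(series, t_out, provenance)
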