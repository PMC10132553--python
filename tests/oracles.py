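"""Independent brute-force references used to cross-check the package."""

import numpy as np
from scipy.stats import pearsonr

from tdaseq import mapper


def brute_filter(X, kind):
    """O(n^2) pairwise-correlation filter via scipy.stats.pearsonr."""
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        rs = [pearsonr(X[i], X[j]).statistic for j in range(n) if j != i]
        out[i] = {"mean_corr": np.mean, "max_corr": np.max,
                  "min_corr": np.min}[kind](rs)
    return out


def threshold_components(X, eps):
    """Connected components of the strict eps-threshold distance graph
    (equivalent to single-linkage clusters cut below eps)."""
    n = X.shape[0]
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in range(n):
                if not seen[j] and np.linalg.norm(X[i] - X[j]) < eps:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return sorted(comps)


def brute_mapper(X, ids, b, p, eps):
    """Fully independent Mapper reference: explicit bins, threshold-graph
    clustering, pairwise intersections. Returns canonical node/edge sets."""
    f = brute_filter(X, "mean_corr")
    lo, hi = f.min(), f.max()
    r = hi - lo
    step = 1 - p / 100.0
    length = r / (1 + (b - 1) * step)
    tol = 1e-9 * max(r, 1.0)  # closed-endpoint membership tolerance
    nodes = []
    for i in range(b):
        a = lo + i * length * step
        members = [k for k in range(len(ids))
                   if a - tol <= f[k] <= a + length + tol]
        if not members:
            continue
        for comp in threshold_components(X[members], eps):
            nodes.append((i, frozenset(ids[members[j]] for j in comp)))
    edges = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            shared = len(nodes[i][1] & nodes[j][1])
            if shared:
                edges[frozenset([nodes[i], nodes[j]])] = shared
    return sorted(nodes), edges


def canonical(graph: mapper.MapperGraph):
    """Node/edge sets keyed by (bin, member-set): relabeling-invariant."""
    nodes = sorted((n.bin_index, frozenset(n.members)) for n in graph.nodes)
    by_id = {n.node_id: (n.bin_index, frozenset(n.members))
             for n in graph.nodes}
    edges = {frozenset([by_id[u], by_id[v]]): w for u, v, w in graph.edges}
    return nodes, edges
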