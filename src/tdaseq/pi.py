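"""Position indices on strand-like Mapper graphs.

A strand-like Mapper graph orders its nodes along the filter axis. The
position index (PI) places each subject at one end (+1), the other end
(-1), or the middle (0): with the m nodes linearized, subjects appearing
in any of the first k nodes get +1, subjects in any of the last k nodes
get -1, everyone else 0. By default k is a quarter of the nodes. Summing
a subject's PI across an ensemble of graphs (e.g. a clustering-scale
sweep) measures how consistently the graphs place that subject: |sum| =
ensemble size means perfectly consistent end placement.

The +1 end is fixed by convention to the low-filter end; ensembles are
aligned by correlating each assignment against the first and flipping
its sign when the correlation is negative, which makes the sums
well-defined across parameter sweeps.

The module also exports the PI subgroup ID lists consumed by external
differential-expression tooling, together with the fold-change contract
for the usual |log2 fold change| cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tdaseq.mapper import MapperGraph

__all__ = [
    "PIAssignment",
    "linearize_nodes",
    "assign_position_index",
    "align_assignments",
    "pi_consistency",
    "export_pi_groups",
    "lfc_to_fold_change",
    "select_by_lfc",
]


@dataclass(frozen=True)
class PIAssignment:
    """Subject -> {-1, 0, +1} with the node order it came from."""

    values: pd.Series
    k: int
    node_order: tuple[int, ...]
    strandlike: bool

    def flipped(self) -> "PIAssignment":
        return PIAssignment(-self.values, self.k, self.node_order, self.strandlike)


def linearize_nodes(graph: MapperGraph) -> tuple[tuple[int, ...], bool]:
    """Order nodes along the filter axis and flag strand-likeness.

    Nodes are sorted by (bin_index, mean member filter value). The graph
    counts as strand-like when its bin-collapsed graph — one vertex per
    occupied bin, bins joined whenever any of their nodes share an edge —
    is a path (or a single vertex). Parallel strands inside a bin are
    tolerated; branches (a bin adjacent to 3+ bins) are not.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot linearize an empty graph")

    def mean_filter(node):
        return float(np.mean([graph.filter_values[m] for m in node.members]))

    order = tuple(
        n.node_id
        for n in sorted(graph.nodes, key=lambda n: (n.bin_index, mean_filter(n)))
    )

    collapsed = nx.Graph()
    bin_of = {n.node_id: n.bin_index for n in graph.nodes}
    collapsed.add_nodes_from(set(bin_of.values()))
    for u, v, _ in graph.edges:
        if bin_of[u] != bin_of[v]:
            collapsed.add_edge(bin_of[u], bin_of[v])
    m = collapsed.number_of_nodes()
    strandlike = (
        m <= 1
        or (
            nx.is_connected(collapsed)
            and collapsed.number_of_edges() == m - 1
            and max(d for _, d in collapsed.degree()) <= 2
        )
    )
    return order, strandlike


def assign_position_index(graph: MapperGraph, k: float = 0.25) -> PIAssignment:
    """Assign +1 / 0 / -1 by position in the linearized node order.

    ``k`` is either an absolute end-block size (int) or a fraction of the
    node count (float in (0,1)); the default quarter follows the usual
    rule of letting each end block cover roughly a quarter of the nodes.
    Subjects landing in both end blocks (impossible on a true strand)
    get 0 with a warning.
    """
    order, strandlike = linearize_nodes(graph)
    m = len(order)
    if 0 < k < 1:  # fraction of the node count
        k_nodes = int(round(k * m))
    else:
        k_nodes = int(k)
    if k_nodes < 0 or 2 * k_nodes > m:
        raise ValueError(f"end-block size k={k_nodes} invalid for {m} nodes")

    members_of = {n.node_id: n.members for n in graph.nodes}
    plus: set[str] = set()
    minus: set[str] = set()
    for node_id in order[:k_nodes]:
        plus.update(members_of[node_id])
    for node_id in order[m - k_nodes:] if k_nodes else []:
        minus.update(members_of[node_id])
    conflict = plus & minus
    if conflict:
        warnings.warn(
            f"{len(conflict)} subject(s) appear in both end blocks; "
            "assigned PI 0",
            RuntimeWarning,
        )
    values = pd.Series(0, index=pd.Index(sorted(graph.subjects()),
                                         name="subject_id"), dtype=int)
    values[list(plus - conflict)] = 1
    values[list(minus - conflict)] = -1
    return PIAssignment(values, k_nodes, order, strandlike)


def align_assignments(assignments: list[PIAssignment]) -> list[PIAssignment]:
    """Fix one orientation across an ensemble.

    PI is antisymmetric under flipping the drawing; each assignment is
    correlated (as a vector over the shared subjects) with the first and
    flipped when the correlation is negative.
    """
    if not assignments:
        return []
    ref = assignments[0].values
    out = [assignments[0]]
    for a in assignments[1:]:
        v = a.values.reindex(ref.index)
        dot = float((ref * v).sum())
        out.append(a.flipped() if dot < 0 else a)
    return out


def pi_consistency(assignments: list[PIAssignment], align: bool = False) -> pd.Series:
    """Per-subject sum of PI values across graphs.

    |sum| equal to the ensemble size signals perfectly consistent end
    placement. Set ``align=True`` to orientation-align the ensemble
    first.
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    if align:
        assignments = align_assignments(assignments)
    index = assignments[0].values.index
    for a in assignments[1:]:
        if not a.values.index.equals(index):
            if set(a.values.index) != set(index):
                raise ValueError("assignments cover different subject sets")
    total = sum(a.values.reindex(index) for a in assignments)
    total.name = "pi_sum"
    return total


def export_pi_groups(
    assignment: PIAssignment, labels=None, out_dir=None
) -> dict:
    """Split subjects into the +1 / -1 / center groups.

    Returns the three ID lists and a counts table; when ``out_dir`` is
    given, writes each list as a plain-text file (one ID per line) for
    downstream differential-expression runs.
    """
    v = assignment.values
    groups = {
        "pi_plus": sorted(v.index[v == 1]),
        "pi_minus": sorted(v.index[v == -1]),
        "center": sorted(v.index[v == 0]),
    }
    counts = {name: len(ids) for name, ids in groups.items()}
    if labels is not None:
        for name, ids in groups.items():
            counts[f"{name}_tumor"] = int(
                sum(labels[s] == "tumor" for s in ids)
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, ids in groups.items():
            (out_dir / f"{name}_subjects.txt").write_text(
                "\n".join(ids) + ("\n" if ids else "")
            )
    return {"groups": groups, "counts": counts}


def lfc_to_fold_change(lfc: float = 0.90) -> float:
    """Linear fold change equivalent to a |log2 fold change| cutoff.

    The default cutoff 0.90 corresponds to a 2^0.90 ~ 1.87-fold
    expression difference.
    """
    return float(2.0 ** lfc)


def select_by_lfc(lfc_values, threshold: float = 0.90) -> np.ndarray:
    """Boolean mask of entries with |LFC| >= threshold."""
    return np.abs(np.asarray(lfc_values, dtype=float)) >= threshold
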