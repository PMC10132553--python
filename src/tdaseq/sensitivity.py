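"""Mapper parameter sweeps and empirical confidence intervals for GSS.

The Mapper construction depends on three parameters: bin count b,
percent overlap p, and clustering scale epsilon. The sensitivity
analysis evaluates the graphical subject score on every grid combination
and then, varying one parameter while holding the other two fixed,
summarizes each subject's empirical score distribution with its mean and
a central 95% interval. Tight (or zero-width) intervals mean the
graphical placement of that subject is robust to the varied parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tdaseq.mapper import MapperParams, build_mapper, compute_filter
from tdaseq.spectral import compute_gss

__all__ = ["ParameterGrid", "GSSEnsemble", "CIReport", "sweep", "empirical_ci"]


def _dedupe(values, name: str) -> tuple:
    vals = tuple(values)
    unique = tuple(dict.fromkeys(vals))
    if len(unique) != len(vals):
        warnings.warn(f"duplicate {name} values in grid; deduplicated",
                      RuntimeWarning)
    return unique


@dataclass(frozen=True)
class ParameterGrid:
    """Default grid: the ranges used on the full-size lung cohort."""

    b_values: tuple = (60, 70, 80, 90, 100, 110)
    p_values: tuple = (30, 40, 50, 60, 70, 80)
    eps_values: tuple = (600, 700, 800, 900, 1000)

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_values", _dedupe(self.b_values, "b"))
        object.__setattr__(self, "p_values", _dedupe(self.p_values, "p"))
        object.__setattr__(self, "eps_values", _dedupe(self.eps_values, "epsilon"))
        if not (self.b_values and self.p_values and self.eps_values):
            raise ValueError("grid axes must be nonempty")

    @property
    def size(self) -> int:
        return len(self.b_values) * len(self.p_values) * len(self.eps_values)


@dataclass(frozen=True)
class GSSEnsemble:
    """Long-format scores indexed by (subject_id, b, p, epsilon)."""

    table: pd.DataFrame  # columns: subject_id, b, p, epsilon, t, gss
    grid: ParameterGrid
    t_rule: str | float
    failed: tuple = field(default_factory=tuple)

    def scores_along(self, vary: str, fixed: dict) -> pd.DataFrame:
        """Subjects x varied-parameter-value score matrix."""
        axis = {"b": "b", "p": "p", "epsilon": "epsilon"}.get(vary)
        if axis is None:
            raise ValueError("vary must be one of b, p, epsilon")
        df = self.table
        for key, val in fixed.items():
            on_grid = getattr(self.grid, f"{'eps' if key == 'epsilon' else key}_values")
            if val not in on_grid:
                raise ValueError(f"fixed {key}={val} is not on the grid")
            df = df[np.isclose(df[key], val)]
        if df.empty:
            raise ValueError(f"no successful runs at fixed={fixed}")
        return df.pivot_table(index="subject_id", columns=axis, values="gss")


@dataclass(frozen=True)
class CIReport:
    """Per-subject mean and central empirical interval."""

    table: pd.DataFrame  # columns: mean, lower, upper (index subject_id)
    level: float
    vary: str
    fixed: dict

    @property
    def widths(self) -> pd.Series:
        return self.table["upper"] - self.table["lower"]


def sweep(
    score_matrix,
    labels,
    grid: ParameterGrid,
    subject_ids=None,
    t_rule: str | float = "auto",
    filter_kind: str = "mean_corr",
    linkage: str = "single",
    smoothing_alpha: float = 1.0,
    weight_rule: str = "tumor_fraction",
) -> GSSEnsemble:
    """Compute the GSS on every (b, p, epsilon) grid combination.

    The correlation filter is computed once and reused (it does not
    depend on the Mapper parameters). Combinations that fail are
    recorded with their error rather than silently dropped.
    """
    X = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if subject_ids is None and hasattr(score_matrix, "index"):
        subject_ids = list(score_matrix.index)
    filter_values = compute_filter(X, filter_kind, subject_ids)
    rows = []
    failed = []
    for b in grid.b_values:
        for p in grid.p_values:
            for eps in grid.eps_values:
                params = MapperParams(int(b), float(p), float(eps),
                                      filter_kind, linkage)
                try:
                    graph = build_mapper(X, params, subject_ids, filter_values)
                    gss = compute_gss(graph, labels, t_rule,
                                      smoothing_alpha, weight_rule)
                except Exception as exc:  # noqa: BLE001 — recorded, not dropped
                    failed.append((int(b), float(p), float(eps), str(exc)))
                    continue
                t_val = gss.t if isinstance(gss.t, float) else np.nan
                frame = gss.scores.reset_index()
                frame["b"], frame["p"], frame["epsilon"] = int(b), float(p), float(eps)
                frame["t"] = t_val
                rows.append(frame)
    if not rows:
        raise RuntimeError(f"all {grid.size} grid combinations failed: {failed[:3]}")
    table = pd.concat(rows, ignore_index=True)[
        ["subject_id", "b", "p", "epsilon", "t", "gss"]
    ]
    return GSSEnsemble(table, grid, t_rule, tuple(failed))


def empirical_ci(
    ensemble: GSSEnsemble,
    vary: str,
    fixed: dict,
    level: float = 0.95,
) -> CIReport:
    """Vary-one-fix-two empirical confidence intervals.

    Per subject, over the varied axis: the mean, and the empirical
    quantiles at (1-level)/2 and (1+level)/2 with linear interpolation
    between order statistics (so e.g. scores 1..100 at level 0.95 give
    the interval [3.475, 97.525]).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    wide = ensemble.scores_along(vary, fixed)
    if wide.shape[1] < 2:
        raise ValueError(
            f"need >= 2 grid points along {vary} at fixed={fixed}"
        )
    values = wide.to_numpy()
    lo_q, hi_q = (1 - level) / 2, (1 + level) / 2
    table = pd.DataFrame(
        {
            "mean": values.mean(axis=1),
            "lower": np.quantile(values, lo_q, axis=1, method="linear"),
            "upper": np.quantile(values, hi_q, axis=1, method="linear"),
        },
        index=wide.index,
    )
    return CIReport(table, level, vary, dict(fixed))
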