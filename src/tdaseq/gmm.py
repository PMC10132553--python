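"""Gaussian-mixture standardization of per-subject expression profiles.

Bulk RNA-seq log2(FPKM) values per subject are bimodal: a low-expression
mode and a high-expression mode. Each subject's profile is modelled as a
one-dimensional Gaussian mixture

    f(x) = sum_j c_j N(x; mu_j, sigma_j),

fitted by EM. The mixture supports four standardized scores. With
membership weights (responsibilities)

    omega_j(x) = c_j N(x; mu_j, sigma_j) / sum_k c_k N(x; mu_k, sigma_k)

and assignment estimates ``s~`` (soft: s~ = omega; hard: one-hot argmax),
the scores are

* T0 -- the z-score under the hard-assigned component; in simulations,
  where the true generating component is known, a three-branch corrected
  form is available that accounts for misassignment.
* T1 -- invert component variances first, then combine:
  ``(sum_j s~_j sigma_j^(-1/2)) (x - sum_j s~_j mu_j)``.
* T2 -- combine variances first, then invert:
  ``(sum_j s~_j sigma_j)^(-1/2) (x - sum_j s~_j mu_j)``.
* T3 -- total-variance standardizer, adding the between-component term
  ``(mu_j - mu_bar)^2`` to the T2 denominator.

Throughout this module ``sigma_j`` denotes component *variances*: that is
the convention under which T2 and T3 are genuine z-like standardizers
(T3's denominator is the law-of-total-variance form). Goodness of fit is
assessed with a two-sided Kolmogorov-Smirnov test of the empirical CDF
against the fitted mixture CDF, and Q-Q points against the standard
normal diagnose which score is closest to normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "ExpressionVector",
    "GMMFit",
    "AssignmentWeights",
    "GofReport",
    "log_transform",
    "fit_gmm",
    "mixture_pdf",
    "mixture_cdf",
    "membership_weights",
    "hard_assignment",
    "score_T1",
    "score_T2",
    "score_T3",
    "score_T0_observed",
    "score_T0_latent",
    "ks_goodness_of_fit",
    "qq_points",
    "qq_slope",
    "standardize",
    "compute_score_matrix",
]


@dataclass(frozen=True)
class ExpressionVector:
    """A single subject's log2-transformed expression values."""

    subject_id: str
    values: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("expression vector must be a nonempty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression vector contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class GMMFit:
    """A fitted 1-D Gaussian mixture; ``variances`` are variances, not SDs."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    converged: bool
    seed: int
    n_iter: int = 0
    ll_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        if not (len(w) == len(mu) == len(var) == self.n_components):
            raise ValueError("weights/means/variances length mismatch")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(w <= 0):
            raise ValueError("mixture weights must be positive")
        if np.any(var <= 0):
            raise ValueError("component variances must be positive")
        if np.any(np.diff(mu) < 0):
            raise ValueError("components must be sorted ascending by mean")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "variances", var)
        object.__setattr__(
            self, "ll_trajectory", np.asarray(self.ll_trajectory, dtype=float)
        )

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(self.variances)


@dataclass(frozen=True)
class AssignmentWeights:
    """Per-value component assignment estimates s~ (rows sum to one)."""

    mode: str  # "soft" | "hard"
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.mode not in ("soft", "hard"):
            raise ValueError(f"unknown assignment mode {self.mode!r}")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("assignment rows must sum to 1")
        if self.mode == "hard" and not np.all(np.isin(w, (0.0, 1.0))):
            raise ValueError("hard assignment rows must be one-hot")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class GofReport:
    ks_statistic: float
    p_value: float
    alpha: float
    reject: bool


def log_transform(
    fpkm, pseudo_count: float = 1.0, subject_id: str = "sample"
) -> ExpressionVector:
    """log2-transform an FPKM vector.

    With ``pseudo_count > 0`` returns ``log2(fpkm + pseudo_count)``; with
    ``pseudo_count == 0`` zero entries are dropped (count reported in
    ``n_dropped``).
    """
    fpkm = np.asarray(fpkm, dtype=float)
    if np.any(fpkm < 0):
        raise ValueError("FPKM values must be nonnegative")
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be nonnegative")
    if pseudo_count > 0:
        return ExpressionVector(subject_id, np.log2(fpkm + pseudo_count))
    keep = fpkm > 0
    if not np.any(keep):
        raise ValueError(
            f"subject {subject_id!r}: all FPKM values are zero and "
            "pseudo_count=0 leaves an empty vector"
        )
    return ExpressionVector(
        subject_id, np.log2(fpkm[keep]), n_dropped=int((~keep).sum())
    )


def _component_log_densities(fit: GMMFit, x: np.ndarray) -> np.ndarray:
    """log(c_j) + log N(x; mu_j, sigma_j) with shape (len(x), N)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.log(fit.weights) + stats.norm.logpdf(
        x[:, None], fit.means[None, :], fit.sds[None, :]
    )


def _loglik(x, weights, means, variances) -> float:
    log_dens = np.log(weights) + stats.norm.logpdf(
        x[:, None], means[None, :], np.sqrt(variances)[None, :]
    )
    return float(logsumexp(log_dens, axis=1).sum())


def fit_gmm(
    x,
    n_components: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = 1e-6,
) -> GMMFit:
    """Maximum-likelihood EM fit of an ``n_components`` Gaussian mixture.

    Initialization is k-means++ on the data driven by ``seed``;
    convergence is declared when the relative log-likelihood change drops
    below ``tol``. Components are returned sorted ascending by mean. A
    non-converged fit is returned with ``converged=False`` and a warning.
    """
    data = x.values if isinstance(x, ExpressionVector) else np.asarray(x, float)
    data = np.atleast_1d(data.astype(float))
    n = data.size
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} observations to fit "
            f"{n_components} components, got {n}"
        )
    svar = float(np.var(data))
    if svar <= var_floor:
        raise ValueError("variance collapse: input vector is (nearly) constant")

    if n_components == 1:
        mu, var = float(np.mean(data)), svar
        ll = _loglik(data, np.ones(1), np.array([mu]), np.array([var]))
        return GMMFit(1, np.ones(1), np.array([mu]), np.array([var]), ll,
                      True, seed, 0, np.array([ll]))

    centers, _ = kmeans_plusplus(
        data[:, None], n_clusters=n_components, random_state=seed
    )
    means = np.sort(centers.ravel())
    variances = np.full(n_components, svar)
    weights = np.full(n_components, 1.0 / n_components)

    trajectory = []
    converged = False
    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E step (log-space responsibilities)
        log_dens = np.log(weights) + stats.norm.logpdf(
            data[:, None], means[None, :], np.sqrt(variances)[None, :]
        )
        log_norm = logsumexp(log_dens, axis=1)
        ll = float(log_norm.sum())
        trajectory.append(ll)
        resp = np.exp(log_dens - log_norm[:, None])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * data[:, None]).sum(axis=0) / nk
        variances = (resp * (data[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)

    order = np.argsort(means)
    weights, means, variances = weights[order], means[order], variances[order]
    ll = _loglik(data, weights, means, variances)
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", RuntimeWarning
        )
    return GMMFit(
        n_components, weights, means, variances, ll, converged, seed, it,
        np.asarray(trajectory),
    )


def mixture_pdf(fit: GMMFit, x) -> np.ndarray | float:
    """Mixture density sum_j c_j N(x; mu_j, sigma_j)."""
    scalar = np.isscalar(x)
    out = np.exp(logsumexp(_component_log_densities(fit, x), axis=1))
    return float(out[0]) if scalar else out


def mixture_cdf(fit: GMMFit, x) -> np.ndarray | float:
    """Mixture CDF sum_j c_j Phi((x - mu_j) / sqrt(sigma_j))."""
    scalar = np.isscalar(x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    out = (
        fit.weights[None, :]
        * stats.norm.cdf(xv[:, None], fit.means[None, :], fit.sds[None, :])
    ).sum(axis=1)
    return float(out[0]) if scalar else out


def membership_weights(fit: GMMFit, x) -> AssignmentWeights:
    """Posterior responsibilities omega_j(x), computed in log-space."""
    log_dens = _component_log_densities(fit, x)
    omega = np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])
    return AssignmentWeights("soft", omega)


def hard_assignment(soft: AssignmentWeights) -> AssignmentWeights:
    """One-hot argmax of the responsibilities; ties go to the lower-mean
    component (components are mean-sorted, argmax returns the first)."""
    idx = np.argmax(soft.weights, axis=1)
    hard = np.zeros_like(soft.weights)
    hard[np.arange(len(idx)), idx] = 1.0
    return AssignmentWeights("hard", hard)


def _prepare_scores(fit: GMMFit, x, stilde: AssignmentWeights):
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    s = stilde.weights
    if s.shape != (xv.size, fit.n_components):
        raise ValueError("assignment shape does not match x / fit")
    mu_bar = s @ fit.means
    return xv, s, mu_bar


def score_T1(fit: GMMFit, x, stilde: AssignmentWeights) -> np.ndarray:
    """T1: invert the variances first, then combine with s~."""
    xv, s, mu_bar = _prepare_scores(fit, x, stilde)
    return (s @ (fit.variances ** -0.5)) * (xv - mu_bar)


def score_T2(fit: GMMFit, x, stilde: AssignmentWeights) -> np.ndarray:
    """T2: combine the variances with s~, then invert."""
    xv, s, mu_bar = _prepare_scores(fit, x, stilde)
    return (s @ fit.variances) ** -0.5 * (xv - mu_bar)


def score_T3(fit: GMMFit, x, stilde: AssignmentWeights) -> np.ndarray:
    """T3: total-variance standardizer (within + between component)."""
    xv, s, mu_bar = _prepare_scores(fit, x, stilde)
    total_var = (
        s * (fit.variances[None, :] + (fit.means[None, :] - mu_bar[:, None]) ** 2)
    ).sum(axis=1)
    return total_var ** -0.5 * (xv - mu_bar)


def score_T0_observed(fit: GMMFit, x) -> np.ndarray:
    """T0 on observed data: z-score under the hard-assigned component."""
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    hard = hard_assignment(membership_weights(fit, xv))
    j = np.argmax(hard.weights, axis=1)
    return (xv - fit.means[j]) / fit.sds[j]


def score_T0_latent(
    fit: GMMFit,
    x,
    true_component,
    tau: float | None = None,
    delta: float | None = None,
) -> np.ndarray:
    """Three-branch T0 for simulations where the generating component is
    known.

    With Z the z-score under the true component, the score is Z when the
    hard assignment agrees with the truth, ``tau^-1 Z - delta`` when the
    value is assigned to the low-mean component but came from the high
    one, and ``tau Z + tau delta`` in the converse case. Defaults (both
    overridable): ``tau = sqrt(sigma_1/sigma_2)`` (SD ratio) and
    ``delta = (mu_1 - mu_2)/sqrt(sigma_2)``.
    """
    if fit.n_components != 2:
        raise ValueError("latent T0 is defined for two-component mixtures only")
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    true = np.broadcast_to(np.asarray(true_component, dtype=int), xv.shape)
    if np.any((true < 0) | (true > 1)):
        raise ValueError("true_component must be 0 (low mean) or 1 (high mean)")
    if tau is None:
        tau = float(np.sqrt(fit.variances[0] / fit.variances[1]))
    if delta is None:
        delta = float((fit.means[0] - fit.means[1]) / fit.sds[1])
    z = (xv - fit.means[true]) / fit.sds[true]
    assigned = np.argmax(
        hard_assignment(membership_weights(fit, xv)).weights, axis=1
    )
    out = z.copy()
    low_but_high = (assigned == 0) & (true == 1)  # s~1 > s1
    high_but_low = (assigned == 1) & (true == 0)  # s~1 < s1
    out[low_but_high] = z[low_but_high] / tau - delta
    out[high_but_low] = tau * z[high_but_low] + tau * delta
    return out


def standardize(
    fit: GMMFit, x, kind: str = "T0", mode: str = "hard"
) -> np.ndarray:
    """Compute one of the T0-T3 score vectors for ``x`` under ``fit``."""
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if kind == "T0":
        return score_T0_observed(fit, xv)
    soft = membership_weights(fit, xv)
    stilde = soft if mode == "soft" else hard_assignment(soft)
    fn = {"T1": score_T1, "T2": score_T2, "T3": score_T3}.get(kind)
    if fn is None:
        raise ValueError(f"unknown score kind {kind!r}")
    return fn(fit, xv, stilde)


def ks_goodness_of_fit(x, fit: GMMFit, alpha: float = 0.01) -> GofReport:
    """Two-sided KS test of the data against the fitted mixture CDF.

    The null hypothesis is that the values follow the fitted mixture; the
    p-value comes from the asymptotic KS distribution. The mixture
    parameters are estimated from the same data, which makes the test
    anti-conservative (no Lilliefors-style correction is applied).
    """
    data = x.values if isinstance(x, ExpressionVector) else np.asarray(x, float)
    data = np.atleast_1d(data)
    if data.size < 1:
        raise ValueError("insufficient data for a KS test")
    res = stats.kstest(
        data, lambda v: mixture_cdf(fit, v), alternative="two-sided",
        method="asymp",
    )
    d, p = float(res.statistic), float(res.pvalue)
    return GofReport(d, p, alpha, p < alpha)


def qq_points(scores) -> tuple[np.ndarray, np.ndarray]:
    """Q-Q points against the standard normal.

    Returns ``(theoretical, empirical)`` with the i-th theoretical
    quantile at plotting position (i - 0.5)/n and the empirical quantiles
    the order statistics.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size < 2 or not np.all(np.isfinite(s)):
        raise ValueError("need at least 2 finite scores for Q-Q points")
    n = s.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, s


def qq_slope(scores) -> float:
    """Least-squares slope of the Q-Q point cloud (1 means normal scale)."""
    theo, emp = qq_points(scores)
    return float(np.polyfit(theo, emp, 1)[0])


def compute_score_matrix(
    fpkm: pd.DataFrame,
    kind: str = "T0",
    mode: str = "hard",
    n_components: int = 2,
    pseudo_count: float = 1.0,
    seed: int = 0,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, GMMFit], pd.DataFrame]:
    """Fit a mixture per subject and standardize every profile.

    ``fpkm`` is genes x subjects. Returns the subjects x genes score
    matrix, the per-subject fits, and a goodness-of-fit table
    (subject_id, D, p_value, reject).
    """
    if pseudo_count <= 0 and bool((fpkm.to_numpy() <= 0).any()):
        raise ValueError(
            "matrix standardization with pseudo_count=0 would drop zero "
            "entries and break gene alignment across subjects; use a "
            "positive pseudo_count"
        )
    scores = {}
    fits: dict[str, GMMFit] = {}
    gof_rows = []
    for sid in fpkm.columns:
        vec = log_transform(fpkm[sid].to_numpy(), pseudo_count, subject_id=str(sid))
        fit = fit_gmm(vec, n_components=n_components, seed=seed)
        fits[str(sid)] = fit
        scores[str(sid)] = standardize(fit, vec.values, kind=kind, mode=mode)
        rep = ks_goodness_of_fit(vec, fit, alpha=alpha)
        gof_rows.append(
            {"subject_id": str(sid), "D": rep.ks_statistic,
             "p_value": rep.p_value, "reject": rep.reject}
        )
    score_df = pd.DataFrame.from_dict(scores, orient="index")
    score_df.columns = list(fpkm.index)
    score_df.index.name = "subject_id"
    return score_df, fits, pd.DataFrame(gof_rows)
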