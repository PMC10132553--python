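"""Seeded synthetic RNA-seq cohorts with the structure the pipeline assumes.

The generator produces a strictly positive FPKM matrix whose per-subject
marginal log2(FPKM) distribution is approximately a two-component Gaussian
mixture (a low- and a high-expression gene mode), and whose subjects lie
along a one-dimensional latent axis ``u``: a healthy core near u = 0 and
two tumor subpopulations (arms A and B) near u = -1 and u = +1. A seeded
subset of "effect" genes shifts linearly in u, with opposite signs on two
disjoint halves of the subset, so the two arms dysregulate expression in
opposite directions.

The two arms are given unequal sizes by default. That asymmetry is what
lets the mean-correlation Mapper filter order the cohort as
arm A < healthy < arm B: with a linear-in-u effect model the covariance
between two subjects' profiles contains a ``u_s * u_s'`` term, so the
*mean* correlation of subject s against the cohort is increasing in
``u_s * mean(u)`` — only a nonzero cohort-mean latent coordinate (unequal
arms) can place the two tumor arms on opposite ends of the filter, which
is the strand-with-tumor-ends geometry the pipeline targets. The
generator deliberately omits library-size effects and count-level noise;
it emulates the statistical shape the pipeline consumes, not sequencing
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "suggest_epsilon",
    "epsilon_grid",
]

#: SD of the latent coordinate u within the healthy core (centered at 0)
#: and within each tumor arm (centered at -1 / +1). The healthy spread is
#: broader so the filter values bridge the arm-to-core transitions and the
#: Mapper strand stays connected.
LATENT_JITTER_CENTER = 0.25
LATENT_JITTER_ARMS = 0.15


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    Defaults give a 400-subject cohort (120 healthy, 40 arm-A, 240 arm-B
    tumors) with 4000 genes of which 800 respond to the latent axis. The
    mixture means/SDs are the fitted values reported for a healthy lung
    profile (low mode ~3.1, high mode ~8.9 on the log2 scale).
    """

    n_healthy: int = 120
    n_tumor_A: int = 40
    n_tumor_B: int = 240
    n_genes: int = 4000
    mixture_means: tuple[float, float] = (3.12, 8.87)
    mixture_sds: tuple[float, float] = (2.61, 2.11)
    low_fraction: float = 0.4
    arm_effect_size: float = 3.0
    n_effect_genes: int = 800
    noise_sd: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_tumor_A", "n_tumor_B", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.low_fraction < 1:
            raise ValueError("low_fraction must be in (0, 1)")
        if min(self.mixture_sds) <= 0:
            raise ValueError("mixture_sds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_effect_genes > self.n_genes:
            raise ValueError("n_effect_genes cannot exceed n_genes")

    @property
    def n_subjects(self) -> int:
        return self.n_healthy + self.n_tumor_A + self.n_tumor_B


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: FPKM matrix (genes x subjects) plus truth."""

    fpkm: pd.DataFrame
    labels: pd.Series  # subject -> {healthy, tumor}
    arms: pd.Series  # subject -> {center, A, B}
    u: pd.Series  # latent coordinate per subject
    config: CohortConfig
    effect_genes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def subject_ids(self) -> list[str]:
        return list(self.fpkm.columns)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a seeded cohort; fully deterministic given ``config.seed``.

    Construction: (1) each gene draws a baseline log2-expression from the
    two-component mixture (a ``low_fraction`` share in the low mode),
    shared by all subjects — this is what makes subjects correlated and
    every subject's marginal approximately the mixture; (2) subjects get
    latent ``u`` (healthy ~ N(0, 0.25), arm A ~ N(-1, 0.15), arm B ~
    N(+1, 0.15)); (3) ``n_effect_genes`` genes shift by
    ``arm_effect_size * u``, with opposite signs on two disjoint halves;
    (4) i.i.d. Gaussian noise with SD ``noise_sd`` is added; (5) FPKM =
    2^logexpr.

    FPKM values are strictly positive (log-normal-mixture expression),
    so ``log2(fpkm)`` recovers the generating log-expression exactly and
    each subject's marginal log-expression is the two-component mixture
    the pipeline assumes (plus the effect-gene shifts). Zero-inflation
    is a real-data feature this generator deliberately omits.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    G, n = cfg.n_genes, cfg.n_subjects

    low = rng.random(G) < cfg.low_fraction
    mu = np.where(low, cfg.mixture_means[0], cfg.mixture_means[1])
    sd = np.where(low, cfg.mixture_sds[0], cfg.mixture_sds[1])
    baseline = rng.normal(mu, sd)

    u = np.concatenate(
        [
            rng.normal(0.0, LATENT_JITTER_CENTER, cfg.n_healthy),
            rng.normal(-1.0, LATENT_JITTER_ARMS, cfg.n_tumor_A),
            rng.normal(+1.0, LATENT_JITTER_ARMS, cfg.n_tumor_B),
        ]
    )
    arms = np.array(
        ["center"] * cfg.n_healthy + ["A"] * cfg.n_tumor_A + ["B"] * cfg.n_tumor_B
    )
    labels = np.where(arms == "center", "healthy", "tumor")

    effect_genes = rng.choice(G, size=cfg.n_effect_genes, replace=False)
    signs = np.zeros(G)
    half = cfg.n_effect_genes // 2
    signs[effect_genes[:half]] = +1.0
    signs[effect_genes[half:]] = -1.0

    logexpr = (
        baseline[:, None]
        + cfg.arm_effect_size * signs[:, None] * u[None, :]
        + rng.normal(0.0, cfg.noise_sd, (G, n))
    )
    fpkm_values = 2.0 ** logexpr

    width = len(str(n))
    subject_ids = [
        f"{arm}-{i:0{width}d}" for i, arm in enumerate(arms)
    ]
    gene_ids = [f"gene{g:05d}" for g in range(G)]
    fpkm = pd.DataFrame(fpkm_values, index=gene_ids, columns=subject_ids)
    idx = pd.Index(subject_ids, name="subject_id")
    return SyntheticCohort(
        fpkm=fpkm,
        labels=pd.Series(labels, index=idx, name="label"),
        arms=pd.Series(arms, index=idx, name="arm"),
        u=pd.Series(u, index=idx, name="u"),
        config=cfg,
        effect_genes=np.sort(effect_genes),
    )


def suggest_epsilon(
    score_matrix, factor: float = 1.5, max_subjects: int = 500, seed: int = 0
) -> float:
    """Clustering scale for Mapper on this cohort's score matrix.

    Returns ``factor`` times the median pairwise Euclidean distance
    between subject score vectors. The median pairwise distance tracks
    the within-neighborhood spread; scaling it up guarantees that
    subjects sharing a cover bin (hence similar filter values) merge into
    one node unless they are genuinely far apart in score space.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.shape[0] > max_subjects:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_subjects, replace=False)]
    return factor * float(np.median(pdist(X)))


def epsilon_grid(eps_star: float, n: int = 5) -> np.ndarray:
    """A sweep grid around ``eps_star`` spanning 0.75x to 1.25x.

    Mirrors the relative spread of the scale-parameter range used on the
    full-size cohort (600..1000 around a working value of 800).
    """
    return eps_star * np.linspace(0.75, 1.25, n)
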