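import numpy as np
import pytest

from tdaseq import gmm, mapper, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 100-subject cohort for unit tests."""
    cfg = synthetic.CohortConfig(
        n_healthy=30, n_tumor_A=10, n_tumor_B=60,
        n_genes=300, n_effect_genes=60, seed=7,
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    scores, fits, gof = gmm.compute_score_matrix(
        small_cohort.fpkm, kind="T0", seed=1, pseudo_count=0.0
    )
    return scores, fits, gof


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic cohort scored end to end (shared: expensive)."""
    cohort = synthetic.generate_cohort()
    scores, fits, gof = gmm.compute_score_matrix(
        cohort.fpkm, kind="T0", seed=1, pseudo_count=0.0
    )
    X = scores.to_numpy()
    filt = mapper.compute_filter(X, "mean_corr")
    eps_star = synthetic.suggest_epsilon(X)
    return {
        "cohort": cohort, "scores": scores, "fits": fits, "gof": gof,
        "X": X, "filter": filt, "eps_star": eps_star,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
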