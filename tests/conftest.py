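import numpy as np
import pytest

from ummdr import CovariateMatrix, GenotypeMatrix, SurvivalData


@pytest.fixture
def six_subjects():
    """Six subjects, one binary covariate, distinct times, mixed censoring.

    Small enough for brute-force maximization of the partial likelihood.
    """
    surv = SurvivalData(
        time=np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0]),
        status=np.array([1, 1, 0, 1, 1, 0]),
    )
    x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
    return surv, x


@pytest.fixture
def eight_subjects_split():
    """Eight subjects where S mostly (not perfectly) marks the early events.

    Perfect separation would push the partial-likelihood maximizer to
    infinity, so the groups are interleaved once to keep the MLE finite.
    """
    surv = SurvivalData(
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]),
        status=np.array([1, 1, 1, 1, 1, 0, 1, 1]),
    )
    S = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
    return surv, S


@pytest.fixture
def toy_dataset():
    """n=40, p=5 deterministic dataset with a planted pair (0, 1)."""
    rng = np.random.default_rng(42)
    G = GenotypeMatrix(rng.integers(0, 3, size=(40, 5)))
    # the planted pair acts through an XOR-like cell pattern
    risk = ((G.values[:, 0] > 0) ^ (G.values[:, 1] > 0)).astype(float)
    z = rng.standard_normal(40)
    t = rng.exponential(np.exp(-1.5 * risk - 0.3 * z))
    status = (rng.uniform(size=40) < 0.8).astype(int)
    surv = SurvivalData(t + 1e-3, status)
    Z = CovariateMatrix(z[:, None], ["z"])
    return G, surv, Z
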