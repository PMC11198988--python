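import numpy as np
import pytest

from connmanifold.manifold import align, build_affinity, build_template, embed
from connmanifold.spd import CovarianceSet, center_set, shrinkage_covariance
from connmanifold.synth import SyntheticStudyConfig, make_study


def random_spd(rng: np.random.Generator, n: int) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((n, n))
    return A @ A.T / n + np.eye(n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A desk-scale synthetic study shared across tests: 8 subjects, 42 regions."""
    cfg = SyntheticStudyConfig(
        n_subjects=8, n_regions=42, volumes_per_epoch=120, seed=0
    )
    return make_study(cfg)


@pytest.fixture(scope="session")
def centered_small_study(small_study):
    """Ledoit-Wolf covariances of the small study, centered at the grand mean."""
    covs = [[shrinkage_covariance(ts) for ts in row] for row in small_study.timeseries]
    return center_set(CovarianceSet(matrices=covs))


@pytest.fixture(scope="session")
def small_template(centered_small_study):
    cs = centered_small_study
    return build_template([cs.centered[i][0] for i in range(cs.n_subjects)])


@pytest.fixture(scope="session")
def small_eccentricity(centered_small_study, small_template):
    """Aligned per-subject/epoch eccentricity array (subjects x epochs x regions)."""
    cs = centered_small_study
    n_sub, n_epochs = cs.n_subjects, cs.n_epochs
    R = len(cs.region_ids)
    ecc = np.empty((n_sub, n_epochs, R))
    for i in range(n_sub):
        for j in range(n_epochs):
            emb = align(embed(build_affinity(cs.centered[i][j]), 3), small_template)
            ecc[i, j] = np.linalg.norm(emb.coords, axis=1)
    return ecc
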