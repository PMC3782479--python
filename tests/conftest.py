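import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from disotree import FamilyConfig, generate_family, map_scores_to_alignment


@pytest.fixture(scope="session")
def default_family():
    """The default 3-clade synthetic family (fixed seed)."""
    return generate_family(FamilyConfig(seed=11))


@pytest.fixture(scope="session")
def default_matrix(default_family):
    return map_scores_to_alignment(
        default_family.alignment, default_family.profiles
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_gapped_matrix(rng, n=5, length=40, gap_rate=0.2):
    """A random aligned disorder matrix with NaN gaps, every pair overlapping."""
    from disotree.seqio import AlignedDisorderMatrix

    while True:
        values = rng.random((n, length))
        mask = rng.random((n, length)) < gap_rate
        mask[:, 0] = False  # guarantee a shared column
        values[mask] = np.nan
        return AlignedDisorderMatrix([f"P{i}" for i in range(n)], values)


def random_dendrogram(rng, n_leaves=10):
    """A random binary dendrogram by clustering random points."""
    from disotree.distree import DistanceMatrix, cluster

    pts = rng.random((n_leaves, 6))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    ids = [f"L{i:02d}" for i in range(n_leaves)]
    return cluster(DistanceMatrix(ids, (d + d.T) / 2))
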