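import numpy as np
import pandas as pd
import pytest

from lesioncast.atlas import RegionAtlas, build_distance_matrix, default_atlas


@pytest.fixture(scope="session")
def unit_square_atlas() -> RegionAtlas:
    """Four regions at the corners of a unit square (z = 0).

    The six pairwise distances are four sides (1) and two diagonals (sqrt 2),
    so after min-max normalization sides map to 0 and diagonals to 1.
    """
    return RegionAtlas(
        region_ids=np.array([1, 2, 3, 4]),
        names=("a", "b", "c", "d"),
        centroids=np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]]
        ),
        level2_parent=("west", "east", "west", "east"),
        level1_parent=("all", "all", "all", "all"),
    )


@pytest.fixture(scope="session")
def bundled_atlas() -> RegionAtlas:
    return default_atlas()


@pytest.fixture(scope="session")
def bundled_dist(bundled_atlas):
    return build_distance_matrix(bundled_atlas)


def random_atlas(n_regions: int, seed: int) -> RegionAtlas:
    rng = np.random.default_rng(seed)
    return RegionAtlas(
        region_ids=np.arange(1, n_regions + 1),
        names=tuple(f"r{i}" for i in range(n_regions)),
        centroids=rng.uniform(0, 10, size=(n_regions, 3)),
        level2_parent=tuple("lobe" for _ in range(n_regions)),
        level1_parent=tuple("hemi" for _ in range(n_regions)),
    )


@pytest.fixture(scope="session")
def logistic_cohort():
    """n=100, 20 features, binary outcome from a known logistic model."""
    rng = np.random.default_rng(11)
    n, p = 100, 20
    x = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    beta = np.zeros(p)
    beta[:3] = [2.0, -2.0, 1.5]
    lin = x.to_numpy() @ beta - 1.0
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(int)
    return x, y, beta
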