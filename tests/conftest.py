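import numpy as np
import pytest

from histomarkers import synthetic
from histomarkers.detection import DetectionConfig, VotingScale

# configuration matched to the generator's 8-12 px nuclei
NUCLEI_CONFIG = DetectionConfig(scales=(VotingScale(4, 8), VotingScale(8, 16)))


@pytest.fixture(scope="session")
def single_disk():
    """One isolated low-noise disk of radius 12 on a bright background."""
    spec = synthetic.SyntheticImageSpec(
        width=96, height=96, n_cells=1, radius_range=(12, 12),
        eccentricity_range=(1.0, 1.0), texture_amplitude=10, noise_sd=2,
        rng_seed=3)
    return synthetic.synth_cell_image(spec)


@pytest.fixture(scope="session")
def touching_pair():
    """Two equal disks forced to touch (centers 1.5 r apart)."""
    spec = synthetic.SyntheticImageSpec(
        width=96, height=96, n_cells=2, radius_range=(10, 10),
        eccentricity_range=(1.0, 1.0), texture_amplitude=10, noise_sd=2,
        rng_seed=5)
    return synthetic.synth_cell_image(spec, forced_centers=[(40, 48), (55, 48)])


@pytest.fixture(scope="session")
def separated_tile():
    """Twenty nuclei with center spacing at least twice the largest radius."""
    spec = synthetic.SyntheticImageSpec(
        n_cells=20, rng_seed=7, min_center_distance=24.0)
    return synthetic.synth_cell_image(spec)


@pytest.fixture(scope="session")
def strong_survival_cohort():
    spec = synthetic.SyntheticSurvivalSpec(
        n=200, p=50, true_beta=(0.7, -0.7, 0.7, -0.7, 0.7),
        censor_rate=0.3, rng_seed=11)
    return synthetic.synth_survival_cohort(spec)
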