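import numpy as np
import pytest

from silfat import phantom as ph


COARSE = (6.0, 6.0, 6.0)  # mm; desk-scale voxel pitch used throughout the suite


@pytest.fixture(scope="session")
def male_params():
    return ph.PhantomParams(sex="male", height_mm=1763.0)


@pytest.fixture(scope="session")
def male_phantom(male_params):
    return ph.generate_phantom(male_params, spacing=COARSE, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """30 phantoms with volumes retained (coarse grid)."""
    cfg = ph.PopulationConfig(spacing_mm=COARSE)
    vols, table = ph.generate_cohort(30, cfg, seed=5)
    return vols, table


@pytest.fixture(scope="session")
def analytic_20k():
    """One large closed-form cohort table reused by epidemiology tests."""
    return ph.analytic_cohort_table(20000, seed=99)
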