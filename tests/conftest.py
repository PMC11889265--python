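import numpy as np
import pandas as pd
import pytest

from cedose.synthetic import PhantomSpec, SurvivalSimParams, simulate_outcomes


@pytest.fixture
def sphere_spec():
    """1 mL spherical tumor (r = 6.2 mm) on a 1 mm grid, catheter at center."""
    return PhantomSpec(
        grid_shape=(17, 17, 17),
        voxel_size_mm=(1.0, 1.0, 1.0),
        tumor_center=(8.0, 8.0, 8.0),
        tumor_radii_mm=(6.2, 6.2, 6.2),
        catheter_tips=((8.0, 8.0, 8.0),),
        kernel_sigma_mm=4.0,
        background_fraction=0.0,
    )


def make_aft_design(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate design for survival-simulation recovery tests: spreads
    coverage/dose/age/ECOG/volume over study-like ranges."""
    return pd.DataFrame(
        {
            "tvt_percent": rng.uniform(5, 100, n),
            "absorbed_dose_Gy": rng.uniform(5, 400, n),
            "age_y": rng.uniform(35, 70, n),
            "ecog": rng.integers(0, 3, n),
            "baseline_tumor_mL": rng.uniform(1, 23, n),
        }
    )


@pytest.fixture
def simulated_records():
    """A 120-patient simulated outcome table for analysis-path tests."""
    rng = np.random.default_rng(42)
    design = make_aft_design(120, rng)
    return simulate_outcomes(design, SurvivalSimParams(seed=7))
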