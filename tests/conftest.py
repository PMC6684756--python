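import numpy as np
import pandas as pd
import pytest

from xerograd import CohortSimConfig, PhantomSpec, simulate_cohort, to_model_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom: 40 Gy plateau, 5 mm sigmoid falloff, ellipsoidal gland."""
    return PhantomSpec(
        grid_shape=(101, 15, 15),
        spacing_mm=(1.0, 2.0, 2.0),
        plateau_dose_gy=40.0,
        falloff_center_mm=50.0,
        falloff_scale_mm=5.0,
        gland_center_mm=(30.0, 14.0, 14.0),
        gland_radii_mm=(10.0, 10.0, 10.0),
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """One default synthetic cohort (n=88) in the modelling layout."""
    sim = simulate_cohort(CohortSimConfig(seed=20240521))
    return to_model_table(sim.cohort)


def random_cohort(rng, n=40, n_features=("md", "gradx", "pgm"), p_pos=0.3):
    """Featureless-of-structure random cohort for oracle equivalence tests."""
    cols = {"patient_id": [f"R{i}" for i in range(n)]}
    for name, col in (("md", "md_gy"), ("gradx", "gradx_gy_per_mm"), ("pgm", "pgm_mm")):
        if name in n_features:
            cols[col] = rng.normal(size=n)
    while True:
        labels = (rng.random(n) < p_pos).astype(int)
        if 0 < labels.sum() < n:
            break
    cols["label"] = labels
    return pd.DataFrame(cols)
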