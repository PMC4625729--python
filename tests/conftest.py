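import numpy as np
import pandas as pd
import pytest

from ilaquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_64():
    """A 64^3 noiseless phantom with 10% GGO and 5% emphysema."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64), ggo_fraction=0.10, emph_fraction=0.05,
        vessel_fraction=0.02, noise_sd=0.0, seed=3,
    )
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


def make_cohort(rows) -> pd.DataFrame:
    """Hand-built cohort table with neutral covariates."""
    n = len(rows)
    df = pd.DataFrame(rows, columns=["haa_pct", "visual_status"])
    df.insert(0, "subject_id", [f"T{i:03d}" for i in range(n)])
    df["emph_pct"] = 2.0
    df["tlc_ml"] = 5500.0
    df["age"] = 60.0
    df["sex"] = "male"
    df["race"] = "white"
    df["bmi"] = 28.0
    df["pack_years"] = 30.0
    df["current_smoker"] = False
    df["genotype"] = 0
    return df


@pytest.fixture
def toy_cohort():
    """Eight subjects spanning all three visual levels around a 10% cut."""
    return make_cohort(
        [
            (12.0, "ila"),
            (11.0, "ila"),
            (4.0, "ila"),
            (13.0, "no_ila"),
            (3.0, "no_ila"),
            (2.5, "no_ila"),
            (7.0, "indeterminate"),
            (6.0, "indeterminate"),
        ]
    )
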