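import numpy as np
import pandas as pd
import pytest

from lipidtraj.simulate import (CohortConfig, GroupSpec, LipidSpec,
                                generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort, small enough for fast unit tests."""
    return generate_cohort(CohortConfig(n_subjects=250, seed=123))


@pytest.fixture(scope="session")
def three_group_hdl_cohort():
    """Three well-separated flat HDL-C groups (40/55/85 mg/dl, sigma 4)."""
    cfg = CohortConfig(
        n_subjects=400, seed=7,
        lipids={"hdl": LipidSpec(
            groups=[GroupSpec(0.45, (40.0,)), GroupSpec(0.40, (55.0,)),
                    GroupSpec(0.15, (85.0,))],
            resid_sd=4.0, subject_sd=0.0, vim_exponent=0.0, sd_spread=0.1)})
    cfg.outcome.coefficients = {"hdl_group1": 1.0, "hdl_group2": 1.3, "age_c": 0.05}
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def hdl_series(cohort) -> pd.DataFrame:
    return cohort.measurements.query("lipid == 'hdl'")[
        ["subject_id", "rel_year", "value", "on_med"]].reset_index(drop=True)
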