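import numpy as np
import pandas as pd
import pytest

from rvometals.cohort import build_analysis_cohort
from rvometals.simulate import CohortSimConfig, simulate_cohort

NULL_COVARIATES = {
    "age": 0.0,
    "sex": 0.0,
    "bmi": 0.0,
    "smoking": 0.0,
    "hypertension": 0.0,
    "diabetes": 0.0,
    "hyperlipidemia": 0.0,
}


@pytest.fixture(scope="session")
def sim_cohort():
    """A default-condition simulated cohort (with missingness) and its truth."""
    raw, truth = simulate_cohort(CohortSimConfig(n_participants=20000, seed=7))
    cohort, flow = build_analysis_cohort(raw)
    return {"raw": raw, "truth": truth, "cohort": cohort, "flow": flow}


@pytest.fixture(scope="session")
def lead_effect_cohort():
    """A complete-data cohort with a strong lead effect and null covariates."""
    cfg = CohortSimConfig(
        n_participants=50000,
        seed=11,
        beta_log10_pb=1.2,
        outcome_prevalence_target=0.02,
        covariate_effects=NULL_COVARIATES,
        missing_rates={},
    )
    raw, truth = simulate_cohort(cfg)
    cohort, _ = build_analysis_cohort(raw)
    return cohort


def make_raw_row(**overrides) -> dict:
    """A complete, unremarkable raw participant record; override per test."""
    row = {
        "SEQN": 1,
        "RIDAGEYR": 55.0,
        "RIAGENDR": 2.0,
        "BMXBMI": 27.0,
        "SMQ020": 2.0,
        "SMQ040": np.nan,
        "BPXSY1": 120.0,
        "BPXSY2": 118.0,
        "BPXSY3": 122.0,
        "BPXDI1": 76.0,
        "BPXDI2": 78.0,
        "BPXDI3": 74.0,
        "BPQ020": 2.0,
        "BPQ040A": 2.0,
        "BPQ050": 2.0,
        "BPQ080": 2.0,
        "BPQ090D": 2.0,
        "RX_ANTIHTN": 0.0,
        "RX_ANTIDM": 0.0,
        "RX_LIPID": 0.0,
        "DIQ010": 2.0,
        "DIQ050": 2.0,
        "DIQ070": 2.0,
        "LBXGH": 5.4,
        "LBDLDL": 110.0,
        "LBXTC": 180.0,
        "LBXTR": 120.0,
        "OPDDBVO": 1.0,
        "OPDDCVO": 1.0,
        "OPDSBVO": 1.0,
        "OPDSCVO": 1.0,
        "LBXBPB": 0.10,
        "LBXBCD": 5.0,
        "LBXTHG": 8.0,
    }
    row.update(overrides)
    return row


def raw_frame(*rows) -> pd.DataFrame:
    return pd.DataFrame([make_raw_row(**r) for r in rows])
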