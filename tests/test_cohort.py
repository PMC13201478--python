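"""Cohort derivation: RVO coding, covariate algorithms, inclusion flow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvometals.cohort import (
    FlowCounts,
    LODPolicy,
    build_analysis_cohort,
    derive_diabetes,
    derive_hyperlipidemia,
    derive_hypertension,
    derive_rvo,
    derive_smoking,
)

from .conftest import raw_frame


class TestDeriveRVO:
    @pytest.mark.parametrize(
        "codes, status, subtype",
        [
            # right-eye branch occlusion alone
            ({"OPDDBVO": 2}, "case", "BRVO"),
            # central code present -> CRVO even with a branch code positive
            ({"OPDDCVO": 2, "OPDSBVO": 2}, "case", "CRVO"),
            ({"OPDSCVO": 3}, "case", "CRVO"),
            ({}, "control", "none"),
        ],
    )
    def test_coding_rules(self, codes, status, subtype):
        out = derive_rvo(raw_frame(codes))
        assert out.loc[0, "rvo_status"] == status
        assert out.loc[0, "rvo_subtype"] == subtype

    def test_all_codes_absent_is_missing(self):
        out = derive_rvo(
            raw_frame(
                {c: np.nan for c in ("OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO")}
            )
        )
        assert pd.isna(out.loc[0, "rvo_status"])

    def test_partial_missing_without_positive_is_missing(self):
        out = derive_rvo(raw_frame({"OPDSCVO": np.nan}))
        assert pd.isna(out.loc[0, "rvo_status"])

    def test_positive_code_overrides_missing(self):
        out = derive_rvo(raw_frame({"OPDDBVO": 2, "OPDSCVO": np.nan}))
        assert out.loc[0, "rvo_status"] == "case"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        codes=st.lists(
            st.one_of(st.none(), st.integers(min_value=1, max_value=3)),
            min_size=4,
            max_size=4,
        ),
        bump=st.integers(min_value=0, max_value=3),
    )
    def test_monotone_in_codes(self, codes, bump):
        """Raising any ophthalmic code from 1 to 2 never unmakes a case."""
        names = ("OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO")
        base = {n: (np.nan if c is None else float(c)) for n, c in zip(names, codes)}
        before = derive_rvo(raw_frame(base)).loc[0, "rvo_status"]
        raised = dict(base)
        raised[names[bump]] = 2.0
        after = derive_rvo(raw_frame(raised)).loc[0, "rvo_status"]
        assert after == "case" or before != "case"


class TestCovariateAlgorithms:
    @pytest.mark.parametrize(
        "over, expected",
        [
            ({"SMQ020": 2}, "never"),
            ({"SMQ020": 1, "SMQ040": 3}, "former"),
            ({"SMQ020": 1, "SMQ040": 2}, "current"),
            ({"SMQ020": 1, "SMQ040": 1}, "current"),
        ],
    )
    def test_smoking(self, over, expected):
        assert derive_smoking(raw_frame(over)).loc[0] == expected

    def test_smoking_missing_followup(self):
        assert pd.isna(derive_smoking(raw_frame({"SMQ020": 1})).loc[0])

    @pytest.mark.parametrize(
        "over, expected",
        [
            ({"BPXSY2": 145.0}, "yes"),
            ({"BPXDI3": 95.0}, "yes"),
            ({"BPQ050": 1.0}, "yes"),  # antihypertensive drugs alone
            ({"BPQ020": 1.0}, "yes"),
            ({"RX_ANTIHTN": 1.0}, "yes"),
            ({}, "no"),
            ({"BPXSY1": 140.0}, "yes"),  # threshold inclusive
        ],
    )
    def test_hypertension(self, over, expected):
        assert derive_hypertension(raw_frame(over)).loc[0] == expected

    def test_hypertension_all_missing(self):
        cols = [
            "BPXSY1", "BPXSY2", "BPXSY3", "BPXDI1", "BPXDI2", "BPXDI3",
            "BPQ020", "BPQ040A", "BPQ050", "RX_ANTIHTN",
        ]
        out = derive_hypertension(raw_frame({c: np.nan for c in cols}))
        assert pd.isna(out.loc[0])

    @pytest.mark.parametrize(
        "over, expected",
        [
            ({"LBXGH": 6.5}, "yes"),  # boundary inclusive
            ({"LBXGH": 6.4}, "no"),
            ({"DIQ010": 1.0}, "yes"),
            ({"DIQ050": 1.0}, "yes"),
            ({"RX_ANTIDM": 1.0}, "yes"),
            ({"DIQ010": 3.0, "LBXGH": 5.8}, "borderline"),
            ({}, "no"),
        ],
    )
    def test_diabetes(self, over, expected):
        assert derive_diabetes(raw_frame(over)).loc[0] == expected

    @pytest.mark.parametrize(
        "over, expected",
        [
            ({"LBXTC": 245.0}, "yes"),
            ({"LBDLDL": 160.0}, "yes"),  # boundary inclusive
            ({"LBXTR": 200.0}, "yes"),
            ({"BPQ080": 1.0}, "yes"),
            ({"BPQ090D": 1.0}, "yes"),
            ({"RX_LIPID": 1.0}, "yes"),
            ({}, "no"),
        ],
    )
    def test_hyperlipidemia(self, over, expected):
        assert derive_hyperlipidemia(raw_frame(over)).loc[0] == expected

    def test_derivations_are_pure(self):
        frame = raw_frame({"BPXSY2": 150.0, "LBXGH": 7.0})
        for fn in (derive_smoking, derive_hypertension, derive_diabetes,
                   derive_hyperlipidemia):
            a, b = fn(frame), fn(frame)
            pd.testing.assert_series_equal(a, b)


class TestBuildCohort:
    def test_hand_traced_flow(self):
        """5 rows: one under-age, one missing all ophthalmic codes, one
        missing lead -> n_final=2 with counted exclusions."""
        raw = raw_frame(
            {"RIDAGEYR": 39.0},
            {
                "RIDAGEYR": 41.0,
                **{c: np.nan for c in ("OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO")},
            },
            {"RIDAGEYR": 50.0, "LBXBPB": np.nan},
            {"RIDAGEYR": 60.0},
            {"RIDAGEYR": 70.0, "OPDDBVO": 2.0},
        )
        cohort, flow = build_analysis_cohort(raw)
        assert flow.n_initial == 5
        assert flow.n_after_age_filter == 4
        assert flow.n_excluded_missing_rvo == 1
        assert flow.n_excluded_missing_metals == 1
        assert flow.n_final == 2
        assert set(cohort["rvo_status"]) == {"control", "case"}

    def test_complete_rows_all_kept(self):
        raw = raw_frame({}, {"RIDAGEYR": 80.0}, {"OPDDCVO": 2.0})
        cohort, flow = build_analysis_cohort(raw)
        assert flow.n_final == flow.n_initial == 3

    def test_log10_matches_concentrations(self):
        raw = raw_frame({"LBXBPB": 0.25, "LBXBCD": 4.0, "LBXTHG": 2.0})
        cohort, _ = build_analysis_cohort(raw)
        for m in ("pb", "cd", "hg"):
            assert cohort[f"log10_{m}"].iloc[0] == pytest.approx(
                np.log10(cohort[m].iloc[0])
            )

    def test_lod_substitution_gives_finite_log(self):
        raw = raw_frame({"LBXBPB": 0.0})
        cohort, _ = build_analysis_cohort(
            raw, LODPolicy(lods={"pb": 0.02})
        )
        assert np.isfinite(cohort["log10_pb"].iloc[0])
        assert cohort["pb"].iloc[0] == pytest.approx(0.02 / np.sqrt(2))

    def test_nonpositive_without_lod_errors(self):
        with pytest.raises(ValueError, match="non-positive"):
            build_analysis_cohort(raw_frame({"LBXBPB": 0.0}))

    def test_negative_concentration_errors(self):
        with pytest.raises(ValueError):
            build_analysis_cohort(raw_frame({"LBXBCD": -1.0}))

    def test_empty_after_filtering_errors(self):
        with pytest.raises(ValueError, match="no participants"):
            build_analysis_cohort(raw_frame({"RIDAGEYR": 30.0}))

    def test_flow_counts_consistency_enforced(self):
        with pytest.raises(ValueError):
            FlowCounts(10, 9, 1, 1, 8)

    def test_derived_status_matches_simulator_truth(self, sim_cohort):
        cohort = sim_cohort["cohort"]
        truth = sim_cohort["truth"].table
        merged = cohort.merge(truth, left_on="id", right_on="SEQN")
        derived = (merged["rvo_status"] == "case").astype(int)
        assert (derived == merged["outcome"]).all()
        cases = merged[merged["outcome"] == 1]
        assert (cases["rvo_subtype"] == cases["subtype"]).all()
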