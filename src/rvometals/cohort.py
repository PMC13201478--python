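"""Analysis-cohort derivation from raw NHANES-style tables.

The raw table is one row per participant, keyed by NHANES field codes
(SMQ020, BPXSY1..3, OPDDBVO, ...).  This module applies, in order: the age
filter (>= 40 years), retinal-vein-occlusion (RVO) outcome coding from the
four ophthalmic grading variables, exclusion of rows without an outcome or
without blood-metal measurements, the four covariate algorithms (smoking,
hypertension, diabetes, hyperlipidemia), and the log10 transform of the
metal concentrations.

Outcome coding: any of OPDDBVO / OPDDCVO / OPDSBVO / OPDSCVO >= 2 marks an
RVO case; a central-vein code >= 2 classifies the case as CRVO even when a
branch code is also positive.  A participant with no positive code and at
least one missing code cannot be confirmed RVO-free and is treated as
missing (excluded, counted in the flow).

Covariate categories may remain missing in the derived cohort; downstream
models apply complete-case filtering per model rather than at build time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OPHTHALMIC_COLS",
    "METAL_COLS",
    "LODPolicy",
    "FlowCounts",
    "derive_rvo",
    "derive_smoking",
    "derive_hypertension",
    "derive_diabetes",
    "derive_hyperlipidemia",
    "build_analysis_cohort",
    "read_raw_table",
]

#: Ophthalmic grading variables: (right branch, right central, left branch,
#: left central).  A value >= 2 means the finding is present.
OPHTHALMIC_COLS = ("OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO")
_CENTRAL_COLS = ("OPDDCVO", "OPDSCVO")

#: Blood metal columns and their units as carried through the analysis:
#: lead in umol/L, cadmium and mercury in nmol/L.  No unit conversion is
#: performed; inputs are assumed to already be on these scales.
METAL_COLS = {"pb": "LBXBPB", "cd": "LBXBCD", "hg": "LBXTHG"}


@dataclass(frozen=True)
class LODPolicy:
    """How to handle non-positive / below-detection metal values before log10.

    When a detection limit is supplied for a metal, values below it (or
    non-positive values) are replaced by LOD/sqrt(2), the usual convention
    for assay floors.  Without a limit, non-positive values are an error:
    they cannot be log-transformed and silently dropping them would bias
    the exposure distribution.
    """

    lods: dict[str, float] = field(default_factory=dict)

    def apply(self, metal: str, values: pd.Series) -> pd.Series:
        lod = self.lods.get(metal)
        out = values.astype(float).copy()
        if lod is not None:
            sub = lod / math.sqrt(2.0)
            out[out < lod] = sub
            out[out <= 0] = sub
        elif (out.dropna() <= 0).any():
            raise ValueError(
                f"non-positive {metal} concentration with no detection limit "
                "configured; supply an LODPolicy with an LOD for this metal"
            )
        return out


@dataclass
class FlowCounts:
    """Participant counts through the inclusion/exclusion flow."""

    n_initial: int
    n_after_age_filter: int
    n_excluded_missing_rvo: int
    n_excluded_missing_metals: int
    n_final: int

    def __post_init__(self):
        ok = (
            0 <= self.n_final
            and self.n_after_age_filter <= self.n_initial
            and self.n_final
            == self.n_after_age_filter
            - self.n_excluded_missing_rvo
            - self.n_excluded_missing_metals
        )
        if not ok:
            raise ValueError(f"inconsistent flow counts: {self}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "initial",
                    "age>=40",
                    "excluded: missing RVO grading",
                    "excluded: missing blood metals",
                    "final",
                ],
                "n": [
                    self.n_initial,
                    self.n_after_age_filter,
                    self.n_excluded_missing_rvo,
                    self.n_excluded_missing_metals,
                    self.n_final,
                ],
            }
        )


def derive_rvo(raw: pd.DataFrame) -> pd.DataFrame:
    """Code RVO status and subtype from the four ophthalmic variables.

    Returns a frame with columns ``rvo_status`` ('case' / 'control' / NaN
    for missing) and ``rvo_subtype`` ('BRVO' / 'CRVO' / 'none').
    """
    codes = raw.reindex(columns=list(OPHTHALMIC_COLS)).astype(float)
    present = codes >= 2
    any_present = present.any(axis=1)
    any_missing = codes.isna().any(axis=1)
    central = codes[list(_CENTRAL_COLS)].ge(2).any(axis=1)

    status = pd.Series(np.where(any_present, "case", "control"), index=raw.index)
    # No positive code + any missing code -> cannot confirm RVO-free.
    status[~any_present & any_missing] = np.nan
    subtype = pd.Series("none", index=raw.index)
    subtype[any_present & central] = "CRVO"
    subtype[any_present & ~central] = "BRVO"
    return pd.DataFrame({"rvo_status": status, "rvo_subtype": subtype})


def derive_smoking(raw: pd.DataFrame) -> pd.Series:
    """Smoking status: never (SMQ020=2), former (SMQ020=1 & SMQ040=3),
    current (SMQ020=1 & SMQ040 in {1,2}); otherwise missing."""
    smq020 = raw.get("SMQ020", pd.Series(np.nan, index=raw.index)).astype(float)
    smq040 = raw.get("SMQ040", pd.Series(np.nan, index=raw.index)).astype(float)
    out = pd.Series(np.nan, index=raw.index, dtype=object)
    out[smq020 == 2] = "never"
    out[(smq020 == 1) & (smq040 == 3)] = "former"
    out[(smq020 == 1) & smq040.isin((1, 2))] = "current"
    return out


def _any_at_least(raw, cols, threshold):
    present = raw.reindex(columns=cols).astype(float)
    return present.ge(threshold).any(axis=1), present.notna().any(axis=1)


def derive_hypertension(raw: pd.DataFrame) -> pd.Series:
    """Hypertension: any SBP >= 140 or any DBP >= 90 (of up to three
    readings), self-reported diagnosis (BPQ020=1), self-reported
    antihypertensive use (BPQ040A=1 or BPQ050=1), or an antihypertensive in
    the medication list.  Missing when no determinant was observed."""
    sbp_hit, sbp_obs = _any_at_least(raw, ["BPXSY1", "BPXSY2", "BPXSY3"], 140)
    dbp_hit, dbp_obs = _any_at_least(raw, ["BPXDI1", "BPXDI2", "BPXDI3"], 90)
    q = raw.reindex(columns=["BPQ020", "BPQ040A", "BPQ050"]).astype(float)
    q_hit = q.eq(1).any(axis=1)
    med = raw.get("RX_ANTIHTN", pd.Series(np.nan, index=raw.index)).astype(float)
    yes = sbp_hit | dbp_hit | q_hit | med.eq(1)
    observed = sbp_obs | dbp_obs | q.notna().any(axis=1) | med.notna()
    out = pd.Series(np.where(yes, "yes", "no"), index=raw.index, dtype=object)
    out[~observed] = np.nan
    return out


def derive_diabetes(raw: pd.DataFrame) -> pd.Series:
    """Diabetes: self-report yes (DIQ010=1), HbA1c >= 6.5% (inclusive),
    insulin (DIQ050=1) or oral antidiabetics (DIQ070=1), or an antidiabetic
    in the medication list.  Borderline: self-report borderline (DIQ010=3)
    without any 'yes' trigger.  Missing when nothing was observed."""
    diq010 = raw.get("DIQ010", pd.Series(np.nan, index=raw.index)).astype(float)
    hba1c = raw.get("LBXGH", pd.Series(np.nan, index=raw.index)).astype(float)
    ins = raw.get("DIQ050", pd.Series(np.nan, index=raw.index)).astype(float)
    oral = raw.get("DIQ070", pd.Series(np.nan, index=raw.index)).astype(float)
    med = raw.get("RX_ANTIDM", pd.Series(np.nan, index=raw.index)).astype(float)
    yes = diq010.eq(1) | hba1c.ge(6.5) | ins.eq(1) | oral.eq(1) | med.eq(1)
    observed = (
        diq010.notna() | hba1c.notna() | ins.notna() | oral.notna() | med.notna()
    )
    out = pd.Series(np.where(yes, "yes", "no"), index=raw.index, dtype=object)
    out[~yes & diq010.eq(3)] = "borderline"
    out[~observed] = np.nan
    return out


def derive_hyperlipidemia(raw: pd.DataFrame) -> pd.Series:
    """Hyperlipidemia: self-report (BPQ080=1), LDL >= 160 mg/dL, total
    cholesterol >= 240 mg/dL, triglycerides >= 200 mg/dL (all inclusive),
    lipid-lowering medication self-report (BPQ090D=1) or medication-list
    flag.  Missing when no determinant was observed."""
    labs = raw.reindex(columns=["LBDLDL", "LBXTC", "LBXTR"]).astype(float)
    lab_hit = (
        labs["LBDLDL"].ge(160) | labs["LBXTC"].ge(240) | labs["LBXTR"].ge(200)
    )
    q = raw.reindex(columns=["BPQ080", "BPQ090D"]).astype(float)
    med = raw.get("RX_LIPID", pd.Series(np.nan, index=raw.index)).astype(float)
    yes = lab_hit | q.eq(1).any(axis=1) | med.eq(1)
    observed = labs.notna().any(axis=1) | q.notna().any(axis=1) | med.notna()
    out = pd.Series(np.where(yes, "yes", "no"), index=raw.index, dtype=object)
    out[~observed] = np.nan
    return out


def build_analysis_cohort(
    raw: pd.DataFrame,
    lod_policy: LODPolicy | None = None,
    *,
    min_age: float = 40.0,
) -> tuple[pd.DataFrame, FlowCounts]:
    """Derive the analysis cohort and the inclusion/exclusion flow counts.

    Parameters
    ----------
    raw : DataFrame
        Raw participant table with NHANES-style columns (see module doc).
        Must carry RIDAGEYR, RIAGENDR, BMXBMI, the four ophthalmic codes
        and the three blood-metal columns.
    lod_policy : LODPolicy, optional
        Below-detection handling for metals; default errors on
        non-positive values.
    min_age : float
        Inclusion age, inclusive.

    Returns
    -------
    (cohort, flow) : (DataFrame, FlowCounts)
        Cohort columns: id, rvo_status, rvo_subtype, age, sex, bmi,
        smoking, hypertension, diabetes, hyperlipidemia, pb, cd, hg,
        log10_pb, log10_cd, log10_hg.

    Raises
    ------
    ValueError
        If no participants survive filtering, or a metal concentration is
        negative / non-positive without an LOD.
    """
    lod_policy = lod_policy or LODPolicy()
    n_initial = len(raw)
    age = raw["RIDAGEYR"].astype(float)
    kept = raw.loc[age >= min_age].copy()
    n_after_age = len(kept)

    rvo = derive_rvo(kept)
    has_rvo = rvo["rvo_status"].notna()
    n_excl_rvo = int((~has_rvo).sum())
    kept = kept.loc[has_rvo]
    rvo = rvo.loc[has_rvo]

    metals = kept.reindex(columns=list(METAL_COLS.values())).astype(float)
    if (metals.dropna(how="any") < 0).any().any():
        raise ValueError("negative blood metal concentration in input")
    complete_metals = metals.notna().all(axis=1)
    n_excl_metals = int((~complete_metals).sum())
    kept = kept.loc[complete_metals]
    rvo = rvo.loc[complete_metals]

    n_final = len(kept)
    flow = FlowCounts(n_initial, n_after_age, n_excl_rvo, n_excl_metals, n_final)
    if n_final == 0:
        raise ValueError("no participants remain after inclusion/exclusion")

    sex_code = kept["RIAGENDR"].astype(float)
    cohort = pd.DataFrame(
        {
            "id": kept["SEQN"] if "SEQN" in kept else kept.index,
            "rvo_status": rvo["rvo_status"],
            "rvo_subtype": rvo["rvo_subtype"],
            "age": kept["RIDAGEYR"].astype(float),
            "sex": np.where(sex_code == 1, "male", "female"),
            "bmi": kept.get("BMXBMI", pd.Series(np.nan, index=kept.index)).astype(
                float
            ),
            "smoking": derive_smoking(kept),
            "hypertension": derive_hypertension(kept),
            "diabetes": derive_diabetes(kept),
            "hyperlipidemia": derive_hyperlipidemia(kept),
        },
        index=kept.index,
    )
    for metal, col in METAL_COLS.items():
        conc = lod_policy.apply(metal, kept[col].astype(float))
        cohort[metal] = conc
        cohort[f"log10_{metal}"] = np.log10(conc)
    return cohort.reset_index(drop=True), flow


def read_raw_table(path: str | Path) -> pd.DataFrame:
    """Read a raw participant table: CSV/TSV by extension, or SAS
    transport (.xpt) via pandas."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xpt":
        return pd.read_sas(path, format="xport")
    sep = "\t" if suffix in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)
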