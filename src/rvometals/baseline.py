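"""Baseline-characteristics table: group summaries and hypothesis tests.

Continuous variables are compared between RVO cases and controls with the
Mann-Whitney U test (midrank ties, tie-corrected normal approximation with
continuity correction; exact enumeration for tiny tie-free samples), and
summarized both as median (IQR) and mean +/- SD.  Categorical variables are
compared with a chi-square test: Yates-corrected for 2x2 tables, plain
Pearson otherwise.  Missing values are excluded per variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "mann_whitney_u", "chi_square", "baseline_table"]

_EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    degrees_of_freedom: int | None = None

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both samples have at most 8 observations
    and no ties cross groups; otherwise the normal approximation with
    midranks, tie-corrected variance and continuity correction.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must contain observed values")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N and tie_free
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann_whitney_u",
    )


def chi_square(table) -> TestResult:
    """Chi-square test of independence on a contingency table.

    2x2 tables get the Yates continuity correction; larger tables plain
    Pearson.  No exact-test fallback is applied for sparse cells.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    is_2x2 = t.shape == (2, 2)
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=is_2x2)
    return TestResult(
        statistic=float(chi2),
        p_value=float(min(p, 1.0)),
        method="chi_square_yates" if is_2x2 else "chi_square_pearson",
        degrees_of_freedom=int(dof),
    )


_CONTINUOUS = ["age", "bmi", "pb", "cd", "hg"]
_CATEGORICAL = {
    "sex": ["male", "female"],
    "smoking": ["never", "current", "former"],
    "hypertension": ["yes", "no"],
    "diabetes": ["yes", "no", "borderline"],
    "hyperlipidemia": ["yes", "no"],
}


def _cont_summary(v: pd.Series) -> str:
    v = v.dropna()
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return (
        f"{v.mean():.2f} ± {v.std(ddof=1):.2f}; "
        f"median {med:.2f} ({q1:.2f}-{q3:.2f})"
    )


def baseline_table(
    cohort: pd.DataFrame,
    *,
    continuous: list[str] | None = None,
    categorical: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Build the baseline-characteristics table for cases vs controls.

    One row per variable (one per level for categorical variables), with
    per-group summaries and the test p-value on the variable's first row.
    """
    continuous = continuous if continuous is not None else _CONTINUOUS
    categorical = categorical if categorical is not None else _CATEGORICAL
    groups = {"case": cohort[cohort["rvo_status"] == "case"],
              "control": cohort[cohort["rvo_status"] == "control"]}
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both outcome groups must be represented")

    rows = []
    for var in continuous:
        if var not in cohort:
            continue
        test = mann_whitney_u(groups["case"][var], groups["control"][var])
        rows.append(
            {
                "variable": var,
                "level": "",
                "rvo": _cont_summary(groups["case"][var]),
                "control": _cont_summary(groups["control"][var]),
                "test": test.method,
                "statistic": test.statistic,
                "p_value": test.p_value,
            }
        )
    for var, levels in categorical.items():
        if var not in cohort:
            continue
        counts = {
            g: df[var].value_counts().reindex(levels).fillna(0).astype(int)
            for g, df in groups.items()
        }
        # Drop levels absent from both groups so empty categories do not
        # produce zero marginals.
        keep = [
            lv for lv in levels if counts["case"][lv] + counts["control"][lv] > 0
        ]
        table = np.array(
            [[counts["case"][lv] for lv in keep], [counts["control"][lv] for lv in keep]]
        ).T
        test = chi_square(table)
        for i, lv in enumerate(keep):
            n_case, n_ctrl = counts["case"][lv], counts["control"][lv]
            tot_case = sum(counts["case"][l] for l in keep)
            tot_ctrl = sum(counts["control"][l] for l in keep)
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "rvo": f"{n_case} ({100 * n_case / tot_case:.2f}%)",
                    "control": f"{n_ctrl} ({100 * n_ctrl / tot_ctrl:.2f}%)",
                    "test": test.method if i == 0 else "",
                    "statistic": test.statistic if i == 0 else np.nan,
                    "p_value": test.p_value if i == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
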