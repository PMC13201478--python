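"""Single-metal association models for RVO risk.

Each blood metal enters a binary logistic model either as continuous log10
concentration or as tertile indicators (T2, T3 vs the lowest tertile T1);
both come univariable or adjusted for the traditional risk factors (age,
sex, BMI, smoking, hypertension, diabetes with borderline merged into no,
hyperlipidemia).  Odds ratios carry Wald 95% intervals, exp(beta +/- 1.96 SE).

The public surface is statsmodels-flavoured: build a
:class:`SingleMetalLogit` from a derived cohort, call :meth:`fit`, read the
:class:`SingleMetalResults`.  The one-call helpers :func:`continuous_or`
and :func:`tertile_or` wrap that round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .logistic import LogisticFit, fit_logistic

__all__ = [
    "ORResult",
    "TertileAssignment",
    "SingleMetalLogit",
    "SingleMetalResults",
    "assign_tertiles",
    "continuous_or",
    "tertile_or",
    "adjustment_design",
]

METALS = ("pb", "cd", "hg")
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ORResult:
    """One fitted exposure contrast."""

    exposure: str
    model_type: str  # 'univariable' | 'multivariable'
    contrast: str  # 'continuous-log10' | 'T3-vs-T1'
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int

    def __post_init__(self):
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("CI does not bracket the OR")


@dataclass(frozen=True)
class TertileAssignment:
    """Tertile labels plus the two cut points that produced them."""

    labels: pd.Series  # 'T1' / 'T2' / 'T3'
    cuts: tuple[float, float]


def assign_tertiles(values) -> TertileAssignment:
    """Split values at the empirical 33.3/66.7 percentiles.

    Cut points use numpy's linear-interpolation percentile; a value equal
    to a cut goes to the lower tertile, so assignment is deterministic and
    order-independent even with tied blocks spanning a cut.
    """
    v = pd.Series(values).astype(float)
    if v.dropna().nunique() < 3:
        raise ValueError("need at least 3 distinct values for tertiles")
    c1, c2 = np.percentile(v.dropna(), [100 / 3, 200 / 3])
    labels = pd.Series(
        np.where(v <= c1, "T1", np.where(v <= c2, "T2", "T3")),
        index=v.index,
        dtype=object,
    )
    labels[v.isna()] = np.nan
    return TertileAssignment(labels=labels, cuts=(float(c1), float(c2)))


def adjustment_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate encoding for the fully adjusted models.

    age, BMI continuous; male indicator (female reference); smoking as two
    indicators against never; hypertension/hyperlipidemia yes=1; diabetes
    yes=1 with borderline merged into the reference ("prediabetes
    classified into the normal group").  Rows with a missing covariate
    carry NaN and are dropped by the caller's complete-case filter.
    """
    d = pd.DataFrame(index=cohort.index)
    d["age"] = cohort["age"].astype(float)
    d["male"] = cohort["sex"].map({"male": 1.0, "female": 0.0})
    d["bmi"] = cohort["bmi"].astype(float)
    smoking = cohort["smoking"]
    d["smoking_current"] = smoking.map(
        {"current": 1.0, "former": 0.0, "never": 0.0}
    )
    d["smoking_former"] = smoking.map(
        {"former": 1.0, "current": 0.0, "never": 0.0}
    )
    d["hypertension"] = cohort["hypertension"].map({"yes": 1.0, "no": 0.0})
    d["diabetes"] = cohort["diabetes"].map(
        {"yes": 1.0, "no": 0.0, "borderline": 0.0}
    )
    d["hyperlipidemia"] = cohort["hyperlipidemia"].map({"yes": 1.0, "no": 0.0})
    return d


class SingleMetalLogit:
    """Logistic model of RVO status on one blood metal.

    Parameters
    ----------
    cohort : DataFrame
        Derived analysis cohort (needs rvo_status, log10_<metal>, and the
        covariate columns when ``adjusted``).
    metal : {'pb', 'cd', 'hg'}
    contrast : {'continuous', 'tertile'}
        Continuous log10 concentration, or T2/T3 indicators against T1.
    adjusted : bool
        Add the full covariate set.
    """

    def __init__(self, cohort, metal, *, contrast="continuous", adjusted=False):
        if metal not in METALS:
            raise ValueError(f"metal must be one of {METALS}")
        if contrast not in ("continuous", "tertile"):
            raise ValueError("contrast must be 'continuous' or 'tertile'")
        self.cohort = cohort
        self.metal = metal
        self.contrast = contrast
        self.adjusted = adjusted
        self._build()

    def _build(self):
        cohort = self.cohort
        y = cohort["rvo_status"].map({"case": 1.0, "control": 0.0})
        parts = [pd.Series(1.0, index=cohort.index, name="intercept")]
        if self.contrast == "continuous":
            parts.append(cohort[f"log10_{self.metal}"].rename("exposure"))
            self._exposure_index = 1
        else:
            tert = assign_tertiles(cohort[self.metal])
            self.tertiles = tert
            parts.append((tert.labels == "T2").astype(float).rename("T2"))
            parts.append((tert.labels == "T3").astype(float).rename("T3"))
            parts[-2][tert.labels.isna()] = np.nan
            parts[-1][tert.labels.isna()] = np.nan
            self._exposure_index = 2
        if self.adjusted:
            parts.append(adjustment_design(cohort))
        design = pd.concat(parts, axis=1)
        used = design.notna().all(axis=1) & y.notna()
        self.exog = design.loc[used]
        self.endog = y.loc[used]
        self.n_dropped = int((~used).sum())
        if self.contrast == "tertile":
            labels = self.tertiles.labels.loc[used]
            if labels.value_counts().reindex(["T1", "T2", "T3"]).fillna(0).eq(0).any():
                raise ValueError("a tertile is empty after complete-case filtering")

    def fit(self) -> "SingleMetalResults":
        fit = fit_logistic(self.exog.to_numpy(), self.endog.to_numpy())
        return SingleMetalResults(self, fit)


class SingleMetalResults:
    """Results wrapper exposing the reported exposure contrast."""

    def __init__(self, model: SingleMetalLogit, fit: LogisticFit):
        self.model = model
        self.fit = fit

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def or_result(self) -> ORResult:
        i = self.model._exposure_index
        b, se = self.fit.params[i], self.fit.bse[i]
        lo, hi = self.fit.wald_ci(i)
        return ORResult(
            exposure=self.model.metal,
            model_type="multivariable" if self.model.adjusted else "univariable",
            contrast=(
                "continuous-log10"
                if self.model.contrast == "continuous"
                else "T3-vs-T1"
            ),
            or_=float(np.exp(b)),
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p_value=self.fit.wald_p(i),
            n_used=self.fit.n_used,
        )

    def summary(self) -> pd.DataFrame:
        """Per-coefficient table: beta, SE, OR, 95% CI, p."""
        names = list(self.model.exog.columns)
        b = self.fit.params
        se = self.fit.bse
        z = np.divide(b, se, out=np.full_like(b, np.nan), where=se > 0)
        return pd.DataFrame(
            {
                "coef": b,
                "se": se,
                "or": np.exp(b),
                "ci_low": np.exp(b - _Z95 * se),
                "ci_high": np.exp(b + _Z95 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=names,
        )


def continuous_or(cohort, metal, adjusted: bool = False) -> ORResult:
    """OR per unit log10 concentration for one metal."""
    res = SingleMetalLogit(
        cohort, metal, contrast="continuous", adjusted=adjusted
    ).fit()
    if not res.converged:
        raise RuntimeError(f"logistic fit failed to converge for {metal}")
    return res.or_result


def tertile_or(cohort, metal, adjusted: bool = False) -> ORResult:
    """Top-vs-bottom tertile OR for one metal (T2 retained in the model)."""
    res = SingleMetalLogit(cohort, metal, contrast="tertile", adjusted=adjusted).fit()
    if not res.converged:
        raise RuntimeError(
            f"logistic fit failed to converge for {metal} tertiles "
            "(possible separation)"
        )
    return res.or_result


def association_table(cohort, metals=METALS) -> pd.DataFrame:
    """The four contrasts per metal, shaped like the printed association table."""
    rows = []
    for metal in metals:
        for adjusted in (False, True):
            cont = continuous_or(cohort, metal, adjusted)
            tert = tertile_or(cohort, metal, adjusted)
            rows.append(
                {
                    "exposure": metal,
                    "model": cont.model_type,
                    "or_continuous": cont.or_,
                    "ci_continuous": f"({cont.ci_low:.3f}, {cont.ci_high:.3f})",
                    "p_continuous": cont.p_value,
                    "or_t3_vs_t1": tert.or_,
                    "ci_t3_vs_t1": f"({tert.ci_low:.2f}, {tert.ci_high:.2f})",
                    "p_t3_vs_t1": tert.p_value,
                    "n_used": cont.n_used,
                }
            )
    return pd.DataFrame(rows)
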