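"""Transcriptomic candidate screening and qPCR validation statistics.

Three stages follow the expression work downstream of the cohort analysis:

* :func:`intersect_degs` — overlap of two differential-expression gene
  tables (one per lead dose vs control), with Venn counts.
* :func:`screen_candidates` — the three-criteria filter on normalized
  counts across NC / 10uM / 30uM: strict dose-monotonicity in either
  direction, abundance (max count strictly greater than 1), and membership
  in a supplied eye-associated gene list.
* :func:`ddct_fold_change` — relative quantification of qPCR Ct values by
  the 2^-ddCt method normalized to a reference gene (GAPDH), with
  two-sample t-tests of treated vs control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VennCounts",
    "CandidateGene",
    "FoldChangeResult",
    "intersect_degs",
    "screen_candidates",
    "ddct_fold_change",
    "significance_stars",
]


@dataclass(frozen=True)
class VennCounts:
    only_a: int
    only_b: int
    shared: int


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    monotone_direction: str  # 'decreasing' | 'increasing' | 'none'
    abundance_pass: bool
    annotation_pass: bool

    @property
    def selected(self) -> bool:
        return (
            self.monotone_direction != "none"
            and self.abundance_pass
            and self.annotation_pass
        )


@dataclass
class FoldChangeResult:
    """2^-ddCt quantification of one target gene in one treated group."""

    gene: str
    ddct: pd.Series  # per treated replicate
    fold_changes: pd.Series  # per treated replicate, 2^-ddct
    fold_change: float  # 2^(-mean ddct)
    control_folds: pd.Series  # per control replicate (mean 1 by construction)
    p_value_fold: float  # t-test on fold-change scale (default report)
    p_value_ddct: float  # t-test on the ddCt scale
    stars: str


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate gene identifiers in {name}: {sorted(df.loc[dup, 'gene'])[:5]}"
        )


def intersect_degs(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame
) -> tuple[pd.DataFrame, VennCounts]:
    """Intersect two DEG tables on gene identifier.

    Returns the shared genes (with per-table directions, and a
    ``concordant`` flag when both tables carry a ``direction`` column) and
    the Venn counts.  Direction agreement is reported, not required.
    """
    _check_unique(deg_a, "table A")
    _check_unique(deg_b, "table B")
    a, b = set(deg_a["gene"]), set(deg_b["gene"])
    shared_ids = sorted(a & b)
    counts = VennCounts(
        only_a=len(a - b), only_b=len(b - a), shared=len(shared_ids)
    )
    shared = pd.DataFrame({"gene": shared_ids})
    if "direction" in deg_a and "direction" in deg_b:
        da = deg_a.set_index("gene")["direction"]
        db = deg_b.set_index("gene")["direction"]
        shared["direction_a"] = shared["gene"].map(da)
        shared["direction_b"] = shared["gene"].map(db)
        shared["concordant"] = shared["direction_a"] == shared["direction_b"]
    return shared, counts


def screen_candidates(
    counts: pd.DataFrame, eye_genes, *, abundance_threshold: float = 1.0
) -> list[CandidateGene]:
    """Apply the three-criteria candidate filter to dose count triples.

    Parameters
    ----------
    counts : DataFrame
        Either indexed by gene with columns ['NC', '10uM', '30uM'], or
        carrying a 'gene' column plus those three.
    eye_genes : set of str
        Literature-curated eye-associated gene identifiers (supplied, not
        computed).
    abundance_threshold : float
        A gene passes abundance iff its maximum count strictly exceeds
        this (default 1).

    Monotonicity is strict in either direction: NC > c10 > c30
    (decreasing) or NC < c10 < c30 (increasing); ties break monotonicity.
    """
    df = counts.reset_index() if "gene" not in counts.columns else counts.copy()
    eye = set(eye_genes)
    out = []
    for _, row in df.iterrows():
        nc, c10, c30 = (float(row[c]) for c in ("NC", "10uM", "30uM"))
        if any(v < 0 for v in (nc, c10, c30)):
            raise ValueError(f"negative count for gene {row['gene']}")
        if nc > c10 > c30:
            direction = "decreasing"
        elif nc < c10 < c30:
            direction = "increasing"
        else:
            direction = "none"
        out.append(
            CandidateGene(
                gene=str(row["gene"]),
                monotone_direction=direction,
                abundance_pass=max(nc, c10, c30) > abundance_threshold,
                annotation_pass=str(row["gene"]) in eye,
            )
        )
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "GAPDH",
    control_label: str = "control",
    treated_label: str = "treated",
    *,
    equal_var: bool = True,
) -> FoldChangeResult:
    """Relative expression of ``target_gene`` by the 2^-ddCt method.

    Per sample: dCt = Ct(target) - Ct(reference); ddCt subtracts the
    control-group mean dCt; per-replicate fold = 2^-ddCt and the summary
    fold is 2^(-mean treated ddCt).  Treated vs control is compared with a
    two-sided two-sample t-test (Student's by default, Welch via
    ``equal_var=False``) on the fold-change scale; the ddCt-scale p-value
    is also reported.

    Raises
    ------
    ValueError
        If any sample lacks a reference- or target-gene Ct (named in the
        message), or a group has fewer than 2 replicates.
    """
    sub = ct_table[ct_table["group"].isin((control_label, treated_label))]
    wide = sub.pivot_table(
        index=["sample", "group"], columns="gene", values="ct", aggfunc="mean"
    )
    for gene in (reference_gene, target_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            missing = (
                wide.index.get_level_values("sample")[wide[gene].isna()].tolist()
                if gene in wide.columns
                else sorted(sub["sample"].unique())
            )
            raise ValueError(f"missing {gene} Ct for sample(s): {missing}")
    dct = (wide[target_gene] - wide[reference_gene]).reset_index()
    dct.columns = ["sample", "group", "dct"]
    ctrl = dct[dct["group"] == control_label].set_index("sample")["dct"]
    trt = dct[dct["group"] == treated_label].set_index("sample")["dct"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need at least 2 replicates per group")
    ddct_trt = trt - ctrl.mean()
    ddct_ctrl = ctrl - ctrl.mean()
    folds_trt = 2.0 ** (-ddct_trt)
    folds_ctrl = 2.0 ** (-ddct_ctrl)
    def _ttest_p(a, b):
        # Degenerate zero-variance groups (noiseless worked examples):
        # identical means carry no evidence, different means are exact.
        if np.std(a) == 0 and np.std(b) == 0:
            return 1.0 if np.isclose(np.mean(a), np.mean(b)) else 0.0
        return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)

    p_fold = _ttest_p(folds_trt, folds_ctrl)
    p_ddct = _ttest_p(ddct_trt, ddct_ctrl)
    return FoldChangeResult(
        gene=target_gene,
        ddct=ddct_trt,
        fold_changes=folds_trt,
        fold_change=float(2.0 ** (-ddct_trt.mean())),
        control_folds=folds_ctrl,
        p_value_fold=p_fold,
        p_value_ddct=p_ddct,
        stars=significance_stars(p_fold),
    )
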