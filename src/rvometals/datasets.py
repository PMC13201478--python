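"""Small published reference datasets used for verification and examples.

These are published observed values: the baseline contingency tables of
the NHANES 2005-2008 RVO analytic cohort (cases vs controls) and the
normalized-count dose triples of the six qPCR-validated candidate genes.
They serve as fixed inputs for worked examples and cross-checks; nothing
here is computed by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "baseline_contingency_tables",
    "validation_gene_counts",
    "EYE_GENES",
]

#: Case/control counts per categorical covariate level; rows are levels,
#: columns (RVO, control).
_BASELINE_TABLES = {
    "sex": {"male": (19, 2676), "female": (13, 2707)},
    "smoking": {"never": (14, 2541), "current": (6, 1093), "former": (12, 1746)},
    "hypertension": {"yes": (24, 3149), "no": (8, 2234)},
    "diabetes": {"yes": (8, 1054), "no": (24, 4249), "borderline": (0, 80)},
    "hyperlipidemia": {"yes": (19, 3117), "no": (13, 2266)},
}


def baseline_contingency_tables() -> dict[str, pd.DataFrame]:
    """Published case/control counts per covariate, as levels x group frames."""
    return {
        var: pd.DataFrame(levels, index=["rvo", "control"]).T
        for var, levels in _BASELINE_TABLES.items()
    }


def validation_gene_counts() -> pd.DataFrame:
    """Normalized counts (NC, 10uM, 30uM lead nitrate) for the six
    dose-responsive, eye-annotated candidate genes taken to qPCR."""
    rows = [
        ("SAXO2", 1.36, 0.22, 0.04),
        ("HSD11B2", 2.51, 1.36, 0.55),
        ("PRICKLE4", 2.52, 1.04, 0.97),
        ("PLCXD1", 4.83, 2.18, 1.12),
        ("IKBKGP1", 1.95, 4.80, 5.41),
        ("GP1BB", 1.17, 2.86, 4.81),
    ]
    return pd.DataFrame(rows, columns=["gene", "NC", "10uM", "30uM"])


#: The six validated genes are all literature-annotated as eye-associated.
EYE_GENES = frozenset(
    {"SAXO2", "HSD11B2", "PRICKLE4", "PLCXD1", "IKBKGP1", "GP1BB"}
)
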