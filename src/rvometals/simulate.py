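"""Synthetic data generators with known ground truth.

Three simulators cover the three data shapes the pipeline consumes:

* :func:`simulate_cohort` — an NHANES-style raw participant table (questionnaire
  codes, triplicate blood-pressure readings, labs, four ophthalmic grading
  codes, blood metals) in which a rare retinal-vein-occlusion outcome follows a
  configurable logistic model on log10 metal concentrations and covariates.
* :func:`simulate_expression` — a genes x {NC, 10uM, 30uM} normalized-count
  matrix with designated dose-monotone genes.
* :func:`simulate_qpcr` — a long-format qPCR Ct table (target + reference gene,
  control vs treated) with a known true fold change.

All three are deterministic under a fixed seed and return the latent truth
alongside the data, so every downstream derivation and model can be checked
against what was actually generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CohortSimConfig",
    "CohortTruth",
    "ExpressionSimConfig",
    "simulate_cohort",
    "simulate_expression",
    "simulate_qpcr",
]

_METAL_RAW = {"pb": "LBXBPB", "cd": "LBXBCD", "hg": "LBXTHG"}


def _default_covariate_effects() -> dict[str, float]:
    # Log-odds for the traditional risk factors; magnitudes chosen to be
    # epidemiologically plausible for a venous occlusive outcome (age is the
    # dominant factor, per decade-scale risk gradients).
    return {
        "age": 0.06,  # per year
        "sex": 0.35,  # male vs female
        "bmi": 0.0,  # per kg/m^2
        "smoking": 0.15,  # current vs never/former
        "hypertension": 0.70,
        "diabetes": 0.25,
        "hyperlipidemia": 0.10,
    }


def _default_missing_rates() -> dict[str, float]:
    # Roughly the observed exclusion flow: ~21% without usable fundus
    # grading, ~3% without a complete blood-metal panel.
    return {"ophthalmic": 0.21, "metals": 0.03}


@dataclass
class CohortSimConfig:
    """Generative settings for the NHANES-like cohort.

    Metal concentrations are multivariate log-normal: ``log10`` values are
    drawn jointly normal with the given means, SDs and correlation, then
    exponentiated.  Defaults approximate the observed control-group blood
    levels (lead ~0.10 umol/L, cadmium ~5 nmol/L, mercury ~8 nmol/L, all
    right-skewed) with modest positive correlation between metals.

    The outcome is a latent Bernoulli whose logit is linear in the log10
    metal levels and the covariates; the intercept is calibrated by
    bisection so the marginal prevalence hits ``outcome_prevalence_target``.
    """

    n_participants: int = 5415
    outcome_prevalence_target: float = 32 / 5415
    beta_log10_pb: float = math.log(2.189)
    beta_log10_cd: float = 0.0
    beta_log10_hg: float = 0.0
    covariate_effects: dict[str, float] = field(
        default_factory=_default_covariate_effects
    )
    metal_log_means: dict[str, float] = field(
        default_factory=lambda: {"pb": -1.02, "cd": 0.62, "hg": 0.72}
    )
    metal_log_sds: dict[str, float] = field(
        default_factory=lambda: {"pb": 0.28, "cd": 0.33, "hg": 0.42}
    )
    metal_correlation: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 0.25, 0.10], [0.25, 1.0, 0.10], [0.10, 0.10, 1.0]]
        )
    )
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0 < self.outcome_prevalence_target < 1:
            raise ValueError("outcome_prevalence_target must lie in (0, 1)")
        corr = np.asarray(self.metal_correlation, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("metal_correlation must be symmetric 3x3")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("metal_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("metal_correlation must be positive semidefinite")
        for k, v in self.missing_rates.items():
            if not 0 <= v < 1:
                raise ValueError(f"missing rate for {k!r} must be in [0, 1)")


@dataclass
class CohortTruth:
    """Latent ground truth for one simulated cohort."""

    table: pd.DataFrame  # per participant: SEQN, eta, p, outcome, subtype
    intercept: float
    config: CohortSimConfig


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection on b0 so that mean(sigmoid(b0 + eta)) == target."""

    def marginal(b0):
        return np.mean(expit(b0 + eta))

    lo, hi = -40.0, 40.0
    if marginal(lo) > target or marginal(hi) < target:
        raise ValueError(
            "prevalence target unreachable given the configured effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if marginal(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-free truncated normal via inverse-CDF on uniforms."""
    from scipy import stats

    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a raw NHANES-style participant table plus its latent truth.

    Returns
    -------
    (raw, truth)
        ``raw`` carries the NHANES field codes the cohort module consumes
        (RIDAGEYR, RIAGENDR, BMXBMI, SMQ020/040, BPXSY1-3, BPXDI1-3,
        BPQ020/040A/050/080/090D, DIQ010/050/070, LBXGH, LBDLDL, LBXTC,
        LBXTR, RX_* medication flags, OPDDBVO/OPDDCVO/OPDSBVO/OPDSCVO,
        LBXBPB/LBXBCD/LBXTHG).  ``truth`` records each participant's latent
        linear predictor, outcome probability, outcome and subtype.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    age = np.round(_truncated_normal(rng, 60.0, 12.4, 40.0, 85.0, n))
    male = rng.uniform(size=n) < 0.497
    bmi = np.round(_truncated_normal(rng, 29.3, 6.4, 15.0, 60.0, n), 1)

    smoking = rng.choice(
        np.array(["never", "current", "former"]), size=n, p=[0.472, 0.203, 0.325]
    )
    htn = rng.uniform(size=n) < 0.585
    dm = rng.choice(
        np.array(["yes", "no", "borderline"]), size=n, p=[0.195, 0.790, 0.015]
    )
    hld = rng.uniform(size=n) < 0.579

    # Metals: jointly log-normal on the log10 scale.
    order = ["pb", "cd", "hg"]
    mu = np.array([config.metal_log_means[m] for m in order])
    sd = np.array([config.metal_log_sds[m] for m in order])
    cov = np.asarray(config.metal_correlation, dtype=float) * np.outer(sd, sd)
    log10_metals = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    conc = 10.0 ** log10_metals

    eff = config.covariate_effects
    eta = (
        config.beta_log10_pb * log10_metals[:, 0]
        + config.beta_log10_cd * log10_metals[:, 1]
        + config.beta_log10_hg * log10_metals[:, 2]
        + eff.get("age", 0.0) * (age - 60.0)
        + eff.get("sex", 0.0) * male
        + eff.get("bmi", 0.0) * (bmi - 29.0)
        + eff.get("smoking", 0.0) * (smoking == "current")
        + eff.get("hypertension", 0.0) * htn
        + eff.get("diabetes", 0.0) * (dm == "yes")
        + eff.get("hyperlipidemia", 0.0) * hld
    )
    b0 = _calibrate_intercept(eta, config.outcome_prevalence_target)
    p_outcome = expit(b0 + eta)
    outcome = rng.uniform(size=n) < p_outcome

    raw = pd.DataFrame({"SEQN": np.arange(1, n + 1)})
    raw["RIDAGEYR"] = age
    raw["RIAGENDR"] = np.where(male, 1, 2)
    raw["BMXBMI"] = bmi

    # Smoking questionnaire codes.
    raw["SMQ020"] = np.where(smoking == "never", 2, 1)
    smq040 = np.full(n, np.nan)
    smq040[smoking == "former"] = 3
    cur = smoking == "current"
    smq040[cur] = rng.choice([1, 2], size=int(cur.sum()), p=[0.8, 0.2])
    raw["SMQ040"] = smq040

    # Blood pressure: three readings, all below threshold for normotensives.
    sbp_base = _truncated_normal(rng, 119.0, 8.0, 90.0, 139.0, (3, n))
    dbp_base = _truncated_normal(rng, 74.0, 7.0, 50.0, 89.0, (3, n))
    for i in range(3):
        raw[f"BPXSY{i + 1}"] = np.round(sbp_base[i])
        raw[f"BPXDI{i + 1}"] = np.round(dbp_base[i])
    raw["BPQ020"] = 2.0
    raw["BPQ040A"] = 2.0
    raw["BPQ050"] = 2.0
    raw["RX_ANTIHTN"] = 0.0
    # Each hypertensive gets at least one positive trigger.
    idx_htn = np.flatnonzero(htn)
    mech = rng.choice(3, size=idx_htn.size, p=[0.6, 0.25, 0.15])
    bp_rows = idx_htn[mech == 0]
    which = rng.integers(0, 3, size=bp_rows.size)
    high = np.round(140.0 + np.abs(rng.normal(12.0, 8.0, size=bp_rows.size)))
    for i in range(3):
        col = f"BPXSY{i + 1}"
        sel = bp_rows[which == i]
        vals = raw[col].to_numpy()
        vals[sel] = high[which == i]
        raw[col] = vals
    bpq020 = raw["BPQ020"].to_numpy()
    bpq020[idx_htn[mech == 1]] = 1.0
    raw["BPQ020"] = bpq020
    med_rows = idx_htn[mech == 2]
    bpq050 = raw["BPQ050"].to_numpy()
    bpq050[med_rows] = 1.0
    raw["BPQ050"] = bpq050
    rx = raw["RX_ANTIHTN"].to_numpy()
    rx[med_rows] = 1.0
    raw["RX_ANTIHTN"] = rx

    # Diabetes determinants.
    raw["DIQ010"] = np.where(dm == "borderline", 3.0, 2.0)
    raw["DIQ050"] = 2.0
    raw["DIQ070"] = 2.0
    raw["RX_ANTIDM"] = 0.0
    hba1c = _truncated_normal(rng, 5.4, 0.35, 4.2, 6.4, n)
    hba1c[dm == "borderline"] = _truncated_normal(
        rng, 6.0, 0.2, 5.7, 6.4, int((dm == "borderline").sum())
    )
    idx_dm = np.flatnonzero(dm == "yes")
    mech = rng.choice(3, size=idx_dm.size, p=[0.45, 0.35, 0.2])
    diq010 = raw["DIQ010"].to_numpy()
    diq010[idx_dm[mech == 0]] = 1.0
    raw["DIQ010"] = diq010
    lab_rows = idx_dm[mech == 1]
    hba1c[lab_rows] = 6.5 + np.abs(rng.normal(0.8, 0.8, size=lab_rows.size))
    med_rows = idx_dm[mech == 2]
    diq070 = raw["DIQ070"].to_numpy()
    diq070[med_rows] = 1.0
    raw["DIQ070"] = diq070
    rx = raw["RX_ANTIDM"].to_numpy()
    rx[med_rows] = 1.0
    raw["RX_ANTIDM"] = rx
    raw["LBXGH"] = np.round(hba1c, 1)

    # Lipids.
    raw["BPQ080"] = 2.0
    raw["BPQ090D"] = 2.0
    raw["RX_LIPID"] = 0.0
    ldl = _truncated_normal(rng, 112.0, 24.0, 40.0, 159.0, n)
    tc = _truncated_normal(rng, 192.0, 24.0, 110.0, 239.0, n)
    tg = _truncated_normal(rng, 121.0, 38.0, 40.0, 199.0, n)
    idx_hld = np.flatnonzero(hld)
    mech = rng.choice(3, size=idx_hld.size, p=[0.4, 0.4, 0.2])
    bpq080 = raw["BPQ080"].to_numpy()
    bpq080[idx_hld[mech == 0]] = 1.0
    raw["BPQ080"] = bpq080
    lab_rows = idx_hld[mech == 1]
    lab_kind = rng.integers(0, 3, size=lab_rows.size)
    ldl[lab_rows[lab_kind == 0]] = 160.0 + np.abs(
        rng.normal(15.0, 15.0, size=int((lab_kind == 0).sum()))
    )
    tc[lab_rows[lab_kind == 1]] = 240.0 + np.abs(
        rng.normal(15.0, 15.0, size=int((lab_kind == 1).sum()))
    )
    tg[lab_rows[lab_kind == 2]] = 200.0 + np.abs(
        rng.normal(40.0, 40.0, size=int((lab_kind == 2).sum()))
    )
    med_rows = idx_hld[mech == 2]
    bpq090d = raw["BPQ090D"].to_numpy()
    bpq090d[med_rows] = 1.0
    raw["BPQ090D"] = bpq090d
    rx = raw["RX_LIPID"].to_numpy()
    rx[med_rows] = 1.0
    raw["RX_LIPID"] = rx
    raw["LBDLDL"] = np.round(ldl)
    raw["LBXTC"] = np.round(tc)
    raw["LBXTR"] = np.round(tg)

    # Ophthalmic grading: controls get 1 ("not present") in all four codes;
    # a case gets 2 in the code matching a randomly assigned subtype/eye.
    for col in ("OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO"):
        raw[col] = 1.0
    idx_case = np.flatnonzero(outcome)
    central = rng.uniform(size=idx_case.size) < 0.3  # BRVO more common
    right = rng.uniform(size=idx_case.size) < 0.5
    subtype = np.where(central, "CRVO", "BRVO")
    code_col = np.where(
        central,
        np.where(right, "OPDDCVO", "OPDSCVO"),
        np.where(right, "OPDDBVO", "OPDSBVO"),
    )
    for col in ("OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO"):
        vals = raw[col].to_numpy()
        vals[idx_case[code_col == col]] = 2.0
        raw[col] = vals

    for metal, col in _METAL_RAW.items():
        raw[col] = conc[:, order.index(metal)]

    # MCAR missingness.  'ophthalmic' blanks all four grading codes jointly
    # (no usable fundus record); 'metals' blanks the whole metal panel.
    for key, rate in config.missing_rates.items():
        if rate <= 0:
            continue
        mask = rng.uniform(size=n) < rate
        if key == "ophthalmic":
            cols = ["OPDDBVO", "OPDDCVO", "OPDSBVO", "OPDSCVO"]
        elif key == "metals":
            cols = list(_METAL_RAW.values())
        elif key in _METAL_RAW:
            cols = [_METAL_RAW[key]]
        else:
            cols = [key]
        for col in cols:
            vals = raw[col].astype(float).to_numpy()
            vals[mask] = np.nan
            raw[col] = vals

    truth_table = pd.DataFrame(
        {
            "SEQN": raw["SEQN"],
            "eta": b0 + eta,
            "p_outcome": p_outcome,
            "outcome": outcome.astype(int),
            "subtype": "none",
        }
    )
    truth_table.loc[idx_case, "subtype"] = subtype
    return raw, CohortTruth(table=truth_table, intercept=b0, config=config)


@dataclass
class ExpressionSimConfig:
    """Settings for the dose-response expression matrix.

    ``noise_cv`` is the coefficient of variation of multiplicative
    log-normal measurement noise; 0 gives the exact expected counts.
    Monotone fold steps per dose increment are drawn uniformly from
    ``fold_step_range``.
    """

    n_genes: int = 1000
    frac_monotone_down: float = 0.05
    frac_monotone_up: float = 0.05
    baseline_log_mean: float = 0.5  # log10 scale
    baseline_log_sd: float = 0.6
    noise_cv: float = 0.1
    fold_step_range: tuple[float, float] = (1.5, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for f in (self.frac_monotone_down, self.frac_monotone_up):
            if not 0 <= f <= 1:
                raise ValueError("monotone fractions must be in [0, 1]")
        if self.frac_monotone_down + self.frac_monotone_up > 1:
            raise ValueError("monotone fractions must sum to at most 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a normalized-count matrix over conditions NC / 10uM / 30uM.

    Returns
    -------
    (counts, truth)
        ``counts`` is indexed by gene id with columns ['NC', '10uM',
        '30uM']; ``truth`` maps gene id -> class ('down', 'up', 'flat').
        Designated monotone genes have strictly ordered *expected* counts
        in their assigned direction (exactly ordered when noise_cv = 0).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_down = int(round(config.frac_monotone_down * n))
    n_up = int(round(config.frac_monotone_up * n))
    labels = np.array(["down"] * n_down + ["up"] * n_up + ["flat"] * (n - n_down - n_up))
    rng.shuffle(labels)

    base = 10.0 ** rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    lo, hi = config.fold_step_range
    f1 = rng.uniform(lo, hi, n)
    f2 = rng.uniform(lo, hi, n)
    expected = np.tile(base[:, None], (1, 3)).astype(float)
    down = labels == "down"
    up = labels == "up"
    expected[down, 1] = base[down] / f1[down]
    expected[down, 2] = base[down] / (f1[down] * f2[down])
    expected[up, 1] = base[up] * f1[up]
    expected[up, 2] = base[up] * f1[up] * f2[up]

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n, 3))
        observed = expected * noise
    else:
        observed = expected

    genes = [f"G{i + 1:05d}" for i in range(n)]
    counts = pd.DataFrame(observed, index=genes, columns=["NC", "10uM", "30uM"])
    counts.index.name = "gene"
    return counts, pd.Series(labels, index=genes, name="class")


def simulate_qpcr(
    n_replicates: int,
    true_fold_change: float,
    ct_noise_sd: float,
    seed: int,
    *,
    target_gene: str = "TARGET",
    reference_gene: str = "GAPDH",
    control_label: str = "control",
    treated_label: str = "treated",
) -> pd.DataFrame:
    """Generate a long-format Ct table with a known target fold change.

    The treated group's target-gene Ct is shifted by ``-log2(fold)`` relative
    to control, so the expected treated-vs-control ddCt equals
    ``-log2(true_fold_change)`` and relative quantification recovers the
    configured fold exactly when ``ct_noise_sd = 0``.

    Returns a DataFrame with columns (sample, group, gene, ct).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    shift = -math.log2(true_fold_change)
    for group, delta in ((control_label, 0.0), (treated_label, shift)):
        for r in range(n_replicates):
            sample = f"{group}_{r + 1}"
            ct_ref = 15.0 + rng.normal(0.0, ct_noise_sd)
            ct_tgt = 20.0 + delta + rng.normal(0.0, ct_noise_sd)
            rows.append((sample, group, reference_gene, ct_ref))
            rows.append((sample, group, target_gene, ct_tgt))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
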