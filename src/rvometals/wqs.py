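"""Weighted-quantile-sum (WQS) regression with signed bootstrap weights.

Procedure
---------
1. Split the cohort into a training (default 80%) and a test (20%) partition.
2. For each of ``n_boot`` bootstrap resamples of the training rows (with
   replacement): recompute each metal's quantile cuts on the resample,
   quantile-transform the resampled concentrations to 0-based ranks, and fit
   a joint logistic regression of the outcome on the metal ranks.
3. Normalize each resample's metal coefficients to unit L1 norm
   (``w_bi = beta_bi / sum_j |beta_bj|``) and average the signed normalized
   vectors over the successful resamples.  This per-resample convention
   yields an absolute-sum of at most 1 (equality only when every metal's
   coefficient keeps a constant sign across resamples); an alternative
   convention — L1-normalize the *mean* coefficient vector — is available
   via ``normalization='mean-coef'``.
4. Quantile-transform the test-set concentrations using cuts from the full
   training partition and form the WQS score as the weighted sum of ranks.
5. Regress the test-set outcome on the score; report that coefficient and
   its Wald p-value.

Unlike canonical WQS, weights are signed: no non-negativity or directional
homogeneity is imposed on the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logistic import fit_logistic

__all__ = ["WQSConfig", "WQSResult", "WQS", "quantile_cuts", "quantile_ranks", "wqs_fit"]


@dataclass
class WQSConfig:
    """Settings for the WQS fit."""

    metals: tuple[str, ...] = ("pb", "cd", "hg")
    n_quantiles: int = 4
    n_boot: int = 1000
    train_fraction: float = 0.8
    seed: int = 0
    covariates: tuple[str, ...] = ()
    stratify: bool = False  # outcome-stratified split instead of simple random
    normalization: str = "per-resample"  # or 'mean-coef'

    def validate(self) -> None:
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be at least 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if self.normalization not in ("per-resample", "mean-coef"):
            raise ValueError("unknown normalization convention")
        if len(self.metals) == 0:
            raise ValueError("need at least one metal")


@dataclass
class WQSResult:
    """Fitted WQS model."""

    weights: pd.Series  # signed, one per metal
    score_coefficient: float
    score_p: float
    boot_coefficients: pd.DataFrame  # per-resample raw logistic coefficients
    train_index: np.ndarray
    test_index: np.ndarray
    n_boot_used: int
    n_boot_failed: int
    config: WQSConfig

    def summary(self) -> pd.DataFrame:
        out = self.weights.to_frame("weight")
        out["mean_coef"] = self.boot_coefficients.mean()
        out["sd_coef"] = self.boot_coefficients.std(ddof=1)
        return out


def quantile_cuts(values, n_quantiles: int) -> np.ndarray:
    """Interior cut points (n_quantiles - 1) by linear-interpolation percentiles."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("cannot compute quantile cuts of constant values")
    pcts = 100.0 * np.arange(1, n_quantiles) / n_quantiles
    return np.percentile(v, pcts)


def quantile_ranks(values, cuts) -> np.ndarray:
    """0-based quantile rank: the number of cut points strictly below the value.

    A value equal to a cut falls in the lower quantile, matching the
    tertile tie rule used elsewhere.
    """
    v = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(cuts), v, side="left").astype(float)


class WQS:
    """Weighted-quantile-sum model of a binary outcome on a metal mixture.

    Parameters
    ----------
    cohort : DataFrame
        Derived analysis cohort; must be complete for the configured metal
        columns (and encoded covariates, if any).
    config : WQSConfig
    """

    def __init__(self, cohort: pd.DataFrame, config: WQSConfig | None = None):
        self.config = config or WQSConfig()
        self.config.validate()
        cfg = self.config
        y = cohort["rvo_status"].map({"case": 1.0, "control": 0.0})
        cols = [cohort[m].astype(float) for m in cfg.metals]
        X = pd.concat(cols, axis=1)
        X.columns = list(cfg.metals)
        cov = None
        if cfg.covariates:
            from .exposure import adjustment_design

            cov = adjustment_design(cohort)[list(cfg.covariates)]
        used = X.notna().all(axis=1) & y.notna()
        if cov is not None:
            used &= cov.notna().all(axis=1)
        self.metals_raw = X.loc[used].reset_index(drop=True)
        self.endog = y.loc[used].to_numpy()
        self.cov = cov.loc[used].to_numpy() if cov is not None else None

    def _split(self, rng) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        n = self.endog.size
        if cfg.stratify:
            train = []
            for cls in (0.0, 1.0):
                idx = np.flatnonzero(self.endog == cls)
                perm = rng.permutation(idx)
                train.append(perm[: int(round(cfg.train_fraction * idx.size))])
            train_idx = np.sort(np.concatenate(train))
        else:
            perm = rng.permutation(n)
            train_idx = np.sort(perm[: int(round(cfg.train_fraction * n))])
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        for name, idx in (("training", train_idx), ("test", test_idx)):
            if np.unique(self.endog[idx]).size < 2:
                raise ValueError(
                    f"{name} partition lacks both outcome classes; "
                    "use a stratified split or more data"
                )
        return train_idx, test_idx

    def fit(self) -> WQSResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        train_idx, test_idx = self._split(rng)
        Xtr = self.metals_raw.to_numpy()[train_idx]
        ytr = self.endog[train_idx]
        cov_tr = self.cov[train_idx] if self.cov is not None else None
        n_tr, p = Xtr.shape

        betas = np.full((cfg.n_boot, p), np.nan)
        n_failed = 0
        for b in range(cfg.n_boot):
            take = rng.integers(0, n_tr, size=n_tr)
            xb, yb = Xtr[take], ytr[take]
            if np.unique(yb).size < 2:
                n_failed += 1
                continue
            ranks = np.empty_like(xb)
            try:
                for j in range(p):
                    ranks[:, j] = quantile_ranks(
                        xb[:, j], quantile_cuts(xb[:, j], cfg.n_quantiles)
                    )
                parts = [np.ones((n_tr, 1)), ranks]
                if cov_tr is not None:
                    parts.append(cov_tr[take])
                fit = fit_logistic(np.column_stack(parts), yb, check=False)
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            if not fit.converged:
                n_failed += 1
                continue
            betas[b] = fit.params[1 : 1 + p]

        ok = ~np.isnan(betas).any(axis=1)
        n_used = int(ok.sum())
        if n_used == 0:
            raise RuntimeError("all bootstrap fits failed")
        boot = pd.DataFrame(betas[ok], columns=list(cfg.metals))

        if cfg.normalization == "per-resample":
            l1 = boot.abs().sum(axis=1)
            weights = (boot.div(l1, axis=0)).mean()
        else:  # 'mean-coef'
            mean_beta = boot.mean()
            weights = mean_beta / mean_beta.abs().sum()
        weights.name = "weight"

        # Score the test partition with cuts from the full training set.
        Xte = self.metals_raw.to_numpy()[test_idx]
        score = np.zeros(test_idx.size)
        for j in range(p):
            cuts = quantile_cuts(Xtr[:, j], cfg.n_quantiles)
            score += weights.iloc[j] * quantile_ranks(Xte[:, j], cuts)
        parts = [np.ones((test_idx.size, 1)), score[:, None]]
        if self.cov is not None:
            parts.append(self.cov[test_idx])
        score_fit = fit_logistic(np.column_stack(parts), self.endog[test_idx])
        return WQSResult(
            weights=weights,
            score_coefficient=float(score_fit.params[1]),
            score_p=score_fit.wald_p(1),
            boot_coefficients=boot,
            train_index=train_idx,
            test_index=test_idx,
            n_boot_used=n_used,
            n_boot_failed=n_failed,
            config=cfg,
        )


def wqs_fit(cohort, config: WQSConfig | None = None) -> WQSResult:
    """One-call helper: build the WQS model and fit it."""
    return WQS(cohort, config).fit()
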