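"""Percent variance explained (PVE) with percentile-bootstrap confidence intervals.

For an outcome ``out`` and its prediction ``out_hat``,

    PVE(out, out_hat) = (1 - (var(out) - var(out_hat)) / var(out)) * 100

which is algebraically ``100 * var(out_hat) / var(out)``.  PVE is reported at
three levels: the baseline model's phenotypic PVE(y, yhat_b), the genetic
model's residual-level PVE(r_b, rhat_b), and the ensemble's phenotypic
PVE(y, yhat_ensemble).  An alternative residual-based definition
``(1 - var(out - out_hat)/var(out)) * 100`` is available behind a flag; the
two agree when predictions and prediction errors are uncorrelated.
Confidence intervals resample test individuals with replacement and re-apply
the already-trained models (no refitting), taking the 2.5/97.5 percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._utils import child_rng

logger = logging.getLogger(__name__)

PVE_LEVELS = ("baseline_phenotypic", "genetic_residual", "ensemble_phenotypic")
DEFAULT_BOOTSTRAP_REPS = 100
MIN_STRATUM_SIZE = 30


@dataclass
class PVEResult:
    level: str
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    stratum: str = "ALL"
    n: int = 0
    bootstrap_reps: int = 0
    seed: int = 0
    wide_ci_flag: bool = False
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def pve(out, out_hat, residual_based: bool = False) -> float:
    """Percent variance explained; unbiased (n-1) variance estimator throughout."""
    out = np.asarray(out, dtype=float)
    out_hat = np.asarray(out_hat, dtype=float)
    if out.shape != out_hat.shape:
        raise ValueError("out and out_hat must have equal length")
    if out.size < 2:
        raise ValueError("need at least two observations")
    v = np.var(out, ddof=1)
    if v <= 0:
        raise ValueError("var(out) must be positive")
    if residual_based:
        return float((1.0 - np.var(out - out_hat, ddof=1) / v) * 100.0)
    return float((1.0 - (v - np.var(out_hat, ddof=1)) / v) * 100.0)


def _level_vectors(test, features, model, level, phenotype):
    """(out, out_hat) pairs for a PVE level, from already-trained models."""
    y = test[phenotype].to_numpy(dtype=float)
    y_hat_b = model.baseline.predict(test)
    if level == "baseline_phenotypic":
        return y, y_hat_b
    r_b = y - y_hat_b
    r_hat_b = model.genetic.predict(test, features)
    if level == "genetic_residual":
        return r_b, r_hat_b
    if level == "ensemble_phenotypic":
        return y, y_hat_b + r_hat_b
    raise ValueError(f"unknown PVE level: {level!r}")


def bootstrap_pve(
    test: pd.DataFrame,
    features,
    model,
    level: str,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    phenotype: str | None = None,
    residual_based: bool = False,
) -> PVEResult:
    """Point estimate and percentile CI for one PVE level on a test set.

    Rows with a missing phenotype (outlier-masked) are excluded first.
    Predictions are computed once; each bootstrap replicate resamples
    individuals with replacement at the test sample size.  Replicates with
    zero phenotype variance are dropped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    phenotype = phenotype or model.baseline.phenotype
    usable = test[phenotype].notna().to_numpy()
    test = test[usable].reset_index(drop=True)
    feats = features
    if features is not None and hasattr(features, "scores"):
        from .prs import FeatureTable
        feats = FeatureTable(features.scores.iloc[np.flatnonzero(usable)], features.meta)
    out, out_hat = _level_vectors(test, feats, model, level, phenotype)
    estimate = pve(out, out_hat, residual_based)

    n = out.size
    rng = child_rng(seed, "bootstrap", level, phenotype)
    samples, dropped = [], 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        if np.var(out[idx], ddof=1) <= 0:
            dropped += 1
            continue
        samples.append(pve(out[idx], out_hat[idx], residual_based))
    if dropped:
        logger.warning("bootstrap_pve: dropped %d zero-variance replicate(s)", dropped)
    lo, hi = (
        np.percentile(samples, [2.5, 97.5]) if samples else (float("nan"),) * 2
    )
    return PVEResult(
        level=level, estimate=estimate, ci_low=float(lo), ci_high=float(hi),
        stratum="ALL", n=int(n), bootstrap_reps=len(samples), seed=seed,
        extras={"n_dropped_replicates": dropped},
    )


def evaluate_stratified(
    test: pd.DataFrame,
    features,
    model,
    strata: str = "group",
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    phenotype: str | None = None,
    levels=PVE_LEVELS,
    residual_based: bool = False,
) -> list[PVEResult]:
    """One PVEResult per stratum per level, plus the pooled ALL stratum.

    Each stratum is resampled at its own sample size.  Strata below
    ``MIN_STRATUM_SIZE`` are flagged wide-CI; strata with n <= 1 are skipped
    with a warning.
    """
    if strata not in test.columns:
        raise ValueError(f"grouping column {strata!r} absent from test table")
    phenotype = phenotype or model.baseline.phenotype
    results: list[PVEResult] = []
    strata_values = ["ALL"] + sorted(test[strata].astype(str).unique())
    for value in strata_values:
        sub_mask = (
            np.ones(len(test), dtype=bool)
            if value == "ALL"
            else (test[strata].astype(str) == value).to_numpy()
        )
        sub = test[sub_mask].reset_index(drop=True)
        if sub[phenotype].notna().sum() <= 1:
            logger.warning("evaluate_stratified: skipping stratum %r (n <= 1)", value)
            continue
        from .prs import FeatureTable
        sub_feats = FeatureTable(features.scores.iloc[sub_mask.nonzero()[0]], features.meta)
        for level in levels:
            res = bootstrap_pve(
                sub, sub_feats, model, level, reps=reps,
                seed=seed, phenotype=phenotype, residual_based=residual_based,
            )
            res.stratum = value
            res.wide_ci_flag = res.n < MIN_STRATUM_SIZE
            results.append(res)
    return results


def results_table(results: list[PVEResult]) -> pd.DataFrame:
    rows = [r.as_dict() for r in results]
    for r in rows:
        r.pop("extras", None)
    return pd.DataFrame(rows)
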