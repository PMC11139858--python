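"""Phenotype harmonization, relatedness filtering, and train/test splitting.

A cohort table is a pandas DataFrame with one row per individual and columns
``individual_id``, ``age`` (years), ``sex``, ``group`` (self-reported
race/ethnicity-style label), ``study``, ``bmi`` (kg/m2), ``sbp``/``dbp``
(mmHg), ``med_use`` (bool) plus any extra covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: mmHg added to measured SBP / DBP for individuals on antihypertensive
#: medication, approximating their untreated blood pressure.
MED_ADJUSTMENT = {"sbp": 15.0, "dbp": 10.0}

#: Degree-3 relatedness bound on the kinship coefficient, 2**(-9/2) ~= 0.0442.
DEGREE3_KINSHIP = 2.0 ** (-9 / 2)

REQUIRED_COLUMNS = ("individual_id", "age", "sex", "group", "study", "bmi", "med_use")


def validate_cohort(cohort: pd.DataFrame, phenotypes=("sbp", "dbp")) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")
    if cohort["individual_id"].duplicated().any():
        raise ValueError("individual_id values must be unique")
    for ph in phenotypes:
        if ph in cohort.columns and (cohort[ph].dropna() <= 0).any():
            raise ValueError(f"{ph} must be positive where present")


def harmonize_phenotypes(
    cohort: pd.DataFrame,
    outlier_quantiles: tuple[float, float] = (0.01, 0.99),
    phenotypes=("sbp", "dbp"),
) -> tuple[pd.DataFrame, dict]:
    """Medication-adjust blood pressure, then drop per-phenotype outliers.

    Measured SBP/DBP of individuals with ``med_use`` are increased by 15 and
    10 mmHg respectively (adjustment first).  Then, per phenotype, individuals
    strictly above the high quantile or strictly below the low quantile of the
    adjusted values — quantiles computed over the complete input — are removed
    from that phenotype's analysis set by masking the value to NaN.  Rows are
    retained so the two phenotypes keep separate analysis sets.

    A ``med_adjusted`` flag marks adjusted tables; harmonizing an already
    adjusted table never re-adds the constants.  Returns the harmonized table
    and a removal report.
    """
    validate_cohort(cohort, phenotypes)
    low_q, high_q = outlier_quantiles
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("outlier quantiles must satisfy 0 <= low < high <= 1")
    out = cohort.copy().reset_index(drop=True)
    already = bool(out.attrs.get("med_adjusted", False)) or (
        "med_adjusted" in out.columns and out["med_adjusted"].any()
    )
    report: dict = {
        "medication_adjustment_applied": not already,
        "quantile_method": "linear interpolation (numpy default)",
        "outlier_quantiles": [low_q, high_q],
        "removed": {},
    }
    med = out["med_use"].astype(bool)
    for ph in phenotypes:
        if ph not in out.columns:
            continue
        if not already:
            out.loc[med, ph] = out.loc[med, ph] + MED_ADJUSTMENT[ph]
        vals = out[ph]
        lo, hi = vals.quantile([low_q, high_q], interpolation="linear")
        outlier = (vals < lo) | (vals > hi)
        report["removed"][ph] = int(outlier.sum())
        report.setdefault("bounds", {})[ph] = [float(lo), float(hi)]
        out.loc[outlier, ph] = np.nan
        if out[ph].notna().sum() == 0:
            raise ValueError(f"outlier removal left no usable {ph} values")
    out["med_adjusted"] = True
    out.attrs["med_adjusted"] = True
    return out, report


def filter_unrelated(
    cohort: pd.DataFrame,
    kinship: pd.DataFrame,
    threshold: float = DEGREE3_KINSHIP,
) -> pd.DataFrame:
    """Remove individuals until no pair has kinship >= ``threshold``.

    ``kinship`` has columns id_a, id_b, kinship.  Removal is greedy by
    descending relatedness degree (number of remaining related partners),
    with deterministic id-order tie-breaking.
    """
    ids = set(cohort["individual_id"].astype(str))
    pairs = kinship[kinship["kinship"] >= threshold]
    adj: dict[str, set[str]] = {}
    for a, b in zip(pairs["id_a"].astype(str), pairs["id_b"].astype(str)):
        if a == b or a not in ids or b not in ids:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    removed = set()
    while True:
        degrees = {v: len(nbrs) for v, nbrs in adj.items() if nbrs}
        if not degrees:
            break
        worst = max(degrees, key=lambda v: (degrees[v], v))
        removed.add(worst)
        for nbr in adj.pop(worst):
            adj[nbr].discard(worst)

    out = cohort[~cohort["individual_id"].astype(str).isin(removed)].reset_index(drop=True)
    out.attrs["n_removed_related"] = len(removed)
    return out


def split_train_test(
    cohort: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive random split; deterministic given ``seed``."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    train = cohort.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = cohort.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test
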