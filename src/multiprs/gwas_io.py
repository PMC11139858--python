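"""Reading, writing and algebra of GWAS summary statistics and LD-region files.

Summary statistics are carried as pandas DataFrames in a canonical dialect:

========  =====================================================
column    meaning
========  =====================================================
CHR       chromosome label (string)
POS       1-based position (int)
EA        effect allele (the allele BETA counts)
OA        other allele
BETA      effect estimate, mmHg per effect allele
SE        standard error of BETA (> 0)
P         two-sided p-value in (0, 1]
N         sample size behind the estimate
SOURCE    label of the originating GWAS
========  =====================================================

Other file dialects are read through an explicit column mapping.  All
operations key variants on (CHR, POS) and resolve allele orientation
explicitly; rsIDs are never used.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N", "SOURCE"]

#: Default mapping canonical-name -> file-column-name (identity dialect).
CANONICAL_DIALECT = {c: c for c in ["CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N"]}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _finalize_sumstats(df: pd.DataFrame, source_id: str | None) -> pd.DataFrame:
    df = df.copy()
    df["CHR"] = df["CHR"].astype(str)
    df["POS"] = df["POS"].astype(np.int64)
    for col in ("BETA", "SE", "P"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "N" not in df.columns:
        df["N"] = np.nan
    if source_id is not None:
        df["SOURCE"] = source_id
    elif "SOURCE" not in df.columns:
        df["SOURCE"] = "unknown"
    return df[SUMSTATS_COLUMNS].reset_index(drop=True)


def read_summary_stats(
    path, dialect: dict[str, str] | None = None, source_id: str | None = None
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into the canonical dialect.

    Parameters
    ----------
    path
        TSV file with a header row.  Scientific-notation p-values are accepted.
    dialect
        Mapping from canonical column names (CHR, POS, EA, OA, BETA, SE, P and
        optionally N) to the column names used in the file.  Defaults to the
        canonical names themselves.
    source_id
        Value for the SOURCE column; defaults to the file stem.

    Records violating the invariants (SE <= 0, P outside (0, 1], non-ACGT
    alleles) are dropped, counted in ``result.attrs["n_rejected"]`` and logged.
    A missing mapped column raises ``ValueError`` naming it.
    """
    dialect = dict(dialect or CANONICAL_DIALECT)
    raw = pd.read_csv(
        path, sep="\t", dtype={dialect.get("CHR", "CHR"): str},
        float_precision="round_trip",
    )
    missing = [
        canon for canon, col in dialect.items()
        if col not in raw.columns and canon != "N"
    ]
    if missing:
        raise ValueError(
            "summary-statistics file is missing mapped column(s): "
            + ", ".join(sorted(dialect[c] for c in missing))
            + f" (canonical: {', '.join(sorted(missing))})"
        )
    df = pd.DataFrame(
        {canon: raw[col] for canon, col in dialect.items() if col in raw.columns}
    )
    if source_id is None:
        source_id = getattr(path, "stem", None) or str(path).rsplit("/", 1)[-1].split(".")[0]
    df = _finalize_sumstats(df, source_id)
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    ok = (
        (df["SE"] > 0)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & df["EA"].isin(_VALID_ALLELES)
        & df["OA"].isin(_VALID_ALLELES)
        & df["BETA"].notna()
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("read_summary_stats: rejected %d invalid record(s)", n_rejected)
    out = df[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    """Write summary statistics in the canonical TSV dialect (bit-exact round trip)."""
    cols = [c for c in SUMSTATS_COLUMNS if c != "SOURCE"]
    stats.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.17g")


def is_strand_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """A/T and C/G pairs are unresolvable when array strand is unknown."""
    return ea.map(_COMPLEMENT) == oa


def harmonize_alleles(
    stats: pd.DataFrame,
    panel_variants: pd.DataFrame,
    keep_ambiguous: bool = False,
) -> pd.DataFrame:
    """Orient summary statistics to a panel's counted allele.

    ``panel_variants`` needs columns CHR, POS, EA (the allele the dosage
    counts) and OA.  When the stats alleles are swapped relative to the panel,
    BETA's sign is flipped and the alleles exchanged.  Strand-ambiguous pairs
    (A/T, C/G) are dropped unless ``keep_ambiguous``; allele pairs that match
    neither orientation are dropped.  Drop counts are reported in
    ``result.attrs`` and logged, never fatal.
    """
    panel = panel_variants[["CHR", "POS", "EA", "OA"]].rename(
        columns={"EA": "EA_panel", "OA": "OA_panel"}
    )
    panel = panel.assign(CHR=panel["CHR"].astype(str), POS=panel["POS"].astype(np.int64))
    merged = stats.merge(panel, on=["CHR", "POS"], how="inner")
    n_absent = len(stats) - len(merged)

    same = (merged["EA"] == merged["EA_panel"]) & (merged["OA"] == merged["OA_panel"])
    swapped = (merged["EA"] == merged["OA_panel"]) & (merged["OA"] == merged["EA_panel"])
    ambiguous = is_strand_ambiguous(merged["EA"], merged["OA"])

    keep = (same | swapped) & (keep_ambiguous | ~ambiguous)
    n_mismatch = int((~(same | swapped)).sum())
    n_ambiguous = int(((same | swapped) & ambiguous & ~keep_ambiguous).sum())

    out = merged[keep].copy()
    flip = swapped[keep]
    out.loc[flip, "BETA"] = -out.loc[flip, "BETA"]
    out["EA"] = out["EA_panel"]
    out["OA"] = out["OA_panel"]
    out = out.drop(columns=["EA_panel", "OA_panel"]).reset_index(drop=True)
    out.attrs["n_dropped_mismatch"] = n_mismatch
    out.attrs["n_dropped_ambiguous"] = n_ambiguous
    out.attrs["n_absent_from_panel"] = n_absent
    if n_mismatch or n_ambiguous:
        logger.info(
            "harmonize_alleles: dropped %d mismatched and %d strand-ambiguous variant(s)",
            n_mismatch, n_ambiguous,
        )
    return out


def run_marginal_gwas(
    panel,
    phenotype,
    covariates: pd.DataFrame | None = None,
    source_id: str = "marginal_gwas",
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage, adjusting for covariates.

    Uses the Frisch–Waugh–Lovell projection: phenotype and every dosage column
    are residualised on the covariate design (plus intercept), then the
    per-variant slope, its standard error and a two-sided t-test p-value are
    computed in one vectorised pass.  Zero-variance dosages yield a record
    with NaN estimates (flagged, excluded downstream).
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    n = y.size
    dosages = panel.dosages
    if dosages.shape[0] != n:
        raise ValueError("phenotype length does not match panel individuals")

    if covariates is not None and len(covariates.columns):
        X = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), X])
    else:
        X = np.ones((n, 1))
    k = X.shape[1]
    if n <= k + 2:
        raise ValueError("sample size too small for the covariate count")

    Q, _ = np.linalg.qr(X)
    y_t = y - Q @ (Q.T @ y)
    G_t = dosages - Q @ (Q.T @ dosages)

    gg = np.einsum("ij,ij->j", G_t, G_t)
    monomorphic = gg <= 1e-12
    gg_safe = np.where(monomorphic, 1.0, gg)
    beta = (G_t.T @ y_t) / gg_safe
    df_resid = n - k - 1
    rss = y_t @ y_t - beta**2 * gg_safe
    sigma2 = np.maximum(rss, 0.0) / df_resid
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df_resid)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    beta[monomorphic] = np.nan
    se[monomorphic] = np.nan
    p[monomorphic] = np.nan

    out = panel.variants[["CHR", "POS", "EA", "OA"]].copy().reset_index(drop=True)
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    out["N"] = n
    out["SOURCE"] = source_id
    out.attrs["n_monomorphic"] = int(monomorphic.sum())
    return out


def meta_analyze(studies: list[pd.DataFrame], source_id: str = "meta") -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis of harmonized summary statistics.

    All studies must share variant keys and allele orientation.
    """
    base = studies[0][["CHR", "POS", "EA", "OA"]].copy()
    w_sum = np.zeros(len(base))
    wb_sum = np.zeros(len(base))
    n_sum = np.zeros(len(base))
    for s in studies:
        aligned = base.merge(
            s, on=["CHR", "POS", "EA", "OA"], how="left", validate="one_to_one"
        )
        if aligned["BETA"].isna().any():
            raise ValueError("meta_analyze requires identical variant sets")
        w = 1.0 / aligned["SE"].to_numpy() ** 2
        w_sum += w
        wb_sum += w * aligned["BETA"].to_numpy()
        n_sum += aligned["N"].to_numpy()
    beta = wb_sum / w_sum
    se = np.sqrt(1.0 / w_sum)
    out = base
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
    out["N"] = n_sum
    out["SOURCE"] = source_id
    return out


def subtract_gwas(meta: pd.DataFrame, sub: pd.DataFrame) -> pd.DataFrame:
    """Remove a sub-cohort's contribution from fixed-effects meta summary statistics.

    For each shared variant, with inverse-variance weights w = 1/SE²::

        w_rem    = w_meta - w_sub
        beta_rem = (w_meta * beta_meta - w_sub * beta_sub) / w_rem
        se_rem   = sqrt(1 / w_rem)

    and the p-value is recomputed from the Wald statistic.  This exactly
    inverts inverse-variance meta-analysis when the sub-cohort entered the
    meta as an independent study.  Variants absent from ``sub`` pass through
    unchanged; variants where the sub-cohort's weight is not strictly smaller
    than the meta's are dropped with a warning (counted in
    ``result.attrs["n_dropped_weight"]``).
    """
    sub_aligned = harmonize_alleles(sub, meta, keep_ambiguous=True)
    sub_key = sub_aligned.set_index(["CHR", "POS", "EA", "OA"])
    meta_idx = pd.MultiIndex.from_frame(meta[["CHR", "POS", "EA", "OA"]])
    shared = meta_idx.isin(sub_key.index)

    out = meta.copy().reset_index(drop=True)
    if not shared.any():
        out.attrs["n_dropped_weight"] = 0
        return out

    sub_rows = sub_key.reindex(meta_idx[shared])
    w_meta = 1.0 / out.loc[shared, "SE"].to_numpy() ** 2
    w_sub = 1.0 / sub_rows["SE"].to_numpy() ** 2
    bad = w_sub >= w_meta
    w_rem = w_meta - w_sub
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_rem = (w_meta * out.loc[shared, "BETA"].to_numpy() - w_sub * sub_rows["BETA"].to_numpy()) / w_rem
        se_rem = np.sqrt(1.0 / w_rem)

    idx = np.flatnonzero(shared)
    out.loc[idx, "BETA"] = beta_rem
    out.loc[idx, "SE"] = se_rem
    out.loc[idx, "P"] = np.clip(
        2.0 * sps.norm.sf(np.abs(beta_rem / se_rem)), np.finfo(float).tiny, 1.0
    )
    n_rem = out.loc[idx, "N"].to_numpy() - sub_rows["N"].to_numpy()
    out.loc[idx, "N"] = np.maximum(n_rem, 1)

    n_bad = int(bad.sum())
    if n_bad:
        logger.warning(
            "subtract_gwas: dropped %d variant(s) where the sub-cohort weight "
            "was not smaller than the meta weight", n_bad,
        )
        out = out.drop(index=idx[bad]).reset_index(drop=True)
    out.attrs["n_dropped_weight"] = n_bad
    return out


def read_ld_regions(path) -> pd.DataFrame:
    """Load LD-region definitions from a BED file (0-based, half-open).

    Returns a DataFrame with columns CHR, START, END, REGION_ID.  A fourth BED
    column supplies region ids; otherwise ids are assigned as chrom:start-end.
    Overlapping intervals on one chromosome violate the partition assumption
    and raise ``ValueError``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line has fewer than 3 columns: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if not start < end:
                raise ValueError(f"BED interval with start >= end: {line!r}")
            region_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, region_id))
    regions = pd.DataFrame(rows, columns=["CHR", "START", "END", "REGION_ID"])
    for chrom, grp in regions.groupby("CHR"):
        grp = grp.sort_values("START")
        if (grp["START"].to_numpy()[1:] < grp["END"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping LD regions on chromosome {chrom}")
    return regions.reset_index(drop=True)


def write_ld_regions(regions: pd.DataFrame, path) -> None:
    regions.to_csv(
        path, sep="\t", index=False, header=False,
        columns=["CHR", "START", "END", "REGION_ID"],
    )


def assign_regions(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Map each variant to the REGION_ID whose half-open interval contains it.

    BED convention: a variant at 1-based position POS falls in [START, END)
    when START <= POS - 1 < END.  Variants outside every region map to NaN.
    """
    result = pd.Series(pd.NA, index=variants.index, dtype="object")
    for chrom, grp in regions.groupby("CHR"):
        mask = variants["CHR"].astype(str) == str(chrom)
        if not mask.any():
            continue
        pos0 = variants.loc[mask, "POS"].to_numpy() - 1
        grp = grp.sort_values("START")
        idx = np.searchsorted(grp["START"].to_numpy(), pos0, side="right") - 1
        valid = (idx >= 0) & (pos0 < grp["END"].to_numpy()[np.clip(idx, 0, None)])
        ids = np.where(valid, grp["REGION_ID"].to_numpy()[np.clip(idx, 0, None)], None)
        result.loc[mask] = ids
    return result
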