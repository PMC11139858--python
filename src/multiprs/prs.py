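"""Clump-and-threshold polygenic risk scores, global and per-LD-region.

A PRS is a weighted allele-dosage sum: for individual *i* with dosages
``d_ij`` and GWAS effect estimates ``beta_j`` over an LD-clumped, p-value
thresholded variant set *S*,

    PRS_i = sum_{j in S} beta_j * d_ij .

Scores are emitted as raw weighted sums in mmHg units (no per-column
standardisation; tree ensembles are scale-invariant and a flag exists for
linear engines).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import assign_regions

logger = logging.getLogger(__name__)

#: The clump-and-threshold p-value grid (loosest threshold last).
DEFAULT_THRESHOLDS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
#: Threshold used for single-PRS (level 1) and per-LD-region local scores.
LOCAL_THRESHOLD = 1e-2
DEFAULT_R2_MAX = 0.1
DEFAULT_WINDOW_KB = 1000.0


@dataclass
class GenotypePanel:
    """Individuals x variants dosage matrix with variant metadata.

    ``variants`` carries CHR, POS, EA (counted allele), OA and is indexed by
    variant id "CHR:POS:EA:OA".  Dosages are additive counts of EA in [0, 2];
    NaN marks missing calls (mean-imputed at scoring time).
    """

    individual_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match ids/variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if "VID" not in self.variants.columns:
            self.variants = self.variants.copy()
            self.variants["VID"] = variant_ids(self.variants)
        self.variants = self.variants.set_index(
            pd.Index(self.variants["VID"], name="VID"), drop=False
        )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        """Empirical frequency of the counted allele."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def mafs(self) -> np.ndarray:
        freq = self.allele_frequencies()
        return np.minimum(freq, 1.0 - freq)

    def subset_variants(self, mask) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypePanel(
            self.individual_ids,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_individuals(self, ids) -> "GenotypePanel":
        pos = pd.Index(self.individual_ids).get_indexer(ids)
        if (pos < 0).any():
            raise KeyError("individual id(s) absent from panel")
        return GenotypePanel(
            np.asarray(ids), self.variants.reset_index(drop=True), self.dosages[pos]
        )

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        """Variant-major TSV: metadata columns then one column per individual."""
        meta = self.variants[["VID", "CHR", "POS", "EA", "OA"]].reset_index(drop=True)
        dos = pd.DataFrame(
            self.dosages.T, columns=[str(i) for i in self.individual_ids]
        )
        pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
        meta_cols = ["VID", "CHR", "POS", "EA", "OA"]
        ids = [c for c in df.columns if c not in meta_cols]
        return cls(np.array(ids), df[meta_cols].copy(), df[ids].to_numpy(dtype=float).T)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with DS (dosage) and GT fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(self.variants["CHR"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(i) for i in self.individual_ids) + "\n"
            )
            # EA is written as ALT so DS counts the effect allele
            for j, row in enumerate(self.variants.itertuples(index=False)):
                ds = self.dosages[:, j]
                gts = np.select(
                    [np.isnan(ds), ds < 0.5, ds < 1.5], ["./.", "0/0", "0/1"], "1/1"
                )
                fields = [
                    f"{g}:{'.' if np.isnan(d) else format(d, '.6g')}"
                    for g, d in zip(gts, ds)
                ]
                fh.write(
                    f"{row.CHR}\t{row.POS}\t{row.VID}\t{row.OA}\t{row.EA}\t.\tPASS\t.\t"
                    "GT:DS\t" + "\t".join(fields) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read dosages from a VCF (DS field preferred, GT fallback)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = np.array(vcf.samples)
        meta, cols = [], []
        for v in vcf:
            alt = v.ALT[0] if v.ALT else "."
            try:
                ds = np.asarray(v.format("DS"), dtype=float).ravel()
            except (KeyError, TypeError, ValueError):
                gt = np.asarray(v.gt_types, dtype=float)  # 0,1,3 -> 0,1,2; 2=unknown
                ds = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
            meta.append((str(v.CHROM), int(v.POS), alt, v.REF))
            cols.append(ds)
        variants = pd.DataFrame(meta, columns=["CHR", "POS", "EA", "OA"])
        return cls(ids, variants, np.column_stack(cols) if cols else np.empty((len(ids), 0)))


def variant_ids(variants: pd.DataFrame) -> pd.Series:
    return (
        variants["CHR"].astype(str) + ":" + variants["POS"].astype(str)
        + ":" + variants["EA"].astype(str) + ":" + variants["OA"].astype(str)
    )


@dataclass
class FeatureTable:
    """PRS columns with per-column provenance metadata.

    ``scores`` is indexed by individual id; ``meta`` has one row per column
    with fields name, source_id, p_threshold, region_id ("GLOBAL" for
    genome-wide scores) and n_variants_used.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.scores.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.meta) and self.meta["name"].duplicated().any():
            raise ValueError("duplicate PRS column metadata")

    @property
    def columns(self) -> list[str]:
        return list(self.scores.columns)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if not self.scores.index.equals(other.scores.index):
            raise ValueError("feature tables cover different individuals")
        return FeatureTable(
            pd.concat([self.scores, other.scores], axis=1),
            pd.concat([self.meta, other.meta], ignore_index=True),
        )

    def select(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.scores[names].copy(),
            self.meta[self.meta["name"].isin(names)].reset_index(drop=True),
        )

    def standardized(self) -> "FeatureTable":
        """Z-scored copy, for linear engines where scale matters."""
        sd = self.scores.std(ddof=1).replace(0.0, 1.0)
        return FeatureTable((self.scores - self.scores.mean()) / sd, self.meta.copy())

    def to_tsv(self, path, meta_path=None) -> None:
        self.scores.rename_axis("individual_id").to_csv(path, sep="\t", float_format="%.10g")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta.to_dict(orient="records"), fh, indent=1)

    @classmethod
    def from_tsv(cls, path, meta_path=None) -> "FeatureTable":
        scores = pd.read_csv(path, sep="\t", index_col="individual_id")
        scores.index = scores.index.astype(str)
        meta = pd.DataFrame()
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = pd.DataFrame(json.load(fh))
        return cls(scores, meta)


def filter_variants(panel: GenotypePanel, min_maf: float = 0.01) -> GenotypePanel:
    """Drop variants with empirical MAF below ``min_maf`` (boundary inclusive)."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    keep = panel.mafs() >= min_maf
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("MAF filter removed every variant; nothing to score")
    if n_removed:
        logger.info("filter_variants: removed %d variant(s) below MAF %g", n_removed, min_maf)
    out = panel.subset_variants(keep)
    out.variants.attrs["n_removed_maf"] = n_removed
    return out


def ld_clump(
    stats: pd.DataFrame,
    reference: GenotypePanel,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> list[str]:
    """Greedy p-value-ordered LD clumping; returns ordered index-variant ids.

    Repeatedly takes the remaining variant with the smallest p-value as an
    index and removes remaining variants on the same chromosome within
    ``window_kb`` whose squared dosage correlation with it is >= ``r2_max``.
    Ties on p are broken by (CHR, POS), making the output invariant to the
    input row order.  Variants absent from the reference are excluded with a
    logged count.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")

    stats = stats[stats["BETA"].notna() & stats["P"].notna()]
    vids = variant_ids(stats)
    in_ref = vids.isin(reference.variants.index)
    n_missing = int((~in_ref).sum())
    if n_missing:
        logger.info("ld_clump: %d stats variant(s) absent from reference panel", n_missing)
    stats = stats[in_ref.to_numpy()]
    if stats.empty:
        return []

    order = stats.assign(_vid=vids[in_ref.to_numpy()]).sort_values(
        ["P", "CHR", "POS"], kind="mergesort"
    )
    col_of = {v: i for i, v in enumerate(reference.variants.index)}
    D = reference.dosages
    # centred dosage columns for fast pairwise r2 (mean-imputed)
    Dc = D - np.nanmean(D, axis=0, keepdims=True)
    Dc = np.nan_to_num(Dc)
    norms = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))

    chrs = order["CHR"].to_numpy()
    poss = order["POS"].to_numpy()
    vlist = order["_vid"].to_numpy()
    refcol = np.array([col_of[v] for v in vlist])
    alive = np.ones(len(vlist), dtype=bool)
    window_bp = window_kb * 1000.0

    index_set: list[str] = []
    for i in range(len(vlist)):
        if not alive[i]:
            continue
        alive[i] = False
        index_set.append(vlist[i])
        near = np.flatnonzero(
            alive & (chrs == chrs[i]) & (np.abs(poss - poss[i]) <= window_bp)
        )
        if near.size == 0:
            continue
        ci = refcol[i]
        cand = refcol[near]
        denom = norms[ci] * norms[cand]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Dc[:, ci] @ Dc[:, cand]) / denom
        r2 = np.where(denom > 0, r**2, 0.0)
        alive[near[r2 >= r2_max]] = False
    return index_set


def score_prs(
    panel: GenotypePanel,
    stats: pd.DataFrame,
    index_set: list[str],
    p_threshold: float,
) -> tuple[np.ndarray, int]:
    """Weighted allele-dosage sum over index variants passing ``p_threshold``.

    Returns the per-individual score vector and the number of contributing
    variants.  Missing dosages are mean-imputed per variant.  An empty
    contributing set yields an all-zero column with a warning.
    """
    svid = variant_ids(stats)
    chosen = stats[(svid.isin(index_set)).to_numpy() & (stats["P"] <= p_threshold).to_numpy()]
    chosen_vids = variant_ids(chosen)
    missing = ~chosen_vids.isin(panel.variants.index)
    if missing.any():
        raise KeyError(f"index variants absent from panel: {list(chosen_vids[missing])[:5]}")
    if chosen.empty:
        warnings.warn("score_prs: no variants pass the threshold; emitting zeros")
        return np.zeros(panel.n_individuals), 0
    cols = pd.Index(panel.variants.index).get_indexer(chosen_vids)
    D = panel.dosages[:, cols]
    if np.isnan(D).any():
        D = np.where(np.isnan(D), np.nanmean(D, axis=0, keepdims=True), D)
    return D @ chosen["BETA"].to_numpy(), int(len(chosen))


def build_feature_table(
    panel: GenotypePanel,
    sources: list[pd.DataFrame],
    level,
    thresholds=DEFAULT_THRESHOLDS,
    regions: pd.DataFrame | None = None,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> FeatureTable:
    """Construct the PRS feature matrix for a model complexity level.

    level 1
        one source, one column at the loosest threshold (1e-2).
    level 2
        one source, one column per threshold in the grid (7 by default).
    level 3
        every source x every threshold (21 columns with 3 sources).
    "local"
        one source at threshold 1e-2, clumped and scored independently
        within each LD region; regions with no contributing variant are
        dropped so downstream LASSO never sees constant columns.

    Clumping is performed once per source (or per region) and the p-value
    threshold applied per column to the clumped set.
    """
    index = pd.Index([str(i) for i in panel.individual_ids], name="individual_id")

    def _columns_for(stats, use_thresholds, source):
        idx_set = ld_clump(stats, panel, r2_max=r2_max, window_kb=window_kb)
        cols, meta = {}, []
        for thr in use_thresholds:
            score, n_used = score_prs(panel, stats, idx_set, thr)
            name = f"{source}_p{thr:g}"
            cols[name] = score
            meta.append(
                dict(name=name, source_id=source, p_threshold=thr,
                     region_id="GLOBAL", n_variants_used=n_used)
            )
        return cols, meta

    if level in (1, "1"):
        if len(sources) != 1:
            raise ValueError("level 1 uses exactly one summary-statistics source")
        cols, meta = _columns_for(sources[0], [LOCAL_THRESHOLD], _source_id(sources[0]))
    elif level in (2, "2"):
        if len(sources) != 1:
            raise ValueError("level 2 uses exactly one summary-statistics source")
        cols, meta = _columns_for(sources[0], list(thresholds), _source_id(sources[0]))
    elif level in (3, "3"):
        if len(sources) < 2:
            raise ValueError("level 3 combines several summary-statistics sources")
        cols, meta = {}, []
        for s in sources:
            c, m = _columns_for(s, list(thresholds), _source_id(s))
            cols.update(c)
            meta.extend(m)
    elif str(level).lower() == "local":
        if len(sources) != 1:
            raise ValueError("local PRSs use exactly one summary-statistics source")
        if regions is None:
            raise ValueError("local PRSs require LD-region definitions")
        stats = sources[0]
        source = _source_id(stats)
        region_of = assign_regions(stats, regions)
        cols, meta = {}, []
        for region_id in regions["REGION_ID"]:
            sub = stats[(region_of == region_id).to_numpy()]
            if sub.empty:
                continue
            idx_set = ld_clump(sub, panel, r2_max=r2_max, window_kb=window_kb)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score, n_used = score_prs(panel, sub, idx_set, LOCAL_THRESHOLD)
            if n_used == 0:
                continue
            name = f"{source}_{region_id}"
            cols[name] = score
            meta.append(
                dict(name=name, source_id=source, p_threshold=LOCAL_THRESHOLD,
                     region_id=region_id, n_variants_used=n_used)
            )
    else:
        raise ValueError(f"unknown feature level: {level!r}")

    return FeatureTable(pd.DataFrame(cols, index=index), pd.DataFrame(meta))


def _source_id(stats: pd.DataFrame) -> str:
    vals = stats["SOURCE"].unique()
    return str(vals[0]) if len(vals) else "unknown"
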