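"""Synthetic genotypes, cohorts and discovery GWAS with block-LD structure.

The generator emulates the statistical structure the two-stage ensemble
framework assumes: a multi-population dosage panel with contiguous LD blocks,
blood-pressure phenotypes driven by covariates (optionally non-linearly) plus
a polygenic score whose effects may differ across populations, medication
masking of measured values, and independent discovery cohorts from which
marginal GWAS summary statistics are computed.

Genotypes come from a block-wise latent-Gaussian threshold model: within a
block every variant shares the block's per-population allele frequency and a
latent equicorrelation calibrated (via the tetrachoric relation) so that the
mean pairwise dosage r² matches the configured ``block_r2``; blocks are
independent.  Population allele frequencies diverge from a common anchor by a
Balding–Nichols draw with divergence ``fst``.

All structural randomness (frequencies, block layout, causal effects,
population assignment) is a deterministic function of ``config.seed``;
individual-level sampling draws from per-operation child generators, so a
discovery cohort shares the panel's structure while containing new
individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri
from scipy import stats as sps

from ._utils import bvn_cdf, child_rng, child_seed
from .prs import GenotypePanel, variant_ids
from . import gwas_io

# Self-reported group mix: fractions approximating a large multi-ethnic
# U.S. cohort (~49/23/19/7/2 percent).
DEFAULT_POPULATIONS = (
    {"label": "White", "fraction": 0.49, "fst": 0.02},
    {"label": "Black", "fraction": 0.23, "fst": 0.10},
    {"label": "Hispanic", "fraction": 0.19, "fst": 0.05},
    {"label": "Asian", "fraction": 0.07, "fst": 0.08},
    {"label": "Other", "fraction": 0.02, "fst": 0.05},
)

_BLOCK_SPAN_BP = 1_000_000
_VARIANT_SPACING_BP = 997  # prime spacing keeps positions distinct and compact


@dataclass
class CovariateEffects:
    """Linear and optional non-linear covariate effects on SBP (mmHg units).

    Defaults size the covariate-explained share of SBP variance at roughly a
    quarter to a third, matching what demographic covariates achieve in large
    blood-pressure cohorts.  ``age_bmi`` adds an age x BMI product term;
    ``age_after_60`` adds extra slope beyond age 60 (piecewise age effect).
    DBP effects are these scaled by ``dbp_factor``.
    """

    age: float = 0.45          # mmHg per year, centred at 55
    sex: float = 4.0           # male minus female
    bmi: float = 0.9           # mmHg per kg/m2, centred at 28
    age_bmi: float = 0.0       # mmHg per (year * kg/m2), both centred
    age_after_60: float = 0.0  # extra mmHg per year beyond age 60
    group_offsets: dict = field(
        default_factory=lambda: {
            "White": 0.0, "Black": 5.0, "Hispanic": 1.0, "Asian": -2.0, "Other": 1.0
        }
    )
    dbp_factor: float = 0.5


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator."""

    n_individuals: int = 5000
    n_variants: int = 500
    n_blocks: int = 50
    populations: tuple = DEFAULT_POPULATIONS
    block_r2: float = 0.5
    causal_fraction: float = 0.2
    h2_prs: float = 0.10
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    group_effect_scale: dict = field(default_factory=dict)
    effect_corr: float = 1.0   # cross-population correlation of causal effects
    residual_sd: float = 13.0  # mmHg, SBP noise; DBP uses dbp_factor * this scale
    maf_range: tuple = (0.05, 0.5)
    n_related_pairs: int = 0
    related_kinship: float = 0.25
    sbp_intercept: float = 125.0
    dbp_intercept: float = 75.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.covariate_effects, dict):
            self.covariate_effects = CovariateEffects(**self.covariate_effects)
        self.populations = tuple(dict(p) for p in self.populations)
        self.validate()

    def validate(self) -> None:
        for name in ("n_individuals", "n_variants", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_blocks > self.n_variants:
            raise ValueError("n_blocks cannot exceed n_variants")
        if not 0.0 <= self.block_r2 <= 1.0:
            raise ValueError("block_r2 must lie in [0, 1]")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in [0, 1]")
        if not 0.0 <= self.h2_prs < 1.0:
            raise ValueError("h2_prs must lie in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not 0.0 <= self.effect_corr <= 1.0:
            raise ValueError("effect_corr must lie in [0, 1]")
        fracs = [p["fraction"] for p in self.populations]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("population mixing fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-8:
            raise ValueError("population mixing fractions must sum to 1")
        if self.h2_prs > 0 and self.causal_fraction == 0:
            raise ValueError("h2_prs > 0 requires a positive causal_fraction")

    @property
    def labels(self) -> list[str]:
        return [p["label"] for p in self.populations]


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated panel + cohort.

    ``effects`` holds the realized per-allele effect sizes (mmHg) per
    population, group multipliers folded in; ``scores`` the true genetic score
    per individual; ``realized_variance`` the empirical share decomposition.
    """

    effects: pd.DataFrame          # index VID, one column per population label
    covariate_coefficients: dict
    kinship_pairs: pd.DataFrame    # id_a, id_b, kinship
    realized_variance: dict
    scores: pd.DataFrame           # individual_id, score_sbp, score_dbp
    noise_sd: dict                 # phenotype -> residual sd used
    config_echo: dict

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.effects.to_csv(path / "true_effects.tsv", sep="\t", float_format="%.17g")
        self.kinship_pairs.to_csv(path / "kinship_pairs.tsv", sep="\t", index=False)
        self.scores.to_csv(path / "true_scores.tsv", sep="\t", index=False,
                           float_format="%.17g")
        with open(path / "truth.json", "w") as fh:
            json.dump(
                {
                    "covariate_coefficients": self.covariate_coefficients,
                    "realized_variance": self.realized_variance,
                    "noise_sd": self.noise_sd,
                    "config_echo": self.config_echo,
                },
                fh, indent=1, default=float,
            )

    @classmethod
    def from_dir(cls, path) -> "SimulationTruth":
        path = Path(path)
        effects = pd.read_csv(path / "true_effects.tsv", sep="\t", index_col=0,
                              float_precision="round_trip")
        kin = pd.read_csv(path / "kinship_pairs.tsv", sep="\t")
        scores = pd.read_csv(path / "true_scores.tsv", sep="\t",
                             float_precision="round_trip")
        with open(path / "truth.json") as fh:
            extra = json.load(fh)
        return cls(
            effects=effects,
            covariate_coefficients=extra["covariate_coefficients"],
            kinship_pairs=kin,
            realized_variance=extra["realized_variance"],
            scores=scores,
            noise_sd=extra["noise_sd"],
            config_echo=extra["config_echo"],
        )


# ------------------------------------------------------------------ structure

def _indicator_corr(rho: float, h: float) -> float:
    """Correlation of two equal-threshold Bernoulli indicators under latent rho."""
    p = sps.norm.cdf(h)
    p11 = float(bvn_cdf(h, h, rho))
    return (p11 - p * p) / (p * (1.0 - p))


def _solve_latent_rho(target_r: float, h: float) -> float:
    """Latent correlation giving indicator (hence dosage) correlation target_r."""
    if target_r <= 1e-9:
        return 0.0
    f = lambda rho: _indicator_corr(rho, h) - target_r
    hi = 1.0 - 1e-9
    if f(hi) <= 0:  # unattainable; saturate
        return hi
    return brentq(f, 0.0, hi, xtol=1e-10)


_STRUCTURE_CACHE: dict[str, dict] = {}


def _structure(config: SimulationConfig) -> dict:
    """Structural parameters derived deterministically from config.seed."""
    key = json.dumps(asdict(config), sort_keys=True, default=str)
    if key in _STRUCTURE_CACHE:
        return _STRUCTURE_CACHE[key]
    rng = child_rng(config.seed, "structure")
    sizes = np.full(config.n_blocks, config.n_variants // config.n_blocks)
    sizes[: config.n_variants % config.n_blocks] += 1
    block = np.repeat(np.arange(config.n_blocks), sizes)

    pos = np.concatenate([
        b * _BLOCK_SPAN_BP + 1 + np.arange(s) * _VARIANT_SPACING_BP
        for b, s in enumerate(sizes)
    ])
    # non-ambiguous allele pairs only (A/T and C/G excluded, standard QC)
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
             ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), config.n_variants)]
    variants = pd.DataFrame({
        "CHR": "1",
        "POS": pos,
        "EA": [a for a, _ in alleles],
        "OA": [b for _, b in alleles],
        "BLOCK": block,
    })

    lo, hi = config.maf_range
    anchors = rng.uniform(lo, hi, config.n_blocks)
    freqs = {}
    for p in config.populations:
        fst = p.get("fst", 0.05)
        if fst <= 0:
            fpop = anchors.copy()
        else:
            a = anchors * (1 - fst) / fst
            b = (1 - anchors) * (1 - fst) / fst
            fpop = rng.beta(a, b)
        freqs[p["label"]] = np.clip(fpop, 0.02, 0.98)

    target_r = np.sqrt(config.block_r2)
    rho = {
        lab: np.array([_solve_latent_rho(target_r, ndtri(f[b]))
                       for b in range(config.n_blocks)])
        for lab, f in freqs.items()
    }

    n_causal = int(round(config.causal_fraction * config.n_variants))
    causal_idx = np.sort(rng.choice(config.n_variants, n_causal, replace=False))
    base_eff = rng.standard_normal(n_causal)
    effects = {}
    rc = config.effect_corr
    for p in config.populations:
        lab = p["label"]
        specific = rng.standard_normal(n_causal)
        eff = np.zeros(config.n_variants)
        eff[causal_idx] = rc * base_eff + np.sqrt(max(1 - rc**2, 0.0)) * specific
        effects[lab] = eff * config.group_effect_scale.get(lab, 1.0)

    struct = {
        "variants": variants, "sizes": sizes, "block": block,
        "freqs": freqs, "rho": rho, "effects": effects,
    }
    if len(_STRUCTURE_CACHE) > 32:
        _STRUCTURE_CACHE.clear()
    _STRUCTURE_CACHE[key] = struct
    return struct


def _assign_populations(config, n: int, rng) -> np.ndarray:
    fracs = np.array([p["fraction"] for p in config.populations])
    return rng.choice(len(fracs), size=n, p=fracs)


# ----------------------------------------------------------------- genotypes

def simulate_genotypes(
    config: SimulationConfig,
    seed: int | None = None,
    n_individuals: int | None = None,
    population: str | None = None,
) -> GenotypePanel:
    """Draw a dosage panel with the configured block-LD structure.

    ``seed`` defaults to ``config.seed`` (bit-identical rerun); ``population``
    restricts the draw to one population's allele frequencies (used for
    single-ancestry discovery cohorts).  The returned panel carries the
    per-individual population label in ``panel.populations`` and the block
    assignment in ``panel.variants["BLOCK"]``.
    """
    seed = config.seed if seed is None else seed
    n = config.n_individuals if n_individuals is None else n_individuals
    struct = _structure(config)
    rng = child_rng(seed, "genotypes", n, population or "ALL")

    if population is not None:
        if population not in config.labels:
            raise ValueError(f"unknown population label: {population!r}")
        pop_idx = np.full(n, config.labels.index(population))
    else:
        pop_idx = _assign_populations(config, n, child_rng(config.seed, "assign", n))

    dosages = np.empty((n, config.n_variants))
    for pi, p in enumerate(config.populations):
        rows = np.flatnonzero(pop_idx == pi)
        if rows.size == 0:
            continue
        lab = p["label"]
        start = 0
        for b, size in enumerate(struct["sizes"]):
            h = ndtri(struct["freqs"][lab][b])
            rho = struct["rho"][lab][b]
            shared = rng.standard_normal((rows.size, 2, 1))
            eps = rng.standard_normal((rows.size, 2, size))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
            dosages[rows, start:start + size] = (latent < h).sum(axis=1)
            start += size

    kinship_pairs = []
    if config.n_related_pairs > 0:
        phi = config.related_kinship
        cand = rng.permutation(n)[: 2 * config.n_related_pairs]
        for a, b in cand.reshape(-1, 2):
            share = rng.random(config.n_variants) < 2 * phi
            dosages[b, share] = dosages[a, share]
            kinship_pairs.append((a, b, phi))

    ids = np.array([f"ind{i:06d}" for i in range(n)])
    panel = GenotypePanel(ids, struct["variants"].copy(), dosages)
    panel.populations = np.array(config.labels)[pop_idx]
    panel.kinship_pairs = pd.DataFrame(
        [(ids[a], ids[b], k) for a, b, k in kinship_pairs],
        columns=["id_a", "id_b", "kinship"],
    )
    return panel


def ld_regions_for(config: SimulationConfig) -> pd.DataFrame:
    """LD-region definitions (BED convention) matching the simulated blocks."""
    rows = [
        ("1", b * _BLOCK_SPAN_BP, (b + 1) * _BLOCK_SPAN_BP, f"block{b:03d}")
        for b in range(config.n_blocks)
    ]
    return pd.DataFrame(rows, columns=["CHR", "START", "END", "REGION_ID"])


# -------------------------------------------------------------------- cohort

def _covariate_part(eff: CovariateEffects, age, sex_male, bmi, group) -> np.ndarray:
    a = age - 55.0
    b = bmi - 28.0
    out = (
        eff.age * a + eff.sex * sex_male + eff.bmi * b
        + eff.age_bmi * a * b + eff.age_after_60 * np.maximum(age - 60.0, 0.0)
        + np.array([eff.group_offsets.get(g, 0.0) for g in group])
    )
    return out


def simulate_cohort(
    panel: GenotypePanel,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate phenotypes and covariates for the panel's individuals.

    SBP/DBP arise as covariate function + genetic score + Gaussian noise;
    the genetic score is scaled so its realized variance share equals
    ``h2_prs``.  Medication use is assigned with probability increasing in
    the latent (untreated) SBP, and measured values of medicated individuals
    are lowered by 15 (SBP) / 10 (DBP) mmHg — the inverse of the standard
    harmonization adjustment.
    """
    seed = config.seed if seed is None else seed
    n = panel.n_individuals
    rng = child_rng(seed, "cohort")
    struct = _structure(config)
    eff = config.covariate_effects

    if hasattr(panel, "populations"):
        group = np.asarray(panel.populations)
    else:
        pop_idx = _assign_populations(config, n, child_rng(config.seed, "assign", n))
        group = np.array(config.labels)[pop_idx]

    age = rng.uniform(30, 80, n)
    sex_male = rng.random(n) < 0.45
    bmi = np.clip(rng.normal(28, 5, n), 15, None)
    # study membership loosely tracks group, emulating multi-study cohorts
    study_probs = {lab: np.roll([0.6, 0.3, 0.1], i % 3)
                   for i, lab in enumerate(config.labels)}
    study = np.array([
        rng.choice(["studyA", "studyB", "studyC"], p=study_probs[g]) for g in group
    ])

    cov_part = _covariate_part(eff, age, sex_male, bmi, group)
    var_c = float(np.var(cov_part, ddof=1))
    s2 = config.residual_sd**2

    effects = pd.DataFrame(struct["effects"], index=variant_ids(struct["variants"]))
    raw = np.zeros(n)
    for lab in config.labels:
        rows = group == lab
        if rows.any():
            raw[rows] = panel.dosages[rows] @ effects[lab].to_numpy()
    raw = raw - raw.mean()
    if config.h2_prs > 0:
        var_raw = float(np.var(raw, ddof=1))
        if var_raw <= 0:
            raise ValueError("h2_prs > 0 but the genetic score has zero variance")
        target_var_g = config.h2_prs * (var_c + s2) / (1.0 - config.h2_prs)
        scale = np.sqrt(target_var_g / var_raw)
    else:
        scale = 0.0
    score_sbp = scale * raw
    effects_scaled = effects * scale

    noise_sbp = rng.normal(0.0, config.residual_sd, n)
    sbp_latent = config.sbp_intercept + cov_part + score_sbp + noise_sbp

    # DBP: shared genetic score, covariate effects scaled by dbp_factor
    cov_part_d = eff.dbp_factor * cov_part
    var_cd = float(np.var(cov_part_d, ddof=1))
    sd_d = eff.dbp_factor * config.residual_sd
    if config.h2_prs > 0:
        target_var_gd = config.h2_prs * (var_cd + sd_d**2) / (1.0 - config.h2_prs)
        scale_d = np.sqrt(target_var_gd / float(np.var(raw, ddof=1)))
    else:
        scale_d = 0.0
    score_dbp = scale_d * raw
    noise_dbp = rng.normal(0.0, sd_d, n)
    dbp_latent = config.dbp_intercept + cov_part_d + score_dbp + noise_dbp

    med_use = rng.random(n) < 0.9 * expit((sbp_latent - 140.0) / 10.0)
    sbp = sbp_latent - np.where(med_use, 15.0, 0.0)
    dbp = dbp_latent - np.where(med_use, 10.0, 0.0)

    cohort = pd.DataFrame({
        "individual_id": [str(i) for i in panel.individual_ids],
        "age": age,
        "sex": np.where(sex_male, "male", "female"),
        "group": group,
        "study": study,
        "bmi": bmi,
        "sbp": sbp,
        "dbp": dbp,
        "med_use": med_use,
    })

    def _shares(score, cov, noise):
        tot = np.var(score + cov + noise, ddof=1)
        return {
            "covariate_share": float(np.var(cov, ddof=1) / tot),
            "genetic_share": float(np.var(score, ddof=1) / tot),
            "residual_share": float(np.var(noise, ddof=1) / tot),
        }

    truth = SimulationTruth(
        effects=effects_scaled,
        covariate_coefficients={
            "age": eff.age, "sex": eff.sex, "bmi": eff.bmi,
            "age_bmi": eff.age_bmi, "age_after_60": eff.age_after_60,
            "group_offsets": dict(eff.group_offsets),
            "dbp_factor": eff.dbp_factor,
            "sbp_intercept": config.sbp_intercept,
            "dbp_intercept": config.dbp_intercept,
        },
        kinship_pairs=getattr(
            panel, "kinship_pairs",
            pd.DataFrame(columns=["id_a", "id_b", "kinship"]),
        ),
        realized_variance={
            "sbp": _shares(score_sbp, cov_part, noise_sbp),
            "dbp": _shares(score_dbp, cov_part_d, noise_dbp),
        },
        scores=pd.DataFrame({
            "individual_id": cohort["individual_id"],
            "score_sbp": score_sbp,
            "score_dbp": score_dbp,
        }),
        noise_sd={"sbp": config.residual_sd, "dbp": sd_d,
                  "covariate_sd": {"sbp": float(np.sqrt(var_c)),
                                   "dbp": float(np.sqrt(var_cd))}},
        config_echo=asdict(config),
    )
    return cohort, truth


# ------------------------------------------------------------ discovery GWAS

def simulate_discovery_gwas(
    panel_config: SimulationConfig,
    truth: SimulationTruth,
    n_discovery: int,
    seed: int,
    phenotype: str = "sbp",
    population: str | None = None,
    mode: str = "cohort",
    source_id: str | None = None,
) -> pd.DataFrame:
    """Summary statistics from an independent discovery cohort.

    ``mode="cohort"`` (default, more faithful) simulates ``n_discovery`` new
    individuals under the panel's structural parameters and runs the marginal
    GWAS on them.  ``mode="analytic"`` samples each estimate from its exact
    sampling distribution, beta_hat ~ Normal(marginal beta, SE), with the
    marginal (LD-tagged) effect and SE computed from a moderate reference
    draw — orders of magnitude faster for very large ``n_discovery``.

    Monomorphic variants in the discovery draw are emitted with NaN estimates
    (missing flag) and excluded downstream.
    """
    if n_discovery <= 3:
        raise ValueError("n_discovery too small")
    if source_id is None:
        source_id = f"sim_gwas_{population or 'ALL'}"
    env_sd = float(np.sqrt(
        truth.noise_sd["covariate_sd"][phenotype] ** 2 + truth.noise_sd[phenotype] ** 2
    ))
    score_col = f"score_{phenotype}"

    def _scores(panel):
        group = panel.populations
        out = np.zeros(panel.n_individuals)
        eff = truth.effects
        # effects table rows align with panel variants by VID
        eff = eff.reindex(panel.variants.index)
        for lab in eff.columns:
            rows = group == lab
            if rows.any():
                out[rows] = panel.dosages[rows] @ eff[lab].to_numpy()
        # rescale SBP-scaled effects to the requested phenotype
        if score_col == "score_dbp":
            ref = truth.scores
            num = float(np.std(ref["score_dbp"], ddof=1))
            den = float(np.std(ref["score_sbp"], ddof=1))
            out = out * (num / den if den > 0 else 0.0)
        return out

    if mode == "cohort":
        panel = simulate_genotypes(
            panel_config, seed=child_seed(seed, "discovery", source_id),
            n_individuals=n_discovery, population=population,
        )
        rng = child_rng(seed, "discovery-noise", source_id)
        y = _scores(panel) + rng.normal(0.0, env_sd, n_discovery)
        stats = gwas_io.run_marginal_gwas(panel, y, source_id=source_id)
        return stats
    elif mode == "analytic":
        n_ref = min(4000, max(2000, n_discovery))
        panel = simulate_genotypes(
            panel_config, seed=child_seed(seed, "discovery-ref", source_id),
            n_individuals=n_ref, population=population,
        )
        g = panel.dosages
        score = _scores(panel)
        var_g = g.var(axis=0, ddof=1)
        mono = var_g <= 1e-12
        var_g_safe = np.where(mono, 1.0, var_g)
        gc = g - g.mean(axis=0)
        beta_marg = (gc.T @ (score - score.mean())) / ((n_ref - 1) * var_g_safe)
        var_y = float(np.var(score, ddof=1)) + env_sd**2
        resid_var = np.maximum(var_y - beta_marg**2 * var_g_safe, 1e-12)
        se = np.sqrt(resid_var / (n_discovery * var_g_safe))
        rng = child_rng(seed, "discovery-analytic", source_id)
        beta_hat = rng.normal(beta_marg, se)
        p = np.clip(2.0 * sps.norm.sf(np.abs(beta_hat / se)), np.finfo(float).tiny, 1.0)
        beta_hat[mono] = np.nan
        se_out = np.where(mono, np.nan, se)
        p = np.where(mono, np.nan, p)
        out = panel.variants[["CHR", "POS", "EA", "OA"]].copy().reset_index(drop=True)
        out["BETA"] = beta_hat
        out["SE"] = se_out
        out["P"] = p
        out["N"] = n_discovery
        out["SOURCE"] = source_id
        out.attrs["n_monomorphic"] = int(mono.sum())
        return out
    raise ValueError(f"unknown mode: {mode!r}")
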