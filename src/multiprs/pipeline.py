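"""Configuration-driven end-to-end orchestration of the ensemble workflow.

A single experiment runs: simulate (or load) inputs -> phenotype
harmonization -> relatedness and MAF filtering -> 70/30 train/test split ->
PRS feature construction at the configured complexity level -> baseline fit
(K-fold CV tuning) -> residuals -> genetic fit (with a LASSO selection stage
for local PRSs) -> bootstrap PVE evaluation, overall and stratified.  Every
run writes a manifest (config echo, derived seeds, versions) sufficient to
re-run it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import child_seed
from . import cohort as cohort_mod
from . import ensemble as ens
from . import evaluate as ev
from . import gwas_io
from . import prs as prs_mod
from . import simdata

logger = logging.getLogger(__name__)

STAGES = (
    "inputs", "harmonize", "relatedness", "maf_filter", "split",
    "features", "baseline", "genetic", "evaluate", "write",
)


class StageError(RuntimeError):
    """Failure wrapped with the pipeline stage name and a machine-readable code."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.code = STAGES.index(stage) + 10
        super().__init__(f"[stage={stage} code={self.code}] {original}")


@dataclass
class DiscoverySource:
    source_id: str
    population: str | None = None
    n_discovery: int = 20000
    mode: str = "cohort"


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    phenotype: str = "sbp"
    level: object = 3
    baseline_engine: str = "gbt"
    genetic_engine: str = "gbt"
    thresholds: tuple = prs_mod.DEFAULT_THRESHOLDS
    train_fraction: float = 0.7
    cv_folds: int = 5
    n_trials: int = ens.DEFAULT_N_TRIALS
    bootstrap_reps: int = 100
    min_maf: float = 0.01
    kinship_threshold: float = cohort_mod.DEGREE3_KINSHIP
    seed: int = 0
    simulation: simdata.SimulationConfig | None = None
    discovery: list = field(default_factory=list)
    # alternatively, paths to user data
    cohort_path: str | None = None
    dosage_path: str | None = None
    sumstats_paths: list = field(default_factory=list)
    ld_regions_path: str | None = None
    kinship_path: str | None = None

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = simdata.SimulationConfig(**self.simulation)
        self.discovery = [
            DiscoverySource(**d) if isinstance(d, dict) else d for d in self.discovery
        ]
        sim_mode = self.simulation is not None
        path_mode = self.cohort_path is not None
        if sim_mode == path_mode:
            raise ValueError(
                "configure exactly one input mode: a simulation block or data paths"
            )
        if not self.discovery and sim_mode:
            # one predominantly-European source plus two complementary ones
            self.discovery = [
                DiscoverySource("sim_ukbb_icbp", "White", 50000),
                DiscoverySource("sim_mvp", None, 20000),
                DiscoverySource("sim_bbj", "Asian", 20000),
            ]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _load_inputs(config: ExperimentConfig):
    if config.simulation is not None:
        sim = config.simulation
        panel = simdata.simulate_genotypes(sim)
        cohort, truth = simdata.simulate_cohort(panel, sim)
        kinship = truth.kinship_pairs
        regions = simdata.ld_regions_for(sim)
        n_sources = {1: 1, 2: 1, "local": 1}.get(config.level, 3)
        sources = [
            simdata.simulate_discovery_gwas(
                sim, truth, d.n_discovery,
                seed=child_seed(config.seed, "discovery", d.source_id),
                phenotype=config.phenotype, population=d.population,
                mode=d.mode, source_id=d.source_id,
            )
            for d in config.discovery[:n_sources]
        ]
        return panel, cohort, kinship, sources, regions, truth
    panel = prs_mod.GenotypePanel.from_tsv(config.dosage_path)
    cohort = pd.read_csv(config.cohort_path)
    kinship = (
        pd.read_csv(config.kinship_path, sep="\t")
        if config.kinship_path else pd.DataFrame(columns=["id_a", "id_b", "kinship"])
    )
    sources = [gwas_io.read_summary_stats(p) for p in config.sumstats_paths]
    regions = (
        gwas_io.read_ld_regions(config.ld_regions_path)
        if config.ld_regions_path else None
    )
    return panel, cohort, kinship, sources, regions, None


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Execute the full workflow; returns a result bundle and writes artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []

    def _stage(name):
        def deco(fn):
            start = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage info
                raise StageError(name, exc) from exc
            log.append({"stage": name, "seconds": round(time.time() - start, 3)})
            return result
        return deco

    panel, cohort, kinship, sources, regions, truth = _stage("inputs")(
        lambda: _load_inputs(config)
    )
    log[-1]["n_individuals"] = panel.n_individuals
    log[-1]["n_variants"] = panel.n_variants

    harmonized, removal_report = _stage("harmonize")(
        lambda: cohort_mod.harmonize_phenotypes(cohort)
    )
    harmonized = _stage("relatedness")(
        lambda: cohort_mod.filter_unrelated(harmonized, kinship, config.kinship_threshold)
    )
    panel2 = _stage("maf_filter")(
        lambda: prs_mod.filter_variants(
            panel.subset_individuals(harmonized["individual_id"]), config.min_maf
        )
    )
    train, test = _stage("split")(
        lambda: cohort_mod.split_train_test(
            harmonized, config.train_fraction, seed=child_seed(config.seed, "split")
        )
    )

    def _features():
        harm_sources = [
            gwas_io.harmonize_alleles(s, panel2.variants) for s in sources
        ]
        return prs_mod.build_feature_table(
            panel2, harm_sources, config.level,
            thresholds=config.thresholds, regions=regions,
        )

    features = _stage("features")(_features)
    log[-1]["n_prs_columns"] = len(features.columns)

    def _rows(tbl, ids):
        idx = pd.Index(tbl.scores.index).get_indexer([str(i) for i in ids])
        return prs_mod.FeatureTable(tbl.scores.iloc[idx], tbl.meta)

    baseline = _stage("baseline")(
        lambda: ens.fit_baseline(
            train, config.phenotype, engine=config.baseline_engine,
            cv_folds=config.cv_folds, seed=child_seed(config.seed, "baseline"),
            n_trials=config.n_trials,
        )
    )

    def _genetic():
        resid = ens.compute_residuals(baseline, train)
        feats_train = _rows(features, train["individual_id"])
        if str(config.level).lower() == "local":
            selected, lasso_model = ens.select_local_lasso(
                resid, feats_train, cv_folds=config.cv_folds,
                seed=child_seed(config.seed, "lasso"),
            )
            model = ens.fit_genetic(
                train, resid, selected, engine=config.genetic_engine,
                cv_folds=config.cv_folds, seed=child_seed(config.seed, "genetic"),
                n_trials=config.n_trials,
            )
            return model, selected.meta, lasso_model
        model = ens.fit_genetic(
            train, resid, feats_train, engine=config.genetic_engine,
            cv_folds=config.cv_folds, seed=child_seed(config.seed, "genetic"),
            n_trials=config.n_trials,
        )
        return model, features.meta, None

    genetic, used_meta, lasso_model = _stage("genetic")(_genetic)
    genetic.phenotype = config.phenotype
    model = ens.EnsembleModel(
        baseline, genetic,
        provenance={"seed": config.seed, "level": str(config.level)},
    )

    def _evaluate():
        feats_test = _rows(features, test["individual_id"])
        if len(used_meta) != len(features.meta):
            feats_test = feats_test.select(list(used_meta["name"]))
        overall = [
            ev.bootstrap_pve(
                test, feats_test, model, level, reps=config.bootstrap_reps,
                seed=child_seed(config.seed, "bootstrap"), phenotype=config.phenotype,
            )
            for level in ev.PVE_LEVELS
        ]
        stratified = ev.evaluate_stratified(
            test, feats_test, model, strata="group", reps=config.bootstrap_reps,
            seed=child_seed(config.seed, "bootstrap"), phenotype=config.phenotype,
        )
        return overall, stratified

    overall, stratified = _stage("evaluate")(_evaluate)

    def _write():
        features.to_tsv(out_dir / "features.tsv", out_dir / "features_meta.json")
        ev.results_table(overall).to_csv(
            out_dir / "pve_overall.tsv", sep="\t", index=False, float_format="%.10g"
        )
        ev.results_table(stratified).to_csv(
            out_dir / "pve_stratified.tsv", sep="\t", index=False, float_format="%.10g"
        )
        ens.save_bundle(model, out_dir / "model.bundle.json")
        manifest = {
            "config": _plain(dataclasses.asdict(config)),
            "seeds": {
                tag: child_seed(config.seed, tag)
                for tag in ("split", "baseline", "genetic", "lasso", "bootstrap")
            },
            "versions": _versions(),
            "stage_log": log,
            "removal_report": removal_report,
            "n_prs_columns": len(features.columns),
            "feature_meta": features.meta.to_dict(orient="records"),
            "runtime_seconds": round(time.time() - t0, 3),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest

    manifest = _stage("write")(_write)
    return {
        "model": model,
        "features": features,
        "overall": overall,
        "stratified": stratified,
        "manifest": manifest,
        "truth": truth,
        "lasso_model": lasso_model,
        "test": test,
        "train": train,
    }


def _versions() -> dict:
    import sklearn
    import xgboost

    from . import __version__

    return {
        "multiprs": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }
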