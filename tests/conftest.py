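"""Shared fixtures and small independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from multiprs.prs import GenotypePanel
from multiprs.simdata import SimulationConfig, simulate_cohort, simulate_genotypes

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=600, n_variants=60, n_blocks=6, block_r2=0.6, seed=7
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    return simulate_genotypes(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_panel):
    cohort, truth = simulate_cohort(tiny_panel, tiny_config)
    return cohort, truth


def make_sumstats(
    chrom="1", pos=None, ea=None, oa=None, beta=None, se=None, p=None,
    n=10000, source="test",
) -> pd.DataFrame:
    """Hand-rolled summary-statistics frame in the canonical dialect."""
    m = len(beta)
    return pd.DataFrame({
        "CHR": [chrom] * m,
        "POS": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "EA": ea if ea is not None else ["A"] * m,
        "OA": oa if oa is not None else ["G"] * m,
        "BETA": np.asarray(beta, dtype=float),
        "SE": np.asarray(se if se is not None else np.ones(m), dtype=float),
        "P": np.asarray(p if p is not None else np.full(m, 0.5), dtype=float),
        "N": n,
        "SOURCE": source,
    })


def make_panel(dosages, chrom="1", pos=None, ea=None, oa=None) -> GenotypePanel:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "CHR": [chrom] * m,
        "POS": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "EA": ea if ea is not None else ["A"] * m,
        "OA": oa if oa is not None else ["G"] * m,
    })
    return GenotypePanel(np.array([f"i{k}" for k in range(n)]), variants, dosages)


def brute_force_clump(stats: pd.DataFrame, panel: GenotypePanel,
                      r2_max: float, window_kb: float) -> list[str]:
    """Reference greedy clumping: explicit loops, pandas-free bookkeeping."""
    from multiprs.prs import variant_ids

    rows = stats.copy()
    rows["VID"] = variant_ids(stats)
    rows = rows[rows["VID"].isin(panel.variants.index) & rows["BETA"].notna()]
    remaining = rows.sort_values(["P", "CHR", "POS"], kind="mergesort").to_dict("records")
    picked = []
    while remaining:
        idx = remaining.pop(0)
        picked.append(idx["VID"])
        survivors = []
        for cand in remaining:
            if cand["CHR"] == idx["CHR"] and abs(cand["POS"] - idx["POS"]) <= window_kb * 1000:
                a = panel.dosages[:, panel.variants.index.get_loc(idx["VID"])]
                b = panel.dosages[:, panel.variants.index.get_loc(cand["VID"])]
                if np.std(a) > 0 and np.std(b) > 0:
                    r2 = np.corrcoef(a, b)[0, 1] ** 2
                else:
                    r2 = 0.0
                if r2 >= r2_max:
                    continue
            survivors.append(cand)
        remaining = survivors
    return picked


def meta_oracle(studies: list[pd.DataFrame]) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effects meta-analysis by direct per-variant loops (oracle)."""
    m = len(studies[0])
    betas = np.empty(m)
    ses = np.empty(m)
    for j in range(m):
        w = np.array([1.0 / s["SE"].iloc[j] ** 2 for s in studies])
        b = np.array([s["BETA"].iloc[j] for s in studies])
        betas[j] = np.sum(w * b) / np.sum(w)
        ses[j] = np.sqrt(1.0 / np.sum(w))
    return betas, ses


def random_ld_panel(rng, n=120, max_variants=50) -> GenotypePanel:
    """Random panel with haphazard LD: mixtures of shared latent signals."""
    m = int(rng.integers(4, max_variants + 1))
    n_latent = max(2, m // 3)
    latent = rng.standard_normal((n, n_latent))
    load = rng.uniform(0.0, 1.0, m)
    src = rng.integers(0, n_latent, m)
    freqs = rng.uniform(0.1, 0.9, m)
    from scipy.special import ndtri

    dosages = np.empty((n, m))
    for hap in range(2):
        eps = rng.standard_normal((n, m))
        z = load * latent[:, src] + np.sqrt(1 - load**2) * eps
        alleles = z < ndtri(freqs)
        dosages = alleles.astype(float) if hap == 0 else dosages + alleles
    pos = np.sort(rng.choice(np.arange(1, 3_000_000, 500), m, replace=False))
    return make_panel(dosages, pos=pos)
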