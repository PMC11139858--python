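"""Shared numerical helpers: seeded RNG spawning and bivariate-normal orthant mass."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.special import ndtr, owens_t


def child_rng(seed: int, *tags: object) -> np.random.Generator:
    """Derive an independent, reproducible generator from ``seed`` and a tag path.

    Tags are hashed with CRC32 so the same (seed, tags) pair always maps to the
    same stream regardless of call order elsewhere in the program.
    """
    keys = tuple(zlib.crc32(str(t).encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))


def child_seed(seed: int, *tags: object) -> int:
    """A plain integer seed (< 2**31) derived from ``seed`` and a tag path."""
    return int(child_rng(seed, *tags).integers(0, 2**31 - 1))


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorised Owen's-T identity; |rho| must be < 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12:
        rho = np.sign(rho) * (1.0 - 1e-12)
    # avoid division by zero at h == 0 / k == 0; error is O(eps)
    eps = 1e-12
    hs = np.where(np.abs(h) < eps, eps, h)
    ks = np.where(np.abs(k) < eps, eps, k)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (ks - rho * hs) / (hs * denom)
    a_k = (hs - rho * ks) / (ks * denom)
    result = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hs, a_h) - owens_t(ks, a_k)
    beta = np.where((hs * ks > 0) | ((hs * ks == 0) & (hs + ks >= 0)), 0.0, 0.5)
    return np.clip(result - beta, 0.0, 1.0)
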