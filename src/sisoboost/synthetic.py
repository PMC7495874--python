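"""Seeded generators for labelled feature tables and manifold fixtures.

``make_benchmark_mimic`` emulates a two-class interface-residue benchmark:
train 62 positives / 88 negatives, test 26/38, 114 features arranged in
four correlated blocks with the class signal confined to a few informative
directions.  ``make_swiss_roll`` provides a labelled Swiss roll whose
intrinsic (unrolled) coordinates are returned for geodesic oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .manifold import FeatureTable


@dataclass
class BlobSpec:
    n_pos: int = 62
    n_neg: int = 88
    n_pos_test: int = 26
    n_neg_test: int = 38
    dim: int = 114
    separation: float = 4.0
    n_informative: int = 10
    block_structure: int = 4
    block_corr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.dim:
            raise ValueError("n_informative cannot exceed dim")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")


@dataclass
class SwissRollSpec:
    n: int = 800
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _block_cholesky(dim: int, n_blocks: int, corr: float) -> np.ndarray:
    """Cholesky factor of a block covariance: ``corr`` within blocks of
    near-equal size, 0 across blocks, unit variances."""
    cov = np.zeros((dim, dim))
    bounds = np.linspace(0, dim, n_blocks + 1).astype(int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        cov[a:b, a:b] = corr
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def _sample_split(
    rng: np.random.Generator,
    n_pos: int,
    n_neg: int,
    shift: np.ndarray,
    chol: np.ndarray,
    rotation: np.ndarray,
    prefix: str,
) -> FeatureTable:
    n = n_pos + n_neg
    dim = shift.size
    y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    Z = rng.standard_normal((n, dim)) @ chol.T
    Z[y == 1] += shift
    X = Z @ rotation
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    return FeatureTable(ids=ids, X=X, y=y)


def make_benchmark_mimic(spec: BlobSpec | None = None) -> tuple[FeatureTable, FeatureTable]:
    """Deterministic (per seed) train/test pair of labelled blob tables.

    The positive class is shifted by ``separation`` (in within-class sd
    units) along a direction supported on ``n_informative`` coordinates;
    features are then mixed by a random rotation so the signal is spread
    across columns.
    """
    spec = spec or BlobSpec()
    rng = np.random.default_rng(spec.seed)
    chol = _block_cholesky(spec.dim, spec.block_structure, spec.block_corr)

    direction = np.zeros(spec.dim)
    support = rng.choice(spec.dim, size=spec.n_informative, replace=False)
    raw = rng.standard_normal(spec.n_informative)
    direction[support] = raw / np.linalg.norm(raw)
    shift = spec.separation * direction

    # random orthogonal matrix via QR with sign fix
    q, r = np.linalg.qr(rng.standard_normal((spec.dim, spec.dim)))
    rotation = q * np.sign(np.diag(r))

    train = _sample_split(rng, spec.n_pos, spec.n_neg, shift, chol, rotation, "tr")
    test = _sample_split(
        rng, spec.n_pos_test, spec.n_neg_test, shift, chol, rotation, "te"
    )
    return train, test


def make_swiss_roll(spec: SwissRollSpec | None = None) -> tuple[FeatureTable, np.ndarray]:
    """3-D Swiss roll with its intrinsic 2-D parameterisation.

    Points lie on ``(t cos t, h, t sin t)`` for ``t in [1.5pi, 4.5pi]``;
    intrinsic coordinates are (arc length along the spiral, height), so
    intrinsic pairwise distances are Euclidean in that plane.  Binary
    labels threshold ``t`` at its midpoint.
    """
    spec = spec or SwissRollSpec()
    rng = np.random.default_rng(spec.seed)
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.random(spec.n))
    height = 21.0 * rng.random(spec.n)
    X = np.column_stack([t * np.cos(t), height, t * np.sin(t)])
    if spec.noise_sd > 0:
        X = X + rng.normal(scale=spec.noise_sd, size=X.shape)
    # arc length of r = t spiral: s(t) = (t*sqrt(1+t^2) + asinh(t)) / 2
    arclen = 0.5 * (t * np.sqrt(1.0 + t ** 2) + np.arcsinh(t))
    intrinsic = np.column_stack([arclen, height])
    y = (t > 3.0 * np.pi).astype(int)
    ids = [f"sr{i:04d}" for i in range(spec.n)]
    return FeatureTable(ids=ids, X=X, y=y), intrinsic
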