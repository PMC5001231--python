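"""Synthetic perfectly co-expressed modules and the two benchmark studies.

The generator builds an n × N matrix whose rows are affine transforms of a
single base profile: the base row is drawn U(0,1)^N, and every other row is
α·base + β with α, β ~ U(0,1). Every pairwise Pearson correlation then has
absolute value 1, the raw matrix has rank 2, and its centered/standardized
form has rank 1 — the ideal that CCI and R12 score against. Two studies
probe how the indices degrade away from that ideal:

* a **noise sweep** adds i.i.d. Gaussian noise at a grid of σ levels and
  records CCI together with R_F, the relative Frobenius distance between the
  noisy and clean transformed matrices;
* a **robustness comparison** pits CCI against correlation density while
  either appending independently generated outlier rows or stacking a second,
  independently correlated (interfering) module of growing size.

Both emit tidy tables, one row per (level, repetition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import cci_value, density, transform
from .containers import ExpressionMatrix, GeneModule
from .exceptions import CCIError

__all__ = [
    "NOISE_SIGMA_GRID",
    "ROBUSTNESS_SIGMAS",
    "SimulationConfig",
    "make_correlated_matrix",
    "add_gaussian_noise",
    "frobenius_deviation_ratio",
    "add_outlier_rows",
    "make_interfering_modules",
    "run_noise_sweep",
    "run_robustness_comparison",
    "make_two_condition_study",
]

#: Noise levels of the sweep (standard deviation of the added Gaussian noise).
NOISE_SIGMA_GRID = (0.01, 0.02, 0.05, 0.07, 0.1, 0.15, 0.2, 0.3, 0.5, 1.0)

#: The two noise levels at which the CCI-vs-density comparison is run.
ROBUSTNESS_SIGMAS = (0.05, 0.2)

# Scale factors below this are redrawn: a row with a vanishing scale is
# numerically constant and its standardized form is dominated by float
# rounding, which inflates the numerical rank of an otherwise rank-1 matrix.
MIN_SCALE = 1e-2


@dataclass
class SimulationConfig:
    """Knobs of the benchmark studies; defaults are the standard conditions."""

    n_rows: int = 50
    n_cols: int = 100
    noise_sigma: float = 0.0
    n_outliers: int = 0
    interfering_size: int = 0
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 3:
            raise CCIError("need n_rows >= 2 and n_cols >= 3")
        if self.noise_sigma < 0 or self.n_outliers < 0 or self.interfering_size < 0:
            raise CCIError("noise_sigma, n_outliers, interfering_size must be >= 0")
        if self.n_reps < 1:
            raise CCIError("n_reps must be >= 1")


def _uniform_scale(rng: np.random.Generator) -> float:
    a = rng.uniform(0.0, 1.0)
    while a < MIN_SCALE:
        a = rng.uniform(0.0, 1.0)
    return a


def make_correlated_matrix(n: int, N: int, rng: np.random.Generator) -> np.ndarray:
    """n × N matrix with every pairwise |Pearson correlation| equal to 1.

    Row 1 is the base profile U(0,1)^N; row i (i > 1) is α_i·base + β_i with
    α_i, β_i ~ U(0,1) (α redrawn below ``MIN_SCALE``, see module notes).
    """
    if n < 2 or N < 3:
        raise CCIError("need n >= 2 and N >= 3")
    base = rng.uniform(0.0, 1.0, size=N)
    G = np.empty((n, N))
    G[0] = base
    for i in range(1, n):
        alpha = _uniform_scale(rng)
        beta = rng.uniform(0.0, 1.0)
        G[i] = alpha * base + beta
    return G


def add_gaussian_noise(matrix, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise with standard deviation sigma."""
    if sigma < 0:
        raise CCIError(f"sigma must be >= 0, got {sigma}")
    X = np.asarray(matrix, dtype=float)
    if sigma == 0.0:
        return X.copy()
    return X + rng.normal(0.0, sigma, size=X.shape)


def frobenius_deviation_ratio(noisy_matrix, clean_matrix) -> float:
    """R_F = ‖Ĝ_noisy − Ĝ‖_F / ‖Ĝ‖_F on the centered, standardized forms."""
    A = np.asarray(noisy_matrix, dtype=float)
    B = np.asarray(clean_matrix, dtype=float)
    if A.shape != B.shape:
        raise CCIError(f"shape mismatch: {A.shape} vs {B.shape}")
    Ah, Bh = transform(A), transform(B)
    return float(np.linalg.norm(Ah - Bh) / np.linalg.norm(Bh))


def add_outlier_rows(matrix, k: int, rng: np.random.Generator) -> np.ndarray:
    """Append k independently generated U(0,1)^N rows (uncorrelated outliers)."""
    if k < 0:
        raise CCIError(f"k must be >= 0, got {k}")
    X = np.asarray(matrix, dtype=float)
    if k == 0:
        return X.copy()
    return np.vstack([X, rng.uniform(0.0, 1.0, size=(k, X.shape[1]))])


def make_interfering_modules(
    n1: int, n2: int, N: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Stack two independently generated correlated blocks (n1 then n2 rows).

    Each block is a fresh correlated matrix with Gaussian noise at ``sigma``;
    correlations across the two blocks are whatever the two random base
    profiles happen to share. ``n2 = 0`` reduces to a single module.
    """
    if n1 < 2 or (n2 != 0 and n2 < 2):
        raise CCIError("block sizes must be >= 2 (n2 may be 0)")
    block1 = add_gaussian_noise(make_correlated_matrix(n1, N, rng), sigma, rng)
    if n2 == 0:
        return block1
    block2 = add_gaussian_noise(make_correlated_matrix(n2, N, rng), sigma, rng)
    return np.vstack([block1, block2])


def run_noise_sweep(
    config: SimulationConfig | None = None,
    sigma_grid=NOISE_SIGMA_GRID,
) -> pd.DataFrame:
    """CCI and R_F across the noise grid.

    For every σ and every repetition a fresh correlated matrix is generated,
    noise added, and both the CCI of the noisy matrix and its R_F against
    the clean matrix recorded.

    Returns
    -------
    DataFrame with columns (sigma, rep, cci, r_f), one row per repetition.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sigma in sigma_grid:
        for rep in range(cfg.n_reps):
            clean = make_correlated_matrix(cfg.n_rows, cfg.n_cols, rng)
            noisy = add_gaussian_noise(clean, sigma, rng)
            rows.append(
                (sigma, rep, cci_value(noisy), frobenius_deviation_ratio(noisy, clean))
            )
    return pd.DataFrame(rows, columns=["sigma", "rep", "cci", "r_f"])


def _default_level_grid(n1: int) -> tuple[int, ...]:
    return tuple(range(0, n1 + 1, 5))


def run_robustness_comparison(
    config: SimulationConfig | None = None,
    scenario: str = "outliers",
    level_grid=None,
    sigmas=ROBUSTNESS_SIGMAS,
) -> pd.DataFrame:
    """CCI vs density under outliers or an interfering module.

    ``scenario="outliers"`` sweeps the number of appended independent rows;
    ``scenario="interference"`` sweeps the size of a second correlated block.
    Within a repetition the same module (and the same outlier/interference
    pool) is reused across levels, and the normalized columns divide each
    repetition's trajectory by its own level-0 value, so normalized values
    start at exactly 1 and the across-repetition spread at each level
    reflects metric stability, not baseline variation.

    Returns
    -------
    DataFrame with columns
    (scenario, sigma, level, rep, cci, density, cci_normalized, density_normalized).
    """
    if scenario not in ("outliers", "interference"):
        raise CCIError(f"scenario must be 'outliers' or 'interference', got {scenario!r}")
    cfg = config or SimulationConfig(n_reps=100)
    levels = tuple(level_grid) if level_grid is not None else _default_level_grid(cfg.n_rows)
    if levels[0] != 0:
        raise CCIError("level grid must start at 0 (the normalization baseline)")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    kmax = max(levels)
    for sigma in sigmas:
        for rep in range(cfg.n_reps):
            module = add_gaussian_noise(
                make_correlated_matrix(cfg.n_rows, cfg.n_cols, rng), sigma, rng
            )
            if scenario == "outliers":
                pool = rng.uniform(0.0, 1.0, size=(kmax, cfg.n_cols))
            else:
                pool = add_gaussian_noise(
                    make_correlated_matrix(max(kmax, 2), cfg.n_cols, rng), sigma, rng
                )
            base_cci = base_den = None
            for k in levels:
                X = module if k == 0 else np.vstack([module, pool[:k]])
                c, d = cci_value(X), density(X)
                if k == 0:
                    base_cci, base_den = c, d
                rows.append(
                    (scenario, sigma, k, rep, c, d, c / base_cci, d / base_den)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "sigma", "level", "rep",
            "cci", "density", "cci_normalized", "density_normalized",
        ],
    )


def make_two_condition_study(
    seed: int,
    n_modules_specific: int = 10,
    n_modules_shared: int = 10,
    module_size: int = 20,
    n_background: int = 200,
    n_samples: int = 40,
    sigma: float = 0.05,
) -> tuple[list[GeneModule], ExpressionMatrix, ExpressionMatrix]:
    """Two-condition genomes with planted co-expressed blocks.

    The first ``n_modules_specific`` gene blocks are co-expressed (correlated
    block + Gaussian noise at ``sigma``) in condition A only; the next
    ``n_modules_shared`` blocks are co-expressed in both conditions; the
    remaining ``n_background`` genes are i.i.d. U(0,1) noise everywhere. The
    two conditions have independent sample sets of equal size.

    Returns
    -------
    (modules, expr_a, expr_b) — one :class:`GeneModule` per planted block.
    """
    rng = np.random.default_rng(seed)
    n_blocks = n_modules_specific + n_modules_shared
    n_genes = n_blocks * module_size + n_background
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]

    def build(correlated_blocks, prefix):
        values = rng.uniform(0.0, 1.0, size=(n_genes, n_samples))
        for b in correlated_blocks:
            rows = slice(b * module_size, (b + 1) * module_size)
            block = make_correlated_matrix(module_size, n_samples, rng)
            values[rows] = add_gaussian_noise(block, sigma, rng)
        return ExpressionMatrix(values, gene_ids,
                                [f"{prefix}{j:03d}" for j in range(n_samples)])

    expr_a = build(range(n_blocks), "a")
    expr_b = build(range(n_modules_specific, n_blocks), "b")
    modules = [
        GeneModule(name=f"mod{b:02d}",
                   genes=tuple(gene_ids[b * module_size:(b + 1) * module_size]))
        for b in range(n_blocks)
    ]
    return modules, expr_a, expr_b
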