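"""Null models for a module's CCI.

Two complementary nulls:

* **Within-row permutation**: shuffle every row of the module matrix
  independently, destroying cross-gene correlation while keeping each gene's
  value distribution; ``p_permute`` is the fraction of M permuted CCIs that
  meet or exceed the observed one.
* **Random gene sets**: draw n genes uniformly from the whole expression
  matrix M times and score each draw; the observed CCI is reported as a
  z-score against the mean and standard deviation of these draws. The
  random-set CCI distribution is bell-shaped in practice, and z-scores remain
  comparable across conditions, which makes this the preferred significance
  measure; the permutation null sits far below it on real-structured data and
  mostly certifies that the observed value is not a data-distribution
  artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .concordance import cci_value
from .containers import ExpressionMatrix
from .exceptions import CCIError, UndefinedStatisticError

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "ZScoreResult",
    "permute_within_rows",
    "permutation_pvalue",
    "sample_random_module_null",
    "cci_zscore",
    "bonferroni_z_threshold",
]


@dataclass(frozen=True)
class NullDistribution:
    """M resampled statistic values plus their summary.

    ``std`` is the sample standard deviation (ddof=1); with M < 2 it is 0.
    """

    kind: str  # "permutation" | "random_geneset"
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise CCIError("null distribution needs a 1-D array of >= 1 values")

    @property
    def M(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        if self.M < 2 or np.ptp(self.values) == 0.0:
            # identical draws (e.g. sampling the whole gene universe)
            return 0.0
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class ZScoreResult:
    """Observed CCI standardized against a random-gene-set null."""

    observed_cci: float
    z: float
    null: NullDistribution
    p_one_tail: float


def permute_within_rows(matrix, rng: np.random.Generator) -> np.ndarray:
    """Permute the entries of every row independently (columns decoupled)."""
    X = np.asarray(matrix, dtype=float)
    return rng.permuted(X, axis=1)


def permutation_pvalue(
    module_matrix, M: int, rng: np.random.Generator
) -> tuple[float, NullDistribution]:
    """Permutation p-value for a module's CCI.

    p = #(CCI_p >= CCI)/M with no pseudocount, so p = 0 is possible; the
    smallest resolvable nonzero p is 1/M.
    """
    if M < 1:
        raise CCIError(f"M must be >= 1, got {M}")
    X = np.asarray(module_matrix, dtype=float)
    observed = cci_value(X)
    null = np.empty(M)
    for m in range(M):
        null[m] = cci_value(permute_within_rows(X, rng))
    p = float(np.count_nonzero(null >= observed) / M)
    return p, NullDistribution(kind="permutation", values=null)


def sample_random_module_null(
    genome: ExpressionMatrix, n: int, M: int, rng: np.random.Generator
) -> NullDistribution:
    """CCI null from M random n-gene sets drawn from the whole matrix.

    Each repetition draws n distinct genes uniformly (a fresh draw every
    time; sets may overlap each other or any tested module). Genes that are
    constant across samples are excluded from the sampling frame, since
    their rows cannot be standardized.
    """
    if M < 2:
        raise CCIError(f"M must be >= 2 for a usable null, got {M}")
    valid = np.flatnonzero(~genome.constant_gene_mask())
    n_dropped = genome.n_genes - valid.size
    if n_dropped:
        logger.warning("excluding %d constant gene(s) from the sampling frame", n_dropped)
    if n > valid.size:
        raise CCIError(
            f"cannot sample {n} genes: only {valid.size} non-constant genes available"
        )
    values = np.empty(M)
    V = genome.values
    for m in range(M):
        idx = rng.choice(valid, size=n, replace=False)
        values[m] = cci_value(V[idx])
    return NullDistribution(kind="random_geneset", values=values)


def cci_zscore(observed_cci: float, null: NullDistribution) -> ZScoreResult:
    """Standardize an observed CCI against a null distribution.

    z = (observed − null mean)/null sd; the one-tail p is the standard
    normal upper tail of z, relying on the null's bell shape.
    """
    sd = null.std
    # CCI is O(1); spread at float-rounding scale means every draw was the
    # same gene set up to row order
    if sd <= 1e-12:
        raise UndefinedStatisticError(
            "null distribution has zero spread; z-score is undefined "
            "(did every draw return the same gene set?)"
        )
    z = (observed_cci - null.mean) / sd
    return ZScoreResult(
        observed_cci=float(observed_cci),
        z=float(z),
        null=null,
        p_one_tail=float(stats.norm.sf(z)),
    )


def bonferroni_z_threshold(alpha: float, m_tests: int) -> float:
    """Upper-tail normal quantile at alpha/m_tests.

    A module is called significant when its z-score reaches this threshold
    τ, which controls the family-wise one-tail error at ``alpha`` over
    ``m_tests`` modules.
    """
    if not 0.0 < alpha < 1.0:
        raise CCIError(f"alpha must be in (0, 1), got {alpha}")
    if m_tests < 1:
        raise CCIError(f"m_tests must be >= 1, got {m_tests}")
    return float(stats.norm.isf(alpha / m_tests))
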