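"""SVD-based concordance statistics for co-expressed gene modules.

A module of n genes measured over N samples is concordant when its rows are
mutually linearly correlated. If every pairwise Pearson correlation has
absolute value 1, each row is an affine transform of a common base profile,
so the raw matrix G has rank at most 2; after centering each row to mean 0
and scaling it to unit norm, the transformed matrix Ĝ has rank exactly 1 and
its squared Frobenius norm equals n. Two indices quantify closeness to that
ideal:

* ``concordance_index_r12``: (S11² + S22²)/‖G‖² on the raw matrix — the
  fraction of squared Frobenius norm captured by a rank-2 fit; equals 1 in
  the perfectly co-expressed case.
* ``cci`` (centralized concordance index): Ŝ11²/n on the transformed matrix,
  equivalently the largest eigenvalue of the module's gene–gene Pearson
  correlation matrix divided by n. Ranges over [1/n, 1]; 1 means perfect
  mutual (anti-)correlation, 1/n means mutually uncorrelated rows.

The transformation makes CCI invariant to per-row affine rescaling and to
which genes are highly expressed, which a raw-matrix index is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGeneError, DimensionError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "centralize_rows",
    "standardize_rows",
    "transform",
    "row_pearson_matrix",
    "concordance_index_r12",
    "cci",
    "density",
    "numerical_rank",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """CCI and companions for one module matrix.

    Attributes
    ----------
    cci : float
        Ŝ11²/n of the centralized, row-standardized matrix; in [1/n, 1].
    r12 : float
        (S11² + S22²)/‖G‖² of the raw matrix; in (0, 1].
    singular_values : ndarray
        Descending singular values of the transformed matrix; their squares
        sum to n because every standardized row has unit norm.
    n : int
        Number of genes (rows) used.
    N : int
        Number of samples (columns).
    """

    cci: float
    r12: float
    singular_values: np.ndarray
    n: int
    N: int


def _check_matrix(X, min_rows=2, min_cols=3):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError(f"expected a 2-D matrix, got {X.ndim}-D")
    if not np.isfinite(X).all():
        raise DimensionError("matrix contains non-finite entries")
    n, N = X.shape
    if n < min_rows:
        raise DimensionError(f"need at least {min_rows} rows (genes), got {n}")
    if N < min_cols:
        raise DimensionError(f"need at least {min_cols} columns (samples), got {N}")
    return X


def centralize_rows(matrix) -> np.ndarray:
    """Subtract each row's mean so every output row has mean zero."""
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise DimensionError("matrix contains non-finite entries")
    return X - X.mean(axis=1, keepdims=True)


def standardize_rows(centered, gene_ids=None) -> np.ndarray:
    """Scale each (already centered) row to unit Euclidean norm.

    Raises
    ------
    DegenerateGeneError
        If any row has zero norm (a constant gene), naming the offender.
    """
    X = np.asarray(centered, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0.0
    if zero.any():
        idx = np.flatnonzero(zero)
        names = [gene_ids[i] for i in idx] if gene_ids is not None else [f"row {i}" for i in idx]
        raise DegenerateGeneError(names)
    return X / norms[:, None]


def transform(matrix, gene_ids=None) -> np.ndarray:
    """Centralize then standardize: the Ĝ form all CCI computations use."""
    return standardize_rows(centralize_rows(matrix), gene_ids=gene_ids)


def _drop_constant(X, gene_ids):
    """Remove zero-variance rows; return (X, gene_ids, dropped_names)."""
    const = np.ptp(X, axis=1) == 0.0
    if not const.any():
        return X, gene_ids, []
    idx = np.flatnonzero(const)
    names = [gene_ids[i] for i in idx] if gene_ids is not None else [f"row {i}" for i in idx]
    logger.warning("dropping %d constant row(s): %s", len(names), ", ".join(map(str, names[:5])))
    keep = ~const
    kept_ids = [g for g, k in zip(gene_ids, keep) if k] if gene_ids is not None else None
    return X[keep], kept_ids, names


def row_pearson_matrix(matrix, gene_ids=None) -> np.ndarray:
    """Gene–gene Pearson correlation matrix, computed as Ĝ Ĝᵀ.

    The inner product of two centered unit-norm rows is exactly their Pearson
    correlation, so the transformed matrix's Gram matrix is the correlation
    matrix: symmetric, unit diagonal, entries in [-1, 1].
    """
    X = _check_matrix(matrix)
    Gh = transform(X, gene_ids=gene_ids)
    R = Gh @ Gh.T
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def concordance_index_r12(matrix) -> float:
    """Rank-2 energy fraction (S11² + S22²)/‖G‖² of the raw matrix."""
    X = _check_matrix(matrix)
    s = np.linalg.svd(X, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise UndefinedStatisticError("R12 is undefined for an all-zero matrix")
    return float(np.sum(s[:2] ** 2) / total)


def cci(matrix, gene_ids=None, on_constant="error") -> ConcordanceResult:
    """Centralized concordance index of a module matrix.

    Parameters
    ----------
    matrix : array-like of shape (n, N)
        Raw module expression submatrix, genes in rows. Needs n >= 2, N >= 3.
    gene_ids : sequence of str, optional
        Row names used in error/warning messages.
    on_constant : {"error", "drop"}
        Zero-variance rows cannot be standardized. ``"error"`` (default)
        raises; ``"drop"`` removes them with a warning and reports the
        reduced n in the result.

    Returns
    -------
    ConcordanceResult
        With ``cci`` = Ŝ11²/n, ``r12`` computed on the raw matrix, and the
        full singular-value spectrum of the transformed matrix.
    """
    X = _check_matrix(matrix)
    if on_constant == "drop":
        X, gene_ids, _ = _drop_constant(X, gene_ids)
        if X.shape[0] < 2:
            raise DimensionError("fewer than 2 non-constant rows remain")
    elif on_constant != "error":
        raise ValueError(f"on_constant must be 'error' or 'drop', got {on_constant!r}")
    r12 = concordance_index_r12(X)
    Gh = transform(X, gene_ids=gene_ids)
    s = np.linalg.svd(Gh, compute_uv=False)
    n, N = X.shape
    return ConcordanceResult(
        cci=float(s[0] ** 2 / n),
        r12=r12,
        singular_values=s,
        n=n,
        N=N,
    )


def cci_value(matrix) -> float:
    """Bare CCI = Ŝ11²/n, skipping the result object (hot path for nulls)."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if (norms == 0.0).any():
        raise DegenerateGeneError([f"row {i}" for i in np.flatnonzero(norms == 0.0)])
    s1 = np.linalg.svd(Xc / norms[:, None], compute_uv=False)[0]
    return float(s1**2 / X.shape[0])


def density(matrix, gene_ids=None) -> float:
    """Mean absolute pairwise Pearson correlation over the n(n-1)/2 gene pairs.

    The standard weighted-network density of a module when edge weights are
    |ρ|; the baseline metric CCI is compared against.
    """
    X = _check_matrix(matrix, min_cols=3)
    R = row_pearson_matrix(X, gene_ids=gene_ids)
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.abs(R[iu]).mean())


def numerical_rank(matrix, rtol=None) -> int:
    """Count singular values above a scale-aware tolerance.

    The default tolerance is ``max(n, N) * eps * S11``, the standard
    numerical-rank convention; pass ``rtol`` (relative to S11) to override.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise DimensionError("matrix contains non-finite entries")
    if X.size == 0:
        return 0
    s = np.linalg.svd(X, compute_uv=False)
    if s[0] == 0.0:
        return 0
    tol = s[0] * (rtol if rtol is not None else max(X.shape) * np.finfo(float).eps)
    return int(np.count_nonzero(s > tol))
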