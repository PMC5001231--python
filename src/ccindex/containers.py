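"""In-memory containers: expression matrices and gene modules.

An :class:`ExpressionMatrix` is a genes × samples numeric table with unique
row (gene) and column (sample) identifiers; every concordance statistic in
this package acts on one, or on the submatrix named by a :class:`GeneModule`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CCIError, DimensionError

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "GeneModule"]


@dataclass
class ExpressionMatrix:
    """Genes-in-rows expression table with identifier metadata.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression values, any units; must be finite.
    gene_ids : sequence of str
        Unique row identifiers, one per gene.
    sample_ids : sequence of str
        Unique column identifiers, one per sample.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise CCIError(f"expression values must be 2-D, got {self.values.ndim}-D")
        n, N = self.values.shape
        if len(self.gene_ids) != n:
            raise CCIError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != N:
            raise CCIError(f"{len(self.sample_ids)} sample ids for {N} columns")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise CCIError(f"duplicate gene id(s): {', '.join(dup[:5])}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise CCIError(f"duplicate sample id(s): {', '.join(dup[:5])}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise CCIError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with gene ids in the index, samples in columns."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def constant_gene_mask(self) -> np.ndarray:
        """Boolean mask of genes with zero variance across samples."""
        return np.ptp(self.values, axis=1) == 0.0

    def resolve_module(self, module: "GeneModule") -> tuple[np.ndarray, list[str], list[str]]:
        """Map a module's gene list onto this matrix.

        Genes absent from the matrix are dropped with a logged warning; fewer
        than two surviving genes is an error.

        Returns
        -------
        (row_indices, used_genes, missing_genes)
        """
        idx, used, missing = [], [], []
        for g in module.genes:
            i = self._gene_index.get(g)
            if i is None:
                missing.append(g)
            else:
                idx.append(i)
                used.append(g)
        if missing:
            logger.warning(
                "module %s: %d/%d genes absent from expression matrix",
                module.name, len(missing), len(module.genes),
            )
        if len(used) < 2:
            raise DimensionError(
                f"module {module.name!r}: only {len(used)} of {len(module.genes)} "
                f"genes found in the expression matrix (need >= 2)"
            )
        return np.asarray(idx, dtype=int), used, missing

    def submatrix(self, module: "GeneModule") -> tuple[np.ndarray, list[str]]:
        """Return (values, used_genes) for the module's rows."""
        idx, used, _ = self.resolve_module(module)
        return self.values[idx], used


@dataclass(frozen=True)
class GeneModule:
    """An ordered set of gene identifiers naming a submatrix of rows."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        dup = _duplicates(self.genes)
        if dup:
            raise CCIError(f"module {self.name!r}: duplicate gene(s) {', '.join(dup[:5])}")
        if len(self.genes) < 2:
            raise CCIError(f"module {self.name!r}: needs >= 2 genes, got {len(self.genes)}")

    @property
    def size(self) -> int:
        return len(self.genes)


def _duplicates(seq) -> list[str]:
    seen, dup = set(), []
    for x in seq:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup
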