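"""Condition-specific co-expression screening.

Each gene module (typically discovered in one condition by a network-mining
algorithm such as lmQCM or WGCNA) is scored in two conditions: its CCI is
computed from each condition's expression matrix and standardized against a
size-matched random-gene-set null drawn from that same matrix. With m
modules tested, the z threshold τ is the upper-tail normal quantile at
alpha/m (Bonferroni-style family-wise compensation). A module significant
(z ≥ τ) in exactly one condition is condition-specific.

Null draws are seeded from (master seed, module size) only, so two modules
of the same size share one cached null within a condition, the same gene
index lists are drawn in both conditions, and swapping the two matrices
swaps the specific_to_a/specific_to_b verdicts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .concordance import cci_value
from .containers import ExpressionMatrix, GeneModule
from .exceptions import CCIError
from .significance import (
    NullDistribution,
    ZScoreResult,
    bonferroni_z_threshold,
    cci_zscore,
    permutation_pvalue,
    sample_random_module_null,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleScreenRecord",
    "ScreenResult",
    "score_module_in_condition",
    "screen_condition_specific_modules",
    "split_by_condition",
]

VERDICTS = ("specific_to_a", "specific_to_b", "concordant_both", "concordant_neither")


@dataclass(frozen=True)
class ModuleScreenRecord:
    """Per-module outcome of a two-condition screen."""

    module: str
    n_requested: int
    n_used_a: int
    n_used_b: int
    cci_a: float
    cci_b: float
    z_a: float
    z_b: float
    tau: float
    verdict: str
    p_permute_a: float | None = None
    p_permute_b: float | None = None


@dataclass(frozen=True)
class ScreenResult:
    """All screen records plus the threshold and summary counts."""

    records: list[ModuleScreenRecord]
    tau: float
    alpha: float
    m_tests: int
    seed: int

    def counts(self) -> dict[str, int]:
        out = {v: 0 for v in VERDICTS}
        for r in self.records:
            out[r.verdict] += 1
        return out


def _verdict(z_a: float, z_b: float, tau: float) -> str:
    sig_a, sig_b = z_a >= tau, z_b >= tau
    if sig_a and sig_b:
        return "concordant_both"
    if sig_a:
        return "specific_to_a"
    if sig_b:
        return "specific_to_b"
    return "concordant_neither"


def score_module_in_condition(
    module: GeneModule,
    expr: ExpressionMatrix,
    M: int = 1000,
    rng: np.random.Generator | None = None,
    null: NullDistribution | None = None,
) -> tuple[float, ZScoreResult, NullDistribution]:
    """CCI of a module in one condition plus its random-gene-set z-score.

    The null is size-matched: M sets of ``n_used`` genes drawn from the same
    condition's matrix. Pass a precomputed ``null`` to reuse one across
    same-size modules; otherwise ``rng`` drives a fresh draw.

    Returns
    -------
    (cci, ZScoreResult, NullDistribution)
    """
    sub, used = expr.submatrix(module)
    observed = cci_value(sub)
    if null is None:
        if rng is None:
            raise CCIError("provide either a precomputed null or an rng")
        null = sample_random_module_null(expr, len(used), M, rng)
    zres = cci_zscore(observed, null)
    return observed, zres, null


def screen_condition_specific_modules(
    modules: list[GeneModule],
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    alpha: float = 0.05,
    M: int = 1000,
    seed: int = 0,
    include_permutation: bool = False,
    M_permute: int | None = None,
) -> ScreenResult:
    """Score every module in both conditions and classify condition specificity.

    τ = upper-tail normal quantile at alpha/len(modules). Modules whose gene
    lists resolve to fewer than two genes in a condition are skipped with a
    warning. Optional within-row permutation p-values (``include_permutation``)
    are reported alongside but do not enter the verdict.
    """
    if not modules:
        raise CCIError("empty module list")
    m_tests = len(modules)
    tau = bonferroni_z_threshold(alpha, m_tests)
    null_cache: dict[tuple[str, int], NullDistribution] = {}

    def condition_null(expr: ExpressionMatrix, label: str, n: int) -> NullDistribution:
        key = (label, n)
        if key not in null_cache:
            # seeded by size only: identical draws for both condition roles
            rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
            null_cache[key] = sample_random_module_null(expr, n, M, rng)
        return null_cache[key]

    records = []
    for module in modules:
        try:
            sub_a, used_a = expr_a.submatrix(module)
            sub_b, used_b = expr_b.submatrix(module)
        except CCIError as exc:
            logger.warning("skipping module %s: %s", module.name, exc)
            continue
        cci_a, cci_b = cci_value(sub_a), cci_value(sub_b)
        z_a = cci_zscore(cci_a, condition_null(expr_a, "a", len(used_a))).z
        z_b = cci_zscore(cci_b, condition_null(expr_b, "b", len(used_b))).z
        p_a = p_b = None
        if include_permutation:
            Mp = M_permute or M
            rng_p = np.random.default_rng(np.random.SeedSequence([seed, module.size, 1]))
            p_a, _ = permutation_pvalue(sub_a, Mp, rng_p)
            rng_p = np.random.default_rng(np.random.SeedSequence([seed, module.size, 2]))
            p_b, _ = permutation_pvalue(sub_b, Mp, rng_p)
        records.append(
            ModuleScreenRecord(
                module=module.name,
                n_requested=module.size,
                n_used_a=len(used_a),
                n_used_b=len(used_b),
                cci_a=cci_a,
                cci_b=cci_b,
                z_a=z_a,
                z_b=z_b,
                tau=tau,
                verdict=_verdict(z_a, z_b, tau),
                p_permute_a=p_a,
                p_permute_b=p_b,
            )
        )
    summary = ScreenResult(records=records, tau=tau, alpha=alpha, m_tests=m_tests, seed=seed)
    logger.info("screen: %s", summary.counts())
    return summary


def split_by_condition(
    expr: ExpressionMatrix, groups: dict[str, str]
) -> dict[str, ExpressionMatrix]:
    """Split one matrix into per-condition matrices by a sample→label map.

    Exactly two labels are required; samples missing from the map are an
    error (silent dropping would change N unnoticed).
    """
    missing = [s for s in expr.sample_ids if s not in groups]
    if missing:
        raise CCIError(f"samples missing from the group map: {', '.join(missing[:5])}")
    labels = sorted(set(groups[s] for s in expr.sample_ids))
    if len(labels) != 2:
        raise CCIError(f"need exactly 2 condition labels, got {len(labels)}: {labels}")
    out = {}
    for lab in labels:
        cols = [i for i, s in enumerate(expr.sample_ids) if groups[s] == lab]
        out[lab] = ExpressionMatrix(
            expr.values[:, cols],
            expr.gene_ids,
            [expr.sample_ids[i] for i in cols],
        )
    return out
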