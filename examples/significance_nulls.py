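"""Assess a module's CCI against both null models.

A 15-gene co-expressed module is planted in a 300-gene expression matrix.
The within-row permutation null destroys all cross-gene correlation; the
random-gene-set null asks how the module compares with same-size gene sets
from the same dataset. The z-score against the latter, with a
Bonferroni-adjusted threshold, is the screening criterion.
"""

import numpy as np

from ccindex import (
    ExpressionMatrix,
    add_gaussian_noise,
    bonferroni_z_threshold,
    cci_zscore,
    make_correlated_matrix,
    permutation_pvalue,
    sample_random_module_null,
)
from ccindex.concordance import cci_value

rng = np.random.default_rng(1)
n_genes, n_samples, module_n = 300, 50, 15

values = rng.uniform(size=(n_genes, n_samples))
values[:module_n] = add_gaussian_noise(
    make_correlated_matrix(module_n, n_samples, rng), 0.1, rng)
genome = ExpressionMatrix(values, [f"g{i:03d}" for i in range(n_genes)],
                          [f"s{j:02d}" for j in range(n_samples)])

module_matrix = genome.values[:module_n]
observed = cci_value(module_matrix)
print(f"observed module CCI = {observed:.4f}  (n = {module_n}, N = {n_samples})")

M = 1000
p_perm, perm_null = permutation_pvalue(module_matrix, M=M, rng=rng)
print(f"permutation null: mean = {perm_null.mean:.4f}, sd = {perm_null.std:.5f}, "
      f"p_permute = {p_perm:.3f} (smallest resolvable p = {1 / M})")

rand_null = sample_random_module_null(genome, n=module_n, M=M, rng=rng)
z = cci_zscore(observed, rand_null)
tau = bonferroni_z_threshold(alpha=0.05, m_tests=1)
print(f"random-gene-set null: mean = {rand_null.mean:.4f}, sd = {rand_null.std:.4f}")
print(f"z = {z.z:.2f}, one-tail p = {z.p_one_tail:.3g}, threshold tau = {tau:.3f}")
print()
print("The permutation null sits far below the random-set null (it erases even the")
print("incidental correlation real gene sets carry), so p_permute saturates at 0 and")
print("adds little; the z-score is the informative, cross-condition-comparable score.")
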