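# ccindex — centralized concordance index for gene co-expression modules

Gene co-expression network analysis produces *modules*: sets of genes whose
expression profiles are claimed to rise and fall together across samples.
`ccindex` answers, with a single rigorous statistic, how well a module lives
up to that claim in a given dataset — and whether it does so in one
biological condition but not another (e.g. tumor vs. control).

## The statistic

Write a module's expression as a matrix G ∈ ℝⁿˣᴺ (n genes, N samples, one
row per gene). If every pair of rows were perfectly correlated
(|ρ(gᵢ, gⱼ)| = 1), each row would be an affine transform of a single shared
profile, so rank(G) ≤ 2; after centering each row to mean 0 and scaling it
to unit norm (Ĝ), rank(Ĝ) = 1 and ‖Ĝ‖²_F = n. Real modules are scored by how
close they come to that ideal:

- **R₁₂ = (S₁₁² + S₂₂²)/‖G‖²** — the fraction of the raw matrix's squared
  Frobenius norm captured by its two leading singular values; 1 iff G is
  (numerically) rank ≤ 2.
- **CCI = Ŝ₁₁²/n** — the *centralized concordance index*: the squared top
  singular value of Ĝ over the module size. Since ĜĜᵀ is exactly the
  gene–gene Pearson correlation matrix, CCI = λ_max(correlation matrix)/n.
  It ranges over [1/n, 1]: 1 for perfect mutual (anti-)correlation, 1/n for
  mutually uncorrelated genes, and it is invariant to per-gene affine
  rescaling, sign flips and sample reordering.

Significance comes from two resampling nulls: within-row **permutation**
(p_permute = #(CCI_p ≥ CCI)/M) and **random gene sets** — M same-size gene
sets drawn from the whole matrix, against which the observed CCI is
standardized as z = (CCI − mean(CCI_r))/sd(CCI_r). With m modules tested,
a module is significant when z ≥ τ, the upper-tail normal quantile at
0.05/m. A module significant in exactly one of two conditions is
*condition-specific*.

## Worked example

```python
import numpy as np
from ccindex import make_correlated_matrix, add_gaussian_noise, cci, density

rng = np.random.default_rng(0)
module = add_gaussian_noise(make_correlated_matrix(20, 60, rng), sigma=0.05, rng=rng)
background = rng.uniform(size=(20, 60))

for name, block in [("co-expressed module", module), ("background genes", background)]:
    res = cci(block)
    print(f"{name}: CCI = {res.cci:.4f}, R12 = {res.r12:.4f}, "
          f"density = {density(block):.4f}")
```

prints

```
co-expressed module: CCI = 0.7586, R12 = 0.9979, density = 0.6874
background genes: CCI = 0.1196, R12 = 0.7783, density = 0.1121
```

The planted module scores near the top of the scale on all three metrics
(CCI below 1 only because of the σ = 0.05 noise), while twenty uncorrelated
genes sit at the noise floor — CCI 0.12, close to the theoretical minimum
1/n = 0.05 plus finite-sample spread. Note R₁₂ alone is a weak
discriminator (0.78 even for pure noise), which is why the centralized,
standardized CCI is the index of record.

The `examples/` directory has one narrative script per capability:

| script | shows |
| --- | --- |
| `score_a_module.py` | CCI / R₁₂ / density of a module vs background |
| `significance_nulls.py` | permutation and random-gene-set nulls, z-score, τ |
| `noise_sweep.py` | mean CCI and R_F across noise levels σ |
| `robustness_vs_density.py` | CCI vs density under outliers and interference |
| `condition_specific_screen.py` | end-to-end two-condition module screen |

## Command line

The same functionality is exposed as `cci` with four subcommands, reading
genes-in-rows delimited tables and GMT module files:

```sh
cci score    --expr expr.tsv --modules modules.gmt --out scores.tsv
cci null     --expr expr.tsv --modules modules.gmt --M 1000 --null both --seed 1 --out null.tsv
cci screen   --expr-a tumor.tsv --expr-b control.tsv --modules modules.gmt \
             --alpha 0.05 --M 1000 --seed 1 --out screen.tsv
cci simulate --scenario noise --n 50 --N 100 --reps 1000 --seed 1 --out sweep.tsv
```

All outputs carry a `#`-prefixed header with the effective configuration
and seed; rerunning with the same seed reproduces the data rows byte for
byte.

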