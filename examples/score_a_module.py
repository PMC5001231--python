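"""Score one gene module: CCI, R12 and correlation density.

Builds a 20-gene module whose rows are affine transforms of one base
profile plus mild noise, embeds it in a background of uncorrelated genes,
and scores both gene sets.
"""

import numpy as np

from ccindex import add_gaussian_noise, cci, density, make_correlated_matrix

rng = np.random.default_rng(0)

module = add_gaussian_noise(make_correlated_matrix(20, 60, rng), sigma=0.05, rng=rng)
background = rng.uniform(size=(20, 60))

for name, block in [("co-expressed module", module), ("background genes", background)]:
    res = cci(block)
    print(f"{name}: CCI = {res.cci:.4f}, R12 = {res.r12:.4f}, "
          f"density = {density(block):.4f}  (n = {res.n}, N = {res.N})")

print()
print("CCI is the largest eigenvalue of the module's gene-gene Pearson matrix over n:")
print("1.0 means every gene tracks one shared profile (up to sign and affine scale),")
print("1/n = 0.05 means the genes are mutually uncorrelated. The co-expressed block")
print("scores near 1 on all three metrics; the background sits near the noise floor.")
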