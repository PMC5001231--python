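"""CCI versus correlation density under outliers and interfering modules.

Density (mean |Pearson| over gene pairs) is the usual weighted-network
quality score for a module. Two stress tests show where CCI behaves
better: appending uncorrelated outlier genes, and stacking a second,
independently co-expressed module onto the first. Values are normalized
per repetition to the clean-module baseline.
"""

import numpy as np

from ccindex import SimulationConfig, run_robustness_comparison

cfg = SimulationConfig(n_rows=50, n_cols=100, n_reps=50, seed=11)

for scenario, label in [("outliers", "outlier genes appended"),
                        ("interference", "interfering module size")]:
    table = run_robustness_comparison(cfg, scenario=scenario, sigmas=(0.05,))
    g = table.groupby("level")

    def iqr(s):
        q1, q3 = np.percentile(s, [25, 75])
        return q3 - q1

    print(f"--- {label} (sigma = 0.05, normalized to level 0) ---")
    print(f"{'level':>5} {'CCI mean':>9} {'CCI IQR':>8} {'dens mean':>10} {'dens IQR':>9}")
    for level, grp in g:
        print(f"{level:5d} {grp.cci_normalized.mean():9.3f} {iqr(grp.cci_normalized):8.3f} "
              f"{grp.density_normalized.mean():10.3f} {iqr(grp.density_normalized):9.3f}")
    print()

print("Under outliers, both metrics fall, but the CCI spread (IQR) stays tighter")
print("than density's. Under interference, density flattens once the second module")
print("passes half the size of the first, while CCI keeps decreasing - so CCI still")
print("signals that the gene set is not one concordant module.")
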