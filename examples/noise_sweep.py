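"""How CCI degrades with measurement noise.

For each noise level sigma, repeatedly generate a perfectly co-expressed
50 x 100 module, add N(0, sigma^2) noise, and record the CCI and R_F (the
relative Frobenius distance between the noisy and clean transformed
matrices). 100 repetitions per level keep this example quick.
"""

from ccindex import SimulationConfig, run_noise_sweep

table = run_noise_sweep(SimulationConfig(n_reps=100, seed=7))
summary = table.groupby("sigma")[["cci", "r_f"]].agg(["mean", "std"])

print(f"{'sigma':>6} {'mean CCI':>9} {'sd CCI':>8} {'mean R_F':>9}")
for sigma, row in summary.iterrows():
    print(f"{sigma:6.2f} {row[('cci', 'mean')]:9.4f} {row[('cci', 'std')]:8.4f} "
          f"{row[('r_f', 'mean')]:9.4f}")

print()
print("Mean CCI decays monotonically from 1 as sigma grows, while R_F grows:")
print("the index responds smoothly to noise rather than collapsing, which is what")
print("makes it usable as a graded concordance score rather than a pass/fail test.")
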