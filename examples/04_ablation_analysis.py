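"""Laser-ablation recoil analysis on synthetic traces.

Generates double-exponential recoil traces with known ground truth
(initial recoil velocity drawn from a hump over closure stage), fits
each trace, summarizes the fitted velocities across the closure-stage
bins, and locates the straightness-recoil crossover.
"""

import numpy as np

import vertexclosure as vc
from vertexclosure.experiment import crossover_fit, fit_recoil, stage_binned_stats

traces, truth = vc.generate_ablation_traces(n=40, noise=0.02, seed=5)
fits = [fit_recoil(tr) for tr in traces]
vr = np.array([f.vr for f in fits])
vr_true = np.array([t["vr"] for t in truth])
dA = np.array([t["dA"] for t in truth])

err = np.abs(vr - vr_true) / vr_true
print(f"fitted {len(fits)} recoil traces; median |vr error| = {np.median(err):.2%}")

print("\nrecoil velocity by closure stage (um/s):")
print(stage_binned_stats(vr, dA).to_string(index=False,
                                           float_format=lambda x: f"{x:.3f}"))
print("\nThe middle bin (0.4 <= dA < 0.7) carries the largest median "
      "velocity: junction tension peaks mid-closure.")

# straightness-recoil crossover on synthetic pairs with a planted knee
rng = np.random.default_rng(2)
s = rng.uniform(0.8, 1.0, size=97)
v = 0.2 + 2.5 * np.maximum(s - 0.93, 0.0) + 0.01 * rng.normal(size=97)
fit = crossover_fit(s, v)
print(f"\ncrossover fit: S* = {fit.breakpoint:.3f} "
      f"(95% CI {fit.ci_low:.3f}-{fit.ci_high:.3f}), slope {fit.slope:.2f}")
print("Above S*, recoil velocity rises linearly with junction straightness; "
      "below it, wiggly junctions carry no measurable tension.")
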