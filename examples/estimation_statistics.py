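"""Estimation statistics: mean difference with a BCa bootstrap 95% CI.

Simulates per-neuron complex-spike rates for two genotype groups (14 vs 15
neurons, 100-s recordings) whose generator rates differ by -0.259 Hz, and
reports the recovered effect the way the analysis pipeline does: the mean
difference (KO - WT) with its bias-corrected-and-accelerated bootstrap CI,
alongside the pooled Student's t test.
"""

import numpy as np

from pcsense import conditions as cond, spiketrain, stats, synthgen

rng = np.random.default_rng(3)
groups = {}
for name, cs_rate, n in (("WT", cond.WT_CS_RATE_HZ, cond.N_NEURONS_WT),
                         ("KO", cond.ko_cs_rate_hz(), cond.N_NEURONS_KO)):
    rates = []
    for _ in range(n):
        rec = synthgen.gen_pc_recording(synthgen.PCParams(cs_rate=cs_rate), rng)
        rates.append(spiketrain.train_stats(rec.cs).rate)
    groups[name] = np.array(rates)
    print(f"{name}: mean CS rate {groups[name].mean():.3f} Hz (n={n})")

gc = stats.bootstrap_md_ci(groups["WT"], groups["KO"], n_boot=5000, seed=4)
print(f"MD (KO-WT) = {gc.md:.3f} Hz [95% CI {gc.ci95[0]:.3f}, {gc.ci95[1]:.3f}]")
print(f"Student's t = {gc.t:.2f}, p = {gc.p:.4f}")
print(f"imposed generator offset: {cond.CS_RATE_MD_HZ} Hz")

# The CI quantifies the effect size directly: an interval excluding zero
# corresponds to a significant rate reduction, and the point estimate
# recovers the imposed -0.259-Hz offset up to counting noise.
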