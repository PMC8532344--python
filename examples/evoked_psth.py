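"""Stimulus-locked complex-spike probability (PSTH) comparison.

Builds two groups of neurons whose stimulus-evoked complex spikes arrive at
different latencies (13 ms vs 6.5 ms, 80% of trials), computes each
neuron's trial-occupancy PSTH (fraction of trials with >= 1 spike per 1-ms
bin over [-20, +50) ms), and compares the groups with a mixed two-way ANOVA
(group x time-bin) plus per-bin Holm-Sidak-adjusted t tests.
"""

import numpy as np

from pcsense import evoked, synthgen


def group_psth(latency_ms, n_neurons, seed0):
    trains, stim = [], None
    for s in range(n_neurons):
        tpl = synthgen.EvokedCSTemplate(cs_latency_ms=latency_ms,
                                        cs_latency_sd_ms=0.5, cs_prob=0.8,
                                        baseline=synthgen.PCParams(cs_rate=0.5))
        ses = synthgen.gen_evoked_spikes(tpl, 40, seed=seed0 + s,
                                         inter_stim_s=0.5, jitter_s=0.0)
        trains.append(ses.cs)
        stim = ses.stim_times
    return evoked.compute_psth(trains, stim, label="CS")


late = group_psth(13.0, 8, seed0=100)    # WT-like: CS follows the C wave
early = group_psth(6.5, 8, seed0=200)    # KO-like: anticipated CS

res = evoked.compare_psth(late, early)
anova = res["anova"]
print(f"mixed ANOVA: group F={anova.f_between:.2f} (p={anova.p_between:.3g}), "
      f"interaction F={anova.f_interaction:.2f} (p={anova.p_interaction:.3g})")
sig = res["bin_centers_ms"][res["reject"]]
print(f"{sig.size} bins differ after Holm-Sidak: "
      f"{np.array2string(sig, precision=1)}")

# The interaction term captures the latency shift: occupancy peaks move from
# the 13-ms neighbourhood to the 6.5-ms one, so the significant bins cluster
# around both latencies.
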