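"""Intrinsic excitability of one integrate-and-fire cell.

Runs the +75 pA / 750-ms current-step protocol on a synthetic cell with a
600-pA ground-truth rheobase, then recovers: passive properties from the
hyperpolarizing step (resting potential, input resistance, capacitance),
rheobase as the first firing step, the AP threshold by the 5%-of-maximal-
rise-slope criterion, and the rheobase-normalised f-I slope from the
instantaneous frequencies of the first six APs per sweep.
"""

from pcsense import intrinsic, synthgen

cell = synthgen.make_cell(rheobase_pA=600.0, fi_slope=0.2)
sweeps = synthgen.gen_patch_sweeps(cell, synthgen.StepProtocol())

hyper = next(sw for sw in sweeps if sw.step_pA < 0)
passive = intrinsic.passive_props(hyper)
print(f"passive: V_rest {passive.v_rest:.1f} mV, R_in {passive.r_in:.1f} MOhm, "
      f"C_m {passive.c_m:.0f} pF (tau {passive.tau_ms:.1f} ms)")

result = intrinsic.analyze_cell(sweeps)
print(f"rheobase {result.rheobase_pA:.0f} pA "
      f"(ground truth {cell.rheobase_pA:.0f} pA, protocol step 75 pA)")
print(f"AP threshold {result.ap_threshold_mV:.1f} mV "
      f"(generator threshold {cell.v_thresh:.1f} mV)")
print(f"f-I slope {result.fi_slope:.3f} Hz/pA over "
      f"{len(result.fi_points)} suprathreshold sweeps")

# The measured rheobase quantizes the true value up to the next 75-pA step;
# the f-I slope matches the generator's gain because instantaneous
# frequencies are linear in current above rheobase.
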