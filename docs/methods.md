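# Methods

This note documents the models, estimators and numerical choices behind
`pcsense`, and what the synthetic-data generators do and do not emulate.

## Scope and design

The package analyses cerebellar Purkinje-cell (PC) physiology at five
levels: spontaneous spike trains, sensory evoked potentials (SEP),
stimulus-locked firing probability, intrinsic excitability from
current-clamp steps, and dendritic morphometry. Because raw recordings of
this kind are rarely shareable, every analysis ships with a generator that
produces synthetic data with known ground truth; the test suite and the
acceptance script quantify how well the analysis chain recovers imposed
effects under realistic sample sizes. The package is used from Python
(`examples/` walks through each capability); a thin `pcsense` CLI wraps the
same functions for shell use.

## Spike trains

**Generative model.** Simple spikes (SS) are an ordinary gamma-renewal
process: i.i.d. ISIs ~ Gamma(shape k = 1/CV², mean 1/rate), the simplest
renewal family with a free coefficient of variation (CV = 1 recovers a
Poisson process). Complex spikes (CS) are homogeneous Poisson at a low rate
(default 1 Hz). The CS→SS interaction is a hard pause: every SS within
`cs_pause` (default 15 ms) after a CS is deleted. A hard pause is the
simplest mechanism reproducing a post-CS dip in SS firing probability; real
pauses are graded and history-dependent.

**Statistics.** Firing rate is n_spikes/duration (convention; stated
because "rate" is otherwise ambiguous for finite windows). CV = σ_ISI/μ_ISI
with the population (1/n) SD, so the small hand-computed oracles are exact.
CV2 = mean over adjacent pairs of 2|ISI_{n+1}−ISI_n|/(ISI_{n+1}+ISI_n); it
is bounded by [0, 2] and has expectation 1 for Poisson firing. The
predominant firing rate is the centre of the modal bin of the 1/ISI
histogram, bin width 2 Hz (free choice — the underlying notion of "mode of
the firing rate" does not pin down a binning), bins centred on multiples of
the width, ties broken toward the lower rate. Statistics requiring ≥3
spikes are reported as NaN below that, never zero-filled. Units recorded
for less than 100 s are rejected by the inclusion rule.

**DC removal** is a single-pole high-pass: the signal minus its
exponentially weighted running mean with time constant τ (supported range
0.4–1 ms), initialised at the first sample. Its discrete transfer function
is a(1−z⁻¹)/(1−az⁻¹) with a = exp(−1/(fs·τ)); tests verify the measured
gain against this closed form and against the analog RC response in the
high-sampling limit.

**Spike detection** is plain threshold crossing (direction given by the
threshold's sign) with a refractory lockout (default 1 ms). At
peak-SNR 5 with a sensible threshold (~0.8× peak) it recovers ≥99% of
rendered template spikes within 0.2 ms; with white wide-band noise and a
threshold near half the peak it degrades, because false crossings land in
the lockout window ahead of true spikes.

**CS classification** (when ground-truth labels are unavailable) uses a
trailing-pause rule: an event is CS iff the gap to the next event reaches
max(absolute threshold, 2 × median ISI). The relative term is required: a
slow regular train would otherwise classify every spike as CS. The rule is
reliable only when the enforced pause exceeds the upper tail of the SS ISI
distribution (fast, regular SS firing); at 60 Hz with CV 0.5 and a 15-ms
pause the SS ISI distribution overlaps the pause and no gap-based rule can
reach high precision. Synthetic pipelines therefore use generator labels;
the classifier is provided for label-free data with its limits stated.

## Sensory evoked potentials

Sessions are white Gaussian noise (default SD 5 μV — free parameter) plus,
per stimulus, each template component added as a negative Gaussian bump.
Component widths are full width at half maximum (default 1.5 ms, σ≈0.64 ms);
wider components would merge the two knock-out-like peaks at ~4.1 and
~6.5 ms into a single minimum. Amplitude defaults to −80 μV (free).
Stimuli repeat every 10 ± 2 s (uniform jitter).

Epoching cuts [−20, +50) ms around each stimulus (70-ms windows, half-open,
0 = stimulus onset) at 25 kHz; windows that do not fit inside the trace are
dropped with a warning. Baseline correction subtracts each trial's mean
over [−20, 0) ms and is idempotent. Averages carry pointwise SEM (SD/√n).

**Component detection** operates on the averaged, baseline-corrected trace:
a light Gaussian smoothing (σ = 0.3 ms) suppresses sample-level noise that
would otherwise displace the argmin by several samples, then local negative
minima within (0, 50] ms whose depth and prominence both exceed 3× the
per-trial pre-stimulus noise floor are reported at sample precision. The
noise floor is the pooled SD of pre-stimulus samples across trials — not
the SD of the average — so a pure-noise session yields no components while
a genuine component a few times the trial noise is found after averaging.

**Group comparison** uses per-animal average SEPs as the experimental unit
and a pointwise pooled-variance Student's t at every sample; contiguous
runs with p < α are reported as latency spans. No correction across
latencies is applied at this stage (the spans are descriptive); under the
null the pointwise rejection rate calibrates to α.

## Stimulus-locked firing (PSTH)

The PSTH is trial-occupancy probability: per neuron and 1-ms bin over
[−20, +50) ms, the fraction of trials with at least one spike in the bin
(bin width is a free choice; occupancy rather than rate keeps the values in
[0, 1] and matches a "probability of firing" reading). Group comparison is
a balanced mixed-design two-way ANOVA — between factor group, within factor
time-bin, neurons as subjects — followed by per-bin pooled t tests with
Holm–Šidák adjustment.

## Intrinsic excitability

**Generator.** The cell is a hybrid integrate-and-fire model: subthreshold
voltage follows the analytic RC solution (τ = R_in·C_m); the first spike of
a step occurs at the RC threshold-crossing time; subsequent spikes are
scheduled so the steady rate equals fi_slope·(I − rheobase). The linear
suprathreshold law is imposed directly (a pure leaky integrate-and-fire
has a logarithmic f–I near rheobase), because the measured quantities —
rheobase, f-I points, slope — are defined against a linear
current/frequency relation. A stereotyped AP waveform (quadratic-ramp rise
over 0.5 ms to +20 mV, linear fall to the reset voltage) is pasted at each
spike time; its rise profile makes the 5%-slope threshold criterion
analytically checkable. Ground-truth rheobase is (V_thresh − V_rest)/R_in;
a step exactly at that current never fires in finite time, so the measured
value quantizes strictly upward.

**Analysis.** APs are upward crossings of 0 mV with a 2-ms lockout
(doublets faster than the lockout merge — a documented limitation; the
default protocols keep maximal rates below it). Rheobase is the smallest
net depolarizing step (relative to holding) with ≥1 AP during the step;
undefined (NaN, with a warning) if nothing fires. AP threshold is the
voltage where dV/dt (central differences, optional 3-point smoothing) first
reaches 5% of the maximal rise slope before the peak. The f-I analysis is
rheobase-normalised: per suprathreshold sweep, the instantaneous
frequencies (1/ISI) among the first six APs are averaged into one point at
ΔI = step − rheobase (sweeps with a single AP are excluded); the
excitability slope is the OLS slope of these points. Averaging per sweep
(rather than pooling ISIs across sweeps) weights each current level
equally. Passive properties come from the hyperpolarizing step: V_rest from
the pre-step segment, R_in = ΔV_ss/ΔI from the final 20% of the step, τ
from a mono-exponential fit of the onset, C_m = τ/R_in. QC limits (access
resistance ≤ 16 MΩ, holding ≥ −500 pA) are represented as metadata flags.

**Protocols.** Steps of +75 pA and 750 ms, from a 100-ms baseline, with one
−100 pA step for passive properties. The default protocol reaches 1500 pA;
population studies use a 3000-pA ceiling so the upper tail of a lognormal
rheobase distribution (mean 600, SD 215 pA) still fires. Sampling is
20 kHz by default; population studies use 10 kHz (both within the
supported digitization range) to keep replicate sweeps cheap.

## Morphometry

Morphologies are SWC trees. The generator grows a straight apical trunk of
exactly the requested extent (the first segment is a half step so interior
nodes avoid the Sholl radius grid — crossings stay transversal and the
profile is stable under rigid motion), with lateral branches (probability
per trunk node, recursive up to a depth limit) constrained to stay closer
to the soma than the trunk tip, so the farthest node equals the apical
extent by construction. Spines are a Poisson process along the distal
10 μm of the trunk.

**Sholl** counts intersections of the arbour with concentric spheres every
5 μm from the soma (a `planar` flag projects to xy first, matching
image-derived reconstructions). Each parent–child segment is a straight
line; crossings are counted exactly from the quadratic distance function
along the edge, so a segment dipping inside a sphere and back counts both
transversal crossings, while tangencies count zero. A node exactly on a
sphere is credited to the crossing parameter t ∈ (0, 1], i.e. to the edge
arriving from inside — equivalent to the "endpoint counts on the far side"
tie rule for monotone edges. A dense-resampling brute-force oracle (0.1-μm
sampling, sign changes of distance−r) verifies the profile exactly on
random trees. Apical length is the maximum Euclidean soma-to-node distance
(apical orientation is not encoded in SWC). Spine density is count/length
over the annotated segment (default 10 μm).

## Statistics

Group effects are reported as estimation statistics: MD = mean(KO) −
mean(WT) with a bias-corrected-and-accelerated (BCa) bootstrap 95% CI —
within-group resampling, 5000 resamples by default, acceleration from a
leave-one-out jackknife over both groups, fully seeded. The point estimate
is never resampled. BCa (rather than percentile) matches the convention of
standard estimation-statistics tools; measured coverage at n = 30/30 is
~94.5%. Student's t is the pooled-variance two-sample test
(df = n_a + n_b − 2); zero pooled variance returns t = 0, p = 1 for equal
means and a flagged infinite statistic otherwise. Holm–Šidák follows the
step-down closed form with enforced monotonicity. The mixed two-way ANOVA
is the classical balanced split-plot decomposition (between-subjects error
for the group factor; subject×within residual for the within factor and
interaction); it requires complete cells and is cross-checked against an
independent implementation in the tests. A restricted-maximum-likelihood
mixed model would handle unbalanced data but is out of scope.

## Study conditions and recovery

`pcsense.conditions` freezes the synthetic study: group sizes (14/15
neurons, 11/13 cells, 14/15 trees), 100-s recordings, wild-type baselines
(SS 60 Hz, CV 0.5; CS 1 Hz; rheobase 600 pA; apical length 180 μm — the
baselines are free, physiologically typical values) and the knock-out
offsets imposed on the generators (CS rate −0.259 Hz; SS CV +0.138;
rheobase −205 pA; apical length −61.89 μm), together with the reference
95% CIs used as recovery bands. Where a between-cell SD is needed but not
reported, it is inferred from the reference CI of the mean difference
(SD ≈ CI halfwidth / (1.96·√(1/n_a + 1/n_b))): 215 pA for rheobase
(lognormal, so rheobase stays positive with the exact requested mean and
SD) and 37 μm for apical extent (normal, floored at 20 μm).

`pcsense.recovery` re-runs each study end to end and returns per-replicate
recovered MDs; `scripts/acceptance.py` reports the replicate means (100
replicates for the spontaneous and morphology studies, 60 for the
patch-clamp study — sizes chosen so each study completes in about a minute
on one core while the replicate-mean SE stays a few percent of the effect).

## What the generators do not emulate

Real extracellular waveform shapes and sorting ambiguity (spike times are
rendered with one fixed template); graded, history-dependent CS pauses;
SEP component amplitude/shape variability across animals and trials beyond
additive white noise; conductance-based AP dynamics, adaptation and sag;
image segmentation and tracing errors upstream of SWC. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated generative assumptions, not robustness to every artefact of real
recordings.
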