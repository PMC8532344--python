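"""Synthetic-data generators for every analysis stage.

The generators emulate the study conditions of a cerebellar sensory-physiology
experiment: spontaneous Purkinje-cell (PC) firing with simple spikes (SS, a
gamma-renewal process with controllable rate and regularity) and complex
spikes (CS, low-rate Poisson, each imposing a brief SS pause); whisker-evoked
sensory potentials (SEP) built from negative Gaussian components riding on
noise; stimulus-evoked CS with controllable latency and probability;
current-clamp step sweeps from an integrate-and-fire cell with a prescribed
linear f-I gain; and branching SWC morphologies with spine annotations.

Every generator is driven by a :class:`numpy.random.Generator`; identical
parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ContinuousTrace,
    Morphology,
    ParameterError,
    SpikeTrain,
    Sweep,
    SweepSet,
)

__all__ = [
    "PCParams",
    "SEPTemplate",
    "EvokedCSTemplate",
    "PatchCellParams",
    "StepProtocol",
    "TreeParams",
    "PCRecording",
    "EvokedSession",
    "gen_spike_train",
    "gen_pc_recording",
    "gen_sep_session",
    "gen_evoked_spikes",
    "gen_patch_sweeps",
    "gen_morphology",
    "make_cell",
    "gen_cell_population",
    "render_spike_trace",
    "wt_sep_template",
    "ko_sep_template",
    "split_rng",
    "as_rng",
]

# Default SEP component latencies (ms): early trigeminal (T) and late
# cortical (C) waves for the wild-type; the knock-out shows the T wave and an
# anticipated cortical component near 6.5 ms instead of the 12.9-ms C wave.
WT_SEP_LATENCIES_MS = (3.94, 12.87)
KO_SEP_LATENCIES_MS = (4.10, 6.46)

# Free defaults (the study prints no SEP amplitudes or noise levels).
DEFAULT_SEP_AMPLITUDE_UV = -80.0
DEFAULT_SEP_WIDTH_MS = 1.5       # full width at half maximum
DEFAULT_SEP_NOISE_UV = 5.0
DEFAULT_FS_HZ = 25_000.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_rng(seed, n: int) -> list:
    """Split one seed into ``n`` independent child generators.

    Uses :class:`numpy.random.SeedSequence` spawning so each stage of a
    pipeline draws from its own stream while everything derives from a single
    master seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCParams:
    """Generative parameters of one spontaneous PC recording.

    ``ss_rate``/``ss_cv`` set the simple-spike gamma-renewal process
    (ISI shape k = 1/cv^2, mean 1/rate); ``cs_rate`` the Poisson complex-spike
    rate; ``cs_pause`` the SS silence imposed after each CS (seconds).
    """

    ss_rate: float = 60.0     # Hz
    ss_cv: float = 0.5
    cs_rate: float = 1.0      # Hz
    cs_pause: float = 0.015   # s
    duration: float = 100.0   # s
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ss_rate <= 0:
            raise ParameterError("ss_rate must be positive")
        if self.ss_cv <= 0:
            raise ParameterError("ss_cv must be positive")
        if self.cs_rate < 0:
            raise ParameterError("cs_rate must be non-negative")
        if self.cs_pause < 0:
            raise ParameterError("cs_pause must be non-negative")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")


@dataclass(frozen=True)
class PCRecording:
    """A labelled synthetic recording with its ground truth."""

    ss: SpikeTrain
    cs: SpikeTrain
    truth: dict


def gen_spike_train(rate: float, cv: float, duration: float, seed=None,
                    label: str = "unknown") -> SpikeTrain:
    """Gamma-renewal spike train with the requested rate and ISI CV.

    ISIs are i.i.d. Gamma(shape k = 1/cv^2, mean 1/rate), so the ISI
    coefficient of variation is exactly ``cv`` and cv -> 1 recovers a Poisson
    process. The train starts with a full ISI drawn from time 0 (ordinary
    renewal process).
    """
    if rate <= 0 or cv <= 0 or duration <= 0:
        raise ParameterError("rate, cv and duration must all be positive")
    rng = as_rng(seed)
    k = 1.0 / (cv * cv)
    scale = 1.0 / (rate * k)
    times = []
    t = 0.0
    # draw in chunks; expected count is rate*duration
    chunk = max(16, int(rate * duration * 1.2) + 8)
    while t < duration:
        isis = rng.gamma(k, scale, size=chunk)
        cum = t + np.cumsum(isis)
        inside = cum[cum < duration]
        times.append(inside)
        if cum[-1] >= duration:
            break
        t = cum[-1]
    times = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(times, duration, label)


def gen_pc_recording(params: PCParams, seed=None) -> PCRecording:
    """Spontaneous PC recording: SS gamma train + CS Poisson train.

    Each CS deletes every SS falling within ``cs_pause`` after it, mimicking
    the post-CS dip in SS firing probability. Ground-truth (pre-deletion SS
    times and CS times) is retained in ``truth``.
    """
    if seed is None:
        seed = params.seed
    rng_ss, rng_cs = split_rng(seed, 2) if not isinstance(seed, np.random.Generator) \
        else (seed, seed)
    ss_raw = gen_spike_train(params.ss_rate, params.ss_cv, params.duration,
                             rng_ss, label="SS")
    if params.cs_rate > 0:
        cs = gen_spike_train(params.cs_rate, 1.0, params.duration, rng_cs, label="CS")
    else:
        cs = SpikeTrain(np.empty(0), params.duration, "CS")
    ss_times = _apply_cs_pause(ss_raw.times, cs.times, params.cs_pause)
    ss = SpikeTrain(ss_times, params.duration, "SS")
    truth = {
        "params": params,
        "ss_times_raw": ss_raw.times,
        "cs_times": cs.times,
        "n_ss_deleted": ss_raw.n_spikes - ss.n_spikes,
    }
    return PCRecording(ss=ss, cs=cs, truth=truth)


def _apply_cs_pause(ss_times: np.ndarray, cs_times: np.ndarray,
                    pause: float) -> np.ndarray:
    """Remove SS falling in (cs, cs + pause] after any CS."""
    if pause <= 0 or cs_times.size == 0 or ss_times.size == 0:
        return ss_times
    # index of the most recent CS strictly before each SS
    idx = np.searchsorted(cs_times, ss_times, side="left") - 1
    has_prev = idx >= 0
    gap = np.full(ss_times.shape, np.inf)
    gap[has_prev] = ss_times[has_prev] - cs_times[idx[has_prev]]
    return ss_times[gap > pause]


# ---------------------------------------------------------------------------
# sensory evoked potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEPTemplate:
    """Ground-truth description of a synthetic SEP session.

    ``components`` is a sequence of (latency_ms, amplitude_uV, fwhm_ms)
    triples; amplitudes are negative (downward field deflections). Stimuli
    are delivered every ``inter_stim_s`` +- uniform ``jitter_s`` seconds.
    """

    components: tuple = (
        (WT_SEP_LATENCIES_MS[0], DEFAULT_SEP_AMPLITUDE_UV, DEFAULT_SEP_WIDTH_MS),
        (WT_SEP_LATENCIES_MS[1], DEFAULT_SEP_AMPLITUDE_UV, DEFAULT_SEP_WIDTH_MS),
    )
    noise_sd: float = DEFAULT_SEP_NOISE_UV   # uV
    fs: float = DEFAULT_FS_HZ
    n_trials: int = 30
    inter_stim_s: float = 10.0
    jitter_s: float = 2.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.n_trials < 0:
            raise ParameterError("n_trials must be non-negative")
        for lat, amp, width in self.components:
            if not (0.0 < lat < 50.0):
                raise ParameterError(
                    f"component latency {lat} ms outside the (0, 50) ms analysis window")
            if width <= 0:
                raise ParameterError("component width must be positive")


def wt_sep_template(**overrides) -> SEPTemplate:
    """Default wild-type SEP template (T ~3.94 ms, C ~12.87 ms)."""
    return SEPTemplate(**overrides) if overrides else SEPTemplate()


def ko_sep_template(**overrides) -> SEPTemplate:
    """Default knock-out SEP template (T ~4.10 ms, anticipated C ~6.46 ms)."""
    comps = tuple(
        (lat, DEFAULT_SEP_AMPLITUDE_UV, DEFAULT_SEP_WIDTH_MS)
        for lat in KO_SEP_LATENCIES_MS
    )
    kw = {"components": comps}
    kw.update(overrides)
    return SEPTemplate(**kw)


def gen_sep_session(template: SEPTemplate, seed=None):
    """Synthesize a continuous LFP session with stimulus-locked SEPs.

    Returns ``(trace, stim_times)``: white noise of SD ``noise_sd`` plus, for
    every stimulus, each template component added as a negative Gaussian bump
    centred at stimulus time + latency.
    """
    rng = as_rng(seed)
    fs = template.fs
    pad = 1.0  # s of trace before the first and after the last stimulus
    if template.n_trials == 0:
        n = int(round(2 * pad * fs))
        noise = rng.normal(0.0, template.noise_sd, n) if template.noise_sd > 0 \
            else np.zeros(n)
        return ContinuousTrace(noise, fs, "uV"), np.empty(0)
    jit = rng.uniform(-template.jitter_s, template.jitter_s, template.n_trials) \
        if template.jitter_s > 0 else np.zeros(template.n_trials)
    intervals = template.inter_stim_s + jit
    stim_times = pad + np.concatenate(([0.0], np.cumsum(intervals[:-1])))
    total_s = stim_times[-1] + pad
    n = int(round(total_s * fs))
    data = rng.normal(0.0, template.noise_sd, n) if template.noise_sd > 0 \
        else np.zeros(n)
    t = np.arange(n) / fs
    for stim in stim_times:
        for lat_ms, amp, fwhm_ms in template.components:
            sigma = fwhm_ms * _FWHM_TO_SIGMA / 1000.0
            centre = stim + lat_ms / 1000.0
            lo = max(0, int((centre - 5 * sigma) * fs))
            hi = min(n, int((centre + 5 * sigma) * fs) + 1)
            if lo >= hi:
                continue
            tt = t[lo:hi] - centre
            data[lo:hi] += -abs(amp) * np.exp(-0.5 * (tt / sigma) ** 2)
    return ContinuousTrace(data, fs, "uV"), stim_times


# ---------------------------------------------------------------------------
# evoked complex spikes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvokedCSTemplate:
    """Stimulus-evoked CS on top of a spontaneous PC recording.

    Each stimulus elicits, with probability ``cs_prob``, one extra CS at a
    latency drawn from Normal(``cs_latency_ms``, ``cs_latency_sd_ms``).
    """

    cs_latency_ms: float = 12.87
    cs_latency_sd_ms: float = 1.0
    cs_prob: float = 0.8
    baseline: PCParams = field(default_factory=PCParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.cs_prob <= 1.0):
            raise ParameterError("cs_prob must lie in [0, 1]")
        if self.cs_latency_ms <= 0:
            raise ParameterError("cs_latency_ms must be positive")


@dataclass(frozen=True)
class EvokedSession:
    ss: SpikeTrain
    cs: SpikeTrain
    stim_times: np.ndarray
    truth: dict


def gen_evoked_spikes(template: EvokedCSTemplate, n_trials: int,
                      seed=None, inter_stim_s: float = 10.0,
                      jitter_s: float = 2.0) -> EvokedSession:
    """Spontaneous recording plus stimulus-locked CS.

    The baseline SS/CS recording follows :func:`gen_pc_recording`; evoked CS
    are inserted per stimulus, and the post-CS SS pause is applied after
    evoked CS as well.
    """
    if n_trials < 0:
        raise ParameterError("n_trials must be non-negative")
    rng_base, rng_stim, rng_evoked = split_rng(seed, 3)
    pad = 1.0
    jit = rng_stim.uniform(-jitter_s, jitter_s, n_trials) if jitter_s > 0 \
        else np.zeros(n_trials)
    if n_trials:
        stim_times = pad + np.concatenate(([0.0], np.cumsum((inter_stim_s + jit)[:-1])))
        duration = float(stim_times[-1] + pad)
    else:
        stim_times = np.empty(0)
        duration = 2 * pad
    base = PCParams(
        ss_rate=template.baseline.ss_rate, ss_cv=template.baseline.ss_cv,
        cs_rate=template.baseline.cs_rate, cs_pause=template.baseline.cs_pause,
        duration=duration)
    rec = gen_pc_recording(base, rng_base)
    fire = rng_evoked.random(n_trials) < template.cs_prob if n_trials else np.empty(0, bool)
    lat = template.cs_latency_ms / 1000.0 + (
        rng_evoked.normal(0.0, template.cs_latency_sd_ms / 1000.0, n_trials)
        if template.cs_latency_sd_ms > 0 else np.zeros(n_trials))
    evoked = stim_times[fire] + lat[fire] if n_trials else np.empty(0)
    evoked = evoked[(evoked > 0) & (evoked < duration)]
    cs_times = np.unique(np.concatenate([rec.cs.times, evoked]))
    ss_times = _apply_cs_pause(rec.ss.times, cs_times, base.cs_pause)
    truth = dict(rec.truth)
    truth.update({"evoked_cs_times": np.sort(evoked), "stim_times": stim_times,
                  "template": template})
    return EvokedSession(
        ss=SpikeTrain(ss_times, duration, "SS"),
        cs=SpikeTrain(cs_times, duration, "CS"),
        stim_times=stim_times, truth=truth)


# ---------------------------------------------------------------------------
# patch-clamp sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchCellParams:
    """Integrate-and-fire cell with a prescribed suprathreshold f-I gain.

    Subthreshold behaviour is the analytic RC response (tau = r_in * c_m);
    the first spike of a step occurs at the RC threshold-crossing time, and
    subsequent spikes are scheduled so the steady firing rate equals
    ``fi_slope * (I - rheobase)``. A stereotyped action-potential waveform
    (quadratic rise over ``ap_rise_ms``, linear fall to ``reset``) is pasted
    at each spike time.
    """

    v_rest: float = -62.0      # mV (held between -60 and -65 mV)
    r_in: float = 35.0         # MOhm
    c_m: float = 600.0         # pF
    v_thresh: float = -41.0    # mV
    reset: float = -55.0       # mV
    fi_slope: float = 0.2      # Hz/pA above rheobase
    ap_peak: float = 20.0      # mV
    ap_rise_ms: float = 0.5
    ap_fall_ms: float = 1.0
    holding_pA: float = 0.0

    def __post_init__(self) -> None:
        if self.v_thresh <= self.v_rest:
            raise ParameterError("v_thresh must exceed v_rest")
        if self.r_in <= 0 or self.c_m <= 0 or self.fi_slope <= 0:
            raise ParameterError("r_in, c_m and fi_slope must be positive")

    @property
    def tau_ms(self) -> float:
        """Membrane time constant in ms (MOhm * pF = us)."""
        return self.r_in * self.c_m / 1000.0

    @property
    def rheobase_pA(self) -> float:
        """Ground-truth rheobase: (v_thresh - v_rest) / r_in, in pA."""
        return (self.v_thresh - self.v_rest) / self.r_in * 1000.0


def make_cell(rheobase_pA: float = 600.0, **overrides) -> PatchCellParams:
    """Build a cell whose ground-truth rheobase is ``rheobase_pA``.

    The threshold voltage is set from the requested rheobase given the cell's
    input resistance; other parameters keep their defaults unless overridden.
    """
    base = PatchCellParams(**{k: v for k, v in overrides.items() if k != "v_thresh"})
    v_thresh = base.v_rest + rheobase_pA * base.r_in / 1000.0
    kw = {k: v for k, v in overrides.items() if k != "v_thresh"}
    return PatchCellParams(v_thresh=v_thresh, **kw)


def gen_cell_population(n: int, rheobase_mean: float = 600.0,
                        rheobase_sd: float = 215.0, seed=None) -> list:
    """Cells with lognormally distributed ground-truth rheobase.

    The lognormal keeps rheobase positive while matching the requested mean
    and SD exactly, so population mean differences are unbiased.
    """
    rng = as_rng(seed)
    sigma2 = math.log(1.0 + (rheobase_sd / rheobase_mean) ** 2)
    mu = math.log(rheobase_mean) - sigma2 / 2.0
    rheo = rng.lognormal(mu, math.sqrt(sigma2), n)
    return [make_cell(r) for r in rheo]


@dataclass(frozen=True)
class StepProtocol:
    """Current-step protocol: +75 pA increments of 750-ms duration."""

    steps_pA: tuple = tuple([-100.0] + [75.0 * k for k in range(1, 21)])
    onset_s: float = 0.1
    dur_s: float = 0.75
    post_s: float = 0.15
    fs: float = 20_000.0

    def __post_init__(self) -> None:
        if not self.steps_pA:
            raise ParameterError("protocol step list must be non-empty")
        if self.dur_s <= 0:
            raise ParameterError("step duration must be positive")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")


def _lif_spike_times(cell: PatchCellParams, step: float,
                     onset: float, dur: float) -> np.ndarray:
    """Spike times (s, absolute) for one step, per the hybrid model."""
    tau = cell.tau_ms / 1000.0
    dv_inf = step * cell.r_in / 1000.0          # mV at steady state
    v_inf = cell.v_rest + dv_inf
    if v_inf <= cell.v_thresh:
        return np.empty(0)
    t_first = tau * math.log(dv_inf / (v_inf - cell.v_thresh))
    if t_first >= dur:
        return np.empty(0)
    f = cell.fi_slope * (step - cell.rheobase_pA)
    times = [onset + t_first]
    if f > 0:
        isi = 1.0 / f
        t = t_first + isi
        while t < dur:
            times.append(onset + t)
            t += isi
    return np.array(times)


def gen_patch_sweeps(cell: PatchCellParams, protocol: StepProtocol,
                     seed=None, noise_sd_mV: float = 0.0,
                     cell_id: str = "") -> SweepSet:
    """Synthesize the full step-protocol sweep set for one cell.

    Each sweep is the analytic RC membrane response with the stereotyped AP
    waveform pasted at the model's spike times; optional Gaussian voltage
    noise is added on top.
    """
    fs = protocol.fs
    dt = 1.0 / fs
    n = int(round((protocol.onset_s + protocol.dur_s + protocol.post_s) * fs))
    tau = cell.tau_ms / 1000.0
    rng = as_rng(seed) if noise_sd_mV > 0 else None
    sweeps = []
    n_rise = max(1, int(round(cell.ap_rise_ms / 1000.0 * fs)))
    n_fall = max(1, int(round(cell.ap_fall_ms / 1000.0 * fs)))
    rise_frac = (np.arange(1, n_rise + 1) / n_rise) ** 2   # quadratic ramp
    fall_frac = np.arange(1, n_fall + 1) / n_fall
    onset_i = int(round(protocol.onset_s * fs))
    offset_i = int(round((protocol.onset_s + protocol.dur_s) * fs))
    for step in protocol.steps_pA:
        vm = np.full(n, cell.v_rest)
        v_inf = cell.v_rest + step * cell.r_in / 1000.0
        spikes = _lif_spike_times(cell, step, protocol.onset_s, protocol.dur_s)
        # exponential segments between resets during the step
        seg_starts = [onset_i]
        seg_v0 = [cell.v_rest]
        spike_idx = np.round(spikes * fs).astype(int)
        for si in spike_idx:
            seg_starts.append(min(si + n_rise + n_fall, offset_i))
            seg_v0.append(cell.reset)
        bounds = list(spike_idx) + [offset_i]
        for (s0, v0), s1 in zip(zip(seg_starts, seg_v0), bounds):
            if s1 < s0:
                continue
            hi = min(s1 + 1, n)  # inclusive so the AP start voltage is defined
            tt = (np.arange(s0, hi) - s0) * dt
            vm[s0:hi] = v_inf + (v0 - v_inf) * np.exp(-tt / tau)
        # paste AP waveforms
        for si in spike_idx:
            v_start = vm[si] if si < n else cell.v_thresh
            hi = min(si + n_rise, n)
            vm[si:hi] = v_start + (cell.ap_peak - v_start) * rise_frac[: hi - si]
            hi2 = min(si + n_rise + n_fall, n)
            vm[si + n_rise: hi2] = cell.ap_peak + \
                (cell.reset - cell.ap_peak) * fall_frac[: hi2 - si - n_rise]
        # relaxation after the step
        if offset_i < n:
            v_off = vm[offset_i - 1] if offset_i > 0 else cell.v_rest
            if v_off > cell.ap_peak - 1e-9 and spike_idx.size:
                v_off = cell.reset  # AP truncated by step end
            tt = (np.arange(offset_i, n) - offset_i) * dt
            vm[offset_i:] = cell.v_rest + (v_off - cell.v_rest) * np.exp(-tt / tau)
        if rng is not None:
            vm = vm + rng.normal(0.0, noise_sd_mV, n)
        sweeps.append(Sweep(vm, fs, cell.holding_pA, step,
                            protocol.onset_s, protocol.dur_s))
    return SweepSet(tuple(sweeps), cell_id=cell_id)


# ---------------------------------------------------------------------------
# morphologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeParams:
    """Branching-tree generator parameters (micrometres)."""

    apical_extent: float = 180.0
    branch_prob: float = 0.35
    segment_len: float = 5.0
    max_depth: int = 3
    spine_density: float = 2.3   # spines/um on the annotated distal dendrite
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.apical_extent <= 0:
            raise ParameterError("apical_extent must be positive")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ParameterError("branch_prob must lie in [0, 1]")
        if self.segment_len <= 0:
            raise ParameterError("segment_len must be positive")
        if self.spine_density < 0:
            raise ParameterError("spine_density must be non-negative")


def gen_morphology(params: TreeParams, seed=None):
    """Rooted SWC tree with a straight apical trunk and lateral branches.

    The trunk runs from the soma (origin) straight along +y for exactly
    ``apical_extent`` um, so the farthest node from the soma equals the
    apical extent by construction. Lateral branches spawn at trunk nodes
    below 70% of the extent with probability ``branch_prob``; branch tips
    stay strictly closer to the soma than the trunk tip. Spines are placed
    as a Poisson process along the distal 10 um of the trunk.

    Returns ``(Morphology, spines DataFrame(node_id, arc_pos_um))``.
    """
    if seed is None:
        seed = params.seed
    rng = as_rng(seed)
    seg = params.segment_len
    ext = params.apical_extent
    ids = [1]
    types = [1]
    xyz = [(0.0, 0.0, 0.0)]
    radii = [5.0]
    parents = [-1]
    next_id = 2

    def add_node(parent_id, pos, ntype=4, radius=1.0):
        nonlocal next_id
        ids.append(next_id)
        types.append(ntype)
        xyz.append(tuple(pos))
        radii.append(radius)
        parents.append(parent_id)
        next_id += 1
        return next_id - 1

    # main apical trunk, straight +y, total length exactly `ext`; the first
    # segment is a half step so interior nodes sit off any radius grid that
    # shares the segment spacing (keeps circle crossings transversal)
    lengths = [seg / 2.0]
    remaining = ext - seg / 2.0
    n_full = int(remaining // seg)
    lengths += [seg] * n_full
    if remaining - n_full * seg > 1e-9:
        lengths.append(remaining - n_full * seg)
    trunk_ids = []
    y = 0.0
    parent = 1
    for L in lengths:
        y += L
        parent = add_node(parent, (0.0, y, 0.0))
        trunk_ids.append((parent, y))

    def grow_branch(attach_id, attach_pos, length, depth):
        nonlocal rng
        phi = rng.uniform(0.0, 2.0 * math.pi)
        theta = rng.uniform(math.radians(60.0), math.radians(90.0))
        direction = np.array([math.sin(theta) * math.cos(phi),
                              math.cos(theta),
                              math.sin(theta) * math.sin(phi)])
        n_seg = max(1, int(round(length / seg)))
        pos = np.asarray(attach_pos, dtype=float)
        parent = attach_id
        for i in range(n_seg):
            pos = pos + direction * (length / n_seg)
            parent = add_node(parent, pos)
            if depth < params.max_depth and rng.random() < params.branch_prob:
                grow_branch(parent, pos, length / 2.0, depth + 1)

    if params.branch_prob > 0:
        for node_id, h in trunk_ids:
            if h >= 0.7 * ext:
                continue
            if rng.random() < params.branch_prob:
                length = min(0.3 * ext, rng.uniform(10.0, 40.0))
                grow_branch(node_id, (0.0, h, 0.0), length, 1)

    morph = Morphology(np.array(ids), np.array(types), np.array(xyz),
                       np.array(radii), np.array(parents), soma_id=1)

    # spine annotations on the distal 10 um of the trunk
    dend_len = min(10.0, ext)
    n_spines = rng.poisson(params.spine_density * dend_len)
    arc = np.sort(rng.uniform(0.0, dend_len, n_spines))
    # attach each spine to the nearest trunk node in the distal segment
    tip_id = trunk_ids[-1][0]
    spines = pd.DataFrame({
        "node_id": np.full(n_spines, tip_id, dtype=int),
        "arc_pos_um": arc,
    })
    return morph, spines


# ---------------------------------------------------------------------------
# extracellular trace rendering
# ---------------------------------------------------------------------------

def render_spike_trace(train: SpikeTrain, fs: float = DEFAULT_FS_HZ,
                       amplitude: float = 200.0, noise_sd: float = 0.0,
                       seed=None, units: str = "uV") -> ContinuousTrace:
    """Render spike times as a voltage trace with a fixed biphasic template.

    Each spike adds a short biphasic waveform (positive deflection of
    ``amplitude`` rising over ~0.12 ms, a ~0.2-ms peak plateau, then a small
    undershoot) at its spike time, on Gaussian background noise. Used to
    exercise threshold-crossing spike detection against ground-truth times.
    """
    n = int(round(train.duration * fs))
    rng = as_rng(seed)
    data = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    n_rise = max(2, int(round(0.12e-3 * fs)))
    n_top = max(2, int(round(0.2e-3 * fs)))
    n_fall = max(2, int(round(0.3e-3 * fs)))
    n_under = max(2, int(round(0.4e-3 * fs)))
    tpl = np.concatenate([
        np.linspace(0.0, 1.0, n_rise, endpoint=False),
        np.ones(n_top),
        np.linspace(1.0, -0.3, n_fall, endpoint=False),
        np.linspace(-0.3, 0.0, n_under),
    ]) * amplitude
    # align the start of the peak plateau with the spike time
    idx = np.round(train.times * fs).astype(int) - n_rise
    for i in idx:
        lo = max(i, 0)
        hi = min(i + tpl.size, n)
        if hi > lo:
            data[lo:hi] += tpl[lo - i: hi - i]
    return ContinuousTrace(data, fs, units)
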