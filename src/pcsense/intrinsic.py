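"""Patch-clamp sweep analysis: action potentials, rheobase, f-I curves,
AP threshold and passive membrane properties.

Rheobase is the smallest net depolarizing step (relative to holding) whose
sweep fires at least one AP during the step. The f-I analysis is
rheobase-normalised: for each suprathreshold sweep the instantaneous
frequencies (1/ISI) between the first six APs are averaged and plotted
against step - rheobase; the excitability slope is the OLS slope of those
points. AP threshold follows the 5%-of-maximal-rise-slope criterion on the
first spike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import optimize

from .core import DataError, ParameterError, Sweep, SweepSet

__all__ = [
    "ExcitabilityResult",
    "PassiveProps",
    "detect_aps",
    "rheobase",
    "ap_threshold",
    "fi_curve",
    "fi_slope",
    "passive_props",
    "analyze_cell",
]

DEFAULT_AP_DETECT_MV = 0.0
DEFAULT_LOCKOUT_MS = 2.0
MAX_FI_APS = 6
# QC limits on sweep metadata (exclusion rules, flagged not enforced)
MAX_ACCESS_RESISTANCE_MOHM = 16.0
MIN_HOLDING_PA = -500.0


@dataclass(frozen=True)
class ExcitabilityResult:
    """Rheobase, rheobase-normalised f-I points and slope, AP threshold."""

    rheobase_pA: float
    fi_points: tuple            # of (delta_I_pA, mean_inst_freq_Hz)
    fi_slope: float             # Hz/pA
    ap_threshold_mV: float


@dataclass(frozen=True)
class PassiveProps:
    """Resting potential, input resistance and membrane capacitance."""

    v_rest: float   # mV
    r_in: float     # MOhm
    c_m: float      # pF
    tau_ms: float


def detect_aps(vm: np.ndarray, fs: float,
               threshold_mV: float = DEFAULT_AP_DETECT_MV,
               lockout_ms: float = DEFAULT_LOCKOUT_MS,
               window_ms: Tuple[float, float] = (-5.0, 5.0)):
    """Detect APs as upward crossings of ``threshold_mV`` with a lockout.

    Returns ``(times_s, windows)`` where each window is the Vm segment
    ``window_ms`` around the crossing (clipped at the sweep edges). Doublets
    closer than the lockout merge into one detection.
    """
    vm = np.asarray(vm, float)
    crossings = np.flatnonzero((vm[:-1] < threshold_mV) & (vm[1:] >= threshold_mV)) + 1
    lock = int(round(lockout_ms / 1000.0 * fs))
    kept = []
    for i in crossings:
        if not kept or i - kept[-1] >= lock:
            kept.append(int(i))
    lo_off = int(round(window_ms[0] / 1000.0 * fs))
    hi_off = int(round(window_ms[1] / 1000.0 * fs))
    windows = [vm[max(0, i + lo_off): min(vm.size, i + hi_off)] for i in kept]
    return np.array(kept) / fs, windows


def _aps_in_step(sweep: Sweep, **kw) -> np.ndarray:
    times, _ = detect_aps(sweep.vm, sweep.fs, **kw)
    sel = (times >= sweep.onset_s) & (times < sweep.onset_s + sweep.dur_s)
    return times[sel]


def rheobase(sweeps: SweepSet, **detect_kw) -> float:
    """Smallest step amplitude whose sweep fires >= 1 AP during the step.

    "Net" current means the step amplitude relative to holding, which is how
    the sweeps are parameterised. Returns NaN (with a warning) if no sweep
    fires.
    """
    if len(sweeps) == 0:
        raise ParameterError("rheobase requires at least one sweep")
    for sw in sweeps:
        if sw.step_pA <= 0:
            continue
        if _aps_in_step(sw, **detect_kw).size:
            return float(sw.step_pA)
    warnings.warn("no sweep fired during the step; rheobase undefined")
    return float("nan")


def ap_threshold(window_vm: np.ndarray, fs: float,
                 smooth: bool = False) -> float:
    """AP threshold: Vm where dV/dt first reaches 5% of the maximal rise slope.

    dV/dt is taken by central differences at the native sampling rate;
    optional 3-point smoothing of the derivative guards against noise
    producing a spurious early 5% crossing. The search is restricted to
    samples before the AP peak.
    """
    v = np.asarray(window_vm, float)
    if v.size < 5:
        raise DataError("AP window too short for a derivative estimate")
    dvdt = np.gradient(v) * fs
    if smooth:
        dvdt = np.convolve(dvdt, np.ones(3) / 3.0, mode="same")
    peak = int(np.argmax(v))
    if peak == 0:
        raise DataError("AP window contains no rising phase")
    rise = dvdt[:peak + 1]
    max_slope = rise.max()
    if max_slope <= 0:
        raise DataError("no positive rise slope in the AP window")
    idx = np.flatnonzero(rise >= 0.05 * max_slope)
    return float(v[idx[0]])


def fi_curve(sweeps: SweepSet, rheobase_pA: float, **detect_kw) -> tuple:
    """Rheobase-normalised f-I points.

    For every suprathreshold sweep, the first ``min(6, n)`` APs give up to 5
    instantaneous frequencies (1/ISI) whose mean is one point at
    x = step - rheobase. Sweeps with a single AP have no defined frequency
    and are excluded.
    """
    if not np.isfinite(rheobase_pA):
        raise ParameterError("rheobase must be defined for the f-I analysis")
    points = []
    for sw in sweeps:
        if sw.step_pA < rheobase_pA:
            continue
        times = _aps_in_step(sw, **detect_kw)
        if times.size < 2:
            continue
        first = times[:MAX_FI_APS]
        freqs = 1.0 / np.diff(first)
        points.append((float(sw.step_pA - rheobase_pA), float(freqs.mean())))
    return tuple(points)


def fi_slope(fi_points) -> float:
    """OLS slope (Hz/pA) of mean instantaneous frequency vs current above
    rheobase. Undefined (NaN) with fewer than 2 points."""
    pts = np.asarray(fi_points, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return float("nan")
    x, y = pts[:, 0], pts[:, 1]
    return float(np.polyfit(x, y, 1)[0])


def passive_props(sweep: Sweep, baseline_s: Optional[Tuple[float, float]] = None
                  ) -> PassiveProps:
    """Passive membrane properties from a subthreshold (hyperpolarizing) step.

    v_rest is the mean Vm over the zero-current segment before the step;
    r_in = steady-state deflection / step amplitude; tau comes from a
    mono-exponential fit of the step onset and c_m = tau / r_in.
    """
    if sweep.step_pA == 0:
        raise ParameterError("zero-amplitude step: input resistance undefined")
    fs = sweep.fs
    vm = sweep.vm
    onset_i = int(round(sweep.onset_s * fs))
    offset_i = int(round((sweep.onset_s + sweep.dur_s) * fs))
    if baseline_s is None:
        b0, b1 = 0, onset_i
    else:
        b0, b1 = (int(round(s * fs)) for s in baseline_s)
    v_rest = float(vm[b0:b1].mean())
    # steady state: last 20% of the step
    ss0 = offset_i - max(1, (offset_i - onset_i) // 5)
    v_ss = float(vm[ss0:offset_i].mean())
    dv = v_ss - v_rest
    r_in = dv / (sweep.step_pA / 1000.0)   # mV / nA = MOhm
    if r_in <= 0:
        raise DataError("non-positive input resistance estimate")
    # mono-exponential fit of the onset transient
    seg = vm[onset_i:offset_i]
    t = np.arange(seg.size) / fs
    def model(t, tau):
        return v_ss + (v_rest - v_ss) * np.exp(-t / tau)
    try:
        popt, _ = optimize.curve_fit(model, t, seg, p0=[0.02],
                                     bounds=(1e-6, 10.0))
    except RuntimeError as exc:  # pragma: no cover - fit failure flag
        raise DataError(f"exponential fit failed: {exc}") from exc
    tau = float(popt[0])
    c_m = tau / r_in * 1e6   # s/MOhm = uF -> pF
    return PassiveProps(v_rest=v_rest, r_in=float(r_in), c_m=float(c_m),
                        tau_ms=tau * 1000.0)


def analyze_cell(sweeps: SweepSet, **detect_kw) -> ExcitabilityResult:
    """Full excitability work-up of one cell's sweep set."""
    rheo = rheobase(sweeps, **detect_kw)
    pts = fi_curve(sweeps, rheo, **detect_kw) if np.isfinite(rheo) else ()
    slope = fi_slope(pts)
    thr = float("nan")
    if np.isfinite(rheo):
        for sw in sweeps:
            if sw.step_pA == rheo:
                times, windows = detect_aps(sw.vm, sw.fs, **detect_kw)
                in_step = [(t, w) for t, w in zip(times, windows)
                           if sw.onset_s <= t < sw.onset_s + sw.dur_s]
                if in_step:
                    thr = ap_threshold(in_step[0][1], sw.fs)
                break
    return ExcitabilityResult(rheobase_pA=rheo, fi_points=pts,
                              fi_slope=slope, ap_threshold_mV=thr)
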