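"""Sensory-evoked-potential (SEP) and stimulus-locked spiking analysis.

The SEP pipeline segments the continuous field recording into 70-ms windows
around each stimulus ([-20, +50) ms, 0 = stimulus onset), subtracts the mean
of the 20-ms pre-stimulus interval per trial, averages, detects the negative
components of the average, and compares groups pointwise with Student's t.

The spiking side computes a peri-stimulus occupancy histogram (PSTH): per
neuron and 1-ms bin, the fraction of trials with at least one spike in the
bin, and compares genotype groups with a mixed two-way ANOVA (genotype x
time-bin) followed by per-bin Holm-Sidak-adjusted t comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal as _signal

from .core import ContinuousTrace, DataError, EpochSet, ParameterError, SpikeTrain
from . import stats as _stats

__all__ = [
    "SEPComponent",
    "PSTH",
    "segment",
    "baseline_correct",
    "average_sep",
    "compare_seps",
    "detect_components",
    "compute_psth",
    "compare_psth",
]

log = logging.getLogger(__name__)

PRE_MS = 20.0
TOTAL_MS = 70.0
DEFAULT_PROMINENCE_FACTOR = 3.0
DEFAULT_SMOOTH_SIGMA_MS = 0.3


@dataclass(frozen=True)
class SEPComponent:
    """One negative SEP component of an averaged trace."""

    latency_ms: float
    amplitude: float          # signed, at the minimum
    polarity: str = "negative"


@dataclass(frozen=True)
class PSTH:
    """Per-neuron firing probability per peri-stimulus bin.

    ``probs`` is (n_neurons, n_bins): the fraction of trials in which the
    neuron fired at least once inside the bin.
    """

    bin_edges_ms: np.ndarray
    probs: np.ndarray
    label: str = "unknown"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, float)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "bin_edges_ms",
                           np.asarray(self.bin_edges_ms, float))
        if np.any((p < 0) | (p > 1)):
            raise DataError("PSTH probabilities must lie in [0, 1]")

    @property
    def bin_centers_ms(self) -> np.ndarray:
        e = self.bin_edges_ms
        return (e[:-1] + e[1:]) / 2.0


def segment(trace: ContinuousTrace, stim_times: np.ndarray,
            pre_ms: float = PRE_MS, total_ms: float = TOTAL_MS,
            source: str = "") -> EpochSet:
    """Cut one epoch per stimulus: [stim - pre_ms, stim + total_ms - pre_ms).

    Stimuli whose full window does not fit inside the trace are dropped with
    a logged warning. An empty stimulus table yields an empty EpochSet.
    """
    stim_times = np.asarray(stim_times, float)
    if stim_times.size and np.any(np.diff(stim_times) < 0):
        raise DataError("stimulus times must be sorted")
    fs = trace.fs
    n_samp = int(round(total_ms / 1000.0 * fs))
    pre_samp = int(round(pre_ms / 1000.0 * fs))
    starts = np.round(stim_times * fs).astype(int) - pre_samp
    ok = (starts >= 0) & (starts + n_samp <= trace.n_samples)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        log.warning("segment: dropped %d stimuli whose window falls outside "
                    "the trace", n_dropped)
    starts = starts[ok]
    if starts.size == 0:
        log.warning("segment: no valid stimuli; returning an empty EpochSet")
        data = np.empty((0, n_samp))
    else:
        data = np.stack([trace.data[s: s + n_samp] for s in starts])
    times_ms = (np.arange(n_samp) - pre_samp) / fs * 1000.0
    return EpochSet(data, times_ms, fs, source=source)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's mean over the pre-stimulus interval [-pre, 0).

    Idempotent; after correction every trial's pre-stimulus mean is zero to
    machine precision.
    """
    if epochs.n_trials == 0:
        return epochs
    pre = epochs.pre_mask
    if not pre.any():
        raise DataError("epochs contain no pre-stimulus samples")
    base = epochs.data[:, pre].mean(axis=1, keepdims=True)
    return EpochSet(epochs.data - base, epochs.times_ms, epochs.fs, epochs.source)


def average_sep(epochs: EpochSet) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM (SD/sqrt(n)) across trials.

    With a single trial the mean is the trial itself and the SEM is NaN.
    """
    if epochs.n_trials == 0:
        raise DataError("cannot average an empty EpochSet")
    mean = epochs.data.mean(axis=0)
    if epochs.n_trials < 2:
        return mean, np.full_like(mean, np.nan)
    sem = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
    return mean, sem


def compare_seps(group_a: Sequence[np.ndarray], group_b: Sequence[np.ndarray],
                 times_ms: np.ndarray, alpha: float = 0.05):
    """Pointwise two-tailed Student's t between per-animal average SEPs.

    ``group_a``/``group_b`` are lists of per-animal mean traces sharing
    ``times_ms``. Returns ``(pvals, spans)`` where ``spans`` is a list of
    (onset_ms, offset_ms) covering contiguous runs with p < alpha. No
    correction across latencies is applied (raw p < alpha spans).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ParameterError("need at least 2 animals per group")
    if a.shape[1] != b.shape[1] or a.shape[1] != len(times_ms):
        raise DataError("groups must share the time axis")
    n_a, n_b = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    from scipy import stats as sps
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # zero pooled variance with equal means: no evidence of difference
    zero = denom == 0
    p[zero & (ma == mb)] = 1.0
    p[zero & (ma != mb)] = 0.0
    sig = p < alpha
    spans = []
    lab, n_runs = ndimage.label(sig)
    for r in range(1, n_runs + 1):
        idx = np.flatnonzero(lab == r)
        spans.append((float(times_ms[idx[0]]), float(times_ms[idx[-1]])))
    return p, spans


def detect_components(mean_trace: np.ndarray, times_ms: np.ndarray,
                      noise_sd: float,
                      prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
                      search_ms: Tuple[float, float] = (0.0, 50.0),
                      smooth_sigma_ms: float = DEFAULT_SMOOTH_SIGMA_MS,
                      fs: Optional[float] = None) -> List[SEPComponent]:
    """Detect negative components of a baseline-corrected average SEP.

    The average is lightly Gaussian-smoothed (``smooth_sigma_ms``) to keep
    sample-level noise from displacing the minima, then local negative
    minima within ``search_ms`` whose depth and prominence both exceed
    ``prominence_factor`` x ``noise_sd`` are reported with sample-precision
    latency and (unsmoothed-scale) amplitude.

    ``noise_sd`` should be the per-trial pre-stimulus noise floor (pooled SD
    over trials of the pre-stimulus samples), not the SD of the average.
    """
    y = np.asarray(mean_trace, float)
    times_ms = np.asarray(times_ms, float)
    if fs is None:
        fs = 1000.0 / np.median(np.diff(times_ms))
    if smooth_sigma_ms > 0:
        sigma_samp = smooth_sigma_ms / 1000.0 * fs
        ys = ndimage.gaussian_filter1d(y, sigma_samp, mode="nearest")
    else:
        ys = y
    floor = max(prominence_factor * noise_sd, 1e-12 * max(np.ptp(ys), 1.0), 1e-300)
    peaks, props = _signal.find_peaks(-ys, height=floor, prominence=floor)
    window = (times_ms[peaks] > search_ms[0]) & (times_ms[peaks] <= search_ms[1])
    peaks = peaks[window]
    return [SEPComponent(latency_ms=float(times_ms[i]), amplitude=float(y[i]))
            for i in peaks]


def compute_psth(trains: Sequence[SpikeTrain], stim_times: np.ndarray,
                 bin_ms: float = 1.0,
                 window_ms: Tuple[float, float] = (-20.0, 50.0),
                 label: str = "unknown") -> PSTH:
    """Trial-occupancy PSTH: fraction of trials with >= 1 spike per bin.

    All neurons share the stimulus table. Bin edges run over ``window_ms``
    with width ``bin_ms``.
    """
    stim_times = np.asarray(stim_times, float)
    if stim_times.size == 0:
        raise ParameterError("compute_psth requires at least one stimulus")
    lo, hi = window_ms
    edges = np.arange(lo, hi + bin_ms / 2.0, bin_ms)
    n_bins = edges.size - 1
    probs = np.zeros((len(trains), n_bins))
    for i, train in enumerate(trains):
        occupied = np.zeros((stim_times.size, n_bins), bool)
        for j, stim in enumerate(stim_times):
            rel = (train.times - stim) * 1000.0
            rel = rel[(rel >= lo) & (rel < hi)]
            if rel.size:
                k = np.floor((rel - lo) / bin_ms).astype(int)
                occupied[j, np.clip(k, 0, n_bins - 1)] = True
        probs[i] = occupied.mean(axis=0)
    return PSTH(edges, probs, label=label)


def compare_psth(psth_a: PSTH, psth_b: PSTH, alpha: float = 0.05) -> dict:
    """Mixed two-way ANOVA (group x time-bin) plus per-bin Holm-Sidak tests.

    Neurons are the subjects (between factor: group; within factor:
    time-bin). Returns the ANOVA result, per-bin raw and adjusted p-values,
    and reject flags.
    """
    if psth_a.probs.shape[1] != psth_b.probs.shape[1]:
        raise ParameterError("PSTHs must share the bin grid")
    if psth_a.probs.shape[0] < 2 or psth_b.probs.shape[0] < 2:
        raise ParameterError("need at least 2 neurons per group")
    data = np.vstack([psth_a.probs, psth_b.probs])
    groups = ["A"] * psth_a.probs.shape[0] + ["B"] * psth_b.probs.shape[0]
    anova = _stats.mixed_anova(data, groups)
    n_bins = data.shape[1]
    raw = np.empty(n_bins)
    for j in range(n_bins):
        a = psth_a.probs[:, j]
        b = psth_b.probs[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raw[j] = 1.0 if a.mean() == b.mean() else 0.0
        else:
            raw[j] = _stats.student_t(a, b)[1]
    adj, reject = _stats.holm_sidak(raw, alpha=alpha)
    return {
        "anova": anova,
        "p_raw": raw,
        "p_adjusted": adj,
        "reject": reject,
        "bin_centers_ms": psth_a.bin_centers_ms,
    }
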