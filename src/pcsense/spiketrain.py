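"""Single-unit spike-train processing and statistics.

Covers DC-drift removal, threshold-crossing spike detection, pause-based
complex-spike classification, the minimum-duration inclusion rule, and the
per-unit statistics used throughout: firing rate, predominant firing rate
(the mode of the instantaneous rate), and the global (CV) and local (CV2)
interspike-interval regularity measures

    CV  = sigma_ISI / mu_ISI
    CV2 = mean over adjacent pairs of 2|ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n)

CV uses the population (1/n) standard deviation so the hand-computable
oracles are exact. Firing rate is n_spikes / duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as _signal

from .core import ContinuousTrace, DataError, ParameterError, SpikeTrain

__all__ = [
    "TrainStats",
    "dc_remove",
    "detect_spikes",
    "classify_cs",
    "qc_min_duration",
    "train_stats",
]

MIN_RECORDING_S = 100.0   # inclusion rule: at least 100 s of recording
DEFAULT_RATE_BIN_HZ = 2.0
DEFAULT_CS_PAUSE_THRESHOLD_S = 0.010


@dataclass(frozen=True)
class TrainStats:
    """Per-unit firing statistics. Undefined fields are NaN, never zero."""

    rate: float
    predominant_rate: float
    cv: float
    cv2: float
    n_spikes: int
    duration: float
    label: str = "unknown"


def dc_remove(trace: ContinuousTrace, tau: float) -> ContinuousTrace:
    """Remove slow DC drift with a single-pole high-pass filter.

    Subtracts an exponentially weighted running mean with time constant
    ``tau`` seconds, i.e. applies H(z) = a (1 - z^-1) / (1 - a z^-1) with
    a = exp(-1 / (fs * tau)). Length and sampling rate are preserved; the
    running mean is initialised at the first sample so a constant trace maps
    to zeros immediately.
    """
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    a = np.exp(-1.0 / (trace.fs * tau))
    x = trace.data
    if x.size == 0:
        return trace
    # running mean m[n] = a m[n-1] + (1-a) x[n]
    zi = _signal.lfiltic([1.0 - a], [1.0, -a], [x[0]], [x[0]])
    m, _ = _signal.lfilter([1.0 - a], [1.0, -a], x, zi=zi)
    return ContinuousTrace(x - m, trace.fs, trace.units, trace.channel)


def detect_spikes(trace: ContinuousTrace, threshold: float,
                  refractory: float = 0.001) -> SpikeTrain:
    """Threshold-crossing spike detection.

    A positive ``threshold`` detects upward crossings (previous sample below,
    current sample at/above threshold); a negative one detects downward
    crossings. Crossings within ``refractory`` seconds of the previous
    accepted event are suppressed. Event time = crossing sample / fs.
    """
    if refractory < 0:
        raise ParameterError("refractory must be non-negative")
    x = trace.data
    if not np.all(np.isfinite(x)):
        raise DataError("trace contains non-finite samples")
    if x.size < 2:
        return SpikeTrain(np.empty(0), max(trace.duration, np.finfo(float).tiny),
                          "unknown")
    if threshold >= 0:
        crossings = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    else:
        crossings = np.flatnonzero((x[:-1] > threshold) & (x[1:] <= threshold)) + 1
    times = crossings / trace.fs
    if refractory > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.array(kept)
    return SpikeTrain(times, trace.duration, "unknown")


def classify_cs(events: SpikeTrain,
                pause_threshold: float = DEFAULT_CS_PAUSE_THRESHOLD_S,
                isi_factor: float = 2.0) -> Tuple[SpikeTrain, SpikeTrain]:
    """Partition a mixed event train into (SS, CS) by the trailing-pause rule.

    An event is classified CS iff the gap to the next event (for the last
    event, to the end of the recording) reaches the pause criterion
    ``max(pause_threshold, isi_factor * median ISI)``; every other event is
    SS. The median-ISI term makes the criterion relative to the train's own
    firing, so a slow but regular train (every gap above the absolute
    threshold) yields no CS; with fewer than 2 events the absolute threshold
    alone applies. The partition is exhaustive and disjoint.

    This is a stand-in for waveform-based sorting and is only reliable when
    the post-CS pause is long relative to the upper tail of the SS ISI
    distribution; with short pauses or slow/irregular SS firing, SS events
    are frequently followed by qualifying gaps and precision degrades.
    """
    if pause_threshold <= 0:
        raise ParameterError("pause_threshold must be positive")
    t = events.times
    if t.size == 0:
        empty = np.empty(0)
        return (SpikeTrain(empty, events.duration, "SS"),
                SpikeTrain(empty, events.duration, "CS"))
    trailing = np.empty(t.size)
    trailing[:-1] = np.diff(t)
    trailing[-1] = events.duration - t[-1]
    criterion = pause_threshold
    if t.size >= 2:
        criterion = max(criterion, isi_factor * float(np.median(np.diff(t))))
    is_cs = trailing >= criterion
    return (SpikeTrain(t[~is_cs], events.duration, "SS"),
            SpikeTrain(t[is_cs], events.duration, "CS"))


def qc_min_duration(train: SpikeTrain, min_s: float = MIN_RECORDING_S) -> bool:
    """Inclusion rule: accept only units recorded for at least ``min_s``."""
    return train.duration >= min_s


def train_stats(train: SpikeTrain,
                rate_bin: float = DEFAULT_RATE_BIN_HZ) -> TrainStats:
    """Firing rate, predominant rate, CV and CV2 of one unit.

    The predominant rate is the centre of the modal bin of the
    instantaneous-rate (1/ISI) histogram, with bins of width ``rate_bin``
    centred on integer multiples of ``rate_bin``; ties break toward the
    lower rate. CV and CV2 need at least 3 spikes (two ISIs); undefined
    statistics are returned as NaN, never zero-filled.
    """
    if rate_bin <= 0:
        raise ParameterError("rate_bin must be positive")
    n = train.n_spikes
    rate = n / train.duration
    cv = cv2 = predominant = float("nan")
    if n >= 3:
        isis = train.isis
        mu = isis.mean()
        cv = isis.std() / mu  # population SD
        pair_sum = isis[1:] + isis[:-1]
        cv2 = float(np.mean(2.0 * np.abs(np.diff(isis)) / pair_sum))
        inst = 1.0 / isis
        # bins centred on multiples of rate_bin
        k = np.floor(inst / rate_bin + 0.5).astype(int)
        counts = np.bincount(k)
        predominant = float(np.argmax(counts) * rate_bin)  # argmax -> lowest tie
    return TrainStats(rate=rate, predominant_rate=predominant, cv=cv, cv2=cv2,
                      n_spikes=n, duration=train.duration, label=train.label)
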