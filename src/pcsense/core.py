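"""Core data containers shared across the analysis modules.

Everything is a thin, validated wrapper over numpy arrays: spike times in
seconds, continuous voltage in the units stated on the trace (microvolts for
extracellular field recordings, millivolts for patch-clamp sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "ContinuousTrace",
    "EpochSet",
    "Sweep",
    "SweepSet",
    "Morphology",
    "ParameterError",
    "DataError",
]


class ParameterError(ValueError):
    """Invalid analysis or generator parameter."""


class DataError(ValueError):
    """Malformed or internally inconsistent input data."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit over a known recording duration.

    Parameters
    ----------
    times : array of float
        Spike times in seconds, strictly increasing, within [0, duration).
    duration : float
        Recording duration in seconds.
    label : str
        Unit label, one of ``"SS"``, ``"CS"`` or ``"unknown"``.
    """

    times: np.ndarray
    duration: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if t.ndim != 1:
            raise DataError("spike times must be a 1-D array")
        if t.size:
            if not np.all(np.diff(t) > 0):
                raise DataError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.duration:
                raise DataError("spike times must lie within [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds (length ``n_spikes - 1``)."""
        return np.diff(self.times)

    @property
    def rate(self) -> float:
        """Mean firing rate, spikes per second over the full duration."""
        return self.n_spikes / self.duration

    def rescaled(self, c: float) -> "SpikeTrain":
        """Multiply all times (and the duration) by ``c > 0``."""
        if c <= 0:
            raise ParameterError("rescale factor must be positive")
        return SpikeTrain(self.times * c, self.duration * c, self.label)


@dataclass(frozen=True)
class ContinuousTrace:
    """Uniformly sampled continuous signal (typically voltage)."""

    data: np.ndarray
    fs: float
    units: str = "uV"
    channel: str = "lfp"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if d.ndim != 1:
            raise DataError("trace data must be 1-D")

    @property
    def n_samples(self) -> int:
        return int(self.data.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-aligned trial matrix with a shared relative time axis.

    ``data`` is (n_trials, n_samples); ``times_ms`` runs from ``-pre_ms``
    to ``total_ms - pre_ms`` (half-open), 0 = stimulus onset.
    """

    data: np.ndarray
    times_ms: np.ndarray
    fs: float
    source: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        t = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "times_ms", t)
        if d.ndim != 2:
            raise DataError("epoch data must be 2-D (trials x samples)")
        if t.ndim != 1 or t.size != d.shape[1]:
            raise DataError("time axis must match the sample dimension")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def pre_mask(self) -> np.ndarray:
        """Boolean mask of the pre-stimulus samples (t < 0)."""
        return self.times_ms < 0.0


@dataclass(frozen=True)
class Sweep:
    """One current-clamp sweep: membrane voltage plus its current step."""

    vm: np.ndarray          # mV
    fs: float               # Hz
    holding_pA: float
    step_pA: float          # net step relative to holding
    onset_s: float
    dur_s: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vm, dtype=float)
        object.__setattr__(self, "vm", v)
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.dur_s <= 0:
            raise ParameterError("step duration must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.vm.size) / self.fs


@dataclass(frozen=True)
class SweepSet:
    """A cell's step-protocol sweeps, ordered by increasing step amplitude."""

    sweeps: tuple
    cell_id: str = ""

    def __post_init__(self) -> None:
        sw = tuple(self.sweeps)
        object.__setattr__(self, "sweeps", sw)
        steps = [s.step_pA for s in sw]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise DataError("sweep steps must be strictly increasing")

    def __iter__(self):
        return iter(self.sweeps)

    def __len__(self) -> int:
        return len(self.sweeps)

    @property
    def steps_pA(self) -> np.ndarray:
        return np.array([s.step_pA for s in self.sweeps])


@dataclass(frozen=True)
class Morphology:
    """SWC node tree (id, type, x, y, z, radius, parent) plus the soma id.

    Node coordinates are in micrometres. The tree must have a single root
    (parent −1) and every parent must precede its child.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray       # (n, 3) um
    radii: np.ndarray
    parents: np.ndarray   # parent node id, -1 for the root
    soma_id: int = 1

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=int)
        parents = np.asarray(self.parents, dtype=int)
        xyz = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "types", np.asarray(self.types, dtype=int))
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "parents", parents)
        if ids.size == 0:
            raise DataError("morphology has no nodes")
        if xyz.shape != (ids.size, 3):
            raise DataError("xyz must be (n_nodes, 3)")
        roots = np.flatnonzero(parents == -1)
        if roots.size != 1:
            raise DataError(f"morphology must have exactly one root, found {roots.size}")
        index = {int(i): k for k, i in enumerate(ids)}
        if len(index) != ids.size:
            raise DataError("duplicate node ids")
        for k, p in enumerate(parents):
            if p == -1:
                continue
            if p not in index:
                raise DataError(f"node {ids[k]} references missing parent {p}")
            if index[p] >= k:
                raise DataError(f"parent {p} does not precede child {ids[k]}")
        if self.soma_id not in index:
            raise DataError(f"soma id {self.soma_id} not among node ids")
        object.__setattr__(self, "_index", index)

    @property
    def n_nodes(self) -> int:
        return int(self.ids.size)

    def node_xyz(self, node_id: int) -> np.ndarray:
        return self.xyz[self._index[int(node_id)]]

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.node_xyz(self.soma_id)

    def edges(self) -> np.ndarray:
        """(n_edges, 2) array of (parent_row, child_row) indices."""
        rows = []
        for k, p in enumerate(self.parents):
            if p != -1:
                rows.append((self._index[int(p)], k))
        return np.array(rows, dtype=int).reshape(-1, 2)
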