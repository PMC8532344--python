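"""File formats: events CSV, raw trace (.dat + JSON sidecar), SWC, spine and
protocol CSVs. Everything round-trips losslessly; tables carry explicit
units in their column names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import ContinuousTrace, DataError, Morphology, Sweep, SweepSet

__all__ = [
    "read_events", "write_events",
    "read_trace", "write_trace",
    "read_swc", "write_swc",
    "read_spines", "write_spines",
    "read_sweepset", "write_sweepset",
]

VALID_LABELS = {"SS", "CS", "STIM"}
EVENT_COLUMNS = ["time_s", "unit_id", "label"]


def write_events(path, table: pd.DataFrame) -> None:
    """Write an event table (columns time_s, unit_id, label) as CSV."""
    _validate_events(table)
    table.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    """Read and validate an events CSV; times must be monotone per unit."""
    table = pd.read_csv(path)
    if list(table.columns) != EVENT_COLUMNS:
        raise DataError(f"events CSV must have columns {EVENT_COLUMNS}, "
                        f"got {list(table.columns)}")
    _validate_events(table)
    return table


def _validate_events(table: pd.DataFrame) -> None:
    bad = set(table["label"].unique()) - VALID_LABELS if len(table) else set()
    if bad:
        raise DataError(f"invalid event labels: {sorted(bad)}; "
                        f"allowed: {sorted(VALID_LABELS)}")
    for unit, sub in table.groupby("unit_id"):
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            rows = sub.index[1:][np.diff(t) <= 0].tolist()
            raise DataError(
                f"unsorted or duplicate timestamps for unit {unit} at rows {rows}")


def write_trace(path, trace: ContinuousTrace) -> None:
    """Write a trace as float32 little-endian .dat plus a JSON sidecar."""
    path = Path(path)
    trace.data.astype("<f4").tofile(path)
    sidecar = {
        "fs_hz": trace.fs,
        "units": trace.units,
        "n_samples": trace.n_samples,
        "channel": trace.channel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trace(path) -> ContinuousTrace:
    """Read a .dat + sidecar trace, or a (time_s, value) CSV fallback.

    The sidecar's n_samples is cross-checked against the payload size; for
    the CSV fallback the sampling rate is inferred and must be uniform.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
        t = table.iloc[:, 0].to_numpy(float)
        v = table.iloc[:, 1].to_numpy(float)
        dt = np.diff(t)
        if dt.size == 0:
            raise DataError("trace CSV needs at least two samples")
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise DataError("non-uniform sample times in trace CSV")
        return ContinuousTrace(v, 1.0 / dt.mean())
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.fromfile(path, dtype="<f4")
    if data.size != meta["n_samples"]:
        raise DataError(
            f"payload has {data.size} samples, sidecar says {meta['n_samples']}")
    return ContinuousTrace(data.astype(float), meta["fs_hz"],
                           meta.get("units", "uV"), meta.get("channel", "lfp"))


def write_swc(path, m: Morphology) -> None:
    """Write a standard 7-column SWC file."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(m.n_nodes):
            x, y, z = m.xyz[i]
            fh.write(f"{m.ids[i]} {m.types[i]} {x:.9g} {y:.9g} {z:.9g} "
                     f"{m.radii[i]:.6g} {m.parents[i]}\n")


def read_swc(path) -> Morphology:
    """Read and validate a standard 7-column SWC file ('#' comments)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise DataError(f"SWC line does not have 7 columns: {line!r}")
            rows.append(parts)
    if not rows:
        raise DataError("SWC file contains no nodes")
    arr = np.array(rows)
    return Morphology(
        ids=arr[:, 0].astype(int),
        types=arr[:, 1].astype(int),
        xyz=arr[:, 2:5].astype(float),
        radii=arr[:, 5].astype(float),
        parents=arr[:, 6].astype(int),
        soma_id=int(arr[0, 0]),
    )


def write_spines(path, spines: pd.DataFrame) -> None:
    spines.to_csv(path, index=False, columns=["node_id", "arc_pos_um"])


def read_spines(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if list(table.columns) != ["node_id", "arc_pos_um"]:
        raise DataError("spines CSV must have columns node_id, arc_pos_um")
    return table


def write_sweepset(directory, sweeps: SweepSet, cell_id: str = "cell") -> Path:
    """Write a sweep set: protocol CSV plus one .dat trace per sweep.

    Returns the protocol CSV path. Protocol columns: sweep_id, holding_pA,
    step_pA, onset_s, dur_s, fs_hz, trace_file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, sw in enumerate(sweeps):
        fname = f"{cell_id}_sweep{k:03d}.dat"
        write_trace(directory / fname,
                    ContinuousTrace(sw.vm, sw.fs, "mV", channel="vm"))
        rows.append({"sweep_id": k, "holding_pA": sw.holding_pA,
                     "step_pA": sw.step_pA, "onset_s": sw.onset_s,
                     "dur_s": sw.dur_s, "fs_hz": sw.fs, "trace_file": fname})
    proto_path = directory / f"{cell_id}_protocol.csv"
    pd.DataFrame(rows).to_csv(proto_path, index=False)
    return proto_path


def read_sweepset(protocol_csv) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`."""
    protocol_csv = Path(protocol_csv)
    table = pd.read_csv(protocol_csv)
    sweeps = []
    for _, row in table.iterrows():
        trace = read_trace(protocol_csv.parent / row["trace_file"])
        sweeps.append(Sweep(trace.data, float(row["fs_hz"]),
                            float(row["holding_pA"]), float(row["step_pA"]),
                            float(row["onset_s"]), float(row["dur_s"])))
    return SweepSet(tuple(sweeps), cell_id=protocol_csv.stem)
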