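"""Delimited-text readers and writers.

Canonical interchange formats, all plain text:

* point sets — header row ``d1..dn,label``; one row per observation in
  time order; comma or tab delimited.
* recordings — rows = samples, columns = channels, plus a sampling rate
  given out of band and a schedule sidecar with columns
  ``label,start_s,end_s`` (half-open intervals in seconds).
* distance / proximity matrices — square tables with label headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DistanceMatrix, LabeledPointSet, ProximityMatrix
from .errors import InvalidInputError, ScheduleError
from .preprocessing import RecordingSegment

def _read_table(path) -> pd.DataFrame:
    """Read comma- or tab-delimited text with exact float round-tripping."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: malformed table: {exc}") from exc


__all__ = [
    "read_pointset",
    "write_pointset",
    "read_recording",
    "write_recording",
    "read_schedule",
    "write_schedule",
    "write_matrix",
    "write_result",
    "write_null_distribution",
]


def write_pointset(points: LabeledPointSet, path, sep: str = ",") -> Path:
    """Write a point set as delimited text with columns d1..dn, label."""
    path = Path(path)
    cols = {f"d{i + 1}": points.coordinates[:, i] for i in range(points.n_dims)}
    cols["label"] = [str(lab) for lab in points.labels]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False,
                              float_format="%.17g")
    return path


def read_pointset(path) -> LabeledPointSet:
    """Read a point set; raises informative errors naming offending lines.

    Line numbers are 1-based file lines (line 1 is the header).
    """
    path = Path(path)
    df = _read_table(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"{path}: missing required 'label' column")
    coord_cols = [c for c in df.columns if c != "label"]
    if not coord_cols:
        raise InvalidInputError(f"{path}: no coordinate columns")
    coords = df[coord_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = ~np.isfinite(coords)
    if bad.any():
        lines = (np.flatnonzero(bad.any(axis=1)) + 2).tolist()
        raise InvalidInputError(
            f"{path}: non-numeric or non-finite coordinate(s) on line(s) {lines}")
    labels = df["label"].astype(str).to_numpy(dtype=object)
    return LabeledPointSet(coords, labels)


def write_schedule(rows, path, sep: str = ",") -> Path:
    """Write (label, start_s, end_s) rows as a schedule sidecar."""
    path = Path(path)
    pd.DataFrame(rows, columns=["label", "start_s", "end_s"]).to_csv(
        path, sep=sep, index=False, float_format="%.17g")
    return path


def read_schedule(path) -> list[tuple[str, float, float]]:
    df = _read_table(path)
    needed = {"label", "start_s", "end_s"}
    if not needed.issubset(df.columns):
        raise ScheduleError(f"{path}: schedule needs columns {sorted(needed)}")
    rows = [(str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples()]
    for lab, s, e in rows:
        if e <= s:
            raise ScheduleError(f"{path}: empty or inverted interval for {lab!r}")
    ordered = sorted(rows, key=lambda r: r[1])
    for (_, _, e0), (lab, s1, _) in zip(ordered, ordered[1:]):
        if s1 < e0:
            raise ScheduleError(
                f"{path}: overlapping schedule intervals near {lab!r}")
    return rows


def write_recording(segments, path, schedule_path=None, sep: str = ",") -> Path:
    """Write segments as one continuous samples-by-channels table
    (concatenated in segment order) plus an optional schedule sidecar."""
    path = Path(path)
    data = np.concatenate([seg.samples.T for seg in segments], axis=0)
    cols = [f"ch{i + 1}" for i in range(segments[0].n_channels)]
    pd.DataFrame(data, columns=cols).to_csv(path, sep=sep, index=False,
                                            float_format="%.17g")
    if schedule_path is not None:
        rate = segments[0].sampling_rate
        rows, t0 = [], 0.0
        for seg in segments:
            rows.append((seg.condition, t0, t0 + seg.n_samples / rate))
            t0 += seg.n_samples / rate
        write_schedule(rows, schedule_path, sep=sep)
    return path


def read_recording(path, sampling_rate: float, schedule_path
                   ) -> list[RecordingSegment]:
    """Cut a samples-by-channels table into condition segments.

    One segment per schedule row; intervals must lie within the recording.
    """
    df = _read_table(path)
    data = df.to_numpy(dtype=float).T  # (C, T)
    duration = data.shape[1] / sampling_rate
    segments = []
    for lab, start, end in read_schedule(schedule_path):
        if start < 0 or end > duration + 0.5 / sampling_rate:
            raise ScheduleError(
                f"interval [{start}, {end}) for {lab!r} outside the "
                f"{duration:.3f} s recording")
        i0 = int(round(start * sampling_rate))
        i1 = int(round(end * sampling_rate))
        segments.append(RecordingSegment(data[:, i0:i1], sampling_rate, lab,
                                         onset_time=start))
    return segments


def write_matrix(matrix, path, sep: str = ",") -> Path:
    """Write a distance or proximity matrix with label headers."""
    path = Path(path)
    if isinstance(matrix, ProximityMatrix):
        labels = list(matrix.label_order)
        values = matrix.values
    elif isinstance(matrix, DistanceMatrix):
        values = matrix.values
        labels = list(range(values.shape[0]))
    else:
        values = np.asarray(matrix, dtype=float)
        labels = list(range(values.shape[0]))
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, sep=sep, float_format="%.17g")
    return path


def write_result(result, path) -> Path:
    """Serialize a permutation result as a key-value JSON report."""
    path = Path(path)
    path.write_text(json.dumps(result.to_report(), indent=2, sort_keys=True)
                    + "\n")
    return path


def write_null_distribution(result, path) -> Path:
    """Dump the full null distribution as one-column delimited text."""
    path = Path(path)
    pd.Series(result.delta_null, name="delta").to_csv(path, index=False)
    return path
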