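"""Reading and writing recordings and event labels.

Recordings: EDF (via the bundled minimal codec) or plain CSV with one column
per channel and a header row of channel ids; CSV carries no sampling rate so
``fs`` must be supplied. Labels: BED-like tab-separated text (half-open
start/end in samples, ``#fs=`` header line) or JSON. Integer fields
round-trip bit-exactly; EDF values round-trip to the format's 16-bit
precision.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import _edf
from .core import ChannelSeries, DataError, EventLabelSet, ParameterError

__all__ = [
    "read_recording",
    "write_recording",
    "read_labels",
    "write_intervals",
]


def _infer_format(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".edf":
        return "edf"
    if ext in (".csv", ".txt"):
        return "csv"
    raise ParameterError(f"cannot infer recording format from {path!r}")


def read_recording(path, format: str | None = None, fs: float | None = None,
                   patient_id: str | None = None) -> list[ChannelSeries]:
    """Read a multichannel recording into one :class:`ChannelSeries` per channel.

    ``fs`` is read from the EDF header and required for CSV.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format or _infer_format(path)).lower()
    if fmt == "edf":
        signals, fs_read, labels, pid = _edf.read_edf(path)
        pid = patient_id if patient_id is not None else pid
        return [
            ChannelSeries(values=sig, fs=fs_read, patient_id=pid, channel_id=label)
            for sig, label in zip(signals, labels)
        ]
    if fmt == "csv":
        if fs is None:
            raise ParameterError("fs is required when reading CSV recordings")
        frame = pd.read_csv(path)
        if frame.shape[0] == 0:
            raise DataError(f"{path}: empty recording")
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().values.any() and not frame.isna().values.any():
            row, col = np.argwhere(numeric.isna().values)[0]
            raise DataError(
                f"{path}: non-numeric value {frame.iloc[row, col]!r} at "
                f"row {row}, column {frame.columns[col]!r}"
            )
        if numeric.isna().values.any():
            row, col = np.argwhere(numeric.isna().values)[0]
            raise DataError(f"{path}: missing value at row {row}, "
                            f"column {frame.columns[col]!r}")
        pid = patient_id or ""
        return [
            ChannelSeries(values=numeric[c].to_numpy(dtype=float), fs=fs,
                          patient_id=pid, channel_id=str(c))
            for c in frame.columns
        ]
    raise ParameterError(f"unknown recording format {fmt!r}")


def write_recording(path, channels: list[ChannelSeries], format: str | None = None) -> None:
    """Write channels to EDF or CSV (format inferred from suffix by default)."""
    if not channels:
        raise DataError("no channels to write")
    fmt = (format or _infer_format(path)).lower()
    fs = channels[0].fs
    if any(c.fs != fs for c in channels):
        raise DataError("all channels must share fs")
    n = len(channels[0])
    if any(len(c) != n for c in channels):
        raise DataError("all channels must share length")
    if fmt == "edf":
        _edf.write_edf(
            path,
            [c.values for c in channels],
            fs=fs,
            labels=[c.channel_id or f"ch{i}" for i, c in enumerate(channels)],
            patient_id=channels[0].patient_id or "X",
        )
    elif fmt == "csv":
        frame = pd.DataFrame(
            {c.channel_id or f"ch{i}": c.values for i, c in enumerate(channels)}
        )
        frame.to_csv(path, index=False)
    else:
        raise ParameterError(f"unknown recording format {fmt!r}")


def write_intervals(path, labels: EventLabelSet, format: str | None = None) -> None:
    """Serialize an :class:`EventLabelSet` as BED-like TSV or JSON."""
    fmt = format or ("json" if str(path).endswith(".json") else "tsv")
    if fmt == "json":
        payload = {
            "fs": labels.fs,
            "source": labels.source,
            "intervals": [[int(s), int(e)] for s, e in labels.intervals],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    with open(path, "w") as fh:
        fh.write(f"#fs={labels.fs:g}\tsource={labels.source}\n")
        fh.write("start\tend\n")
        for s, e in labels.intervals:
            fh.write(f"{int(s)}\t{int(e)}\n")


def read_labels(path, strict: bool = False) -> EventLabelSet:
    """Read event labels from TSV or JSON.

    In lenient mode overlapping intervals are merged with a warning; strict
    mode raises on overlapping or inverted intervals.
    """
    if str(path).endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        return EventLabelSet(
            intervals=np.asarray(payload["intervals"], dtype=np.int64).reshape(-1, 2),
            fs=float(payload["fs"]),
            source=payload.get("source", "consensus"),
            strict=strict,
        )
    fs = None
    source = "consensus"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    key, _, value = token.partition("=")
                    if key == "fs":
                        fs = float(value)
                    elif key == "source":
                        source = value
                continue
            fields = line.split("\t")
            if fields[0] == "start":
                continue
            try:
                rows.append((int(fields[0]), int(fields[1])))
            except (IndexError, ValueError) as exc:
                raise DataError(f"{path}:{lineno}: malformed interval line "
                                f"{line!r}") from exc
    if fs is None:
        raise DataError(f"{path}: missing '#fs=' header")
    return EventLabelSet(
        intervals=np.asarray(rows, dtype=np.int64).reshape(-1, 2),
        fs=fs, source=source, strict=strict,
    )
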