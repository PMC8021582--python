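"""Minimal EDF (European Data Format) reader/writer.

Implements the subset of EDF needed to round-trip multichannel recordings:
ASCII fixed-width header, one or more fixed-duration data records of
little-endian 16-bit integers, linear digital->physical calibration per
signal. Annotations (EDF+ TAL channels) and discontinuous recordings are out
of scope. Values survive a round trip to within the 16-bit quantization of
the physical range, which is the format's own precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DataError

_HDR = 256  # fixed part
_PER_SIGNAL = 256

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class _SignalHeader:
    label: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into EDF's 8-char ASCII fields without losing too much."""
    for fmt in (f"{x:.8g}", f"{x:.6g}", f"{x:.4g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return fmt
    return f"{x:.1g}"[:width]


def write_edf(path, signals, fs: float, labels=None, patient_id: str = "X",
              recording_id: str = "X") -> None:
    """Write ``signals`` (list of equal-length 1-D float arrays) as EDF.

    One data record per second when ``fs`` divides the length evenly and is
    integral; otherwise a single record spanning the whole signal.
    """
    sigs = [np.asarray(s, dtype=float) for s in signals]
    if not sigs:
        raise DataError("no signals to write")
    n = sigs[0].size
    if any(s.size != n for s in sigs):
        raise DataError("all signals must share length")
    if labels is None:
        labels = [f"ch{i}" for i in range(len(sigs))]

    if float(fs).is_integer() and n % int(fs) == 0 and n >= int(fs):
        samples_per_record = int(fs)
        n_records = n // samples_per_record
        record_duration = 1.0
    else:
        samples_per_record = n
        n_records = 1
        record_duration = n / fs

    headers = []
    scaled = []
    for s, label in zip(sigs, labels):
        pmin, pmax = float(np.min(s)), float(np.max(s))
        if pmin == pmax:  # constant signal: widen range so calibration is defined
            pmin, pmax = pmin - 1.0, pmax + 1.0
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.round((s - pmin) * gain + _DIG_MIN).astype("<i2")
        headers.append(_SignalHeader(label, pmin, pmax, _DIG_MIN, _DIG_MAX,
                                     samples_per_record))
        scaled.append(dig)

    ns = len(sigs)
    header_bytes = _HDR + _PER_SIGNAL * ns
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(patient_id, 80))
        fh.write(_pad(recording_id, 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad(_fmt_float(record_duration), 8))
        fh.write(_pad(str(ns), 4))
        for h in headers:
            fh.write(_pad(h.label, 16))
        for _ in headers:
            fh.write(_pad("", 80))  # transducer
        for _ in headers:
            fh.write(_pad("uV", 8))
        for h in headers:
            fh.write(_pad(_fmt_float(h.physical_min), 8))
        for h in headers:
            fh.write(_pad(_fmt_float(h.physical_max), 8))
        for h in headers:
            fh.write(_pad(str(h.digital_min), 8))
        for h in headers:
            fh.write(_pad(str(h.digital_max), 8))
        for _ in headers:
            fh.write(_pad("", 80))  # prefiltering
        for h in headers:
            fh.write(_pad(str(h.samples_per_record), 8))
        for _ in headers:
            fh.write(_pad("", 32))
        for rec in range(n_records):
            lo = rec * samples_per_record
            hi = lo + samples_per_record
            for dig in scaled:
                fh.write(dig[lo:hi].tobytes())


def read_edf(path):
    """Read an EDF file written by :func:`write_edf` (or any plain EDF subset).

    Returns ``(signals, fs, labels, patient_id)`` where ``signals`` is a list
    of 1-D float arrays in physical units.
    """
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise DataError(f"{path}: truncated EDF header")

        def field(lo, hi):
            return head[lo:hi].decode("ascii", errors="replace").strip()

        patient_id = field(8, 88)
        try:
            n_records = int(field(236, 244))
            record_duration = float(field(244, 252))
            ns = int(field(252, 256))
        except ValueError as exc:
            raise DataError(f"{path}: malformed EDF header: {exc}") from exc
        if ns < 1 or n_records < 1 or record_duration <= 0:
            raise DataError(f"{path}: implausible EDF header")

        sig_head = fh.read(_PER_SIGNAL * ns)
        if len(sig_head) < _PER_SIGNAL * ns:
            raise DataError(f"{path}: truncated EDF signal headers")

        def sig_field(offset, width, i):
            lo = offset * ns + width * i
            return sig_head[lo:lo + width].decode("ascii", errors="replace").strip()

        labels, pmins, pmaxs, dmins, dmaxs, sprs = [], [], [], [], [], []
        for i in range(ns):
            labels.append(sig_field(0, 16, i))
            pmins.append(float(sig_field(16 + 80 + 8, 8, i)))
            pmaxs.append(float(sig_field(16 + 80 + 8 + 8, 8, i)))
            dmins.append(int(sig_field(16 + 80 + 8 + 16, 8, i)))
            dmaxs.append(int(sig_field(16 + 80 + 8 + 24, 8, i)))
            sprs.append(int(sig_field(16 + 80 + 8 + 32 + 80, 8, i)))

        rec_len = sum(sprs)
        raw = np.frombuffer(fh.read(2 * rec_len * n_records), dtype="<i2")
        if raw.size < rec_len * n_records:
            raise DataError(f"{path}: truncated EDF data records")

    raw = raw.reshape(n_records, rec_len)
    signals = []
    offset = 0
    for i in range(ns):
        dig = raw[:, offset:offset + sprs[i]].reshape(-1).astype(float)
        offset += sprs[i]
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        signals.append((dig - dmins[i]) * gain + pmins[i])
    fs = sprs[0] / record_duration
    if any(abs(s / record_duration - fs) > 1e-9 for s in sprs):
        raise DataError(f"{path}: signals with differing sampling rates not supported")
    if not math.isfinite(fs) or fs <= 0:
        raise DataError(f"{path}: bad sampling rate")
    return signals, fs, labels, patient_id
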