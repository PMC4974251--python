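"""Minimal European Data Format (EDF) codec.

Writes and reads plain EDF: ASCII headers, 16-bit little-endian samples,
one physical dimension per signal.  Physical min/max are set per channel
from the data range with 5% headroom, so the quantization step of a
round-trip is (range * 1.1) / 65535.  The exact sample count is stashed in
the reserved header field (``NS=<n>``) so a round-trip restores the
original length even though EDF pads the final data record.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # fall back to a compact float representation that fits
        s = f"{float(value):.{max(width - 7, 0)}g}"
    if len(s) > width:
        raise ValueError(f"cannot format {value!r} in {width} ascii chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    physical_dim: str = "uV",
    record_dur: float = 1.0,
) -> None:
    """Write ``data`` (channels x samples, physical units) as EDF."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    spr = fs * record_dur
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record_dur * fs must be an integer sample count")
    spr = int(round(spr))
    n_rec = max(1, math.ceil(n_samp / spr))

    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    for c in range(n_ch):
        lo, hi = float(data[c].min()), float(data[c].max())
        span = hi - lo
        if span <= 0:
            lo, hi = lo - 1.0, hi + 1.0
        else:
            lo -= 0.05 * span
            hi += 0.05 * span
        phys_min[c], phys_max[c] = lo, hi

    header = bytearray()
    header += _fmt(0, 8)                      # version
    header += _fmt("synthetic", 80)           # patient id (synthetic data)
    header += _fmt("gonogo-erp", 80)          # recording id
    header += _fmt("01.01.00", 8)             # start date (placeholder)
    header += _fmt("00.00.00", 8)             # start time
    header += _fmt(256 * (1 + n_ch), 8)       # header bytes
    header += _fmt(f"NS={n_samp}", 44)        # reserved: true sample count
    header += _fmt(n_rec, 8)
    header += _fmt(f"{record_dur:g}", 8)
    header += _fmt(n_ch, 4)
    for lab in labels:
        header += _fmt(lab, 16)
    for _ in range(n_ch):
        header += _fmt("simulated", 80)       # transducer
    for _ in range(n_ch):
        header += _fmt(physical_dim, 8)
    for c in range(n_ch):
        header += _fmt(f"{phys_min[c]:.8g}"[:8], 8)
    for c in range(n_ch):
        header += _fmt(f"{phys_max[c]:.8g}"[:8], 8)
    for _ in range(n_ch):
        header += _fmt(_DIG_MIN, 8)
    for _ in range(n_ch):
        header += _fmt(_DIG_MAX, 8)
    for _ in range(n_ch):
        header += _fmt("", 80)                # prefiltering
    for _ in range(n_ch):
        header += _fmt(spr, 8)
    for _ in range(n_ch):
        header += _fmt("", 32)                # per-signal reserved

    # re-read the 8-char physical bounds actually written so that encoding
    # uses exactly the stored (truncated) values -> decode matches encode
    pmin_s = [float(f"{phys_min[c]:.8g}"[:8]) for c in range(n_ch)]
    pmax_s = [float(f"{phys_max[c]:.8g}"[:8]) for c in range(n_ch)]

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    dig = np.empty_like(padded, dtype=np.int16)
    for c in range(n_ch):
        gain = (pmax_s[c] - pmin_s[c]) / (_DIG_MAX - _DIG_MIN)
        vals = np.round((padded[c] - pmin_s[c]) / gain) + _DIG_MIN
        dig[c] = np.clip(vals, _DIG_MIN, _DIG_MAX).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records: for each record, each signal's samples contiguously
        arr = dig.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(arr.astype("<i2").tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples in physical units, fs, labels)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (truncated header)")
    hdr = raw[:256].decode("ascii", errors="replace")
    n_rec = int(hdr[236:244])
    record_dur = float(hdr[244:252])
    n_ch = int(hdr[252:256])
    reserved = hdr[192:236].strip()

    off = 256
    sig_hdr = raw[off : off + 256 * n_ch].decode("ascii", errors="replace")

    def field(width: int, cursor: list[int]) -> list[str]:
        start = cursor[0]
        out = [sig_hdr[start + i * width : start + (i + 1) * width].strip()
               for i in range(n_ch)]
        cursor[0] = start + width * n_ch
        return out

    cur = [0]
    labels = field(16, cur)
    field(80, cur)  # transducer
    field(8, cur)   # dimension
    pmin = [float(x) for x in field(8, cur)]
    pmax = [float(x) for x in field(8, cur)]
    dmin = [int(x) for x in field(8, cur)]
    dmax = [int(x) for x in field(8, cur)]
    field(80, cur)  # prefiltering
    spr = [int(x) for x in field(8, cur)]

    data_bytes = raw[256 * (1 + n_ch):]
    per_rec = sum(spr)
    dig = np.frombuffer(data_bytes, dtype="<i2", count=n_rec * per_rec)
    out = np.empty((n_ch, n_rec * spr[0]))
    if len(set(spr)) != 1:
        raise ValueError("mixed samples-per-record not supported")
    arr = dig.reshape(n_rec, n_ch, spr[0])
    for c in range(n_ch):
        gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
        out[c] = (arr[:, c, :].reshape(-1).astype(float) - dmin[c]) * gain + pmin[c]
    fs = spr[0] / record_dur
    if reserved.startswith("NS="):
        n_samp = int(reserved[3:])
        out = out[:, :n_samp]
    return out, fs, labels
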