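"""Minimal 16-bit EDF writer (single data record).

Reading is delegated to :mod:`mne`; no installed library writes EDF, so this
module implements the small subset of the format the package needs: one data
record holding the whole signal, identical physical scaling for all channels,
physical min/max chosen to cover the data range.  The quantization step is
``(phys_max - phys_min) / (dig_max - dig_min)`` and the written file is exact
to half that step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


def _ascii8(value: float) -> str:
    """Format a number into at most 8 ASCII characters, reparseable."""
    for fmt in (".8g", ".6g", ".4g", ".2g"):
        s = format(value, fmt)
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot represent {value!r} in 8 EDF header characters")


def _field(values, width: int) -> bytes:
    out = b""
    for v in values:
        b = str(v).encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field {v!r} exceeds {width} characters")
        out += b.ljust(width)
    return out


def write_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write ``data`` (channels x samples, µV) as a single-record 16-bit EDF."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("need a non-empty channels x samples matrix")
    if not np.isfinite(data).all():
        raise ValueError("EDF cannot represent non-finite samples")
    n_ch, n_s = data.shape

    # Physical range symmetric-ish around data, reparsed from its 8-char header
    # form so the digital conversion matches what a reader will compute.
    lo, hi = float(data.min()), float(data.max())
    span = max(hi - lo, 1.0)
    pmin_s = _ascii8(lo - 0.005 * span)
    pmax_s = _ascii8(hi + 0.005 * span)
    pmin, pmax = float(pmin_s), float(pmax_s)
    if not (pmin < pmax and pmin <= lo and hi <= pmax):
        raise ValueError(f"data range [{lo}, {hi}] not representable in EDF header")

    duration = n_s / fs
    header = b""
    header += b"0".ljust(8)                                    # version
    header += b"X X X X".ljust(80)                             # patient id
    header += b"Startdate 01-JAN-2000 X X X".ljust(80)         # recording id
    header += b"01.01.00" + b"00.00.00"                        # start date/time
    header += str(256 * (n_ch + 1)).encode().ljust(8)          # header bytes
    header += b"".ljust(44)                                    # reserved
    header += b"1".ljust(8)                                    # number of records
    header += _ascii8(duration).encode().ljust(8)              # record duration (s)
    header += str(n_ch).encode().ljust(4)                      # number of signals
    header += _field(labels, 16)
    header += _field([""] * n_ch, 80)                          # transducer
    header += _field(["uV"] * n_ch, 8)                         # physical dimension
    header += _field([pmin_s] * n_ch, 8)
    header += _field([pmax_s] * n_ch, 8)
    header += _field([DIG_MIN] * n_ch, 8)
    header += _field([DIG_MAX] * n_ch, 8)
    header += _field([""] * n_ch, 80)                          # prefiltering
    header += _field([n_s] * n_ch, 8)                          # samples per record
    header += _field([""] * n_ch, 32)                          # reserved

    gain = (pmax - pmin) / (DIG_MAX - DIG_MIN)
    digital = np.round((data - pmin) / gain + DIG_MIN)
    if digital.min() < DIG_MIN or digital.max() > DIG_MAX:
        raise ValueError("digital values out of 16-bit range; data exceeds declared span")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.astype("<i2").tobytes())


def quantization_step(data: np.ndarray) -> float:
    """Quantization step the writer will use for ``data`` (µV per digital unit)."""
    lo, hi = float(np.min(data)), float(np.max(data))
    span = max(hi - lo, 1.0)
    pmin = float(_ascii8(lo - 0.005 * span))
    pmax = float(_ascii8(hi + 0.005 * span))
    return (pmax - pmin) / (DIG_MAX - DIG_MIN)
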