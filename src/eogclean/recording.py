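"""Recording data model and readers/writers.

A :class:`Recording` is the package's in-memory container for a multichannel
EEG signal: a ``(n_channels, n_samples)`` float matrix in microvolts together
with the sampling rate and ordered channel labels.  Sample indexing is
0-based, time intervals are half-open ``[start, end)`` in samples, and time in
seconds is ``index / fs``.

Two on-disk formats are supported:

* European Data Format (EDF, 16-bit) — read through :mod:`mne`, written by the
  package's own single-record writer.  The round trip is lossy only by the
  16-bit quantization step implied by the physical min/max.
* Delimited text matrix — one channel per row, with a JSON sidecar
  ``<path>.json`` holding ``{"fs": ..., "labels": [...]}``.  Lossless up to
  the text float representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "Montage", "read_recording", "write_recording"]


def _norm_label(label: str) -> str:
    return label.strip().casefold()


@dataclass
class Recording:
    """Multichannel signal matrix with sampling metadata.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array of samples in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    labels
        Channel names, one per row of ``data``, in file/acquisition order.
    meta
        Free-form provenance notes (never interpreted by the pipeline).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(np.asarray(self.data, dtype=np.float64))
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        self.labels = [str(l) for l in self.labels]
        n_ch, n_s = self.data.shape
        if n_ch != len(self.labels):
            raise ValueError(f"{n_ch} data rows but {len(self.labels)} labels")
        if n_ch < 2:
            raise ValueError("a Recording needs at least 2 channels")
        if n_s < 2:
            raise ValueError("a Recording needs at least 2 samples")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite samples")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based index / fs)."""
        return np.arange(self.n_samples) / self.fs

    def copy(self, data: np.ndarray | None = None, **meta_updates) -> "Recording":
        """Return a copy, optionally replacing the signal matrix."""
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            labels=list(self.labels),
            meta=new_meta,
        )

    def channel_index(self, label: str) -> int:
        """Index of a channel by label (whitespace-trimmed, case-insensitive)."""
        target = _norm_label(label)
        for i, l in enumerate(self.labels):
            if _norm_label(l) == target:
                return i
        raise KeyError(f"channel {label!r} not found in {self.labels}")


@dataclass
class Montage:
    """Declaration of which channels sit over the forehead.

    The identification step correlates independent components with these
    channels, so at least two are required — one near each eye.
    """

    frontal: list[str]

    def __post_init__(self) -> None:
        self.frontal = [str(l) for l in self.frontal]
        if len(self.frontal) < 2:
            raise ValueError("montage needs at least two frontal channels")
        if len({_norm_label(l) for l in self.frontal}) != len(self.frontal):
            raise ValueError("duplicate frontal channel labels")

    def resolve(self, labels: list[str]) -> list[int]:
        """Map frontal labels onto indices into ``labels``.

        Matching is by exact string after trimming whitespace, case-insensitive.
        """
        lut = {_norm_label(l): i for i, l in enumerate(labels)}
        missing = [l for l in self.frontal if _norm_label(l) not in lut]
        if missing:
            raise KeyError(f"frontal channels {missing} not present in recording labels {labels}")
        return [lut[_norm_label(l)] for l in self.frontal]


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "edf" if path.suffix.lower() == ".edf" else "delimited"


def read_recording(
    path,
    format: str | None = None,
    fs: float | None = None,
    labels: list[str] | None = None,
    delimiter: str | None = None,
) -> Recording:
    """Read a recording from an EDF file or a delimited numeric matrix.

    For delimited matrices (one channel per row) the sampling rate and labels
    come from a JSON sidecar ``<path>.json`` or from the ``fs``/``labels``
    arguments; a missing sampling rate is an error, never a silent default.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        return Recording(data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names),
                         meta={"source": str(path), "format": "edf"})
    if fmt == "delimited":
        sidecar = _sidecar_path(path)
        if sidecar.is_file():
            side = json.loads(sidecar.read_text())
            fs = side.get("fs", fs)
            labels = side.get("labels", labels)
        if fs is None:
            raise ValueError(
                f"no sampling rate for {path}: provide fs= or a sidecar {sidecar.name}"
            )
        try:
            data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse delimited matrix {path}: {exc}") from exc
        if labels is None:
            labels = [f"ch{i}" for i in range(data.shape[0])]
        return Recording(data=data, fs=float(fs), labels=list(labels),
                         meta={"source": str(path), "format": "delimited"})
    raise ValueError(f"unknown format {fmt!r} (expected 'edf' or 'delimited')")


def write_recording(rec: Recording, path, format: str | None = None,
                    delimiter: str = "\t") -> None:
    """Write a recording; the file is re-readable by :func:`read_recording`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        from ._edf import write_edf

        write_edf(path, rec.data, rec.fs, rec.labels)
    elif fmt == "delimited":
        np.savetxt(path, rec.data, delimiter=delimiter, fmt="%.10g")
        _sidecar_path(path).write_text(
            json.dumps({"fs": rec.fs, "labels": rec.labels}, indent=1)
        )
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'edf' or 'delimited')")
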