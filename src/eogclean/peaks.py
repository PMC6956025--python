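"""Ocular peak detection and correction-window construction (steps 4–5).

A sample ``m`` of a flagged component ``y`` is an ocular peak when it is a
strict local maximum of ``|y|``, its magnitude exceeds ``3 * mean(|y|)``
(the mean taken over the whole component), and it lies at least 0.5 s after
the previously kept peak.  One-second windows centred on the kept peaks are
merged into disjoint half-open sample intervals; if the merged windows cover
more than 60 % of the component, the whole component is marked for rejection
instead of in-window correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PeakSet", "ArtifactWindows", "detect_eog_peaks", "build_windows", "decide_action"]


@dataclass
class PeakSet:
    """Detected ocular peaks of one component (ascending sample indices)."""

    samples: np.ndarray
    amplitudes: np.ndarray
    component: int | None = None
    fs: float = float("nan")

    def __len__(self) -> int:
        return len(self.samples)

    def times(self) -> np.ndarray:
        return self.samples / self.fs


@dataclass
class ArtifactWindows:
    """Merged, disjoint, sorted half-open sample intervals around peaks."""

    intervals: tuple[tuple[int, int], ...]
    n_samples: int

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.intervals:
            if not (0 <= s < e <= self.n_samples):
                raise ValueError(f"interval [{s}, {e}) outside [0, {self.n_samples})")
            if s <= prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = e

    @property
    def coverage(self) -> float:
        """Fraction of samples covered by the windows, in [0, 1]."""
        covered = sum(e - s for s, e in self.intervals)
        return covered / self.n_samples if self.n_samples else 0.0

    def mask(self) -> np.ndarray:
        """Boolean mask, True inside the windows."""
        m = np.zeros(self.n_samples, dtype=bool)
        for s, e in self.intervals:
            m[s:e] = True
        return m

    def contains(self, sample: int) -> bool:
        return any(s <= sample < e for s, e in self.intervals)


def detect_eog_peaks(y: np.ndarray, fs: float, amp_factor: float = 3.0,
                     min_separation_s: float = 0.5, tie_break: str = "largest",
                     component: int | None = None) -> PeakSet:
    """Find ocular peaks in a component series.

    Candidates are strict 1-sample local maxima of ``|y|`` whose magnitude
    exceeds ``amp_factor * mean(|y|)``.  Candidates closer than
    ``min_separation_s`` to an already-kept peak are dropped.  With the
    default ``tie_break='largest'`` candidates are considered in descending
    amplitude order, so each artifact contributes its apex rather than a
    filter side lobe; ``'earliest'`` scans in time order and keeps the
    earlier peak, matching the consecutive-peak phrasing of the rule.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("component series must be 1-D")
    if not np.isfinite(y).all():
        raise ValueError("component series contains non-finite values")
    if not fs > 0:
        raise ValueError("fs must be positive")
    ay = np.abs(y)
    threshold = amp_factor * ay.mean()
    inner = np.flatnonzero((ay[1:-1] > ay[:-2]) & (ay[1:-1] > ay[2:])) + 1
    cand = inner[ay[inner] > threshold]
    min_gap = min_separation_s * fs
    kept: list[int] = []
    if tie_break == "earliest":
        last = -np.inf
        for m in cand:
            if m - last >= min_gap:
                kept.append(int(m))
                last = m
    elif tie_break == "largest":
        for m in sorted(cand, key=lambda m: -ay[m]):
            if all(abs(m - k) >= min_gap for k in kept):
                kept.append(int(m))
        kept.sort()
    else:
        raise ValueError(f"tie_break must be 'earliest' or 'largest', got {tie_break!r}")
    kept_arr = np.asarray(kept, dtype=np.int64)
    return PeakSet(samples=kept_arr, amplitudes=ay[kept_arr], component=component, fs=fs)


def build_windows(peaks: PeakSet, fs: float, n_samples: int,
                  width_s: float = 1.0) -> ArtifactWindows:
    """Place a window of ``width_s`` seconds around each peak and merge.

    Each peak ``m`` yields ``[m - w//2, m + w - w//2)`` samples, clipped to
    ``[0, n_samples)``; overlapping or adjacent windows are merged.
    """
    if not width_s > 0:
        raise ValueError("width_s must be positive")
    w = int(round(width_s * fs))
    half = w // 2
    raw = []
    for m in peaks.samples:
        s = max(0, int(m) - half)
        e = min(n_samples, int(m) - half + w)
        if e > s:
            raw.append((s, e))
    merged: list[list[int]] = []
    for s, e in sorted(raw):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return ArtifactWindows(intervals=tuple((s, e) for s, e in merged), n_samples=n_samples)


def decide_action(windows: ArtifactWindows, reject_fraction: float = 0.60) -> str:
    """Choose between in-window correction and whole-component rejection.

    The component is rejected when windows cover *more than* the rejection
    fraction (strict inequality), otherwise corrected only inside windows.
    """
    return "reject_component" if windows.coverage > reject_fraction else "correct_in_windows"
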