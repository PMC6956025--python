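"""Artifact-removal and distortion metrics.

Removal efficacy is quantified by the artifact-removal percentage

    lambda = 100 * (1 - (R_ref - R_cleaned) / (R_ref - R_contam))

where ``R_ref`` is the lag-1 autocorrelation of the true (pure) signal and
``R_cleaned`` / ``R_contam`` are Pearson correlations of the pure signal with
the cleaned and contaminated signals (the reference term is an
autocorrelation while the others are cross-correlations; the formula is
applied literally as defined), and by the change in signal-to-noise ratio

    dSNR = 10 log10(var(pure) / var(cleaned - pure))
         - 10 log10(var(pure) / var(contam - pure))   [dB].

Distortion is quantified by the RMSE between pure and cleaned signals (µV)
and by the magnitude-squared coherence C_xy(f) = |R_xy|^2 / (R_xx R_yy),
estimated with Welch-averaged periodograms.  Peak-detection quality is the
sensitivity Se = TP / (TP + FN) in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "MetricsReport",
    "lambda_removal",
    "delta_snr",
    "rmse",
    "msc",
    "peak_sensitivity",
    "sensitivity_from_counts",
    "evaluate_recordings",
]

SNR_CAP_DB = 120.0


class UndefinedMetricWarning(UserWarning):
    """A metric is undefined for the given inputs and reported as NaN."""


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    return float(a @ b / denom) if denom > 0 else 0.0


def _check_equal_length(*series) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(s, dtype=np.float64).ravel() for s in series]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError(f"series lengths differ: {[a.size for a in arrs]}")
    return tuple(arrs)


def lambda_removal(pure, contam, cleaned, min_contrast: float = 0.02) -> float:
    """Artifact-removal percentage; 100 at ideal removal, 0 at no removal.

    The metric compares correlation shifts relative to the reference term
    ``R_ref`` (the lag-1 autocorrelation of the pure signal, applied
    literally as defined).  It is only meaningful where the artifact
    actually depressed the pure–contaminated correlation below that
    reference: when ``R_ref - R_contam < min_contrast`` the denominator is
    (near) zero or negative, the ratio is numerically meaningless, and the
    channel is reported as NaN with a warning so channel averages skip it.
    """
    pure, contam, cleaned = _check_equal_length(pure, contam, cleaned)
    r_ref = _corr(pure[:-1], pure[1:])
    r_contam = _corr(pure, contam)
    r_cleaned = _corr(pure, cleaned)
    denom = r_ref - r_contam
    if denom < min_contrast:
        warnings.warn(
            f"lambda undefined: R_ref - R_contam = {denom:.4f} < {min_contrast} "
            "(channel insufficiently contaminated)",
            UndefinedMetricWarning, stacklevel=2,
        )
        return float("nan")
    return 100.0 * (1.0 - (r_ref - r_cleaned) / denom)


def delta_snr(pure, contam, cleaned, cap_db: float = SNR_CAP_DB) -> float:
    """SNR improvement of cleaning in dB, capped at ±``cap_db``."""
    pure, contam, cleaned = _check_equal_length(pure, contam, cleaned)
    var_contam = np.var(contam - pure)
    var_cleaned = np.var(cleaned - pure)
    if var_contam == 0 and var_cleaned == 0:
        return 0.0
    if var_cleaned == 0:
        return cap_db
    if var_contam == 0:
        return -cap_db
    return float(np.clip(10.0 * np.log10(var_contam / var_cleaned), -cap_db, cap_db))


def rmse(pure, cleaned) -> float:
    """Root-mean-square error between two series (µV)."""
    pure, cleaned = _check_equal_length(pure, cleaned)
    return float(np.sqrt(np.mean((cleaned - pure) ** 2)))


def msc(pure, cleaned, fs: float, nperseg: int | None = None,
        noverlap: int | None = None, window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence via Welch averaging.

    Defaults to 2-s segments with 50 % overlap.  At least two averaged
    segments are required — the coherence of a single segment is
    identically 1.
    """
    pure, cleaned = _check_equal_length(pure, cleaned)
    if nperseg is None:
        nperseg = int(round(2.0 * fs))
    if noverlap is None:
        noverlap = nperseg // 2
    step = nperseg - noverlap
    n_segments = 1 + (pure.size - nperseg) // step if pure.size >= nperseg else 0
    if n_segments < 2:
        raise ValueError(
            f"{pure.size} samples give {n_segments} Welch segment(s) of {nperseg}; "
            "need at least 2 for a meaningful coherence"
        )
    freqs, coh = signal.coherence(pure, cleaned, fs=fs, window=window,
                                  nperseg=nperseg, noverlap=noverlap)
    return freqs, np.clip(coh, 0.0, 1.0)


def sensitivity_from_counts(tp: int, fn: int) -> float:
    """Sensitivity Se = 100 * TP / (TP + FN), in percent."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined with no positives")
    return 100.0 * tp / (tp + fn)


def peak_sensitivity(detected_s, truth_s, tol_s: float = 0.1) -> tuple[float, int, int]:
    """Match detections to annotated peaks and return (Se %, TP, FN).

    Matching is greedy one-to-one in time order: each annotated peak takes
    the earliest unused detection within ``±tol_s`` seconds.  Empty truth
    makes the sensitivity undefined (NaN, with a warning).
    """
    detected = np.sort(np.asarray(detected_s, dtype=np.float64).ravel())
    truth = np.sort(np.asarray(truth_s, dtype=np.float64).ravel())
    if truth.size == 0:
        warnings.warn("no annotated peaks; sensitivity undefined", stacklevel=2)
        return float("nan"), 0, 0
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    j = 0
    for t in truth:
        while j < detected.size and detected[j] < t - tol_s:
            j += 1
        k = j
        while k < detected.size and detected[k] <= t + tol_s:
            if not used[k]:
                used[k] = True
                tp += 1
                break
            k += 1
    fn = truth.size - tp
    return sensitivity_from_counts(tp, fn), tp, fn


@dataclass
class MetricsReport:
    """Per-channel and channel-averaged evaluation of one cleaning run."""

    channel_labels: list[str]
    lam: np.ndarray
    dsnr: np.ndarray
    rmse_uV: np.ndarray
    msc_freqs: np.ndarray
    msc_mean_curve: np.ndarray
    msc_band_mean: float
    lam_mean: float = field(init=False)
    dsnr_mean: float = field(init=False)
    rmse_mean: float = field(init=False)
    sensitivity: float | None = None
    tp: int | None = None
    fn: int | None = None

    def __post_init__(self) -> None:
        self.lam_mean = float(np.nanmean(self.lam))
        self.dsnr_mean = float(np.nanmean(self.dsnr))
        self.rmse_mean = float(np.nanmean(self.rmse_uV))

    def to_dict(self) -> dict:
        out = {
            "channels": list(self.channel_labels),
            "lambda": [float(v) for v in self.lam],
            "lambda_mean": self.lam_mean,
            "delta_snr_db": [float(v) for v in self.dsnr],
            "delta_snr_mean_db": self.dsnr_mean,
            "rmse_uV": [float(v) for v in self.rmse_uV],
            "rmse_mean_uV": self.rmse_mean,
            "msc_freqs_hz": [float(v) for v in self.msc_freqs],
            "msc_mean_curve": [float(v) for v in self.msc_mean_curve],
            "msc_band_mean": float(self.msc_band_mean),
        }
        if self.sensitivity is not None:
            out.update(sensitivity_pct=float(self.sensitivity), tp=self.tp, fn=self.fn)
        return out


def evaluate_recordings(pure: Recording, contam: Recording, cleaned: Recording,
                        band: tuple[float, float] = (1.0, 47.0),
                        nperseg: int | None = None) -> MetricsReport:
    """Compute all metrics per channel, then average over channels."""
    if pure.data.shape != contam.data.shape or pure.data.shape != cleaned.data.shape:
        raise ValueError("recordings must have identical shapes")
    n_ch = pure.n_channels
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedMetricWarning)
        lam = np.array([lambda_removal(pure.data[i], contam.data[i], cleaned.data[i])
                        for i in range(n_ch)])
    dsnr = np.array([delta_snr(pure.data[i], contam.data[i], cleaned.data[i])
                     for i in range(n_ch)])
    errs = np.array([rmse(pure.data[i], cleaned.data[i]) for i in range(n_ch)])
    curves = []
    freqs = None
    for i in range(n_ch):
        freqs, coh = msc(pure.data[i], cleaned.data[i], fs=pure.fs, nperseg=nperseg)
        curves.append(coh)
    mean_curve = np.mean(curves, axis=0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_mean = float(mean_curve[in_band].mean())
    return MetricsReport(
        channel_labels=list(pure.labels), lam=lam, dsnr=dsnr, rmse_uV=errs,
        msc_freqs=freqs, msc_mean_curve=mean_curve, msc_band_mean=band_mean,
    )
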