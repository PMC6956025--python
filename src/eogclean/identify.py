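"""Automatic identification of ocular components (pipeline step 3).

Blink and eye-movement sources project overwhelmingly onto the forehead
electrodes, so an ocular component shows (i) a large average absolute mixing
weight over the frontal channels and (ii) a high Pearson correlation with at
least one frontal channel's time series.  A component is flagged when its
averaged absolute frontal weight lies above the Tukey outlier fence

    threshold = Q3 + 1.5 * IQR

of the weight distribution over all components, and its best absolute frontal
correlation reaches ``min_abs_corr``.  Flagging any number of components
(e.g., separate vertical and horizontal ocular sources) is legal, as is
flagging none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ica import ICADecomposition
from .recording import Montage, Recording

__all__ = [
    "EOGReport",
    "frontal_correlations",
    "mean_abs_frontal_weights",
    "tukey_flag",
    "identify_eog_components",
]


@dataclass
class EOGReport:
    """Outcome of the ocular-component screen.

    Attributes
    ----------
    R
        Pearson correlations, frontal channels x components.
    wbar
        Averaged absolute frontal mixing weight per component.
    threshold
        Tukey fence value applied to ``wbar``.
    flagged
        Indices of components identified as ocular (sorted).
    ranks
        All component indices ordered by best absolute frontal correlation,
        descending.
    """

    R: np.ndarray
    wbar: np.ndarray
    threshold: float
    flagged: tuple[int, ...]
    ranks: tuple[int, ...]
    frontal_labels: tuple[str, ...] = ()
    min_abs_corr: float = 0.5

    def max_abs_corr(self) -> np.ndarray:
        """Best absolute frontal correlation per component."""
        return np.abs(self.R).max(axis=0)

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "flagged": list(self.flagged),
            "ranks": list(self.ranks),
            "wbar": [float(v) for v in self.wbar],
            "max_abs_corr": [float(v) for v in self.max_abs_corr()],
            "frontal_labels": list(self.frontal_labels),
            "min_abs_corr": float(self.min_abs_corr),
        }


def _safe_corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with each row of ``b``.

    Zero-variance rows yield correlation 0 with a warning rather than NaN.
    """
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a ** 2).sum(axis=1))
    sb = np.sqrt((b ** 2).sum(axis=1))
    bad_a, bad_b = sa == 0, sb == 0
    if bad_a.any() or bad_b.any():
        warnings.warn("zero-variance series in correlation; reporting 0", stacklevel=3)
    sa[bad_a] = 1.0
    sb[bad_b] = 1.0
    r = (a @ b.T) / np.outer(sa, sb)
    r[bad_a, :] = 0.0
    r[:, bad_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def frontal_correlations(decomp: ICADecomposition, rec: Recording,
                         montage: Montage) -> np.ndarray:
    """Correlation of each frontal channel with each component time series."""
    idx = montage.resolve(rec.labels)
    return _safe_corr_rows(rec.data[idx], decomp.S)


def mean_abs_frontal_weights(A: np.ndarray, frontal_indices) -> np.ndarray:
    """Average of |mixing weight| over the frontal channels, per component."""
    frontal_indices = list(frontal_indices)
    if not frontal_indices:
        raise ValueError("frontal_indices must be non-empty")
    return np.abs(np.asarray(A)[frontal_indices, :]).mean(axis=0)


def tukey_flag(wbar: np.ndarray) -> tuple[float, set[int]]:
    """Tukey fence outlier test: flag values strictly above Q3 + 1.5 IQR.

    Quartiles use linear interpolation between order statistics.
    """
    wbar = np.asarray(wbar, dtype=np.float64)
    if wbar.size < 4:
        raise ValueError(
            f"need at least 4 components for a quartile fence, got {wbar.size}; "
            "select components manually instead"
        )
    q1, q3 = np.percentile(wbar, [25, 75], method="linear")
    threshold = float(q3 + 1.5 * (q3 - q1))
    flagged = {int(j) for j in np.flatnonzero(wbar > threshold)}
    return threshold, flagged


def identify_eog_components(decomp: ICADecomposition, rec: Recording,
                            montage: Montage, min_abs_corr: float = 0.5) -> EOGReport:
    """Screen all components and flag the ocular ones.

    The weight fence is the quantitative gate; the frontal correlation is a
    confirmatory filter guarding against non-frontal outliers.  An empty
    flagged set is a legal outcome.
    """
    idx = montage.resolve(rec.labels)
    R = frontal_correlations(decomp, rec, montage)
    wbar = mean_abs_frontal_weights(decomp.A, idx)
    threshold, fence = tukey_flag(wbar)
    best = np.abs(R).max(axis=0)
    flagged = tuple(sorted(j for j in fence if best[j] >= min_abs_corr))
    ranks = tuple(int(j) for j in np.argsort(-best, kind="stable"))
    return EOGReport(
        R=R, wbar=wbar, threshold=threshold, flagged=flagged, ranks=ranks,
        frontal_labels=tuple(montage.frontal), min_abs_corr=min_abs_corr,
    )
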