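"""End-to-end ocular-artifact removal pipeline.

Orchestrates the seven processing steps — band-pass filter and average
reference, Infomax ICA, ocular-component identification, peak detection,
window construction, per-component correction or rejection, and inverse
ICA — and exposes three removal methods behind one interface:

* ``pm``     — the selective method: flagged components are corrected only
  inside 1-s windows around detected ocular peaks (or rejected entirely
  when windows cover more than 60 % of the component);
* ``wica``   — wavelet-enhanced ICA baseline: flagged components are
  threshold-cleaned over their full length;
* ``icarej`` — rejection baseline: flagged components are zeroed.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import wavelets
from .config import DEFAULT_CONFIG, merge_config, resolve_levels
from .ica import ICADecomposition, fit_infomax, reconstruct
from .identify import EOGReport, identify_eog_components
from .peaks import ArtifactWindows, build_windows, decide_action, detect_eog_peaks
from .preprocess import preprocess
from .recording import Montage, Recording

__all__ = ["CleaningResult", "remove_eog", "METHODS"]

METHODS = ("pm", "wica", "icarej")
log = logging.getLogger("eogclean")


@dataclass
class CleaningResult:
    """Everything produced by one cleaning run.

    ``actions`` records, for every component, one of ``untouched``,
    ``corrected_in_windows``, ``corrected_full`` (wICA baseline) or
    ``rejected``.  ``preprocessed`` is the filtered/re-referenced input the
    cleaning is relative to; comparisons against a pure reference should
    preprocess that reference identically.
    """

    cleaned: Recording
    method: str
    actions: dict[int, str]
    report: EOGReport
    windows: dict[int, ArtifactWindows]
    config: dict
    seed: int
    preprocessed: Recording = None
    decomposition: ICADecomposition = None
    peak_times: dict[int, np.ndarray] = field(default_factory=dict)

    def to_report_dict(self) -> dict:
        """JSON-serializable run metadata (no signal data)."""
        return {
            "method": self.method,
            "seed": self.seed,
            "n_components": self.report.wbar.size,
            "actions": {str(k): v for k, v in self.actions.items()},
            "identification": self.report.to_dict(),
            "windows": {
                str(k): {"intervals": [list(iv) for iv in w.intervals],
                         "coverage": w.coverage}
                for k, w in self.windows.items()
            },
            "peak_times_s": {str(k): [float(t) for t in v]
                             for k, v in self.peak_times.items()},
            "converged": bool(self.decomposition.converged),
            "n_iter": int(self.decomposition.n_iter),
            "config": self.config,
        }


def remove_eog(rec: Recording, montage: Montage, method: str = "pm",
               config: dict | None = None, seed: int = 0) -> CleaningResult:
    """Run the full artifact-removal pipeline on a recording."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    cfg = merge_config(DEFAULT_CONFIG, config)
    fcfg, wcfg = cfg["filter"], cfg["wavelet"]

    rec_p = preprocess(rec, low=fcfg["low_hz"], high=fcfg["high_hz"],
                       order=fcfg["order"], reference=cfg["reference"])
    log.info("preprocess: band %.3g-%.3g Hz order %d, reference=%s",
             fcfg["low_hz"], fcfg["high_hz"], fcfg["order"], cfg["reference"])

    decomp = fit_infomax(rec_p, seed=seed, max_iter=cfg["ica"]["max_iter"],
                         tol=cfg["ica"]["tol"])
    log.info("ica: %d components, converged=%s after %d iterations",
             decomp.n_components, decomp.converged, decomp.n_iter)

    report = identify_eog_components(decomp, rec_p, montage,
                                     min_abs_corr=cfg["identify"]["min_abs_corr"])
    log.info("identify: fence=%.4g, flagged=%s", report.threshold, report.flagged)

    levels = resolve_levels(wcfg["levels"], rec_p.fs)
    keep = tuple(wcfg["keep"])
    S_mod = decomp.S.copy()
    reject: list[int] = []
    actions = {j: "untouched" for j in range(decomp.n_components)}
    windows_map: dict[int, ArtifactWindows] = {}
    peak_times: dict[int, np.ndarray] = {}

    for j in report.flagged:
        if method == "icarej":
            reject.append(j)
            actions[j] = "rejected"
            continue
        if method == "wica":
            S_mod[j] = wavelets.wica_clean_component(
                decomp.S[j], basis=wcfg["basis"], levels=levels,
                threshold_scale=cfg["wica"]["threshold_scale"])
            actions[j] = "corrected_full"
            continue
        # method == "pm"
        pk = detect_eog_peaks(decomp.S[j], rec_p.fs,
                              amp_factor=cfg["peaks"]["amp_factor"],
                              min_separation_s=cfg["peaks"]["min_separation_s"],
                              tie_break=cfg["peaks"]["tie_break"], component=j)
        win = build_windows(pk, rec_p.fs, n_samples=rec_p.n_samples,
                            width_s=cfg["windows"]["width_s"])
        windows_map[j] = win
        peak_times[j] = pk.times()
        action = decide_action(win, reject_fraction=cfg["windows"]["reject_fraction"])
        log.info("component %d: %d peaks, coverage %.1f%% -> %s",
                 j, len(pk), 100 * win.coverage, action)
        if action == "reject_component":
            reject.append(j)
            actions[j] = "rejected"
        elif win.intervals:
            S_mod[j] = wavelets.clean_component_selective(
                decomp.S[j], win, rec_p.fs, basis=wcfg["basis"], levels=levels,
                keep=keep, crossfade_s=wcfg["crossfade_s"])
            actions[j] = "corrected_in_windows"

    if not report.flagged:
        log.info("no ocular components flagged; output equals preprocessed input")
    cleaned = reconstruct(decomp, S_mod, reject=reject)
    cleaned = Recording(data=cleaned.data, fs=rec_p.fs, labels=list(rec_p.labels),
                        meta={**rec_p.meta, "cleaned_with": method})
    return CleaningResult(cleaned=cleaned, method=method, actions=actions,
                          report=report, windows=windows_map, config=cfg, seed=seed,
                          preprocessed=rec_p, decomposition=decomp,
                          peak_times=peak_times)
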