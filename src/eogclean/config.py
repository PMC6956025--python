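"""Pipeline configuration: defaults, YAML loading, deep merging."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "filter": {"low_hz": 1.0, "high_hz": 47.0, "order": 4},
    "reference": "average",
    "ica": {"max_iter": 512, "tol": 1e-6, "method": "infomax"},
    "identify": {"frontal_channels": None, "min_abs_corr": 0.5},
    "peaks": {"amp_factor": 3.0, "min_separation_s": 0.5, "tie_break": "largest"},
    "windows": {"width_s": 1.0, "reject_fraction": 0.60},
    "wavelet": {"basis": "sym4", "levels": 5, "keep": ["D1", "D2", "D3"],
                "crossfade_s": 0.01},
    "wica": {"threshold_scale": 1.0},
    "msc": {"segment_s": 2.0},
}


def merge_config(base: dict, override: dict | None) -> dict:
    """Deep-merge ``override`` into a copy of ``base``."""
    merged = copy.deepcopy(base)
    if override:
        for key, value in override.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key] = merge_config(merged[key], value)
            else:
                merged[key] = copy.deepcopy(value)
    return merged


def load_config(path) -> dict:
    """Load a YAML config file and merge it over the defaults."""
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return merge_config(DEFAULT_CONFIG, loaded)


def resolve_levels(levels, fs: float) -> int:
    """Resolve the wavelet level setting; ``"auto"`` tracks a ~0–6.25 Hz cut."""
    if levels == "auto":
        import math

        return max(1, math.ceil(math.log2(fs / 6.25)))
    return int(levels)
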