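"""Flat YAML configuration files mapping parameter names to values.

An empty or absent file yields the full default parameter set; every key is
validated against the ModelParams fields and invariants.  Protocol-level
overrides (repetition counts, seeds) live under their own keys and are
returned separately.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .params import ModelParams

__all__ = ["load_config", "PROTOCOL_KEYS"]

PROTOCOL_KEYS = {
    "n_presentations", "presentation", "pause", "test_duration",
    "disparity", "n_seeds", "n_reps", "fractions", "disparities",
    "delta_epsilons", "weight_factor", "n_stimuli",
}


def load_config(path: str | Path | None) -> tuple[ModelParams, dict]:
    """Read a key = value mapping; returns (ModelParams, protocol_overrides).

    Unknown keys fail fast naming the offending key; out-of-range values are
    rejected by the ModelParams invariants."""
    if path is None:
        return ModelParams(), {}
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    proto = {k: raw.pop(k) for k in list(raw) if k in PROTOCOL_KEYS}
    params = ModelParams.from_dict(raw)
    return params, proto
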