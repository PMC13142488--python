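"""Pipeline configuration: defaults, validation, YAML loading, hashing.

Keys are grouped by stage (``calib``, ``isotope``, ``xic``, ``lion``,
``summarize``, ``da``) plus a top-level ``seed``. Unknown keys are rejected
before any computation runs; every applied default is recoverable from
``PipelineConfig.to_dict()`` and the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    seed: int = 0

    # identification-report filters
    q_threshold: float = 0.01
    min_runs: int = 3

    # calibration
    calib_min_runs: int = 3
    calib_variability_quantile: float = 0.95
    calib_knots: int = 5
    calib_holdout: float = 0.2

    # isotope envelope
    isotope_threshold: float = 0.10
    isotope_lambda_coeff: float = 0.00052
    isotope_delta: float = 1.0033548

    # XIC extraction and scoring
    xic_tol_ppm: float = 15.0
    xic_rt_halfwidth: float = 1.0  # minutes
    xic_im_halfwidth: float = 0.05  # 1/K0
    xic_weights: Tuple[float, float, float] = (0.4, 0.4, 0.2)
    xic_min_shape: float = 0.5
    xic_min_apex_intensity: float = 0.0
    xic_scale_ms1: float = 3.0
    xic_scale_ms2: float = 2.0
    xic_top_fragments: int = 6

    # LION
    lion_min_quality: float = 0.3
    lion_max_missing_fraction: float = 0.5
    lion_scale: float = 1.0

    # summarization
    summarize_mode: str = "integrated"
    summarize_min_precursors: int = 3
    summarize_top_n_rescale: int = 3

    # differential abundance / benchmark
    da_fc_cut: float = 0.5
    da_p_cut: float = 0.05
    da_fpr_max: float = 0.1
    da_min_valid_per_group: Optional[int] = None  # None -> 5-of-8 pro rata
    da_min_precursors: int = 2

    def __post_init__(self) -> None:
        if self.summarize_mode not in ("ms1", "ms2", "integrated"):
            raise ValueError(f"unknown summarize_mode {self.summarize_mode!r}")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if abs(sum(self.xic_weights) - 1.0) > 1e-9:
            raise ValueError("xic_weights must sum to 1")
        if self.lion_scale <= 0:
            raise ValueError("lion_scale must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["xic_weights"] = list(d["xic_weights"])
        return d


# YAML uses dotted section keys (e.g. "xic.tol_ppm"); map to dataclass fields.
_KEY_MAP = {
    "seed": "seed",
    "report.q_threshold": "q_threshold",
    "report.min_runs": "min_runs",
    "calib.min_runs": "calib_min_runs",
    "calib.variability_quantile": "calib_variability_quantile",
    "calib.knots": "calib_knots",
    "calib.holdout": "calib_holdout",
    "isotope.threshold": "isotope_threshold",
    "isotope.lambda_coeff": "isotope_lambda_coeff",
    "isotope.delta": "isotope_delta",
    "xic.tol_ppm": "xic_tol_ppm",
    "xic.rt_halfwidth": "xic_rt_halfwidth",
    "xic.im_halfwidth": "xic_im_halfwidth",
    "xic.weights": "xic_weights",
    "xic.min_shape": "xic_min_shape",
    "xic.min_apex_intensity": "xic_min_apex_intensity",
    "xic.scale_ms1": "xic_scale_ms1",
    "xic.scale_ms2": "xic_scale_ms2",
    "xic.top_fragments": "xic_top_fragments",
    "lion.min_quality": "lion_min_quality",
    "lion.max_missing_fraction": "lion_max_missing_fraction",
    "lion.scale": "lion_scale",
    "summarize.mode": "summarize_mode",
    "summarize.min_precursors": "summarize_min_precursors",
    "summarize.top_n_rescale": "summarize_top_n_rescale",
    "da.fc_cut": "da_fc_cut",
    "da.p_cut": "da_p_cut",
    "da.fpr_max": "da_fpr_max",
    "da.min_valid_per_group": "da_min_valid_per_group",
    "da.min_precursors": "da_min_precursors",
}


def load_config(path=None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus overrides.

    The YAML may use either flat dotted keys (``xic.tol_ppm: 10``) or nested
    sections (``xic: {tol_ppm: 10}``). Unknown keys raise immediately.
    """
    flat: Dict[str, object] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat.update(_flatten(raw))
    if overrides:
        flat.update(_flatten(overrides))
    kwargs = {}
    unknown = []
    for key, value in flat.items():
        target = _KEY_MAP.get(key, key if key in PipelineConfig.__dataclass_fields__ else None)
        if target is None:
            unknown.append(key)
        else:
            kwargs[target] = tuple(value) if target == "xic_weights" else value
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def _flatten(d: dict, prefix: str = "") -> Dict[str, object]:
    out: Dict[str, object] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the effective parameters (changes iff any changes)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
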