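"""Run configuration: every numeric threshold of the pipeline in one place.

Defaults trace either to a quoted analysis constant (eligibility >= 15 tags,
100-fold conservation rule, 800 bp synteny window with 50% aligned / 25%
orthologous bases, 5-fold housekeeping rule, 60% / 8 hr developmental rule,
12-cluster cut with < 200-member filtering, 301 bp motif window, 150 bp
transcript-to-TSC matching, 5x upsampling, 2 hr / 1 hr smoothing, 3 hr DTW
band, phyloP 0.1 selection threshold) or to a documented package default
(peak-caller parameters).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    # peak calling
    min_pos_count: int = 2
    max_gap: int = 50
    min_total: int = 15
    # conservation
    min_tags: int = 15
    fold: float = 100.0
    low_ref: float = 100.0
    synteny_window: int = 800
    frac_aligned: float = 0.5
    frac_orth: float = 0.25
    rescue_min_tags: int = 10
    # expression classification
    min_max_rpm: float = 10.0
    entropy_min_max_rpm: float = 2.0
    concordance_thresholds: tuple = (10.0, 25.0)
    hk_fold: float = 5.0
    dev_frac: float = 0.6
    dev_window_hr: int = 8
    k: int = 12
    min_cluster: int = 200
    # motifs
    motif_window: int = 301
    motif_pvalue: float = 1e-3
    tfbs_pvalue: float = 2e-4
    # gene assignment
    tss_match: int = 150
    # time-series registration
    upsample: int = 5
    smooth_pre: float = 2.0
    band: float = 3.0
    smooth_post: float = 1.0
    # sequence conservation
    phylop_thresh: float = 0.1
    # simulation / reproducibility
    n_tscs: int = 300
    depth: float = 5e4
    time_points: int = 24
    seed: int = 0
    out_dir: str = "promevo_out"
    blacklist: list = field(default_factory=list)

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) \
                    and f.name not in ("seed",) and v is not None:
                if v < 0:
                    raise ValueError(f"{f.name} must be nonnegative")
        for name in ("min_total", "min_tags", "fold", "synteny_window",
                     "hk_fold", "dev_frac", "dev_window_hr", "k",
                     "motif_window", "tss_match", "upsample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "concordance_thresholds" in data:
            data["concordance_thresholds"] = tuple(data["concordance_thresholds"])
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
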