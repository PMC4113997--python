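"""Run configuration: every tunable knob across the pipelines, in one place.

Loaded from a YAML key-value file; unknown keys are rejected so typos fail
loudly rather than silently running defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # audio / features
    sample_rate_hz: float = 40_000.0
    window_ms: float = 10.0
    step_ms: float = 1.0
    n_tapers: int = 2
    bandwidth_param: float = 1.5
    band_low_hz: float = 860.0
    band_high_hz: float = 8600.0
    silence_threshold_db: float | None = None   # None = noise floor + 12 dB
    min_syllable_ms: float = 10.0
    min_gap_ms: float = 5.0
    # imitation scoring
    tau: float | None = None                    # None = median pairwise distance
    stride_frames: int | None = None            # None = one tutor-motif duration
    n_bouts: int = 20
    capacity_control_mean: float = 0.197
    capacity_unrelated_mean: float = 0.104
    # stereotypy
    n_select: int = 100
    n_sample: int = 100
    exclude_self: bool = True
    sample_with_replacement: bool = True
    stereotypy_percentile: float = 95.0
    min_overlap_frac: float = 0.5
    # neural response
    half_window_ms: float = 150.0
    n_shuffles: int = 1000
    shift_range_ms: float = 1000.0
    bootstrap_bin_ms: float = 10.0
    latency_bin_ms: float = 2.0
    significance_alpha: float = 0.05            # 95th-percentile criterion
    antidromic_window_ms: tuple[float, float] = (2.0, 17.0)
    antidromic_band_hz: tuple[float, float] = (200.0, 2000.0)
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        for key in ("antidromic_window_ms", "antidromic_band_hz"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        return asdict(self)
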