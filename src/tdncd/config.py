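"""Run configuration with YAML round-tripping.

Defaults are the canonical analysis settings: 100 s windows stepped by 10 s
at TR = 2 s, alpha 0.05 with Bonferroni families of 24 (tdNCD distances) and
264 (FC), and per-kind selection thresholds 0.001 (sFC) / 0.00001 (dFC) /
0.05 (tdNCD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml


@dataclass
class RunConfig:
    window_seconds: float = 100.0
    step_seconds: float = 10.0
    tr_seconds: float = 2.0
    alpha: float = 0.05
    family_tdncd: int = 24
    family_fc: int = 264
    feature_kinds: list[str] = field(
        default_factory=lambda: ["sfc_edge", "tdncd_roi_distance"]
    )
    selection_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "sfc_edge": 0.001,
            "dfc_window_edge": 0.00001,
            "tdncd_roi_distance": 0.05,
        }
    )
    classifier: str = "fcnet"
    task: str = "nc_vs_ad"
    seed: int = 0
    out_dir: str = "tdncd_out"
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
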