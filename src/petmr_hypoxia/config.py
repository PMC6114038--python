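"""Run configuration for the file-based pipeline (YAML/JSON)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class TimepointPaths:
    """Input files for one imaging session (one week)."""

    series: str | None = None        # 4-D multi-echo NIfTI
    echo_times: str | None = None    # JSON/text list, ms
    fmiso: str | None = None         # 3-D SUV NIfTI
    fdg: str | None = None           # 3-D SUV NIfTI (baseline only in the study)
    gtv_t: str | None = None
    gtv_ln: str | None = None
    nt: str | None = None
    background: str | None = None


@dataclass
class RunConfig:
    """Everything one patient's pipeline run needs."""

    patient: str
    timepoints: dict[int, TimepointPaths] = field(default_factory=dict)
    threshold_factor: float = 1.4
    noise_floor_multiplier: float = 5.0
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.noise_floor_multiplier < 0:
            raise ValueError("noise_floor_multiplier must be >= 0")
        for week in self.timepoints:
            if int(week) < 0:
                raise ValueError("week labels must be non-negative integers")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        timepoints = {int(w): TimepointPaths(**tp)
                      for w, tp in raw.pop("timepoints", {}).items()}
        return cls(timepoints=timepoints, **raw)
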