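"""Run configuration: flat key=value files with CLI overrides.

Defaults reproduce the published thresholds: reporting score >= 140
(7 units at 20 points each), a +/-5000 bp gene window, alpha 0.01 at the
meta-analysis stage, and the ten-fold grade cut-offs 1e-5 .. 1e-1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

from .grading import DEFAULT_CUTOFFS


@dataclass
class RunConfig:
    points_per_unit: float = 20.0
    min_score: float = 140.0
    min_units: int = 7
    min_energy: Optional[float] = None
    modes: List[str] = field(default_factory=lambda: ["hoogsteen", "reverse_hoogsteen"])
    orientations: List[str] = field(default_factory=lambda: ["antiparallel", "parallel"])
    energy_table: Optional[str] = None
    segment_length: Optional[int] = None
    overlap: Optional[int] = None
    report_all: bool = False
    grade_cutoffs: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    window: int = 5000
    alpha: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> Dict[str, str]:
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                out[k] = ""
            elif isinstance(v, list):
                out[k] = ",".join(str(x) for x in v)
            elif isinstance(v, dict):
                out[k] = ",".join(f"{g}:{c!r}" for g, c in sorted(v.items()))
            else:
                out[k] = str(v)
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        cfg = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, val = line.partition("=")
                cfg.set(key.strip(), val.strip())
        return cfg

    def set(self, key: str, val: str) -> None:
        if not hasattr(self, key):
            raise KeyError(f"unknown configuration key {key!r}")
        if key in ("modes", "orientations"):
            setattr(self, key, [v for v in val.split(",") if v])
        elif key == "grade_cutoffs":
            cut = {}
            for part in val.split(","):
                g, _, c = part.partition(":")
                cut[int(g)] = float(c)
            setattr(self, key, cut)
        elif key in ("min_energy", "segment_length", "overlap", "energy_table"):
            if val == "" or val.lower() == "none":
                setattr(self, key, None)
            elif key == "energy_table":
                setattr(self, key, val)
            elif key in ("segment_length", "overlap"):
                setattr(self, key, int(val))
            else:
                setattr(self, key, float(val))
        elif key == "report_all":
            setattr(self, key, val.lower() in ("1", "true", "yes"))
        elif key in ("min_units", "window", "seed"):
            setattr(self, key, int(val))
        elif key in ("points_per_unit", "min_score", "alpha"):
            setattr(self, key, float(val))
        else:
            setattr(self, key, val)
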