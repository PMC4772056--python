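"""Analysis configuration: one YAML file drives the whole batch pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .integration import DEFAULT_WINDOWS, WATER_EXCLUSION_HALFWIDTH
from .simulate import WATER_DELTA_30C, WATER_SLOPE

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Every tunable of the automatic analysis, with its default.

    The two booleans ``auto_phase``/``auto_reference`` mirror the options
    of the original processing dialog; both default to on.
    """

    zero_fill_to: int = 32768
    auto_phase: bool = True
    auto_reference: bool = True
    baseline_lam: float = 1e7
    baseline_p: float = 0.0
    snr_min: float = 250.0
    fh_band: tuple[float, float] = (1.45, 1.55)
    eq2_uses_h: bool = False
    tail_correction: bool = True
    j_includes_sn2: bool = False
    water_delta_30c: float = WATER_DELTA_30C
    water_slope: float = WATER_SLOPE
    water_exclusion_halfwidth: float = WATER_EXCLUSION_HALFWIDTH
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fh_band" in raw:
            raw["fh_band"] = tuple(raw["fh_band"])
        if "windows" in raw:
            raw["windows"] = {k: tuple(v) for k, v in raw["windows"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.as_yaml())

    def as_yaml(self) -> str:
        d = asdict(self)
        d["fh_band"] = list(d["fh_band"])
        d["windows"] = {k: list(v) for k, v in d["windows"].items()}
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def digest(self) -> str:
        """Short stable hash of the canonical YAML form."""
        return hashlib.sha256(self.as_yaml().encode()).hexdigest()[:12]
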