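"""Run configuration: one serialisable object drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .optics import DEFAULT_SCALE


@dataclass
class RunConfig:
    """All knobs of a quantification run.

    Round-trips losslessly through YAML/JSON; the config hash recorded in
    run manifests is taken over the canonical JSON form.
    """

    images: list[str] = field(default_factory=list)
    standard_images: list[str] = field(default_factory=list)
    output_dir: str = "feulgen_out"

    scale: float = DEFAULT_SCALE           # pixels per um^2
    t_floor: float = 1e-3                  # transmittance clamp (OD cap 3)

    od_threshold: float | None = None      # None = Otsu with floor
    min_area_um2: float = 8.0
    max_area_um2: float = 400.0
    split_touching: bool = False
    include_flagged: bool = False

    min_standard_nuclei: int = 10
    standard_2c_pg: float = 2.5
    c1_pg: float = 3.0                     # species haploid mass; human 3 pg

    alpha: float = 0.05
    dunn_adjust: str = "none"

    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.t_floor < 1:
            raise ValueError("t_floor must be in (0, 1)")
        if self.scale <= 0 or self.c1_pg <= 0 or self.standard_2c_pg <= 0:
            raise ValueError("scale, c1_pg and standard_2c_pg must be positive")
        if self.min_area_um2 < 0 or self.max_area_um2 <= self.min_area_um2:
            raise ValueError("need 0 <= min_area_um2 < max_area_um2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.dunn_adjust not in ("none", "bonferroni", "holm"):
            raise ValueError("dunn_adjust must be none, bonferroni or holm")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
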