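"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .render import RenderParams
from .segmentation import SegConfig
from .simulate import SimParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a run plus the sample manifest.

    ``samples`` maps a sample id to a record with image paths, pixel size
    (um/px), time points (h) and an optional group label.  The orientation
    bands are (periclinal_max_deg, anticlinal_min_deg); rectangularity
    thresholds gate packet membership.
    """

    sim: SimParams = field(default_factory=SimParams)
    render: RenderParams = field(default_factory=RenderParams)
    seg: SegConfig = field(default_factory=SegConfig)
    orientation_bands: tuple[float, float] = (30.0, 60.0)
    strong_overlap: float = 0.5
    min_overlap: float = 0.25
    solidity_min: float = 0.9
    rect_fill_min: float = 0.8
    welch: bool = False
    samples: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orientation_bands"] = list(self.orientation_bands)
        if d["sim"].get("initial_sheet") is not None:
            d["sim"]["initial_sheet"] = list(d["sim"]["initial_sheet"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if sim.get("initial_sheet") is not None:
            sim["initial_sheet"] = tuple(sim["initial_sheet"])
        render = d.pop("render", {})
        seg = d.pop("seg", {})
        bands = d.pop("orientation_bands", (30.0, 60.0))
        return cls(
            sim=SimParams(**sim),
            render=RenderParams(**render),
            seg=SegConfig(**seg),
            orientation_bands=tuple(bands),
            **d,
        )

    def save(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls.from_dict(data)
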