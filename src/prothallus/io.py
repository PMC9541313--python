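"""File formats: TIFF images, label maps, CSV tables, JSON manifests.

All tables are plain CSV with fixed column schemas and deterministic row
ordering (sample, time, cell id), mirroring the style of published
source-data tables; every manifest echoes the configuration hash that
produced the outputs so results are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .images import LabelMap, PixelImage
from .segmentation import max_project

__all__ = [
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "ResultBundle",
    "write_tables",
    "read_tables",
    "config_hash",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

EVENT_COLUMNS = [
    "sample_id", "window", "parent_id", "daughter_ids", "orientation",
    "wall_margin_angle", "packet_type", "layer", "qc_flags",
]
LINEAGE_COLUMNS = ["sample_id", "parent_id", "daughter_id", "window"]
CELL_COLUMNS = [
    "sample_id", "time_h", "cell_id", "area_um2", "centroid_x_um",
    "centroid_y_um", "layer", "is_trichome", "divided",
]


def read_image(
    path,
    pixel_size: float | None = None,
    time_h: float | None = None,
    sample_id: str | None = None,
    project: bool = False,
) -> PixelImage:
    """Read a 2D (or Z-stack) TIFF as a :class:`PixelImage`.

    Pixel size is required metadata (microscope magnification is never
    guessed); a Z-stack is max-projected when ``project=True``, otherwise a
    stack raises.
    """
    if pixel_size is None or not pixel_size > 0:
        raise ValueError(f"{path}: pixel_size (um/px) metadata is required")
    arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim == 3:
        if not project:
            raise ValueError(
                f"{path}: Z-stack found; pass project=True for a "
                "maximum-intensity projection"
            )
        slices = [
            PixelImage(a, pixel_size, time_h=time_h, sample_id=sample_id)
            for a in arr
        ]
        return max_project(slices)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image or 3D stack")
    return PixelImage(
        arr.astype(float), pixel_size, time_h=time_h, sample_id=sample_id
    )


def write_image(path, img: PixelImage) -> None:
    """Write intensities as 16-bit TIFF (clipped to the uint16 range)."""
    data = np.clip(np.rint(img.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_labelmap(
    path, pixel_size: float, time_h: float | None = None,
    sample_id: str | None = None,
) -> LabelMap:
    arr = np.squeeze(tifffile.imread(str(path)))
    return LabelMap(
        arr.astype(np.int32), pixel_size, time_h=time_h, sample_id=sample_id
    )


def write_labelmap(path, lm: LabelMap) -> None:
    tifffile.imwrite(str(path), lm.labels.astype(np.int32))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ResultBundle:
    """Everything one analysis run writes: tables, overlays, manifest."""

    cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CELL_COLUMNS))
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    lineage: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=LINEAGE_COLUMNS))
    stats: dict = field(default_factory=dict)
    overlays: dict = field(default_factory=dict)  # name -> RGB float array
    config: dict = field(default_factory=dict)


def _ordered(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    df = df.reindex(columns=cols)
    sort_by = [c for c in ("sample_id", "time_h", "window", "parent_id", "cell_id", "daughter_id") if c in cols]
    if len(df):
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    return df


def write_tables(bundle: ResultBundle, directory) -> dict:
    """Write the bundle as CSV/JSON/PNG files; returns the manifest."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(bundle.config)
    files = {}
    for name, df, cols in (
        ("cells", bundle.cells, CELL_COLUMNS),
        ("events", bundle.events, EVENT_COLUMNS),
        ("lineage", bundle.lineage, LINEAGE_COLUMNS),
    ):
        path = out / f"{name}.csv"
        _ordered(df, cols).to_csv(path, index=False)
        files[name] = path.name
    if bundle.stats:
        path = out / "stats.json"
        path.write_text(json.dumps(bundle.stats, indent=2, default=str))
        files["stats"] = path.name
    for name, rgb in bundle.overlays.items():
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        path = out / f"{name}.png"
        plt.imsave(path, np.clip(rgb, 0, 1))
        files[name] = path.name
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": chash,
        "config": bundle.config,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_tables(directory) -> ResultBundle:
    """Re-read a written bundle (tables and manifest; overlays are not
    round-tripped)."""
    out = Path(directory)
    manifest = json.loads((out / "manifest.json").read_text())
    bundle = ResultBundle(config=manifest.get("config", {}))
    for name, cols in (
        ("cells", CELL_COLUMNS), ("events", EVENT_COLUMNS), ("lineage", LINEAGE_COLUMNS)
    ):
        path = out / f"{name}.csv"
        if path.exists():
            setattr(bundle, name, pd.read_csv(path))
    stats = out / "stats.json"
    if stats.exists():
        bundle.stats = json.loads(stats.read_text())
    return bundle
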