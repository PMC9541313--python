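"""Core raster containers shared across the pipeline.

Conventions (used everywhere): arrays are indexed ``[row, col]``, 0-based;
physical coordinates are ``(x, y) = (col, row) * pixel_size`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PixelImage", "LabelMap"]


@dataclass
class PixelImage:
    """A 2D intensity image with physical pixel size.

    Attributes
    ----------
    intensities : 2D float array of non-negative intensities.
    pixel_size : micrometres per pixel (isotropic); must be positive.
    time_h : acquisition time in hours, if part of a time-lapse.
    sample_id : identifier of the gametophyte the image belongs to.
    flags : free-form QC flags (e.g. ``constant_input`` set by preprocessing).
    """

    intensities: np.ndarray
    pixel_size: float
    time_h: float | None = None
    sample_id: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("PixelImage requires a 2D array")
        if self.pixel_size is None or not self.pixel_size > 0:
            raise ValueError("pixel_size (um/px) must be a positive number")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class LabelMap:
    """An integer partition of an image into cells; 0 is background."""

    labels: np.ndarray
    pixel_size: float
    time_h: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap requires a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer array")
        if self.pixel_size is None or not self.pixel_size > 0:
            raise ValueError("pixel_size (um/px) must be a positive number")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def foreground(self) -> np.ndarray:
        return self.labels > 0
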