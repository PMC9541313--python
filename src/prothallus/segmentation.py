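"""Watershed cell segmentation of wall-stained gametophyte images.

The stain marks cell walls, so cells appear as dim basins enclosed by bright
ridges.  Segmentation is marker-controlled watershed: a tissue mask from
thresholding, seeds from the h-minima of the wall-probability image, flooding
of the wall probability from the seeds, then merging of sub-resolution
regions into the neighbour sharing the longest boundary.  Everything is
deterministic for a fixed image and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .images import LabelMap, PixelImage

__all__ = [
    "SegConfig",
    "CellRecord",
    "EmptySegmentationError",
    "max_project",
    "preprocess",
    "segment",
    "quantify_areas",
    "colorize_areas",
    "AREA_COLORMAP",
]


class EmptySegmentationError(RuntimeError):
    """No tissue found in the image."""


@dataclass(frozen=True)
class SegConfig:
    """Knobs of the watershed segmentation.

    blur_sigma : Gaussian smoothing of the raw image (px).
    background_percentile : intensity percentile subtracted as background;
        assumes the frame includes a margin of background around the tissue
        (as in typical acquisitions), hence a low default.
    h_minima_depth : seed depth (px) applied to the smoothed distance
        transform of the non-wall tissue; shallower basins are not seeded.
        This is the h-maxima-of-distance formulation of h-minima seeding.
    min_cell_area : regions smaller than this (um^2) are merged away; the
        default is below any plausible meristem cell and only removes specks.
    border_policy : 'keep' or 'drop' cells touching the image border.
    tophat_radius : disk radius (px) of the white top-hat that detects thin
        bright wall ridges independently of local background.
    dist_sigma : Gaussian smoothing (px) of the distance transform before
        seed extraction (suppresses seeds from boundary wiggles).
    mask_erosion : px to erode the tissue mask so its rim sits near the
        outer wall crest rather than the blurred outer slope.
    """

    blur_sigma: float = 1.0
    background_percentile: float = 5.0
    h_minima_depth: float = 1.0
    min_cell_area: float = 20.0
    border_policy: str = "keep"
    tophat_radius: int = 5
    dist_sigma: float = 1.5
    mask_erosion: int = 2
    # depth (px) of the outer rim band that is re-grown by proximity after
    # flooding, so no cell can flange along its neighbours' outer walls
    rim_regrow_px: int = 3

    def validate(self) -> None:
        if self.min_cell_area <= 0:
            raise ValueError("min_cell_area must be positive")
        if not 0 <= self.background_percentile <= 100:
            raise ValueError("background_percentile must be in [0, 100]")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1 px")


@dataclass
class CellRecord:
    """One segmented cell with its physical measurements."""

    cell_id: int
    area: float  # um^2
    centroid: tuple[float, float]  # (x, y) um
    boundary: np.ndarray  # polygon vertices (x, y) um
    layer: str = "unassigned"
    is_trichome: bool = False
    divided: bool | None = None


def max_project(stack: list[PixelImage]) -> PixelImage:
    """Maximum-intensity projection of a Z-stack of equally shaped slices."""
    if not stack:
        raise ValueError("empty stack")
    shape = stack[0].shape
    ps = stack[0].pixel_size
    for s in stack[1:]:
        if s.shape != shape:
            raise ValueError(f"slice shape {s.shape} != {shape}")
        if s.pixel_size != ps:
            raise ValueError("slices disagree on pixel size")
    out = np.maximum.reduce([s.intensities for s in stack])
    return PixelImage(out, pixel_size=ps, time_h=stack[0].time_h,
                      sample_id=stack[0].sample_id)


def preprocess(img: PixelImage, cfg: SegConfig = SegConfig()) -> PixelImage:
    """Smooth, background-subtract and normalize to a [0, 1] wall probability.

    A constant input cannot be normalized; it yields an all-zero image with
    ``flags['constant_input'] = True`` rather than an exception.
    """
    cfg.validate()
    x = img.intensities.astype(float)
    if cfg.blur_sigma > 0:
        x = ndi.gaussian_filter(x, cfg.blur_sigma)
    x = x - np.percentile(x, cfg.background_percentile)
    np.clip(x, 0.0, None, out=x)
    peak = x.max()
    flags = dict(img.flags)
    if peak <= 0:
        flags["constant_input"] = True
        x = np.zeros_like(x)
    else:
        x = x / peak
    out = PixelImage(x, pixel_size=img.pixel_size, time_h=img.time_h,
                     sample_id=img.sample_id)
    out.flags = flags
    return out


def _tissue_mask(wallprob: np.ndarray, min_px: int) -> np.ndarray:
    """Tissue = interiors + walls, separated from background by two-stage Otsu
    (first cut isolates bright walls, second separates dim interiors from the
    darker background), then closing, hole filling and speck removal."""
    nz = wallprob[wallprob > 0]
    if nz.size == 0:
        return np.zeros(wallprob.shape, dtype=bool)
    # estimate thresholds on a strongly smoothed copy so they are stable
    # regardless of how much of the frame the tissue occupies, but apply
    # them to the unsmoothed image so the mask hugs the outer walls
    xs = ndi.gaussian_filter(wallprob, 2.0)
    t_wall = threshold_otsu(xs) if xs.max() > xs.min() else 0.0
    low = xs[xs < t_wall]
    if low.size > 1 and low.max() > low.min():
        t_bg = max(threshold_otsu(low), 0.25 * t_wall)
    else:
        t_bg = 0.5 * t_wall
    rough = wallprob > t_bg
    rough = morphology.closing(rough, morphology.disk(3))
    rough = ndi.binary_fill_holes(rough)
    comp, _ = ndi.label(rough)
    sizes = np.bincount(comp.ravel())
    keep = sizes >= max(min_px, 16)
    keep[0] = False
    return keep[comp]


def _regrow_rim(labels: np.ndarray, mask: np.ndarray, depth: int = 3) -> np.ndarray:
    """Reassign the outer rim band of the tissue to the nearest cell.

    The watershed floods the outer wall crest (an intensity plateau) from
    whichever neighbouring basin reaches it first, which lets one cell run a
    thin flange along its neighbours' outer walls and steal their margin
    contact.  Vacating the rim band and re-growing labels by proximity gives
    every cell its own stretch of the tissue margin.  Labels lying entirely
    inside the band (e.g. thin protrusion tips) are left untouched.
    """
    from skimage.segmentation import expand_labels

    band = mask & ~ndi.binary_erosion(mask, iterations=depth)
    if not band.any():
        return labels
    in_band = np.bincount(labels[band].ravel(), minlength=int(labels.max()) + 1)
    total = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    fully_inside = (in_band == total)
    vacate = band & ~fully_inside[labels]
    labels = labels.copy()
    labels[vacate] = 0
    grown = expand_labels(labels, distance=2 * depth + 2)
    labels[vacate] = grown[vacate]
    return labels


def _merge_small(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Merge regions below min_px into the neighbour with the longest shared
    boundary (ties: smaller label id). Iterates smallest-first."""
    labels = labels.copy()
    while True:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        present = np.flatnonzero(counts)
        small = present[counts[present] < min_px]
        if small.size == 0 or present.size <= 1:
            break
        # process the single smallest region, then re-scan
        target = small[np.argmin(counts[small])]
        region = labels == target
        ring = ndi.binary_dilation(region) & ~region
        neigh = labels[ring]
        neigh = neigh[(neigh > 0) & (neigh != target)]
        if neigh.size == 0:
            labels[region] = 0  # isolated speck
            continue
        vcounts = np.bincount(neigh)
        best = np.flatnonzero(vcounts == vcounts.max())[0]
        labels[region] = best
    return labels


def segment(
    wallprob: PixelImage, cfg: SegConfig = SegConfig()
) -> LabelMap:
    """Marker-controlled watershed of a preprocessed wall-probability image.

    Walls are detected as thin bright ridges (white top-hat + Otsu); seeds
    are h-maxima of the smoothed distance transform of the non-wall tissue,
    plus one seed for every interior compartment the maxima missed (thin
    cells), excluding compartments touching the mask rim (blur slope).
    Regions below ``min_cell_area`` are merged into the neighbour sharing
    the longest boundary.
    """
    cfg.validate()
    ps = wallprob.pixel_size
    min_px = max(1, int(round(cfg.min_cell_area / ps**2)))
    x = wallprob.intensities
    mask = _tissue_mask(x, min_px)
    if cfg.mask_erosion > 0:
        mask = ndi.binary_erosion(mask, iterations=cfg.mask_erosion)
    if not mask.any():
        raise EmptySegmentationError("no tissue mask found in image")

    tophat = morphology.white_tophat(x, footprint=morphology.disk(cfg.tophat_radius))
    in_mask = tophat[mask]
    wall_thr = threshold_otsu(in_mask) if in_mask.max() > in_mask.min() else np.inf
    wall = tophat > wall_thr
    interior = mask & ~wall

    dist = ndi.distance_transform_edt(interior)
    if cfg.dist_sigma > 0:
        dist = ndi.gaussian_filter(dist, cfg.dist_sigma)
    seeds = morphology.h_maxima(dist, cfg.h_minima_depth).astype(bool) & mask

    # rescue: thin cells whose basin is too shallow for the h-criterion get
    # one seed per enclosed interior compartment; compartments touching the
    # mask rim are the outer blur slope, not cells
    comp, nc = ndi.label(interior)
    rim = mask & ~ndi.binary_erosion(mask, iterations=1)
    sizes = np.bincount(comp.ravel(), minlength=nc + 1)
    rescue = sizes >= min_px
    rescue[0] = False
    rescue[np.unique(comp[rim & (comp > 0)])] = False
    rescue[np.unique(comp[seeds & (comp > 0)])] = False

    markers, n = ndi.label(seeds | rescue[comp])
    if n == 0:  # flat interior (e.g. all-zero wall probability): one region
        markers = mask.astype(np.int32)
    labels = watershed(x, markers=markers, mask=mask)
    labels = _regrow_rim(labels, mask, depth=cfg.rim_regrow_px)
    labels = _merge_small(labels, min_px)

    if cfg.border_policy == "drop":
        border = np.unique(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            )
        )
        labels[np.isin(labels, border[border > 0])] = 0

    # relabel densely 1..K, ordered by original id
    ids = np.flatnonzero(np.bincount(labels.ravel())[1:]) + 1
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    out = lut[labels]
    if ids.size == 0:
        raise EmptySegmentationError("segmentation produced no cells")
    return LabelMap(out, pixel_size=ps, time_h=wallprob.time_h,
                    sample_id=wallprob.sample_id)


def _boundary_polygon(region_mask: np.ndarray, offset, ps: float) -> np.ndarray:
    padded = np.pad(region_mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    contour = max(contours, key=len)  # outer boundary
    rows = contour[:, 0] - 1 + offset[0]
    cols = contour[:, 1] - 1 + offset[1]
    return np.column_stack([cols * ps, rows * ps])


def quantify_areas(lm: LabelMap, pixel_size: float | None = None) -> list[CellRecord]:
    """One record per label: area (px count x pixel_size^2), centroid, boundary."""
    ps = pixel_size if pixel_size is not None else lm.pixel_size
    records = []
    for prop in measure.regionprops(lm.labels):
        rmin, cmin, _, _ = prop.bbox
        boundary = _boundary_polygon(prop.image, (rmin, cmin), ps)
        cy, cx = prop.centroid
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                area=float(prop.area) * ps**2,
                centroid=(float(cx) * ps, float(cy) * ps),
                boundary=boundary,
            )
        )
    return records


def _blue_red_colormap():
    from matplotlib.colors import LinearSegmentedColormap

    return LinearSegmentedColormap.from_list(
        "area_blue_red",
        [(0, 0, 1), (0, 1, 1), (0, 1, 0), (1, 1, 0), (1, 0, 0)],
    )


AREA_COLORMAP = _blue_red_colormap()


def colorize_areas(
    cells: list[CellRecord], lm: LabelMap, cap: float = 2000.0
) -> tuple[np.ndarray, dict]:
    """Per-cell area colour map from blue (0) to red (>= cap um^2).

    Returns an RGB float image (background black) and metadata recording the
    cap and colormap so figures are self-describing.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    rgb = np.zeros(lm.shape + (3,), dtype=float)
    for rec in cells:
        frac = min(rec.area, cap) / cap
        rgb[lm.labels == rec.cell_id] = AREA_COLORMAP(frac)[:3]
    meta = {"cap_um2": cap, "colormap": "area_blue_red (blue->cyan->green->yellow->red)"}
    return rgb, meta
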