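"""Cell tracking across time-lapse windows.

Gametophytes are moved between imaging sessions, so consecutive label maps
are first aligned by a rigid transform (centroid alignment plus a grid search
over rotation).  Cells are then matched by label overlap: every cell at the
later time point is assigned to the earlier cell containing the largest
fraction of its (back-transformed) area.  An earlier cell with two or more
well-overlapping children is a division; poorly overlapping children are
flagged unmatched rather than silently attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .images import LabelMap

__all__ = [
    "RigidTransform",
    "LineageLink",
    "WindowMeta",
    "RegistrationError",
    "register",
    "match_lineage",
    "divided_map",
    "compose_descendants",
]


class RegistrationError(RuntimeError):
    """Tissue masks could not be aligned with sufficient overlap."""


@dataclass(frozen=True)
class RigidTransform:
    """Maps t0 coordinates into t1 coordinates (rotation about ``center``).

    ``p1 = scale * R(rotation) @ (p0 - center) + center + translation`` with
    coordinates and translation in micrometres.  ``scale`` compensates
    isotropic tissue growth between imaging sessions (1.0 = strictly rigid);
    the alignment itself remains a rotation + translation search.
    """

    rotation_deg: float
    translation: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def matrix(self) -> np.ndarray:
        a = np.deg2rad(self.rotation_deg)
        return self.scale * np.array(
            [[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]
        )

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        return (pts - c) @ self.matrix().T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        # p0 = (1/s) R^T (p1 - c - t) + c : rotate by -angle and scale by
        # 1/s about (c + t), then translate by -t
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return RigidTransform(
            rotation_deg=-self.rotation_deg,
            translation=tuple(-t),
            center=tuple(c + t),
            scale=1.0 / self.scale,
        )


@dataclass(frozen=True)
class WindowMeta:
    """One tracking window [t0, t1] in hours."""

    t0_h: float
    t1_h: float

    @property
    def timeframe_h(self) -> float:
        return self.t1_h - self.t0_h

    def validate(self) -> None:
        if not self.timeframe_h > 0:
            raise ValueError("window must have positive duration")


@dataclass
class LineageLink:
    """One t0 cell and the t1 cells assigned to it."""

    parent_id: int
    child_ids: list[int]
    overlap_fractions: list[float]
    child_areas: list[float] = field(default_factory=list)
    strong_overlap: float = 0.5
    min_child_share: float = 0.1

    @property
    def strong_children(self) -> list[int]:
        """Children counting towards a division call: well-overlapping and
        not a sliver of the sibling set; ordered largest-first so the first
        two are the principal daughters."""
        strong = [
            (c, a)
            for c, f, a in zip(
                self.child_ids, self.overlap_fractions,
                self.child_areas or [1.0] * len(self.child_ids),
            )
            if f >= self.strong_overlap
        ]
        total = sum(a for _, a in strong)
        if total <= 0:
            return []
        kept = [(c, a) for c, a in strong if a / total >= self.min_child_share]
        kept.sort(key=lambda ca: (-ca[1], ca[0]))
        return [c for c, _ in kept]

    @property
    def divided(self) -> bool:
        return len(self.strong_children) >= 2


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([ys.mean(), xs.mean()])


def _rotate_shift_overlap(mask0, mask1, c0, c1, angle_deg) -> int:
    """Overlap with mask1 of mask0 transformed by rotation ``angle_deg``
    (in the package's (x, y) transform convention) about c0, then shifted
    c0 -> c1.  A content rotation of +angle in (x, y) equals
    ``ndi.rotate(-angle)`` in array coordinates.  mask0 is expected to be
    pre-scaled (growth compensation) with c0 its scaled centroid."""
    a_ndi = -angle_deg
    rot = ndi.rotate(
        mask0.astype(np.uint8), a_ndi, reshape=False, order=0,
        mode="constant", cval=0,
    )
    # ndi.rotate pivots about the array centre; move the rotated c0 onto c1
    centre = (np.array(mask0.shape) - 1) / 2.0
    a = np.deg2rad(a_ndi)
    rmat = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    c0_rot = rmat @ (c0 - centre) + centre
    shift = c1 - c0_rot
    shifted = ndi.shift(rot, shift, order=0, mode="constant", cval=0)
    return int(np.sum(shifted.astype(bool) & mask1))


def register(
    lm0: LabelMap,
    lm1: LabelMap,
    max_rotation: float = 30.0,
    coarse_step: float = 1.0,
    fine_step: float = 0.1,
    min_overlap_frac: float = 0.5,
    compensate_growth: bool = True,
) -> RigidTransform:
    """Registration of two tissue masks (deterministic grid search).

    With ``compensate_growth`` the isotropic growth between sessions is
    first estimated as sqrt(area1 / area0) of the tissue masks and divided
    out, so only rotation and translation are searched: centroids are
    aligned, then rotation is scanned in [-max_rotation, max_rotation] at
    ``coarse_step`` resolution and refined at ``fine_step`` around the best
    coarse angle.  Raises :class:`RegistrationError` if the best overlap
    covers less than ``min_overlap_frac`` of the smaller tissue mask.
    """
    if lm0.pixel_size != lm1.pixel_size:
        raise ValueError("label maps disagree on pixel size")
    mask0 = lm0.foreground()
    mask1 = lm1.foreground()
    if not mask0.any() or not mask1.any():
        raise RegistrationError("empty label map")
    if mask0.shape != mask1.shape:
        # pad to a common canvas (top-left anchored)
        shape = (
            max(mask0.shape[0], mask1.shape[0]),
            max(mask0.shape[1], mask1.shape[1]),
        )
        m0 = np.zeros(shape, bool)
        m0[: mask0.shape[0], : mask0.shape[1]] = mask0
        m1 = np.zeros(shape, bool)
        m1[: mask1.shape[0], : mask1.shape[1]] = mask1
        mask0, mask1 = m0, m1
    c0_orig = _mask_centroid(mask0)
    scale = 1.0
    if compensate_growth:
        scale = float(np.sqrt(mask1.sum() / mask0.sum()))
        zoomed = ndi.zoom(mask0.astype(np.uint8), scale, order=0)
        m0 = np.zeros(
            (max(zoomed.shape[0], mask1.shape[0]),
             max(zoomed.shape[1], mask1.shape[1])),
            bool,
        )
        m0[: zoomed.shape[0], : zoomed.shape[1]] = zoomed.astype(bool)
        if m0.shape != mask1.shape:
            m1 = np.zeros(m0.shape, bool)
            m1[: mask1.shape[0], : mask1.shape[1]] = mask1
            mask1 = m1
        mask0 = m0
    c0 = _mask_centroid(mask0)
    c1 = _mask_centroid(mask1)

    def best_in(angles):
        scored = [
            (_rotate_shift_overlap(mask0, mask1, c0, c1, a), -abs(a), a)
            for a in angles
        ]
        return max(scored)  # ties: smaller |angle|

    coarse = np.arange(-max_rotation, max_rotation + 1e-9, coarse_step)
    ov, _, a_best = best_in(coarse)
    fine = np.arange(
        a_best - coarse_step + fine_step, a_best + coarse_step, fine_step
    )
    ov_f, _, a_fine = best_in(fine)
    if ov_f >= ov:
        a_best, ov = a_fine, ov_f

    smaller = min(mask0.sum(), mask1.sum())
    if ov < min_overlap_frac * smaller:
        raise RegistrationError(
            f"best overlap {ov} px is below {min_overlap_frac:.0%} of the "
            f"smaller tissue mask ({smaller} px)"
        )
    ps = lm0.pixel_size
    # pixel-space (row, col) -> physical (x, y): swap and scale.  The
    # transform pivots about the unscaled t0 centroid: p1 = s R (p0 - c) + c
    # + t with t chosen so the scaled-rotated centroid lands on c1.
    c0_xy = np.array([c0_orig[1], c0_orig[0]]) * ps
    c1_xy = np.array([c1[1], c1[0]]) * ps
    return RigidTransform(
        rotation_deg=a_best,
        translation=tuple(c1_xy - c0_xy),
        center=tuple(c0_xy),
        scale=scale,
    )


def warp_labels(lm0: LabelMap, tf: RigidTransform, out_shape=None) -> np.ndarray:
    """Resample lm0 onto the t1 pixel grid under ``tf`` (nearest neighbour)."""
    ps = lm0.pixel_size
    shape = out_shape if out_shape is not None else lm0.shape
    # inverse map: for each t1 pixel find the t0 pixel
    inv_mat = np.linalg.inv(tf.matrix())
    c = np.array(tf.center) / ps  # in px (x, y)
    t = np.array(tf.translation) / ps
    rows, cols = np.indices(shape)
    xy1 = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
    xy0 = (xy1 - c - t) @ inv_mat.T + c
    r0 = np.rint(xy0[:, 1]).astype(int)
    c0 = np.rint(xy0[:, 0]).astype(int)
    ok = (
        (r0 >= 0)
        & (r0 < lm0.shape[0])
        & (c0 >= 0)
        & (c0 < lm0.shape[1])
    )
    out = np.zeros(shape, dtype=lm0.labels.dtype)
    out.ravel()[ok.nonzero()[0]] = lm0.labels[r0[ok], c0[ok]]
    return out


def _label_boundaries(labels: np.ndarray) -> np.ndarray:
    b = np.zeros(labels.shape, dtype=bool)
    for axis in (0, 1):
        b |= labels != np.roll(labels, 1, axis=axis)
    return b


def _refine_pass(
    warped0: np.ndarray, labels1: np.ndarray, blocks: int, max_shift_px: float
) -> np.ndarray:
    """One block-wise displacement correction (phase correlation on the
    label-boundary images; sparse shifts interpolated bilinearly; nearest-
    neighbour label resampling).  Tiles with little structure, or whose
    estimated shift exceeds ``max_shift_px`` (likely a wall-grid aliasing
    artifact), keep zero shift."""
    from scipy.interpolate import RegularGridInterpolator
    from skimage.registration import phase_cross_correlation

    h, w = warped0.shape
    e0 = _label_boundaries(warped0)
    e1 = _label_boundaries(labels1)
    rows = np.linspace(0, h, blocks + 1).astype(int)
    cols = np.linspace(0, w, blocks + 1).astype(int)
    centres_r = (rows[:-1] + rows[1:]) / 2.0
    centres_c = (cols[:-1] + cols[1:]) / 2.0
    field = np.zeros((blocks, blocks, 2))
    for i in range(blocks):
        for j in range(blocks):
            a = e0[rows[i]:rows[i + 1], cols[j]:cols[j + 1]]
            b = e1[rows[i]:rows[i + 1], cols[j]:cols[j + 1]]
            if a.sum() < 50 or b.sum() < 50:
                continue
            shift, _, _ = phase_cross_correlation(
                b.astype(float), a.astype(float)
            )
            if np.abs(shift).max() <= max_shift_px:
                field[i, j] = shift
    interp = RegularGridInterpolator(
        (centres_r, centres_c), field, bounds_error=False, fill_value=None,
        method="linear",
    )
    rr, cc = np.indices((h, w))
    shifts = interp(np.stack([rr.ravel(), cc.ravel()], axis=1))
    src_r = np.rint(rr.ravel() - shifts[:, 0]).astype(int)
    src_c = np.rint(cc.ravel() - shifts[:, 1]).astype(int)
    ok = (src_r >= 0) & (src_r < h) & (src_c >= 0) & (src_c < w)
    out = np.zeros_like(warped0)
    out.ravel()[np.flatnonzero(ok)] = warped0[src_r[ok], src_c[ok]]
    return out


def _local_refine(warped0: np.ndarray, labels1: np.ndarray) -> np.ndarray:
    """Correct residual differential-growth displacement coarse-to-fine.

    Tissue growth is not perfectly isotropic (the meristem region barely
    expands while mature regions do), so after the global alignment local
    residuals of up to a cell diameter remain.  Three passes of block-wise
    phase correlation with decreasing tile size remove them; the shift cap
    scales with the tile so a fine tile cannot lock onto the wrong wall of
    the quasi-periodic wall grid.
    """
    h, w = warped0.shape
    for blocks in (2, 4, 8):
        cap = 0.25 * min(h, w) / blocks
        warped0 = _refine_pass(warped0, labels1, blocks, max(cap, 4.0))
    return warped0


def match_lineage(
    lm0: LabelMap,
    lm1: LabelMap,
    tf: RigidTransform,
    meta: WindowMeta,
    strong_overlap: float = 0.5,
    min_overlap: float = 0.25,
    min_child_share: float = 0.1,
    refine_local: bool = True,
) -> tuple[list[LineageLink], list[int]]:
    """Assign every t1 cell to its best-overlapping t0 cell.

    Returns ``(links, unmatched)``: links grouped per parent (sorted by
    parent id; children sorted by id) and the list of t1 labels whose best
    overlap fraction is below ``min_overlap`` (new or edge cells).  A parent
    divided when >= 2 of its children have overlap fraction >=
    ``strong_overlap`` and each holds at least ``min_child_share`` of the
    strong children's combined area (guards against sub-resolution
    fragments masquerading as daughters).
    """
    meta.validate()
    warped0 = warp_labels(lm0, tf, out_shape=lm1.shape)
    if refine_local:
        warped0 = _local_refine(warped0, lm1.labels)
    n0 = int(warped0.max()) + 1
    n1 = int(lm1.labels.max()) + 1
    idx = warped0.astype(np.int64) * n1 + lm1.labels.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=n0 * n1).reshape(n0, n1)
    child_area = counts.sum(axis=0)

    by_parent: dict[int, list[tuple[int, float]]] = {}
    unmatched: list[int] = []
    for child in range(1, n1):
        if child_area[child] == 0:
            continue
        overlaps = counts[1:, child]
        best = int(overlaps.max())
        frac = best / child_area[child]
        if frac < min_overlap:
            unmatched.append(child)
            continue
        parent = int(np.flatnonzero(overlaps == best)[0]) + 1  # tie: smallest id
        by_parent.setdefault(parent, []).append((child, frac))

    links = []
    for parent in sorted(by_parent):
        kids = sorted(by_parent[parent])
        links.append(
            LineageLink(
                parent_id=parent,
                child_ids=[k for k, _ in kids],
                overlap_fractions=[f for _, f in kids],
                child_areas=[float(child_area[k]) for k, _ in kids],
                strong_overlap=strong_overlap,
                min_child_share=min_child_share,
            )
        )
    return links, unmatched


def divided_map(
    links: list[LineageLink], lm0: LabelMap
) -> tuple[dict[int, bool], np.ndarray, dict]:
    """Per-t0-cell divided flags plus the red/green overlay.

    Cells that divided in the window are painted red, cells that did not
    divide green; returns (flags, RGB image, counts).
    """
    flags = {int(l): False for l in lm0.label_ids()}
    for link in links:
        if link.parent_id in flags:
            flags[link.parent_id] = link.divided
    rgb = np.zeros(lm0.shape + (3,), dtype=float)
    red = (0.85, 0.1, 0.1)
    green = (0.1, 0.65, 0.1)
    for lab, divided in flags.items():
        rgb[lm0.labels == lab] = red if divided else green
    counts = {
        "divided": int(sum(flags.values())),
        "not_divided": int(len(flags) - sum(flags.values())),
    }
    return flags, rgb, counts


def compose_descendants(
    link_chain: list[list[LineageLink]],
) -> dict[int, set[int]]:
    """Descendant sets of first-window parents across consecutive windows.

    A multi-day series is always decomposed into consecutive windows and
    composed here, never matched end-to-end directly.
    """
    if not link_chain:
        return {}
    current = {
        link.parent_id: set(link.child_ids) for link in link_chain[0]
    }
    for links in link_chain[1:]:
        nxt = {link.parent_id: set(link.child_ids) for link in links}
        for root, kids in current.items():
            current[root] = set().union(
                *(nxt.get(k, {k}) for k in kids)
            ) if kids else set()
    return current
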