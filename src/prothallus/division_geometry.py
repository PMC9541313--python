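"""Layer assignment, division-orientation calls, packets and trichomes.

The tissue margin (boundary of the non-trichome tissue) is the reference
curve for everything here: marginal cells touch it, submarginal cells touch
marginal cells, and a division's orientation is the acute angle between its
new wall and the local margin tangent — above 60 degrees anticlinal, below
30 degrees periclinal, oblique in between (configurable bands, symmetric
about 45 degrees).  Three-celled packets are two adjacent rectangular
marginal cells over one rectangular submarginal cell; their four division
types are I (upper anticlinal), II (upper periclinal), III (lower
anticlinal) and IV (lower periclinal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as sg
from scipy import ndimage as ndi
from skimage import measure

from .images import LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "MarginPolyline",
    "DivisionEvent",
    "Packet",
    "PacketDivisionRecord",
    "extract_margin",
    "assign_layers",
    "classify_orientation",
    "division_wall",
    "detect_packets",
    "classify_packet_division",
    "flag_trichomes",
    "layer_update_exclusions",
]

ORIENT_ANTICLINAL = "anticlinal"
ORIENT_PERICLINAL = "periclinal"
ORIENT_OBLIQUE = "oblique"
ORIENT_UNASSIGNED = "unassigned"


@dataclass
class MarginPolyline:
    """Closed tissue-margin polyline with smoothed per-vertex unit tangents."""

    points: np.ndarray  # (n, 2) (x, y) um, closed ring (no repeated endpoint)
    tangents: np.ndarray  # (n, 2) unit tangents

    @classmethod
    def from_ring(cls, points: np.ndarray, smooth: int = 5) -> "MarginPolyline":
        pts = np.asarray(points, dtype=float)
        n = len(pts)
        k = max(1, min(smooth // 2, (n - 1) // 2))
        tangents = np.empty_like(pts)
        for i in range(n):
            d = pts[(i + k) % n] - pts[(i - k) % n]
            nd = np.linalg.norm(d)
            if nd < 1e-12:
                d = pts[(i + 1) % n] - pts[i - 1]
                nd = np.linalg.norm(d) or 1.0
            tangents[i] = d / nd
        return cls(points=pts, tangents=tangents)

    def nearest_index(self, xy) -> int:
        return int(np.argmin(np.linalg.norm(self.points - np.asarray(xy), axis=1)))

    def tangent_at(self, xy) -> np.ndarray:
        return self.tangents[self.nearest_index(xy)]


@dataclass
class DivisionEvent:
    """A detected division with its classified wall orientation."""

    parent_id: int
    daughter_ids: tuple[int, ...]
    new_wall: np.ndarray | None  # (m, 2) wall pixel coordinates (um)
    orientation: str = ORIENT_UNASSIGNED
    wall_margin_angle: float = float("nan")
    layer_of_parent: str = "unassigned"
    window: object = None
    qc_flags: list = field(default_factory=list)


@dataclass(frozen=True)
class Packet:
    """Three-celled packet: two adjacent upper (marginal) cells, one lower."""

    upper_a_id: int
    upper_b_id: int
    lower_id: int
    detected_at: float | None = None

    @property
    def member_ids(self) -> tuple[int, int, int]:
        return (self.upper_a_id, self.upper_b_id, self.lower_id)


@dataclass
class PacketDivisionRecord:
    """Division types observed in one packet over one window.

    ``division_types`` is a multiset (sorted tuple) because the two upper
    cells can contribute the same type twice, e.g. ('II', 'II', 'III') for
    the cluster-of-six pattern.
    """

    packet: Packet
    division_types: tuple  # sorted tuple drawn from {'I','II','III','IV'}
    is_complex: bool = False  # some member divided more than once

    @property
    def status(self) -> str:
        if self.is_complex:
            return "complex"
        return "none" if not self.division_types else "typed"


# ---------------------------------------------------------------------------


def _resample_ring(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed ring at even arc-length ``spacing`` (um)."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(8, int(round(total / spacing)))
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, arc, closed[:, 0])
    y = np.interp(targets, arc, closed[:, 1])
    return np.column_stack([x, y])


def extract_margin(
    lm: LabelMap,
    trichome_flags: dict[int, bool] | None = None,
    smooth: int = 11,
    spacing_um: float = 1.0,
) -> MarginPolyline:
    """Margin of the union of non-trichome cells.

    The pixel contour is resampled at ``spacing_um`` so the smoothed
    tangent (over ``smooth`` vertices) averages a physical scale rather than
    a pixel count.  If exclusion of trichomes disconnects the tissue, the
    largest component's margin is returned and a warning is logged.
    """
    trichome_flags = trichome_flags or {}
    keep = lm.labels > 0
    for lab, is_tri in trichome_flags.items():
        if is_tri:
            keep &= lm.labels != lab
    if not keep.any():
        raise ValueError("no non-trichome tissue in label map")
    comp, nc = ndi.label(keep)
    if nc > 1:
        logger.warning("tissue disconnected into %d components; using largest", nc)
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        keep = comp == int(np.argmax(sizes))
    contours = measure.find_contours(np.pad(keep, 1).astype(float), 0.5)
    ring = max(contours, key=len)[:-1] - 1  # drop duplicated endpoint, unpad
    ps = lm.pixel_size
    pts = np.column_stack([ring[:, 1] * ps, ring[:, 0] * ps])
    pts = _resample_ring(pts, spacing_um)
    return MarginPolyline.from_ring(pts, smooth=smooth)


def _adjacency(labels: np.ndarray) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for axis in (0, 1):
        a = labels[:-1, :] if axis == 0 else labels[:, :-1]
        b = labels[1:, :] if axis == 0 else labels[:, 1:]
        sel = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[sel].ravel(), b[sel].ravel()):
            adj.setdefault(int(u), set()).add(int(v))
            adj.setdefault(int(v), set()).add(int(u))
    return adj


def assign_layers(
    lm: LabelMap,
    margin: MarginPolyline | None = None,
    trichome_flags: dict[int, bool] | None = None,
    exclude_submarginal: set[int] | frozenset = frozenset(),
) -> dict[int, str]:
    """Marginal / submarginal / inner call for every cell.

    Marginal cells share boundary with the tissue margin; submarginal cells
    are the one layer in direct contact with marginal cells; the rest are
    inner.  Trichome-flagged cells are labelled 'trichome' and ignored when
    the margin is computed.  ``exclude_submarginal`` demotes listed labels to
    inner even if geometrically adjacent to a marginal cell — used for the
    between-window bookkeeping rule that a cell added inward by a
    *submarginal* cell's periclinal division does not count as submarginal
    in the following window (see :func:`layer_update_exclusions`).
    """
    trichome_flags = trichome_flags or {}
    tri = {lab for lab, f in trichome_flags.items() if f}
    keep = lm.labels > 0
    for lab in tri:
        keep &= lm.labels != lab
    rim = keep & ~ndi.binary_erosion(keep)
    marginal = {int(l) for l in np.unique(lm.labels[rim]) if l > 0 and l not in tri}
    adj = _adjacency(lm.labels)
    out: dict[int, str] = {}
    for lab in (int(l) for l in lm.label_ids()):
        if lab in tri:
            out[lab] = "trichome"
        elif lab in marginal:
            out[lab] = "marginal"
        elif any(n in marginal for n in adj.get(lab, ())) and lab not in exclude_submarginal:
            out[lab] = "submarginal"
        else:
            out[lab] = "inner"
    return out


def layer_update_exclusions(
    events: list[DivisionEvent],
    layers_before: dict[int, str],
    margin_after: MarginPolyline,
    daughter_centroids: dict[int, np.ndarray],
) -> set[int]:
    """Labels to demote from submarginal in the *next* window.

    For each periclinal division of a submarginal cell, the daughter lying
    farther from the margin (added inwards) is excluded from the submarginal
    layer in the following window.  Daughters added inward by *marginal*
    periclinal divisions become regular submarginal cells and need no special
    handling (the geometric rule already classifies them).
    """
    excluded: set[int] = set()
    for ev in events:
        if ev.orientation != ORIENT_PERICLINAL:
            continue
        if layers_before.get(ev.parent_id) != "submarginal":
            continue
        dists = {}
        for d in ev.daughter_ids:
            if d not in daughter_centroids:
                continue
            c = daughter_centroids[d]
            i = margin_after.nearest_index(c)
            dists[d] = float(np.linalg.norm(margin_after.points[i] - c))
        if dists:
            excluded.add(max(dists, key=lambda d: (dists[d], d)))
    return excluded


def division_wall(lm1: LabelMap, daughter_ids) -> np.ndarray | None:
    """Pixel midpoints (um) of the interface between two sibling labels."""
    if len(daughter_ids) < 2:
        return None
    ps = lm1.pixel_size
    pts = []
    d1, d2 = daughter_ids[0], daughter_ids[1]
    m1 = lm1.labels == d1
    m2 = lm1.labels == d2
    grown = ndi.binary_dilation(m1, iterations=2)
    sel = grown & m2
    rows, cols = np.nonzero(sel)
    if rows.size == 0:
        return None
    pts = np.column_stack([cols * ps, rows * ps])
    return pts


def classify_orientation(
    event: DivisionEvent,
    margin: MarginPolyline,
    parent_centroid,
    anticlinal_min_deg: float = 60.0,
    periclinal_max_deg: float = 30.0,
) -> DivisionEvent:
    """Set the event's orientation from its wall/margin angle.

    The wall's principal direction (PCA of its pixels) is compared with the
    margin tangent at the margin vertex nearest the parent centroid; the
    acute angle decides the call.  Degenerate walls (< 2 px) keep orientation
    'unassigned' with a QC flag.
    """
    wall = event.new_wall
    if wall is None or len(wall) < 2:
        event.orientation = ORIENT_UNASSIGNED
        event.qc_flags.append("degenerate_wall")
        return event
    centred = wall - wall.mean(axis=0)
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)
    wall_dir = evecs[:, int(np.argmax(evals))]
    tangent = margin.tangent_at(parent_centroid)
    cosang = abs(float(np.dot(wall_dir, tangent)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    event.wall_margin_angle = angle
    if angle > anticlinal_min_deg:
        event.orientation = ORIENT_ANTICLINAL
    elif angle < periclinal_max_deg:
        event.orientation = ORIENT_PERICLINAL
    else:
        event.orientation = ORIENT_OBLIQUE
    return event


def _rectangularity(region_mask: np.ndarray) -> tuple[float, float]:
    """(solidity, min-area-rectangle fill) of a binary region."""
    contour = max(
        measure.find_contours(np.pad(region_mask, 1).astype(float), 0.5), key=len
    )
    poly = sg.Polygon(contour[:, ::-1])
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        return 0.0, 0.0
    solidity = poly.area / poly.convex_hull.area
    mrr = poly.minimum_rotated_rectangle
    rect_fill = poly.area / mrr.area if mrr.area > 0 else 0.0
    return float(solidity), float(rect_fill)


def detect_packets(
    lm: LabelMap,
    layers: dict[int, str],
    time_h: float | None = None,
    solidity_min: float = 0.9,
    rect_fill_min: float = 0.8,
) -> list[Packet]:
    """Enumerate disjoint three-celled packets.

    Candidates are (two adjacent marginal cells, one submarginal cell
    adjacent to both), all three passing the rectangularity test (solidity
    and minimum-area-bounding-rectangle fill).  Overlapping candidates are
    resolved greedily by descending mean rectangularity; each cell joins at
    most one packet.
    """
    adj = _adjacency(lm.labels)
    rect: dict[int, tuple[float, float]] = {}

    def rectangularity(lab: int) -> tuple[float, float]:
        if lab not in rect:
            rect[lab] = _rectangularity(lm.labels == lab)
        return rect[lab]

    def passes(lab: int) -> bool:
        s, r = rectangularity(lab)
        return s >= solidity_min and r >= rect_fill_min

    marginal = sorted(l for l, lay in layers.items() if lay == "marginal")
    submarg = {l for l, lay in layers.items() if lay == "submarginal"}
    candidates = []
    for ua in marginal:
        for ub in sorted(adj.get(ua, ())):
            if ub <= ua or layers.get(ub) != "marginal":
                continue
            commons = adj.get(ua, set()) & adj.get(ub, set()) & submarg
            for low in sorted(commons):
                if not (passes(ua) and passes(ub) and passes(low)):
                    continue
                score = np.mean(
                    [np.mean(rectangularity(l)) for l in (ua, ub, low)]
                )
                candidates.append((float(score), ua, ub, low))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used: set[int] = set()
    packets = []
    for _, ua, ub, low in candidates:
        if used & {ua, ub, low}:
            continue
        used |= {ua, ub, low}
        packets.append(Packet(ua, ub, low, detected_at=time_h))
    return packets


def classify_packet_division(
    packet: Packet, events: list[DivisionEvent], meta=None
) -> PacketDivisionRecord:
    """Type the divisions seen in one packet during one window.

    Any member cell dividing more than once makes the record complex
    (excluded from the type statistics); otherwise each member division
    contributes I/II (upper anticlinal/periclinal) or III/IV (lower
    anticlinal/periclinal).  Oblique or unassigned orientations contribute
    no type.
    """
    members = set(packet.member_ids)
    per_member: dict[int, int] = {m: 0 for m in members}
    types: list[str] = []
    for ev in events:
        if ev.parent_id not in members:
            continue
        per_member[ev.parent_id] += 1
        upper = ev.parent_id in (packet.upper_a_id, packet.upper_b_id)
        if ev.orientation == ORIENT_ANTICLINAL:
            types.append("I" if upper else "III")
        elif ev.orientation == ORIENT_PERICLINAL:
            types.append("II" if upper else "IV")
    is_complex = any(n >= 2 for n in per_member.values())
    return PacketDivisionRecord(
        packet=packet,
        division_types=tuple(sorted(types)) if not is_complex else (),
        is_complex=is_complex,
    )


def flag_trichomes(
    lm: LabelMap,
    truth_flags: dict[int, bool] | None = None,
    frac_outside_min: float = 0.6,
    aspect_min: float = 3.0,
) -> dict[int, bool]:
    """Trichome flag per cell.

    In truth mode (``truth_flags`` given) flags pass through.  Otherwise a
    cell is flagged when >= ``frac_outside_min`` of its area lies outside
    the convex hull of the remaining tissue, or its aspect ratio is at least
    ``aspect_min`` with the long axis along the outward normal.
    """
    labels = lm.labels
    ids = [int(l) for l in lm.label_ids()]
    if truth_flags is not None:
        return {l: bool(truth_flags.get(l, False)) for l in ids}
    fg = labels > 0
    centroid_all = np.array(ndi.center_of_mass(fg))
    out: dict[int, bool] = {}
    props = {p.label: p for p in measure.regionprops(labels)}
    for lab in ids:
        region = labels == lab
        others = fg & ~region
        if not others.any():
            out[lab] = False
            continue
        hull = _convex_hull_mask(others)
        outside = region & ~hull
        frac_outside = outside.sum() / region.sum()
        if frac_outside >= frac_outside_min:
            out[lab] = True
            continue
        p = props[lab]
        minor = p.axis_minor_length or 1.0
        aspect = p.axis_major_length / minor
        if aspect >= aspect_min:
            c = np.array(p.centroid)
            outward = c - centroid_all
            nrm = np.linalg.norm(outward)
            if nrm > 0:
                outward /= nrm
                # regionprops orientation: angle of major axis vs row axis
                ang = p.orientation
                major = np.array([np.cos(ang), -np.sin(ang)])  # (row, col)
                if abs(float(np.dot(major, outward))) >= 0.7:
                    out[lab] = True
                    continue
        out[lab] = False
    return out


def _convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    from skimage.morphology import convex_hull_image

    return convex_hull_image(mask)
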