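"""End-to-end analysis of time-lapse windows.

``analyze_window`` performs one full tracking window: register the two label
maps, match cells, detect divisions, extract the margin, assign layers,
classify each division's orientation, and collect everything the statistics
layer needs.  ``analyze_series`` chains consecutive windows, carrying the
between-window submarginal bookkeeping rule.  ``run_synthetic_window`` wires
a simulated series through rendering and segmentation so every stage can be
scored against the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .division_geometry import (
    DivisionEvent,
    MarginPolyline,
    assign_layers,
    classify_orientation,
    division_wall,
    extract_margin,
    flag_trichomes,
    layer_update_exclusions,
)
from .evaluation import match_labels
from .images import LabelMap
from .lineage import LineageLink, WindowMeta, match_lineage, register
from .render import RenderParams, render_series
from .segmentation import SegConfig, preprocess, segment
from .simulate import TruthSeries

__all__ = [
    "WindowAnalysis",
    "analyze_window",
    "analyze_series",
    "run_synthetic_window",
    "evaluate_window_against_truth",
    "evaluate_series_against_truth",
]


@dataclass
class WindowAnalysis:
    """Everything measured in one tracking window."""

    meta: WindowMeta
    links: list[LineageLink]
    unmatched: list[int]
    events: list[DivisionEvent]
    layers0: dict[int, str]
    trichomes0: dict[int, bool]
    margin0: MarginPolyline
    areas0: dict[int, float]  # um^2 at window start
    divided0: dict[int, bool]
    layer_counts: dict[str, int]
    centroids0: dict[int, np.ndarray] = field(default_factory=dict)
    lm0: LabelMap | None = None
    lm1: LabelMap | None = None

    def restricted_stats_set(self, keep) -> dict:
        """Per-set record limited to an analysis region.

        ``keep(label)`` selects which start-frame cells are analyzed, as in
        time-lapse studies that quantify a marked region of the tissue
        rather than the whole sheet; counts and events are filtered
        consistently.
        """
        events = [e for e in self.events if keep(e.parent_id)]
        counts = {
            layer: sum(
                1
                for lab, lay in self.layers0.items()
                if lay == layer and not self.trichomes0.get(lab, False)
                and keep(lab)
            )
            for layer in ("marginal", "submarginal", "inner")
        }
        return {
            "events": events,
            "layer_counts": counts,
            "timeframe_h": self.meta.timeframe_h,
        }

    def stats_set(self) -> dict:
        """The per-set record consumed by :func:`prothallus.quantify.layer_rates`."""
        return {
            "events": self.events,
            "layer_counts": self.layer_counts,
            "timeframe_h": self.meta.timeframe_h,
        }


def _centroids(lm: LabelMap) -> dict[int, np.ndarray]:
    ps = lm.pixel_size
    return {
        int(p.label): np.array([p.centroid[1] * ps, p.centroid[0] * ps])
        for p in measure.regionprops(lm.labels)
    }


def _wall_mask_of(wallprob, tophat_radius: int = 5) -> np.ndarray:
    """Wall-ridge mask of a preprocessed image (same detector as segmentation)."""
    from skimage import morphology
    from skimage.filters import threshold_otsu

    from scipy import ndimage as ndi

    x = wallprob.intensities
    tophat = morphology.white_tophat(x, footprint=morphology.disk(tophat_radius))
    vals = tophat[x > 0]
    thr = threshold_otsu(vals) if vals.size and vals.max() > vals.min() else np.inf
    # dilate by 1 px so a candidate interface within warp error of an old
    # wall still registers as pre-existing
    return ndi.binary_dilation(tophat > thr)


def analyze_window(
    lm0: LabelMap,
    lm1: LabelMap,
    meta: WindowMeta,
    trichome_truth0: dict[int, bool] | None = None,
    exclude_submarginal: set[int] | frozenset = frozenset(),
    orientation_bands: tuple[float, float] = (30.0, 60.0),
    wallprob0=None,
) -> WindowAnalysis:
    """Track one window and classify its divisions.

    ``trichome_truth0`` supplies ground-truth trichome flags for the start
    label map (synthetic mode); otherwise the geometric trichome rule is
    used.  Wall coordinates are measured on the end frame and mapped back to
    start-frame coordinates before comparison with the start margin.

    If the preprocessed start image ``wallprob0`` is supplied, candidate
    divisions whose interface already shows a wall at the window start are
    rejected: a genuinely new wall cannot pre-date the window, so such
    candidates are segmentation merges (or older divisions), not events of
    this window.
    """
    tf = register(lm0, lm1)
    links, unmatched = match_lineage(lm0, lm1, tf, meta)
    wall0 = _wall_mask_of(wallprob0) if wallprob0 is not None else None
    trich0 = flag_trichomes(lm0, truth_flags=trichome_truth0)
    margin0 = extract_margin(lm0, trich0)
    layers0 = assign_layers(
        lm0, margin0, trich0, exclude_submarginal=exclude_submarginal
    )
    cent0 = _centroids(lm0)
    areas0 = {
        int(p.label): float(p.area) * lm0.pixel_size**2
        for p in measure.regionprops(lm0.labels)
    }
    inv = tf.inverse()
    per_max, per_min = orientation_bands[0], orientation_bands[1]
    events: list[DivisionEvent] = []
    divided0 = {int(l): False for l in lm0.label_ids()}
    for link in links:
        if not link.divided:
            continue
        strong = link.strong_children
        wall1 = division_wall(lm1, strong[:2])
        wall_t0 = inv.apply(wall1) if wall1 is not None else None
        if wall0 is not None and wall_t0 is not None:
            cols = np.rint(wall_t0[:, 0] / lm0.pixel_size).astype(int)
            rows = np.rint(wall_t0[:, 1] / lm0.pixel_size).astype(int)
            ok = (
                (rows >= 0) & (rows < lm0.shape[0])
                & (cols >= 0) & (cols < lm0.shape[1])
            )
            if ok.any() and wall0[rows[ok], cols[ok]].mean() > 0.5:
                continue  # wall already present at t0: not a new division
        divided0[link.parent_id] = True
        ev = DivisionEvent(
            parent_id=link.parent_id,
            daughter_ids=tuple(strong),
            new_wall=wall_t0,
            layer_of_parent=layers0.get(link.parent_id, "unassigned"),
            window=meta,
        )
        # reference the margin at the wall itself when available: more local
        # than the parent centroid for large or irregular parents
        ref_point = (
            wall_t0.mean(axis=0) if wall_t0 is not None
            else cent0[link.parent_id]
        )
        classify_orientation(
            ev,
            margin0,
            ref_point,
            anticlinal_min_deg=per_min,
            periclinal_max_deg=per_max,
        )
        events.append(ev)
    layer_counts = {
        layer: sum(
            1
            for lab, lay in layers0.items()
            if lay == layer and not trich0.get(lab, False)
        )
        for layer in ("marginal", "submarginal", "inner")
    }
    return WindowAnalysis(
        meta=meta,
        links=links,
        unmatched=unmatched,
        events=events,
        layers0=layers0,
        trichomes0=trich0,
        margin0=margin0,
        areas0=areas0,
        divided0=divided0,
        layer_counts=layer_counts,
        centroids0=cent0,
        lm0=lm0,
        lm1=lm1,
    )


def analyze_series(
    lms: list[LabelMap],
    metas: list[WindowMeta],
    trichome_truth: list[dict[int, bool] | None] | None = None,
    orientation_bands: tuple[float, float] = (30.0, 60.0),
) -> list[WindowAnalysis]:
    """Analyze consecutive windows of one sample.

    Applies the between-window rule: a daughter added inward by a
    submarginal cell's periclinal division is excluded from the submarginal
    layer in the following window.
    """
    if len(lms) != len(metas) + 1:
        raise ValueError("need one label map per time point (windows + 1)")
    out: list[WindowAnalysis] = []
    exclusions: set[int] = set()
    for w, meta in enumerate(metas):
        truth0 = trichome_truth[w] if trichome_truth else None
        wa = analyze_window(
            lms[w],
            lms[w + 1],
            meta,
            trichome_truth0=truth0,
            exclude_submarginal=frozenset(exclusions),
            orientation_bands=orientation_bands,
        )
        out.append(wa)
        # prepare next window's exclusions, expressed in t(w+1) labels
        truth1 = trichome_truth[w + 1] if trichome_truth and w + 1 < len(
            trichome_truth
        ) else None
        trich1 = flag_trichomes(lms[w + 1], truth_flags=truth1)
        margin1 = extract_margin(lms[w + 1], trich1)
        cent1 = _centroids(lms[w + 1])
        exclusions = layer_update_exclusions(
            wa.events, wa.layers0, margin1, cent1
        )
    return out


# ---------------------------------------------------------------------------
# synthetic-data wiring
# ---------------------------------------------------------------------------


def run_synthetic_window(
    series: TruthSeries,
    window: int,
    rp: RenderParams | None = None,
    cfg: SegConfig | None = None,
    use_truth_trichomes: bool = True,
):
    """Render, segment and analyze one simulated window.

    Returns ``(analysis, seg_maps, truth_maps, label_maps_to_cells)`` where
    the last item maps each segmented start/end label map onto simulator
    cell ids via IoU matching against the rendered truth label maps.
    """
    rp = rp or RenderParams()
    cfg = cfg or SegConfig()
    rendered = render_series(series, rp)
    img0, tl0, l2c0 = rendered[window]
    img1, tl1, l2c1 = rendered[window + 1]
    wp0 = preprocess(img0, cfg)
    seg0 = segment(wp0, cfg)
    seg1 = segment(preprocess(img1, cfg), cfg)
    m0 = match_labels(seg0, tl0, min_iou=0.5)
    m1 = match_labels(seg1, tl1, min_iou=0.5)
    seg_to_cell0 = {s: l2c0[t] for s, (t, _) in m0.items()}
    seg_to_cell1 = {s: l2c1[t] for s, (t, _) in m1.items()}
    trich_truth0 = None
    if use_truth_trichomes:
        cells0 = {c.id: c for c in series.snapshot_cells(window)}
        trich_truth0 = {
            s: cells0[cid].is_trichome
            for s, cid in seg_to_cell0.items()
            if cid in cells0
        }
    t0, t1 = series.snapshots[window][0], series.snapshots[window + 1][0]
    wa = analyze_window(
        seg0, seg1, WindowMeta(t0, t1), trichome_truth0=trich_truth0,
        wallprob0=wp0,
    )
    return wa, (seg0, seg1), (tl0, tl1), (seg_to_cell0, seg_to_cell1)


def run_synthetic_series(
    series: TruthSeries,
    rp: RenderParams | None = None,
    cfg: SegConfig | None = None,
    use_truth_trichomes: bool = True,
):
    """Render a simulated series once and analyze every window.

    Returns a list of ``(analysis, seg_to_cell0, seg_to_cell1)`` tuples, one
    per 48-h window.
    """
    rp = rp or RenderParams()
    cfg = cfg or SegConfig()
    rendered = render_series(series, rp)
    segs, wps, maps = [], [], []
    for img, tl, l2c in rendered:
        wp = preprocess(img, cfg)
        seg = segment(wp, cfg)
        m = match_labels(seg, tl, min_iou=0.5)
        segs.append(seg)
        wps.append(wp)
        maps.append({s: l2c[t] for s, (t, _) in m.items()})
    out = []
    for w in range(len(rendered) - 1):
        trich_truth0 = None
        if use_truth_trichomes:
            cells0 = {c.id: c for c in series.snapshot_cells(w)}
            trich_truth0 = {
                s: cells0[cid].is_trichome
                for s, cid in maps[w].items()
                if cid in cells0
            }
        t0, t1 = series.snapshots[w][0], series.snapshots[w + 1][0]
        wa = analyze_window(
            segs[w], segs[w + 1], WindowMeta(t0, t1),
            trichome_truth0=trich_truth0, wallprob0=wps[w],
        )
        out.append((wa, maps[w], maps[w + 1]))
    return out


def evaluate_series_against_truth(
    series: TruthSeries,
    results: list,
    windows: list[int] | tuple[int, ...],
) -> dict:
    """Score division detection over a span of windows of one series.

    Detections are matched to the simulator's event log by parent cell id
    (unique per event, since a cell divides once).  A division whose fresh
    wall is not yet resolvable at its window's start is typically detected
    one window later, with the merged daughter region as the apparent
    parent; such late detections are matched to their truth event through
    the lineage (the apparent parent is one of the event's daughters).
    Late detections of events before the evaluated span are excluded from
    scoring rather than counted as false positives.
    """
    windows = list(windows)
    truth_events = {}
    for w in windows:
        for e in series.events_in_window(w):
            truth_events[e.parent_id] = e
    daughter_to_event = {
        d: e for e in series.events for d in e.daughter_ids
    }
    tp, fp, excluded = set(), [], 0
    orient_pairs = []
    for w, (wa, m0, _) in zip(windows, (results[w] for w in windows)):
        for ev in wa.events:
            cid = m0.get(ev.parent_id)
            if cid is None:
                fp.append((w, None))
                continue
            te = truth_events.get(cid)
            if te is not None and cid not in tp:
                tp.add(cid)
                orient_pairs.append((te.orientation, ev.orientation))
                continue
            late = daughter_to_event.get(cid)
            if late is not None and late.parent_id not in tp:
                if late.parent_id in truth_events:
                    tp.add(late.parent_id)
                    orient_pairs.append((late.orientation, ev.orientation))
                else:
                    excluded += 1  # late detection of a pre-span event
                continue
            fp.append((w, cid))
    fn = set(truth_events) - tp
    n_truth = len(truth_events)
    orient_ok = sum(1 for a, b in orient_pairs if a == b)
    return {
        "n_truth": n_truth,
        "tp": len(tp),
        "fp": len(fp),
        "fn": len(fn),
        "excluded_pre_span": excluded,
        "precision": len(tp) / max(len(tp) + len(fp), 1),
        "recall": len(tp) / max(n_truth, 1),
        "orientation_accuracy": orient_ok / max(len(orient_pairs), 1),
    }


def evaluate_window_against_truth(
    series: TruthSeries,
    window: int,
    wa: WindowAnalysis,
    seg_to_cell0: dict[int, int],
) -> dict:
    """Division-detection precision/recall and orientation accuracy.

    Detected division parents (as simulator cell ids via the segmentation
    match) are compared with the simulator's event log for the window;
    orientation accuracy is computed over the correctly detected events.
    """
    truth_events = {
        e.parent_id: e for e in series.events_in_window(window)
    }
    detected: dict[int, DivisionEvent] = {}
    for ev in wa.events:
        cid = seg_to_cell0.get(ev.parent_id)
        if cid is not None:
            detected[cid] = ev
    tp = set(detected) & set(truth_events)
    fp = set(detected) - set(truth_events)
    fn = set(truth_events) - set(detected)
    orient_ok = sum(
        1
        for cid in tp
        if detected[cid].orientation == truth_events[cid].orientation
    )
    return {
        "n_truth": len(truth_events),
        "n_detected": len(detected),
        "tp": len(tp),
        "fp": len(fp),
        "fn": len(fn),
        "precision": len(tp) / len(detected) if detected else float("nan"),
        "recall": len(tp) / len(truth_events) if truth_events else float("nan"),
        "orientation_accuracy": orient_ok / len(tp) if tp else float("nan"),
    }
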