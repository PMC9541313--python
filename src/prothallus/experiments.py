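"""Predefined verification studies on synthetic gametophytes.

Each study simulates ground-truthed tissue, runs the full measurement
pipeline on rendered images, and scores the result against the simulator's
event log.  They are used by the validation suite and the reproduction
script; all randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .division_geometry import DivisionEvent, Packet, PacketDivisionRecord
from .evaluation import match_labels, segmentation_score
from .lineage import WindowMeta
from .pipeline import (
    analyze_window,
    evaluate_series_against_truth,
    run_synthetic_series,
)
from .quantify import (
    dividing_cell_fractions,
    layer_rates,
    packet_percentages,
    size_vs_division,
)
from .render import RenderParams, render
from .segmentation import preprocess, segment
from .simulate import SimParams, simulate

__all__ = [
    "segmentation_benchmark",
    "tracking_benchmark",
    "equation_oracle_benchmark",
    "rate_recovery_study",
    "size_division_study",
]


def _sheet_params(seed: int, n_windows: int = 3) -> SimParams:
    return SimParams(
        n_windows=n_windows, rng_seed=seed, initial_sheet=(4, 10, 22, 16)
    )


def segmentation_benchmark(seeds=range(1, 21), min_iou: float = 0.7) -> dict:
    """Segment rendered ~50-cell snapshots and match them one-to-one to the
    truth label maps at the given IoU, with and without noise."""
    totals = {"noisy": [0, 0], "noiseless": [0, 0]}
    for seed in seeds:
        series = simulate(_sheet_params(seed))
        cells = series.snapshot_cells(-1)
        for kind, rp in (
            ("noisy", RenderParams(rng_seed=seed)),
            ("noiseless", RenderParams(noise_sd=0.0, blur_sigma=0.0, rng_seed=seed)),
        ):
            img, truth, _ = render(cells, rp)
            score = segmentation_score(
                segment(preprocess(img)), truth, min_iou=min_iou
            )
            totals[kind][0] += score["n_matched"]
            totals[kind][1] += score["n_truth"]
    return {
        "match_rate_noisy": totals["noisy"][0] / totals["noisy"][1],
        "match_rate_noiseless": totals["noiseless"][0] / totals["noiseless"][1],
        "n_cells": totals["noisy"][1],
    }


def tracking_benchmark(seeds=range(1, 16), windows=(2, 3)) -> dict:
    """Detect divisions over simulated 48-h windows and score event
    detection and orientation calls against the simulator's log.

    Scoring is per series across its analyzed windows, so a division whose
    fresh wall only becomes resolvable one window later is matched to its
    event rather than double-counted as a false positive plus a miss.
    """
    agg = {"tp": 0, "fp": 0, "fn": 0, "orient_ok": 0, "orient_n": 0}
    n_windows = 0
    for seed in seeds:
        series = simulate(_sheet_params(seed, n_windows=max(windows) + 1))
        results = run_synthetic_series(series)
        res = evaluate_series_against_truth(series, results, windows)
        agg["tp"] += res["tp"]
        agg["fp"] += res["fp"]
        agg["fn"] += res["fn"]
        agg["orient_ok"] += res["orientation_accuracy"] * res["tp"]
        agg["orient_n"] += res["tp"]
        n_windows += len(windows)
    precision = agg["tp"] / max(agg["tp"] + agg["fp"], 1)
    recall = agg["tp"] / max(agg["tp"] + agg["fn"], 1)
    return {
        "precision": precision,
        "recall": recall,
        "orientation_accuracy": agg["orient_ok"] / max(agg["orient_n"], 1),
        "n_events": agg["tp"] + agg["fn"],
        "n_windows": n_windows,
    }


# ---------------------------------------------------------------------------
# equation oracle
# ---------------------------------------------------------------------------


def _brute_force_packet(records_by_set):
    """Independent recount of the packet-type equations."""
    means = {t: [] for t in ("I", "II", "III", "IV")}
    for sid in records_by_set:
        ok = [r for r in records_by_set[sid] if not r.is_complex]
        if not ok:
            continue
        for t in means:
            at_risk = 2.0 if t in ("I", "II") else 1.0
            vals = []
            for r in ok:
                n = sum(1 for x in r.division_types if x == t)
                vals.append(n / at_risk * 100.0)
            means[t].append(sum(vals) / len(vals))
    return {
        t: (sum(v) / len(v) if v else float("nan")) for t, v in means.items()
    }


def _brute_force_rates(sets):
    out = {}
    for sid, rec in sets.items():
        row = {}
        for layer in ("marginal", "submarginal"):
            n_cells = rec["layer_counts"].get(layer, 0)
            if n_cells <= 0:
                continue
            for orient in ("anticlinal", "periclinal"):
                n = 0
                for e in rec["events"]:
                    if e.layer_of_parent == layer and e.orientation == orient:
                        n += 1
                row[f"{layer}_{orient}"] = (
                    n / n_cells / rec["timeframe_h"] * 48.0 * 100.0
                )
        out[sid] = row
    return out


def _brute_force_fractions(sets):
    out = {}
    for sid, events in sets.items():
        row = {}
        for layer in ("marginal", "submarginal"):
            a = sum(1 for e in events
                    if e.layer_of_parent == layer and e.orientation == "anticlinal")
            p = sum(1 for e in events
                    if e.layer_of_parent == layer and e.orientation == "periclinal")
            if a + p:
                row[f"{layer}_anticlinal"] = a / (a + p) * 100.0
                row[f"{layer}_periclinal"] = p / (a + p) * 100.0
        out[sid] = row
    return out


def equation_oracle_benchmark(seed: int = 0, n_tables: int = 1000) -> dict:
    """Compare every percentage operation against an independent recount on
    randomized event tables; returns the maximum absolute discrepancy."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        # packet records
        table = {}
        for s in range(int(rng.integers(1, 4))):
            recs = []
            for _ in range(int(rng.integers(1, 5))):
                if rng.random() < 0.1:
                    recs.append(PacketDivisionRecord(Packet(1, 2, 3), (), True))
                else:
                    types = list(rng.choice(["I", "II"], size=rng.integers(0, 3)))
                    types += list(rng.choice(["III", "IV"], size=rng.integers(0, 2)))
                    recs.append(
                        PacketDivisionRecord(Packet(1, 2, 3), tuple(sorted(types)))
                    )
            table[f"s{s}"] = recs
        res = packet_percentages(table)
        oracle = _brute_force_packet(table)
        for t, v in oracle.items():
            if np.isfinite(v):
                worst = max(worst, abs(res.mean[t] - v))

        # layer-rate sets
        sets = {}
        for s in range(int(rng.integers(1, 4))):
            events = [
                DivisionEvent(
                    parent_id=i, daughter_ids=(0, 1), new_wall=None,
                    orientation=str(rng.choice(
                        ["anticlinal", "periclinal", "oblique"])),
                    layer_of_parent=str(rng.choice(["marginal", "submarginal"])),
                )
                for i in range(int(rng.integers(0, 10)))
            ]
            sets[f"s{s}"] = {
                "events": events,
                "layer_counts": {"marginal": int(rng.integers(1, 40)),
                                 "submarginal": int(rng.integers(1, 20))},
                "timeframe_h": float(rng.choice([24.0, 48.0])),
            }
        res = layer_rates(sets)
        oracle = _brute_force_rates(sets)
        for sid, row in oracle.items():
            for k, v in row.items():
                worst = max(worst, abs(res.per_set[sid][k] - v))

        frac_sets = {sid: rec["events"] for sid, rec in sets.items()}
        res = dividing_cell_fractions(frac_sets)
        oracle = _brute_force_fractions(frac_sets)
        for sid, row in oracle.items():
            for k, v in row.items():
                worst = max(worst, abs(res["per_set"][sid][k] - v))
    return {"max_abs_discrepancy": worst, "n_tables": n_tables}


# ---------------------------------------------------------------------------
# parameter recovery (layer-rate estimates vs simulator probabilities)
# ---------------------------------------------------------------------------


def rate_recovery_study(
    seed: int = 1,
    n_samples: int = 30,
    marginal_periclinal: float = 0.30,
    submarginal_periclinal: float = 0.05,
    roi_fraction: float = 0.15,
) -> dict:
    """Recover per-48-h periclinal division probabilities from images.

    ``n_samples`` established meristem sheets are simulated for one window
    with the given per-cell periclinal probabilities, rendered, and analyzed
    by the full pipeline.  As in time-lapse practice, the analysis covers a
    marked region of each sheet (the central 1 - 2*roi_fraction of the long
    axis), excluding the distal tips.  Returns the pooled rate estimates,
    their binomial 95% confidence half-widths around the true values, and
    the across-set t-test between marginal and submarginal periclinal rates.
    """
    sets = {}
    tot = {"m": 0, "mp": 0, "s": 0, "sp": 0}
    for k in range(n_samples):
        params = SimParams(
            n_windows=1,
            rng_seed=seed * 1000 + k,
            q1=0.30,
            q2=marginal_periclinal,
            q3=0.30,
            q4=submarginal_periclinal,
            size_gate=0.0,
            size_max=float("inf"),
            apical_fraction=1.0,
            p_trichome=0.0,
            initial_sheet=(3, 20, 20, 20),
            growth_factor=1.25,
        )
        series = simulate(params)
        (wa, _, _), = run_synthetic_series(
            series, rp=RenderParams(pixel_size=0.4)
        )
        xs = np.array([c[0] for c in wa.centroids0.values()])
        lo = xs.min() + roi_fraction * (xs.max() - xs.min())
        hi = xs.max() - roi_fraction * (xs.max() - xs.min())
        ss = wa.restricted_stats_set(
            lambda lab: lo <= wa.centroids0[lab][0] <= hi
        )
        sets[f"g{k}"] = ss
        tot["m"] += ss["layer_counts"]["marginal"]
        tot["s"] += ss["layer_counts"]["submarginal"]
        tot["mp"] += sum(
            1 for e in ss["events"]
            if e.layer_of_parent == "marginal" and e.orientation == "periclinal"
        )
        tot["sp"] += sum(
            1 for e in ss["events"]
            if e.layer_of_parent == "submarginal"
            and e.orientation == "periclinal"
        )
    rates = layer_rates(sets)
    est_m = 100.0 * tot["mp"] / tot["m"]
    est_s = 100.0 * tot["sp"] / tot["s"]
    ci_m = 196.0 * np.sqrt(
        marginal_periclinal * (1 - marginal_periclinal) / tot["m"]
    )
    ci_s = 196.0 * np.sqrt(
        submarginal_periclinal * (1 - submarginal_periclinal) / tot["s"]
    )
    tt = rates.ttests["marginal_p_vs_submarginal_p"]
    return {
        "marginal_periclinal_pct": est_m,
        "submarginal_periclinal_pct": est_s,
        "true_marginal_pct": 100.0 * marginal_periclinal,
        "true_submarginal_pct": 100.0 * submarginal_periclinal,
        "ci95_halfwidth_marginal": ci_m,
        "ci95_halfwidth_submarginal": ci_s,
        "within_ci_marginal": abs(est_m - 100 * marginal_periclinal) <= ci_m,
        "within_ci_submarginal": abs(est_s - 100 * submarginal_periclinal) <= ci_s,
        "t_marginal_vs_submarginal": tt.t,
        "p_marginal_vs_submarginal": tt.p,
        "n_marginal_cells": tot["m"],
        "n_submarginal_cells": tot["s"],
        "layer_rate_means": rates.mean,
    }


def size_division_study(seed: int = 1, n_samples: int = 5) -> dict:
    """Divided vs non-divided cell areas with the size gate active.

    Each sample is a sheet grown for five windows under default (size-gated,
    apically localized) division rules; the final window is imaged and
    tracked, and start-of-window areas are pooled across samples.
    """
    areas, divided, trich = {}, {}, {}
    offset = 0
    for k in range(n_samples):
        params = SimParams(
            n_windows=5, rng_seed=seed * 1000 + k,
            initial_sheet=(5, 12, 20, 15),
        )
        series = simulate(params)
        w = params.n_windows - 1
        pts = np.vstack(
            [c.polygon for _, cc in series.snapshots[w:w + 2] for c in cc]
        )
        rp = RenderParams(pixel_size=0.5)
        origin = pts.min(axis=0) - rp.pad_px * rp.pixel_size
        ext = pts.max(axis=0) - origin + rp.pad_px * rp.pixel_size
        shape = (int(np.ceil(ext[1] / rp.pixel_size)),
                 int(np.ceil(ext[0] / rp.pixel_size)))
        frames = []
        for j in (w, w + 1):
            rpj = dataclasses.replace(rp, rng_seed=seed * 1000 + k + j)
            img, tl, l2c = render(
                series.snapshot_cells(j), rpj, origin=origin, shape=shape
            )
            wp = preprocess(img)
            frames.append((segment(wp), wp, tl, l2c))
        (seg0, wp0, tl0, l2c0), (seg1, _, _, _) = frames
        m0 = {
            sl: l2c0[t]
            for sl, (t, _) in match_labels(seg0, tl0, min_iou=0.5).items()
        }
        cells0 = {c.id: c for c in series.snapshot_cells(w)}
        trich0 = {
            sl: cells0[cid].is_trichome
            for sl, cid in m0.items() if cid in cells0
        }
        wa = analyze_window(
            seg0, seg1,
            WindowMeta(series.snapshots[w][0], series.snapshots[w + 1][0]),
            trichome_truth0=trich0, wallprob0=wp0,
        )
        for lab, area in wa.areas0.items():
            areas[offset + lab] = area
            divided[offset + lab] = wa.divided0.get(lab, False)
            trich[offset + lab] = wa.trichomes0.get(lab, False)
        offset += 100000
    res = size_vs_division(areas, divided, trich)
    return {
        "mean_area_divided": res.mean_divided,
        "mean_area_not_divided": res.mean_not_divided,
        "n_divided": res.n_divided,
        "n_not_divided": res.n_not_divided,
        "t": res.ttest.t,
        "p": res.ttest.p,
    }
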