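"""The study's quantitative endpoints.

All statistics follow the same conventions:

* the unit of replication is the time-lapse *set* (one sample over one
  window), so standard errors are computed across sets, not across cells;
* SE = SD / sqrt(n) with SD the ddof=1 sample standard deviation;
* "Student's two-tailed t-test" means the pooled-variance two-sample t;
  Welch's correction is available behind ``welch=True``;
* every per-48-h rate from a 24-h window is normalized by x(48/timeframe);
* oblique-orientation events are excluded from anticlinal/periclinal rates
  (they are retained in event tables);
* undefined per-set values (no cells, or no events, in the relevant layer)
  are dropped listwise and counted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .division_geometry import DivisionEvent, PacketDivisionRecord

__all__ = [
    "PacketStats",
    "LayerStats",
    "SizeComparison",
    "GrowthResult",
    "TTestResult",
    "packet_percentages",
    "layer_rates",
    "dividing_cell_fractions",
    "size_vs_division",
    "growth_rate_comparison",
]

PACKET_TYPES = ("I", "II", "III", "IV")
# cells at risk per packet for each type: two upper cells for I/II, one
# lower cell for III/IV
_CELLS_AT_RISK = {"I": 2, "II": 2, "III": 1, "IV": 1}


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    n1: int
    n2: int

    @classmethod
    def undefined(cls, n1=0, n2=0):
        return cls(float("nan"), float("nan"), float("nan"), n1, n2)


def ttest_two_sample(a, b, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test; pooled variance unless ``welch``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return TTestResult.undefined(len(a), len(b))
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(getattr(res, "df", len(a) + len(b) - 2))
    return TTestResult(float(res.statistic), float(res.pvalue), df, len(a), len(b))


def _mean_se(values) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se, n


@dataclass
class PacketStats:
    """Per-type percentages of packet divisions, aggregated across sets."""

    per_set: dict[str, dict[str, float]]  # set id -> type -> mean %
    mean: dict[str, float]
    se: dict[str, float]
    n_sets: int
    n_packets: int
    n_complex_excluded: int
    ttests: dict[str, TTestResult]


def _packet_type_percentages(rec: PacketDivisionRecord) -> dict[str, float]:
    counts = {t: rec.division_types.count(t) for t in PACKET_TYPES}
    return {
        t: counts[t] / _CELLS_AT_RISK[t] * 100.0 for t in PACKET_TYPES
    }


def packet_percentages(
    records_by_set: dict[str, list[PacketDivisionRecord]], welch: bool = False
) -> PacketStats:
    """Percentage of each division type (I-IV) in three-celled packets.

    Per packet: type I and II percentages are (count / 2 cells) x 100, type
    III and IV are (count / 1 cell) x 100; totals across types may exceed
    100%.  Complex packets (any member with more than one division in the
    window) are excluded.  Per-set means are averaged across sets with SE,
    and I-vs-II and III-vs-IV pooled t-tests are reported.
    """
    if not records_by_set:
        raise ValueError("no packet record sets supplied (empty grouping)")
    per_set: dict[str, dict[str, float]] = {}
    n_packets = 0
    n_complex = 0
    set_values: dict[str, list[float]] = {t: [] for t in PACKET_TYPES}
    for set_id in sorted(records_by_set):
        recs = [r for r in records_by_set[set_id]]
        n_complex += sum(r.is_complex for r in recs)
        usable = [r for r in recs if not r.is_complex]
        if not usable:
            continue
        n_packets += len(usable)
        percs = [_packet_type_percentages(r) for r in usable]
        per_set[str(set_id)] = {
            t: float(np.mean([p[t] for p in percs])) for t in PACKET_TYPES
        }
        for t in PACKET_TYPES:
            set_values[t].append(per_set[str(set_id)][t])
    mean, se = {}, {}
    for t in PACKET_TYPES:
        mean[t], se[t], _ = _mean_se(set_values[t])
    ttests = {
        "I_vs_II": ttest_two_sample(set_values["I"], set_values["II"], welch),
        "III_vs_IV": ttest_two_sample(set_values["III"], set_values["IV"], welch),
    }
    return PacketStats(
        per_set=per_set,
        mean=mean,
        se=se,
        n_sets=len(per_set),
        n_packets=n_packets,
        n_complex_excluded=n_complex,
        ttests=ttests,
    )


LAYER_KEYS = (
    "marginal_anticlinal",
    "marginal_periclinal",
    "submarginal_anticlinal",
    "submarginal_periclinal",
)


@dataclass
class LayerStats:
    """Per-48-h division rates by layer and orientation, across sets."""

    per_set: dict[str, dict[str, float]]
    mean: dict[str, float]
    se: dict[str, float]
    n_sets: dict[str, int]
    dropped: dict[str, int]  # sets excluded for an empty layer
    n_oblique_excluded: int
    ttests: dict[str, TTestResult]


def layer_rates(
    sets: dict[str, dict],
    welch: bool = False,
) -> LayerStats:
    """The four per-48-h layer division rates.

    ``sets`` maps a set id to ``{"events": [DivisionEvent...],
    "layer_counts": {"marginal": int, "submarginal": int},
    "timeframe_h": float}`` with layer counts taken at the window start
    (before the imaging interval) and each event carrying the layer of its
    parent at the window start.  Rate = events / cells_at_start / timeframe
    x 48 x 100 (%).  Oblique events are excluded (counted); sets with zero
    cells in a layer contribute no value for that layer's rates.
    """
    per_set: dict[str, dict[str, float]] = {}
    values: dict[str, list[float]] = {k: [] for k in LAYER_KEYS}
    dropped = {"marginal": 0, "submarginal": 0}
    n_oblique = 0
    for set_id in sorted(sets):
        rec = sets[set_id]
        events: list[DivisionEvent] = rec["events"]
        counts = rec["layer_counts"]
        tf = float(rec["timeframe_h"])
        if tf <= 0:
            raise ValueError(f"set {set_id}: non-positive timeframe")
        n_oblique += sum(
            1
            for e in events
            if e.orientation not in ("anticlinal", "periclinal")
        )
        row: dict[str, float] = {}
        for layer in ("marginal", "submarginal"):
            n_cells = int(counts.get(layer, 0))
            if n_cells <= 0:
                dropped[layer] += 1
                continue
            for orient in ("anticlinal", "periclinal"):
                n_ev = sum(
                    1
                    for e in events
                    if e.layer_of_parent == layer and e.orientation == orient
                )
                key = f"{layer}_{orient}"
                row[key] = n_ev / n_cells / tf * 48.0 * 100.0
                values[key].append(row[key])
        per_set[str(set_id)] = row
    mean, se, n_sets = {}, {}, {}
    for k in LAYER_KEYS:
        mean[k], se[k], n_sets[k] = _mean_se(values[k])
    ttests = {
        "marginal_a_vs_submarginal_a": ttest_two_sample(
            values["marginal_anticlinal"], values["submarginal_anticlinal"], welch
        ),
        "marginal_p_vs_submarginal_p": ttest_two_sample(
            values["marginal_periclinal"], values["submarginal_periclinal"], welch
        ),
        "marginal_a_vs_p": ttest_two_sample(
            values["marginal_anticlinal"], values["marginal_periclinal"], welch
        ),
        "submarginal_a_vs_p": ttest_two_sample(
            values["submarginal_anticlinal"], values["submarginal_periclinal"], welch
        ),
    }
    return LayerStats(
        per_set=per_set,
        mean=mean,
        se=se,
        n_sets=n_sets,
        dropped=dropped,
        n_oblique_excluded=n_oblique,
        ttests=ttests,
    )


def dividing_cell_fractions(
    sets: dict[str, list[DivisionEvent]], welch: bool = False
) -> dict:
    """Orientation split among the division events of each layer.

    Per set and layer: anticlinal % = anticlinal events / all a+p events in
    that layer x 100 (and likewise periclinal; the two sum to 100 when no
    oblique events occur).  Cells dividing more than once contribute every
    event.  Sets with zero a/p events in a layer are excluded (counted).
    """
    values = {
        "marginal_anticlinal": [],
        "marginal_periclinal": [],
        "submarginal_anticlinal": [],
        "submarginal_periclinal": [],
    }
    per_set: dict[str, dict[str, float]] = {}
    dropped = {"marginal": 0, "submarginal": 0}
    for set_id in sorted(sets):
        events = sets[set_id]
        row = {}
        for layer in ("marginal", "submarginal"):
            n_a = sum(
                1 for e in events
                if e.layer_of_parent == layer and e.orientation == "anticlinal"
            )
            n_p = sum(
                1 for e in events
                if e.layer_of_parent == layer and e.orientation == "periclinal"
            )
            if n_a + n_p == 0:
                dropped[layer] += 1
                continue
            row[f"{layer}_anticlinal"] = n_a / (n_a + n_p) * 100.0
            row[f"{layer}_periclinal"] = n_p / (n_a + n_p) * 100.0
            values[f"{layer}_anticlinal"].append(row[f"{layer}_anticlinal"])
            values[f"{layer}_periclinal"].append(row[f"{layer}_periclinal"])
        per_set[str(set_id)] = row
    out = {"per_set": per_set, "dropped": dropped, "mean": {}, "se": {}, "n_sets": {}}
    for k, v in values.items():
        out["mean"][k], out["se"][k], out["n_sets"][k] = _mean_se(v)
    out["ttests"] = {
        "marginal_a_vs_p": ttest_two_sample(
            values["marginal_anticlinal"], values["marginal_periclinal"], welch
        ),
        "submarginal_a_vs_p": ttest_two_sample(
            values["submarginal_anticlinal"], values["submarginal_periclinal"], welch
        ),
    }
    return out


@dataclass
class SizeComparison:
    """Mean area of divided vs non-divided cells at the window start."""

    mean_divided: float
    se_divided: float
    n_divided: int
    mean_not_divided: float
    se_not_divided: float
    n_not_divided: int
    ttest: TTestResult


def size_vs_division(
    areas: dict[int, float],
    divided: dict[int, bool],
    trichome_flags: dict[int, bool] | None = None,
    welch: bool = False,
) -> SizeComparison:
    """Compare areas (um^2, window start) of cells that divided vs not.

    Trichome-flagged cells are excluded from both groups.  Means and SEs are
    always reported; the t-test is undefined (NaN) when a group has n < 2.
    """
    trichome_flags = trichome_flags or {}
    div, nondiv = [], []
    for cid, area in areas.items():
        if trichome_flags.get(cid, False):
            continue
        if cid not in divided:
            continue
        (div if divided[cid] else nondiv).append(float(area))
    m1, s1, n1 = _mean_se(div)
    m2, s2, n2 = _mean_se(nondiv)
    return SizeComparison(
        mean_divided=m1,
        se_divided=s1,
        n_divided=n1,
        mean_not_divided=m2,
        se_not_divided=s2,
        n_not_divided=n2,
        ttest=ttest_two_sample(div, nondiv, welch),
    )


@dataclass
class GrowthResult:
    """Whole-gametophyte 48-h growth rates (area ratio), compared by group."""

    rates: dict[str, float]  # sample id -> area(t1)/area(t0)
    groups: dict[str, str]  # sample id -> group label
    group_means: dict[str, float]
    group_ses: dict[str, float]
    ttest: TTestResult


def growth_rate_comparison(
    samples: dict[str, dict], group_a: str = "PI", group_b: str = "mock",
    welch: bool = False,
) -> GrowthResult:
    """Growth rate per sample = tissue area at 48 h / area at 0 h
    (trichomes excluded upstream), compared between two groups."""
    rates, groups = {}, {}
    for sid in sorted(samples):
        rec = samples[sid]
        a0, a1 = float(rec["area_t0"]), float(rec["area_t1"])
        if a0 <= 0:
            raise ValueError(f"sample {sid}: zero or negative baseline area")
        rates[str(sid)] = a1 / a0
        groups[str(sid)] = str(rec["group"])
    means, ses = {}, {}
    by_group: dict[str, list[float]] = {}
    for sid, rate in rates.items():
        by_group.setdefault(groups[sid], []).append(rate)
    for g, vals in by_group.items():
        means[g], ses[g], _ = _mean_se(vals)
    return GrowthResult(
        rates=rates,
        groups=groups,
        group_means=means,
        group_ses=ses,
        ttest=ttest_two_sample(
            by_group.get(group_a, []), by_group.get(group_b, []), welch
        ),
    )
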