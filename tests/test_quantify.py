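"""Statistics layer: equations, oracles, t-tests."""

import numpy as np
import pytest
from scipy import stats

from prothallus.division_geometry import (
    DivisionEvent,
    Packet,
    PacketDivisionRecord,
)
from prothallus.quantify import (
    PACKET_TYPES,
    dividing_cell_fractions,
    growth_rate_comparison,
    layer_rates,
    packet_percentages,
    size_vs_division,
)


def make_record(types, is_complex=False):
    return PacketDivisionRecord(
        packet=Packet(1, 2, 3), division_types=tuple(sorted(types)),
        is_complex=is_complex,
    )


def make_event(layer, orientation, parent=0):
    return DivisionEvent(parent_id=parent, daughter_ids=(1, 2), new_wall=None,
                         orientation=orientation, layer_of_parent=layer)


class TestPacketPercentages:
    def test_single_type_I_is_fifty_percent(self):
        res = packet_percentages({"set1": [make_record(["I"])]})
        assert res.mean["I"] == pytest.approx(50.0)
        assert res.mean["II"] == 0.0
        assert res.mean["III"] == 0.0
        assert res.mean["IV"] == 0.0

    def test_cluster_of_six_scores_II_and_III_full(self):
        res = packet_percentages({"s": [make_record(["II", "II", "III"])]})
        assert res.mean["II"] == pytest.approx(100.0)
        assert res.mean["III"] == pytest.approx(100.0)

    def test_complex_packets_excluded(self):
        recs = [make_record(["I"]), make_record((), is_complex=True)]
        res = packet_percentages({"s": recs})
        assert res.n_packets == 1
        assert res.n_complex_excluded == 1

    def test_empty_grouping_raises(self):
        with pytest.raises(ValueError):
            packet_percentages({})

    def test_brute_force_oracle(self, rng):
        """Equation output equals a direct recount on random record tables."""
        for _ in range(300):
            n_sets = rng.integers(1, 5)
            table = {}
            for s in range(n_sets):
                recs = []
                for _ in range(rng.integers(1, 6)):
                    if rng.random() < 0.15:
                        recs.append(make_record((), is_complex=True))
                    else:
                        n_upper = rng.integers(0, 3)
                        n_lower = rng.integers(0, 2)
                        types = [rng.choice(["I", "II"]) for _ in range(n_upper)]
                        types += [rng.choice(["III", "IV"]) for _ in range(n_lower)]
                        recs.append(make_record(types))
                table[f"s{s}"] = recs
            res = packet_percentages(table)
            # oracle: recount every record by hand
            expect = {t: [] for t in PACKET_TYPES}
            for s, recs in table.items():
                ok = [r for r in recs if not r.is_complex]
                if not ok:
                    continue
                for t in PACKET_TYPES:
                    cells = 2 if t in ("I", "II") else 1
                    vals = [r.division_types.count(t) / cells * 100 for r in ok]
                    expect[t].append(np.mean(vals))
            for t in PACKET_TYPES:
                if expect[t]:
                    assert res.mean[t] == pytest.approx(np.mean(expect[t]))


class TestLayerRates:
    def one_set(self, events, n_m, n_s, tf):
        return {"s": {"events": events,
                      "layer_counts": {"marginal": n_m, "submarginal": n_s},
                      "timeframe_h": tf}}

    def test_24h_window_normalized_to_48h(self):
        events = [make_event("marginal", "anticlinal", i) for i in range(5)]
        res = layer_rates(self.one_set(events, 50, 10, 24.0))
        assert res.per_set["s"]["marginal_anticlinal"] == pytest.approx(20.0)

    def test_zero_events_zero_rates(self):
        res = layer_rates(self.one_set([], 10, 5, 48.0))
        assert all(v == 0.0 for v in res.per_set["s"].values())

    def test_normalization_property(self, rng):
        """A 24-h window with events E equals a 48-h window with 2E."""
        events24 = [make_event("marginal", "periclinal", i) for i in range(3)]
        events48 = [make_event("marginal", "periclinal", i) for i in range(6)]
        r24 = layer_rates(self.one_set(events24, 20, 5, 24.0))
        r48 = layer_rates(self.one_set(events48, 20, 5, 48.0))
        assert (r24.per_set["s"]["marginal_periclinal"]
                == pytest.approx(r48.per_set["s"]["marginal_periclinal"]))

    def test_oblique_events_excluded_and_counted(self):
        events = [make_event("marginal", "oblique", 1),
                  make_event("marginal", "anticlinal", 2)]
        res = layer_rates(self.one_set(events, 10, 2, 48.0))
        assert res.n_oblique_excluded == 1
        assert res.per_set["s"]["marginal_anticlinal"] == pytest.approx(10.0)

    def test_empty_layer_dropped_with_count(self):
        res = layer_rates(self.one_set([], 10, 0, 48.0))
        assert res.dropped["submarginal"] == 1
        assert "submarginal_anticlinal" not in res.per_set["s"]

    def test_brute_force_oracle(self, rng):
        for _ in range(300):
            sets = {}
            for s in range(rng.integers(1, 4)):
                events = []
                for i in range(rng.integers(0, 10)):
                    events.append(make_event(
                        rng.choice(["marginal", "submarginal"]),
                        rng.choice(["anticlinal", "periclinal", "oblique"]),
                        parent=i,
                    ))
                sets[f"s{s}"] = {
                    "events": events,
                    "layer_counts": {"marginal": int(rng.integers(1, 40)),
                                     "submarginal": int(rng.integers(1, 20))},
                    "timeframe_h": float(rng.choice([24.0, 48.0])),
                }
            res = layer_rates(sets)
            for sid, rec in sets.items():
                for layer in ("marginal", "submarginal"):
                    for orient in ("anticlinal", "periclinal"):
                        n = sum(1 for e in rec["events"]
                                if e.layer_of_parent == layer
                                and e.orientation == orient)
                        expect = (n / rec["layer_counts"][layer]
                                  / rec["timeframe_h"] * 48.0 * 100.0)
                        got = res.per_set[sid][f"{layer}_{orient}"]
                        assert got == pytest.approx(expect)


class TestDividingCellFractions:
    def test_all_anticlinal(self):
        events = [make_event("marginal", "anticlinal", i) for i in range(4)]
        res = dividing_cell_fractions({"s": events})
        assert res["per_set"]["s"]["marginal_anticlinal"] == 100.0
        assert res["per_set"]["s"]["marginal_periclinal"] == 0.0

    def test_three_to_one_split(self):
        events = [make_event("submarginal", "anticlinal", i) for i in range(3)]
        events.append(make_event("submarginal", "periclinal", 9))
        res = dividing_cell_fractions({"s": events})
        assert res["per_set"]["s"]["submarginal_anticlinal"] == pytest.approx(75.0)
        assert res["per_set"]["s"]["submarginal_periclinal"] == pytest.approx(25.0)

    def test_fractions_sum_to_hundred_without_oblique(self, rng):
        for _ in range(200):
            events = [make_event("marginal",
                                 rng.choice(["anticlinal", "periclinal"]), i)
                      for i in range(rng.integers(1, 9))]
            res = dividing_cell_fractions({"s": events})
            total = (res["per_set"]["s"]["marginal_anticlinal"]
                     + res["per_set"]["s"]["marginal_periclinal"])
            assert total == pytest.approx(100.0)

    def test_empty_layer_excluded(self):
        res = dividing_cell_fractions({"s": []})
        assert res["dropped"] == {"marginal": 1, "submarginal": 1}


class TestSizeVsDivision:
    def test_identical_groups_give_t_zero_p_one(self):
        areas = {i: a for i, a in enumerate([10, 20, 30, 10, 20, 30])}
        divided = {0: True, 1: True, 2: True, 3: False, 4: False, 5: False}
        res = size_vs_division(areas, divided)
        assert res.ttest.t == pytest.approx(0.0, abs=1e-12)
        assert res.ttest.p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # groups {1,2} vs {3,4}: pooled variance 0.5, se = sqrt(0.5) ~ 0.7071,
        # t = (1.5 - 3.5)/0.7071 = -2.8284, df = 2, two-sided p = 0.10557
        # (closed form: sf(t; df=2) = 0.5 * (1 - t / sqrt(2 + t^2)))
        areas = {0: 1.0, 1: 2.0, 2: 3.0, 3: 4.0}
        divided = {0: True, 1: True, 2: False, 3: False}
        res = size_vs_division(areas, divided)
        assert res.ttest.t == pytest.approx(-2.8284271, abs=1e-6)
        assert res.ttest.p == pytest.approx(0.1055728, abs=1e-6)
        assert res.ttest.df == 2

    def test_scale_invariance(self, rng):
        areas = {i: float(a) for i, a in enumerate(rng.uniform(50, 500, 30))}
        divided = {i: bool(rng.random() < 0.4) for i in areas}
        if len({v for v in divided.values()}) < 2:
            divided[0], divided[1] = True, False
        r1 = size_vs_division(areas, divided)
        r2 = size_vs_division({i: a * 7.3 for i, a in areas.items()}, divided)
        assert r1.ttest.t == pytest.approx(r2.ttest.t)
        assert r1.ttest.p == pytest.approx(r2.ttest.p)

    def test_trichomes_excluded(self):
        areas = {0: 10.0, 1: 20.0, 2: 999.0}
        divided = {0: True, 1: False, 2: False}
        res = size_vs_division(areas, divided, {2: True})
        assert res.n_divided + res.n_not_divided == 2

    def test_small_group_reports_means_not_t(self):
        res = size_vs_division({0: 5.0, 1: 6.0}, {0: True, 1: False})
        assert res.mean_divided == 5.0
        assert np.isnan(res.ttest.t)

    def test_welch_matches_scipy(self, rng):
        a = rng.normal(100, 30, 12)
        b = rng.normal(160, 60, 9)
        areas = {i: v for i, v in enumerate(np.concatenate([a, b]))}
        divided = {i: i < 12 for i in areas}
        res = size_vs_division(areas, divided, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.ttest.t == pytest.approx(ref.statistic)
        assert res.ttest.p == pytest.approx(ref.pvalue)


class TestGrowthRates:
    def test_ratio_examples(self):
        res = growth_rate_comparison({
            "a": {"area_t0": 100.0, "area_t1": 100.0, "group": "PI"},
            "b": {"area_t0": 100.0, "area_t1": 200.0, "group": "mock"},
        })
        assert res.rates["a"] == pytest.approx(1.0)
        assert res.rates["b"] == pytest.approx(2.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(ValueError):
            growth_rate_comparison(
                {"a": {"area_t0": 0.0, "area_t1": 1.0, "group": "PI"}}
            )

    def test_null_p_values_uniform(self):
        """Under identical growth laws the two-group p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(200):
            samples = {}
            for i in range(12):
                a0 = rng.uniform(5000, 20000)
                samples[f"pi{i}"] = {"area_t0": a0,
                                     "area_t1": a0 * rng.normal(1.4, 0.1),
                                     "group": "PI"}
            for i in range(12):
                a0 = rng.uniform(5000, 20000)
                samples[f"mock{i}"] = {"area_t0": a0,
                                       "area_t1": a0 * rng.normal(1.4, 0.1),
                                       "group": "mock"}
            pvals.append(growth_rate_comparison(samples).ttest.p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
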