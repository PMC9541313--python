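"""The growth simulator: division grammar, lineage bookkeeping, invariants."""

import numpy as np
import pytest
import shapely.geometry as sg

from prothallus.simulate import (
    SimParams,
    SimulationLimitError,
    simulate,
)


def test_zero_windows_is_a_single_spore():
    s = simulate(SimParams(n_windows=0))
    assert len(s.snapshots) == 1
    assert s.n_cells(0) == 1
    assert s.snapshot_cells(0)[0].role == "spore"
    assert s.events == []


def test_forced_oblique_self_renewal():
    s = simulate(
        SimParams(
            n_windows=1, p_oblique=1.0, p_terminate=0.0,
            q1=0, q2=0, q3=0, q4=0, p_trichome=0.0,
        )
    )
    assert len(s.events) == 1
    assert s.events[0].orientation == "oblique"
    roles = sorted(c.role for c in s.snapshot_cells(1))
    assert roles == ["apical_initial", "derivative"]


def test_forced_termination_ends_apical_phase():
    s = simulate(
        SimParams(
            n_windows=2, p_oblique=0.0, p_terminate=1.0,
            q1=0, q2=0, q3=0, q4=0, p_trichome=0.0,
        )
    )
    assert s.events[0].orientation == "periclinal"
    assert all(c.role != "apical_initial" for c in s.snapshot_cells(-1))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        simulate(SimParams(q1=0.8, q2=0.5))
    with pytest.raises(ValueError):
        simulate(SimParams(growth_factor=0.9))
    with pytest.raises(ValueError):
        simulate(SimParams(p_oblique=1.2))


def test_cell_count_limit_raises():
    with pytest.raises(SimulationLimitError):
        simulate(
            SimParams(n_windows=6, initial_sheet=(3, 12, 20, 20),
                      max_cells=40, size_gate=0.0, size_max=float("inf"), apical_fraction=1.0)
        )


def test_lineage_is_a_forest(sheet_series):
    daughters = [
        d for (kids, _) in sheet_series.lineage.values() for d in kids
    ]
    assert len(daughters) == len(set(daughters))


def test_total_area_non_decreasing(sheet_series):
    areas = [sum(c.area for c in cells) for _, cells in sheet_series.snapshots]
    assert all(b >= a - 1e-6 for a, b in zip(areas, areas[1:]))


def test_polygons_stay_simple(sheet_series):
    for _, cells in sheet_series.snapshots:
        for c in cells:
            assert sg.Polygon(c.polygon).is_valid


def test_at_most_one_apical_initial():
    s = simulate(SimParams(n_windows=6, rng_seed=3))
    for _, cells in s.snapshots:
        assert sum(c.role == "apical_initial" for c in cells) <= 1


def test_meristem_parents_dominate_division_events():
    s = simulate(SimParams(n_windows=6, rng_seed=1))
    assert len(s.events) > 0
    meristem_roles = {"packet_upper", "packet_lower", "apical_initial",
                      "derivative", "spore"}
    id_to_role = {}
    for _, cells in s.snapshots:
        for c in cells:
            id_to_role.setdefault(c.id, c.role)
    frac_meristem = np.mean(
        [id_to_role[e.parent_id] in meristem_roles for e in s.events]
    )
    assert frac_meristem > 0.5  # quiescent 'ordinary' cells rarely divide


def test_cell_count_increases_each_window():
    s = simulate(SimParams(n_windows=6, rng_seed=1, initial_sheet=(3, 10, 20, 20)))
    counts = [len(cells) for _, cells in s.snapshots]
    assert all(b >= a for a, b in zip(counts, counts[1:]))
    assert counts[-1] > counts[0]


def test_periclinal_rate_matches_q2():
    """Empirical marginal periclinal frequency converges to q2 (binomial CI)."""
    q2 = 0.30
    n_events = 0
    n_cells = 0
    for seed in range(40):
        p = SimParams(
            n_windows=2, rng_seed=seed, q1=0.15, q2=q2, q3=0.2, q4=0.05,
            size_gate=0.0, size_max=float("inf"), apical_fraction=1.0, p_trichome=0.0,
            initial_sheet=(3, 10, 20, 20), growth_factor=1.25,
        )
        s = simulate(p)
        for w in range(2):
            start = s.snapshot_cells(w)
            n_cells += sum(c.layer == "marginal" for c in start)
            n_events += sum(
                1 for e in s.events_in_window(w)
                if e.layer_of_parent == "marginal"
                and e.orientation == "periclinal"
                and not e.is_trichome_initiation
            )
    phat = n_events / n_cells
    ci = 1.96 * np.sqrt(q2 * (1 - q2) / n_cells)
    assert abs(phat - q2) < ci + 0.01


def test_orientation_bookkeeping_against_margin():
    """Anticlinal walls run along the margin normal, periclinal along the
    tangent, measured on the emitted geometry."""
    from prothallus.simulate import _margin_tangent, _smooth_margin

    s = simulate(
        SimParams(n_windows=2, rng_seed=2, size_gate=0.0, size_max=float("inf"), apical_fraction=1.0,
                  p_trichome=0.0, initial_sheet=(3, 12, 20, 20),
                  growth_factor=1.25)
    )
    angles = {"anticlinal": [], "periclinal": []}
    for w in range(2):
        cells = s.snapshot_cells(w + 1)
        polys = [sg.Polygon(c.polygon) for c in cells if not c.is_trichome]
        from shapely.ops import unary_union

        union = unary_union(polys)
        if union.geom_type == "MultiPolygon":
            union = max(union.geoms, key=lambda g: g.area)
        ring = np.array(union.exterior.coords[:-1])
        margin = _smooth_margin(ring)
        for e in s.events_in_window(w):
            if e.orientation not in angles or e.is_trichome_initiation:
                continue
            wall = e.new_wall
            d = wall[1] - wall[0]
            d = d / np.linalg.norm(d)
            tangent, _ = _margin_tangent(margin, wall.mean(axis=0))
            ang = np.degrees(np.arccos(np.clip(abs(d @ tangent), 0, 1)))
            angles[e.orientation].append(ang)
    # by construction; a small minority sit on ambiguous margin stretches
    anti = np.array(angles["anticlinal"])
    peri = np.array(angles["periclinal"])
    assert np.mean(anti > 60) > 0.9
    assert np.mean(peri < 30) > 0.9


def test_simulation_is_deterministic():
    a = simulate(SimParams(n_windows=4, rng_seed=7))
    b = simulate(SimParams(n_windows=4, rng_seed=7))
    assert len(a.events) == len(b.events)
    for ea, eb in zip(a.events, b.events):
        assert ea.parent_id == eb.parent_id
        assert ea.orientation == eb.orientation
        np.testing.assert_allclose(ea.new_wall, eb.new_wall)
    for (ta, ca), (tb, cb) in zip(a.snapshots, b.snapshots):
        assert ta == tb
        for x, y in zip(ca, cb):
            np.testing.assert_allclose(x.polygon, y.polygon)
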