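"""Cell-based growth simulator for fern gametophyte apical meristems.

The simulator reproduces, as explicit stochastic rules on a polygonal cell
mesh, the division grammar seen in time-lapse imaging of *Woodsia obtusa*
gametophytes:

* **Apical-initial phase** — a single wedge-shaped apical cell at the tissue
  apex self-renews by oblique division (probability ``p_oblique`` per 48-h
  window), producing a new apical cell plus a trapezoid derivative, or
  terminates by periclinal division (``p_terminate``), after which no apical
  initial exists and the multicellular meristem takes over.
* **Meristem phase** — every marginal cell of the apical meristem divides
  anticlinally with probability ``q1`` or periclinally with ``q2`` per window;
  every submarginal meristem cell divides anticlinally with ``q3`` or
  periclinally with ``q4``.  The meristem occupies an apical sector of the
  tissue (``apical_fraction`` of directions around the tissue centroid,
  centred on the apex; 1.0 makes every marginal/submarginal cell active, as
  in parameter-recovery experiments).  These four rules generate the four
  packet division types (I–IV): anticlinal / periclinal division of an upper
  (marginal) or lower (submarginal) packet cell.  Inner cells and cells
  outside the meristem sector are quiescent and only expand.
* **Trichomes** — with probability ``p_trichome`` per window an eligible cell
  initiates a trichome by asymmetric division: a marginal cell cuts off a
  small triangular daughter at its outer corner which then protrudes outward;
  an inner cell produces an out-of-plane daughter rendered as a bright disk.
* **Growth and size gating** — non-dividing cells expand linearly by
  ``growth_factor`` per window; a cell may divide only if its area is at
  least ``size_gate`` (um^2), which by construction makes dividing cells
  smaller on average than grown non-dividers.

Every division is logged as a :class:`TruthEvent` with its orientation,
packet type, parent layer and window, so the emitted :class:`TruthSeries` is
a complete ground truth for testing segmentation, lineage tracking and the
downstream statistics.

Orientation is defined geometrically: anticlinal chords run along the local
margin normal through the parent centroid, periclinal chords along the margin
tangent, oblique chords at 45 degrees.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from .mesh import CellMesh, MeshError

__all__ = [
    "SimParams",
    "SimCell",
    "TruthEvent",
    "TruthSeries",
    "SimulationLimitError",
    "simulate",
    "export_truth",
]

WINDOW_H = 48.0  # one simulation step covers one 48-h imaging window

ROLE_SPORE = "spore"
ROLE_APICAL = "apical_initial"
ROLE_DERIVATIVE = "derivative"
ROLE_UPPER = "packet_upper"
ROLE_LOWER = "packet_lower"
ROLE_ORDINARY = "ordinary"
ROLE_TRICHOME = "trichome"


class SimulationLimitError(RuntimeError):
    """Raised when a parameter set exceeds a configured simulation limit."""


@dataclass(frozen=True)
class SimParams:
    """Stochastic rules of one simulated gametophyte (probabilities per 48 h).

    ``q1``/``q2`` are the anticlinal/periclinal division probabilities of
    marginal (packet-upper) cells, ``q3``/``q4`` those of submarginal
    (packet-lower) cells.  Defaults are configuration placeholders chosen to
    reproduce the qualitative ordering seen in live imaging (periclinal >
    anticlinal in the marginal layer; anticlinal > periclinal below), not
    measured estimates.
    """

    n_windows: int = 6
    p_oblique: float = 0.60
    p_terminate: float = 0.25
    q1: float = 0.15
    q2: float = 0.35
    q3: float = 0.30
    q4: float = 0.10
    p_trichome: float = 0.02
    growth_factor: float = 1.20
    size_gate: float = 150.0
    # differentiation threshold: cells that have expanded beyond this area
    # (um^2) have left the meristem and no longer divide; infinity disables
    size_max: float = 600.0
    rng_seed: int = 0
    max_cells: int = 2000
    spore_diameter: float = 30.0  # um; germinated spore cell width
    min_thickness: float = 5.0  # um; a division may not create thinner daughters
    apical_fraction: float = 0.5  # fraction of directions forming the meristem sector
    # (rows, cols, cell_w_um, cell_h_um): start from a mature rectangular
    # sheet (no apical-initial phase) instead of a single spore; used for
    # experiments on established multicellular meristems
    initial_sheet: tuple[int, int, float, float] | None = None

    def validate(self) -> None:
        probs = {
            "p_oblique": self.p_oblique,
            "p_terminate": self.p_terminate,
            "q1": self.q1,
            "q2": self.q2,
            "q3": self.q3,
            "q4": self.q4,
            "p_trichome": self.p_trichome,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.q1 + self.q2 > 1.0 + 1e-12:
            raise ValueError("q1 + q2 must not exceed 1")
        if self.q3 + self.q4 > 1.0 + 1e-12:
            raise ValueError("q3 + q4 must not exceed 1")
        if self.p_oblique + self.p_terminate > 1.0 + 1e-12:
            raise ValueError("p_oblique + p_terminate must not exceed 1")
        if self.growth_factor < 1.0:
            raise ValueError("growth_factor must be >= 1")
        if self.n_windows < 0:
            raise ValueError("n_windows must be non-negative")
        if self.size_gate < 0:
            raise ValueError("size_gate must be non-negative")
        if self.size_max <= self.size_gate:
            raise ValueError("size_max must exceed size_gate")
        if self.max_cells < 1:
            raise ValueError("max_cells must be positive")
        if not 0.0 < self.apical_fraction <= 1.0:
            raise ValueError("apical_fraction must be in (0, 1]")
        if self.min_thickness < 0:
            raise ValueError("min_thickness must be non-negative")
        if self.initial_sheet is not None:
            rows, cols, cw, ch = self.initial_sheet
            if rows < 1 or cols < 1 or cw <= 0 or ch <= 0:
                raise ValueError("initial_sheet must be (rows>=1, cols>=1, w>0, h>0)")


@dataclass
class SimCell:
    """One cell of a simulated snapshot (polygon vertices in um, CCW)."""

    id: int
    polygon: np.ndarray
    role: str
    layer: str
    birth_window: int
    out_of_plane: bool = False  # bears an out-of-plane (vertical) trichome

    @property
    def is_trichome(self) -> bool:
        return self.role == ROLE_TRICHOME

    @property
    def area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))

    @property
    def centroid(self) -> np.ndarray:
        from .mesh import _polygon_centroid

        return _polygon_centroid(self.polygon)


@dataclass(frozen=True)
class TruthEvent:
    """A logged division: who divided, how, where, and when."""

    parent_id: int
    daughter_ids: tuple[int, ...]
    orientation: str  # anticlinal | periclinal | oblique
    packet_type: str  # I | II | III | IV | none
    layer_of_parent: str
    window: int
    new_wall: np.ndarray  # 2x2 chord endpoints (um)
    half: int = 0  # 0/1: first or second 24-h half of the window
    is_trichome_initiation: bool = False


@dataclass
class TruthSeries:
    """Ground-truth time-lapse: snapshots, lineage forest, and event log."""

    snapshots: list[tuple[float, list[SimCell]]]
    lineage: dict[int, tuple[tuple[int, ...], int]]  # parent -> (daughters, window)
    events: list[TruthEvent]
    params: SimParams
    meta: dict = field(default_factory=dict)

    def snapshot_cells(self, index: int) -> list[SimCell]:
        return self.snapshots[index][1]

    def events_in_window(self, window: int) -> list[TruthEvent]:
        return [e for e in self.events if e.window == window]

    def n_cells(self, index: int) -> int:
        return len(self.snapshots[index][1])


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _smooth_margin(points: np.ndarray) -> np.ndarray:
    """Resample the margin ring at ~1 um so tangents average a physical
    scale; uses the same resampling as the measurement pipeline so that
    constructed wall orientations agree with measured ones."""
    from .division_geometry import _resample_ring

    if len(points) < 3:
        return points
    return _resample_ring(points, 1.0)


def _margin_tangent(points: np.ndarray, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent and outward normal of a CCW margin ring nearest ``xy``.

    The tangent is smoothed over ~5 um of neighbouring ring vertices; for a
    CCW ring the outward normal is the tangent rotated by -90 degrees.
    """
    n = len(points)
    i = int(np.argmin(np.linalg.norm(points - xy, axis=1)))
    k = min(5, (n - 1) // 2) if n >= 8 else 1
    t = points[(i + k) % n] - points[(i - k) % n]
    nt = np.linalg.norm(t)
    if nt < 1e-12:
        t = points[(i + 1) % n] - points[i]
        nt = np.linalg.norm(t)
    t = t / nt
    return t, np.array([t[1], -t[0]])


class _State:
    """Mutable simulation state: mesh plus per-cell bookkeeping."""

    def __init__(self, params: SimParams):
        self.mesh = CellMesh()
        self.out_of_plane: set[int] = set()
        self.trichome_apex: dict[int, int] = {}  # trichome cell -> apex vertex id
        if params.initial_sheet is None:
            r = params.spore_diameter / 2.0
            cid = self.mesh.add_cell([(-r, -r), (r, -r), (r, r), (-r, r)])
            self.roles = {cid: ROLE_SPORE}
            self.birth = {cid: 0}
            self.apical: int | None = cid
            self.terminated = False
        else:
            rows, cols, cw, ch = params.initial_sheet
            # real prothalli are rounded sheets: chamfer the grid's corner
            # cells (a sharp 90-degree corner makes the local margin tangent
            # ill-defined for the cell sitting on it)
            chamfer = {}
            if rows >= 2 and cols >= 4:
                chamfer = {
                    (0, 0): lambda i, j: [vid[i + 1, j], vid[i + 1, j + 1], vid[i, j + 1]],
                    (0, cols - 1): lambda i, j: [vid[i, j], vid[i + 1, j], vid[i + 1, j + 1]],
                    (rows - 1, 0): lambda i, j: [vid[i, j], vid[i + 1, j + 1], vid[i, j + 1]],
                    (rows - 1, cols - 1): lambda i, j: [vid[i, j], vid[i + 1, j], vid[i, j + 1]],
                }
            vid = {}
            for i in range(rows + 1):
                for j in range(cols + 1):
                    vid[i, j] = self.mesh.add_vertex(
                        (j * cw - cols * cw / 2.0, -i * ch + rows * ch / 2.0)
                    )
            self.roles = {}
            for i in range(rows):
                for j in range(cols):
                    if (i, j) in chamfer:
                        loop = chamfer[(i, j)](i, j)
                    else:
                        loop = [vid[i, j], vid[i + 1, j], vid[i + 1, j + 1], vid[i, j + 1]]
                    pts = np.array([self.mesh.vertices[v] for v in loop])
                    from .mesh import _polygon_area

                    if _polygon_area(pts) < 0:
                        loop = loop[::-1]
                    cid = self.mesh.add_cell(None, vertex_ids=loop)
                    self.roles[cid] = ROLE_ORDINARY
            self.birth = {c: 0 for c in self.mesh.cell_ids()}
            self.apical = None
            self.terminated = True
            lay = self.layers()
            for cid in self.mesh.cell_ids():
                self.roles[cid] = {
                    "marginal": ROLE_UPPER,
                    "submarginal": ROLE_LOWER,
                    "inner": ROLE_ORDINARY,
                }[lay[cid]]

    def trichome_ids(self) -> frozenset[int]:
        return frozenset(c for c, r in self.roles.items() if r == ROLE_TRICHOME)

    def layers(self) -> dict[int, str]:
        """Geometric layer of every cell: marginal / submarginal / inner."""
        mesh = self.mesh
        trich = self.trichome_ids()
        marginal = mesh.boundary_cells(exclude=trich)
        adj = mesh.adjacency()
        out = {}
        for cid in mesh.cell_ids():
            if cid in trich:
                out[cid] = "marginal" if cid in marginal else "inner"
                continue
            if cid in marginal:
                out[cid] = "marginal"
            elif any(n in marginal and n not in trich for n in adj[cid]):
                out[cid] = "submarginal"
            else:
                out[cid] = "inner"
        return out


def _snapshot(state: _State, layers: dict[int, str], time_h: float) -> tuple[float, list[SimCell]]:
    cells = []
    for cid in state.mesh.cell_ids():
        cells.append(
            SimCell(
                id=cid,
                polygon=state.mesh.coords(cid).copy(),
                role=state.roles[cid],
                layer=layers[cid],
                birth_window=state.birth[cid],
                out_of_plane=cid in state.out_of_plane,
            )
        )
    return (time_h, cells)


def simulate(params: SimParams) -> TruthSeries:
    """Run the division-grammar simulation and return its full ground truth.

    Deterministic for a fixed ``params.rng_seed``.  Raises
    :class:`SimulationLimitError` if the cell count would exceed
    ``params.max_cells`` (e.g. a non-terminating parameter set run for many
    windows).
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    state = _State(params)
    layers = state.layers()
    snapshots = [_snapshot(state, layers, 0.0)]
    lineage: dict[int, tuple[tuple[int, ...], int]] = {}
    events: list[TruthEvent] = []
    meta = {"thickness_skips": 0, "growth_lambdas": []}

    for w in range(params.n_windows):
        layers = state.layers()
        mesh = state.mesh
        trich = state.trichome_ids()

        # meristem sector: directions from the tissue centroid within
        # apical_fraction * 180 degrees of the apex axis (+y)
        tissue_c = np.vstack([mesh.coords(c) for c in mesh.cell_ids()]).mean(axis=0)
        half_angle = params.apical_fraction * 180.0

        def in_meristem(cid: int) -> bool:
            if params.apical_fraction >= 1.0:
                return True
            v = mesh.cell_centroid(cid) - tissue_c
            if np.linalg.norm(v) < 1e-9:
                return True
            ang = np.degrees(np.arccos(np.clip(v[1] / np.linalg.norm(v), -1, 1)))
            return ang <= half_angle

        # -------- decide this window's divisions (sorted ids => determinism)
        plans: list[tuple[int, str]] = []  # (cid, orientation or 'trichome')
        for cid in mesh.cell_ids():
            if cid in trich or cid in state.out_of_plane:
                continue
            role = state.roles[cid]
            u = rng.random()
            if role in (ROLE_SPORE, ROLE_APICAL):
                if u < params.p_oblique:
                    plans.append((cid, "oblique"))
                elif u < params.p_oblique + params.p_terminate:
                    plans.append((cid, "terminate"))
                continue
            area = mesh.cell_area(cid)
            if area < params.size_gate or area > params.size_max:
                continue
            if not in_meristem(cid):
                continue
            lay = layers[cid]
            if lay == "marginal":
                if u < params.q1:
                    plans.append((cid, "anticlinal"))
                elif u < params.q1 + params.q2:
                    plans.append((cid, "periclinal"))
            elif lay == "submarginal":
                if u < params.q3:
                    plans.append((cid, "anticlinal"))
                elif u < params.q3 + params.q4:
                    plans.append((cid, "periclinal"))

        dividing = {cid for cid, _ in plans}

        # -------- trichome initiations (marginal or inner, non-dividing)
        trichome_plans: list[int] = []
        if params.p_trichome > 0:
            for cid in mesh.cell_ids():
                if cid in trich or cid in dividing or cid in state.out_of_plane:
                    continue
                if state.roles[cid] in (ROLE_SPORE, ROLE_APICAL):
                    continue
                if layers[cid] not in ("marginal", "inner"):
                    continue
                area = mesh.cell_area(cid)
                if area < params.size_gate or area > params.size_max:
                    continue
                if rng.random() < params.p_trichome:
                    trichome_plans.append(cid)
        dividing |= set(trichome_plans)

        # -------- growth: the whole sheet expands (dividers grow before they
        # divide); repeated halving is what keeps meristem cells small
        factors = {cid: params.growth_factor for cid in mesh.cell_ids()}
        margin_pts = _smooth_margin(mesh.margin_points(exclude=trich))
        meta["growth_lambdas"].append(mesh.grow(factors))
        for tcid, vid in state.trichome_apex.items():
            if tcid in state.out_of_plane or tcid not in mesh.loops:
                continue
            _, nrm = _margin_tangent(margin_pts, mesh.vertices[vid])
            old = mesh.vertices[vid].copy()
            mesh.displace_vertex(vid, 10.0 * nrm)  # the spike elongates
            affected = [c for c, lp in mesh.loops.items() if vid in lp]
            if not all(mesh.is_simple(c) for c in affected):
                mesh.vertices[vid] = old  # protrusion would fold a neighbour

        # -------- execute planned divisions
        margin_pts = _smooth_margin(mesh.margin_points(exclude=trich))
        for cid, kind in plans:
            c = mesh.cell_centroid(cid)
            tangent, normal = _margin_tangent(margin_pts, c)
            if kind in ("periclinal", "terminate"):
                direction, orientation = tangent, "periclinal"
            elif kind == "anticlinal":
                direction, orientation = normal, "anticlinal"
            else:
                direction, orientation = _rot(tangent, 45.0), "oblique"
            # thickness gate: never create daughters thinner than
            # min_thickness.  The chord passes through the centroid, which
            # for non-rectangular cells (e.g. triangles) need not bisect the
            # extent, so check the distance from the chord to each side.
            pts = mesh.coords(cid)
            across = np.array([-direction[1], direction[0]])
            across /= np.linalg.norm(across)
            proj = pts @ across
            pc = float(c @ across)
            if min(proj.max() - pc, pc - proj.min()) < params.min_thickness:
                meta["thickness_skips"] += 1
                continue
            try:
                d1, d2, wall = mesh.split_with_line(cid, c, direction)
            except MeshError:
                continue  # degenerate geometry: skip this division
            lay = layers[cid]
            role = state.roles.pop(cid)
            state.birth[d1] = state.birth[d2] = w
            if kind == "oblique":
                # outer daughter (farther along the outward normal) renews the
                # wedge-shaped apical initial; the other is a derivative
                proj = [
                    float((mesh.cell_centroid(d) - c) @ normal) for d in (d1, d2)
                ]
                apical = d1 if proj[0] >= proj[1] else d2
                other = d2 if apical == d1 else d1
                state.roles[apical] = ROLE_APICAL
                state.roles[other] = ROLE_DERIVATIVE
                state.apical = apical
            elif kind == "terminate":
                state.roles[d1] = state.roles[d2] = ROLE_DERIVATIVE
                state.apical = None
                state.terminated = True
            else:
                new_role = ROLE_UPPER if lay == "marginal" else ROLE_LOWER
                state.roles[d1] = state.roles[d2] = new_role
            packet = "none"
            if role in (ROLE_UPPER, ROLE_LOWER, ROLE_DERIVATIVE, ROLE_ORDINARY):
                if lay == "marginal" and orientation == "anticlinal":
                    packet = "I"
                elif lay == "marginal" and orientation == "periclinal":
                    packet = "II"
                elif lay == "submarginal" and orientation == "anticlinal":
                    packet = "III"
                elif lay == "submarginal" and orientation == "periclinal":
                    packet = "IV"
            events.append(
                TruthEvent(
                    parent_id=cid,
                    daughter_ids=(d1, d2),
                    orientation=orientation,
                    packet_type=packet,
                    layer_of_parent=lay,
                    window=w,
                    new_wall=wall,
                    half=int(rng.integers(2)),
                )
            )
            lineage[cid] = ((d1, d2), w)
            if cid in state.trichome_apex:
                del state.trichome_apex[cid]

        # -------- execute trichome initiations
        for cid in trichome_plans:
            if cid not in mesh.loops:
                continue
            res = _initiate_trichome(state, cid, layers[cid], margin_pts, w)
            if res is None:
                continue
            tri, sib, wall, apex_vid = res
            state.birth[tri] = state.birth[sib] = w
            # the asymmetric corner cut has no prescribed axis; record the
            # orientation its wall actually has relative to the margin
            wdir = wall[1] - wall[0]
            wn = np.linalg.norm(wdir)
            tri_orient = "oblique"
            if wn > 1e-9:
                tan, _ = _margin_tangent(margin_pts, wall.mean(axis=0))
                ang = np.degrees(
                    np.arccos(np.clip(abs((wdir / wn) @ tan), 0, 1))
                )
                tri_orient = (
                    "anticlinal" if ang > 60.0
                    else "periclinal" if ang < 30.0 else "oblique"
                )
            events.append(
                TruthEvent(
                    parent_id=cid,
                    daughter_ids=(tri, sib),
                    orientation=tri_orient,
                    packet_type="none",
                    layer_of_parent=layers[cid],
                    window=w,
                    new_wall=wall,
                    half=int(rng.integers(2)),
                    is_trichome_initiation=True,
                )
            )
            lineage[cid] = ((tri, sib), w)

        if len(mesh.loops) > params.max_cells:
            raise SimulationLimitError(
                f"cell count {len(mesh.loops)} exceeds max_cells="
                f"{params.max_cells} at window {w}; the parameter set is not "
                "viable for this many windows"
            )

        # -------- refresh meristem roles from geometry once terminated
        layers = state.layers()
        if state.terminated:
            for cid in mesh.cell_ids():
                if state.roles[cid] == ROLE_TRICHOME:
                    continue
                lay = layers[cid]
                if lay == "marginal":
                    state.roles[cid] = ROLE_UPPER
                elif lay == "submarginal":
                    state.roles[cid] = ROLE_LOWER
                else:
                    state.roles[cid] = ROLE_ORDINARY

        snapshots.append(_snapshot(state, layers, WINDOW_H * (w + 1)))

    return TruthSeries(
        snapshots=snapshots, lineage=lineage, events=events, params=params,
        meta=meta,
    )


def export_truth(series: TruthSeries, directory, render_params=None) -> dict:
    """Write a simulated series to disk: stain images and ground-truth label
    maps (TIFF), per-snapshot cell tables, lineage and event tables (CSV),
    and a JSON manifest.  Returns the manifest.  Everything round-trips
    through the package's readers.
    """
    import json
    from pathlib import Path

    import pandas as pd

    from .io import write_image, write_labelmap
    from .render import RenderParams, render_series

    rp = render_params or RenderParams()
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)

    snapshots_meta = []
    if series.snapshots:
        rendered = render_series(series, rp)
        for (time_h, cells), (img, lm, l2c) in zip(series.snapshots, rendered):
            stem = f"t{int(round(time_h)):04d}h"
            write_image(out / f"image_{stem}.tif", img)
            write_labelmap(out / f"labels_{stem}.tif", lm)
            cell_rows = []
            by_id = {c.id: c for c in cells}
            for label, cid in sorted(l2c.items()):
                c = by_id[cid]
                cell_rows.append(
                    dict(
                        time_h=time_h, label=label, cell_id=cid, role=c.role,
                        layer=c.layer, birth_window=c.birth_window,
                        is_trichome=c.is_trichome, out_of_plane=c.out_of_plane,
                        area_um2=c.area,
                    )
                )
            pd.DataFrame(cell_rows).to_csv(out / f"cells_{stem}.csv", index=False)
            snapshots_meta.append(
                {"time_h": time_h, "image": f"image_{stem}.tif",
                 "labels": f"labels_{stem}.tif", "cells": f"cells_{stem}.csv",
                 "n_cells": len(cells)}
            )

    lineage_rows = [
        {"parent_id": p, "daughter_id": d, "window": w}
        for p, (daughters, w) in sorted(series.lineage.items())
        for d in daughters
    ]
    pd.DataFrame(
        lineage_rows, columns=["parent_id", "daughter_id", "window"]
    ).to_csv(out / "lineage.csv", index=False)

    event_rows = [
        {
            "parent_id": e.parent_id,
            "daughter_ids": "|".join(str(d) for d in e.daughter_ids),
            "orientation": e.orientation,
            "packet_type": e.packet_type,
            "layer": e.layer_of_parent,
            "window": e.window,
            "half": e.half,
            "is_trichome_initiation": e.is_trichome_initiation,
        }
        for e in series.events
    ]
    pd.DataFrame(
        event_rows,
        columns=["parent_id", "daughter_ids", "orientation", "packet_type",
                 "layer", "window", "half", "is_trichome_initiation"],
    ).to_csv(out / "events.csv", index=False)

    manifest = {
        "pixel_size_um": rp.pixel_size,
        "time_points_h": [t for t, _ in series.snapshots],
        "n_snapshots": len(series.snapshots),
        "rng_seed": series.params.rng_seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in series.params.__dict__.items()},
        "render_params": dict(rp.__dict__),
        "snapshots": snapshots_meta,
        "meta": {"thickness_skips": series.meta.get("thickness_skips", 0)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _initiate_trichome(state, cid, layer, margin_pts, window):
    """Asymmetric division producing a trichome daughter.

    A marginal parent cuts off a small triangular daughter at its outermost
    corner (which later protrudes outward along the margin normal); an inner
    parent produces an out-of-plane daughter occupying the outer half of the
    cell, rendered downstream as a bright disk.
    """
    mesh = state.mesh
    c = mesh.cell_centroid(cid)
    state.roles.pop(cid)
    if layer == "marginal":
        # outermost vertex of the cell = farthest from the tissue centroid
        pts = mesh.coords(cid)
        loop = list(mesh.loops[cid])
        tissue_c = margin_pts.mean(axis=0)
        k = int(np.argmax(np.linalg.norm(pts - tissue_c, axis=1)))
        corner = pts[k]
        axis = c - corner
        axis_len = np.linalg.norm(axis)
        if axis_len < 1e-9:
            state.roles[cid] = ROLE_UPPER
            return None
        # the trichome initial is a small triangle at the outer corner
        # regardless of how large its mother is
        f = min(0.7, 9.0 / axis_len)
        point = corner + f * axis
        direction = np.array([-axis[1], axis[0]])
        try:
            d1, d2, wall = mesh.split_with_line(cid, point, direction)
        except MeshError:
            state.roles[cid] = ROLE_UPPER
            return None
        corner_vid = loop[k]
        tri = d1 if corner_vid in mesh.loops[d1] else d2
        sib = d2 if tri == d1 else d1
        state.roles[tri] = ROLE_TRICHOME
        state.roles[sib] = ROLE_UPPER
        state.trichome_apex[tri] = corner_vid
        return tri, sib, wall, corner_vid
    # inner-origin trichome: the daughter protrudes out of the sheet, so the
    # in-plane geometry is unchanged; the mother now bears an out-of-plane
    # trichome (rendered as a bright wall ring) and stops dividing
    state.roles[cid] = ROLE_ORDINARY
    state.out_of_plane.add(cid)
    return None
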