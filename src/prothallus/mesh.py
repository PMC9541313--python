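"""Shared-vertex planar cell mesh.

The gametophyte is modelled as a planar subdivision: a set of simple polygons
(cells) that share vertices along common walls.  A cell division inserts a
chord through the parent polygon; because the chord endpoints are inserted
into every loop that uses the intersected edges, the subdivision stays
conforming and the two daughters tile the parent exactly.  Growth is affine
per cell (scaling about the cell centroid) with shared vertices moved to the
mean of the positions requested by their incident cells, which keeps the mesh
conforming at the cost of slightly damping differential expansion.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CellMesh", "MeshError"]

_EPS = 1e-9


class MeshError(ValueError):
    """Raised on degenerate geometry (non-simple polygon, failed split...)."""


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    if abs(a) < _EPS:
        return pts.mean(axis=0)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return np.array([cx, cy])


class CellMesh:
    """A conforming planar subdivision of polygonal cells.

    Vertices are stored once and referenced by id from per-cell loops
    (counter-clockwise).  All coordinates are in micrometres.
    """

    def __init__(self) -> None:
        self.vertices: dict[int, np.ndarray] = {}
        self.loops: dict[int, list[int]] = {}
        self._next_vid = 0
        self._next_cid = 1  # cell ids start at 1 so 0 can mean background

    # ------------------------------------------------------------------ build
    def add_vertex(self, xy) -> int:
        vid = self._next_vid
        self.vertices[vid] = np.asarray(xy, dtype=float).copy()
        self._next_vid += 1
        return vid

    def add_cell(self, coords, vertex_ids=None) -> int:
        """Add a cell from coordinates (new vertices) or existing vertex ids."""
        if vertex_ids is None:
            coords = np.asarray(coords, dtype=float)
            if _polygon_area(coords) < 0:
                coords = coords[::-1]
            vertex_ids = [self.add_vertex(p) for p in coords]
        cid = self._next_cid
        self._next_cid += 1
        self.loops[cid] = list(vertex_ids)
        if self.cell_area(cid) <= _EPS:
            raise MeshError(f"cell {cid} has non-positive area")
        return cid

    # ---------------------------------------------------------------- queries
    def cell_ids(self) -> list[int]:
        return sorted(self.loops)

    def coords(self, cid: int) -> np.ndarray:
        return np.array([self.vertices[v] for v in self.loops[cid]])

    def cell_area(self, cid: int) -> float:
        return _polygon_area(self.coords(cid))

    def cell_centroid(self, cid: int) -> np.ndarray:
        return _polygon_centroid(self.coords(cid))

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.loops)

    def _directed_edges(self, cids):
        for cid in cids:
            loop = self.loops[cid]
            for i, a in enumerate(loop):
                yield cid, a, loop[(i + 1) % len(loop)]

    def adjacency(self) -> dict[int, set[int]]:
        """cell id -> set of cell ids sharing at least one full edge."""
        owner: dict[tuple[int, int], int] = {}
        adj: dict[int, set[int]] = {c: set() for c in self.loops}
        for cid, a, b in self._directed_edges(self.loops):
            other = owner.get((b, a))
            if other is not None and other != cid:
                adj[cid].add(other)
                adj[other].add(cid)
            owner[(a, b)] = cid
        return adj

    def boundary_edges(self, exclude=frozenset()) -> list[tuple[int, int]]:
        """Directed edges used by exactly one included cell (the tissue margin)."""
        cids = [c for c in self.loops if c not in exclude]
        directed = set()
        for _, a, b in self._directed_edges(cids):
            directed.add((a, b))
        return [(a, b) for (a, b) in directed if (b, a) not in directed]

    def margin_ring(self, exclude=frozenset()) -> list[int]:
        """Vertex ids of the outer boundary ring (CCW), excluding given cells.

        If exclusion disconnects the boundary into several rings the one
        enclosing the largest area is returned.
        """
        edges = self.boundary_edges(exclude)
        if not edges:
            raise MeshError("mesh has no boundary")
        nxt = dict(edges)
        if len(nxt) != len(edges):
            raise MeshError("non-manifold boundary")
        rings = []
        remaining = dict(nxt)
        while remaining:
            start = min(remaining)
            ring = [start]
            cur = remaining.pop(start)
            while cur != start:
                ring.append(cur)
                cur = remaining.pop(cur)
            rings.append(ring)
        best = max(
            rings,
            key=lambda r: abs(_polygon_area(np.array([self.vertices[v] for v in r]))),
        )
        return best

    def margin_points(self, exclude=frozenset()) -> np.ndarray:
        return np.array([self.vertices[v] for v in self.margin_ring(exclude)])

    def boundary_cells(self, exclude=frozenset()) -> set[int]:
        """Cells owning at least one boundary edge of the included tissue."""
        boundary = set(self.boundary_edges(exclude))
        out = set()
        for cid, a, b in self._directed_edges(
            [c for c in self.loops if c not in exclude]
        ):
            if (a, b) in boundary:
                out.add(cid)
        return out

    # ----------------------------------------------------------------- splits
    def _insert_on_edge(self, a: int, b: int, frac: float) -> int:
        """Create a vertex at ``frac`` along edge (a, b) in every loop using it."""
        pos = self.vertices[a] + frac * (self.vertices[b] - self.vertices[a])
        vid = self.add_vertex(pos)
        for loop in self.loops.values():
            n = len(loop)
            for i in range(n):
                u, v = loop[i], loop[(i + 1) % n]
                if (u, v) == (a, b) or (u, v) == (b, a):
                    loop.insert(i + 1, vid)
                    break
        return vid

    def split_with_line(self, cid: int, point, direction):
        """Split cell ``cid`` by the line through ``point`` along ``direction``.

        Returns ``(cid_a, cid_b, wall)`` where wall is the 2x2 array of chord
        endpoints.  The parent cell is removed; daughters get fresh ids.  For a
        non-convex cell the two boundary crossings bracketing ``point`` are used.
        """
        point = np.asarray(point, dtype=float)
        d = np.asarray(direction, dtype=float)
        nd = np.linalg.norm(d)
        if nd < _EPS:
            raise MeshError("zero-length split direction")
        d = d / nd
        nrm = np.array([-d[1], d[0]])

        loop = self.loops[cid]
        pts = self.coords(cid)
        s = (pts - point) @ nrm  # signed distance to the line
        t = (pts - point) @ d  # coordinate along the line
        scale = max(1.0, float(np.abs(pts).max()))
        tol = _EPS * scale

        crossings = []  # (t_along_line, kind, payload)
        n = len(loop)
        for i in range(n):
            j = (i + 1) % n
            if abs(s[i]) <= tol:
                crossings.append((t[i], "vertex", loop[i]))
            elif s[i] * s[j] < 0 and abs(s[j]) > tol:
                u = s[i] / (s[i] - s[j])
                # snap near-endpoint crossings to the existing vertex: avoids
                # near-duplicate vertices that fold into slivers under growth
                if u < 0.02:
                    crossings.append((t[i], "vertex", loop[i]))
                elif u > 0.98:
                    crossings.append((t[j], "vertex", loop[j]))
                else:
                    ti = t[i] + u * (t[j] - t[i])
                    crossings.append((ti, "edge", (loop[i], loop[j], u)))
        neg = [c for c in crossings if c[0] < 0]
        pos = [c for c in crossings if c[0] >= 0]
        if not neg or not pos:
            raise MeshError(f"split line misses cell {cid}")
        pick_a = max(neg, key=lambda c: c[0])
        pick_b = min(pos, key=lambda c: c[0])

        ends = []
        for _, kind, payload in (pick_a, pick_b):
            if kind == "vertex":
                ends.append(payload)
            else:
                a, b, u = payload
                ends.append(self._insert_on_edge(a, b, u))
        w1, w2 = ends
        if w1 == w2:
            raise MeshError(f"degenerate split of cell {cid}")

        loop = self.loops[cid]  # may have grown by insertions
        i1, i2 = loop.index(w1), loop.index(w2)
        if i1 < i2:
            loop_a = loop[i1 : i2 + 1]
            loop_b = loop[i2:] + loop[: i1 + 1]
        else:
            loop_a = loop[i1:] + loop[: i2 + 1]
            loop_b = loop[i2 : i1 + 1]
        for lp in (loop_a, loop_b):
            # validate before mutating so a failed split leaves the parent
            # intact (stray collinear vertices on its edges are harmless)
            pts = np.array([self.vertices[v] for v in lp])
            if len(lp) < 3 or _polygon_area(pts) <= _EPS:
                raise MeshError(f"degenerate daughter from cell {cid}")
        del self.loops[cid]
        children = [self.add_cell(None, vertex_ids=lp) for lp in (loop_a, loop_b)]
        wall = np.array([self.vertices[w1], self.vertices[w2]])
        return children[0], children[1], wall

    # ----------------------------------------------------------------- growth
    def grow(self, factors: dict[int, float]) -> float:
        """Scale each cell about its centroid by ``factors[cid]`` (default 1),
        then move each shared vertex to the mean of its incident cells' wishes.

        Differential expansion can fold thin cells; if the full move would
        make any polygon non-simple the displacement is scaled back (the
        largest factor in {1, 0.7, 0.5, 0.3, 0.15, 0} that keeps every cell
        simple is used).  Returns the factor applied.
        """
        values = {factors.get(c, 1.0) for c in self.loops}
        if len(values) == 1:
            # uniform expansion: the conforming solution is exact global
            # scaling about the tissue centroid (no averaging, no folding)
            g = values.pop()
            pts = np.vstack([self.coords(c) for c in self.cell_ids()])
            centre = pts.mean(axis=0)
            for vid in {v for lp in self.loops.values() for v in lp}:
                self.vertices[vid] = centre + g * (self.vertices[vid] - centre)
            return 1.0
        centroids = {c: self.cell_centroid(c) for c in self.loops}
        wishes: dict[int, list[np.ndarray]] = {}
        for cid, loop in self.loops.items():
            g = factors.get(cid, 1.0)
            c = centroids[cid]
            for vid in loop:
                wishes.setdefault(vid, []).append(c + g * (self.vertices[vid] - c))
        start = {vid: self.vertices[vid].copy() for vid in wishes}
        target = {vid: np.mean(ws, axis=0) for vid, ws in wishes.items()}
        lam = {vid: 1.0 for vid in wishes}
        for vid in wishes:
            self.vertices[vid] = target[vid]
        for it in range(10):
            bad = [c for c in self.loops if not self.is_simple(c)]
            if not bad:
                break
            # damp only the offending cells' vertices; their neighbours join
            # the bad set on later iterations if the damping exposes them
            for c in bad:
                for vid in self.loops[c]:
                    lam[vid] = 0.0 if it >= 6 else lam[vid] * 0.5
                    self.vertices[vid] = (
                        (1 - lam[vid]) * start[vid] + lam[vid] * target[vid]
                    )
        else:
            for vid in wishes:  # pathological mesh: skip growth entirely
                self.vertices[vid] = start[vid]
            return 0.0
        return float(np.mean(list(lam.values())))

    def displace_vertex(self, vid: int, delta) -> None:
        self.vertices[vid] = self.vertices[vid] + np.asarray(delta, dtype=float)

    # -------------------------------------------------------------- integrity
    def is_simple(self, cid: int) -> bool:
        import shapely.geometry as sg

        return sg.Polygon(self.coords(cid)).is_valid
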