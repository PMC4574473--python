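"""Synthetic tracked-tissue generator.

Produces polygonal cell networks with programmed deformations and
topological events, together with an analytic ground-truth budget of the
cumulative shear each class of event contributes.  The generator is purely
kinematic: cells are polygons on a (perturbed) hexagonal lattice moved by
prescribed affine maps, with T1 flips, divisions and extrusions applied as
explicit topological surgery.  There is no mechanics — the generator is a
test substrate emulating tracked time-lapse data, not a vertex model.

Two lattices are provided:

* :func:`generate` — hexagonal lattice with an affine per-frame map and a
  scripted event schedule;
* :func:`generate_sliding_rows` — a brick lattice whose rows slide
  rigidly in alternating directions, producing rows of alternating simple
  shear, automatic T1 transitions and a compensating correlation term
  while the net pure shear vanishes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from shapely.geometry import LineString, Polygon
from shapely.ops import split as shapely_split

from .network import SCHEMA, CellNetworkFrame, TrackedTissue
from .triangulation import mean_elongation, triangulate_frame

__all__ = [
    "SynthScript",
    "ShearBudget",
    "generate",
    "generate_sliding_rows",
    "canonical_t1_frame",
    "hex_tissue",
]


# ---------------------------------------------------------------------------
# script and budget containers
# ---------------------------------------------------------------------------

@dataclass
class SynthScript:
    """Recipe for a synthetic video on a hexagonal lattice.

    Rates are in 1/h; the affine map applied between frames is
    ``expm(dt * (dilation/2 * I + shear + rotation * eps))`` where
    ``shear`` is the symmetric traceless matrix with components
    ``(shear_xx, shear_xy)``.

    ``events`` is a list of tuples:

    * ``("t1", frame, cell_a, cell_b)`` — flip the bond between a and b
    * ``("division", frame, cell, axis_angle)`` — split the cell by a cut
      through its centroid perpendicular to ``axis_angle`` (the axis
      connecting the daughter centers)
    * ``("extrusion", frame, cell)`` — collapse the cell to its centroid
    """

    rows: int = 10
    cols: int = 10
    spacing: float = 4.0        # cell diameter scale [µm]
    disorder: float = 0.0       # vertex jitter amplitude, fraction of spacing
    n_frames: int = 10
    dt: float = 1.0 / 12.0      # 5-minute frames [h]
    t0: float = 16.0            # start time [hAPF]
    shear_xx: float = 0.0
    shear_xy: float = 0.0
    rotation: float = 0.0
    dilation: float = 0.0
    events: list = field(default_factory=list)
    seed: int = 0


@dataclass
class ShearBudget:
    """Ground-truth cumulative contributions (dimensionless, xx/xy pairs).

    ``total`` is the applied affine shear integrated over the video;
    ``t1/division/extrusion`` are minus the retriangulation jumps of the
    area-weighted mean elongation, computed by direct re-evaluation at the
    event frame; ``cell_shape`` is the change of mean triangle elongation
    between the first and last frames.
    """

    total: np.ndarray
    cell_shape: np.ndarray
    t1: np.ndarray
    division: np.ndarray
    extrusion: np.ndarray

    @property
    def correlation(self):
        """Correlation budget implied by the exact decomposition."""
        return self.total - (self.cell_shape + self.t1 + self.division + self.extrusion)


# ---------------------------------------------------------------------------
# mutable topology state
# ---------------------------------------------------------------------------

class _Topology:
    """Mutable cell-network topology with base (material) coordinates.

    Derived structure (incidences, adjacency, cyclic orders) is cached and
    invalidated on topological surgery; orientation-preserving affine maps
    leave all cyclic orders unchanged, so the cache is reused across
    frames.
    """

    def __init__(self):
        self.vpos = {}            # vertex_id -> base (x, y)
        self.cell_vertices = {}   # cell_id -> list of vertex ids, CCW
        self.next_vid = 0
        self.next_cid = 0
        self._cache = None

    def invalidate(self):
        self._cache = None

    # derived structures ---------------------------------------------------
    def vertex_cells(self):
        inc = {}
        for cid, ring in self.cell_vertices.items():
            for vid in ring:
                inc.setdefault(vid, set()).add(cid)
        out = {}
        for vid, cells in inc.items():
            p = self.vpos[vid]
            out[vid] = tuple(
                sorted(
                    cells,
                    key=lambda c: np.arctan2(
                        self.centroid(c)[1] - p[1], self.centroid(c)[0] - p[0]
                    ),
                )
            )
        return out

    def centroid(self, cid):
        poly = np.array([self.vpos[v] for v in self.cell_vertices[cid]])
        return _polygon_centroid(poly)

    def neighbors(self):
        """CCW-ordered neighbor lists (cells sharing >= 2 vertices)."""
        pairs = {}
        vc = {}
        for cid, ring in self.cell_vertices.items():
            for vid in ring:
                vc.setdefault(vid, set()).add(cid)
        for vid, cells in vc.items():
            cl = sorted(cells)
            for i, a in enumerate(cl):
                for b in cl[i + 1:]:
                    pairs[(a, b)] = pairs.get((a, b), 0) + 1
        adj = {cid: [] for cid in self.cell_vertices}
        for (a, b), n in pairs.items():
            if n >= 2:
                adj[a].append(b)
                adj[b].append(a)
        out = {}
        for cid, nbrs in adj.items():
            c = self.centroid(cid)
            out[cid] = sorted(
                nbrs,
                key=lambda n: np.arctan2(
                    self.centroid(n)[1] - c[1], self.centroid(n)[0] - c[0]
                ),
            )
        return out

    def resort_cell(self, cid):
        """Re-order a cell's vertex ring CCW by angle around its centroid."""
        ring = self.cell_vertices[cid]
        pts = np.array([self.vpos[v] for v in ring])
        c = pts.mean(axis=0)
        order = np.argsort(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
        self.cell_vertices[cid] = [ring[i] for i in order]

    def new_vertex(self, pos):
        vid = self.next_vid
        self.next_vid += 1
        self.vpos[vid] = (float(pos[0]), float(pos[1]))
        return vid

    def _build_cache(self):
        """Topology-dependent structure, cyclic orders from base geometry."""
        vids = sorted(self.vpos)
        cids = sorted(self.cell_vertices)
        vindex = {v: i for i, v in enumerate(vids)}
        # flattened polygon rings for vectorized shoelace/centroid
        ring_idx = np.fromiter(
            (vindex[v] for c in cids for v in self.cell_vertices[c]), dtype=int
        )
        lens = np.array([len(self.cell_vertices[c]) for c in cids], dtype=int)
        offsets = np.concatenate(([0], np.cumsum(lens)))
        nxt = np.empty_like(ring_idx)
        for k in range(len(cids)):
            lo, hi = offsets[k], offsets[k + 1]
            nxt[lo:hi] = np.concatenate((ring_idx[lo + 1: hi], ring_idx[lo: lo + 1]))
        self._cache = {
            "vids": vids,
            "cids": cids,
            "vindex": vindex,
            "ring_idx": ring_idx,
            "ring_nxt": nxt,
            "offsets": offsets,
            "vertex_cells": self.vertex_cells(),
            "neighbors": self.neighbors(),
            "cell_vertices": {c: tuple(r) for c, r in self.cell_vertices.items()},
        }
        return self._cache

    def to_frame(self, frame_index, time, transform):
        """Emit an immutable CellNetworkFrame with lab coords M @ base.

        The map must be orientation preserving (det > 0) so that cached
        counter-clockwise orders remain valid.
        """
        cache = self._cache or self._build_cache()
        vids = cache["vids"]
        base = np.array([self.vpos[v] for v in vids])
        lab = base @ np.asarray(transform).T
        x, y = lab[cache["ring_idx"], 0], lab[cache["ring_idx"], 1]
        xn, yn = lab[cache["ring_nxt"], 0], lab[cache["ring_nxt"], 1]
        cross = x * yn - xn * y
        off = cache["offsets"]
        areas = 0.5 * np.add.reduceat(cross, off[:-1])
        cx = np.add.reduceat((x + xn) * cross, off[:-1]) / (6.0 * areas)
        cy = np.add.reduceat((y + yn) * cross, off[:-1]) / (6.0 * areas)
        cells = pd.DataFrame(
            {"cell_id": cache["cids"], "x": cx, "y": cy, "area": areas}
        ).set_index("cell_id")
        vc = cache["vertex_cells"]
        vertices = pd.DataFrame(
            {
                "vertex_id": vids,
                "x": lab[:, 0],
                "y": lab[:, 1],
                "boundary": [len(vc.get(v, ())) < 3 for v in vids],
            }
        ).set_index("vertex_id")
        return CellNetworkFrame(
            frame_index=frame_index,
            time=time,
            cells=cells,
            neighbors=cache["neighbors"],
            vertices=vertices,
            vertex_cells=vc,
            cell_vertices=cache["cell_vertices"],
        )


def _shoelace(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def _polygon_centroid(poly):
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


# ---------------------------------------------------------------------------
# hexagonal lattice construction
# ---------------------------------------------------------------------------

def _build_hex_topology(rows, cols, spacing, disorder, rng):
    """Pointy-top hexagonal lattice; returns (_Topology, grid cell map)."""
    rc = spacing / np.sqrt(3.0)   # circumradius; cell width = spacing
    topo = _Topology()
    key_to_vid = {}

    def vertex_at(p):
        key = (round(p[0], 6), round(p[1], 6))
        if key not in key_to_vid:
            key_to_vid[key] = topo.new_vertex(p)
        return key_to_vid[key]

    grid = {}
    angles = np.deg2rad(30 + 60 * np.arange(6))
    for r in range(rows):
        for c in range(cols):
            cx = c * spacing + (r % 2) * spacing / 2.0
            cy = r * 1.5 * rc
            ring = [
                vertex_at((cx + rc * np.cos(a), cy + rc * np.sin(a)))
                for a in angles
            ]
            cid = topo.next_cid
            topo.next_cid += 1
            topo.cell_vertices[cid] = ring
            grid[(r, c)] = cid
    if disorder > 0:
        amp = disorder * spacing
        for vid, (x, y) in topo.vpos.items():
            dx, dy = rng.uniform(-amp, amp, size=2)
            topo.vpos[vid] = (x + dx, y + dy)
    return topo, grid


def hex_tissue(rows=6, cols=6, spacing=4.0, disorder=0.0, n_frames=2, dt=1.0 / 12.0, seed=0):
    """Static hexagonal-lattice tissue (no deformation, no events)."""
    script = SynthScript(
        rows=rows, cols=cols, spacing=spacing, disorder=disorder,
        n_frames=n_frames, dt=dt, seed=seed,
    )
    return generate(script)[0]


# ---------------------------------------------------------------------------
# topological surgery in base coordinates
# ---------------------------------------------------------------------------

def _apply_t1(topo, a, b, shrink=0.15):
    """Flip the bond between adjacent cells a and b.

    Returns ``(c, d, info)`` with ``info`` carrying the new vertex ids,
    bond midpoint and growth directions for post-flip bond regrowth.
    """
    ring_a = set(topo.cell_vertices[a])
    ring_b = set(topo.cell_vertices[b])
    shared = sorted(ring_a & ring_b)
    if len(shared) != 2:
        raise ValueError(f"cells {a},{b} do not share a simple bond")
    v1, v2 = shared
    inc = {}
    for cid, ring in topo.cell_vertices.items():
        for vid in (v1, v2):
            if vid in ring:
                inc.setdefault(vid, set()).add(cid)
    third1 = inc[v1] - {a, b}
    third2 = inc[v2] - {a, b}
    if len(third1) != 1 or len(third2) != 1:
        raise ValueError(f"bond {a}-{b} does not have two 3-fold end vertices")
    c, d = third1.pop(), third2.pop()
    p1, p2 = np.array(topo.vpos[v1]), np.array(topo.vpos[v2])
    m = 0.5 * (p1 + p2)
    half = shrink * np.linalg.norm(p2 - p1)
    ca, cb = topo.centroid(a), topo.centroid(b)
    dir_a, dir_b = _unit(ca - m), _unit(cb - m)
    ua = topo.new_vertex(m + half * dir_a)
    ub = topo.new_vertex(m + half * dir_b)
    # a and b lose the bond edge: both old vertices collapse to one corner
    for cid, keep in ((a, ua), (b, ub)):
        ring = [v for v in topo.cell_vertices[cid] if v not in (v1, v2)]
        ring.append(keep)
        topo.cell_vertices[cid] = ring
        topo.resort_cell(cid)
    # c and d gain the new bond: their single old corner becomes two
    for cid, drop in ((c, v1), (d, v2)):
        ring = [v for v in topo.cell_vertices[cid] if v != drop]
        ring.extend([ua, ub])
        topo.cell_vertices[cid] = ring
        topo.resort_cell(cid)
    del topo.vpos[v1], topo.vpos[v2]
    topo.invalidate()
    info = {
        "ua": ua,
        "ub": ub,
        "mid": m,
        "dir_a": dir_a,
        "dir_b": dir_b,
        "target_half": 0.5 * float(np.linalg.norm(p2 - p1)),
    }
    return c, d, info


def _unit(v):
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate direction")
    return v / n


def _apply_division(topo, cid, axis_angle):
    """Split a cell by a cut through its centroid; returns (d1, d2).

    ``axis_angle`` is the division axis (direction connecting daughter
    centers); the cut line is perpendicular to it.
    """
    ring = topo.cell_vertices[cid]
    pts = np.array([topo.vpos[v] for v in ring])
    cen = _polygon_centroid(pts)
    cut_dir = np.array(
        [np.cos(axis_angle + np.pi / 2.0), np.sin(axis_angle + np.pi / 2.0)]
    )
    span = 10.0 * (pts.max() - pts.min() + 1.0)
    line = LineString([cen - span * cut_dir, cen + span * cut_dir])
    poly = Polygon(pts)
    pieces = [g for g in shapely_split(poly, line).geoms]
    if len(pieces) != 2:
        raise ValueError(f"cut of cell {cid} produced {len(pieces)} pieces")
    # match piece corners back to existing vertices / create cut vertices
    pos_of = {v: np.array(topo.vpos[v]) for v in ring}
    new_vids = {}

    def resolve(pt):
        p = np.array(pt)
        for v, q in pos_of.items():
            if np.linalg.norm(p - q) < 1e-9:
                return v, False
        key = (round(p[0], 9), round(p[1], 9))
        if key not in new_vids:
            new_vids[key] = topo.new_vertex(p)
        return new_vids[key], True

    daughters = []
    daughter_rings = []
    for piece in pieces:
        coords = list(piece.exterior.coords)[:-1]
        dring = [resolve(pt)[0] for pt in coords]
        did = topo.next_cid
        topo.next_cid += 1
        daughters.append(did)
        daughter_rings.append(dring)
    if len(new_vids) != 2:
        raise ValueError("division cut must cross exactly two cell edges")
    for did, dring in zip(daughters, daughter_rings):
        topo.cell_vertices[did] = dring
        topo.resort_cell(did)
    # insert cut vertices into the neighbors whose shared edge was crossed
    ring_cycle = list(ring)
    for key, nv in new_vids.items():
        p = np.array(key)
        # find the old edge containing this point
        for i in range(len(ring_cycle)):
            a_id = ring_cycle[i]
            b_id = ring_cycle[(i + 1) % len(ring_cycle)]
            pa, pb = pos_of[a_id], pos_of[b_id]
            t = np.dot(p - pa, pb - pa) / max(np.dot(pb - pa, pb - pa), 1e-30)
            if -1e-9 < t < 1 + 1e-9 and np.linalg.norm(pa + t * (pb - pa) - p) < 1e-7:
                for ocid, oring in topo.cell_vertices.items():
                    if ocid in daughters or ocid == cid:
                        continue
                    if a_id in oring and b_id in oring and nv not in oring:
                        topo.cell_vertices[ocid] = oring + [nv]
                        topo.resort_cell(ocid)
                break
    del topo.cell_vertices[cid]
    topo.invalidate()
    return daughters[0], daughters[1]


def _apply_extrusion(topo, cid):
    """Collapse a cell to its centroid (T2 transition)."""
    ring = topo.cell_vertices[cid]
    cen = topo.centroid(cid)
    u = topo.new_vertex(cen)
    dead = set(ring)
    for ocid in list(topo.cell_vertices):
        if ocid == cid:
            continue
        oring = topo.cell_vertices[ocid]
        if dead & set(oring):
            newring = [v for v in oring if v not in dead]
            newring.append(u)
            topo.cell_vertices[ocid] = newring
            topo.resort_cell(ocid)
    for v in dead:
        del topo.vpos[v]
    del topo.cell_vertices[cid]
    topo.invalidate()


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _capture_job(topo, job):
    """Record the original geometry a ramped event will shrink."""
    ev = job["ev"]
    if ev[0] == "t1":
        a, b = ev[2], ev[3]
        shared = sorted(set(topo.cell_vertices[a]) & set(topo.cell_vertices[b]))
        if len(shared) != 2:
            raise ValueError(f"cells {a},{b} do not share a simple bond")
        v1, v2 = shared
        p1, p2 = np.array(topo.vpos[v1]), np.array(topo.vpos[v2])
        job["orig"] = {v1: p1, v2: p2}
        job["mid"] = 0.5 * (p1 + p2)
        job["target_half"] = 0.5 * float(np.linalg.norm(p2 - p1))
    else:  # extrusion: the whole cell shrinks toward its centroid
        cell = ev[2]
        ring = topo.cell_vertices[cell]
        job["orig"] = {v: np.array(topo.vpos[v]) for v in ring}
        job["mid"] = topo.centroid(cell)


def _shrink_job(topo, job, frac):
    m = job["mid"]
    for v, p0 in job["orig"].items():
        if v in topo.vpos:
            topo.vpos[v] = tuple(m + frac * (p0 - m))


def _velocity_gradient(script):
    eps = np.array([[0.0, -1.0], [1.0, 0.0]])
    shear = np.array(
        [[script.shear_xx, script.shear_xy], [script.shear_xy, -script.shear_xx]]
    )
    return 0.5 * script.dilation * np.eye(2) + shear + script.rotation * eps


def generate(script: SynthScript, ramp=3):
    """Generate a tracked tissue plus its ground-truth shear budget.

    Returns ``(tissue, budget)`` where ``budget`` is a :class:`ShearBudget`
    over the interior analysis ROI (stored on the tissue as roi ``"bulk"``).

    T1s and extrusions are choreographed continuously: the involved bond
    (or cell) shrinks over ``ramp`` frames before the topological change,
    which then occurs at nearly fixed geometry, and the gained bond
    regrows over ``ramp`` frames afterwards.  This mirrors how neighbor
    exchanges and T2 transitions proceed in a real junctional network and
    keeps cell centers continuous, so the retriangulation jump is purely
    topological.  Per-event jumps for the budget are evaluated by
    brute-force recomputation of the area-weighted mean triangle
    elongation immediately before and after the topological surgery.
    """
    rng = np.random.default_rng(script.seed)
    topo, grid = _build_hex_topology(
        script.rows, script.cols, script.spacing, script.disorder, rng
    )
    # interior ROI: cells at least 2 rings away from the lattice margin
    margin = 2
    roi = {
        grid[(r, c)]
        for r in range(margin, script.rows - margin)
        for c in range(margin, script.cols - margin)
    }
    if not roi:
        raise ValueError("lattice too small for an interior ROI")

    by_frame = {}
    jobs = []
    for ev in script.events:
        fi = int(ev[1])
        if fi < 1 or fi >= script.n_frames:
            raise ValueError(f"event frame {fi} out of range")
        by_frame.setdefault(fi, []).append(ev)
        if ev[0] in ("t1", "extrusion"):
            jobs.append({"ev": ev, "frame": fi, "start": max(1, fi - ramp)})

    dL = _velocity_gradient(script)
    step = expm(script.dt * dL)
    transform = np.eye(2)

    frames = []
    lineage_rows, ext_rows, t1_rows = [], [], []
    jumps = {"t1": np.zeros(2), "division": np.zeros(2), "extrusion": np.zeros(2)}
    roi_now = set(roi)
    for fi in range(script.n_frames):
        time = script.t0 + fi * script.dt
        if fi > 0:
            transform = step @ transform
        # pre-event shrink / post-event regrowth choreography
        for job in jobs:
            ev = job["ev"]
            if job["start"] <= fi < job["frame"]:
                if "orig" not in job:
                    _capture_job(topo, job)
                frac = ((job["frame"] - fi) / (job["frame"] - job["start"] + 1.0)) ** 2
                _shrink_job(topo, job, frac)
            elif fi >= job["frame"] and ev[0] == "t1" and "info" in job:
                grow = min(1.0, (fi - job["frame"] + 1.0) / (ramp + 1.0))
                info = job["info"]
                topo.vpos[info["ua"]] = tuple(
                    info["mid"] + grow * job.get("target_half", info["target_half"]) * info["dir_a"]
                )
                topo.vpos[info["ub"]] = tuple(
                    info["mid"] + grow * job.get("target_half", info["target_half"]) * info["dir_b"]
                )
        todays = by_frame.get(fi, [])
        if todays:
            pre_frame = topo.to_frame(fi, time, transform)
            q_pre = np.array(
                mean_elongation(_roi_triangulation(pre_frame, roi_now))
            )
            for ev in todays:
                kind = ev[0]
                if kind == "t1":
                    _, _, a, b = ev
                    c, d, info = _apply_t1(topo, a, b, shrink=0.3)
                    job = next(j for j in jobs if j["ev"] is ev)
                    job["info"] = info
                    t1_rows.append((fi, *sorted((a, b)), *sorted((c, d))))
                elif kind == "division":
                    _, _, cell, axis = ev
                    d1, d2 = _apply_division(topo, cell, axis)
                    lineage_rows.append((cell, d1, d2, fi))
                    if cell in roi_now:
                        roi_now -= {cell}
                        roi_now |= {d1, d2}
                elif kind == "extrusion":
                    _, _, cell = ev
                    _apply_extrusion(topo, cell)
                    ext_rows.append((cell, fi))
                    roi_now.discard(cell)
                else:
                    raise ValueError(f"unknown event kind {kind!r}")
                post_frame = topo.to_frame(fi, time, transform)
                q_post = np.array(
                    mean_elongation(_roi_triangulation(post_frame, roi_now))
                )
                jumps[kind] += q_post - q_pre
                q_pre = q_post
            frames.append(post_frame)
        else:
            frames.append(topo.to_frame(fi, time, transform))

    tissue = TrackedTissue(
        frames=frames,
        lineage=pd.DataFrame(lineage_rows, columns=SCHEMA["lineage"]),
        extrusions=pd.DataFrame(ext_rows, columns=SCHEMA["extrusions"]),
        t1_events=pd.DataFrame(t1_rows, columns=SCHEMA["t1_events"]),
        roi={"bulk": roi},
    )
    total_time = (script.n_frames - 1) * script.dt
    total = np.array([script.shear_xx, script.shear_xy]) * total_time
    q0 = np.array(mean_elongation(_roi_triangulation(frames[0], roi)))
    q1 = np.array(mean_elongation(_roi_triangulation(frames[-1], roi_now)))
    budget = ShearBudget(
        total=total,
        cell_shape=q1 - q0,
        t1=-jumps["t1"],
        division=-jumps["division"],
        extrusion=-jumps["extrusion"],
    )
    tissue.grid = {v: k for k, v in grid.items()}
    return tissue, budget


def _roi_triangulation(frame, roi_cells):
    """Triangulation restricted to vertices whose cells all lie in the ROI."""
    tri = triangulate_frame(frame)
    keep = np.array(
        [all(c in roi_cells for c in t) for t in tri.cell_triplets], dtype=bool
    )
    return dataclasses.replace(
        tri,
        cell_triplets=tri.cell_triplets[keep],
        corners=tri.corners[keep],
        area=tri.area[keep],
        theta=tri.theta[keep],
        q_xx=tri.q_xx[keep],
        q_xy=tri.q_xy[keep],
        vertex_ids=tri.vertex_ids[keep],
        degenerate=tri.degenerate[keep],
    )


# ---------------------------------------------------------------------------
# sliding rows (alternating simple shear)
# ---------------------------------------------------------------------------

def generate_sliding_rows(
    n_rows=8,
    n_cols=16,
    cell_width=4.0,
    cell_height=4.0,
    shift_rate=0.5,
    n_frames=25,
    dt=1.0 / 12.0,
    t0=16.0,
    jitter=0.25,
    seed=0,
):
    """Brick lattice with rows sliding rigidly in alternating directions.

    Row ``j`` translates with offset ``(-1)^j * shift_rate * cell_width *
    t``; cell boundaries within each row carry a fixed jitter (fraction of
    the cell width) so that the T1 flips between rows are staggered in
    time rather than simultaneous.  Cell centers move rigidly with their
    row, so triangles spanning adjacent rows undergo alternating simple
    shear while the net pure shear of the tissue vanishes.

    Returns ``(tissue, budget)``; the T1 budget is minus the cumulative
    retriangulation jump, evaluated per interval by re-computing the mean
    elongation of the previous interval's triangle set at the new
    geometry.
    """
    rng = np.random.default_rng(seed)
    w, h = cell_width, cell_height
    phase = rng.uniform(-jitter, jitter, size=(n_rows, n_cols + 1))

    def row_offset(j, t):
        return (1.0 if j % 2 == 0 else -1.0) * shift_rate * w * t

    def division_points(j, t):
        return (np.arange(n_cols + 1) + np.concatenate(([0.0], phase[j, 1:-1], [0.0]))) * w + row_offset(j, t)

    def build_frame(fi, time):
        t = fi * dt
        cell_id = lambda i, j: j * n_cols + i
        xs = {j: division_points(j, t) for j in range(n_rows)}
        topo_cells = {}
        vid_map = {}
        vpos = {}
        next_vid = [0]

        def vid_for(key, pos):
            if key not in vid_map:
                vid_map[key] = next_vid[0]
                vpos[next_vid[0]] = pos
                next_vid[0] += 1
            return vid_map[key]

        # a division point k of row j is a vertical boundary segment; its
        # bottom end ("b", j, k) sits at y = j*h shared with one cell of
        # row j-1, its top end ("t", j, k) at y = (j+1)*h shared with one
        # cell of row j+1 -- the same keys are used from both sides
        for j in range(n_rows):
            for i in range(n_cols):
                x0, x1 = xs[j][i], xs[j][i + 1]
                ring = [vid_for(("b", j, i), (x0, j * h))]
                # bottom edge left-to-right: top ends of row j-1 points
                if j > 0:
                    for k in range(n_cols + 1):
                        if x0 + 1e-9 < xs[j - 1][k] < x1 - 1e-9:
                            ring.append(vid_for(("t", j - 1, k), (xs[j - 1][k], j * h)))
                ring.append(vid_for(("b", j, i + 1), (x1, j * h)))
                ring.append(vid_for(("t", j, i + 1), (x1, (j + 1) * h)))
                # top edge right-to-left: bottom ends of row j+1 points
                if j < n_rows - 1:
                    for k in sorted(range(n_cols + 1), key=lambda k: -xs[j + 1][k]):
                        if x0 + 1e-9 < xs[j + 1][k] < x1 - 1e-9:
                            ring.append(vid_for(("b", j + 1, k), (xs[j + 1][k], (j + 1) * h)))
                ring.append(vid_for(("t", j, i), (x0, (j + 1) * h)))
                topo_cells[cell_id(i, j)] = ring

        # division points of adjacent rows coincide in position only at
        # exact T1 instants, which generic frame sampling avoids
        cells_rows = []
        for cid, ring in topo_cells.items():
            poly = np.array([vpos[v] for v in ring])
            cells_rows.append((cid, *_polygon_centroid(poly), _shoelace(poly)))
        cells = pd.DataFrame(
            cells_rows, columns=["cell_id", "x", "y", "area"]
        ).set_index("cell_id").sort_index()
        inc = {}
        for cid, ring in topo_cells.items():
            for v in ring:
                inc.setdefault(v, set()).add(cid)
        vertex_cells = {}
        for v, cc in inc.items():
            p = vpos[v]
            vertex_cells[v] = tuple(
                sorted(cc, key=lambda c: np.arctan2(cells.loc[c, "y"] - p[1], cells.loc[c, "x"] - p[0]))
            )
        vertices = pd.DataFrame(
            {
                "vertex_id": sorted(vpos),
                "x": [vpos[v][0] for v in sorted(vpos)],
                "y": [vpos[v][1] for v in sorted(vpos)],
                "boundary": [len(inc.get(v, ())) < 3 for v in sorted(vpos)],
            }
        ).set_index("vertex_id")
        pairs = {}
        for v, cc in inc.items():
            cl = sorted(cc)
            for ii, a in enumerate(cl):
                for b in cl[ii + 1:]:
                    pairs[(a, b)] = pairs.get((a, b), 0) + 1
        adj = {cid: [] for cid in topo_cells}
        for (a, b), n in pairs.items():
            if n >= 2:
                adj[a].append(b)
                adj[b].append(a)
        neighbors = {}
        for cid, nbrs in adj.items():
            cx, cy = cells.loc[cid, "x"], cells.loc[cid, "y"]
            neighbors[cid] = sorted(
                nbrs, key=lambda n: np.arctan2(cells.loc[n, "y"] - cy, cells.loc[n, "x"] - cx)
            )
        return CellNetworkFrame(
            frame_index=fi,
            time=t0 + fi * dt,
            cells=cells,
            neighbors=neighbors,
            vertices=vertices,
            vertex_cells=vertex_cells,
            cell_vertices={c: tuple(r) for c, r in topo_cells.items()},
        )

    frames = [build_frame(fi, t0 + fi * dt) for fi in range(n_frames)]
    roi = {
        j * n_cols + i
        for j in range(2, n_rows - 2)
        for i in range(3, n_cols - 3)
    }
    tissue = TrackedTissue(frames=frames, roi={"bulk": roi})

    # T1 budget: per-interval retriangulation jump by direct summation --
    # triangles destroyed are taken at their last frame and triangles
    # created at their first frame, mean-centered per frame
    t1_jump = np.zeros(2)
    prev_tri = _roi_triangulation(frames[0], roi)
    for f in frames[1:]:
        tri = _roi_triangulation(f, roi)
        set1 = set(map(tuple, np.sort(prev_tri.cell_triplets, axis=1)))
        set2 = set(map(tuple, np.sort(tri.cell_triplets, axis=1)))

        def centered(trr, other_set):
            qbar = np.array(mean_elongation(trr))
            w = trr.area[~trr.degenerate].sum()
            rows = np.array(
                [tuple(sorted(t)) not in other_set for t in map(tuple, trr.cell_triplets)],
                dtype=bool,
            ) & ~trr.degenerate
            a = trr.area[rows]
            return np.array(
                [np.sum(a * (trr.q_xx[rows] - qbar[0])),
                 np.sum(a * (trr.q_xy[rows] - qbar[1]))]
            ) / w

        t1_jump += centered(tri, set1) - centered(prev_tri, set2)
        prev_tri = tri
    q0 = np.array(mean_elongation(_roi_triangulation(frames[0], roi)))
    q1 = np.array(mean_elongation(prev_tri))
    budget = ShearBudget(
        total=np.zeros(2),
        cell_shape=q1 - q0,
        t1=-t1_jump,
        division=np.zeros(2),
        extrusion=np.zeros(2),
    )
    return tissue, budget



# ---------------------------------------------------------------------------
# canonical four-cell T1 patch
# ---------------------------------------------------------------------------

def canonical_t1_frame(progress, frame_index=0, time=16.0, size=2.0, bond=0.8):
    """Four-cell quartet with a central bond that shrinks, flips, regrows.

    ``progress`` runs from 0 (vertical bond between the left/right cells)
    through 0.5 (4-fold vertex) to 1 (horizontal bond between top/bottom
    cells).  Cells: 0 = left, 1 = right, 2 = top, 3 = bottom.
    """
    if not 0.0 <= progress <= 1.0:
        raise ValueError("progress must be in [0, 1]")
    s = size
    corners = {
        "bl": (-s, -s),
        "br": (s, -s),
        "tr": (s, s),
        "tl": (-s, s),
    }
    if progress < 0.5:
        half = bond * (0.5 - progress)
        inner = {"v1": (0.0, half), "v2": (0.0, -half)}
        rings = {
            0: ["tl", "bl", "v2", "v1"],
            1: ["br", "tr", "v1", "v2"],
            2: ["tr", "tl", "v1"],
            3: ["bl", "br", "v2"],
        }
    elif progress == 0.5:
        inner = {"v0": (0.0, 0.0)}
        rings = {
            0: ["tl", "bl", "v0"],
            1: ["br", "tr", "v0"],
            2: ["tr", "tl", "v0"],
            3: ["bl", "br", "v0"],
        }
    else:
        half = bond * (progress - 0.5)
        inner = {"u1": (-half, 0.0), "u2": (half, 0.0)}
        rings = {
            0: ["tl", "bl", "u1"],
            1: ["br", "tr", "u2"],
            2: ["tr", "tl", "u1", "u2"],
            3: ["bl", "br", "u2", "u1"],
        }
    names = list(corners) + list(inner)
    pos = {**corners, **inner}
    vid = {n: i for i, n in enumerate(names)}
    topo = _Topology()
    for n in names:
        topo.vpos[vid[n]] = pos[n]
        topo.next_vid += 1
    for cid, ring in rings.items():
        topo.cell_vertices[cid] = [vid[n] for n in ring]
        topo.resort_cell(cid)
    topo.next_cid = 4
    return topo.to_frame(frame_index, time, np.eye(2))
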