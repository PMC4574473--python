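"""Data model and I/O for tracked polygonal cell networks.

A tracked tissue is a sequence of :class:`CellNetworkFrame` objects sharing
stable cell ids, plus lineage and event records (divisions, extrusions, T1
neighbor exchanges) and named regions of interest.  The on-disk schema is a
directory of tidy CSV tables or a single SQLite file with the same tables;
both dialects round-trip exactly.

Conventions
-----------
* coordinates in micrometres, x pointing distally (PD axis), y anteriorly
  (AP axis); time in hours after puparium formation (hAPF)
* neighbor lists are ordered counter-clockwise around each cell
* an event recorded at frame ``f`` separates frames ``f-1`` and ``f``:
  frame ``f`` is the first frame showing the post-event topology.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellNetworkFrame",
    "TrackedTissue",
    "SchemaError",
    "read_tracked_tissue",
    "write_tracked_tissue",
    "detect_events",
    "area_balance",
    "variance_ratio",
]

#: table name -> column list of the relational schema
SCHEMA = {
    "frames": ["frame", "time_hapf"],
    "cells": ["frame", "cell_id", "x", "y", "area"],
    "neighbors": ["frame", "cell_id", "neighbor_id", "position"],
    "vertices": ["frame", "vertex_id", "x", "y", "boundary"],
    "vertex_cells": ["frame", "vertex_id", "cell_id", "position"],
    "cell_vertices": ["frame", "cell_id", "vertex_id", "position"],
    "lineage": ["mother", "daughter_1", "daughter_2", "frame"],
    "extrusions": ["cell_id", "frame"],
    "t1_events": ["frame", "lost_1", "lost_2", "gained_1", "gained_2"],
    "roi": ["roi_id", "cell_id"],
}


class SchemaError(ValueError):
    """Raised for malformed or internally inconsistent tissue files."""


@dataclass
class CellNetworkFrame:
    """One time point of a tracked cell network.

    Parameters
    ----------
    frame_index : int
    time : float
        Time of the frame in hAPF.
    cells : pandas.DataFrame
        Indexed by ``cell_id`` with columns ``x, y, area`` (centers are the
        area centroids of the cell polygons, areas in µm²).
    neighbors : dict
        ``cell_id -> list of neighbor cell_ids`` in counter-clockwise order.
    vertices : pandas.DataFrame
        Indexed by ``vertex_id`` with columns ``x, y, boundary``.
    vertex_cells : dict
        ``vertex_id -> tuple of incident cell_ids`` in cyclic order.
    cell_vertices : dict
        ``cell_id -> tuple of vertex_ids`` tracing the cell polygon CCW.
    """

    frame_index: int
    time: float
    cells: pd.DataFrame
    neighbors: dict
    vertices: pd.DataFrame
    vertex_cells: dict
    cell_vertices: dict

    # -- geometry helpers -------------------------------------------------
    def polygon(self, cell_id):
        """(n, 2) array of the cell's vertex positions in CCW order."""
        vids = list(self.cell_vertices[cell_id])
        return self.vertices.loc[vids, ["x", "y"]].to_numpy(dtype=float)

    def contacts(self):
        """Set of frozenset cell pairs in contact in this frame."""
        out = set()
        for c, nbrs in self.neighbors.items():
            for n in nbrs:
                out.add(frozenset((c, n)))
        return out

    def bonds(self):
        """DataFrame of bonds: two cells and their two shared vertices.

        Bonds with fewer than two shared vertices (degenerate contacts at
        k-fold vertices) get ``vertex_2 = -1``.
        """
        shared = {}
        for vid, cells in self.vertex_cells.items():
            k = len(cells)
            for i in range(k):
                pair = frozenset((cells[i], cells[(i + 1) % k]))
                if len(pair) == 2:
                    shared.setdefault(pair, []).append(vid)
        rows = []
        contacts = self.contacts()
        for bid, pair in enumerate(sorted(shared, key=sorted)):
            c1, c2 = sorted(pair)
            if pair not in contacts:
                continue
            vids = shared[pair]
            v1 = vids[0]
            v2 = vids[1] if len(vids) > 1 else -1
            rows.append((bid, c1, c2, v1, v2))
        return pd.DataFrame(
            rows, columns=["bond_id", "cell_1", "cell_2", "vertex_1", "vertex_2"]
        )

    # -- validation -------------------------------------------------------
    def validate(self):
        """Check the structural invariants; raise :class:`SchemaError`."""
        if (self.cells["area"] <= 0).any():
            bad = self.cells.index[self.cells["area"] <= 0].tolist()
            raise SchemaError(f"non-positive cell areas: {bad}")
        for c, nbrs in self.neighbors.items():
            if len(set(nbrs)) != len(nbrs):
                raise SchemaError(f"duplicate neighbor entries for cell {c}")
            for n in nbrs:
                if n not in self.neighbors or c not in self.neighbors[n]:
                    raise SchemaError(
                        f"non-symmetric neighbor relation: {c} -> {n}"
                    )
        boundary = self.vertices["boundary"].astype(bool)
        for vid, cells in self.vertex_cells.items():
            if len(cells) < 3 and not boundary.loc[vid]:
                raise SchemaError(
                    f"interior vertex {vid} touches {len(cells)} cells (< 3)"
                )
        # polygons must be CCW (positive shoelace area)
        for c in self.cells.index:
            poly = self.polygon(c)
            if _shoelace(poly) <= 0:
                raise SchemaError(f"cell {c} polygon not counter-clockwise")


def _shoelace(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


@dataclass
class TrackedTissue:
    """A time series of cell network frames with lineage and event records."""

    frames: list
    lineage: pd.DataFrame = None
    extrusions: pd.DataFrame = None
    t1_events: pd.DataFrame = None
    roi: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lineage is None:
            self.lineage = pd.DataFrame(columns=SCHEMA["lineage"])
        if self.extrusions is None:
            self.extrusions = pd.DataFrame(columns=SCHEMA["extrusions"])
        if self.t1_events is None:
            self.t1_events = pd.DataFrame(columns=SCHEMA["t1_events"])

    @property
    def times(self):
        return np.array([f.time for f in self.frames])

    def frame_by_index(self, frame_index):
        for f in self.frames:
            if f.frame_index == frame_index:
                return f
        raise KeyError(frame_index)

    def roi_cells(self, roi_id=None):
        """Cells of a named ROI, or all cells present in every frame."""
        if roi_id is not None:
            return set(self.roi[roi_id])
        common = set(self.frames[0].cells.index)
        for f in self.frames[1:]:
            common &= set(f.cells.index)
        return common

    def validate(self, check_events=True):
        for f in self.frames:
            f.validate()
        idx = [f.frame_index for f in self.frames]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise SchemaError("frame indices not strictly increasing")
        if check_events:
            _check_event_consistency(self)


def _check_event_consistency(tissue):
    """Every recorded event must match the topology diff of its frames."""
    by_index = {f.frame_index: f for f in tissue.frames}
    for _, row in tissue.lineage.iterrows():
        f = int(row["frame"])
        if f not in by_index:
            continue
        pre = by_index.get(f - 1)
        post = by_index[f]
        mother, d1, d2 = int(row["mother"]), int(row["daughter_1"]), int(row["daughter_2"])
        ok = (
            (pre is None or mother in pre.cells.index)
            and mother not in post.cells.index
            and d1 in post.cells.index
            and d2 in post.cells.index
        )
        if not ok:
            raise SchemaError(
                f"event/topology mismatch: division of cell {mother} at frame {f}"
            )
    for _, row in tissue.extrusions.iterrows():
        f = int(row["frame"])
        if f not in by_index:
            continue
        pre = by_index.get(f - 1)
        cid = int(row["cell_id"])
        if cid in by_index[f].cells.index or (pre is not None and cid not in pre.cells.index):
            raise SchemaError(
                f"event/topology mismatch: extrusion of cell {cid} at frame {f}"
            )
    for _, row in tissue.t1_events.iterrows():
        f = int(row["frame"])
        if f not in by_index or (f - 1) not in by_index:
            continue
        pre, post = by_index[f - 1], by_index[f]
        lost = frozenset((int(row["lost_1"]), int(row["lost_2"])))
        gained = frozenset((int(row["gained_1"]), int(row["gained_2"])))
        if lost not in pre.contacts() or lost in post.contacts():
            raise SchemaError(f"event/topology mismatch: T1 lost bond {set(lost)} at frame {f}")
        if gained not in post.contacts() or gained in pre.contacts():
            raise SchemaError(f"event/topology mismatch: T1 gained bond {set(gained)} at frame {f}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _tissue_to_tables(tissue):
    frames_rows, cells_rows, nb_rows, vx_rows, vc_rows, cv_rows = [], [], [], [], [], []
    for f in tissue.frames:
        frames_rows.append((f.frame_index, f.time))
        for cid, row in f.cells.iterrows():
            cells_rows.append((f.frame_index, cid, row["x"], row["y"], row["area"]))
        for cid, nbrs in f.neighbors.items():
            for pos, n in enumerate(nbrs):
                nb_rows.append((f.frame_index, cid, n, pos))
        for vid, row in f.vertices.iterrows():
            vx_rows.append((f.frame_index, vid, row["x"], row["y"], int(row["boundary"])))
        for vid, cells in f.vertex_cells.items():
            for pos, cid in enumerate(cells):
                vc_rows.append((f.frame_index, vid, cid, pos))
        for cid, vids in f.cell_vertices.items():
            for pos, vid in enumerate(vids):
                cv_rows.append((f.frame_index, cid, vid, pos))
    roi_rows = [
        (roi_id, cid) for roi_id, cells in sorted(tissue.roi.items()) for cid in sorted(cells)
    ]
    return {
        "frames": pd.DataFrame(frames_rows, columns=SCHEMA["frames"]),
        "cells": pd.DataFrame(cells_rows, columns=SCHEMA["cells"]),
        "neighbors": pd.DataFrame(nb_rows, columns=SCHEMA["neighbors"]),
        "vertices": pd.DataFrame(vx_rows, columns=SCHEMA["vertices"]),
        "vertex_cells": pd.DataFrame(vc_rows, columns=SCHEMA["vertex_cells"]),
        "cell_vertices": pd.DataFrame(cv_rows, columns=SCHEMA["cell_vertices"]),
        "lineage": tissue.lineage[SCHEMA["lineage"]].copy(),
        "extrusions": tissue.extrusions[SCHEMA["extrusions"]].copy(),
        "t1_events": tissue.t1_events[SCHEMA["t1_events"]].copy(),
        "roi": pd.DataFrame(roi_rows, columns=SCHEMA["roi"]),
    }


def _tables_to_tissue(tables):
    missing = set(SCHEMA) - set(tables)
    if missing:
        raise SchemaError(f"missing tables: {sorted(missing)}")
    for name, cols in SCHEMA.items():
        absent = set(cols) - set(tables[name].columns)
        if absent:
            raise SchemaError(f"table {name!r} missing columns {sorted(absent)}")
    frames = []
    ftab = tables["frames"].sort_values("frame")
    cells_g = dict(list(tables["cells"].groupby("frame")))
    nb_g = dict(list(tables["neighbors"].groupby("frame")))
    vx_g = dict(list(tables["vertices"].groupby("frame")))
    vc_g = dict(list(tables["vertex_cells"].groupby("frame")))
    cv_g = dict(list(tables["cell_vertices"].groupby("frame")))
    for _, frow in ftab.iterrows():
        fi = int(frow["frame"])
        cells = (
            cells_g[fi]
            .astype({"cell_id": int})
            .set_index("cell_id")[["x", "y", "area"]]
            .sort_index()
        )
        neighbors = {
            int(cid): [int(v) for v in grp.sort_values("position")["neighbor_id"]]
            for cid, grp in nb_g[fi].groupby("cell_id")
        }
        for cid in cells.index:
            neighbors.setdefault(int(cid), [])
        vertices = (
            vx_g[fi]
            .astype({"vertex_id": int, "boundary": bool})
            .set_index("vertex_id")[["x", "y", "boundary"]]
            .sort_index()
        )
        vertex_cells = {
            int(vid): tuple(int(v) for v in grp.sort_values("position")["cell_id"])
            for vid, grp in vc_g[fi].groupby("vertex_id")
        }
        cell_vertices = {
            int(cid): tuple(int(v) for v in grp.sort_values("position")["vertex_id"])
            for cid, grp in cv_g[fi].groupby("cell_id")
        }
        frames.append(
            CellNetworkFrame(
                frame_index=fi,
                time=float(frow["time_hapf"]),
                cells=cells,
                neighbors=neighbors,
                vertices=vertices,
                vertex_cells=vertex_cells,
                cell_vertices=cell_vertices,
            )
        )
    roi = {
        str(roi_id): set(int(c) for c in grp["cell_id"])
        for roi_id, grp in tables["roi"].groupby("roi_id")
    }
    int_cols = {
        "lineage": ["mother", "daughter_1", "daughter_2", "frame"],
        "extrusions": ["cell_id", "frame"],
        "t1_events": ["frame", "lost_1", "lost_2", "gained_1", "gained_2"],
    }
    evt = {}
    for name, cols in int_cols.items():
        t = tables[name][SCHEMA[name]].reset_index(drop=True)
        if len(t):
            t = t.astype({c: int for c in cols})
        evt[name] = t
    return TrackedTissue(
        frames=frames,
        lineage=evt["lineage"],
        extrusions=evt["extrusions"],
        t1_events=evt["t1_events"],
        roi=roi,
    )


def write_tracked_tissue(tissue, path):
    """Write a tissue to ``path``: a ``.sqlite`` file or a CSV directory."""
    path = Path(path)
    tables = _tissue_to_tables(tissue)
    if path.suffix == ".sqlite":
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            for name, tab in tables.items():
                tab.to_sql(name, con, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(path / f"{name}.csv", index=False)
    return path


def read_tracked_tissue(path, validate=True):
    """Read a tissue written by :func:`write_tracked_tissue`.

    Raises :class:`SchemaError` for missing tables/columns, topological
    inconsistencies, or event records that contradict the frame topology.
    """
    path = Path(path)
    if path.is_dir():
        tables = {}
        for name in SCHEMA:
            f = path / f"{name}.csv"
            if not f.exists():
                raise SchemaError(f"missing table file {f.name}")
            tables[name] = pd.read_csv(f)
    elif path.suffix == ".sqlite":
        with sqlite3.connect(path) as con:
            names = [
                r[0]
                for r in con.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            ]
            tables = {n: pd.read_sql(f"SELECT * FROM {n}", con) for n in names}
    else:
        raise SchemaError(f"unknown tissue container: {path}")
    tissue = _tables_to_tissue(tables)
    if validate:
        tissue.validate()
    return tissue


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_events(tissue):
    """Populate T1/division/extrusion records by diffing adjacent frames.

    Divisions are read off the lineage map (mother disappears, daughters
    appear); a cell id that disappears without daughters is an extrusion.  A
    T1 is a lost cell-cell contact paired with a reciprocal gained contact
    among the same four-cell quartet: the gained pair are common neighbors
    of the lost pair before the exchange (or vice versa).  Contact changes
    that cannot be paired are collected as ``ambiguous`` rather than being
    silently resolved.

    Returns a new :class:`TrackedTissue`; the input is not modified.  The
    ambiguous record list is attached as attribute ``ambiguous_events``.
    """
    mothers = {int(r["mother"]): (int(r["daughter_1"]), int(r["daughter_2"]), int(r["frame"]))
               for _, r in tissue.lineage.iterrows()}
    t1_rows, ext_rows, ambiguous = [], [], []
    for pre, post in zip(tissue.frames[:-1], tissue.frames[1:]):
        fi = post.frame_index
        pre_ids = set(pre.cells.index)
        post_ids = set(post.cells.index)
        disappeared = pre_ids - post_ids
        appeared = post_ids - pre_ids
        divided = set()
        daughters = set()
        for cid in disappeared:
            if cid in mothers:
                d1, d2, _ = mothers[cid]
                if d1 in appeared and d2 in appeared:
                    divided.add(cid)
                    daughters |= {d1, d2}
                    continue
            ext_rows.append((cid, fi))
        unexplained_new = appeared - daughters
        for cid in unexplained_new:
            ambiguous.append(("new-cell", fi, (cid,)))
        churn = disappeared | appeared
        pre_contacts = {p for p in pre.contacts() if not (p & churn)}
        post_contacts = {p for p in post.contacts() if not (p & churn)}
        lost = pre_contacts - post_contacts
        gained = post_contacts - pre_contacts
        used_gains = set()
        for lpair in sorted(lost, key=sorted):
            a, b = sorted(lpair)
            common = set(pre.neighbors[a]) & set(pre.neighbors[b])
            # a reciprocal gain must connect two common neighbors of (a, b)
            matches = [g for g in gained if g not in used_gains and set(g) <= common]
            if len(matches) == 1:
                g = matches[0]
                used_gains.add(g)
                g1, g2 = sorted(g)
                t1_rows.append((fi, a, b, g1, g2))
            else:
                ambiguous.append(("lost-contact", fi, (a, b)))
        for g in sorted(gained - used_gains, key=sorted):
            ambiguous.append(("gained-contact", fi, tuple(sorted(g))))
    out = TrackedTissue(
        frames=tissue.frames,
        lineage=tissue.lineage.copy(),
        extrusions=pd.DataFrame(ext_rows, columns=SCHEMA["extrusions"]),
        t1_events=pd.DataFrame(t1_rows, columns=SCHEMA["t1_events"]),
        roi=dict(tissue.roi),
    )
    out.ambiguous_events = ambiguous
    return out


# ---------------------------------------------------------------------------
# Area balance (isotropic decomposition)
# ---------------------------------------------------------------------------

def area_balance(tissue, roi=None):
    """Decompose the tissue area expansion rate into cellular contributions.

    Per interval the expansion rate ``v = dln(A)/dt`` of the tracked region
    splits into the mean-cell-area term ``dln(a)/dt``, the division rate
    ``k_d`` and the extrusion rate ``k_e``::

        v = dln(a)/dt + k_d - k_e

    All rates use a log-difference discretization:
    ``k_d = ln((N + n_d)/N)/dt`` and ``k_e = ln((N + n_d)/(N + n_d - n_e))/dt``
    with ``N`` the cell count at interval start and ``n_d``/``n_e`` the
    division/extrusion counts, so the identity closes exactly per interval.

    Returns a DataFrame with per-interval rates, the closure residual and
    cumulative curves ``ln(A/A0)`` per term.
    """
    cells0 = tissue.roi_cells(roi)
    # track the region forward through divisions/extrusions
    desc = {int(r["mother"]): (int(r["daughter_1"]), int(r["daughter_2"]))
            for _, r in tissue.lineage.iterrows()}
    div_frame = {int(r["mother"]): int(r["frame"]) for _, r in tissue.lineage.iterrows()}
    ext_frame = {int(r["cell_id"]): int(r["frame"]) for _, r in tissue.extrusions.iterrows()}

    rows = []
    members = set(cells0)
    prev = tissue.frames[0]
    missing = members - set(prev.cells.index)
    if missing:
        raise SchemaError(f"ROI cells untracked at first frame: {sorted(missing)[:5]}")
    for post in tissue.frames[1:]:
        n_pre = len(members)
        a_pre = prev.cells.loc[sorted(members), "area"].mean()
        nxt = set()
        n_div = n_ext = 0
        for cid in members:
            if cid in post.cells.index:
                nxt.add(cid)
            elif cid in desc and div_frame[cid] == post.frame_index:
                n_div += 1
                nxt |= set(desc[cid])
            elif cid in ext_frame and ext_frame[cid] == post.frame_index:
                n_ext += 1
            else:
                raise SchemaError(
                    f"ROI cell {cid} lost at frame {post.frame_index} without event record"
                )
        missing = nxt - set(post.cells.index)
        if missing:
            raise SchemaError(f"ROI daughters missing: {sorted(missing)[:5]}")
        n_post = len(nxt)
        a_post = post.cells.loc[sorted(nxt), "area"].mean()
        dt = post.time - prev.time
        kd = np.log((n_pre + n_div) / n_pre) / dt
        ke = np.log((n_pre + n_div) / (n_pre + n_div - n_ext)) / dt
        da = np.log(a_post / a_pre) / dt
        v = np.log((n_post * a_post) / (n_pre * a_pre)) / dt
        rows.append(
            dict(
                time=0.5 * (prev.time + post.time),
                dt=dt,
                v=v,
                cell_area_rate=da,
                k_d=kd,
                k_e=ke,
                residual=v - (da + kd - ke),
                n_cells=n_pre,
                n_divisions=n_div,
                n_extrusions=n_ext,
            )
        )
        members = nxt
        prev = post
    out = pd.DataFrame(rows)
    for col, cum in [
        ("v", "cum_v"),
        ("cell_area_rate", "cum_cell_area"),
        ("k_d", "cum_k_d"),
        ("k_e", "cum_k_e"),
    ]:
        out[cum] = np.cumsum(out[col] * out["dt"])
    return out


def variance_ratio(final_contributions):
    """Reproducibility statistic across replicates.

    ``final_contributions`` is an (n_replicates, n_contributions) array of
    final-time cumulative contributions.  Returns
    ``sum_i Var(c_i) / Var(sum_i c_i)`` (variances across replicates).  A
    ratio of ~1 means independent contributions; a large ratio means the
    contributions co-vary so that their sum is more reproducible than the
    parts.  If the variance of the sum vanishes the ratio is ``inf``.
    """
    c = np.asarray(final_contributions, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 replicates of the contribution vector")
    num = np.var(c, axis=0, ddof=1).sum()
    den = np.var(c.sum(axis=1), ddof=1)
    if den == 0.0:
        return np.inf
    return num / den
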