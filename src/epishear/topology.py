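"""Shear contributions of topological changes via retriangulation jumps.

When the cell network changes topology (T1 neighbor exchange, division,
extrusion) the triangulation changes discontinuously while the tissue does
not deform.  The shear contributed by an event class is minus the jump in
the area-weighted mean triangle elongation caused by replacing the
affected triangles, divided by the interval.

The jump of each event is evaluated through the intermediate-state
bookkeeping: the triangles an event destroys are taken at the pre-event
frame (their last observed state) and the triangles it creates at the
post-event frame (their first state), each mean-centered on the
persistent-triangle average and normalized by that frame's triangulated
area, with the post-frame term corotated by the mean tissue rotation.
With this convention the event contributions are exactly additive: the
shear decomposition closes to machine precision whenever every triangle
that appears or disappears is attributed to an event, and any
unattributed change surfaces in the closure residual instead of being
silently redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import IntervalKinematics
from .nematic import rotate_nematic
from .triangulation import Triangulation

__all__ = [
    "TopologicalContribution",
    "topological_contribution",
    "bond_orientation",
    "gain_loss_histograms",
    "t1_rate",
    "correlation_attribution",
    "upcoming_t1_rows",
]


@dataclass
class TopologicalContribution:
    """Per-interval shear rates from each event class (nematic xx/xy).

    ``unattributed`` is minus the jump rate of triangle turnover not
    assigned to any event (boundary churn, ambiguous clusters); it ends
    up in the closure residual by construction.
    """

    t1: np.ndarray
    division: np.ndarray
    extrusion: np.ndarray
    unattributed: np.ndarray
    n_t1: int = 0
    n_division: int = 0
    n_extrusion: int = 0
    n_unattributed: int = 0
    skipped: list = field(default_factory=list)

    @property
    def total(self):
        return self.t1 + self.division + self.extrusion


def topological_contribution(
    frame1,
    frame2,
    tri1: Triangulation,
    tri2: Triangulation,
    kin: IntervalKinematics,
    events,
    dt,
):
    """Shear contributions (T, C, E) of the events between two frames.

    ``events`` is a dict with optional keys ``t1`` (rows of
    ``(lost_1, lost_2, gained_1, gained_2)``), ``division``
    (``(mother, daughter_1, daughter_2)``) and ``extrusion``
    (``(cell_id,)``).  ``tri1``/``tri2`` are the (possibly ROI-restricted)
    triangulations bracketing the interval and ``kin`` the matched-triangle
    kinematics between them.  For each event, the destroyed triangles are
    taken from ``tri1`` and the created ones from ``tri2``; the jump is
    the change in their mean-centered area-weighted elongation, the
    post-frame term corotated by the mean rotation.  Events whose
    triangles cannot be located are skipped and reported.
    """
    from .triangulation import mean_elongation

    valid1 = ~tri1.degenerate
    valid2 = ~tri2.degenerate
    w1 = float(tri1.area[valid1].sum())
    w2 = float(tri2.area[valid2].sum())
    unmatched1 = valid1.copy()
    unmatched2 = valid2.copy()
    if kin is not None and len(kin) > 0:
        qm1 = np.array(
            [np.average(kin.q_xx1, weights=kin.area1), np.average(kin.q_xy1, weights=kin.area1)]
        )
        qm2 = np.array(
            [np.average(kin.q_xx2, weights=kin.area2), np.average(kin.q_xy2, weights=kin.area2)]
        )
        dth = kin.mean_omega * dt
        unmatched1[kin.idx1] = False
        unmatched2[kin.idx2] = False
    else:
        # event-only patch: no persistent triangles to center on; a common
        # reference makes the jump equal the full mean-elongation change
        qm1 = qm2 = np.array(mean_elongation(tri1))
        dth = 0.0

    out = TopologicalContribution(
        t1=np.zeros(2),
        division=np.zeros(2),
        extrusion=np.zeros(2),
        unattributed=np.zeros(2),
    )

    def centered_sum(tri, rows, qm, w):
        a = tri.area[rows]
        return np.array(
            [np.sum(a * (tri.q_xx[rows] - qm[0])), np.sum(a * (tri.q_xy[rows] - qm[1]))]
        ) / w

    def jump(old_rows, new_rows):
        s_old = centered_sum(tri1, old_rows, qm1, w1)
        s_new = centered_sum(tri2, new_rows, qm2, w2)
        rxx, rxy = rotate_nematic(s_new[0], s_new[1], -dth)
        return np.array([rxx, rxy]) - s_old

    def take(mask, rows):
        rows = np.asarray(rows, dtype=int)
        sel = rows[mask[rows]]
        mask[sel] = False
        return sel

    def rows_with_pair(tri, a, b):
        has = (tri.cell_triplets == a).any(axis=1) & (tri.cell_triplets == b).any(axis=1)
        return np.nonzero(has)[0]

    for a, b, c, d in events.get("t1", []):
        old_rows = take(unmatched1, rows_with_pair(tri1, a, b))
        new_rows = take(unmatched2, rows_with_pair(tri2, c, d))
        if len(old_rows) == 0 and len(new_rows) == 0:
            out.skipped.append(("t1", (a, b, c, d)))
            continue
        out.t1 -= jump(old_rows, new_rows) / dt
        out.n_t1 += 1

    for mother, d1, d2 in events.get("division", []):
        old_rows = take(unmatched1, tri1.rows_with_cell(mother))
        new_rows = take(
            unmatched2,
            np.unique(
                np.concatenate([tri2.rows_with_cell(d1), tri2.rows_with_cell(d2)])
            ),
        )
        if len(old_rows) == 0 and len(new_rows) == 0:
            out.skipped.append(("division", (mother, d1, d2)))
            continue
        out.division -= jump(old_rows, new_rows) / dt
        out.n_division += 1

    for (cell,) in events.get("extrusion", []):
        old_rows = take(unmatched1, tri1.rows_with_cell(cell))
        ring = set(frame1.neighbors.get(cell, []))
        cand = np.nonzero(
            np.array([set(t) <= ring for t in map(tuple, tri2.cell_triplets)], dtype=bool)
        )[0]
        new_rows = take(unmatched2, cand)
        if len(old_rows) == 0 and len(new_rows) == 0:
            out.skipped.append(("extrusion", (cell,)))
            continue
        out.extrusion -= jump(old_rows, new_rows) / dt
        out.n_extrusion += 1

    left1 = np.nonzero(unmatched1)[0]
    left2 = np.nonzero(unmatched2)[0]
    if len(left1) or len(left2):
        out.unattributed = -jump(left1, left2) / dt
        out.n_unattributed = len(left1) + len(left2)
    return out


# ---------------------------------------------------------------------------
# bond-orientation statistics
# ---------------------------------------------------------------------------

def bond_orientation(cell_a, cell_b, tri: Triangulation):
    """Orientation in [0, pi) of the connector of the two triangle centers
    adjacent to the bond between ``cell_a`` and ``cell_b``.

    The connector of the two triangle centroids is a robust proxy for the
    (often very short) cell-boundary orientation; for a straight bond it
    is orthogonal to the bond itself.  Raises for boundary bonds (fewer
    than two adjacent triangles).
    """
    has = (tri.cell_triplets == cell_a).any(axis=1) & (
        tri.cell_triplets == cell_b
    ).any(axis=1)
    rows = np.nonzero(has)[0]
    if len(rows) < 2:
        raise ValueError(f"bond {cell_a}-{cell_b} is not interior")
    cent = tri.corners[rows[:2]].mean(axis=1)
    d = cent[1] - cent[0]
    return float(np.arctan2(d[1], d[0]) % np.pi)


def _all_connection_angles(tri: Triangulation):
    """Connector angles of every interior bond of a triangulation."""
    pairs = {}
    for row, t in enumerate(map(tuple, tri.cell_triplets)):
        for i in range(3):
            for j in range(i + 1, 3):
                pairs.setdefault(tuple(sorted((t[i], t[j]))), []).append(row)
    angles = []
    for rows in pairs.values():
        if len(rows) == 2:
            c = tri.corners[rows].mean(axis=1)
            d = c[1] - c[0]
            angles.append(np.arctan2(d[1], d[0]) % np.pi)
    return np.array(angles)


def gain_loss_histograms(tissue, triangulations, t_center, window=1.5, n_bins=12):
    """Effective angular proportions of lost and gained cell connections.

    For the T1 events within ``t_center +/- window/2`` (hours), computes
    the angular distribution of lost connections (evaluated in the
    pre-event frame) and gained connections (post-event frame) and
    subtracts the angular distribution of all connections pooled over the
    same frames.  Angles are connector orientations mod pi in
    ``n_bins`` equal bins (default 15 degrees).

    Returns a DataFrame with bin centers and effective proportions; raises
    if no events fall in the window.
    """
    by_index = {f.frame_index: i for i, f in enumerate(tissue.frames)}
    times = tissue.times
    lost_angles, gained_angles, all_angles = [], [], []
    frames_used = set()
    for _, row in tissue.t1_events.iterrows():
        fi = int(row["frame"])
        if fi not in by_index or (by_index[fi] - 1) < 0:
            continue
        t = times[by_index[fi]]
        if abs(t - t_center) > window / 2.0:
            continue
        tri_pre = triangulations[by_index[fi] - 1]
        tri_post = triangulations[by_index[fi]]
        try:
            lost_angles.append(
                bond_orientation(int(row["lost_1"]), int(row["lost_2"]), tri_pre)
            )
            gained_angles.append(
                bond_orientation(int(row["gained_1"]), int(row["gained_2"]), tri_post)
            )
        except ValueError:
            continue
        frames_used.update((by_index[fi] - 1, by_index[fi]))
    if not lost_angles and not gained_angles:
        raise ValueError("no T1 events in window")
    for i in sorted(frames_used):
        all_angles.append(_all_connection_angles(triangulations[i]))
    all_angles = np.concatenate(all_angles) if all_angles else np.array([])
    edges = np.linspace(0.0, np.pi, n_bins + 1)

    def prop(a):
        if len(a) == 0:
            return np.zeros(n_bins)
        h, _ = np.histogram(a, bins=edges)
        return h / h.sum()

    base = prop(all_angles)
    return pd.DataFrame(
        {
            "angle": 0.5 * (edges[:-1] + edges[1:]),
            "effective_lost": prop(np.array(lost_angles)) - base,
            "effective_gained": prop(np.array(gained_angles)) - base,
            "n_lost": len(lost_angles),
            "n_gained": len(gained_angles),
        }
    )


def t1_rate(tissue, window=1.0):
    """T1 transitions per cell per hour in sliding windows.

    Returns a DataFrame (time, rate) on the frame time base.
    """
    times = tissue.times
    by_index = {f.frame_index: i for i, f in enumerate(tissue.frames)}
    ev_times = np.array(
        [times[by_index[int(f)]] for f in tissue.t1_events["frame"] if int(f) in by_index]
    )
    n_cells = np.array([len(f.cells) for f in tissue.frames], dtype=float)
    rows = []
    for i, t in enumerate(times):
        lo, hi = t - window / 2.0, t + window / 2.0
        span = min(hi, times[-1]) - max(lo, times[0])
        if span <= 0:
            continue
        n_ev = int(np.sum((ev_times >= lo) & (ev_times <= hi))) if len(ev_times) else 0
        rows.append((t, n_ev / (n_cells[i] * span)))
    return pd.DataFrame(rows, columns=["time", "rate"])


# ---------------------------------------------------------------------------
# correlation-shear attribution
# ---------------------------------------------------------------------------

def upcoming_t1_rows(tissue, tri: Triangulation, frame_pos, horizon=9):
    """Rows of triangles that will disappear due to a T1 within ``horizon``
    frames after frame position ``frame_pos`` (offline forward knowledge).

    Returns ``(rows, truncated)`` where ``truncated`` flags a horizon
    reaching beyond the end of the video.
    """
    frame_indices = [f.frame_index for f in tissue.frames]
    fi = frame_indices[frame_pos]
    horizon_end = fi + horizon
    truncated = horizon_end > frame_indices[-1]
    sel = tissue.t1_events[
        (tissue.t1_events["frame"] > fi) & (tissue.t1_events["frame"] <= horizon_end)
    ]
    rows = set()
    for _, row in sel.iterrows():
        a, b = int(row["lost_1"]), int(row["lost_2"])
        has = (tri.cell_triplets == a).any(axis=1) & (tri.cell_triplets == b).any(axis=1)
        rows.update(np.nonzero(has)[0].tolist())
    return np.array(sorted(rows), dtype=int), truncated


def correlation_attribution(kin: IntervalKinematics, flagged_rows):
    """Partition the covariance correlation term over a triangle subset.

    The correlation shear is a weighted covariance; with means shared
    across the partition it is additive over subsets, so the flagged
    subset's share plus the remainder equals the total.  ``flagged_rows``
    indexes into the matched-triangle arrays of ``kin``.

    Returns a dict with nematic pairs ``d_subset``, ``d_rest``, ``d_total``
    and the subset ``area_fraction``.
    """
    n = len(kin)
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(flagged_rows, dtype=int)] = True
    w = kin.area1 / kin.area1.sum()
    mv = np.sum(w * kin.v)
    mo = np.sum(w * kin.omega)
    mqxx = np.sum(w * kin.q_xx1)
    mqxy = np.sum(w * kin.q_xy1)

    def part(sel):
        ws, vs, os_ = w[sel], kin.v[sel], kin.omega[sel]
        qx, qy = kin.q_xx1[sel], kin.q_xy1[sel]
        dxx = -np.sum(ws * (vs - mv) * (qx - mqxx)) + 2.0 * np.sum(
            ws * (os_ - mo) * (qy - mqxy)
        )
        dxy = -np.sum(ws * (vs - mv) * (qy - mqxy)) - 2.0 * np.sum(
            ws * (os_ - mo) * (qx - mqxx)
        )
        return np.array([dxx, dxy])

    d_sub = part(mask)
    d_rest = part(~mask)
    return {
        "d_subset": d_sub,
        "d_rest": d_rest,
        "d_total": d_sub + d_rest,
        "area_fraction": float(kin.area1[mask].sum() / kin.area1.sum()),
    }
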