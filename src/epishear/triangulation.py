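"""Triangle tiling of a cell network and triangle state tensors.

Every interior vertex touching exactly three cells yields one triangle whose
corners are the three cell centers; a vertex touching k > 3 cells is
decomposed into k - 2 triangles by a fan rooted at the lowest incident
cell id (deterministic and area-tiling).  The triangles tile the region
spanned by the cell centers without gaps or overlaps.

Each triangle's shape is encoded by factoring the linear map ``S`` that
takes a fixed unit-area equilateral reference triangle (one edge along +x)
onto the triangle::

    S = sqrt(A) * exp(Q) * R(theta)

with ``A`` the triangle area, ``Q`` a symmetric traceless (nematic)
elongation tensor in the lab frame and ``R`` a rotation.  An equilateral
triangle of any size and orientation has Q = 0; stretching the material by
``diag(e^q, e^-q)`` adds q to Q_xx.  The decomposition is unique for
non-degenerate (positive-area) triangles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nematic import exp_traceless, log_spd_unimodular

__all__ = [
    "REFERENCE_CORNERS",
    "Triangulation",
    "triangulate_frame",
    "triangle_state",
    "triangle_corners_from_state",
    "mean_elongation",
    "cell_elongation",
]

# unit-area equilateral reference triangle, first edge along +x, CCW
_side = np.sqrt(4.0 / np.sqrt(3.0))
REFERENCE_CORNERS = np.array(
    [
        [0.0, 0.0],
        [_side, 0.0],
        [0.5 * _side, 0.5 * _side * np.sqrt(3.0)],
    ]
)
_REF_EDGES = np.column_stack(
    (REFERENCE_CORNERS[1] - REFERENCE_CORNERS[0], REFERENCE_CORNERS[2] - REFERENCE_CORNERS[0])
)
_REF_EDGES_INV = np.linalg.inv(_REF_EDGES)


@dataclass
class Triangulation:
    """All triangles of one frame, stored as parallel arrays.

    Attributes
    ----------
    frame_index : int
    cell_triplets : (n, 3) int array
        Cell ids at the three corners, in CCW geometric order.
    corners : (n, 3, 2) float array
    area : (n,) float array  [µm²]
    theta : (n,) float array  [rad]
    q_xx, q_xy : (n,) float arrays
        Components of the elongation nematic.
    vertex_ids : (n,) int array
        Originating network vertex of each triangle.
    degenerate : (n,) bool array
        Zero-area triangles (collinear centers); excluded from averages.
    """

    frame_index: int
    cell_triplets: np.ndarray
    corners: np.ndarray
    area: np.ndarray
    theta: np.ndarray
    q_xx: np.ndarray
    q_xy: np.ndarray
    vertex_ids: np.ndarray
    degenerate: np.ndarray

    def __len__(self):
        return len(self.area)

    @property
    def centroids(self):
        return self.corners.mean(axis=1)

    @property
    def total_area(self):
        return float(self.area[~self.degenerate].sum())

    def triplet_index(self):
        """dict mapping sorted cell-id triplet -> row index."""
        return {
            tuple(sorted(t)): i for i, t in enumerate(map(tuple, self.cell_triplets))
        }

    def rows_with_cell(self, cell_id):
        return np.nonzero((self.cell_triplets == cell_id).any(axis=1))[0]

    def to_frame(self):
        """Tidy per-triangle DataFrame."""
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "vertex_id": self.vertex_ids,
                "cell_1": self.cell_triplets[:, 0],
                "cell_2": self.cell_triplets[:, 1],
                "cell_3": self.cell_triplets[:, 2],
                "area": self.area,
                "theta": self.theta,
                "q_xx": self.q_xx,
                "q_xy": self.q_xy,
                "degenerate": self.degenerate,
            }
        )


def _states_from_corners(corners):
    """Vectorized state decomposition for (n, 3, 2) corner arrays.

    Corners must be CCW (positive area).  Returns (area, theta, qxx, qxy,
    degenerate).
    """
    e1 = corners[:, 1] - corners[:, 0]
    e2 = corners[:, 2] - corners[:, 0]
    # S maps reference edges onto actual edges
    s = np.einsum("nij,jk->nik", np.stack((e1, e2), axis=-1), _REF_EDGES_INV)
    det = s[:, 0, 0] * s[:, 1, 1] - s[:, 0, 1] * s[:, 1, 0]
    degenerate = det <= 1e-12 * np.maximum(1.0, np.einsum("nij,nij->n", s, s))
    safe_det = np.where(degenerate, 1.0, det)
    # left Cauchy-Green tensor, normalized to det 1: B = S S^T / det(S)
    b = np.einsum("nij,nkj->nik", s, s) / safe_det[:, None, None]
    qxx, qxy = log_spd_unimodular(b)
    qxx, qxy = 0.5 * qxx, 0.5 * qxy
    # rotation: R = exp(-Q) S / sqrt(det)
    r = np.einsum(
        "nij,njk->nik", exp_traceless(-qxx, -qxy), s / np.sqrt(safe_det)[:, None, None]
    )
    theta = np.arctan2(r[:, 1, 0], r[:, 0, 0])
    area = np.where(degenerate, 0.0, det)  # reference triangle has unit area
    qxx = np.where(degenerate, 0.0, qxx)
    qxy = np.where(degenerate, 0.0, qxy)
    theta = np.where(degenerate, 0.0, theta)
    return area, theta, qxx, qxy, degenerate


def triangle_state(corners):
    """State tensor (area, theta, Q) of a single CCW triangle.

    Raises ``ValueError`` for collinear corners.
    """
    corners = np.asarray(corners, dtype=float)[None]
    area, theta, qxx, qxy, degen = _states_from_corners(corners)
    if degen[0]:
        raise ValueError("degenerate (collinear or clockwise) triangle")
    return float(area[0]), float(theta[0]), float(qxx[0]), float(qxy[0])


def triangle_corners_from_state(area, theta, q_xx, q_xy, origin=(0.0, 0.0)):
    """Reconstruct CCW corners from (A, theta, Q), up to translation."""
    s = np.sqrt(area) * exp_traceless(np.array([q_xx]), np.array([q_xy]))[0]
    c, si = np.cos(theta), np.sin(theta)
    s = s @ np.array([[c, -si], [si, c]])
    return np.asarray(origin, dtype=float) + REFERENCE_CORNERS @ s.T


def triangulate_frame(frame, include_boundary=False):
    """Tile a :class:`~epishear.network.CellNetworkFrame` with triangles.

    One triangle per interior 3-fold vertex; k-fold vertices (k > 3) are
    fanned from the lowest incident cell id.  Vertices flagged as boundary
    are skipped unless ``include_boundary`` is set (margin cells are
    excluded from the analysis region, matching the tracked-ROI handling).
    """
    centers = frame.cells[["x", "y"]]
    triplets, vertex_ids = [], []
    boundary = frame.vertices["boundary"].astype(bool)
    for vid in sorted(frame.vertex_cells):
        if not include_boundary and boundary.loc[vid]:
            continue
        cells = frame.vertex_cells[vid]
        k = len(cells)
        if k < 3:
            continue
        if k == 3:
            triplets.append(tuple(cells))
            vertex_ids.append(vid)
        else:
            # fan the k-gon of adjacent cell centers from the lowest cell id
            rot = cells.index(min(cells))
            cyc = cells[rot:] + cells[:rot]
            for i in range(1, k - 1):
                triplets.append((cyc[0], cyc[i], cyc[i + 1]))
                vertex_ids.append(vid)
    if not triplets:
        return Triangulation(
            frame_index=frame.frame_index,
            cell_triplets=np.empty((0, 3), dtype=int),
            corners=np.empty((0, 3, 2)),
            area=np.empty(0),
            theta=np.empty(0),
            q_xx=np.empty(0),
            q_xy=np.empty(0),
            vertex_ids=np.empty(0, dtype=int),
            degenerate=np.empty(0, dtype=bool),
        )
    triplets = np.array(triplets, dtype=int)
    corners = centers.loc[triplets.ravel()].to_numpy(dtype=float).reshape(-1, 3, 2)
    # enforce CCW corner order (swap last two corners where clockwise)
    e1 = corners[:, 1] - corners[:, 0]
    e2 = corners[:, 2] - corners[:, 0]
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    flip = cross < 0
    corners[flip] = corners[flip][:, [0, 2, 1]]
    triplets[flip] = triplets[flip][:, [0, 2, 1]]
    area, theta, qxx, qxy, degen = _states_from_corners(corners)
    return Triangulation(
        frame_index=frame.frame_index,
        cell_triplets=triplets,
        corners=corners,
        area=area,
        theta=theta,
        q_xx=qxx,
        q_xy=qxy,
        vertex_ids=np.array(vertex_ids, dtype=int),
        degenerate=degen,
    )


def mean_elongation(tri, rows=None):
    """Area-weighted mean elongation nematic ``(Q_xx, Q_xy)``.

    Area weighting makes the triangle average equal the tissue-scale
    deformation of the tiled region (the convention used throughout the
    package).  Degenerate triangles are excluded.
    """
    if len(tri) == 0:
        raise ValueError("empty triangulation")
    mask = ~tri.degenerate
    if rows is not None:
        sel = np.zeros(len(tri), dtype=bool)
        sel[rows] = True
        mask &= sel
    w = tri.area[mask]
    if w.sum() == 0:
        raise ValueError("no valid triangles to average")
    return (
        float(np.average(tri.q_xx[mask], weights=w)),
        float(np.average(tri.q_xy[mask], weights=w)),
    )


def cell_elongation(tri):
    """Per-cell elongation: area-weighted mean over each cell's triangles.

    Returns a DataFrame indexed by cell id with columns ``q_xx, q_xy``.
    """
    mask = ~tri.degenerate
    ids = tri.cell_triplets[mask].ravel()
    w = np.repeat(tri.area[mask], 3)
    qxx = np.repeat(tri.q_xx[mask], 3)
    qxy = np.repeat(tri.q_xy[mask], 3)
    df = pd.DataFrame({"cell_id": ids, "w": w, "wqxx": w * qxx, "wqxy": w * qxy})
    g = df.groupby("cell_id").sum()
    return pd.DataFrame(
        {"q_xx": g["wqxx"] / g["w"], "q_xy": g["wqxy"] / g["w"]}
    )
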