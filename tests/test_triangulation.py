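import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon
from shapely.ops import unary_union

from epishear.synth import canonical_t1_frame, hex_tissue
from epishear.triangulation import (
    REFERENCE_CORNERS,
    cell_elongation,
    mean_elongation,
    triangle_corners_from_state,
    triangle_state,
    triangulate_frame,
)


def test_hex_lattice_triangles_equilateral(hex_static):
    """Interior vertices of a regular hex lattice give Q = 0 triangles."""
    tri = triangulate_frame(hex_static.frames[0])
    n_interior = sum(
        1
        for v, cells in hex_static.frames[0].vertex_cells.items()
        if len(cells) >= 3 and not hex_static.frames[0].vertices.loc[v, "boundary"]
    )
    assert len(tri) == n_interior
    assert np.max(np.hypot(tri.q_xx, tri.q_xy)) < 1e-9
    assert (tri.area > 0).all()


def test_fourfold_vertex_fans_into_two_triangles():
    frame = canonical_t1_frame(0.5)
    tri = triangulate_frame(frame)
    assert len(tri) == 2
    # fan tiles the quad of the four centers without gap or overlap
    quad_area = unary_union(
        [Polygon(tri.corners[i]) for i in range(2)]
    ).area
    assert tri.total_area == pytest.approx(quad_area, rel=1e-9)


def test_tiling_no_gaps_no_overlaps():
    """Sum of triangle areas equals the area of the union region."""
    tissue = hex_tissue(rows=7, cols=7, disorder=0.12, seed=5)
    tri = triangulate_frame(tissue.frames[0])
    union = unary_union([Polygon(c) for c in tri.corners])
    assert tri.total_area == pytest.approx(union.area, rel=1e-6)


def test_triangle_state_equilateral_is_isotropic():
    a, theta, qxx, qxy = triangle_state(3.0 * REFERENCE_CORNERS + 7.0)
    assert a == pytest.approx(9.0)
    assert (qxx, qxy) == pytest.approx((0.0, 0.0), abs=1e-12)


def test_triangle_state_pure_stretch():
    """diag(e^q, e^-q) applied to an equilateral gives Q_xx = q."""
    q = 0.3
    stretched = REFERENCE_CORNERS @ np.diag([np.exp(q), np.exp(-q)]).T
    a, theta, qxx, qxy = triangle_state(stretched)
    assert qxx == pytest.approx(q, abs=1e-12)
    assert qxy == pytest.approx(0.0, abs=1e-12)
    assert a == pytest.approx(1.0, abs=1e-12)


def test_collinear_corners_rejected():
    with pytest.raises(ValueError):
        triangle_state([[0, 0], [1, 0], [2, 0]])


@settings(deadline=None, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=6, max_size=6
    )
)
def test_state_roundtrip_recovers_corners(flat):
    """(A, theta, Q) -> corners -> state reproduces the triangle."""
    corners = np.array(flat).reshape(3, 2)
    e1, e2 = corners[1] - corners[0], corners[2] - corners[0]
    if abs(e1[0] * e2[1] - e1[1] * e2[0]) < 1e-3:
        return  # nearly degenerate; rejected by construction
    if e1[0] * e2[1] - e1[1] * e2[0] < 0:
        corners = corners[[0, 2, 1]]
    a, theta, qxx, qxy = triangle_state(corners)
    rebuilt = triangle_corners_from_state(a, theta, qxx, qxy, origin=corners[0])
    assert np.allclose(rebuilt, corners, atol=1e-10)


@settings(deadline=None, max_examples=40)
@given(
    phi=st.floats(min_value=-np.pi, max_value=np.pi),
    q=st.floats(min_value=0.0, max_value=1.5),
    ang=st.floats(min_value=0.0, max_value=np.pi),
)
def test_rotation_equivariance(phi, q, ang):
    """Rotating the corners by phi advances the nematic angle by 2 phi."""
    nem = np.array([[np.cos(2 * ang), np.sin(2 * ang)], [np.sin(2 * ang), -np.cos(2 * ang)]])
    from epishear.nematic import exp_traceless

    stretch = exp_traceless(np.array([q * np.cos(2 * ang)]), np.array([q * np.sin(2 * ang)]))[0]
    base = REFERENCE_CORNERS @ stretch.T
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    _, _, qxx0, qxy0 = triangle_state(base)
    _, _, qxx1, qxy1 = triangle_state(base @ rot.T)
    mag0, mag1 = np.hypot(qxx0, qxy0), np.hypot(qxx1, qxy1)
    assert mag1 == pytest.approx(mag0, abs=1e-9)
    expected = np.angle(np.exp(2j * (np.arctan2(qxy0, qxx0) / 2 + phi)))
    got = np.arctan2(qxy1, qxx1)
    if mag0 > 1e-6:
        assert np.angle(np.exp(1j * (got - expected))) == pytest.approx(0.0, abs=1e-6)


@settings(deadline=None, max_examples=25)
@given(scale=st.floats(min_value=0.1, max_value=30.0))
def test_scale_invariance(scale):
    """Dilation leaves Q unchanged and multiplies A by scale^2."""
    corners = np.array([[0.0, 0.0], [2.0, 0.2], [0.7, 1.5]])
    a0, _, qxx0, qxy0 = triangle_state(corners)
    a1, _, qxx1, qxy1 = triangle_state(scale * corners)
    assert a1 == pytest.approx(scale**2 * a0, rel=1e-9)
    assert (qxx1, qxy1) == pytest.approx((qxx0, qxy0), abs=1e-9)


def test_mean_elongation_uniform_affine_stretch():
    """Affine stretch of an isotropic lattice shifts mean Q_xx by the log
    stretch (affine maps act identically on all triangles)."""
    tissue = hex_tissue(rows=7, cols=7)
    frame = tissue.frames[0]
    q = 0.2
    stretch = np.diag([np.exp(q), np.exp(-q)])
    import dataclasses

    cells = frame.cells.copy()
    cells[["x", "y"]] = cells[["x", "y"]].to_numpy() @ stretch.T
    vertices = frame.vertices.copy()
    vertices[["x", "y"]] = vertices[["x", "y"]].to_numpy() @ stretch.T
    stretched = dataclasses.replace(frame, cells=cells, vertices=vertices)
    qxx, qxy = mean_elongation(triangulate_frame(stretched))
    assert qxx == pytest.approx(q, abs=1e-9)
    assert qxy == pytest.approx(0.0, abs=1e-9)


def test_mean_elongation_two_population_weighted_sum():
    """Area-weighted mean equals the explicit weighted sum."""
    tissue = hex_tissue(rows=7, cols=7, disorder=0.1, seed=8)
    tri = triangulate_frame(tissue.frames[0])
    qxx, qxy = mean_elongation(tri)
    w = tri.area[~tri.degenerate]
    assert qxx == pytest.approx(np.sum(w * tri.q_xx[~tri.degenerate]) / w.sum())
    assert qxy == pytest.approx(np.sum(w * tri.q_xy[~tri.degenerate]) / w.sum())


def test_cell_elongation_isotropic_lattice(hex_static):
    ce = cell_elongation(triangulate_frame(hex_static.frames[0]))
    assert np.abs(ce.to_numpy()).max() < 1e-9


def test_mean_elongation_empty_raises():
    tissue = hex_tissue(rows=7, cols=7)
    tri = triangulate_frame(tissue.frames[0])
    with pytest.raises(ValueError):
        mean_elongation(tri, rows=[])
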