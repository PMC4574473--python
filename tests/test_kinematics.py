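import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epishear.kinematics import (
    correlation_terms,
    corotational_rate,
    interval_kinematics,
    rotation_power_spectrum,
    tissue_shear,
    triangle_deformation,
)
from epishear.nematic import rotate_nematic
from epishear.synth import hex_tissue
from epishear.triangulation import triangulate_frame


def _rot(phi):
    return np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])


BASE = np.array([[0.0, 0.0], [2.0, 0.1], [0.8, 1.7]])


def test_pure_shear_rates():
    s, dt = 0.05, 1.0
    m = np.diag([np.exp(s * dt), np.exp(-s * dt)])
    kin = triangle_deformation(BASE, BASE @ m.T, dt)
    assert kin.v == pytest.approx(0.0, abs=1e-12)
    assert kin.omega == pytest.approx(0.0, abs=1e-12)
    assert kin.s_xx == pytest.approx(s, abs=1e-12)
    assert kin.s_xy == pytest.approx(0.0, abs=1e-12)


def test_rigid_rotation_rates():
    dt = 1.0
    kin = triangle_deformation(BASE, BASE @ _rot(0.1).T, dt)
    assert kin.omega == pytest.approx(0.1, abs=1e-12)
    assert (kin.s_xx, kin.s_xy) == pytest.approx((0.0, 0.0), abs=1e-12)
    assert (kin.dq_xx, kin.dq_xy) == pytest.approx((0.0, 0.0), abs=1e-12)
    assert kin.v == pytest.approx(0.0, abs=1e-12)


def test_simple_shear_has_no_xx_component():
    """A simple-shear map is pure xy shear plus rotation, exactly."""
    gamma = 0.4
    m = np.array([[1.0, gamma], [0.0, 1.0]])
    kin = triangle_deformation(BASE, BASE @ m.T, 1.0)
    assert kin.s_xx == pytest.approx(0.0, abs=1e-12)
    assert kin.s_xy == pytest.approx(gamma / 2, abs=1e-12)
    assert kin.omega == pytest.approx(-gamma / 2, abs=1e-12)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(min_value=-1.0, max_value=1.0), min_size=4, max_size=4))
def test_small_deformation_matches_linearization(p):
    """For small M - I, rates agree with the linear velocity gradient to
    second order in the deformation."""
    eps = 0.02
    m = np.eye(2) + eps * np.array(p).reshape(2, 2)
    kin = triangle_deformation(BASE, BASE @ m.T, 1.0)
    lin = m - np.eye(2)
    assert kin.s_xx == pytest.approx(0.5 * (lin[0, 0] - lin[1, 1]), abs=4 * eps**2)
    assert kin.s_xy == pytest.approx(0.5 * (lin[0, 1] + lin[1, 0]), abs=4 * eps**2)
    assert kin.omega == pytest.approx(0.5 * (lin[1, 0] - lin[0, 1]), abs=4 * eps**2)
    assert kin.v == pytest.approx(lin[0, 0] + lin[1, 1], abs=4 * eps**2)
    # corotational elongation change agrees with shear to the same order
    assert kin.dq_xx == pytest.approx(kin.s_xx, abs=6 * eps**2)
    assert kin.dq_xy == pytest.approx(kin.s_xy, abs=6 * eps**2)


@settings(deadline=None, max_examples=40)
@given(st.lists(st.floats(min_value=-0.8, max_value=0.8), min_size=4, max_size=4))
def test_corotational_identity_reconstructs_elongation(p):
    """Q2 is exactly Q1 advanced by dq and corotated: the per-triangle
    identity between elongation change and its corotational rate."""
    m = np.eye(2) + np.array(p).reshape(2, 2)
    if np.linalg.det(m) < 0.05:
        return
    kin = triangle_deformation(BASE, BASE @ m.T, 1.0)
    pred = rotate_nematic(
        kin.q1[0] + kin.dq_xx, kin.q1[1] + kin.dq_xy, kin.omega
    )
    assert pred[0] == pytest.approx(kin.q2[0], abs=1e-10)
    assert pred[1] == pytest.approx(kin.q2[1], abs=1e-10)


def test_affine_deformation_uniform_across_triangles(affine_video):
    """Every triangle of an affinely deformed network has the same rates."""
    tissue, _ = affine_video
    tri1 = triangulate_frame(tissue.frames[0])
    tri2 = triangulate_frame(tissue.frames[1])
    kin = interval_kinematics(tri1, tri2, tissue.frames[1].time - tissue.frames[0].time)
    assert np.ptp(kin.s_xx) < 1e-9
    assert np.ptp(kin.s_xy) < 1e-9
    assert np.ptp(kin.v) < 1e-9
    assert np.ptp(kin.omega) < 1e-9
    assert np.mean(kin.s_xx) == pytest.approx(0.3, abs=1e-9)


def test_tissue_shear_direct_summation_oracle(affine_video):
    tissue, _ = affine_video
    tri1 = triangulate_frame(tissue.frames[0])
    tri2 = triangulate_frame(tissue.frames[1])
    kin = interval_kinematics(tri1, tri2, 1.0 / 12.0)
    (sxx, sxy), v, om = tissue_shear(kin)
    assert sxx == pytest.approx(np.sum(kin.area1 * kin.s_xx) / kin.area1.sum())
    assert sxy == pytest.approx(np.sum(kin.area1 * kin.s_xy) / kin.area1.sum())


def test_global_rotation_changes_only_omega(affine_video):
    """Galilean/rotation invariance: superposing a rigid rotation shifts
    omega and leaves shear and correlation terms unchanged."""
    import dataclasses

    tissue, _ = affine_video
    tri1 = triangulate_frame(tissue.frames[0])
    tri2 = triangulate_frame(tissue.frames[1])
    dt = 1.0 / 12.0
    kin = interval_kinematics(tri1, tri2, dt)
    phi = 0.07
    rot = _rot(phi)
    tri2r = dataclasses.replace(tri2, corners=tri2.corners @ rot.T)
    # re-derive the rotated states
    from epishear.triangulation import _states_from_corners

    area, theta, qxx, qxy, degen = _states_from_corners(tri2r.corners)
    tri2r = dataclasses.replace(
        tri2r, area=area, theta=theta, q_xx=qxx, q_xy=qxy, degenerate=degen
    )
    kin_r = interval_kinematics(tri1, tri2r, dt)
    # exact to second order in (rotation x per-interval strain): the
    # composite of two finite non-commuting maps mixes their generators
    strain = 0.3 * dt
    tol = 2.0 * phi * strain / dt
    assert np.allclose(kin_r.omega, kin.omega + phi / dt, atol=tol)
    assert np.allclose(kin_r.s_xx, kin.s_xx, atol=tol)
    assert np.allclose(kin_r.s_xy, kin.s_xy, atol=tol)
    d0 = correlation_terms(kin).d
    d1 = correlation_terms(kin_r).d
    assert d1 == pytest.approx(d0, abs=tol)


def test_corotational_rate_removes_rigid_rotation():
    """Rigid rotation of an elongated lattice: DQ/Dt = 0 although the
    plain elongation components change."""
    q1 = (0.25, 0.0)
    phi = 0.3
    q2 = rotate_nematic(*q1, phi)
    assert abs(q2[0] - q1[0]) > 0.01  # plain difference is nonzero
    rate = corotational_rate(q1, q2, phi, dt=1.0)
    assert rate == pytest.approx((0.0, 0.0), abs=1e-12)


def test_corotational_rate_pure_shear_on_isotropic():
    s = 0.1
    rate = corotational_rate((0.0, 0.0), (s, 0.0), 0.0, dt=1.0)
    assert rate[0] == pytest.approx(s)


def test_correlation_terms_uniform_rates_vanish(affine_video):
    tissue, _ = affine_video
    tri1 = triangulate_frame(tissue.frames[0])
    tri2 = triangulate_frame(tissue.frames[1])
    kin = interval_kinematics(tri1, tri2, 1.0 / 12.0)
    corr = correlation_terms(kin)
    assert corr.d == pytest.approx((0.0, 0.0), abs=1e-9)


def test_correlation_terms_covariance_oracle(rng):
    """Random rates: De/Dr match a direct covariance computation."""
    import dataclasses

    tissue = hex_tissue(rows=8, cols=8, disorder=0.1, seed=1)
    tri1 = triangulate_frame(tissue.frames[0])
    tri2 = triangulate_frame(tissue.frames[1])
    kin = interval_kinematics(tri1, tri2, 1.0)
    n = len(kin)
    v = rng.normal(0, 0.1, n)
    om = rng.normal(0, 0.1, n)
    kin = dataclasses.replace(kin, v=v, omega=om)
    w = kin.area1 / kin.area1.sum()

    def cov(a, b):
        return np.sum(w * a * b) - np.sum(w * a) * np.sum(w * b)

    corr = correlation_terms(kin)
    assert corr.d_area[0] == pytest.approx(-cov(v, kin.q_xx1), rel=1e-10)
    assert corr.d_area[1] == pytest.approx(-cov(v, kin.q_xy1), rel=1e-10)
    assert corr.d_rot[0] == pytest.approx(2 * cov(om, kin.q_xy1), rel=1e-10)
    assert corr.d_rot[1] == pytest.approx(-2 * cov(om, kin.q_xx1), rel=1e-10)


# ---------------------------------------------------------------------------
# rotation-rate power spectrum
# ---------------------------------------------------------------------------

def _grid_points(nx, ny, spacing):
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    return np.column_stack([xs.ravel(), ys.ravel()])


def test_spectrum_uniform_field_has_no_nondc_structure():
    pts = _grid_points(24, 24, 2.0)
    spec = rotation_power_spectrum(pts, np.full(len(pts), 0.3), d0=4.0)
    dc = spec.power[np.argmin(np.abs(spec.qy)), np.argmin(np.abs(spec.qx))]
    assert spec.power.max() <= max(dc, 1e-12)


def test_spectrum_alternating_bands_peak_at_band_wavevector():
    """Bands of +/- omega with period p peak at |q_y| = 2 pi / p."""
    spacing = 2.0
    pts = _grid_points(40, 40, spacing)
    period = 8 * spacing  # four rows up, four rows down
    omega = np.sign(np.sin(2 * np.pi * pts[:, 1] / period) + 1e-9)
    spec = rotation_power_spectrum(pts, omega, d0=4.0, spacing=spacing)
    qx, qy = spec.q_peak
    assert abs(qx) < 1e-9
    dq = spec.qy[1] - spec.qy[0]
    assert abs(abs(qy) - 2 * np.pi / period) < dq / 2 + 1e-12


def test_spectrum_white_noise_is_flat(rng):
    pts = _grid_points(32, 32, 2.0)
    omega = rng.normal(size=len(pts))
    spec = rotation_power_spectrum(pts, omega, d0=4.0, spacing=2.0)
    p = spec.power.copy()
    p[np.argmin(np.abs(spec.qy)), np.argmin(np.abs(spec.qx))] = np.nan
    # no single mode dominates a white spectrum
    assert np.nanmax(p) < 30 * np.nanmean(p)


def test_spectrum_region_too_small():
    pts = _grid_points(3, 3, 2.0)
    with pytest.raises(ValueError):
        rotation_power_spectrum(pts, np.zeros(len(pts)), d0=4.0, spacing=2.0)
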