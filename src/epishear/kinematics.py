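"""Per-interval deformation of triangles and of the tissue.

For a triangle tracked between two frames, the linear map ``M`` between
its corner sets is factored through its (principal) matrix logarithm,
``M = exp(dt * L)``, giving the per-interval rates

* area expansion rate   ``v = tr(L) = ln(det M) / dt``
* rotation rate         ``omega`` — antisymmetric part of ``L``
* pure shear rate       ``s`` — symmetric traceless part of ``L``

These are the deformation rates of the triangle as a piece of material:
a rigid rotation gives ``s = 0``, a row of triangles under simple shear
has ``s_xx = 0`` exactly, and for an affine deformation of the whole
network every triangle carries identical rates.

Alongside, each triangle's *corotational elongation change*
``dq = (rotate(Q2, -omega*dt) - Q1) / dt`` is reported.  For a triangle
that starts isotropic, or for small deformations, ``dq`` equals ``s``;
at finite elongation the two differ, and it is exactly this difference,
summed over fluctuating triangles, that the correlation term of the
shear decomposition accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nematic import rotate_nematic
from .triangulation import Triangulation, _states_from_corners, triangle_state

__all__ = [
    "TriangleKinematics",
    "IntervalKinematics",
    "CorrelationTerms",
    "triangle_deformation",
    "match_triangles",
    "interval_kinematics",
    "tissue_shear",
    "corotational_rate",
    "correlation_terms",
    "rotation_power_spectrum",
]


@dataclass
class TriangleKinematics:
    """Deformation rates of a single triangle over one interval."""

    v: float          # area expansion rate [1/h]
    omega: float      # rotation rate [1/h]
    s_xx: float       # pure shear rate nematic [1/h]
    s_xy: float
    dq_xx: float      # corotational elongation change rate [1/h]
    dq_xy: float
    q1: tuple         # elongation at interval start
    q2: tuple         # elongation at interval end


def _wrap_angle(dphi):
    """Wrap angles to (-pi, pi]."""
    return dphi - 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))


def _log_generators(m):
    """Principal matrix log of stacked 2x2 maps with det > 0.

    Returns ``(v_log, omega_ang, g_xx, g_xy)``: the log-determinant, the
    antisymmetric (rotation) angle and the symmetric traceless (shear)
    components of ``log(M)``.  Uses the closed form for 2x2 matrices:
    after normalizing to det 1, ``log(A) = mu/f(mu) * (A - tr(A)/2 I)``
    with ``f = sinh`` (real eigenvalues) or ``sin`` (complex pair).
    """
    m = np.asarray(m, dtype=float)
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    if np.any(det <= 0):
        raise ValueError("orientation-reversing or singular triangle map")
    a = m / np.sqrt(det)[..., None, None]
    tau = 0.5 * (a[..., 0, 0] + a[..., 1, 1])
    # eigenvalues exp(+-mu) (tau > 1), exp(+-i mu) (tau < 1), or 1 (tau = 1)
    fac = np.empty_like(tau)
    hyp = tau > 1.0 + 1e-12
    trig = tau < 1.0 - 1e-12
    mid = ~(hyp | trig)
    mu_h = np.arccosh(np.where(hyp, tau, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        fac_h = mu_h / np.sinh(mu_h)
    fac[hyp] = fac_h[hyp]
    mu_t = np.arccos(np.clip(np.where(trig, tau, 1.0), -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        fac_t = mu_t / np.sin(mu_t)
    fac[trig] = fac_t[trig]
    fac[mid] = 1.0
    g = fac[..., None, None] * (a - tau[..., None, None] * _EYE2)
    omega_ang = 0.5 * (g[..., 1, 0] - g[..., 0, 1])
    g_xx = 0.5 * (g[..., 0, 0] - g[..., 1, 1])
    g_xy = 0.5 * (g[..., 0, 1] + g[..., 1, 0])
    return np.log(det), omega_ang, g_xx, g_xy


_EYE2 = np.eye(2)


def _corner_map(corners1, corners2):
    """Linear maps taking frame-1 triangle edges onto frame-2 edges."""
    e1 = np.stack((corners1[:, 1] - corners1[:, 0], corners1[:, 2] - corners1[:, 0]), axis=-1)
    e2 = np.stack((corners2[:, 1] - corners2[:, 0], corners2[:, 2] - corners2[:, 0]), axis=-1)
    det = e1[:, 0, 0] * e1[:, 1, 1] - e1[:, 0, 1] * e1[:, 1, 0]
    inv = np.empty_like(e1)
    inv[:, 0, 0] = e1[:, 1, 1]
    inv[:, 0, 1] = -e1[:, 0, 1]
    inv[:, 1, 0] = -e1[:, 1, 0]
    inv[:, 1, 1] = e1[:, 0, 0]
    inv /= det[:, None, None]
    return np.einsum("nij,njk->nik", e2, inv)


def triangle_deformation(corners1, corners2, dt):
    """Deformation rates between two corner sets of the same triangle.

    Corners must be in the same (cell) order and CCW in both frames;
    ``dt`` is the interval in hours.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _, _, qxx1, qxy1 = triangle_state(corners1)
    _, _, qxx2, qxy2 = triangle_state(corners2)
    c1 = np.asarray(corners1, dtype=float)[None]
    c2 = np.asarray(corners2, dtype=float)[None]
    v_log, ang, gxx, gxy = _log_generators(_corner_map(c1, c2))
    bxx, bxy = rotate_nematic(qxx2, qxy2, -ang[0])
    return TriangleKinematics(
        v=float(v_log[0]) / dt,
        omega=float(ang[0]) / dt,
        s_xx=float(gxx[0]) / dt,
        s_xy=float(gxy[0]) / dt,
        dq_xx=(float(bxx) - qxx1) / dt,
        dq_xy=(float(bxy) - qxy1) / dt,
        q1=(qxx1, qxy1),
        q2=(qxx2, qxy2),
    )


def match_triangles(tri1: Triangulation, tri2: Triangulation):
    """Rows of triangles persisting between two triangulations.

    Returns ``(idx1, idx2)`` such that ``tri1.cell_triplets[idx1]`` and
    ``tri2.cell_triplets[idx2]`` are the same cell triplets (possibly in a
    different corner order).  Degenerate triangles are dropped.
    """
    lookup = tri2.triplet_index()
    idx1, idx2 = [], []
    for i, t in enumerate(map(tuple, tri1.cell_triplets)):
        j = lookup.get(tuple(sorted(t)))
        if j is not None and not tri1.degenerate[i] and not tri2.degenerate[j]:
            idx1.append(i)
            idx2.append(j)
    return np.array(idx1, dtype=int), np.array(idx2, dtype=int)


@dataclass
class IntervalKinematics:
    """Per-triangle deformation rates for all matched triangles.

    ``s_*`` are velocity-gradient pure shear rates, ``dq_*`` corotational
    elongation change rates; see the module docstring.
    """

    dt: float
    idx1: np.ndarray
    idx2: np.ndarray
    area1: np.ndarray
    area2: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    s_xx: np.ndarray
    s_xy: np.ndarray
    dq_xx: np.ndarray
    dq_xy: np.ndarray
    q_xx1: np.ndarray
    q_xy1: np.ndarray
    q_xx2: np.ndarray
    q_xy2: np.ndarray

    def __len__(self):
        return len(self.v)

    @property
    def weights(self):
        """Start-of-interval area weights, normalized."""
        return self.area1 / self.area1.sum()

    @property
    def centroids(self):
        """Placeholder filled by :func:`interval_kinematics`."""
        return self._centroids

    @property
    def mean_v(self):
        return float(np.average(self.v, weights=self.area1))

    @property
    def mean_omega(self):
        return float(np.average(self.omega, weights=self.area1))


def interval_kinematics(tri1: Triangulation, tri2: Triangulation, dt):
    """Vectorized deformation rates of all persistent triangles.

    Frame-2 states are recomputed with corners permuted into frame-1 cell
    order so that rotation angles are comparable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    idx1, idx2 = match_triangles(tri1, tri2)
    if len(idx1) == 0:
        raise ValueError("no persistent triangles between frames")
    cells1 = tri1.cell_triplets[idx1]
    cells2 = tri2.cell_triplets[idx2]
    # source position in frame 2 of each frame-1 corner
    src = np.argmax(cells2[:, None, :] == cells1[:, :, None], axis=2)
    corners1 = tri1.corners[idx1]
    corners2 = np.take_along_axis(tri2.corners[idx2], src[:, :, None], axis=1)
    a2, _, qxx2, qxy2 = _states_from_corners(corners2)[:4]
    a1 = tri1.area[idx1]
    qxx1 = tri1.q_xx[idx1]
    qxy1 = tri1.q_xy[idx1]
    v_log, ang, gxx, gxy = _log_generators(_corner_map(corners1, corners2))
    bxx, bxy = rotate_nematic(qxx2, qxy2, -ang)
    kin = IntervalKinematics(
        dt=dt,
        idx1=idx1,
        idx2=idx2,
        area1=a1,
        area2=a2,
        v=v_log / dt,
        omega=ang / dt,
        s_xx=gxx / dt,
        s_xy=gxy / dt,
        dq_xx=(bxx - qxx1) / dt,
        dq_xy=(bxy - qxy1) / dt,
        q_xx1=qxx1,
        q_xy1=qxy1,
        q_xx2=qxx2,
        q_xy2=qxy2,
    )
    kin._centroids = tri1.corners[idx1].mean(axis=1)
    return kin


def tissue_shear(kin: IntervalKinematics):
    """Area-weighted mean shear rate (and area/rotation rates) of the roi.

    Returns ``(s_xx, s_xy), v, omega``.
    """
    if len(kin) == 0:
        raise ValueError("empty kinematics")
    w = kin.area1
    return (
        (float(np.average(kin.s_xx, weights=w)), float(np.average(kin.s_xy, weights=w))),
        kin.mean_v,
        kin.mean_omega,
    )


def corotational_rate(q1, q2, mean_rotation_angle, dt):
    """Corotational rate of change of a mean elongation nematic.

    ``q1``/``q2`` are ``(Q_xx, Q_xy)`` pairs at the interval ends; the end
    value is rotated back by the (area-weighted) mean rotation before
    differencing, which removes advection of the nematic angle by rigid
    tissue rotation.
    """
    bxx, bxy = rotate_nematic(q2[0], q2[1], -mean_rotation_angle)
    return (bxx - q1[0]) / dt, (bxy - q1[1]) / dt


@dataclass
class CorrelationTerms:
    """Shear from correlated fluctuations of triangle rates and elongation.

    ``d_area`` is the area-correlation part (correlation of local area
    expansion with local elongation), ``d_rot`` the rotation-correlation
    part; ``d = d_area + d_rot``.  Each is a nematic ``(xx, xy)`` rate.
    """

    d_area: tuple
    d_rot: tuple

    @property
    def d(self):
        return (
            self.d_area[0] + self.d_rot[0],
            self.d_area[1] + self.d_rot[1],
        )


def _wcov(a, b, w):
    wm = w / w.sum()
    return float(np.sum(wm * a * b) - np.sum(wm * a) * np.sum(wm * b))


def correlation_terms(kin: IntervalKinematics, weights=None):
    """Covariance estimate of the correlation shear ``D``.

    ``D^e_ij = -cov(v, Q_ij)`` and ``D^r = 2 cov(omega, eps.Q)`` with the
    elongation taken at interval start and area weights::

        D^r_xx =  2 (<omega Q_xy> - <omega><Q_xy>)
        D^r_xy = -2 (<omega Q_xx> - <omega><Q_xx>)

    This is the first-order estimate of the exact residual correlation
    term used in the decomposition bookkeeping; both vanish when the
    triangle rates are uniform.
    """
    if len(kin) == 0:
        raise ValueError("empty kinematics")
    w = kin.area1 if weights is None else np.asarray(weights, dtype=float)
    de = (-_wcov(kin.v, kin.q_xx1, w), -_wcov(kin.v, kin.q_xy1, w))
    dr = (2.0 * _wcov(kin.omega, kin.q_xy1, w), -2.0 * _wcov(kin.omega, kin.q_xx1, w))
    return CorrelationTerms(d_area=de, d_rot=dr)


@dataclass
class RotationSpectrum:
    """2D spatial power spectrum of the local rotation-rate field."""

    qx: np.ndarray      # wave numbers [rad/µm]
    qy: np.ndarray
    power: np.ndarray   # (len(qy), len(qx))
    q_peak: tuple       # (qx, qy) of the largest non-DC local maximum
    d0: float

    @property
    def q_peak_d0(self):
        """Peak wave vector in dimensionless units of d0/(2 pi)."""
        return (
            self.q_peak[0] * self.d0 / (2.0 * np.pi),
            self.q_peak[1] * self.d0 / (2.0 * np.pi),
        )


def rotation_power_spectrum(points, omega, d0=4.0, spacing=None):
    """Spatial power spectrum of a scattered rotation-rate field.

    The per-triangle rotation rates ``omega`` at centroid ``points`` are
    binned to a regular grid (spacing ``d0/2`` by default, with ``d0`` a
    typical cell diameter in µm), mean-subtracted, Hann-windowed and
    Fourier transformed.  Wave numbers are in rad/µm; the dimensionless
    convention ``q * d0 / (2 pi)`` is exposed on the result.
    """
    points = np.asarray(points, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if spacing is None:
        spacing = 0.5 * d0
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    nx = int(np.ceil((hi[0] - lo[0]) / spacing)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / spacing)) + 1
    if nx < 4 or ny < 4:
        raise ValueError("region smaller than 4x4 grid cells")
    ix = np.clip(((points[:, 0] - lo[0]) / spacing).round().astype(int), 0, nx - 1)
    iy = np.clip(((points[:, 1] - lo[1]) / spacing).round().astype(int), 0, ny - 1)
    acc = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx))
    np.add.at(acc, (iy, ix), omega)
    np.add.at(cnt, (iy, ix), 1.0)
    field = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    filled = cnt > 0
    field[filled] -= field[filled].mean()
    win = np.outer(np.hanning(ny), np.hanning(nx))
    spec = np.fft.fftshift(np.fft.fft2(field * win))
    power = np.abs(spec) ** 2
    qx = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(nx, d=spacing))
    qy = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(ny, d=spacing))
    q_peak = _largest_nondc_peak(power, qx, qy)
    return RotationSpectrum(qx=qx, qy=qy, power=power, q_peak=q_peak, d0=d0)


def _largest_nondc_peak(power, qx, qy):
    ny, nx = power.shape
    p = np.pad(power, 1, mode="constant", constant_values=-np.inf)
    core = p[1:-1, 1:-1]
    is_max = (
        (core >= p[:-2, 1:-1])
        & (core >= p[2:, 1:-1])
        & (core >= p[1:-1, :-2])
        & (core >= p[1:-1, 2:])
    )
    dc_y, dc_x = np.argmin(np.abs(qy)), np.argmin(np.abs(qx))
    is_max[dc_y, dc_x] = False
    if not is_max.any():
        return (0.0, 0.0)
    flat = np.where(is_max, power, -np.inf)
    j, i = np.unravel_index(np.argmax(flat), flat.shape)
    return (float(qx[i]), float(qy[j]))
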