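"""Circular laser-ablation recoil analysis and stress-state regressions.

After a circular cut, the tissue boundary recoils into an ellipse.  The
initial normal recoil velocities along the ellipse axes, divided by the
corresponding half-axes, define a velocity-gradient tensor in the ellipse
frame that is rotated into the tissue (PD/AP) frame::

    v_cut = R(theta) diag(V_par/r_par, V_perp/r_perp) R(-theta)

Its half-trace ``C`` is the isotropic expansion rate (a proxy for minus
the tissue pressure) and its traceless part the recoil shear rate (a
proxy for the anisotropic tissue stress).  Regressing the recoil shear
against cell elongation tests the constitutive law
``sigma_tilde = 2 K Q + zeta``: the slope is proportional to the shear
modulus K and the intercept to the cell-autonomous anisotropic stress
zeta, so ``zeta_xx / K = 2 * intercept / slope``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RecoilMeasurement",
    "StressElongationFit",
    "recoil_tensor",
    "fit_zeta_over_K",
    "fit_isotropic",
]


@dataclass
class RecoilMeasurement:
    """Velocity-gradient tensor derived from an elliptical recoil."""

    v_par: float       # initial normal recoil velocity, major axis [µm/h]
    v_perp: float      # minor axis [µm/h]
    r_par: float       # major half-axis [µm]
    r_perp: float      # minor half-axis [µm]
    theta: float       # major-axis angle to the PD (x) axis [rad]
    v_cut: np.ndarray  # 2x2 velocity-gradient tensor [1/h]
    c: float           # half-trace: isotropic expansion rate [1/h]
    s_xx: float        # traceless (shear) part, PD projection [1/h]
    s_xy: float


def recoil_tensor(v_par, v_perp, r_par, r_perp, theta):
    """Recoil velocity-gradient tensor from ellipse measurements.

    Requires ``r_par >= r_perp > 0``.  The result is invariant under
    ``theta -> theta + pi`` (the ellipse axis is a director, not a
    vector).
    """
    if not (r_par >= r_perp > 0):
        raise ValueError("require r_par >= r_perp > 0")
    c_, s_ = np.cos(theta), np.sin(theta)
    rot = np.array([[c_, -s_], [s_, c_]])
    diag = np.diag([v_par / r_par, v_perp / r_perp])
    v_cut = rot @ diag @ rot.T
    c = 0.5 * (v_cut[0, 0] + v_cut[1, 1])
    return RecoilMeasurement(
        v_par=v_par,
        v_perp=v_perp,
        r_par=r_par,
        r_perp=r_perp,
        theta=theta,
        v_cut=v_cut,
        c=float(c),
        s_xx=float(v_cut[0, 0] - c),
        s_xy=float(v_cut[0, 1]),
    )


@dataclass
class StressElongationFit:
    """OLS fit of recoil shear rate against cell elongation."""

    slope: float           # [1/h per unit Q]
    intercept: float       # [1/h]
    slope_err: float
    intercept_err: float
    zeta_xx_over_K: float  # 2 * intercept / slope (dimensionless)
    zeta_xx_over_K_err: float
    r_value: float
    n: int

    @property
    def positive_shear_modulus(self):
        """A positive slope indicates a positive shear modulus K."""
        return self.slope > 0


def fit_zeta_over_K(q_xx, s_xx_cut):
    """Estimate ``zeta_xx / K`` from (cell elongation, recoil shear) pairs.

    Ordinary least squares of ``s_xx_cut`` on ``q_xx``; the constitutive
    law gives ``intercept/slope = zeta_xx / (2 K)``.  Uncertainty is
    propagated from the coefficient standard errors assuming independent
    errors.  The estimate is invariant under rescaling all recoil rates
    by a common factor.
    """
    q = np.asarray(q_xx, dtype=float)
    s = np.asarray(s_xx_cut, dtype=float)
    if len(q) < 3:
        raise ValueError("need >= 3 ablation measurements")
    if np.ptp(q) == 0:
        raise ValueError("degenerate cell-elongation spread")
    res = stats.linregress(q, s)
    ratio = 2.0 * res.intercept / res.slope
    rel = np.sqrt(
        ((res.intercept_stderr / res.intercept) ** 2 if res.intercept != 0 else 0.0)
        + (res.stderr / res.slope) ** 2
    )
    return StressElongationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_err=float(res.stderr),
        intercept_err=float(res.intercept_stderr),
        zeta_xx_over_K=float(ratio),
        zeta_xx_over_K_err=float(abs(ratio) * rel),
        r_value=float(res.rvalue),
        n=len(q),
    )


def fit_isotropic(log_area_ratio, half_vkk):
    """OLS fit of the isotropic recoil rate against log cell area.

    ``log_area_ratio`` is ``ln(a_cell / a_ref)`` with a configurable
    reference area (affects only the intercept); ``half_vkk`` is half the
    trace of the recoil tensor, a proxy for minus the tissue pressure.
    Returns ``(slope, intercept, slope_err, intercept_err,
    tension_positive)``; a positive intercept at the reference area
    indicates the tissue is under contractile tension (negative
    pressure).  The preferred area and area modulus are deliberately not
    derived from this fit — the cell-area spread is too small for a
    reliable estimate.
    """
    x = np.asarray(log_area_ratio, dtype=float)
    y = np.asarray(half_vkk, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 measurements")
    if np.ptp(x) == 0:
        raise ValueError("degenerate cell-area spread")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_err": float(res.stderr),
        "intercept_err": float(res.intercept_stderr),
        "tension_positive": bool(res.intercept > 0),
        "n": len(x),
    }
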