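"""Delayed-viscoelastic two-rectangle continuum model of the pupal wing.

The hinge and blade are modeled as two rectangles attached end to end
along the PD (x) axis, connected to a rigid frame (the cuticle) by
effective elastic links, with friction against the frame.  Within each
region the tissue obeys, projected on the PD axis:

* area balance        ``v = dln(a)/dt + k_d - k_e``
* shear decomposition ``s = dQ/dt + R``  (s: pure shear rate)
* isotropic stress    ``P = -Kbar ln(a/a0) - etabar v``
* anisotropic stress  ``sigma_t = 2 K Q + zeta``
* delayed rearrangements ``(1 + tau_d d/dt) R = Q / tau_r + lambda``

All stresses are normalized by the blade shear modulus K and lengths by
the initial wing length L0.  The hinge pressure is not constitutive but a
Lagrange multiplier imposing the measured hinge area; the blade area
follows from force balance.  Quasi-static force balance equates the
internal stress on each mobile boundary with the elastic-link stress plus
a friction stress proportional to the local strain rate (units K·h).

For constant inputs the model relaxes to the fixed point ``R = 0``,
``Q = -tau_r * lambda``: the final cell elongation is set by the
autonomous rearrangement drive and the stress-relaxation time, not by the
external springs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "RegionParams",
    "BoundaryParams",
    "rect_dims",
    "step_rearrangement",
    "rearrangement_rate",
    "simulate",
    "fit_eq5",
    "integrate_eq5",
    "fit_eq5_joint",
    "fit_rectangle_model",
    "winding_angle",
]


@dataclass
class RegionParams:
    """Material parameters of one region (blade normalization: K = 1).

    Defaults are the wild-type blade estimates; times in hours, rates in
    1/h, stresses in units of the blade shear modulus K.
    """

    K: float = 1.0            # shear modulus [K]
    zeta_xx: float = 0.0      # cell-autonomous anisotropic stress [K]
    tau_r: float = 1.8        # stress-relaxation time [h]
    tau_d: float = 3.7        # rearrangement delay time [h]
    lambda_xx: float = -0.10  # autonomous topological-shear drive [1/h]
    kbar: float = 2.07        # area modulus [K]
    zetabar: float = 0.0      # cell area contractility [K]
    etabar: float = 0.0       # area viscosity [K h]

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_d < 0:
            raise ValueError("require tau_r > 0 and tau_d >= 0")


#: hinge defaults: small anisotropic moduli, slower relaxation
HINGE_DEFAULTS = dict(K=0.0, zeta_xx=0.0, tau_r=4.6, tau_d=2.4, lambda_xx=-0.05)


@dataclass
class BoundaryParams:
    """Elastic links to the cuticle frame and friction (units of K, K·h)."""

    k_ap_blade: float = 0.5     # AP springs on blade height
    k_ap_hinge: float = 10.0    # AP springs on hinge height
    k_pd_blade: float = 4.91    # distal PD link on the wing tip
    k_pd_hinge: float = 9.50    # PD link on the hinge-blade interface
    gamma: float = 21.3         # friction coefficient [K h]
    distal_attachment: bool = True

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("friction coefficient must be positive")


def rect_dims(area, qt_xx):
    """Rectangle length and height representing a region shape.

    The rectangle has the region's area and the aspect ratio implied by
    the shape nematic, ``h/L = exp(-2 Q^t_xx)``::

        L = sqrt(A) exp(Q^t_xx),   h = sqrt(A) exp(-Q^t_xx)

    so ``h * L = A`` identically.
    """
    if np.any(np.asarray(area) <= 0):
        raise ValueError("area must be positive")
    root = np.sqrt(area)
    return root * np.exp(qt_xx), root * np.exp(-qt_xx)


def rearrangement_rate(q, r, p: RegionParams):
    """Instantaneous dR/dt of the delayed rearrangement law (tau_d > 0)."""
    return (q / p.tau_r + p.lambda_xx - r) / p.tau_d


def step_rearrangement(r, q, p: RegionParams, dt):
    """Advance R by one explicit step of the delayed law.

    With ``tau_d = 0`` the law degenerates to the instantaneous algebraic
    branch ``R = Q / tau_r + lambda``.
    """
    if p.tau_d == 0.0:
        return q / p.tau_r + p.lambda_xx
    return r + dt * rearrangement_rate(q, r, p)


def _as_callable(x):
    if callable(x):
        return x
    return lambda t, _x=float(x): _x


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    blade: RegionParams,
    hinge: RegionParams | None = None,
    boundary: BoundaryParams | None = None,
    k_d=0.0,
    k_e=0.0,
    hinge_area=None,
    t_span=(16.0, 32.0),
    dt=0.01,
    init=None,
):
    """Integrate the two-rectangle model (RK4, fixed step).

    Parameters
    ----------
    blade, hinge : RegionParams
        Tissue parameters; ``hinge=None`` runs the single-region (blade
        only) reduction with the proximal side pinned.
    boundary : BoundaryParams
    k_d, k_e : float or callable(t)
        Measured division/extrusion rates of the blade [1/h].
    hinge_area : callable(t), optional
        Imposed hinge area (normalized); defaults to its initial value.
    init : dict, optional
        Initial state; recognized keys ``L``, ``h``, ``Q``, ``R``, ``a``,
        ``a0``, ``L_H``, ``h_H``, ``Q_H``, ``R_H`` (normalized units).
        Initial Q and R should be the observed cell elongation and shear
        rate due to topological changes.

    Returns
    -------
    pandas.DataFrame with per-step state and rates.
    """
    if boundary is None:
        boundary = BoundaryParams()
    init = dict(init or {})
    two = hinge is not None
    st = {
        "L": init.get("L", 0.7),
        "h": init.get("h", 0.35),
        "Q": init.get("Q", 0.0),
        "R": init.get("R", 0.0),
        "a": init.get("a", 1.0),
        "a0": init.get("a0", 1.0),
    }
    if two:
        st.update(
            L_H=init.get("L_H", 0.3),
            h_H=init.get("h_H", 0.35),
            Q_H=init.get("Q_H", 0.0),
            R_H=init.get("R_H", 0.0),
        )
    rest = {"L": st["L"], "h": st["h"]}
    rest["tip"] = st["L"] + (st["L_H"] if two else 0.0)
    if two:
        rest["L_H"] = st["L_H"]
        rest["h_H"] = st["h_H"]
    kd_f, ke_f = _as_callable(k_d), _as_callable(k_e)
    if two:
        ah_f = _as_callable(hinge_area if hinge_area is not None else st["L_H"] * st["h_H"])
    t0, t1 = t_span
    n_steps = int(round((t1 - t0) / dt))

    def rates(t, s):
        """Force balance -> strain rates; returns dict of d/dt terms."""
        g = boundary.gamma
        sig_t = 2.0 * blade.K * s["Q"] + blade.zeta_xx
        p_el = -blade.kbar * np.log(
            s["a"] / (s["a0"] * max(1.0 - blade.zetabar / max(blade.kbar, 1e-12), 1e-6))
        )
        spring_pd_b = boundary.k_pd_blade * (s["L"] - rest["L"])
        if two:
            sig_t_h = 2.0 * hinge.K * s["Q_H"] + hinge.zeta_xx
            eps = 1e-4
            dlog_ah = (np.log(ah_f(t + eps)) - np.log(ah_f(t - eps))) / (2 * eps)
            # unknowns x = [dlnL_H, dlnL_B, dlnh_H, dlnh_B, P_H]
            A = np.zeros((5, 5))
            b = np.zeros(5)
            # (X1) interface balance:
            #   g dlnL_H = sig_xx_B - sig_xx_H - kPDH (L_H - L_H0) + kPD (L - L0)
            #   sig_xx_B = -P_B + sig_t, P_B = p_el - etabar * (dlnL_B + dlnh_B)
            #   sig_xx_H = -P_H + sig_t_h
            A[0, 0] = g
            A[0, 1] = -blade.etabar
            A[0, 3] = -blade.etabar
            A[0, 4] = -1.0
            b[0] = (
                -p_el
                + sig_t
                - sig_t_h
                - boundary.k_pd_hinge * (s["L_H"] - rest["L_H"])
                + spring_pd_b
            )
            # (X2) distal end: fixed tip (dL_B = -dL_H) or free with the
            # blade PD length spring
            if boundary.distal_attachment:
                A[1, 0] = s["L_H"]
                A[1, 1] = s["L"]
                b[1] = 0.0
            else:
                A[1, 1] = g + blade.etabar
                A[1, 3] = blade.etabar
                b[1] = p_el - sig_t - spring_pd_b
            # (Y1) g dlnh_H = -sig_yy_H - kH (h_H - h_H0); sig_yy_H = -P_H - sig_t_h
            A[2, 2] = g
            A[2, 4] = -1.0
            b[2] = sig_t_h - boundary.k_ap_hinge * (s["h_H"] - rest["h_H"])
            # (Y2) g dlnh_B = -sig_yy_B - k (h - h0)
            A[3, 1] = blade.etabar
            A[3, 3] = g + blade.etabar
            b[3] = p_el + sig_t - boundary.k_ap_blade * (s["h"] - rest["h"])
            # (A1) imposed hinge area: dlnL_H + dlnh_H = dln A_H
            A[4, 0] = 1.0
            A[4, 2] = 1.0
            b[4] = dlog_ah
            x = np.linalg.solve(A, b)
            dlnL_H, dlnL_B, dlnh_H, dlnh_B, p_hinge = x
        else:
            # single region, proximal side pinned: [dlnL_B, dlnh_B]
            A = np.array(
                [
                    [g + blade.etabar, blade.etabar],
                    [blade.etabar, g + blade.etabar],
                ]
            )
            b = np.array(
                [
                    p_el - sig_t - spring_pd_b,
                    p_el + sig_t - boundary.k_ap_blade * (s["h"] - rest["h"]),
                ]
            )
            if boundary.distal_attachment:
                A[0] = (1.0, 0.0)
                b[0] = 0.0
            dlnL_B, dlnh_B = np.linalg.solve(A, b)
            dlnL_H = dlnh_H = p_hinge = 0.0
        v_b = dlnL_B + dlnh_B
        shear_b = 0.5 * (dlnL_B - dlnh_B)
        out = {
            "L": s["L"] * dlnL_B,
            "h": s["h"] * dlnh_B,
            "a": s["a"] * (v_b - kd_f(t) + ke_f(t)),
            "a0": s["a0"] * (-kd_f(t) + ke_f(t)),
            "Q": shear_b - s["R"],
            "R": (
                rearrangement_rate(s["Q"], s["R"], blade)
                if blade.tau_d > 0
                else 0.0
            ),
            "_v": v_b,
            "_shear": shear_b,
            "_P_B": p_el - blade.etabar * v_b,
            "_P_H": p_hinge,
        }
        if two:
            shear_h = 0.5 * (dlnL_H - dlnh_H)
            out.update(
                L_H=s["L_H"] * dlnL_H,
                h_H=s["h_H"] * dlnh_H,
                Q_H=shear_h - s["R_H"],
                R_H=(
                    rearrangement_rate(s["Q_H"], s["R_H"], hinge)
                    if hinge.tau_d > 0
                    else 0.0
                ),
                _shear_H=shear_h,
            )
        return out

    def algebraic_r(s):
        if blade.tau_d == 0.0:
            s["R"] = s["Q"] / blade.tau_r + blade.lambda_xx
        if two and hinge.tau_d == 0.0:
            s["R_H"] = s["Q_H"] / hinge.tau_r + hinge.lambda_xx

    state_keys = [k for k in st]
    rows = []
    s = dict(st)
    algebraic_r(s)
    for n in range(n_steps + 1):
        t = t0 + n * dt
        d1 = rates(t, s)
        rows.append(
            {
                "t": t,
                **{k: s[k] for k in state_keys},
                "v": d1["_v"],
                "shear": d1["_shear"],
                "P": d1["_P_B"],
                "P_H": d1["_P_H"],
                **({"shear_H": d1["_shear_H"]} if two else {}),
            }
        )
        if n == n_steps:
            break
        # RK4
        def add(sv, dv, f):
            out = {k: sv[k] + f * dv[k] for k in state_keys}
            algebraic_r(out)
            return out

        d2 = rates(t + dt / 2, add(s, d1, dt / 2))
        d3 = rates(t + dt / 2, add(s, d2, dt / 2))
        d4 = rates(t + dt, add(s, d3, dt))
        s = {
            k: s[k] + dt / 6.0 * (d1[k] + 2 * d2[k] + 2 * d3[k] + d4[k])
            for k in state_keys
        }
        algebraic_r(s)
        if s["L"] <= 0 or s["h"] <= 0 or (two and (s["L_H"] <= 0 or s["h_H"] <= 0)):
            raise RuntimeError("region dimension became non-positive")
    return pd.DataFrame(rows)


def integrate_eq5(t, q_of_t, params: RegionParams, substeps=20, r0=None):
    """Integrate the delayed rearrangement law for a prescribed Q(t).

    ``q_of_t`` is a callable; the ODE ``tau_d dR/dt = Q/tau_r + lambda - R``
    is integrated with RK4 using ``substeps`` internal steps per output
    interval.  ``r0`` defaults to the instantaneous (no-delay) value at the
    first sample.  Returns R at the sample times.
    """
    t = np.asarray(t, dtype=float)
    if params.tau_d == 0.0:
        return np.asarray(q_of_t(t), dtype=float) / params.tau_r + params.lambda_xx
    if r0 is None:
        r0 = float(q_of_t(t[0])) / params.tau_r + params.lambda_xx

    def f(ti, ri):
        return (float(q_of_t(ti)) / params.tau_r + params.lambda_xx - ri) / params.tau_d

    out = np.empty_like(t)
    out[0] = r = r0
    for n in range(len(t) - 1):
        h = (t[n + 1] - t[n]) / substeps
        ti = t[n]
        for _ in range(substeps):
            k1 = f(ti, r)
            k2 = f(ti + h / 2, r + h / 2 * k1)
            k3 = f(ti + h / 2, r + h / 2 * k2)
            k4 = f(ti + h, r + h * k3)
            r = r + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            ti += h
        out[n + 1] = r
    return out


# ---------------------------------------------------------------------------
# fitting the delayed rearrangement law
# ---------------------------------------------------------------------------

def _predict_r(t, q, tau_r, tau_d, lam, r0):
    """Exact solution of the delayed law for piecewise-linear Q(t).

    On each segment with Q linear, the particular solution is
    ``R_p(t) = (Q(t) - m tau_d)/tau_r + lam`` and the homogeneous part
    decays as ``exp(-dt/tau_d)``; this avoids differentiating noisy data.
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    if tau_d <= 0:
        return q / tau_r + lam
    r = np.empty_like(q)
    r[0] = r0
    for n in range(len(t) - 1):
        dtn = t[n + 1] - t[n]
        m = (q[n + 1] - q[n]) / dtn
        rp_n = (q[n] - m * tau_d) / tau_r + lam
        rp_n1 = (q[n + 1] - m * tau_d) / tau_r + lam
        r[n + 1] = rp_n1 + (r[n] - rp_n) * np.exp(-dtn / tau_d)
    return r


@dataclass
class Eq5Fit:
    tau_r: float
    tau_d: float
    lambda_xx: float
    tau_r_err: float
    tau_d_err: float
    lambda_xx_err: float
    rss: float
    identifiable: bool
    result: object


def fit_eq5(t, q, r, tau_r0=2.0, tau_d0=2.0, lambda0=-0.05):
    """Fit ``(1 + tau_d d/dt) R = Q/tau_r + lambda`` to a (Q, R) series.

    Least squares of the exactly-discretized delayed response (initial
    condition pinned to the first observed R).  If the elongation episode
    is monotonic and short, the delay is weakly identified; the fit flags
    this through wide confidence intervals (``identifiable=False`` when
    the relative standard error of ``tau_d`` exceeds 1).
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    params = lmfit.Parameters()
    params.add("tau_r", value=tau_r0, min=1e-3)
    params.add("tau_d", value=tau_d0, min=0.0)
    params.add("lam", value=lambda0)

    def resid(p):
        return (
            _predict_r(t, q, p["tau_r"].value, p["tau_d"].value, p["lam"].value, r[0])
            - r
        )

    res = lmfit.minimize(resid, params, method="leastsq")
    p = res.params

    def err(name):
        e = p[name].stderr
        return float(e) if e is not None else np.nan

    tau_d_err = err("tau_d")
    identifiable = np.isfinite(tau_d_err) and (
        p["tau_d"].value == 0 or tau_d_err < abs(p["tau_d"].value)
    )
    return Eq5Fit(
        tau_r=float(p["tau_r"].value),
        tau_d=float(p["tau_d"].value),
        lambda_xx=float(p["lam"].value),
        tau_r_err=err("tau_r"),
        tau_d_err=tau_d_err,
        lambda_xx_err=err("lam"),
        rss=float(np.sum(res.residual**2)),
        identifiable=bool(identifiable),
        result=res,
    )


def fit_eq5_joint(series, tau_r0=2.0, tau_d0=2.0, lambda0=-0.05):
    """Joint fit of several wings: shared tau_r/tau_d, per-wing lambda.

    ``series`` is a list of ``(t, q, r)`` triples.  Returns
    ``(tau_r, tau_d, [lambda_i], lmfit result)``.
    """
    params = lmfit.Parameters()
    params.add("tau_r", value=tau_r0, min=1e-3)
    params.add("tau_d", value=tau_d0, min=0.0)
    for i in range(len(series)):
        params.add(f"lam_{i}", value=lambda0)

    def resid(p):
        out = []
        for i, (t, q, r) in enumerate(series):
            out.append(
                _predict_r(
                    np.asarray(t), np.asarray(q),
                    p["tau_r"].value, p["tau_d"].value, p[f"lam_{i}"].value,
                    np.asarray(r)[0],
                )
                - np.asarray(r)
            )
        return np.concatenate(out)

    res = lmfit.minimize(resid, params, method="leastsq")
    lams = [float(res.params[f"lam_{i}"].value) for i in range(len(series))]
    return float(res.params["tau_r"].value), float(res.params["tau_d"].value), lams, res


# ---------------------------------------------------------------------------
# fitting the full rectangle model
# ---------------------------------------------------------------------------

_FITTABLE = {
    "zeta_xx": ("blade", "zeta_xx"),
    "kbar": ("blade", "kbar"),
    "zetabar": ("blade", "zetabar"),
    "etabar": ("blade", "etabar"),
    "k_ap_blade": ("boundary", "k_ap_blade"),
    "k_ap_hinge": ("boundary", "k_ap_hinge"),
    "k_pd_blade": ("boundary", "k_pd_blade"),
    "k_pd_hinge": ("boundary", "k_pd_hinge"),
    "gamma": ("boundary", "gamma"),
}


def fit_rectangle_model(
    datasets,
    free,
    blade: RegionParams,
    hinge: RegionParams | None,
    boundary: BoundaryParams,
    observables=("Q", "shear"),
    dt=0.02,
):
    """Fit boundary/material parameters to observed region trajectories.

    ``datasets`` is a list of dicts with keys ``t`` (time points),
    observed columns named like the simulate() output (e.g. ``Q``,
    ``shear``), and optional per-dataset overrides ``k_d``, ``k_e``,
    ``hinge_area``, ``init``, ``distal_attachment``.  ``free`` lists
    parameter names from the fittable set (zeta_xx, kbar, zetabar,
    etabar, the four spring constants and gamma); conditions sharing
    tissue parameters are fitted jointly, and freezing all parameters
    (``free=[]``) just evaluates the forward-simulation residual.

    Returns ``(blade', hinge', boundary', lmfit_result_or_None, rss)``.
    """
    free = list(free)
    unknown = set(free) - set(_FITTABLE)
    if unknown:
        raise ValueError(f"unknown fit parameters: {sorted(unknown)}")

    def build(pvals):
        bl = replace(blade)
        bd = replace(boundary)
        for name, val in pvals.items():
            target, attr = _FITTABLE[name]
            if target == "blade":
                bl = replace(bl, **{attr: val})
            else:
                bd = replace(bd, **{attr: val})
        return bl, bd

    def run_all(pvals):
        bl, bd = build(pvals)
        out = []
        for ds in datasets:
            bdi = replace(
                bd, distal_attachment=ds.get("distal_attachment", bd.distal_attachment)
            )
            t = np.asarray(ds["t"], dtype=float)
            traj = simulate(
                bl,
                hinge,
                bdi,
                k_d=ds.get("k_d", 0.0),
                k_e=ds.get("k_e", 0.0),
                hinge_area=ds.get("hinge_area"),
                t_span=(t[0], t[-1]),
                dt=dt,
                init=ds.get("init"),
            )
            for col in observables:
                pred = np.interp(t, traj["t"], traj[col])
                out.append(pred - np.asarray(ds[col], dtype=float))
        return np.concatenate(out)

    if not free:
        rss = float(np.sum(run_all({}) ** 2))
        return blade, hinge, boundary, None, rss

    params = lmfit.Parameters()
    current = {**{n: getattr(blade, _FITTABLE[n][1]) for n in free if _FITTABLE[n][0] == "blade"},
               **{n: getattr(boundary, _FITTABLE[n][1]) for n in free if _FITTABLE[n][0] == "boundary"}}
    for name in free:
        lo = 1e-4 if name == "gamma" else (0.0 if name != "zeta_xx" else -np.inf)
        params.add(name, value=float(current[name]), min=lo)

    def resid(p):
        return run_all({n: p[n].value for n in free})

    res = lmfit.minimize(resid, params, method="leastsq")
    best = {n: float(res.params[n].value) for n in free}
    bl, bd = build(best)
    return bl, hinge, bd, res, float(np.sum(res.residual**2))


def winding_angle(q, r, fixed_point=None):
    """Total winding angle of a (Q, R) trajectory around its fixed point.

    A delayed response (tau_d > 0) makes the transient spiral; with no
    delay the points are collinear and the winding angle is ~0.
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    if fixed_point is None:
        fixed_point = (q[-1], r[-1])
    # scale axes to comparable magnitude before measuring angles
    sq = max(np.ptp(q), 1e-12)
    sr = max(np.ptp(r), 1e-12)
    x = (q - fixed_point[0]) / sq
    y = (r - fixed_point[1]) / sr
    ang = np.unwrap(np.arctan2(y, x))
    return float(ang[-1] - ang[0])
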