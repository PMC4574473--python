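import numpy as np
import pytest
from scipy.linalg import expm

from epishear.rectmodel import (
    HINGE_DEFAULTS,
    BoundaryParams,
    RegionParams,
    fit_eq5,
    fit_eq5_joint,
    fit_rectangle_model,
    integrate_eq5,
    rect_dims,
    simulate,
    step_rearrangement,
    winding_angle,
)


def test_rect_dims_closed_form():
    L, h = rect_dims(100.0, 0.0)
    assert (L, h) == pytest.approx((10.0, 10.0))
    L, h = rect_dims(100.0, 0.5)
    assert L == pytest.approx(16.4872, abs=1e-3)
    assert h == pytest.approx(6.0653, abs=1e-3)
    assert L * h == pytest.approx(100.0, abs=1e-10)
    # aspect ratio convention ar = exp(2 Q_xx)
    assert L / h == pytest.approx(np.exp(2 * 0.5), rel=1e-12)


def test_step_rearrangement_instantaneous_limit():
    p = RegionParams(tau_r=1.8, tau_d=0.0, lambda_xx=0.0)
    assert step_rearrangement(0.0, 0.18, p, 0.01) == pytest.approx(0.10)


def test_step_rearrangement_exponential_approach():
    """Step elongation input: R approaches its target with time constant
    tau_d, matching the closed-form solution."""
    p = RegionParams(tau_r=2.0, tau_d=1.5, lambda_xx=-0.03)
    q = 0.25
    target = q / p.tau_r + p.lambda_xx
    r = 0.0
    dt = 1e-4
    n = int(2.0 / dt)
    for _ in range(n):
        r = step_rearrangement(r, q, p, dt)
    expected = target * (1.0 - np.exp(-2.0 / p.tau_d))
    assert r == pytest.approx(expected, abs=1e-4)


def test_simulate_zero_drives_static():
    blade = RegionParams(zeta_xx=0.0, lambda_xx=0.0, tau_d=1.0)
    bnd = BoundaryParams(k_ap_blade=2.0, gamma=5.0, distal_attachment=False)
    traj = simulate(blade, None, bnd, t_span=(0, 10), dt=0.01)
    assert np.abs(traj["shear"]).max() == 0.0
    assert np.abs(traj["v"]).max() == 0.0


def test_steady_state_elongation_is_minus_tau_r_lambda():
    """Constant inputs converge to R = 0, Q = -tau_r * lambda."""
    blade = RegionParams(zeta_xx=0.1, tau_r=1.8, tau_d=3.7, lambda_xx=-0.10, etabar=2.0)
    bnd = BoundaryParams(k_ap_blade=2.0, k_pd_blade=3.0, gamma=5.0, distal_attachment=False)
    traj = simulate(
        blade, None, bnd, t_span=(0, 400), dt=0.02, init={"Q": 0.05, "R": 0.02}
    )
    assert traj["Q"].iloc[-1] == pytest.approx(-blade.tau_r * blade.lambda_xx, abs=1e-9)
    assert abs(traj["R"].iloc[-1]) < 1e-9
    assert abs(traj["shear"].iloc[-1]) < 1e-9


def test_single_region_matches_analytic_maxwell_with_delay():
    """Spring-free, friction-only single region reduces to a linear
    (Q, R) system solvable in closed form."""
    blade = RegionParams(
        zeta_xx=0.2, tau_r=1.8, tau_d=3.7, lambda_xx=-0.1, kbar=0.0, etabar=0.0
    )
    g = 4.0
    bnd = BoundaryParams(
        k_ap_blade=0.0, k_pd_blade=0.0, gamma=g, distal_attachment=False
    )
    traj = simulate(blade, None, bnd, t_span=(0, 8), dt=0.005, init={"Q": 0.1, "R": 0.0})
    A = np.array(
        [
            [-2.0 * blade.K / g, -1.0],
            [1.0 / (blade.tau_r * blade.tau_d), -1.0 / blade.tau_d],
        ]
    )
    b = np.array([-blade.zeta_xx / g, blade.lambda_xx / blade.tau_d])
    xfix = -np.linalg.solve(A, b)
    xt = xfix + expm(A * 8.0) @ (np.array([0.1, 0.0]) - xfix)
    assert traj["Q"].iloc[-1] == pytest.approx(xt[0], abs=1e-6)
    assert traj["R"].iloc[-1] == pytest.approx(xt[1], abs=1e-6)


def _wt_setup():
    blade = RegionParams(
        zeta_xx=0.333, tau_r=1.8, tau_d=3.7, lambda_xx=-0.10,
        kbar=2.07, zetabar=0.05, etabar=49.0,
    )
    hinge = RegionParams(**HINGE_DEFAULTS, kbar=2.07)
    bnd = BoundaryParams(
        k_ap_blade=0.5, k_ap_hinge=67.8, k_pd_blade=4.91, k_pd_hinge=9.5, gamma=21.3
    )
    a_h0 = 0.3 * 0.35
    inputs = dict(
        k_d=lambda t: 0.05 * np.exp(-max(t - 16.0, 0.0) / 5.0),
        k_e=0.005,
        hinge_area=lambda t: a_h0 * (0.4 + 0.6 * np.exp(-max(t - 16.0, 0.0) / 4.0)),
    )
    init = {
        "L": 0.7, "h": 0.35, "Q": 0.05, "R": -0.05,
        "L_H": 0.3, "h_H": 0.35, "Q_H": 0.0, "R_H": -0.02,
    }
    return blade, hinge, bnd, inputs, init


def test_two_rectangle_wild_type_phase_signature():
    """Hinge contraction with a pinned distal blade: cell elongation rises
    then falls (phase I/II) while cumulative tissue shear keeps rising."""
    blade, hinge, bnd, inputs, init = _wt_setup()
    traj = simulate(blade, hinge, bnd, t_span=(16, 32), dt=0.01, init=init, **inputs)
    cum = np.cumsum(traj["shear"].to_numpy() * 0.01)
    i_peak = int(traj["Q"].idxmax())
    assert 0 < i_peak < len(traj) - 1                    # interior maximum
    assert traj["Q"].iloc[-1] < traj["Q"].max() - 0.02   # phase II relaxation
    assert cum[-1] > 0.05                                # net PD shear
    assert np.mean(np.diff(cum) > 0) > 0.85              # mostly monotonic
    assert traj["L"].iloc[-1] > traj["L"].iloc[0]        # blade elongates
    # geometry identity hL = A is maintained for the imposed hinge area
    ah = inputs["hinge_area"]
    err = max(
        abs(traj["L_H"].iloc[i] * traj["h_H"].iloc[i] - ah(traj["t"].iloc[i]))
        for i in range(0, len(traj), 200)
    )
    assert err < 1e-4


def test_detached_distal_end_reverses_shear_direction():
    """Removing the distal attachment (the dumpy condition) reverses the
    sign of the net blade shear."""
    blade, hinge, bnd, inputs, init = _wt_setup()
    import dataclasses

    bnd_free = dataclasses.replace(
        bnd, distal_attachment=False, k_pd_blade=0.0, k_ap_blade=0.005
    )
    wt = simulate(blade, hinge, bnd, t_span=(16, 32), dt=0.01, init=init, **inputs)
    dp = simulate(blade, hinge, bnd_free, t_span=(16, 32), dt=0.01, init=init, **inputs)
    cum_wt = np.sum(wt["shear"]) * 0.01
    cum_dp = np.sum(dp["shear"]) * 0.01
    assert cum_wt > 0 and cum_dp < 0
    assert dp["L"].iloc[-1] < wt["L"].iloc[-1]  # blade shortens when detached


# ---------------------------------------------------------------------------
# fitting the delayed rearrangement law
# ---------------------------------------------------------------------------

def _ramp_q(t):
    """Non-monotonic elongation episode: rise, then relax to steady state."""
    t = np.asarray(t, dtype=float)
    return np.where(t < 6.0, 0.2 * t / 6.0, 0.18 + 0.02 * np.exp(-(t - 6.0) / 2.0))


def test_fit_eq5_noise_free_recovery():
    """Noise-free trajectories from the delayed law are refit to the
    generating coefficients to better than 1e-3 relative."""
    true = RegionParams(tau_r=1.8, tau_d=3.7, lambda_xx=-0.10)
    t = np.linspace(0.0, 16.0, 193)
    q = _ramp_q(t)
    r = integrate_eq5(t, _ramp_q, true)
    fit = fit_eq5(t, q, r)
    assert fit.tau_r == pytest.approx(1.8, rel=1e-3)
    assert fit.tau_d == pytest.approx(3.7, rel=1e-3)
    assert fit.lambda_xx == pytest.approx(-0.10, rel=1e-3)
    assert fit.identifiable


def test_fit_eq5_no_delay_limit():
    """tau_d = 0 data: (Q, R) points are collinear and the fitted delay
    is ~0."""
    true = RegionParams(tau_r=2.2, tau_d=0.0, lambda_xx=-0.06)
    t = np.linspace(0.0, 16.0, 100)
    q = _ramp_q(t)
    r = q / true.tau_r + true.lambda_xx
    resid = np.polyfit(q, r, 1)
    assert np.abs(np.polyval(resid, q) - r).max() < 1e-12  # collinear
    fit = fit_eq5(t, q, r, tau_d0=1.0)
    assert fit.tau_d == pytest.approx(0.0, abs=1e-4)
    assert fit.tau_r == pytest.approx(2.2, rel=1e-6)


def test_fit_eq5_monte_carlo_noise(rng):
    """5% noise: estimates are unbiased within the Monte-Carlo error."""
    true = RegionParams(tau_r=1.8, tau_d=3.7, lambda_xx=-0.10)
    t = np.linspace(0.0, 16.0, 97)
    q = _ramp_q(t)
    r = integrate_eq5(t, _ramp_q, true)
    sigma = 0.05 * np.abs(r).max()
    taus_d, taus_r = [], []
    for _ in range(30):
        fit = fit_eq5(t, q, r + rng.normal(0, sigma, len(r)))
        taus_d.append(fit.tau_d)
        taus_r.append(fit.tau_r)
    assert np.median(taus_d) == pytest.approx(3.7, rel=0.25)
    assert np.median(taus_r) == pytest.approx(1.8, rel=0.25)


def test_fit_eq5_joint_shared_timescales():
    """Joint fit across wings shares tau_r/tau_d and recovers per-wing
    lambda values."""
    lams = [-0.11, -0.10, -0.068]
    t = np.linspace(0.0, 16.0, 120)
    series = []
    for lam in lams:
        p = RegionParams(tau_r=1.7, tau_d=4.2, lambda_xx=lam)
        series.append((t, _ramp_q(t), integrate_eq5(t, _ramp_q, p)))
    tau_r, tau_d, fitted, _ = fit_eq5_joint(series)
    assert tau_r == pytest.approx(1.7, rel=1e-3)
    assert tau_d == pytest.approx(4.2, rel=1e-3)
    assert fitted == pytest.approx(lams, rel=1e-3)


def test_delay_produces_spiral_no_delay_collinear():
    """In the (Q, R) plane a delayed transient spirals toward the fixed
    point; without delay the trajectory carries no winding."""
    t = np.linspace(0.0, 16.0, 400)
    delayed = RegionParams(tau_r=1.8, tau_d=3.7, lambda_xx=-0.10)
    r_d = integrate_eq5(t, _ramp_q, delayed)
    assert abs(winding_angle(_ramp_q(t), r_d)) > np.pi / 2
    instant = RegionParams(tau_r=1.8, tau_d=0.0, lambda_xx=-0.10)
    r_i = _ramp_q(t) / instant.tau_r + instant.lambda_xx
    corr = np.corrcoef(_ramp_q(t), r_i)[0, 1]
    assert corr == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# full rectangle-model fit
# ---------------------------------------------------------------------------

def test_fit_rectangle_model_recovers_boundary_params():
    """Simulate-then-fit: boundary constants recovered within the fit
    uncertainty."""
    blade = RegionParams(zeta_xx=0.333, etabar=10.0)
    hinge = RegionParams(**HINGE_DEFAULTS)
    truth = BoundaryParams(k_ap_blade=0.5, k_ap_hinge=20.0, k_pd_hinge=9.5, gamma=21.3)
    a_h0 = 0.3 * 0.35
    ah = lambda t: a_h0 * (0.5 + 0.5 * np.exp(-max(t - 16.0, 0.0) / 4.0))
    init = {"L": 0.7, "h": 0.35, "Q": 0.05, "R": -0.05, "L_H": 0.3, "h_H": 0.35}
    traj = simulate(blade, hinge, truth, hinge_area=ah, t_span=(16, 28), dt=0.02, init=init)
    tt = np.linspace(16, 28, 25)
    obs = {
        "t": tt,
        "Q": np.interp(tt, traj["t"], traj["Q"]),
        "shear": np.interp(tt, traj["t"], traj["shear"]),
        "hinge_area": ah,
        "init": init,
    }
    import dataclasses

    start = dataclasses.replace(truth, k_ap_blade=1.5, k_pd_hinge=5.0)
    _, _, fitted, res, rss = fit_rectangle_model(
        [obs], ["k_ap_blade", "k_pd_hinge"], blade, hinge, start, dt=0.02
    )
    assert fitted.k_ap_blade == pytest.approx(0.5, abs=0.05)
    assert fitted.k_pd_hinge == pytest.approx(9.5, abs=0.25)
    assert rss < 1e-10


def test_fit_rectangle_model_frozen_mask_is_forward_residual():
    blade = RegionParams(zeta_xx=0.1, etabar=5.0)
    bnd = BoundaryParams(k_ap_blade=1.0, gamma=10.0, distal_attachment=False)
    traj = simulate(blade, None, bnd, t_span=(0, 5), dt=0.02, init={"Q": 0.1})
    tt = np.linspace(0, 5, 11)
    obs = {
        "t": tt,
        "Q": np.interp(tt, traj["t"], traj["Q"]) + 0.01,
        "shear": np.interp(tt, traj["t"], traj["shear"]),
        "init": {"Q": 0.1},
        "distal_attachment": False,
    }
    _, _, _, res, rss = fit_rectangle_model([obs], [], blade, None, bnd, dt=0.02)
    assert res is None
    assert rss == pytest.approx(11 * 0.01**2, rel=1e-6)
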