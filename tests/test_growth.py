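"""Growth-map closed form against brute-force integration; lignification."""

import numpy as np
import pytest

from morphorod.growth import (
    GrowthMap,
    GrowthParams,
    InputError,
    LignificationParams,
    advance_growth,
    growth_curve,
    regr_profile,
    young_modulus,
)

H = 3600.0
FIG3 = GrowthParams(ell0=0.01, ell_g=0.03, tau_g=20 * H)


def brute_force_map(params, S, t_end, dt=10.0):
    """Independent oracle: RK4 march of dgamma/dt = REGR(s) gamma at dt = 10 s."""
    gamma = np.ones_like(S)

    def current_s(g):
        out = np.zeros_like(g)
        out[1:] = np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(S))
        return out

    def rhs(g):
        s = current_s(g)
        return np.where(s <= s[-1] - params.ell_g, 0.0, 1.0 / params.tau_g) * g

    steps = int(round(t_end / dt))
    for _ in range(steps):
        k1 = rhs(gamma)
        k2 = rhs(gamma + 0.5 * dt * k1)
        k3 = rhs(gamma + 0.5 * dt * k2)
        k4 = rhs(gamma + dt * k3)
        gamma = gamma + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return current_s(gamma), gamma


def test_analytic_matches_brute_force_integration():
    # material grid refined geometrically toward the apex: at late times the
    # growth zone maps back to a thin material sliver near S = l0
    S = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, FIG3.ell0, 61),
                FIG3.ell0 - np.geomspace(1e-4 * FIG3.ell0, 0.5 * FIG3.ell0, 321),
                [FIG3.ell0],
            ]
        )
    )
    gmap0 = GrowthMap.from_material_grid(FIG3, S)
    for t_h in (10.0, 30.0, 100.0):
        m = gmap0.at_time(t_h * H)
        s_bf, _ = brute_force_map(FIG3, S, t_h * H)
        err = np.max(np.abs(m.s - s_bf)) / m.length
        assert err <= 1e-4, f"t = {t_h} h: relative error {err:.2e}"


def test_exponential_then_linear_elongation():
    # l reaches the growth-zone length 3 cm at t = 20 ln 3 h
    t1 = FIG3.t_linear
    assert np.isclose(t1 / H, 20.0 * np.log(3.0), rtol=1e-12)
    assert np.isclose(FIG3.length(t1), 0.03)
    # early branch is exponential
    assert np.isclose(FIG3.length(10 * H), 0.01 * np.exp(0.5))
    # late branch is linear at lg / tau_g = 0.15 cm/h
    rate = (FIG3.length(100 * H) - FIG3.length(90 * H)) / (10 * H)
    assert np.isclose(rate, 0.03 / (20 * H), rtol=1e-12)
    assert np.isclose(rate * H * 100, 0.15)  # cm per hour


def test_initial_condition_and_monotonicity():
    gmap0 = GrowthMap.initial(FIG3, n_nodes=40)
    assert np.allclose(gmap0.s, gmap0.S)
    assert np.allclose(gmap0.gamma, 1.0)
    prev_len = 0.0
    prev_gamma = np.zeros(40)
    for t in np.linspace(0, 80 * H, 9):
        m = gmap0.at_time(t)
        assert np.all(np.diff(m.s) > 0), "material points must not cross"
        assert np.all(m.gamma >= prev_gamma - 1e-12), "stretch is monotone in t"
        assert m.length >= prev_len
        prev_len, prev_gamma = m.length, m.gamma


def test_exit_times_and_frozen_positions():
    gmap0 = GrowthMap.initial(FIG3, n_nodes=21)
    t1 = FIG3.t_linear
    # base exits exactly when l = lg; apex never exits
    assert np.isclose(gmap0.t_exit[0], t1)
    assert np.isinf(gmap0.t_exit[-1])
    # after exit a node is frozen at distance lg behind the contemporary tip
    S5 = gmap0.S[5]
    t_ex = gmap0.t_exit[5]
    m = gmap0.at_time(t_ex * 1.5)
    assert np.isclose(m.s[5], FIG3.length(t_ex) - FIG3.ell_g, rtol=1e-10)
    later = gmap0.at_time(t_ex * 2.0)
    assert np.isclose(later.s[5], m.s[5], rtol=1e-12)


def test_regr_profile_cases():
    p = GrowthParams(ell0=0.01, ell_g=0.04, tau_g=20 * H)
    assert regr_profile(0.0, 0.05, p) == 0.0  # base below the zone
    assert regr_profile(0.05, 0.05, p) == 1.0 / (20 * H)  # apex always grows
    # whole shoot inside the growth zone
    assert np.all(regr_profile(np.linspace(0, 0.03, 7), 0.03, p) == 1.0 / (20 * H))
    with pytest.raises(InputError):
        regr_profile(0.06, 0.05, p)


def test_regr_recovered_from_stretch_rate():
    gmap0 = GrowthMap.initial(FIG3, n_nodes=31)
    t, dt = 40 * H, 60.0
    m0, m1 = gmap0.at_time(t), gmap0.at_time(t + dt)
    regr_fd = (np.log(m1.gamma) - np.log(m0.gamma)) / dt
    expected = m0.epsdot()
    away_from_exit = np.abs(gmap0.t_exit - t) > 2 * dt
    assert np.allclose(regr_fd[away_from_exit], expected[away_from_exit], atol=1e-9)


def test_young_modulus_lignification():
    lign = LignificationParams(E0=1e7, E1=2e9, tau_l=6 * 86400.0)
    assert young_modulus(5000.0, 4000.0, lign) == pytest.approx(1e7)
    assert young_modulus(0.0, 1e10, lign) == pytest.approx(2e9)
    t_star = 3000.0
    expected = 2e9 - (2e9 - 1e7) / np.e
    assert young_modulus(t_star, t_star + lign.tau_l, lign) == pytest.approx(expected)
    # apex (never exits) stays soft
    assert young_modulus(np.inf, 1e9, lign) == pytest.approx(1e7)
    assert np.all(np.diff(young_modulus(np.array([0.0]), 0.0, lign)) == 0)


def test_numeric_fallback_when_shoot_longer_than_zone():
    p = GrowthParams(ell0=0.05, ell_g=0.03, tau_g=20 * H)
    assert not p.analytic
    gmap0 = GrowthMap.initial(p, n_nodes=41)
    m = gmap0.at_time(30 * H)
    assert np.all(np.diff(m.s) > 0)
    assert m.length > p.ell0
    # material initially below the growth zone never grows: s = S there
    never_grew = gmap0.S <= p.ell0 - p.ell_g
    assert np.allclose(m.s[never_grew], m.S[never_grew], rtol=1e-9)
    # late elongation rate tends to lg / tau_g
    m2 = gmap0.at_time(40 * H)
    rate = (m2.length - m.length) / (10 * H)
    assert np.isclose(rate, p.ell_g / p.tau_g, rtol=0.02)


def test_advance_growth_wrapper_and_curve_export():
    gmap0 = GrowthMap.initial(FIG3, n_nodes=17)
    m = advance_growth(gmap0, FIG3, 10 * H)
    assert m.t == 10 * H
    with pytest.raises(InputError):
        advance_growth(gmap0, GrowthParams(0.01, 0.04, 20 * H), 10 * H)
    df = growth_curve(FIG3, np.linspace(0, 50 * H, 6))
    assert {"t", "ell"}.issubset(df.columns)
    assert df["ell"].is_monotonic_increasing
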