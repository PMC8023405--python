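"""Elastic equilibrium under gravity: beam-theory oracles and buckling."""

import numpy as np
import pytest

from morphorod.elastostatics import (
    ElasticParams,
    InputError,
    contact_force,
    distributed_load,
    self_buckling_alpha0,
    self_buckling_alpha0_bessel,
    self_buckling_length,
    solve_equilibrium,
    stiffnesses,
)
from morphorod.kinematics import Frame, RodGrid

BASELINE = ElasticParams()  # baseline: E = 10 MPa, r = 0.5 mm, nu = 0.5, rho = 1e3


def horizontal_base():
    # clamped horizontal cantilever: d3 along x, gravity along -z
    return Frame(np.array([0.0, 1, 0]), np.array([0.0, 0, 1]), np.array([1.0, 0, 0]))


class TestStiffness:
    def test_bending_stiffness_value(self):
        K1, K2, K3 = stiffnesses(BASELINE)
        assert K1 == pytest.approx(4.909e-7, rel=1e-3)  # EI = E pi r^4 / 4
        assert K1 == K2

    def test_radius_fourth_power_scaling(self):
        K1a = stiffnesses(BASELINE)[0]
        K1b = stiffnesses(BASELINE.with_(r=2 * BASELINE.r))[0]
        assert K1b / K1a == pytest.approx(16.0)

    def test_shear_modulus_conventions(self):
        K1, _, K3 = stiffnesses(BASELINE)  # standard: mu = E/(2(1+nu))
        assert K3 / K1 == pytest.approx(2.0 / 3.0)
        K1p, _, K3p = stiffnesses(BASELINE.with_(shear_modulus_convention="as_printed"))
        assert K3p / K1p == pytest.approx(4.0 * (1.0 + BASELINE.nu_poisson))


class TestContactForce:
    def test_free_tip_and_base_load(self):
        q = distributed_load(BASELINE)
        ell = 0.05
        n = contact_force(np.array([0.0, ell]), ell, q)
        assert np.allclose(n[1], 0.0)  # n(l) = 0
        assert np.isclose(np.linalg.norm(n[0]), q * ell)
        assert np.allclose(n[0] / np.linalg.norm(n[0]), [0, 0, -1.0])
        assert np.all(contact_force(np.array([0.02]), ell, 0.0) == 0.0)


class TestEquilibrium:
    def test_no_gravity_returns_intrinsic_shape(self):
        n = 101
        grid = RodGrid.uniform(0.05, n)
        u_star = np.zeros((n, 2))
        u_star[:, 0] = 12.0  # intrinsic arc
        res = solve_equilibrium(u_star, grid, BASELINE, q=0.0)
        assert res.converged
        assert np.allclose(res.state.u[:, 0], 12.0, atol=1e-12)
        assert np.allclose(res.elastic.m, 0.0)
        assert np.allclose(res.elastic.u_e, 0.0, atol=1e-12)

    def test_heavy_cantilever_small_deflection(self):
        # tip deflection of a light horizontal cantilever: q l^4 / (8 EI)
        ell = 0.0075
        n = 201
        grid = RodGrid.uniform(ell, n)
        q = distributed_load(BASELINE)
        EI = stiffnesses(BASELINE)[0]
        expected = q * ell**4 / (8.0 * EI)
        assert expected <= 1e-3 * ell  # linear regime
        res = solve_equilibrium(
            np.zeros((n, 2)), grid, BASELINE, base_frame=horizontal_base()
        )
        deflection = -res.state.p[-1, 2]
        assert deflection == pytest.approx(expected, rel=0.01)

    def test_elastic_strain_linear_in_small_loads(self):
        ell = 0.0075
        n = 101
        grid = RodGrid.uniform(ell, n)
        q = distributed_load(BASELINE)
        r1 = solve_equilibrium(
            np.zeros((n, 2)), grid, BASELINE, base_frame=horizontal_base(), q=0.2 * q
        )
        r2 = solve_equilibrium(
            np.zeros((n, 2)), grid, BASELINE, base_frame=horizontal_base(), q=0.4 * q
        )
        ratio = r2.state.p[-1, 2] / r1.state.p[-1, 2]
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_moment_balance_residual(self):
        # bent vertical rod: discrete dm/ds must match q (l - s) g x d3
        n = 201
        ell = 0.06
        grid = RodGrid.uniform(ell, n)
        u_star = np.zeros((n, 2))
        u_star[:, 0] = 8.0
        res = solve_equilibrium(u_star, grid, BASELINE)
        q = distributed_load(BASELINE)
        m = res.elastic.m
        d3 = res.state.d3
        g = np.array([0.0, 0.0, -1.0])
        rhs = q * (ell - grid.s)[:, None] * np.cross(g, d3)
        dm = np.gradient(m, grid.s, axis=0, edge_order=2)
        resid = np.max(np.linalg.norm(dm - rhs, axis=1))
        assert resid <= 1e-3 * q * ell
        # boundary condition m(l) = 0 holds exactly
        assert np.all(m[-1] == 0.0)

    def test_planarity_preserved(self):
        n = 151
        grid = RodGrid.uniform(0.06, n)
        u_star = np.zeros((n, 2))
        u_star[:, 0] = 10.0  # bends in the y-z plane; gravity in-plane
        res = solve_equilibrium(u_star, grid, BASELINE)
        assert np.max(np.abs(res.state.p[:, 0])) < 1e-12

    def test_sub_and_supercritical_straight_column(self):
        ellc = self_buckling_length(BASELINE)
        for factor, stays_straight in ((0.9, True), (1.06, False)):
            n = 101
            grid = RodGrid.uniform(factor * ellc, n)
            tilt = np.zeros((n, 3))
            tilt[:, 0] = 1e-3 / grid.length
            res = solve_equilibrium(
                np.zeros((n, 2)),
                grid,
                BASELINE,
                u_init=tilt,
                max_iter=400,
                raise_on_fail=False,
            )
            horizontal = np.hypot(res.state.p[-1, 0], res.state.p[-1, 1])
            if stays_straight:
                assert res.converged
                assert horizontal < 1e-6 * grid.length
            else:
                assert (not res.converged) or horizontal > 1e-3 * grid.length


class TestSelfBuckling:
    def test_greenhill_coefficient_routes_agree(self):
        a_fd = self_buckling_alpha0()
        a_bessel = self_buckling_alpha0_bessel()
        assert a_bessel == pytest.approx(7.837, rel=5e-4)
        assert abs(a_fd - a_bessel) / a_bessel < 1e-4

    def test_eigenvalue_converges_with_mesh(self):
        exact = self_buckling_alpha0_bessel()
        errs = [
            abs(self_buckling_alpha0(n, richardson=False) - exact)
            for n in (100, 200, 400)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_self_buckling_length_baseline(self):
        ellc = self_buckling_length(BASELINE)
        assert ellc == pytest.approx(0.0793, rel=2e-3)
        assert 0.0659 / ellc == pytest.approx(0.83, abs=0.01)

    def test_length_scalings_and_no_gravity_limit(self):
        ellc = self_buckling_length(BASELINE)
        stiffer = BASELINE.with_(E=8 * np.asarray(BASELINE.E))
        assert self_buckling_length(stiffer) == pytest.approx(2 * ellc, rel=1e-12)
        assert np.isinf(self_buckling_length(BASELINE, q=0.0))
        with pytest.raises(InputError):
            self_buckling_length(BASELINE, q=-1.0)
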