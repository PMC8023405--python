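"""Rod reconstruction from strains: closed-form oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from morphorod.kinematics import (
    Frame,
    InputError,
    RodGrid,
    curvature_and_normal,
    integrate_frame,
    read_snapshot,
    tip_position,
    write_snapshot,
)


def se3_exponential(u, s):
    """Exact rod configuration for constant strain u: SE(3) matrix exponential."""
    W = np.array(
        [
            [0.0, -u[2], u[1], 0.0],
            [u[2], 0.0, -u[0], 0.0],
            [-u[1], u[0], 0.0, 1.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    # twist in the body frame: rotation rate [u]x, translation rate e3
    T = expm(W * s)
    return T[:3, :3], T[:3, 3]


def random_u_field(rng, n):
    return rng.normal(0.0, 5.0, (n, 3))


def test_zero_strain_gives_straight_rod():
    grid = RodGrid.uniform(0.03, 51)
    state = integrate_frame(np.zeros((51, 3)), Frame.identity(), grid)
    assert np.allclose(state.p[:, 2], grid.s)
    assert np.allclose(state.p[:, :2], 0.0)
    assert np.allclose(state.directors, np.eye(3)[None])
    assert np.allclose(tip_position(state), [0, 0, 0.03])


@pytest.mark.parametrize(
    "u_const",
    [
        (0.0, 1.0, 0.0),  # planar circular arc, radius 1 m
        (0.3, -0.4, 0.0),
        (1.2, 0.7, 2.0),  # helical: bending plus torsion
    ],
)
def test_constant_strain_matches_matrix_exponential(u_const):
    ell = np.pi / 2
    n = 401
    grid = RodGrid.uniform(ell, n)
    u = np.tile(u_const, (n, 1))
    state = integrate_frame(u, Frame.identity(), grid)
    for i in (n // 2, n - 1):
        R_exact, p_exact = se3_exponential(u_const, grid.s[i])
        assert np.allclose(state.directors[i], R_exact, atol=1e-12)
        assert np.allclose(state.p[i], p_exact, atol=1e-12)


def test_quarter_circle_geometry():
    # u = (0, 1, 0) over l = pi/2: quarter circle of radius 1 in the x-z plane
    n = 201
    grid = RodGrid.uniform(np.pi / 2, n)
    u = np.zeros((n, 3))
    u[:, 1] = 1.0
    state = integrate_frame(u, Frame.identity(), grid)
    tip = tip_position(state)
    assert np.allclose(tip, [1.0, 0.0, 1.0], atol=1e-12)
    assert np.isclose(np.linalg.norm(tip), np.sqrt(2.0))
    # tip tangent rotated 90 degrees from the base tangent
    assert np.isclose(state.d3[-1] @ state.d3[0], 0.0, atol=1e-12)
    # the visible normal points to the arc center (1, 0, 0) at every node
    kappa, nu, defined = curvature_and_normal(state)
    assert defined.all()
    centers = state.p + nu / kappa[:, None]
    assert np.allclose(centers, [1.0, 0.0, 0.0], atol=1e-10)


@given(seed=st.integers(0, 2**31 - 1))
def test_orthonormality_after_reconstruction(seed):
    rng = np.random.default_rng(seed)
    n = 64
    grid = RodGrid.uniform(0.1, n)
    u = rng.normal(0.0, 30.0, (n, 3))
    state = integrate_frame(u, Frame.identity(), grid)
    assert state.frame_gram_error() <= 1e-9
    # d3 = d1 x d2 at every node
    assert np.allclose(np.cross(state.d1, state.d2), state.d3, atol=1e-9)
    # arc length bounds the chord
    assert np.linalg.norm(tip_position(state)) <= grid.length * (1 + 1e-12)


def test_tangent_consistency_and_inextensibility(rng):
    n = 400
    grid = RodGrid.uniform(0.08, n)
    s = grid.s
    u = np.column_stack(
        [30 * np.sin(40 * s), 25 * np.cos(70 * s), 10 * s / s[-1]]
    )
    state = integrate_frame(u, Frame.identity(), grid)
    # discrete tangent matches d3 to discretization order
    dp = np.diff(state.p, axis=0) / np.diff(s)[:, None]
    mid_d3 = 0.5 * (state.d3[1:] + state.d3[:-1])
    assert np.max(np.linalg.norm(dp - mid_d3, axis=1)) < 5e-4
    # reconstructed polyline length equals the arc length to O(h^2)
    chord = np.linalg.norm(np.diff(state.p, axis=0), axis=1).sum()
    assert abs(chord - grid.length) < 1e-5 * grid.length


def test_second_order_convergence():
    ell = 0.1

    def tip_at(n):
        grid = RodGrid.uniform(ell, n)
        s = grid.s
        u = np.column_stack([40 * np.sin(60 * s), 35 * np.cos(90 * s), 20 * s / ell])
        return tip_position(integrate_frame(u, Frame.identity(), grid))

    ref = tip_at(6401)
    e1 = np.linalg.norm(tip_at(101) - ref)
    e2 = np.linalg.norm(tip_at(201) - ref)
    assert e1 / e2 > 3.5  # second-order scheme: halving h quarters the error


def test_curvature_values_and_straight_flag():
    n = 11
    grid = RodGrid.uniform(1.0, n)
    u = np.zeros((n, 3))
    u[:, 0] = 0.3
    u[:, 1] = 0.4
    state = integrate_frame(u, Frame.identity(), grid)
    kappa, nu, defined = curvature_and_normal(state)
    assert np.allclose(kappa, 0.5)
    assert defined.all()
    assert np.allclose(np.linalg.norm(nu, axis=1), 1.0)

    straight = integrate_frame(np.zeros((n, 3)), Frame.identity(), grid)
    kappa, nu, defined = curvature_and_normal(straight)
    assert np.all(kappa == 0.0)
    assert not defined.any()
    assert np.isnan(nu).all()


def test_snapshot_round_trip(tmp_path, rng):
    n = 33
    grid = RodGrid.uniform(0.05, n)
    state = integrate_frame(random_u_field(rng, n), Frame.identity(), grid)
    path = tmp_path / "shape.txt"
    write_snapshot(state, path)
    back = read_snapshot(path)
    assert np.allclose(back.p, state.p)
    assert np.allclose(back.directors, state.directors)
    assert np.allclose(back.u, state.u)


def test_input_validation():
    with pytest.raises(InputError):
        RodGrid(np.array([0.0, 2.0, 1.0]))
    with pytest.raises(InputError):
        RodGrid(np.array([0.1, 0.2]))
    with pytest.raises(InputError):
        Frame(np.array([1.0, 0, 0]), np.array([0.5, 1.0, 0]), np.array([0, 0, 1.0]))
    grid = RodGrid.uniform(1.0, 5)
    with pytest.raises(InputError):
        integrate_frame(np.zeros((4, 3)), Frame.identity(), grid)
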