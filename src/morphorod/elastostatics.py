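"""Quasi-static Kirchhoff equilibrium under distributed gravity.

The visible strain decomposes additively, u = u* + u_e, with the elastic
part set by the contact couple through u_e,j = m_j / K_j. Since inertia is
negligible on the growth time scales, the couple satisfies the Kirchhoff
balance dm/ds = q (l - s) g x d3 with m(l) = 0, where q = rho g A is the
weight per unit length and g the unit gravity direction. The shape enters
through d3, so the equilibrium is a genuinely nonlinear fixed-point problem:
shape -> moment -> strains -> shape, solved here with under-relaxation.

The module also provides the classical self-weight (Greenhill) buckling
normalization: the critical length of a clamped-free vertical column,
l_c = (alpha0 EI / q)^(1/3) with alpha0 ~ 7.837.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.optimize import brentq
from scipy.sparse.linalg import eigsh
from scipy.special import jv

from ._kernels import equilibrium_fixed_point
from .kinematics import Frame, RodGrid, RodState

__all__ = [
    "ElasticParams",
    "ElasticState",
    "EquilibriumResult",
    "EquilibriumError",
    "stiffnesses",
    "distributed_load",
    "contact_force",
    "solve_equilibrium",
    "self_buckling_alpha0",
    "self_buckling_alpha0_bessel",
    "self_buckling_length",
]

DEFAULT_G_DIR = np.array([0.0, 0.0, -1.0])


class InputError(ValueError):
    pass


class EquilibriumError(RuntimeError):
    """Fixed-point non-convergence: the rod is at or beyond a fold/buckling."""

    def __init__(self, message: str, result: "EquilibriumResult | None" = None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class ElasticParams:
    """Elastic and loading constants.

    ``E`` may be a scalar or a per-node array (lignified rods). The printed
    source for the shear modulus of an isotropic rod is ambiguous in this
    problem family; ``shear_modulus_convention`` selects between the standard
    isotropic formula mu = E / (2 (1 + nu)) (default) and the alternative
    mu = 2 E (1 + nu). Torsional stiffness is inert in the planar and
    near-vertical regimes studied, but the choice is surfaced, not hidden.
    """

    E: float | np.ndarray = 1.0e7
    r: float = 5e-4
    nu_poisson: float = 0.5
    rho: float = 1.0e3
    g_accel: float = 9.81
    shear_modulus_convention: str = "standard"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.E) <= 0):
            raise InputError("E must be positive")
        if not (0.0 <= self.nu_poisson <= 0.5):
            raise InputError("Poisson ratio must be in [0, 0.5]")
        if self.r <= 0:
            raise InputError("radius must be positive")
        if self.shear_modulus_convention not in ("standard", "as_printed"):
            raise InputError("shear_modulus_convention: 'standard' or 'as_printed'")

    def with_(self, **kw) -> "ElasticParams":
        return replace(self, **kw)


def stiffnesses(params: ElasticParams):
    """Bending and torsional stiffnesses (K1, K2, K3) = (EI, EI, mu J)."""
    E = np.asarray(params.E, float)
    I = np.pi * params.r**4 / 4.0
    K1 = E * I
    if params.shear_modulus_convention == "standard":
        mu = E / (2.0 * (1.0 + params.nu_poisson))
    else:  # as_printed
        mu = 2.0 * E * (1.0 + params.nu_poisson)
    K3 = mu * 2.0 * I
    return K1, K1, K3


def distributed_load(params: ElasticParams) -> float:
    """Weight per unit length q = rho g A [N/m]."""
    return params.rho * params.g_accel * np.pi * params.r**2


def contact_force(s, ell: float, q: float, g_dir=DEFAULT_G_DIR) -> np.ndarray:
    """n(s) = q (l - s) g: the weight of the rod above the cross section."""
    s = np.atleast_1d(np.asarray(s, float))
    if np.any(s < 0) or np.any(s > ell * (1 + 1e-12)):
        raise InputError("arc length outside [0, l]")
    return q * (ell - s)[:, None] * np.asarray(g_dir, float)[None, :]


@dataclass
class ElasticState:
    """Contact couple/force and elastic strains at equilibrium."""

    m: np.ndarray  # (n, 3) contact couple, lab components [N m]
    n_force: np.ndarray  # (n, 3) contact force [N]
    u_e: np.ndarray  # (n, 3) elastic strain components [1/m]


@dataclass
class EquilibriumResult:
    state: RodState
    elastic: ElasticState
    iterations: int
    converged: bool


def _stiffness_field(params: ElasticParams, n: int) -> np.ndarray:
    K1, K2, K3 = stiffnesses(params)
    K = np.empty((n, 3))
    K[:, 0] = K1
    K[:, 1] = K2
    K[:, 2] = K3
    return K


def solve_equilibrium(
    u_star: np.ndarray,
    grid: RodGrid,
    params: ElasticParams,
    g_dir=DEFAULT_G_DIR,
    base_frame: Frame | None = None,
    *,
    q: float | None = None,
    u_init: np.ndarray | None = None,
    tol_tip: float = 1e-9,
    max_iter: int = 200,
    relax: float = 0.5,
    raise_on_fail: bool = True,
) -> EquilibriumResult:
    """Solve the nonlinear rod equilibrium for given spontaneous strains.

    Parameters
    ----------
    u_star : (n, 2) or (n, 3) spontaneous strain components; any third
        (torsional) component must be zero.
    q : overrides the distributed load (q = 0 switches gravity off).
    u_init : warm start for the visible strains (defaults to u_star).

    Returns the converged configuration and the elastic state; raises
    :class:`EquilibriumError` on non-convergence unless ``raise_on_fail`` is
    false (proximity to self-buckling makes the fixed point non-contractive,
    which is a physical signal, not a numerical accident).
    """
    n = grid.n_nodes
    u_star = np.asarray(u_star, float)
    if u_star.shape == (n, 2):
        u_star3 = np.zeros((n, 3))
        u_star3[:, :2] = u_star
    elif u_star.shape == (n, 3):
        if np.any(u_star[:, 2] != 0.0):
            raise InputError("spontaneous torsion u*_3 must be zero")
        u_star3 = u_star.copy()
    else:
        raise InputError(f"u_star must be ({n}, 2) or ({n}, 3)")
    if base_frame is None:
        base_frame = Frame.identity()
    g_dir = np.asarray(g_dir, float)
    if abs(np.linalg.norm(g_dir) - 1.0) > 1e-9:
        raise InputError("g_dir must be a unit vector")
    if q is None:
        q = distributed_load(params)
    K = _stiffness_field(params, n)
    u0 = np.ascontiguousarray(u_init if u_init is not None else u_star3, float)
    u, R, p, m, iters, converged = equilibrium_fixed_point(
        grid.s,
        np.ascontiguousarray(u_star3),
        np.ascontiguousarray(K),
        float(q),
        np.ascontiguousarray(g_dir),
        base_frame.matrix,
        u0,
        float(tol_tip),
        int(max_iter),
        float(relax),
    )
    state = RodState(grid=grid, p=p, directors=R, u=u)
    elastic = ElasticState(
        m=m,
        n_force=contact_force(grid.s, grid.length, q, g_dir),
        u_e=u - u_star3,
    )
    result = EquilibriumResult(state, elastic, int(iters), bool(converged))
    if not converged and raise_on_fail:
        raise EquilibriumError(
            f"equilibrium fixed point did not converge in {max_iter} iterations "
            f"(l = {grid.length:.4g} m); likely at/beyond a fold or buckling",
            result,
        )
    return result


def self_buckling_alpha0(n: int = 1600, richardson: bool = True) -> float:
    """Marginal self-weight buckling coefficient alpha0 = q l_c^3 / (EI).

    Discretized eigenvalue problem for a clamped-free vertical prismatic
    column: -theta'' = lambda (1 - sigma) theta on (0, 1), theta(0) = 0,
    theta'(1) = 0 (theta is the slope angle). Second-order finite
    differences; Richardson extrapolation in the grid step by default.
    """

    def _eig(m: int) -> float:
        h = 1.0 / m
        main = np.full(m, 2.0)
        main[-1] = 2.0  # ghost-node Neumann at sigma = 1
        off = -np.ones(m - 1)
        A = sparse.diags([off, main, off], [-1, 0, 1], format="csc") / h**2
        A = A.tolil()
        A[m - 1, m - 2] = -2.0 / h**2
        A = A.tocsc()
        sigma = (np.arange(1, m + 1)) * h
        B = sparse.diags(1.0 - sigma, format="csc")
        # largest mu of B x = mu A x  <->  smallest lambda = 1/mu of A x = lambda B x
        mu = eigsh(B, k=1, M=A, which="LA", return_eigenvectors=False)[0]
        return 1.0 / mu

    lam_n = _eig(n)
    if not richardson:
        return float(lam_n)
    lam_half = _eig(n // 2)
    return float((4.0 * lam_n - lam_half) / 3.0)


def self_buckling_alpha0_bessel() -> float:
    """Closed-form route: alpha0 = (9/4) j^2, j the first zero of J_(-1/3)."""
    j = brentq(lambda x: jv(-1.0 / 3.0, x), 1.0, 3.0, xtol=1e-14)
    return 2.25 * j * j


def self_buckling_length(
    params: ElasticParams, q: float | None = None, alpha0: float | None = None
) -> float:
    """Self-buckling length l_c = (alpha0 EI / q)^(1/3).

    Returns +inf when q = 0 (no gravity load means no elastic limit). For a
    lignified (per-node E) rod the uniform initial modulus min(E) is used,
    matching the short-time regime in which the normalization is quoted.
    """
    if q is None:
        q = distributed_load(params)
    if q < 0:
        raise InputError("q must be non-negative")
    if q == 0.0:
        return np.inf
    if alpha0 is None:
        alpha0 = self_buckling_alpha0_bessel()
    E = float(np.min(np.asarray(params.E)))
    EI = E * np.pi * params.r**4 / 4.0
    return float((alpha0 * EI / q) ** (1.0 / 3.0))
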