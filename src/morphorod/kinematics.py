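"""Rod configuration: centerline, director frame, and strain vector.

A rod configuration is the centerline p(s) together with an orthonormal frame
of directors {d1, d2, d3} at each arc-length node; d3 is the centerline
tangent and the Darboux (strain) vector u, expressed in the local basis,
encodes bending (u1, u2) and torsion (u3) through d_j' = u x d_j. The rod is
unshearable and elastically inextensible, so arc length is preserved and the
visible shape is fully determined by u and the clamped base frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import frame_path

__all__ = [
    "RodGrid",
    "Frame",
    "RodState",
    "integrate_frame",
    "curvature_and_normal",
    "tip_position",
    "write_snapshot",
    "read_snapshot",
    "KAPPA_FLOOR",
]

#: curvature below which the visible normal is flagged undefined [1/m]
KAPPA_FLOOR = 1e-8

_ORTHO_TOL = 1e-9


class InputError(ValueError):
    """Invalid input to a kinematic operation."""


@dataclass(frozen=True)
class RodGrid:
    """Arc-length sample points s[0] = 0 <= ... <= s[-1] = current length."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        if s.ndim != 1 or s.size < 2:
            raise InputError("grid needs at least two nodes")
        if s[0] != 0.0:
            raise InputError("grid must start at s = 0")
        if np.any(np.diff(s) <= 0):
            raise InputError("grid must be strictly increasing")

    @classmethod
    def uniform(cls, length: float, n_nodes: int = 200) -> "RodGrid":
        if length <= 0:
            raise InputError("length must be positive")
        return cls(np.linspace(0.0, length, n_nodes))

    @property
    def n_nodes(self) -> int:
        return self.s.size

    @property
    def length(self) -> float:
        return float(self.s[-1])


@dataclass(frozen=True)
class Frame:
    """Orthonormal director triad; d3 = d1 x d2."""

    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        M = self.matrix
        if np.max(np.abs(M.T @ M - np.eye(3))) > _ORTHO_TOL:
            raise InputError("frame is not orthonormal to 1e-9")
        if np.max(np.abs(np.cross(self.d1, self.d2) - self.d3)) > _ORTHO_TOL:
            raise InputError("frame must satisfy d3 = d1 x d2")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation with the directors as columns."""
        return np.column_stack([self.d1, self.d2, self.d3])

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "Frame":
        M = np.asarray(M, float)
        return cls(M[:, 0].copy(), M[:, 1].copy(), M[:, 2].copy())


@dataclass
class RodState:
    """Discrete rod configuration on a grid.

    Attributes
    ----------
    grid : RodGrid
    p : (n, 3) centerline points [m], p[0] = 0
    directors : (n, 3, 3) rotation matrices, columns (d1, d2, d3)
    u : (n, 3) strain components (u1, u2, u3) in the local basis [1/m]
    """

    grid: RodGrid
    p: np.ndarray
    directors: np.ndarray
    u: np.ndarray

    d1 = property(lambda self: self.directors[:, :, 0])
    d2 = property(lambda self: self.directors[:, :, 1])
    d3 = property(lambda self: self.directors[:, :, 2])

    @property
    def base_frame(self) -> Frame:
        return Frame.from_matrix(self.directors[0])

    def frame_gram_error(self) -> float:
        """Max deviation of the director Gram matrices from identity."""
        G = np.einsum("nij,nik->njk", self.directors, self.directors)
        return float(np.max(np.abs(G - np.eye(3))))


def integrate_frame(
    u_components: np.ndarray, base_frame: Frame, grid: RodGrid
) -> RodState:
    """Reconstruct the rod from its strain field.

    Integrates d_j' = u x d_j and p' = d3 from the clamped base using a
    rotation-group-preserving scheme (per-interval exponential of the
    midpoint-averaged strain), so the frame invariants hold to machine
    precision and the centerline is inextensible by construction.
    """
    if not isinstance(base_frame, Frame):
        base_frame = Frame.from_matrix(np.asarray(base_frame, float))
    u = np.ascontiguousarray(u_components, dtype=float)
    if u.shape != (grid.n_nodes, 3):
        raise InputError(f"u must have shape ({grid.n_nodes}, 3), got {u.shape}")
    R, p = frame_path(grid.s, u, base_frame.matrix)
    return RodState(grid=grid, p=p, directors=R, u=u)


def curvature_and_normal(
    state: RodState, kappa_floor: float = KAPPA_FLOOR
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometric curvature kappa = sqrt(u1^2 + u2^2) and visible normal.

    The visible normal nu = kappa^-1 d3' = (u2 d1 - u1 d2)/kappa points from
    the centerline toward the local center of bending. Where kappa is below
    ``kappa_floor`` the normal is undefined; the returned mask flags defined
    nodes and undefined rows are NaN.
    """
    u1, u2 = state.u[:, 0], state.u[:, 1]
    kappa = np.hypot(u1, u2)
    defined = kappa > kappa_floor
    nu = np.full((state.grid.n_nodes, 3), np.nan)
    if np.any(defined):
        num = (
            u2[defined, None] * state.d1[defined]
            - u1[defined, None] * state.d2[defined]
        )
        nu[defined] = num / kappa[defined, None]
    return kappa, nu, defined


def tip_position(state: RodState) -> np.ndarray:
    """Centerline position at the apex s = l."""
    return state.p[-1].copy()


_SNAPSHOT_COLUMNS = (
    "s px py pz d1x d1y d1z d2x d2y d2z d3x d3y d3z u1 u2 u3"
).split()


def write_snapshot(state: RodState, path) -> None:
    """Write a shape snapshot as a delimited text table (SI units)."""
    R = state.directors
    table = np.column_stack(
        [state.grid.s, state.p, R[:, :, 0], R[:, :, 1], R[:, :, 2], state.u]
    )
    np.savetxt(path, table, header=" ".join(_SNAPSHOT_COLUMNS), fmt="%.17g")


def read_snapshot(path) -> RodState:
    table = np.atleast_2d(np.loadtxt(path))
    if table.shape[1] != len(_SNAPSHOT_COLUMNS):
        raise InputError(f"snapshot must have {len(_SNAPSHOT_COLUMNS)} columns")
    grid = RodGrid(table[:, 0])
    p = table[:, 1:4]
    R = np.stack([table[:, 4:7], table[:, 7:10], table[:, 10:13]], axis=2)
    u = table[:, 13:16]
    return RodState(grid=grid, p=p, directors=R, u=u)
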