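"""Subapical growth kinematics and lignification.

Material cross sections are labeled by their initial arc length S in
[0, l0]; growth stretches the centerline through gamma = ds/dS, driven by a
piecewise-constant relative elemental growth rate (REGR): zero below the
apical growth zone of length lg, 1/tau_g inside it. The coupled system

    dgamma/dt = REGR(s) * gamma,   gamma = ds/dS

has a closed-form solution when l0 <= lg: the whole shoot first elongates
exponentially, l(t) = l0 exp(t/tau_g), until l = lg, and afterwards the
shoot length grows linearly at rate lg/tau_g while material points
progressively exit the growth zone (at the recorded time t_exit) and freeze.
Tissue that has exited stiffens: the Young modulus relaxes exponentially
from E0 to E1 with time constant tau_l (lignification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "LignificationParams",
    "GrowthMap",
    "regr_profile",
    "advance_growth",
    "young_modulus",
    "growth_curve",
]


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthParams:
    """Initial length l0 [m], growth-zone length lg [m], growth time tau_g [s]."""

    ell0: float
    ell_g: float
    tau_g: float

    def __post_init__(self) -> None:
        if min(self.ell0, self.ell_g, self.tau_g) <= 0:
            raise InputError("growth parameters must be positive")

    @property
    def analytic(self) -> bool:
        """True when the closed-form branch (l0 <= lg) applies."""
        return self.ell0 <= self.ell_g

    @property
    def t_linear(self) -> float:
        """Time at which l reaches lg and elongation becomes linear."""
        return self.tau_g * np.log(self.ell_g / self.ell0) if self.analytic else 0.0

    def length(self, t) -> np.ndarray | float:
        """Shoot length l(t)."""
        if not self.analytic:
            raise InputError("length(t) closed form requires l0 <= lg")
        t = np.asarray(t, dtype=float)
        t1 = self.t_linear
        out = np.where(
            t <= t1,
            self.ell0 * np.exp(np.minimum(t, t1) / self.tau_g),
            self.ell_g * (1.0 + (t - t1) / self.tau_g),
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LignificationParams:
    """Moduli E0 <= E1 [Pa] and lignification time tau_l [s]."""

    E0: float
    E1: float
    tau_l: float

    def __post_init__(self) -> None:
        if not (self.E1 >= self.E0 > 0) or self.tau_l <= 0:
            raise InputError("need E1 >= E0 > 0 and tau_l > 0")


def regr_profile(s, ell: float, params: GrowthParams):
    """Piecewise-constant REGR at current arc length s for shoot length l.

    Zero for s <= l - lg (below the growth zone), 1/tau_g above.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > ell * (1 + 1e-12)):
        raise InputError("arc length outside [0, l]")
    out = np.where(s <= ell - params.ell_g, 0.0, 1.0 / params.tau_g)
    return out if out.ndim else float(out)


def young_modulus(t_exit, t: float, params: LignificationParams):
    """E(S, t) = E1 - (E1 - E0) exp(-max(0, t - t_exit)/tau_l).

    ``t_exit`` may be +inf for material that never leaves the growth zone
    (the apex), in which case E stays at E0.
    """
    if t < 0:
        raise InputError("time must be non-negative")
    t_exit = np.asarray(t_exit, dtype=float)
    age = np.maximum(0.0, t - t_exit)
    age = np.where(np.isnan(age), 0.0, age)  # t - inf -> nan -> not yet exited
    out = params.E1 - (params.E1 - params.E0) * np.exp(-age / params.tau_l)
    return out if out.ndim else float(out)


@dataclass
class GrowthMap:
    """Material-to-current arc-length map at one instant.

    Attributes
    ----------
    params : GrowthParams
    S : (n,) material coordinates on [0, l0]
    t : current time [s]
    s : (n,) current arc length of each material node [m]
    gamma : (n,) stretch, gamma >= 1
    t_exit : (n,) time each node exits the growth zone (+inf for the apex)
    """

    params: GrowthParams
    S: np.ndarray
    t: float
    s: np.ndarray
    gamma: np.ndarray
    t_exit: np.ndarray

    @classmethod
    def initial(cls, params: GrowthParams, n_nodes: int = 200) -> "GrowthMap":
        """Map at t = 0 on a uniform material grid: s = S, gamma = 1."""
        return cls.from_material_grid(params, np.linspace(0.0, params.ell0, n_nodes))

    @classmethod
    def from_material_grid(cls, params: GrowthParams, S: np.ndarray) -> "GrowthMap":
        """Map at t = 0 on an arbitrary monotone material grid on [0, l0]."""
        S = np.asarray(S, dtype=float)
        if S[0] != 0.0 or not np.isclose(S[-1], params.ell0) or np.any(np.diff(S) <= 0):
            raise InputError("material grid must increase from 0 to l0")
        t_exit = cls._exit_times(params, S)
        return cls(params, S, 0.0, S.copy(), np.ones(S.size), t_exit)

    @staticmethod
    def _exit_times(params: GrowthParams, S: np.ndarray) -> np.ndarray:
        if not params.analytic:
            return _numeric_exit_times(params, S)
        t1 = params.t_linear
        with np.errstate(divide="ignore"):
            return t1 + params.tau_g * np.log(params.ell0 / (params.ell0 - S))

    def at_time(self, t: float) -> "GrowthMap":
        """Evaluate the map at time t >= 0 (closed form when l0 <= lg)."""
        if t < 0:
            raise InputError("time must be non-negative")
        p = self.params
        if not p.analytic:
            return _numeric_at_time(p, self.S, t)
        t1 = p.t_linear
        tg = p.tau_g
        t_eff = np.minimum(t, self.t_exit)  # growth stops at exit
        gamma = np.exp(t_eff / tg)
        if t <= t1:
            s = self.S * np.exp(t / tg)
        else:
            frac = 1.0 - self.S / p.ell0
            grown = p.ell_g * ((t - t1) / tg + 1.0 - frac * np.exp((t - t1) / tg))
            with np.errstate(divide="ignore", invalid="ignore"):
                frozen = p.ell_g * np.log(1.0 / np.where(frac > 0, frac, 1.0))
            s = np.where(t < self.t_exit, grown, frozen)
        return GrowthMap(p, self.S, float(t), s, gamma, self.t_exit)

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def epsdot(self) -> np.ndarray:
        """Material REGR at the map's time: 1/tau_g inside the growth zone."""
        return np.where(self.t < self.t_exit, 1.0 / self.params.tau_g, 0.0)

    def young_modulus(self, lign: LignificationParams) -> np.ndarray:
        return young_modulus(self.t_exit, self.t, lign)


def advance_growth(gmap: GrowthMap, params: GrowthParams, t: float) -> GrowthMap:
    """Functional form of :meth:`GrowthMap.at_time` (map must share params)."""
    if gmap.params != params:
        raise InputError("map was initialized with different growth parameters")
    return gmap.at_time(t)


# -- numerical fallback for l0 > lg (not the regime studied; kept total) -----


def _numeric_march(params: GrowthParams, S: np.ndarray, t_end: float, dt: float):
    """RK4 march of dgamma/dt = REGR(s(S, t)) gamma; yields (t, gamma, t_exit)."""
    n = S.size
    gamma = np.ones(n)
    t_exit = np.full(n, np.inf)
    t = 0.0

    def rhs(g):
        s = _cumtrapz(g, S)
        r = np.where(s <= s[-1] - params.ell_g, 0.0, 1.0 / params.tau_g)
        return r * g

    def margin(g):
        s = _cumtrapz(g, S)
        return s - (s[-1] - params.ell_g)

    m_prev = margin(gamma)
    nsteps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / nsteps
    for _ in range(nsteps):
        k1 = rhs(gamma)
        k2 = rhs(gamma + 0.5 * dt * k1)
        k3 = rhs(gamma + 0.5 * dt * k2)
        k4 = rhs(gamma + dt * k3)
        gamma = gamma + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        m_now = margin(gamma)
        crossed = (m_prev > 0) & (m_now <= 0) & np.isinf(t_exit)
        if np.any(crossed):
            # linear interpolation of the zero crossing within the step
            frac = m_prev[crossed] / (m_prev[crossed] - m_now[crossed])
            t_exit[crossed] = t - dt + dt * np.clip(frac, 0.0, 1.0)
        m_prev = m_now
    return gamma, _cumtrapz(gamma, S), t_exit


def _cumtrapz(gamma: np.ndarray, S: np.ndarray) -> np.ndarray:
    out = np.zeros_like(gamma)
    out[1:] = np.cumsum(0.5 * (gamma[1:] + gamma[:-1]) * np.diff(S))
    return out


def _numeric_at_time(params: GrowthParams, S: np.ndarray, t: float) -> GrowthMap:
    dt = params.tau_g / 2000.0
    gamma, s, t_exit = _numeric_march(params, S, max(t, dt), dt)
    return GrowthMap(params, S, float(t), s, gamma, t_exit)


def _numeric_exit_times(params: GrowthParams, S: np.ndarray) -> np.ndarray:
    # march long enough that everything but the apex has exited
    t_end = 20.0 * params.tau_g
    _, _, t_exit = _numeric_march(params, S, t_end, params.tau_g / 2000.0)
    return t_exit


def growth_curve(
    params: GrowthParams, times: np.ndarray, markers: np.ndarray | None = None
) -> pd.DataFrame:
    """Elongation table: t, l(t), and s(S_i, t) for chosen material markers."""
    gmap0 = GrowthMap.initial(params, n_nodes=17 if markers is None else len(markers))
    if markers is not None:
        t_exit = GrowthMap._exit_times(params, np.asarray(markers, float))
        gmap0 = GrowthMap(
            params,
            np.asarray(markers, float),
            0.0,
            np.asarray(markers, float).copy(),
            np.ones(len(markers)),
            t_exit,
        )
    rows = {}
    ell = []
    for t in times:
        m = gmap0.at_time(float(t))
        ell.append(params.length(float(t)) if params.analytic else m.length)
        for i, Si in enumerate(m.S):
            rows.setdefault(f"s_{i}", []).append(m.s[i])
    out = pd.DataFrame({"t": times, "ell": ell, **rows})
    return out
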