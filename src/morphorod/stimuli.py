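"""Drivers of differential growth: the spontaneous-strain evolution laws.

Differential growth across the cross section tilts the growth-rate profile
and thereby changes the intrinsic (spontaneous) flexural strains u*_1, u*_2
(torsion u*_3 is identically zero here). Three mechanisms contribute rates,
all proportional to the local relative elemental growth rate epsdot (so they
vanish outside the growth zone):

* an endogenous oscillator of period tau_e rotating the growth gradient
  uniformly in time:  du*_1/dt = (alpha epsdot / r) cos(2 pi t / tau_e), and
  the sine for u*_2;
* delayed gravitropism driven by the statolith free-surface normal h, whose
  local components enter through an exponential memory kernel (memory tau_m)
  evaluated a reaction time tau_r in the past;
* delayed proprioception, the same kernel structure applied to the *visible*
  flexural strains u_1, u_2 (memory tau_m_p, delay tau_r_p), which acts to
  straighten the organ.

The statolith normal h itself relaxes viscously toward -g on the avalanche
time tau_a; its evolution law is written in components on the (rotating)
local director basis and is integrated that way (corotational reading).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StimulusParams",
    "StatolithField",
    "StimulusHistory",
    "step_statoliths",
    "endogenous_rate",
    "gravitropic_rate",
    "proprioceptive_rate",
    "total_spontaneous_rate",
]

#: memory-kernel truncation, in units of the memory time; e^-12 ~ 6e-6 keeps
#: the quadrature mass error well below 1e-4 together with the analytic tail
KERNEL_TRUNCATION = 12.0


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class StimulusParams:
    """Sensitivities and characteristic times of the growth-driving stimuli.

    All times in seconds, radius in meters; sensitivities dimensionless.
    ``endogenous_sign`` selects the rotation direction of the endogenous
    oscillator and ``endogenous_phase`` its phase at t = 0 (both are modeling
    conventions, not observables).
    """

    alpha: float = 0.0  # endogenous sensitivity
    tau_e: float = 1200.0  # endogenous period
    beta: float = 0.8  # gravitropic sensitivity
    tau_m: float = 720.0  # gravitropic memory time
    tau_r: float = 720.0  # gravitropic reaction (delay) time
    eta: float = 20.0  # proprioceptive sensitivity
    tau_m_p: float = 720.0  # proprioceptive memory time
    tau_r_p: float = 720.0  # proprioceptive reaction (delay) time
    tau_a: float = 120.0  # statolith avalanche time
    radius: float = 5e-4  # organ radius
    endogenous_phase: float = 0.0
    endogenous_sign: int = 1

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eta", "tau_e", "tau_r", "tau_r_p", "tau_a"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.tau_m <= 0 or self.tau_m_p <= 0:
            raise InputError("memory times must be positive")
        if self.endogenous_sign not in (-1, 1):
            raise InputError("endogenous_sign must be +1 or -1")

    def with_(self, **kw) -> "StimulusParams":
        return replace(self, **kw)


@dataclass
class StatolithField:
    """Unit perceived-gravity vectors h, as components in the local basis."""

    h: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.h = np.atleast_2d(np.asarray(self.h, float))
        norms = np.linalg.norm(self.h, axis=1)
        if np.any(norms < 1e-12):
            raise InputError("statolith vectors must be nonzero")
        self.h = self.h / norms[:, None]

    @classmethod
    def equilibrium(cls, directors: np.ndarray, g_dir: np.ndarray) -> "StatolithField":
        """h = -g expressed in each node's local basis."""
        g = np.asarray(g_dir, float)
        return cls(np.einsum("nij,i->nj", directors, -g))


def step_statoliths(
    field: StatolithField,
    directors: np.ndarray,
    g_dir: np.ndarray,
    tau_a: float,
    dt: float,
) -> StatolithField:
    """Advance h by dt under dh_j/dt = (1/tau_a) [h x (h x g)] . d_j.

    The component rates are taken on the current local basis, which is frozen
    during the step (corotational law: components are not re-projected when
    the frame rotates between steps). A classical RK4 step is used and |h| is
    renormalized, which the continuous law preserves exactly.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    g_dir = np.asarray(g_dir, float)
    if abs(np.linalg.norm(g_dir) - 1.0) > 1e-9:
        raise InputError("g_dir must be a unit vector")
    # with the frame frozen, work entirely in body components
    g_body = np.einsum("nij,i->nj", directors, g_dir)

    def rhs(h):
        hg = np.einsum("nj,nj->n", h, g_body)
        hh = np.einsum("nj,nj->n", h, h)
        return (h * hg[:, None] - g_body * hh[:, None]) / tau_a

    h = field.h
    k1 = rhs(h)
    k2 = rhs(h + 0.5 * dt * k1)
    k3 = rhs(h + 0.5 * dt * k2)
    k4 = rhs(h + dt * k3)
    return StatolithField(h + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4))


class StimulusHistory:
    """Ring buffer of past per-node samples of (h1, h2) and visible (u1, u2).

    Samples live on a fixed time grid of step ``dt``; ``prefill`` may supply
    explicit pre-history for t < t0, otherwise the oldest stored sample is
    treated as the constant pre-history (upright priming). The exponential
    memory kernel with discrete reaction delay,

        I(t) = (1/tau_m) int_-inf^{t - tau_r} e^{-(t - tau_r - tau)/tau_m} x(tau) dtau,

    is evaluated by trapezoidal quadrature over KERNEL_TRUNCATION memory
    times plus an analytic tail on the oldest usable sample.
    """

    def __init__(
        self,
        n_nodes: int,
        dt: float,
        max_reaction: float,
        max_memory: float,
        t0: float = 0.0,
        primed: bool = True,
    ) -> None:
        if dt <= 0:
            raise InputError("dt must be positive")
        self.n_nodes = int(n_nodes)
        self.dt = float(dt)
        self.t0 = float(t0)
        self.primed = bool(primed)
        lookback = int(np.ceil(max_reaction / dt)) + int(
            np.ceil(KERNEL_TRUNCATION * max_memory / dt)
        )
        self.capacity = lookback + 8
        self._h = np.zeros((self.capacity, self.n_nodes, 2))
        self._u = np.zeros((self.capacity, self.n_nodes, 2))
        self.count = 0  # total samples pushed; sample j is at t0 + j*dt
        self._weights: dict[tuple[float, float], np.ndarray] = {}

    @property
    def latest_time(self) -> float:
        if self.count == 0:
            raise InputError("history is empty")
        return self.t0 + (self.count - 1) * self.dt

    def push(self, t: float, h12: np.ndarray, u12: np.ndarray) -> None:
        expected = self.t0 + self.count * self.dt
        if abs(t - expected) > 1e-6 * self.dt:
            raise InputError(
                f"samples must arrive on the time grid (expected t={expected}, got {t})"
            )
        slot = self.count % self.capacity
        self._h[slot] = h12
        self._u[slot] = u12
        self.count += 1

    def prefill(self, h12: np.ndarray, u12: np.ndarray, n_samples: int) -> None:
        """Install explicit pre-history ending just before t0.

        ``h12``/``u12`` may be (n, 2) constants or (n_samples, n, 2) series
        ordered oldest first; shifts t0 back by ``n_samples`` steps.
        """
        if self.count:
            raise InputError("prefill must precede any push")
        self.t0 -= n_samples * self.dt
        h12 = np.asarray(h12, float)
        u12 = np.asarray(u12, float)
        for j in range(n_samples):
            hj = h12 if h12.ndim == 2 else h12[j]
            uj = u12 if u12.ndim == 2 else u12[j]
            self.push(self.t0 + j * self.dt, hj, uj)

    def _kernel_weights(self, tau_m: float) -> np.ndarray:
        key = (tau_m, self.dt)
        w = self._weights.get(key)
        if w is None:
            M = int(np.ceil(KERNEL_TRUNCATION * tau_m / self.dt))
            j = np.arange(M + 1)
            w = (self.dt / tau_m) * np.exp(-j * self.dt / tau_m)
            w[0] *= 0.5
            w[-1] *= 0.5
            w[-1] += np.exp(-M * self.dt / tau_m)  # analytic pre-history tail
            self._weights[key] = w
        return w

    def kernel_average(
        self, field: str, tau_r: float, tau_m: float, t_eval: float
    ) -> np.ndarray:
        """Delayed exponential-kernel average of a stored field at ``t_eval``."""
        if self.count == 0:
            raise InputError("history is empty")
        X = {"h": self._h, "u": self._u}[field]
        j_end_f = (t_eval - tau_r - self.t0) / self.dt
        j_end = int(round(j_end_f))
        if abs(j_end_f - j_end) > 1e-6:
            raise InputError("t_eval - tau_r does not align with the sample grid")
        if j_end > self.count - 1:
            raise InputError("t_eval - tau_r lies in the future of the buffer")
        w = self._kernel_weights(tau_m)
        M = w.size - 1
        if not self.primed and j_end - M < 0:
            raise InputError(
                f"history spans {self.count} samples; need {M - j_end} more "
                f"for the delayed kernel at t={t_eval}"
            )
        idx = np.clip(j_end - np.arange(M + 1), 0, None)
        if self.count > self.capacity and idx.min() < self.count - self.capacity:
            raise InputError("requested samples have been evicted from the ring")
        return np.tensordot(w, X[idx % self.capacity], axes=1)


def endogenous_rate(epsdot, t: float, params: StimulusParams):
    """Endogenous-oscillator contribution to (du*_1/dt, du*_2/dt)."""
    if params.radius <= 0:
        raise InputError("radius must be positive")
    epsdot = np.asarray(epsdot, float)
    if np.any(epsdot < 0):
        raise InputError("epsdot must be non-negative")
    phase = params.endogenous_sign * 2.0 * np.pi * t / params.tau_e
    phase = phase + params.endogenous_phase
    amp = params.alpha * epsdot / params.radius
    return amp * np.cos(phase), amp * np.sin(phase)


def gravitropic_rate(
    history: StimulusHistory, t: float, epsdot, params: StimulusParams
):
    """Delayed gravitropic contribution, fed by the statolith components.

    du*_1/dt = -(beta epsdot / r) <h2>,  du*_2/dt = +(beta epsdot / r) <h1>,
    where <.> is the delayed exponential-kernel average.
    """
    epsdot = np.asarray(epsdot, float)
    if params.beta == 0:
        zero = np.zeros(history.n_nodes) * epsdot
        return zero, zero
    I = history.kernel_average("h", params.tau_r, params.tau_m, t)
    amp = params.beta * epsdot / params.radius
    return -amp * I[:, 1], amp * I[:, 0]


def proprioceptive_rate(
    history: StimulusHistory, t: float, epsdot, params: StimulusParams
):
    """Delayed straightening response driven by the visible flexural strains."""
    epsdot = np.asarray(epsdot, float)
    if params.eta == 0:
        zero = np.zeros(history.n_nodes) * epsdot
        return zero, zero
    I = history.kernel_average("u", params.tau_r_p, params.tau_m_p, t)
    return -params.eta * epsdot * I[:, 0], -params.eta * epsdot * I[:, 1]


def total_spontaneous_rate(
    history: StimulusHistory, t: float, epsdot, params: StimulusParams
) -> np.ndarray:
    """Sum of the three evolution laws; returns (n, 3) with zero torsion."""
    e1, e2 = endogenous_rate(epsdot, t, params)
    g1, g2 = gravitropic_rate(history, t, epsdot, params)
    p1, p2 = proprioceptive_rate(history, t, epsdot, params)
    n = history.n_nodes
    out = np.zeros((n, 3))
    out[:, 0] = e1 + g1 + p1
    out[:, 1] = e2 + g2 + p2
    return out
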