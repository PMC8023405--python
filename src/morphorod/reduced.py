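"""Constant-length reduced model and its stability analysis.

For processes much faster than growth the shoot length, Young modulus and
growth-zone geometry are frozen (l ~ l0 <= lg, E = E0, epsdot = 1/tau_g
everywhere) and the statolith avalanche is taken as instantaneous (h = -g at
all times). What remains is a delayed-feedback system on the spontaneous
strains coupled to the nonlinear elastic equilibrium under gravity. Its
upright state can lose stability in an oscillatory (Hopf/flutter) fashion:

* gravitropic feedback alone destabilizes the vertical only with the help of
  elastic deflections, at a critical length l* below the self-buckling
  length l_c;
* proprioception alone (microgravity: q = 0, beta = 0) destabilizes at a
  critical growth time tau_g independent of length, with a closed-form
  linearization: lambda = -(eta/tau_g) e^(-lambda tau_r_p)/(1 + lambda tau_m_p),
  whose Hopf root is found here numerically;
* with both mechanisms, proprioception lowers l* relative to the purely
  graviceptive case (for the delay/memory values studied).

Stability of the elastic scenarios is probed in the time domain: a small
uniform intrinsic-curvature kick is applied, the tip deflection's late-time
exponential rate is fitted, and the critical parameter is located by
bisection on its sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._kernels import equilibrium_fixed_point
from .elastostatics import (
    DEFAULT_G_DIR,
    ElasticParams,
    EquilibriumError,
    _stiffness_field,
    distributed_load,
    self_buckling_length,
)
from .kinematics import Frame, RodGrid, RodState
from .stimuli import StimulusHistory, StimulusParams

__all__ = [
    "Perturbation",
    "ReducedConfig",
    "ReducedRun",
    "StabilityResult",
    "BracketError",
    "SCENARIOS",
    "simulate_reduced",
    "leading_rate",
    "critical_length",
    "critical_growth_time_microgravity",
    "proprioceptive_hopf",
    "stability_boundary",
]


class InputError(ValueError):
    pass


class BracketError(RuntimeError):
    """The scanned parameter bracket does not straddle the stability change."""


#: parameter zeroing that defines each scenario; q = None means gravity on
SCENARIOS: dict[str, dict] = {
    "graviceptive": {"alpha": 0.0, "eta": 0.0},
    "microgravity": {"alpha": 0.0, "beta": 0.0, "q": 0.0},
    "proprio_graviceptive": {"alpha": 0.0},
    "with_endogenous": {},
}


@dataclass(frozen=True)
class Perturbation:
    """Seed of the instability: a uniform intrinsic-curvature kick.

    ``amplitude_rel`` scales the kick curvature, amplitude_rel / l [1/m];
    ``direction`` is the azimuth of the bending plane; ``rotation_bias``
    (+1, -1 or 0) primes the stimulus history with a slowly rotating
    curvature signal at the estimated natural frequency, selecting the
    chirality of the emerging limit cycle reproducibly.
    """

    amplitude_rel: float = 1e-4
    direction: float = 0.0
    rotation_bias: int = 0


@dataclass(frozen=True)
class ReducedConfig:
    scenario: str = "proprio_graviceptive"
    ell: float = 0.0659
    tau_g: float = 72000.0
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    elastic: ElasticParams = field(default_factory=ElasticParams)
    perturbation: Perturbation = field(default_factory=Perturbation)
    horizon: float | None = None  # default: 30 estimated periods
    dt: float | None = None
    n_nodes: int = 100
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InputError(f"unknown scenario {self.scenario!r}")
        if self.ell <= 0 or self.tau_g <= 0:
            raise InputError("ell and tau_g must be positive")

    def effective(self) -> tuple[StimulusParams, float]:
        """Stimulus parameters with scenario zeroing applied, and load q."""
        zero = dict(SCENARIOS[self.scenario])
        q = zero.pop("q", None)
        sp = replace(self.stimulus, **zero) if zero else self.stimulus
        if q is None:
            q = distributed_load(self.elastic)
        return sp, q


@dataclass
class ReducedRun:
    """Tip trajectory and final configuration of a reduced-model run."""

    times: np.ndarray
    tip: np.ndarray  # (m, 3)
    config: ReducedConfig
    final_state: RodState
    dt: float
    equilibrium_iterations: np.ndarray

    @property
    def tip_xy(self) -> np.ndarray:
        return self.tip[:, :2]

    def to_track(self):
        from .trajectory import TipTrack

        return TipTrack(
            times=self.times.copy(),
            xy=self.tip_xy.copy(),
            z=self.tip[:, 2].copy(),
            provenance="simulated",
        )


@dataclass
class StabilityResult:
    """Critical parameter and leading-mode data of a stability sweep."""

    critical_value: float  # [m] for length sweeps, [s] for tau_g sweeps
    leading_rate: float  # [1/s] at the returned critical value
    leading_frequency: float  # [1/s], cycles per second
    classification: str | None
    scenario: str
    swept: str  # "ell" | "tau_g"
    meta: dict


def proprioceptive_hopf(
    eta: float, tau_m_p: float, tau_r_p: float
) -> tuple[float, float]:
    """Hopf threshold of the pure proprioceptive delay law.

    The straight state of du/dt = -(eta/tau_g) K*u (exponential kernel,
    memory tau_m_p, delay tau_r_p) has characteristic relation
    lambda (1 + lambda tau_m_p) = -(eta/tau_g) e^(-lambda tau_r_p).
    On the imaginary axis lambda = i w this splits into a phase condition,
    arctan(1/(w tau_m_p)) = w tau_r_p, fixing the frequency, and a magnitude
    condition fixing the critical growth time
    tau_g = eta / (w sqrt(1 + (w tau_m_p)^2)).

    Returns (tau_g_crit [s], omega [rad/s]).
    """
    if eta <= 0 or tau_m_p <= 0 or tau_r_p <= 0:
        raise InputError("eta, tau_m_p, tau_r_p must be positive for a Hopf point")
    f = lambda w: w * tau_r_p - np.arctan(1.0 / (w * tau_m_p))
    w = brentq(f, 1e-12 / tau_r_p, 0.5 * np.pi / tau_r_p, xtol=1e-16, rtol=1e-14)
    tau_g = eta / (w * np.hypot(1.0, w * tau_m_p))
    return float(tau_g), float(w)


def _natural_frequency(sp: StimulusParams) -> float:
    """Estimated angular frequency of the emerging oscillation [rad/s].

    Uses the proprioceptive phase relation when eta > 0, else the analogous
    relation for the gravitropic kernel (same functional form); this only
    sets horizons and chirality seeding, not any reported threshold.
    """
    if sp.eta > 0 and sp.tau_r_p > 0:
        return proprioceptive_hopf(sp.eta, sp.tau_m_p, sp.tau_r_p)[1]
    tau_m, tau_r = (sp.tau_m, sp.tau_r) if sp.beta > 0 else (sp.tau_m_p, sp.tau_r_p)
    if tau_r <= 0:
        return 2.0 * np.pi / (80.0 * 60.0)  # generic circumnutation scale
    f = lambda w: w * tau_r - np.arctan(1.0 / (w * tau_m))
    return float(brentq(f, 1e-12 / tau_r, 0.5 * np.pi / tau_r))


def _default_dt(sp: StimulusParams) -> float:
    taus = []
    if sp.beta > 0:
        taus.append(sp.tau_m)
    if sp.eta > 0:
        taus.append(sp.tau_m_p)
    if sp.alpha > 0:
        taus.append(sp.tau_e)
    if not taus:
        taus = [sp.tau_m_p]
    dt = min(taus) / 40.0
    delays = [d for d in (sp.tau_r if sp.beta else 0, sp.tau_r_p if sp.eta else 0) if d]
    if delays:
        d0 = min(delays)
        dt = d0 / max(1, round(d0 / dt))
    return dt


def _rates(
    hist: StimulusHistory, t: float, sp: StimulusParams, epsdot: float, n: int
) -> np.ndarray:
    """Total spontaneous-strain rate (n, 2) for the reduced system."""
    f = np.zeros((n, 2))
    if sp.alpha > 0:
        ph = sp.endogenous_sign * 2.0 * np.pi * t / sp.tau_e + sp.endogenous_phase
        amp = sp.alpha * epsdot / sp.radius
        f[:, 0] += amp * np.cos(ph)
        f[:, 1] += amp * np.sin(ph)
    if sp.beta > 0:
        I = hist.kernel_average("h", sp.tau_r, sp.tau_m, t)
        amp = sp.beta * epsdot / sp.radius
        f[:, 0] -= amp * I[:, 1]
        f[:, 1] += amp * I[:, 0]
    if sp.eta > 0:
        I = hist.kernel_average("u", sp.tau_r_p, sp.tau_m_p, t)
        f -= sp.eta * epsdot * I
    return f


def simulate_reduced(config: ReducedConfig) -> ReducedRun:
    """Time-step the reduced model from a perturbed upright state.

    Per step: spontaneous strains advance by a trapezoidal update of the
    summed evolution laws (both endpoint rates are known because every
    reaction delay exceeds the step), then the elastic equilibrium is solved
    for the visible shape, and the histories of h = -g components and visible
    strains are extended. Raises :class:`EquilibriumError` (with time stamp)
    if the elastic solve fails, e.g. beyond self-buckling.
    """
    sp, q = config.effective()
    n = config.n_nodes
    grid = RodGrid.uniform(config.ell, n)
    R0 = Frame.identity().matrix
    g_dir = np.ascontiguousarray(DEFAULT_G_DIR)
    h_lab = -g_dir  # instantaneous statoliths: h = -g
    K = np.ascontiguousarray(_stiffness_field(config.elastic, n))
    epsdot = 1.0 / config.tau_g

    dt = config.dt if config.dt is not None else _default_dt(sp)
    omega0 = _natural_frequency(sp)
    horizon = (
        config.horizon
        if config.horizon is not None
        else 30.0 * 2.0 * np.pi / omega0
    )
    nsteps = int(np.ceil(horizon / dt))

    if sp.beta > 0 and sp.tau_r < dt or sp.eta > 0 and sp.tau_r_p < dt:
        raise InputError("reaction delays must be at least one time step")

    pert = config.perturbation
    a = pert.amplitude_rel / config.ell
    ustar = np.zeros((n, 3))
    ustar[:, 0] = a * np.cos(pert.direction)
    ustar[:, 1] = a * np.sin(pert.direction)

    max_delay = max(sp.tau_r if sp.beta else 0.0, sp.tau_r_p if sp.eta else 0.0, dt)
    max_mem = max(sp.tau_m if sp.beta else 0.0, sp.tau_m_p if sp.eta else 0.0, dt)
    hist = StimulusHistory(n, dt, max_reaction=max_delay, max_memory=max_mem)

    u_warm = ustar.copy()
    u_warm, R, p, m, iters, conv = equilibrium_fixed_point(
        grid.s, ustar, K, q, g_dir, R0, u_warm, 1e-9, 200, 0.5
    )
    if not conv:
        raise EquilibriumError("equilibrium failed at t = 0 (initial state)")
    h12 = np.einsum("nij,i->nj", R, h_lab)[:, :2]

    if pert.rotation_bias:
        # prime the buffers with a rotating-wave history: the t = 0 fields
        # with their bending plane back-rotated at the estimated natural
        # frequency, so the seeded chirality is dynamically consistent
        n_pre = hist.capacity - 4
        t_pre = (np.arange(n_pre) - n_pre) * dt
        psi = pert.rotation_bias * omega0 * t_pre  # rotation angle vs t = 0
        cos_p, sin_p = np.cos(psi)[:, None], np.sin(psi)[:, None]
        u12_0 = u_warm[:, :2]
        u_pre = np.empty((n_pre, n, 2))
        u_pre[:, :, 0] = cos_p * u12_0[:, 0] - sin_p * u12_0[:, 1]
        u_pre[:, :, 1] = sin_p * u12_0[:, 0] + cos_p * u12_0[:, 1]
        h_pre = np.empty((n_pre, n, 2))
        h_pre[:, :, 0] = cos_p * h12[:, 0] - sin_p * h12[:, 1]
        h_pre[:, :, 1] = sin_p * h12[:, 0] + cos_p * h12[:, 1]
        hist.prefill(h_pre, u_pre, n_pre)
    hist.push(0.0, h12, u_warm[:, :2].copy())

    n_rec = nsteps // config.record_every + 1
    times = np.empty(n_rec)
    tip = np.empty((n_rec, 3))
    eq_iters = np.zeros(n_rec, dtype=int)
    times[0], tip[0], eq_iters[0] = 0.0, p[-1], iters
    rec = 1

    F_prev = _rates(hist, 0.0, sp, epsdot, n)
    for k in range(nsteps):
        t1 = (k + 1) * dt
        F_next = _rates(hist, t1, sp, epsdot, n)
        ustar[:, :2] += 0.5 * dt * (F_prev + F_next)
        u_warm, R, p, m, iters, conv = equilibrium_fixed_point(
            grid.s, ustar, K, q, g_dir, R0, u_warm, 1e-9, 200, 0.5
        )
        if not conv:
            raise EquilibriumError(
                f"equilibrium failed at t = {t1:.1f} s (step {k + 1}); "
                "the configuration is at or beyond an elastic fold"
            )
        h12 = np.einsum("nij,i->nj", R, h_lab)[:, :2]
        hist.push(t1, h12, u_warm[:, :2].copy())
        F_prev = F_next
        if (k + 1) % config.record_every == 0:
            times[rec], tip[rec], eq_iters[rec] = t1, p[-1], iters
            rec += 1

    state = RodState(grid=grid, p=p, directors=R, u=u_warm.copy())
    return ReducedRun(
        times=times[:rec],
        tip=tip[:rec],
        config=config,
        final_state=state,
        dt=dt,
        equilibrium_iterations=eq_iters[:rec],
    )


def leading_rate(
    config: ReducedConfig, fit_frac: float = 0.4
) -> tuple[float, float, ReducedRun]:
    """Exponential rate and frequency of the tip deflection's leading mode.

    Runs the reduced model (with a rotating seed so the deflection magnitude
    is a smooth exponential) and fits log |tip_xy| and the unwrapped phase
    over the trailing ``fit_frac`` of the horizon.

    Returns (rate [1/s], frequency [1/s, cycles], run).
    """
    if config.perturbation.rotation_bias == 0:
        config = replace(
            config, perturbation=replace(config.perturbation, rotation_bias=1)
        )
    run = simulate_reduced(config)
    z = run.tip[:, 0] + 1j * run.tip[:, 1]
    m = z.size
    sel = slice(int((1.0 - fit_frac) * m), m)
    t = run.times[sel]
    r = np.abs(z[sel])
    if np.any(r <= 0):
        return -np.inf, 0.0, run
    rate = np.polyfit(t, np.log(r), 1)[0]
    omega = np.polyfit(t, np.unwrap(np.angle(z[sel])), 1)[0]
    return float(rate), float(abs(omega) / (2.0 * np.pi)), run


def critical_length(
    tau_g: float,
    scenario: str,
    stimulus: StimulusParams | None = None,
    elastic: ElasticParams | None = None,
    *,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-4,
    n_nodes: int = 100,
    horizon_periods: float = 30.0,
    dt: float | None = None,
) -> StabilityResult:
    """Locate the critical shoot length l* by bisection on the leading rate.

    The straight upright state is perturbed by a small curvature kick
    (relative amplitude 1e-4) at each trial length; decay brackets from
    below, growth from above, and the bracket is narrowed to ``tol``
    (default 0.01 cm).
    """
    if scenario not in ("graviceptive", "proprio_graviceptive"):
        raise InputError("critical_length applies to the elastic scenarios")
    stimulus = stimulus or StimulusParams()
    elastic = elastic or ElasticParams()
    ellc = self_buckling_length(elastic)
    if not np.isfinite(ellc):
        raise BracketError(
            "q = 0: no elastic limit (l_c infinite); the shoot is always "
            "stable in the graviceptive scenario"
        )
    lo, hi = bracket if bracket is not None else (0.55 * ellc, 0.97 * ellc)

    cache: dict[float, tuple[float, float]] = {}

    def rate_at(ell: float) -> tuple[float, float]:
        if ell not in cache:
            cfg = ReducedConfig(
                scenario=scenario,
                ell=ell,
                tau_g=tau_g,
                stimulus=stimulus,
                elastic=elastic,
                perturbation=Perturbation(rotation_bias=1),
                n_nodes=n_nodes,
                dt=dt,
                horizon=horizon_periods
                * 2.0
                * np.pi
                / _natural_frequency(replace(stimulus, **SCENARIOS[scenario])),
            )
            try:
                r, f, _ = leading_rate(cfg)
            except EquilibriumError:
                # the growing perturbation drove the rod past an elastic
                # fold: unambiguously on the unstable side of the threshold
                r, f = np.inf, np.nan
            cache[ell] = (r, f)
        return cache[ell]

    r_lo, f_lo = rate_at(lo)
    r_hi, f_hi = rate_at(hi)
    if not (r_lo < 0 < r_hi):
        raise BracketError(
            f"no stability change in [{lo:.4g}, {hi:.4g}] m: "
            f"rate({lo:.4g}) = {r_lo:.3g}/s, rate({hi:.4g}) = {r_hi:.3g}/s"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        r_mid, _ = rate_at(mid)
        if r_mid > 0:
            hi = mid
        else:
            lo = mid
    crit = 0.5 * (lo + hi)
    r_c, f_c = rate_at(lo)
    return StabilityResult(
        critical_value=crit,
        leading_rate=r_c,
        leading_frequency=f_c,
        classification=None,
        scenario=scenario,
        swept="ell",
        meta={
            "tau_g": tau_g,
            "ell_c": ellc,
            "ell_over_ellc": crit / ellc,
            "bracket": (lo, hi),
            "n_nodes": n_nodes,
            "rates": dict(cache),
        },
    )


def critical_growth_time_microgravity(
    eta: float = 20.0,
    tau_m_p: float = 720.0,
    tau_r_p: float = 720.0,
    *,
    stimulus: StimulusParams | None = None,
    time_domain_check: bool = True,
    ell: float = 0.02,
    n_nodes: int = 8,
    rel_tol: float = 0.01,
    horizon_periods: float = 30.0,
) -> StabilityResult:
    """Hopf threshold in tau_g for the proprioception-only (microgravity) law.

    Computed from the pointwise linearized delay relation
    (:func:`proprioceptive_hopf`); optionally cross-checked by time-domain
    bisection with the nonlinear simulator at the given length (the
    threshold is length-independent because the weightless dynamics is
    pointwise in arc length).
    """
    sp = (stimulus or StimulusParams()).with_(
        alpha=0.0, beta=0.0, eta=eta, tau_m_p=tau_m_p, tau_r_p=tau_r_p
    )
    tau_lin, omega = proprioceptive_hopf(eta, tau_m_p, tau_r_p)
    meta: dict = {"omega": omega, "period": 2.0 * np.pi / omega}

    if time_domain_check:

        def rate_at(tau_g: float) -> float:
            cfg = ReducedConfig(
                scenario="microgravity",
                ell=ell,
                tau_g=tau_g,
                stimulus=sp,
                perturbation=Perturbation(rotation_bias=1),
                n_nodes=n_nodes,
                horizon=horizon_periods * 2.0 * np.pi / omega,
            )
            return leading_rate(cfg)[0]

        # unstable below, stable above; the bracket stays near the threshold
        # so the small-perturbation rate fit is not contaminated by
        # saturation onto the nonlinear limit cycle
        lo, hi = 0.85 * tau_lin, 1.3 * tau_lin
        r_lo, r_hi = rate_at(lo), rate_at(hi)
        if not (r_lo > 0 > r_hi):
            raise BracketError(
                f"time-domain rates do not bracket the threshold: "
                f"rate({lo:.0f}s) = {r_lo:.3g}, rate({hi:.0f}s) = {r_hi:.3g}"
            )
        while (hi - lo) > rel_tol * tau_lin:
            mid = 0.5 * (lo + hi)
            if rate_at(mid) > 0:
                lo = mid
            else:
                hi = mid
        meta["tau_g_time_domain"] = 0.5 * (lo + hi)
        meta["agreement"] = abs(meta["tau_g_time_domain"] - tau_lin) / tau_lin

    return StabilityResult(
        critical_value=tau_lin,
        leading_rate=0.0,
        leading_frequency=omega / (2.0 * np.pi),
        classification=None,
        scenario="microgravity",
        swept="tau_g",
        meta=meta,
    )


def stability_boundary(
    scenario: str,
    tau_g_grid,
    stimulus: StimulusParams | None = None,
    elastic: ElasticParams | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Critical length (or the length-independent tau_g threshold) per tau_g.

    Returns a table with columns tau_g, ell_crit, ell_over_ellc, frequency,
    flag; per-point bracket failures are recorded as flags, not raised.
    """
    stimulus = stimulus or StimulusParams()
    elastic = elastic or ElasticParams()
    rows = []
    if scenario == "microgravity":
        res = critical_growth_time_microgravity(
            stimulus.eta,
            stimulus.tau_m_p,
            stimulus.tau_r_p,
            time_domain_check=False,
        )
        for tg in np.asarray(tau_g_grid, float):
            rows.append(
                {
                    "tau_g": tg,
                    "ell_crit": np.nan,
                    "ell_over_ellc": np.nan,
                    "frequency": res.leading_frequency,
                    "flag": "always_unstable"
                    if tg < res.critical_value
                    else "always_stable",
                    "tau_g_crit": res.critical_value,
                }
            )
        return pd.DataFrame(rows)
    ellc = self_buckling_length(elastic)
    for tg in np.asarray(tau_g_grid, float):
        try:
            res = critical_length(tg, scenario, stimulus, elastic, **kwargs)
            rows.append(
                {
                    "tau_g": tg,
                    "ell_crit": res.critical_value,
                    "ell_over_ellc": res.critical_value / ellc,
                    "frequency": res.leading_frequency,
                    "flag": "ok",
                    "tau_g_crit": np.nan,
                }
            )
        except (BracketError, EquilibriumError) as err:
            rows.append(
                {
                    "tau_g": tg,
                    "ell_crit": np.nan,
                    "ell_over_ellc": np.nan,
                    "frequency": np.nan,
                    "flag": f"failed: {err}",
                    "tau_g_crit": np.nan,
                }
            )
    return pd.DataFrame(rows)
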