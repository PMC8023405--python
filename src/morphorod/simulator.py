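"""Full coupled simulation: growth, lignification, statoliths, stimuli,
elasticity.

Each time step advances, in order: (1) the material-to-current arc-length
map (closed form); (2) the Young modulus field by lignification; (3) the
evaluation of all fields on the current grid (the grid is the image of the
fixed material grid, so this is the identity under the Lagrangian scheme
used here); (4) the statolith normals by their avalanche relaxation;
(5) the spontaneous strains by the summed endogenous, gravitropic and
proprioceptive laws with the growth-zone-masked epsdot; (6) the quasi-static
elastic equilibrium; (7) the stimulus histories and outputs.

As the shoot elongates through the critical length of the reduced analysis,
tip trajectories transition from endogenous-dominated small orbits of period
tau_e to exogenous-dominated large orbits near the flutter period, with
trochoid-like patterns in between.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import equilibrium_fixed_point
from .elastostatics import (
    DEFAULT_G_DIR,
    ElasticParams,
    EquilibriumError,
    distributed_load,
)
from .growth import GrowthMap, GrowthParams, LignificationParams
from .kinematics import Frame, RodGrid, RodState, write_snapshot
from .stimuli import StatolithField, StimulusHistory, StimulusParams, step_statoliths

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "SimulationResult",
    "CheckpointError",
    "run_simulation",
    "checkpoint_restart",
]

_CKPT_VERSION = "morphorod-ckpt-1"


class InputError(ValueError):
    pass


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    growth: GrowthParams = field(
        default_factory=lambda: GrowthParams(ell0=0.01, ell_g=0.05, tau_g=72000.0)
    )
    lignification: LignificationParams = field(
        default_factory=lambda: LignificationParams(E0=1e7, E1=2e9, tau_l=518400.0)
    )
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    elastic: ElasticParams = field(default_factory=ElasticParams)
    t_end: float = 86400.0
    dt: float | None = None
    out_every: float | None = None  # output cadence [s]; default: every step
    seed: int = 0
    initial_tilt: float = 1e-4  # kick curvature, units of 1/l0
    tilt_direction: float = 0.0
    n_nodes: int = 100
    curvature_dilution: bool = False  # passive u* rescaling as fibers stretch
    freeze_growth: bool = False  # pin l(t) = l0 (epsdot retained): reduced regime

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise InputError("t_end must be positive")

    def resolved_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        sp = self.stimulus
        taus = [sp.tau_a, sp.tau_m, sp.tau_m_p]
        if sp.alpha > 0:
            taus.append(sp.tau_e)
        dt = min(taus) / 20.0
        delays = [d for d in (sp.tau_r, sp.tau_r_p) if d > 0]
        if delays:
            d0 = min(delays)
            dt = d0 / max(1, round(d0 / dt))
        return dt


@dataclass
class TrajectoryRecord:
    """Tip trajectory, shoot length and (optional) per-window regime labels."""

    times: np.ndarray
    tip: np.ndarray  # (m, 3)
    ell: np.ndarray
    labels: list | None = None

    @property
    def tip_xy(self) -> np.ndarray:
        return self.tip[:, :2]

    def to_track(self):
        from .trajectory import TipTrack

        return TipTrack(
            times=self.times.copy(),
            xy=self.tip[:, :2].copy(),
            z=self.tip[:, 2].copy(),
            provenance="simulated",
        )

    def write(self, path) -> None:
        table = np.column_stack([self.times, self.tip, self.ell])
        np.savetxt(path, table, header="t x y z ell", fmt="%.10g")


@dataclass
class SimulationResult:
    record: TrajectoryRecord
    final_state: RodState
    config: SimulationConfig
    diagnostics: dict


class _SimState:
    """Full mutable state of the stepping loop (checkpointable)."""

    def __init__(self, config: SimulationConfig):
        g = config.growth
        sp = config.stimulus
        n = config.n_nodes
        self.k = 0  # completed steps
        self.dt = config.resolved_dt()
        self.gmap0 = GrowthMap.initial(g, n)
        self.ustar = np.zeros((n, 3))
        a = config.initial_tilt / g.ell0
        self.ustar[:, 0] = a * np.cos(config.tilt_direction)
        self.ustar[:, 1] = a * np.sin(config.tilt_direction)
        self.u_warm = self.ustar.copy()
        self.h_body = np.zeros((n, 3))
        self.h_body[:, 2] = 1.0  # h = -g on the upright frame
        max_delay = max(sp.tau_r, sp.tau_r_p, self.dt)
        max_mem = max(sp.tau_m, sp.tau_m_p, self.dt)
        self.hist = StimulusHistory(n, self.dt, max_delay, max_mem)
        self.F_prev: np.ndarray | None = None
        self.gamma_prev = np.ones(n)
        self.R: np.ndarray | None = None  # directors of the last solved step
        self.p: np.ndarray | None = None


def _epsdot(gmap: GrowthMap) -> np.ndarray:
    return gmap.epsdot()


def _rates_full(
    hist: StimulusHistory, t: float, sp: StimulusParams, epsdot: np.ndarray, n: int
) -> np.ndarray:
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
        f[:, 0] -= sp.eta * epsdot * I[:, 0]
        f[:, 1] -= sp.eta * epsdot * I[:, 1]
    return f


def run_simulation(
    config: SimulationConfig,
    *,
    checkpoint_path=None,
    snapshot_dir=None,
    snapshot_every: float | None = None,
    _state: "_SimState | None" = None,
) -> SimulationResult:
    """Run the full model to ``t_end`` and return the tip trajectory.

    On :class:`EquilibriumError` the partial record up to the failure time is
    attached to the raised error (attribute ``partial``), interpreted as
    mechanical collapse past a fold.
    """
    sp = config.stimulus
    el = config.elastic
    q = distributed_load(el)
    g_dir = np.ascontiguousarray(DEFAULT_G_DIR)
    R0 = Frame.identity().matrix
    n = config.n_nodes
    lign = config.lignification
    I_sec = np.pi * el.r**4 / 4.0
    if el.shear_modulus_convention == "standard":
        shear_fac = 1.0 / (2.0 * (1.0 + el.nu_poisson))
    else:
        shear_fac = 2.0 * (1.0 + el.nu_poisson)

    st = _state if _state is not None else _SimState(config)
    dt = st.dt
    nsteps = int(np.ceil(config.t_end / dt))
    rec_stride = max(1, int(round((config.out_every or dt) / dt)))

    times, tips, ells = [], [], []
    eq_iters = []

    def K_field(gmap: GrowthMap) -> np.ndarray:
        E = gmap.young_modulus(lign)
        K = np.empty((n, 3))
        K[:, 0] = E * I_sec
        K[:, 1] = E * I_sec
        K[:, 2] = shear_fac * E * 2.0 * I_sec
        return K

    def solve_at(gmap: GrowthMap):
        grid_s = np.ascontiguousarray(gmap.s)
        return equilibrium_fixed_point(
            grid_s,
            np.ascontiguousarray(st.ustar),
            np.ascontiguousarray(K_field(gmap)),
            q,
            g_dir,
            R0,
            st.u_warm,
            1e-9,
            200,
            0.5,
        )

    gmap = st.gmap0.at_time(0.0 if config.freeze_growth else st.k * dt)
    if st.k == 0:
        # initial solve and history priming (fresh runs only; a resumed run
        # restores the solved shape so the continuation is bit-identical)
        st.u_warm, R, p, m, iters, conv = solve_at(gmap)
        if not conv:
            raise EquilibriumError("equilibrium failed at the initial state")
        # statoliths start sedimented: h = -g on the initial (tilted) frames
        st.h_body = StatolithField.equilibrium(R, g_dir).h
        st.hist.push(0.0, st.h_body[:, :2].copy(), st.u_warm[:, :2].copy())
        st.F_prev = _rates_full(st.hist, 0.0, sp, _epsdot(gmap), n)
        st.gamma_prev = gmap.gamma.copy()
        times.append(0.0)
        tips.append(p[-1].copy())
        ells.append(gmap.length)
        eq_iters.append(iters)
    else:
        if st.R is None or st.p is None:
            raise CheckpointError("resumed state is missing the solved shape")
        R, p = st.R, st.p

    snap_stride = (
        max(1, int(round(snapshot_every / dt))) if snapshot_every else None
    )
    try:
        for k in range(st.k, nsteps):
            t1 = (k + 1) * dt
            # (1) growth (optionally pinned to the initial map)
            gmap = st.gmap0.at_time(0.0 if config.freeze_growth else t1)
            # (2)-(3) stiffness on the current grid (identity resampling)
            # (4) statoliths on the frames of the previous step
            field_ = StatolithField(st.h_body)
            field_ = step_statoliths(field_, R, g_dir, sp.tau_a, dt)
            st.h_body = field_.h
            # (5) spontaneous strains, trapezoidal in the rates
            F_next = _rates_full(st.hist, t1, sp, _epsdot(gmap), n)
            st.ustar[:, :2] += 0.5 * dt * (st.F_prev + F_next)
            if config.curvature_dilution:
                st.ustar[:, :2] *= (st.gamma_prev / gmap.gamma)[:, None]
            st.gamma_prev = gmap.gamma.copy()
            # (6) elastic equilibrium on the current grid
            st.u_warm, R, p, m, iters, conv = solve_at(gmap)
            if not conv:
                raise EquilibriumError(
                    f"equilibrium failed at t = {t1:.1f} s (step {k + 1}): "
                    "mechanical collapse/fold"
                )
            # (7) histories and outputs
            st.hist.push(t1, st.h_body[:, :2].copy(), st.u_warm[:, :2].copy())
            st.F_prev = F_next
            st.k = k + 1
            st.R, st.p = R, p
            if (k + 1) % rec_stride == 0 or k + 1 == nsteps:
                times.append(t1)
                tips.append(p[-1].copy())
                ells.append(gmap.length)
                eq_iters.append(iters)
            if snap_stride and snapshot_dir and (k + 1) % snap_stride == 0:
                grid = RodGrid(np.ascontiguousarray(gmap.s))
                state = RodState(grid=grid, p=p, directors=R, u=st.u_warm.copy())
                write_snapshot(state, f"{snapshot_dir}/shape_{k + 1:08d}.txt")
            if checkpoint_path and (k + 1) % max(1, nsteps // 4) == 0:
                _write_checkpoint(checkpoint_path, config, st)
    except EquilibriumError as err:
        err.partial = TrajectoryRecord(
            np.asarray(times), np.asarray(tips), np.asarray(ells)
        )
        raise

    if checkpoint_path:
        _write_checkpoint(checkpoint_path, config, st)
    grid = RodGrid(np.ascontiguousarray(gmap.s))
    final = RodState(grid=grid, p=p, directors=R, u=st.u_warm.copy())
    record = TrajectoryRecord(np.asarray(times), np.asarray(tips), np.asarray(ells))
    return SimulationResult(
        record=record,
        final_state=final,
        config=config,
        diagnostics={
            "dt": dt,
            "n_steps": st.k,
            "mean_equilibrium_iterations": float(np.mean(eq_iters)) if eq_iters else 0.0,
        },
    )


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_checkpoint(path, config: SimulationConfig, st: _SimState) -> None:
    np.savez(
        path,
        version=_CKPT_VERSION,
        config=json.dumps(_config_to_dict(config)),
        k=st.k,
        dt=st.dt,
        ustar=st.ustar,
        u_warm=st.u_warm,
        h_body=st.h_body,
        F_prev=st.F_prev if st.F_prev is not None else np.zeros(0),
        gamma_prev=st.gamma_prev,
        R=st.R if st.R is not None else np.zeros(0),
        p=st.p if st.p is not None else np.zeros(0),
        hist_h=st.hist._h,
        hist_u=st.hist._u,
        hist_count=st.hist.count,
        hist_t0=st.hist.t0,
    )


def checkpoint_restart(path) -> tuple[SimulationConfig, _SimState]:
    """Load a checkpoint; resuming reproduces the uninterrupted run exactly.

    Raises :class:`CheckpointError` on a version mismatch or corrupt store.
    """
    try:
        with np.load(path, allow_pickle=False) as z:
            if str(z["version"]) != _CKPT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {z['version']} != {_CKPT_VERSION}"
                )
            d = json.loads(str(z["config"]))
            config = SimulationConfig(
                growth=GrowthParams(**d["growth"]),
                lignification=LignificationParams(**d["lignification"]),
                stimulus=StimulusParams(**d["stimulus"]),
                elastic=ElasticParams(**d["elastic"]),
                **{
                    k: v
                    for k, v in d.items()
                    if k not in ("growth", "lignification", "stimulus", "elastic")
                },
            )
            st = _SimState(config)
            st.k = int(z["k"])
            st.dt = float(z["dt"])
            st.ustar = z["ustar"]
            st.u_warm = z["u_warm"]
            st.h_body = z["h_body"]
            st.F_prev = z["F_prev"] if z["F_prev"].size else None
            st.gamma_prev = z["gamma_prev"]
            st.R = z["R"] if z["R"].size else None
            st.p = z["p"] if z["p"].size else None
            st.hist._h = z["hist_h"]
            st.hist._u = z["hist_u"]
            st.hist.count = int(z["hist_count"])
            st.hist.t0 = float(z["hist_t0"])
    except CheckpointError:
        raise
    except Exception as exc:  # corrupt/foreign file
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    return config, st


def resume_simulation(path, **kwargs) -> SimulationResult:
    """Continue a checkpointed run to its configured t_end."""
    config, st = checkpoint_restart(path)
    return run_simulation(config, _state=st, **kwargs)
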