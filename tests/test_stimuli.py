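"""Statolith dynamics, delay kernels, and the spontaneous-strain laws."""

import numpy as np
import pytest

from morphorod.stimuli import (
    InputError,
    StatolithField,
    StimulusHistory,
    StimulusParams,
    endogenous_rate,
    gravitropic_rate,
    proprioceptive_rate,
    step_statoliths,
    total_spontaneous_rate,
)

G_DIR = np.array([0.0, 0.0, -1.0])


def identity_frames(n):
    return np.tile(np.eye(3), (n, 1, 1))


class TestStatoliths:
    def test_equilibrium_at_minus_g(self):
        n = 4
        field = StatolithField(np.tile([0.0, 0.0, 1.0], (n, 1)))  # h = -g
        out = step_statoliths(field, identity_frames(n), G_DIR, 120.0, 5.0)
        assert np.allclose(out.h, field.h, atol=1e-15)

    def test_projection_follows_tanh_closed_form(self):
        # fixed frame: c = h.g obeys dc/dt = (c^2 - 1)/tau_a, i.e.
        # c(t) = -tanh((t - t0)/tau_a) with t0 = tau_a artanh(c(0))
        tau_a = 120.0
        phi0 = 1.9  # angle from -g
        h0 = np.array([[np.sin(phi0), 0.0, np.cos(phi0)]])
        c0 = h0[0] @ G_DIR
        t0 = tau_a * np.arctanh(c0)
        field = StatolithField(h0)
        dt = tau_a / 200.0
        t = 0.0
        for _ in range(int(3 * tau_a / dt)):
            field = step_statoliths(field, identity_frames(1), G_DIR, tau_a, dt)
            t += dt
            c_exact = -np.tanh((t - t0) / tau_a)
            assert abs(field.h[0] @ G_DIR - c_exact) < 1e-6

    def test_norm_preserved_and_convergence_to_minus_g(self, rng):
        tau_a = 120.0
        n = 16
        h = rng.normal(size=(n, 3))
        field = StatolithField(h)
        frames = identity_frames(n)
        for _ in range(400):
            field = step_statoliths(field, frames, G_DIR, tau_a, tau_a / 10.0)
            assert np.allclose(np.linalg.norm(field.h, axis=1), 1.0, atol=1e-9)
        # every statolith pile relaxes to h = -g
        assert np.allclose(field.h, [0.0, 0.0, 1.0], atol=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(InputError):
            StatolithField(np.zeros((2, 3)))


class TestHistoryKernel:
    def test_kernel_mass_is_one(self):
        # constant unit signal: the delayed kernel average must integrate to 1
        dt = 720.0 / 40.0
        hist = StimulusHistory(3, dt, max_reaction=720.0, max_memory=720.0)
        ones = np.ones((3, 2))
        for k in range(200):
            hist.push(k * dt, ones, ones)
        for tau_m in (720.0, 500.0):
            I = hist.kernel_average("h", 720.0, tau_m, 199 * dt)
            assert np.allclose(I, 1.0, atol=1e-4)

    def test_causality_future_reads_rejected(self):
        dt = 10.0
        hist = StimulusHistory(2, dt, 100.0, 100.0)
        x = np.zeros((2, 2))
        for k in range(50):
            hist.push(k * dt, x, x)
        with pytest.raises(InputError):
            hist.kernel_average("h", 100.0, 100.0, 49 * dt + 200.0)

    def test_unprimed_history_needs_full_span(self):
        dt = 10.0
        hist = StimulusHistory(2, dt, 100.0, 100.0, primed=False)
        x = np.zeros((2, 2))
        for k in range(20):
            hist.push(k * dt, x, x)
        with pytest.raises(InputError):
            hist.kernel_average("u", 100.0, 100.0, 19 * dt)

    def test_off_grid_push_rejected(self):
        hist = StimulusHistory(2, 10.0, 100.0, 100.0)
        x = np.zeros((2, 2))
        hist.push(0.0, x, x)
        with pytest.raises(InputError):
            hist.push(13.0, x, x)


def primed_history(n=5, dt=18.0, h_const=(0.2, -0.4), u_const=(0.7, 0.0)):
    hist = StimulusHistory(n, dt, max_reaction=720.0, max_memory=720.0)
    h = np.tile(h_const, (n, 1))
    u = np.tile(u_const, (n, 1))
    for k in range(60):
        hist.push(k * dt, h, u)
    return hist, 59 * dt


class TestRates:
    def test_endogenous_phase_and_growth_zone_masking(self):
        sp = StimulusParams(alpha=0.5)
        amp = sp.alpha * 1.0 / sp.radius
        r1, r2 = endogenous_rate(1.0, 0.0, sp)
        assert (r1, r2) == pytest.approx((amp, 0.0))
        r1, r2 = endogenous_rate(1.0, sp.tau_e / 4.0, sp)
        assert (r1, r2) == pytest.approx((0.0, amp), abs=1e-12 * amp)
        # rates scale with epsdot: zero outside the growth zone
        assert endogenous_rate(0.0, 0.0, sp) == pytest.approx((0.0, 0.0))

    def test_gravitropic_constant_stimulus_closed_form(self):
        sp = StimulusParams(beta=0.8)
        hist, t = primed_history(h_const=(0.2, -0.4))
        epsdot = 1.0 / 72000.0
        r1, r2 = gravitropic_rate(hist, t, epsdot, sp)
        scale = sp.beta * epsdot / sp.radius
        assert np.allclose(r1, -scale * (-0.4), rtol=1e-4)
        assert np.allclose(r2, scale * 0.2, rtol=1e-4)

    def test_gravitropic_zero_for_upright_or_insensitive(self):
        hist, t = primed_history(h_const=(0.0, 0.0))
        r1, r2 = gravitropic_rate(hist, t, 1e-5, StimulusParams(beta=0.8))
        assert np.allclose(r1, 0.0) and np.allclose(r2, 0.0)
        r1, r2 = gravitropic_rate(hist, t, 1e-5, StimulusParams(beta=0.0))
        assert np.allclose(r1, 0.0) and np.allclose(r2, 0.0)

    def test_proprioceptive_constant_visible_strain(self):
        sp = StimulusParams(eta=20.0)
        hist, t = primed_history(u_const=(0.7, 0.0))
        epsdot = 1.0 / 72000.0
        r1, r2 = proprioceptive_rate(hist, t, epsdot, sp)
        assert np.allclose(r1, -sp.eta * epsdot * 0.7, rtol=1e-4)
        assert np.allclose(r2, 0.0, atol=1e-12)
        r1, _ = proprioceptive_rate(hist, t, epsdot, sp.with_(eta=0.0))
        assert np.allclose(r1, 0.0)

    def test_total_rate_superposition_and_zero_torsion(self):
        hist, t = primed_history()
        epsdot = 1.0 / 72000.0
        sp = StimulusParams(alpha=0.3, beta=0.8, eta=20.0)
        total = total_spontaneous_rate(hist, t, epsdot, sp)
        e = endogenous_rate(epsdot, t, sp)
        g = gravitropic_rate(hist, t, epsdot, sp)
        p = proprioceptive_rate(hist, t, epsdot, sp)
        assert np.allclose(total[:, 0], e[0] + g[0] + p[0])
        assert np.allclose(total[:, 1], e[1] + g[1] + p[1])
        assert np.all(total[:, 2] == 0.0)
        off = StimulusParams(alpha=0.0, beta=0.0, eta=0.0)
        assert np.all(total_spontaneous_rate(hist, t, epsdot, off) == 0.0)
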