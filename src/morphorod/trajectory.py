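"""Quantification and classification of nutation patterns.

The tip of a circumnutating shoot, viewed from above, traces pendular
(straight-segment), elliptic, circular, or trochoid-like curves. Treating
the planar track as the complex signal x + i y makes rotation direction
explicit: counter-clockwise motion has power at positive frequencies,
clockwise at negative ones, and a pendular oscillation splits evenly
between the two. Trochoid-like patterns are the superposition of two tones
of different frequency — epitrochoid-like when they co-rotate, hypotrochoid-
like when they counter-rotate.

Periods are estimated from a Hann-windowed periodogram of x + i y with
parabolic peak interpolation; ellipticity is the ratio of singular values of
the centered planar samples over the trailing analysis window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TipTrack",
    "PatternReport",
    "Thresholds",
    "Tone",
    "estimate_periods",
    "classify_pattern",
    "make_synthetic_track",
    "read_track",
    "write_track",
]


class InputError(ValueError):
    pass


@dataclass
class TipTrack:
    """Planar (top-view) tip trajectory with optional height."""

    times: np.ndarray
    xy: np.ndarray  # (m, 2)
    z: np.ndarray | None = None
    provenance: str = "measured"  # {simulated, measured, synthetic}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.xy = np.asarray(self.xy, float)
        if self.times.ndim != 1 or self.xy.shape != (self.times.size, 2):
            raise InputError("times must be (m,) and xy (m, 2)")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def complex_signal(self) -> np.ndarray:
        return self.xy[:, 0] + 1j * self.xy[:, 1]


@dataclass(frozen=True)
class Thresholds:
    """Operational thresholds for the qualitative pattern labels.

    A track is pendular below ``pendular`` ellipticity and circular above
    ``circular``; a secondary spectral tone is significant if its amplitude
    exceeds ``second_tone_rel`` of the dominant one and its frequency
    magnitude differs by more than ``incommensurate_rel``.
    """

    pendular: float = 0.2
    circular: float = 0.8
    second_tone_rel: float = 0.1
    incommensurate_rel: float = 0.2
    significance: float = 20.0  # peak power over median power
    window_frac: float = 0.5  # trailing fraction used for ellipticity


@dataclass(frozen=True)
class Tone:
    period: float  # [s]
    amplitude: float  # [m]
    frequency: float  # signed [1/s]; sign is the rotation direction


@dataclass
class PatternReport:
    dominant_period: float
    secondary_period: float | None
    ellipticity: float
    rotation_sign: int
    label: str
    tones: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dominant_period": self.dominant_period,
            "secondary_period": self.secondary_period,
            "ellipticity": self.ellipticity,
            "rotation_sign": self.rotation_sign,
            "label": self.label,
        }


def _resample_uniform(track: TipTrack) -> tuple[float, np.ndarray]:
    t = track.times
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=1e-6):
        return float(dt[0]), track.complex_signal()
    tu = np.linspace(t[0], t[-1], t.size)
    x = np.interp(tu, t, track.xy[:, 0])
    y = np.interp(tu, t, track.xy[:, 1])
    return float(tu[1] - tu[0]), x + 1j * y


def estimate_periods(
    track: TipTrack,
    max_tones: int = 2,
    thresholds: Thresholds = Thresholds(),
) -> list[Tone]:
    """Dominant spectral tones of the complex planar signal x + i y.

    Returns up to ``max_tones`` tones ordered by amplitude; an empty list
    means no peak rises above the noise-significance threshold. The sign of
    each tone's frequency is its rotation direction (+ = counter-clockwise).
    """
    if track.times.size < 16:
        raise InputError("track too short for spectral estimation")
    dt, z = _resample_uniform(track)
    z = z - z.mean()
    m = z.size
    win = np.hanning(m)
    Z = np.fft.fft(z * win)
    freqs = np.fft.fftfreq(m, d=dt)
    power = np.abs(Z) ** 2
    med = np.median(power)
    # coherent gain of the window: |Z| at an on-bin tone of unit amplitude
    gain = np.sum(win)

    tones: list[Tone] = []
    excluded = np.zeros(m, bool)
    excluded[0] = True  # DC
    for _ in range(max_tones):
        cand = np.where(~excluded, power, -1.0)
        i = int(np.argmax(cand))
        if cand[i] <= 0 or (med > 0 and cand[i] < thresholds.significance * med):
            break
        # parabolic interpolation on log power around the peak: the vertex
        # gives both the off-bin frequency and the descalloped amplitude
        im, ip = (i - 1) % m, (i + 1) % m
        delta, log_peak = 0.0, np.log(power[i])
        if power[im] > 0 and power[ip] > 0:
            la, lb, lc = np.log(power[im]), np.log(power[i]), np.log(power[ip])
            denom = la - 2 * lb + lc
            if denom != 0:
                delta = float(np.clip(0.5 * (la - lc) / denom, -0.5, 0.5))
                log_peak = lb + 0.25 * (la - lc) * delta
        fsig = freqs[i] + delta / (m * dt)  # fftfreq is already signed
        if fsig == 0:
            break
        amp = float(np.sqrt(np.exp(log_peak)) / gain)
        if tones and amp < 0.01 * tones[0].amplitude:
            break  # below the spectral-leakage floor of the dominant tone
        tones.append(Tone(period=1.0 / abs(fsig), amplitude=amp, frequency=float(fsig)))
        # mask the main lobe of the accepted peak
        half = max(3, m // 1024)
        idx = (np.arange(i - half, i + half + 1)) % m
        excluded[idx] = True
    if tones and track.duration < 4.0 * tones[0].period:
        raise InputError(
            f"track spans {track.duration:.3g} s < 4 periods of the dominant "
            f"tone ({tones[0].period:.3g} s)"
        )
    return tones


def _ellipticity(track: TipTrack, window_frac: float) -> float:
    m = track.times.size
    sel = slice(int((1.0 - window_frac) * m), m)
    pts = track.xy[sel] - track.xy[sel].mean(axis=0)
    sv = np.linalg.svd(pts, compute_uv=False)
    if sv[0] == 0:
        return 0.0
    return float(sv[1] / sv[0])


def classify_pattern(
    track: TipTrack, thresholds: Thresholds = Thresholds()
) -> PatternReport:
    """Label a track as pendular / elliptic / circular / trochoid-like.

    Two significant, incommensurate tones make the pattern trochoid-like:
    epitrochoid-like when they rotate the same way, hypotrochoid-like when
    opposite. Otherwise the label follows the orbit ellipticity.
    """
    tones = estimate_periods(track, max_tones=2, thresholds=thresholds)
    if not tones:
        raise InputError("no significant oscillation detected")
    ell = _ellipticity(track, thresholds.window_frac)
    dom = tones[0]
    secondary = None
    label: str
    if len(tones) > 1:
        sec = tones[1]
        distinct = (
            abs(abs(sec.frequency) - abs(dom.frequency))
            > thresholds.incommensurate_rel * abs(dom.frequency)
        )
        if sec.amplitude >= thresholds.second_tone_rel * dom.amplitude and distinct:
            secondary = sec
    if secondary is not None:
        concordant = np.sign(secondary.frequency) == np.sign(dom.frequency)
        label = "epitrochoid_like" if concordant else "hypotrochoid_like"
    elif ell < thresholds.pendular:
        label = "pendular"
    elif ell > thresholds.circular:
        label = "circular"
    else:
        label = "elliptic"
    rotation = 0 if label == "pendular" else int(np.sign(dom.frequency))
    return PatternReport(
        dominant_period=dom.period,
        secondary_period=secondary.period if secondary else None,
        ellipticity=ell,
        rotation_sign=rotation,
        label=label,
        tones=tones,
    )


def make_synthetic_track(
    A: float,
    B: float,
    omega1: float,
    omega2: float,
    sign: int = 1,
    duration: float = 3600.0,
    dt: float = 5.0,
    noise: float = 0.0,
    seed: int = 0,
) -> TipTrack:
    """Two-tone synthetic trajectory for classifier tests.

    x = A cos(w1 t) + B cos(sign w2 t), y = A sin(w1 t) + B sin(sign w2 t),
    plus optional isotropic Gaussian noise of standard deviation ``noise``.
    sign = +1 gives co-rotating (epitrochoid-like) tones, -1 counter-rotating.
    """
    if A < 0 or B < 0 or omega1 <= 0 or omega2 < 0:
        raise InputError("amplitudes must be >= 0 and frequencies positive")
    if sign not in (-1, 1):
        raise InputError("sign must be +1 or -1")
    t = np.arange(0.0, duration, dt)
    x = A * np.cos(omega1 * t) + B * np.cos(sign * omega2 * t)
    y = A * np.sin(omega1 * t) + B * np.sin(sign * omega2 * t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise, t.size)
        y = y + rng.normal(0.0, noise, t.size)
    return TipTrack(times=t, xy=np.column_stack([x, y]), provenance="synthetic")


def read_track(path, provenance: str = "measured") -> TipTrack:
    """Read a delimited text track with columns t, x, y[, z].

    Values are SI by default; a column header may state a unit in brackets
    or parentheses, e.g. ``t [min]`` or ``x (cm)``, in which case the column
    is converted on load.
    """
    from .units import parse_quantity

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols: dict[str, tuple[str, float]] = {}
    for c in df.columns:
        m = re.match(r"^\s*(\w+)\s*(?:[\[(]\s*([^\])]*)\s*[\])])?\s*$", str(c))
        if not m:
            continue
        name, unit = m.group(1).lower(), (m.group(2) or "").strip()
        factor = parse_quantity(f"1 {unit}" if unit else 1.0, field=str(c))
        cols[name] = (c, factor)
    missing = [c for c in ("t", "x", "y") if c not in cols]
    if missing:
        raise InputError(f"track file lacks columns {missing}; has {list(df.columns)}")

    def col(name):
        raw, factor = cols[name]
        return df[raw].to_numpy(float) * factor

    return TipTrack(
        times=col("t"),
        xy=np.column_stack([col("x"), col("y")]),
        z=col("z") if "z" in cols else None,
        provenance=provenance,
    )


def write_track(track: TipTrack, path) -> None:
    data = {"t": track.times, "x": track.xy[:, 0], "y": track.xy[:, 1]}
    if track.z is not None:
        data["z"] = track.z
    pd.DataFrame(data).to_csv(path, index=False)
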