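"""Undulatory swimming kinematics from digitized landmark trajectories.

Anguilliform swimmers pass a lateral wave of growing amplitude down the
body.  From video-digitized lateral positions of a few body sites (the
tail tip, a site at 0.125 body lengths from the snout and the centre of
mass at 0.35 bl) this module derives, per swimming speed:

* tail-beat frequency ``f`` (cycle counting over a fixed window),
* peak-to-peak amplitudes ``a``, ``a_A``, ``a_B`` (cm),
* body-wave speed ``W`` (site separation / phase lag),
* the Strouhal number ``St = a f / U`` (amplitude in metres),

and fits the linear speed relationships ``f = a + b U`` and
``W = a + b U``.  Analysis windows are drawn by blocked randomisation:
the recording is cut into equal blocks and one segment is drawn
uniformly at random from each block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .errors import (
    DomainError,
    InsufficientDataError,
    UndefinedFrequencyError,
    UndefinedWaveError,
)

__all__ = [
    "LandmarkTrack",
    "KinematicSample",
    "KinematicFit",
    "select_segments",
    "tailbeat_frequency",
    "amplitude",
    "wave_speed",
    "strouhal",
    "fit_kinematic",
]

#: Landmark site positions as fractions of body length from the snout.
SITE_POSITIONS_BL = {"A": 0.125, "B": 0.35, "tail": 1.0}


@dataclass(frozen=True)
class LandmarkTrack:
    """Uniformly sampled lateral position (m) of one body site."""

    times: np.ndarray
    lateral: np.ndarray
    frame_rate: float
    swim_speed: float
    site: str = "tail"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.lateral, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lateral", y)
        if self.frame_rate <= 0:
            raise DomainError("frame_rate must be > 0")
        if t.shape != y.shape or t.size < 2:
            raise DomainError("track needs matching times/lateral of length >= 2")

    def window(self, start: float, end: float) -> np.ndarray:
        mask = (self.times >= start) & (self.times < end)
        if not mask.any():
            raise DomainError(f"window [{start}, {end}) is empty")
        return self.lateral[mask]


@dataclass(frozen=True)
class KinematicSample:
    """Per-speed kinematic summary (amplitudes in cm, St dimensionless)."""

    speed: float
    f: float
    a: float
    a_A: float
    a_B: float
    W: float
    st: float


@dataclass(frozen=True)
class KinematicFit:
    """OLS line ``y = intercept + slope * U`` for f or W vs speed."""

    intercept: float
    slope: float
    r2: float

    def __call__(self, speed: float) -> float:
        return self.intercept + self.slope * speed


def select_segments(
    total_duration: float,
    segment_length: float,
    n_blocks: int,
    seed: int | np.random.Generator,
) -> list[tuple[float, float]]:
    """Blocked random selection of analysis windows.

    The recording of ``total_duration`` seconds is split into
    ``n_blocks`` equal blocks; each block is divided into contiguous
    slots of ``segment_length`` and one slot is drawn uniformly per
    block.  Defaults used experimentally: 1200 s total, 3 blocks of
    400 s, 20 s segments (20 slots per block).  Reproducible under a
    fixed seed; windows never overlap.
    """
    if n_blocks < 1:
        raise DomainError("n_blocks must be >= 1")
    block_length = total_duration / n_blocks
    if segment_length > block_length:
        raise DomainError("segment_length exceeds block length")
    n_slots = block_length / segment_length
    if abs(n_slots - round(n_slots)) > 1e-9:
        raise DomainError("segment_length must divide the block length")
    n_slots = int(round(n_slots))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    windows = []
    for b in range(n_blocks):
        slot = int(rng.integers(n_slots))
        start = b * block_length + slot * segment_length
        windows.append((start, start + segment_length))
    return windows


def _detrended(y: np.ndarray) -> np.ndarray:
    return signal.detrend(y, type="linear")


def _crossing_times(y: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Times of upward zero crossings with hysteresis.

    A crossing is counted only when the (detrended) signal has first
    dropped below -h and then rises above +h, h = 0.3 * robust signal
    scale; the crossing time is the linear interpolation of the zero
    passage.  The hysteresis suppresses noise-induced spurious
    crossings while leaving cycle timing untouched.
    """
    h = 0.3 * float(np.std(y))
    if h == 0:
        return np.array([])
    crossings = []
    armed = y[0] < -h
    last_zero = None
    for i in range(1, len(y)):
        if y[i] < -h:
            armed = True
        if y[i - 1] < 0 <= y[i]:
            # candidate zero passage; record its interpolated time
            frac = -y[i - 1] / (y[i] - y[i - 1])
            last_zero = times[i - 1] + frac * (times[i] - times[i - 1])
        if armed and y[i] > h and last_zero is not None:
            crossings.append(last_zero)
            armed = False
            last_zero = None
    return np.asarray(crossings)


def tailbeat_frequency(
    track: LandmarkTrack, window: tuple[float, float]
) -> float:
    """Tail-beat frequency (Hz) by cycle counting in ``window``.

    Counts upward mean-crossings of the linearly detrended lateral
    signal and divides elapsed cycles by the time spanned between the
    first and last crossing, eliminating window-edge quantisation.
    """
    start, end = window
    mask = (track.times >= start) & (track.times < end)
    if mask.sum() < 4:
        raise DomainError("window too short for frequency estimation")
    y = _detrended(track.lateral[mask])
    t = track.times[mask]
    crossings = _crossing_times(y, t)
    if len(crossings) < 2:
        raise UndefinedFrequencyError(
            "fewer than two oscillation cycles in window"
        )
    return (len(crossings) - 1) / (crossings[-1] - crossings[0])


def amplitude(track: LandmarkTrack, window: tuple[float, float]) -> float:
    """Peak-to-peak lateral excursion (cm) over ``window``.

    The convention is the difference between the two outermost
    positions (max - min), not the half-amplitude.
    """
    y = track.window(*window)
    return float(y.max() - y.min()) * 100.0


def wave_speed(
    track_a: LandmarkTrack,
    track_b: LandmarkTrack,
    separation: float,
    window: tuple[float, float],
) -> float:
    """Body-wave speed (m s^-1) from the phase lag between two sites.

    The posterior site repeats the anterior site's oscillation after a
    travel-time lag; the lag is read off as the phase difference of the
    two signals at the dominant oscillation frequency (cross-spectrum
    phase, the sub-sample-accurate equivalent of the cross-correlation
    peak position), wrapped into one period: ``W = separation / lag``.
    An (effectively) zero lag means an unresolvable, formally infinite
    wave speed and raises :class:`UndefinedWaveError`.
    """
    if separation <= 0:
        raise DomainError("site separation must be > 0")
    start, end = window
    mask = (track_a.times >= start) & (track_a.times < end)
    ya = _detrended(track_a.lateral[mask])
    yb = _detrended(track_b.lateral[(track_b.times >= start) & (track_b.times < end)])
    n = min(len(ya), len(yb))
    if n < 8:
        raise DomainError("window too short for wave-speed estimation")
    ya, yb = ya[:n], yb[:n]
    dt = 1.0 / track_a.frame_rate
    taper = np.hanning(n)
    fa = np.fft.rfft(ya * taper)
    fb = np.fft.rfft(yb * taper)
    power = np.abs(fa)
    power[0] = 0.0
    k0 = int(np.argmax(power))
    f0 = np.fft.rfftfreq(n, dt)[k0]
    if f0 <= 0 or power[k0] == 0:
        raise UndefinedWaveError("no dominant oscillation found")
    # yb(t) = ya(t - L)  =>  phase(fb) - phase(fa) = -2 pi f0 L (mod 2 pi)
    dphi = float(np.angle(fb[k0]) - np.angle(fa[k0]))
    period = 1.0 / f0
    lag = (-dphi / (2.0 * math.pi * f0)) % period
    if lag <= dt / 4 or lag >= period - dt / 4:
        raise UndefinedWaveError("phase lag indistinguishable from zero")
    return separation / lag


def strouhal(amplitude_m: float, frequency: float, speed: float) -> float:
    """Strouhal number St = a * f / U (amplitude in metres, peak-to-peak)."""
    if speed <= 0:
        raise DomainError(f"speed must be > 0, got {speed}")
    return amplitude_m * frequency / speed


def fit_kinematic(
    samples: Sequence[KinematicSample], variable: str
) -> KinematicFit:
    """OLS line for ``variable`` ('f' or 'W') against swimming speed."""
    if variable not in ("f", "W"):
        raise DomainError(f"variable must be 'f' or 'W', got {variable!r}")
    speeds = np.array([s.speed for s in samples])
    y = np.array([getattr(s, variable) for s in samples])
    if len(np.unique(speeds)) < 3:
        raise InsufficientDataError("need samples at >= 3 distinct speeds")
    res = stats.linregress(speeds, y)
    return KinematicFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r2=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
    )
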