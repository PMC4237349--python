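"""Swim-tunnel respirometry: MO2 extraction, the exponential metabolic
model, and derived energetic endpoints.

Oxygen uptake at each swimming speed is the slope of the O2-concentration
decline in a sealed swim-tunnel respirometer, scaled by the effective
water volume and the fish mass:

    MO2 = |d[O2]/dt| * (V_chamber - m_fish) / m_fish      (mgO2 kg^-1 h^-1)

assuming fish density ~ 1 kg L^-1 for the displaced volume.  MO2 as a
function of (blocking-corrected) swimming speed U follows the
exponential model

    MO2(U) = SMR * exp(c * U)

whose extrapolation to U = 0 is the standard metabolic rate SMR.  The
cost of transport COT(U) = MO2(U) / U (per km with the 3.6 conversion
from m s^-1 to km h^-1) is minimised at the optimal swimming speed

    U_opt = 1/c,    COT_min = SMR * c * e / 3.6.

Speeds in a confined flume are corrected for the solid blocking effect
with the fractional error term eps_S = tau * lambda * (A_O/A_T)^(3/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError, InsufficientDataError

__all__ = [
    "O2Trace",
    "MO2Sample",
    "MetabolicModel",
    "BlockingContext",
    "mo2_from_trace",
    "correct_speed",
    "fit_metabolic_model",
    "uopt",
    "cot",
    "cot_min",
]

#: Conversion factor m s^-1 -> km h^-1 used for COT per kilometre.
KMH_PER_MS = 3.6


@dataclass(frozen=True)
class O2Trace:
    """One O2-concentration decline recorded at a fixed tunnel speed.

    ``times`` are hours, ``o2`` is mg L^-1; ``chamber_volume`` in L,
    ``fish_mass`` in kg, ``tunnel_speed`` in m s^-1 (uncorrected).
    """

    times: np.ndarray
    o2: np.ndarray
    chamber_volume: float
    fish_mass: float
    tunnel_speed: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.o2, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "o2", y)
        if t.shape != y.shape:
            raise DomainError("times and o2 must have equal length")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.chamber_volume <= self.fish_mass:
            raise DomainError(
                "chamber volume must exceed fish volume proxy (mass in L)"
            )


@dataclass(frozen=True)
class MO2Sample:
    """Mass-specific oxygen uptake at one swimming speed.

    ``speed`` is blocking-corrected if a context was supplied.  Samples
    failing the slope-quality filter carry ``accepted=False``.
    """

    speed: float
    mo2: float
    r2: float
    p_value: float
    accepted: bool = True


@dataclass(frozen=True)
class MetabolicModel:
    """Fitted exponential metabolic curve MO2 = SMR * exp(c U)."""

    smr: float
    c: float
    fit_r2: float


@dataclass(frozen=True)
class BlockingContext:
    """Solid-blocking correction parameters.

    tau is the flume cross-section shape factor (0.8), lam the test
    object shape factor (0.5); areas are mm^2.  ``exponent`` is the
    power on the area ratio (3/2 in the standard convention), exposed
    for sensitivity analysis.
    """

    fish_area: float
    tunnel_area: float
    tau: float = 0.8
    lam: float = 0.5
    exponent: float = 1.5

    def __post_init__(self) -> None:
        if self.fish_area < 0:
            raise DomainError("fish_area must be >= 0")
        if self.fish_area >= self.tunnel_area:
            raise DomainError("fish_area must be smaller than tunnel_area")
        if not (0 < self.tau <= 1 and 0 < self.lam <= 1):
            raise DomainError("tau and lam must lie in (0, 1]")

    @property
    def epsilon_s(self) -> float:
        """Fractional error quotient eps_S = tau*lam*(A_O/A_T)^exponent."""
        return self.tau * self.lam * (self.fish_area / self.tunnel_area) ** self.exponent


def correct_speed(raw_speed: float, ctx: BlockingContext) -> float:
    """Blocking-corrected speed ``U_F = U_T * (1 + eps_S)`` (>= raw)."""
    return raw_speed * (1.0 + ctx.epsilon_s)


def mo2_from_trace(
    trace: O2Trace,
    min_r2: float = 0.9,
    alpha: float = 0.05,
    ctx: BlockingContext | None = None,
) -> MO2Sample:
    """Extract an MO2 sample from an O2-decline trace.

    The O2 concentration is regressed on time (OLS); the sample is
    accepted only if the slope is negative, significant at ``alpha``
    and the regression r^2 reaches ``min_r2``.  The default r^2 floor
    is 0.9; large-volume tunnels produce noisier traces and a floor of
    0.85 is a common alternative (configurable).

    MO2 uses the effective water volume ``chamber_volume - fish_mass``
    (fish density taken as 1 kg L^-1).
    """
    if not 0 < min_r2 < 1:
        raise DomainError(f"min_r2 must be in (0, 1), got {min_r2}")
    if len(trace.times) < 5:
        raise InsufficientDataError(
            f"need >= 5 O2 samples, got {len(trace.times)}"
        )
    res = stats.linregress(trace.times, trace.o2)
    slope = res.slope
    r2 = res.rvalue**2
    p = res.pvalue
    effective_volume = trace.chamber_volume - trace.fish_mass
    mo2 = abs(slope) * effective_volume / trace.fish_mass
    accepted = (slope < 0) and (p < alpha) and (r2 >= min_r2)
    speed = trace.tunnel_speed if ctx is None else correct_speed(trace.tunnel_speed, ctx)
    return MO2Sample(speed=speed, mo2=mo2, r2=r2, p_value=p, accepted=accepted)


def fit_metabolic_model(samples: Sequence[MO2Sample]) -> MetabolicModel:
    """Fit MO2 = SMR * exp(c U) to accepted samples by nonlinear least
    squares.

    SMR is the model's extrapolation to zero swimming speed.  A single
    high-speed point alongside lower-speed points is a valid input (a
    heavily burdened fish may manage only one speed step).  Requires
    at least three accepted samples at distinct speeds.
    """
    pts = [(s.speed, s.mo2) for s in samples if s.accepted]
    if len({u for u, _ in pts}) < 3:
        raise InsufficientDataError(
            f"need >= 3 accepted samples at distinct speeds, got {len(pts)}"
        )
    u = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(y <= 0):
        raise DomainError("accepted MO2 values must be positive")
    # log-linear start values; NLS refines in natural space
    b, a = np.polyfit(u, np.log(y), 1)
    p0 = (math.exp(a), b)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, smr, c: smr * np.exp(c * x), u, y, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"metabolic model fit did not converge: {exc}") from exc
    smr, c = float(popt[0]), float(popt[1])
    pred = smr * np.exp(c * u)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MetabolicModel(smr=smr, c=c, fit_r2=min(max(r2, 0.0), 1.0))


def uopt(model: MetabolicModel) -> float:
    """Optimal swimming speed U_opt = 1/c, the analytic minimiser of
    COT(U) = SMR e^{cU} / U."""
    if model.c <= 0:
        raise DomainError("no interior COT minimum for c <= 0")
    return 1.0 / model.c


def cot(model: MetabolicModel, speed: float) -> float:
    """Cost of transport at ``speed``: SMR e^{cU} / (3.6 U), in
    mgO2 kg^-1 km^-1."""
    if speed <= 0:
        raise DomainError(f"speed must be > 0, got {speed}")
    return model.smr * math.exp(model.c * speed) / (KMH_PER_MS * speed)


def cot_min(model: MetabolicModel) -> float:
    """Minimum cost of transport COT_min = SMR * c * e / 3.6
    (= COT at U_opt), in mgO2 kg^-1 km^-1."""
    if model.c <= 0:
        raise DomainError("no interior COT minimum for c <= 0")
    return model.smr * model.c * math.e / KMH_PER_MS
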