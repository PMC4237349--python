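"""Spherical drag-dummy physics and empirical drag-curve calibration.

External telemetry tags are emulated in swim-tunnel experiments by
neutrally buoyant spheres ("drag dummies") sized so that each imposes a
chosen drag force at a reference swimming speed.  A sphere's drag is
dominated by shape (pressure) drag, so the quadratic drag law

    F_D = 1/2 * rho * V**2 * c_D * A,    A = pi * (d/2)**2

with ``rho`` the water density, ``c_D`` the sphere drag coefficient and
``A`` the cross-sectional area, is an adequate sizing model.  Measured
force-speed calibrations are summarised as a through-origin polynomial
``F_D = alpha*V**2 + beta*V`` so that zero speed gives zero force.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError, OutOfRangeWarning

__all__ = [
    "FluidEnv",
    "DummySpec",
    "DragCurve",
    "sphere_drag",
    "size_sphere",
    "fit_drag_curve",
    "validate_agreement",
]


@dataclass(frozen=True)
class FluidEnv:
    """Fluid environment in which drags are defined.

    Parameters
    ----------
    density
        Mass density of the water, kg m^-3.  Default is seawater at
        experimental salinity (1020 kg m^-3).
    drag_coefficient
        Dimensionless sphere drag coefficient ``c_D`` (0.45).
    reference_speed
        Speed (m s^-1) at which nominal dummy drags are defined; taken
        as the optimal swimming speed of untagged silver eels
        (0.65 m s^-1).
    """

    density: float = 1020.0
    drag_coefficient: float = 0.45
    reference_speed: float = 0.65

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError(f"density must be > 0, got {self.density}")
        if not 0 < self.drag_coefficient < 2:
            raise DomainError(
                f"drag_coefficient must be in (0, 2), got {self.drag_coefficient}"
            )
        if self.reference_speed <= 0:
            raise DomainError(
                f"reference_speed must be > 0, got {self.reference_speed}"
            )


@dataclass(frozen=True)
class DummySpec:
    """A spherical drag dummy: size class, diameter (m) and nominal drag (N)."""

    label: str
    diameter: float
    nominal_drag: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise DomainError(f"diameter must be > 0, got {self.diameter}")
        if self.nominal_drag <= 0:
            raise DomainError(f"nominal_drag must be > 0, got {self.nominal_drag}")

    @property
    def diameter_cm(self) -> float:
        """Diameter in cm rounded to two decimals (display convention)."""
        return round(self.diameter * 100.0, 2)


@dataclass(frozen=True)
class DragCurve:
    """Empirical through-origin drag polynomial ``F = a*V^2 + b*V``.

    ``quad_coeff`` is in N s^2 m^-2, ``lin_coeff`` in N s m^-1.
    ``speed_range`` is the (min, max) of the calibration speeds.
    """

    quad_coeff: float
    lin_coeff: float
    fit_r2: float
    speed_range: tuple[float, float] = (0.2, 0.9)

    def __call__(self, speed: float | np.ndarray) -> float | np.ndarray:
        return self.quad_coeff * np.asarray(speed) ** 2 + self.lin_coeff * np.asarray(
            speed
        )


#: Published calibration curves for the three dummy sizes, valid on
#: 0.2-0.9 m s^-1 (coefficients of V^2 and V respectively).
MEASURED_CURVES: dict[str, DragCurve] = {
    "small": DragCurve(0.123, -0.004, 0.99, (0.2, 0.9)),
    "intermediate": DragCurve(0.341, -0.065, 0.99, (0.2, 0.9)),
    "large": DragCurve(0.56, -0.068, 0.99, (0.2, 0.9)),
}

#: Nominal drags (N at the reference speed) per size class.
NOMINAL_DRAGS: dict[str, float] = {"small": 0.05, "intermediate": 0.1, "large": 0.2}


def sphere_drag(diameter: float, speed: float, env: FluidEnv = FluidEnv()) -> float:
    """Theoretical drag force (N) on a sphere of ``diameter`` at ``speed``.

    Implements ``F = 1/2 rho V^2 c_D pi (d/2)^2``; scales with V^2 and d^2.
    """
    if diameter <= 0:
        raise DomainError(f"diameter must be > 0, got {diameter}")
    if speed < 0:
        raise DomainError(f"speed must be >= 0, got {speed}")
    area = math.pi * (diameter / 2.0) ** 2
    return 0.5 * env.density * speed**2 * env.drag_coefficient * area


def size_sphere(target_drag: float, env: FluidEnv = FluidEnv()) -> float:
    """Diameter (m) of the sphere producing ``target_drag`` N at the
    reference speed.

    Inverts the sphere drag law: ``d = sqrt(8 F / (rho c_D pi V_ref^2))``.
    """
    if target_drag <= 0:
        raise DomainError(f"target_drag must be > 0, got {target_drag}")
    return math.sqrt(
        8.0
        * target_drag
        / (env.density * env.drag_coefficient * math.pi * env.reference_speed**2)
    )


def fit_drag_curve(
    measurements: Iterable[tuple[float, float, object]],
    average_replicates: bool = True,
) -> DragCurve:
    """Fit the through-origin polynomial ``F = a V^2 + b V`` to force
    calibration data.

    Parameters
    ----------
    measurements
        Iterable of ``(speed m/s, force N, replicate id)`` tuples.
        Replicate forces are averaged per speed before fitting by
        default (set ``average_replicates=False`` to fit raw points).

    Returns
    -------
    DragCurve with least-squares coefficients and coefficient of
    determination (clamped to [0, 1]; degenerate data give low r^2
    rather than an error).
    """
    rows = [(float(s), float(f)) for s, f, _ in measurements]
    if not rows:
        raise InsufficientDataError("no calibration measurements supplied")
    speeds = np.array([r[0] for r in rows])
    forces = np.array([r[1] for r in rows])
    if len(np.unique(speeds)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct speeds, got {len(np.unique(speeds))}"
        )
    if average_replicates:
        uniq = np.unique(speeds)
        forces = np.array([forces[speeds == s].mean() for s in uniq])
        speeds = uniq
    X = np.column_stack([speeds**2, speeds])
    coef, *_ = np.linalg.lstsq(X, forces, rcond=None)
    pred = X @ coef
    ss_res = float(np.sum((forces - pred) ** 2))
    ss_tot = float(np.sum((forces - forces.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return DragCurve(
        quad_coeff=float(coef[0]),
        lin_coeff=float(coef[1]),
        fit_r2=r2,
        speed_range=(float(speeds.min()), float(speeds.max())),
    )


def validate_agreement(
    curve: DragCurve,
    spec: DummySpec,
    env: FluidEnv = FluidEnv(),
    speed: float | None = None,
) -> float:
    """Relative difference between the theoretical sphere drag and the
    calibrated curve at ``speed`` (default: the reference speed).

    Returns ``|F_theory - F_curve| / F_theory``.  Evaluating outside the
    calibration speed range emits :class:`OutOfRangeWarning` but still
    computes (theory and polynomial diverge strongly at low speed).
    """
    if speed is None:
        speed = env.reference_speed
    lo, hi = curve.speed_range
    if not lo <= speed <= hi:
        warnings.warn(
            f"speed {speed} outside calibration range [{lo}, {hi}]",
            OutOfRangeWarning,
            stacklevel=2,
        )
    theory = sphere_drag(spec.diameter, speed, env)
    measured = float(curve(speed))
    return abs(theory - measured) / theory


def standard_dummies(env: FluidEnv = FluidEnv()) -> list[DummySpec]:
    """The three standard dummy size classes sized for 0.05/0.1/0.2 N."""
    return [
        DummySpec(label, size_sphere(drag, env), drag)
        for label, drag in NOMINAL_DRAGS.items()
    ]
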