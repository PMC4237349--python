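"""Critical swimming speed from a stepwise fatigue protocol.

Water speed is raised by a fixed increment dU at fixed intervals dT
until the fish fatigues (refuses to swim and drifts onto the downstream
grid).  The critical swimming speed interpolates within the failing
step (Brett's formula):

    U_crit = U_i + dU * (T_i / dT)

with U_i the highest speed maintained for a full interval and T_i the
time endured at the failing speed.  Whether the animal has fatigued is
an operational judgement made by the experimenter; this module only
evaluates the formula and validates protocol consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, ProtocolViolationError
from .respirometry import BlockingContext, correct_speed

__all__ = ["UcritProtocol", "UcritResult", "compute_ucrit"]


@dataclass(frozen=True)
class UcritProtocol:
    """Stepwise protocol parameters: increment dU (m s^-1), interval
    dT (min) and the first tested speed."""

    speed_increment: float = 0.1
    interval: float = 20.0
    start_speed: float = 0.3

    def __post_init__(self) -> None:
        if self.speed_increment <= 0:
            raise DomainError("speed_increment must be > 0")
        if self.interval <= 0:
            raise DomainError("interval must be > 0")


@dataclass(frozen=True)
class UcritResult:
    u_crit: float
    last_completed_speed: float
    fatigue_time: float
    corrected: bool = False


def compute_ucrit(
    last_completed_speed: float,
    fatigue_time: float,
    protocol: UcritProtocol = UcritProtocol(),
    ctx: BlockingContext | None = None,
) -> UcritResult:
    """Evaluate Brett's formula for one animal.

    ``last_completed_speed`` is U_i, the highest speed maintained for a
    full interval; ``fatigue_time`` is T_i (min) endured at the failing
    speed.  If the fish fatigues during the very first step, pass
    ``last_completed_speed = 0``: the increment for that animal is then
    the start speed itself, so U_crit = start_speed * T_i/dT.

    Passing ``ctx`` applies the solid-blocking correction, which
    commutes with the formula (a common multiplicative factor).
    """
    if last_completed_speed < 0:
        raise DomainError("last_completed_speed must be >= 0")
    if fatigue_time < 0:
        raise DomainError("fatigue_time must be >= 0")
    if fatigue_time > protocol.interval:
        raise ProtocolViolationError(
            f"fatigue_time {fatigue_time} exceeds the interval "
            f"{protocol.interval}: the step was completed, advance U_i"
        )
    if last_completed_speed == 0:
        increment = protocol.start_speed
    else:
        increment = protocol.speed_increment
    u_crit = last_completed_speed + increment * (fatigue_time / protocol.interval)
    if ctx is not None:
        u_crit = correct_speed(u_crit, ctx)
    return UcritResult(
        u_crit=u_crit,
        last_completed_speed=last_completed_speed,
        fatigue_time=fatigue_time,
        corrected=ctx is not None,
    )


def ucrit_from_steps(
    step_speeds,
    completed_minutes,
    protocol: UcritProtocol = UcritProtocol(),
    ctx: BlockingContext | None = None,
) -> UcritResult:
    """Reduce a step log (speed, minutes completed per step) to U_crit.

    All steps except the last must run the full interval; the last step
    is the fatigue step.  A fully completed final step means the trial
    record is truncated and U_crit equals that speed plus nothing -- the
    caller should supply the true fatigue step; here it is treated as
    fatigue at T_i = dT.
    """
    speeds = list(step_speeds)
    mins = list(completed_minutes)
    if len(speeds) != len(mins) or not speeds:
        raise DomainError("step log must be non-empty with matching lengths")
    for s, m in zip(speeds[:-1], mins[:-1]):
        if m < protocol.interval:
            raise ProtocolViolationError(
                f"non-final step at {s} m/s lasted {m} < {protocol.interval} min"
            )
    if len(speeds) == 1:
        last_completed = 0.0
    else:
        last_completed = speeds[-2]
    return compute_ucrit(last_completed, mins[-1], protocol, ctx)
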