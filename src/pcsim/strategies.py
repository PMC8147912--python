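"""Physician strategies: appointment scheduling, treatment order, admission.

Three pluggable strategy interfaces govern a practice's behaviour, with one
concrete case-study implementation each:

* ``FixedIntervalScheduling`` — an individual-block/fixed-interval rule: each
  open session is divided into equal slots of one patient each, and requests
  receive the earliest free slot inside the patient's feasibility window.
* ``PFCFSTreatment`` — priority first-come-first-served: appointment holders
  strictly before walk-ins, emergency walk-ins before ordinary ones, and
  first-come-first-served within each class; service times are log-normal
  with a demand-dependent speed-up once the queue grows past a threshold.
* ``PriorityThresholdAdmission`` — walk-ins are admitted only while the
  predicted completion time of all present and booked work stays within the
  session's buffer plus a threshold θ; emergencies get a relaxed threshold.
  After each session's buffer the practice learns: realized overtime makes θ
  stricter, substantial idle time makes it more permissive.

New strategies register under a name via the module-level registries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .agents import PCP
from .illness import sample_lognormal_mean
from .timebase import MINUTES_PER_DAY, Session, weekly_class


@dataclass(frozen=True)
class StrategyConfig:
    """Parameters of the three case-study strategies (all per practice)."""

    slot_minutes: float = 10.0          # fixed appointment-slot length
    mean_service_min: float = 10.0      # base mean of the service-time law
    service_cv: float = 0.25            # log-normal coefficient of variation
    congestion_queue: int = 4           # queue length that triggers speed-up
    speed_factor: float = 0.8           # service-time factor under congestion
    buffer_hours: float = 1.0           # post-session buffer for delays
    theta0_min: float = 0.0             # initial admission threshold θ
    theta_step_min: float = 5.0         # additive learning step for θ
    theta_min_min: float = -60.0
    theta_max_min: float = 60.0
    emergency_relax_min: float = 30.0   # θ_e = θ + relax for emergencies
    idle_threshold_min: float = 10.0    # idle time that loosens θ
    deterministic: bool = False         # zero-variance service times


# --------------------------------------------------------------------------
# Appointment scheduling
# --------------------------------------------------------------------------

class AppointmentSchedulingStrategy:
    """Interface: slot calendars and slot offers for one practice."""

    def offer(
        self,
        window_lo: float,
        window_hi: float,
        availabilities: Sequence[bool],
    ) -> Optional[tuple[float, Session, int]]:
        """Earliest free slot time t with ``window_lo < t <= window_hi`` in a
        session the patient can attend, or None."""
        raise NotImplementedError

    def book(self, session: Session, slot: int) -> None:
        raise NotImplementedError

    def release(self, session: Session, slot: int) -> None:
        raise NotImplementedError

    def booked_after(self, session: Session, time: float) -> int:
        """Number of still-booked slots of ``session`` at or after ``time``."""
        raise NotImplementedError


class FixedIntervalScheduling(AppointmentSchedulingStrategy):
    """Equal fixed-length slots per session, one patient per slot."""

    def __init__(self, pcp: PCP, config: StrategyConfig = StrategyConfig()) -> None:
        self.pcp = pcp
        self.slot_days = config.slot_minutes / MINUTES_PER_DAY
        self._occupied: dict[tuple[int, int], set[int]] = {}

    def _slots(self, session: Session) -> tuple[float, int]:
        """(scalar time of slot 0, number of slots) of an open session."""
        window = self.pcp.session_window(session)
        if window is None:
            return 0.0, 0
        lo, hi = window
        n = max(0, int(math.floor((hi - lo) / self.slot_days + 1e-9)))
        return lo, n

    def slot_time(self, session: Session, slot: int) -> float:
        start, _ = self._slots(session)
        return start + slot * self.slot_days

    def offer(
        self,
        window_lo: float,
        window_hi: float,
        availabilities: Sequence[bool],
    ) -> Optional[tuple[float, Session, int]]:
        if window_hi <= window_lo:
            return None
        for day in range(int(window_lo), int(window_hi) + 1):
            for half in (0, 1):
                session = Session(day, half)
                if not availabilities[weekly_class(session).index]:
                    continue
                start, n = self._slots(session)
                if n == 0:
                    continue
                taken = self._occupied.get((day, half), ())
                # first slot strictly after window_lo
                k0 = max(0, int(math.ceil((window_lo - start) / self.slot_days - 1e-9)))
                while k0 < n and start + k0 * self.slot_days <= window_lo + 1e-12:
                    k0 += 1
                for k in range(k0, n):
                    t = start + k * self.slot_days
                    if t > window_hi + 1e-12:
                        break
                    if k not in taken:
                        return t, session, k
        return None

    def book(self, session: Session, slot: int) -> None:
        taken = self._occupied.setdefault((session.day, session.half), set())
        if slot in taken:
            raise RuntimeError(f"slot {slot} of {session} double-booked")
        taken.add(slot)

    def release(self, session: Session, slot: int) -> None:
        self._occupied.get((session.day, session.half), set()).discard(slot)

    def booked_after(self, session: Session, time: float) -> int:
        taken = self._occupied.get((session.day, session.half), ())
        if not taken:
            return 0
        start, _ = self._slots(session)
        return sum(1 for k in taken if start + k * self.slot_days >= time - 1e-12)


# --------------------------------------------------------------------------
# Treatment
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class WaitingEntry:
    """One patient present in the waiting room, in priority order.

    The sort key implements PFCFS: class rank (0 = appointment holder,
    1 = emergency walk-in, 2 = ordinary walk-in), then arrival time, then an
    admission sequence number for reproducible ties.
    """

    rank: int
    arrival: float
    seq: int
    patient_id: int = field(compare=False)
    kind: str = field(compare=False)               # "appointment" | "walkin"
    scheduled: Optional[float] = field(compare=False, default=None)
    session: Optional[Session] = field(compare=False, default=None)
    role: Optional[str] = field(compare=False, default=None)  # appointment role


class TreatmentStrategy:
    """Interface: who is treated next, and how long treatment takes."""

    def next_patient(self, waiting_room: list[WaitingEntry]) -> WaitingEntry:
        raise NotImplementedError

    def service_time(
        self, queue_length: int, rng: np.random.Generator
    ) -> float:
        """Service duration in days for the next treatment."""
        raise NotImplementedError


class PFCFSTreatment(TreatmentStrategy):
    """Priority FCFS with demand-dependent log-normal service times."""

    def __init__(self, config: StrategyConfig = StrategyConfig()) -> None:
        self.config = config

    def next_patient(self, waiting_room: list[WaitingEntry]) -> WaitingEntry:
        if not waiting_room:
            raise RuntimeError("waiting room is empty")
        entry = min(waiting_room)
        waiting_room.remove(entry)
        return entry

    def mean_service_days(self, queue_length: int) -> float:
        mean = self.config.mean_service_min
        if queue_length > self.config.congestion_queue:
            mean *= self.config.speed_factor
        return mean / MINUTES_PER_DAY

    def service_time(self, queue_length: int, rng: np.random.Generator) -> float:
        mean = self.mean_service_days(queue_length)
        if self.config.deterministic:
            return mean
        return max(
            sample_lognormal_mean(mean, self.config.service_cv, rng), 1e-9
        )


# --------------------------------------------------------------------------
# Admission
# --------------------------------------------------------------------------

class AdmissionStrategy:
    """Interface: admit or reject an arriving patient; per-session learning."""

    def admit(
        self,
        kind: str,
        emergency: bool,
        now: float,
        session_close: float,
        predicted_work_days: float,
    ) -> bool:
        raise NotImplementedError

    def end_of_buffer_learning(self, overtime_min: float, idle_min: float) -> None:
        raise NotImplementedError


class PriorityThresholdAdmission(AdmissionStrategy):
    """Threshold rule on the predicted completion of present + booked work.

    Appointment holders are always admitted (admitted patients must be
    treated, so the practice honours its own bookings).  A walk-in is
    admitted iff the predicted completion time of everyone present plus the
    remaining booked appointments stays within the session's buffer end plus
    the current threshold θ; emergencies get θ + a relaxation.
    """

    def __init__(self, config: StrategyConfig = StrategyConfig()) -> None:
        self.config = config
        self.theta_days = config.theta0_min / MINUTES_PER_DAY

    @property
    def theta_min(self) -> float:
        return self.theta_days * MINUTES_PER_DAY

    def admit(
        self,
        kind: str,
        emergency: bool,
        now: float,
        session_close: float,
        predicted_work_days: float,
    ) -> bool:
        if kind == "appointment":
            return True
        theta = self.theta_days
        if emergency:
            theta += self.config.emergency_relax_min / MINUTES_PER_DAY
        buffer_end = session_close + self.config.buffer_hours / 24.0
        return now + predicted_work_days <= buffer_end + theta + 1e-12

    def end_of_buffer_learning(self, overtime_min: float, idle_min: float) -> None:
        step = self.config.theta_step_min / MINUTES_PER_DAY
        lo = self.config.theta_min_min / MINUTES_PER_DAY
        hi = self.config.theta_max_min / MINUTES_PER_DAY
        if overtime_min > 1e-9:
            self.theta_days = max(lo, self.theta_days - step)
        elif idle_min >= self.config.idle_threshold_min:
            self.theta_days = min(hi, self.theta_days + step)


# --------------------------------------------------------------------------
# Registries
# --------------------------------------------------------------------------

SCHEDULING_REGISTRY: dict[str, Callable[..., AppointmentSchedulingStrategy]] = {
    "fixed_interval": FixedIntervalScheduling,
}
TREATMENT_REGISTRY: dict[str, Callable[..., TreatmentStrategy]] = {
    "pfcfs": PFCFSTreatment,
}
ADMISSION_REGISTRY: dict[str, Callable[..., AdmissionStrategy]] = {
    "priority_threshold": PriorityThresholdAdmission,
}


def build_strategies(
    pcp: PCP, config: StrategyConfig
) -> tuple[AppointmentSchedulingStrategy, TreatmentStrategy, AdmissionStrategy]:
    """Instantiate the strategy triple named on a practice."""
    try:
        sched = SCHEDULING_REGISTRY[pcp.scheduling_strategy](pcp, config)
        treat = TREATMENT_REGISTRY[pcp.treatment_strategy](config)
        admit = ADMISSION_REGISTRY[pcp.admission_strategy](config)
    except KeyError as exc:  # pragma: no cover - configuration guard
        raise ValueError(f"unknown strategy name {exc} on practice {pcp.id}")
    return sched, treat, admit
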