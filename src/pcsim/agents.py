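"""Patient and physician agents, ratings, and care-seeking choice logic.

Patients maintain internal, never-communicated ratings of the physicians in
their consideration set: one appointment rating per physician and one
walk-in rating per (physician, weekly session).  Initial ratings blend a
distance decay kernel with the overlap between the patient's weekly
availabilities and the practice's opening hours; experiences then scale the
relevant rating multiplicatively (failed requests, rejections at the door
and long waits decrease it, granted requests and short waits increase it).
Appointment requests go to the up-to-two highest-rated physicians; walk-in
visits target the feasible (physician, session) pair with the highest
walk-in rating.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .illness import AgeClass, Illness
from .timebase import Session, weekly_class

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres between two WGS84 coordinates."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


class Experience(enum.Enum):
    """Patient experiences that move ratings."""

    REQUEST_GRANTED = "request_granted"
    REQUEST_FAILED = "request_failed"
    SHORT_WAIT = "short_wait"
    LONG_WAIT = "long_wait"
    REJECTED_AT_DOOR = "rejected_at_door"


@dataclass(frozen=True)
class BehaviorConfig:
    """Tunables of patient preference formation and updating.

    Only the monotone directions of the rating updates are normative; the
    concrete kernel and factors are package choices, all configurable.
    """

    distance_weight: float = 1.0
    match_weight: float = 1.0
    distance_scale_km: float = 5.0      # d0 in the kernel 1 / (1 + d / d0)
    factor_request_granted: float = 1.1
    factor_request_failed: float = 0.8
    factor_short_wait: float = 1.05
    factor_long_wait: float = 0.9
    factor_rejected_at_door: float = 0.6
    rating_cap: float = 100.0
    long_wait_threshold_min: float = 30.0
    family_switch_margin: float = 0.2   # challenger must exceed incumbent by 20 %
    consideration_size: int = 5         # k nearest practices

    def factor(self, experience: Experience) -> float:
        return {
            Experience.REQUEST_GRANTED: self.factor_request_granted,
            Experience.REQUEST_FAILED: self.factor_request_failed,
            Experience.SHORT_WAIT: self.factor_short_wait,
            Experience.LONG_WAIT: self.factor_long_wait,
            Experience.REJECTED_AT_DOOR: self.factor_rejected_at_door,
        }[experience]


@dataclass(frozen=True)
class PCP:
    """Static attributes of a primary care physician's practice.

    ``opening_hours`` holds one entry per weekly session class (dense index
    0..13): a ``(open, close)`` pair of decimal times, or None when closed.
    """

    id: str
    lat: float
    lon: float
    opening_hours: tuple[Optional[tuple[float, float]], ...]
    scheduling_strategy: str = "fixed_interval"
    admission_strategy: str = "priority_threshold"
    treatment_strategy: str = "pfcfs"

    def __post_init__(self) -> None:
        # window sanity (open < close) is a scenario-validation concern so
        # that every violation can be reported at once
        if len(self.opening_hours) != 14:
            raise ValueError("opening_hours must have 14 entries")

    def is_open(self, class_index: int) -> bool:
        return self.opening_hours[class_index] is not None

    def session_window(self, session: Session) -> Optional[tuple[float, float]]:
        """Scalar (open, close) of the given session, or None when closed."""
        window = self.opening_hours[weekly_class(session).index]
        if window is None:
            return None
        return session.day + window[0], session.day + window[1]


@dataclass(eq=False)
class Appointment:
    """A booked (time, physician, patient) triple with its calendar slot."""

    time: float                    # scalar day value of the slot
    session: Session
    slot: int                      # slot index within the session grid
    pcp_id: str
    patient_id: int
    role: str                      # "acute" | "regular"
    cancelled: bool = False


@dataclass(eq=False)
class Patient:
    """One patient agent; location, condition, age class and availabilities
    are constant over a run, everything else evolves with the simulation."""

    id: int
    lat: float
    lon: float
    health: float                  # condition c in [0, 1]; 0 = perfectly healthy
    age_class: AgeClass
    availabilities: tuple[bool, ...]          # one flag per weekly session class
    considered: tuple[str, ...] = ()          # PCP ids, nearest first
    chronic_illness: Optional[Illness] = None
    appointment_ratings: dict[str, float] = field(default_factory=dict)
    walkin_ratings: dict[str, np.ndarray] = field(default_factory=dict)
    acute_illnesses: list = field(default_factory=list)   # active IllnessCases
    emergency: bool = False
    acute_appointment: Optional[Appointment] = None
    regular_appointment: Optional[Appointment] = None
    family_physician: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.availabilities) != 14:
            raise ValueError("availabilities must have 14 entries")

    @property
    def chronic(self) -> bool:
        return self.chronic_illness is not None


def _availability_overlap(patient: Patient, pcp: PCP) -> float:
    """Fraction of the patient's available weekly sessions the PCP is open."""
    available = [k for k in range(14) if patient.availabilities[k]]
    if not available:
        return 0.0
    open_count = sum(1 for k in available if pcp.is_open(k))
    return open_count / len(available)


def initial_ratings(
    patient: Patient,
    pcps: Sequence[PCP],
    config: BehaviorConfig = BehaviorConfig(),
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Build the initial appointment and walk-in ratings for every considered
    physician from distance decay and opening-hours/availability overlap."""
    if not pcps:
        raise ValueError("patient's consideration set is empty")
    app: dict[str, float] = {}
    walk: dict[str, np.ndarray] = {}
    for pcp in pcps:
        d = haversine_km(patient.lat, patient.lon, pcp.lat, pcp.lon)
        kernel = 1.0 / (1.0 + d / config.distance_scale_km)
        base = (
            config.distance_weight * kernel
            + config.match_weight * _availability_overlap(patient, pcp)
        )
        app[pcp.id] = base
        row = np.zeros(14)
        for k in range(14):
            if patient.availabilities[k] and pcp.is_open(k):
                row[k] = base
        walk[pcp.id] = row
    return app, walk


def update_rating(
    patient: Patient,
    pcp_id: str,
    experience: Experience,
    config: BehaviorConfig = BehaviorConfig(),
    session: Optional[Session] = None,
) -> None:
    """Apply one experience to the relevant rating.

    Appointment-related experiences (requests, waits at appointments) touch
    the appointment rating; when ``session`` is given the experience refers
    to a walk-in visit and touches the walk-in rating of that weekly session.
    """
    if pcp_id not in patient.appointment_ratings:
        raise ValueError(f"{pcp_id} is not in the patient's consideration set")
    f = config.factor(experience)
    if session is None:
        value = patient.appointment_ratings[pcp_id] * f
        patient.appointment_ratings[pcp_id] = min(max(value, 0.0), config.rating_cap)
    else:
        k = weekly_class(session).index
        row = patient.walkin_ratings[pcp_id]
        row[k] = min(max(row[k] * f, 0.0), config.rating_cap)


def choose_appointment_targets(patient: Patient) -> list[str]:
    """The up-to-two highest appointment-rated physicians, descending;
    ties break on the lexicographically smaller identifier."""
    if not patient.appointment_ratings:
        raise ValueError("patient has no rated physicians")
    ranked = sorted(
        patient.appointment_ratings.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return [pcp_id for pcp_id, _ in ranked[:2]]


def choose_walkin_target(
    patient: Patient,
    candidates: Sequence[tuple[str, Session]],
) -> Optional[tuple[str, Session]]:
    """Feasible (physician, session) pair maximizing the walk-in rating.

    Ties break on the earlier session, then the smaller physician id.
    Returns None when no candidate exists (the patient forgoes care).
    """
    best: Optional[tuple[str, Session]] = None
    best_key: Optional[tuple[float, int, int, str]] = None
    for pcp_id, session in candidates:
        rating = float(patient.walkin_ratings[pcp_id][weekly_class(session).index])
        key = (-rating, session.day, session.half, pcp_id)
        if best_key is None or key < best_key:
            best, best_key = (pcp_id, session), key
    return best


def reevaluate_family_physician(
    patient: Patient, config: BehaviorConfig = BehaviorConfig()
) -> Optional[str]:
    """Possibly switch the family physician to the top-rated practice.

    The incumbent is only displaced when the challenger's appointment rating
    exceeds the incumbent's by the configured margin (hysteresis keeps
    chronic care continuous under small rating fluctuations).
    """
    if not patient.chronic:
        raise ValueError("only chronic patients hold a family physician")
    top = choose_appointment_targets(patient)[0]
    incumbent = patient.family_physician
    if incumbent is None:
        patient.family_physician = top
        return top
    r_top = patient.appointment_ratings[top]
    r_inc = patient.appointment_ratings[incumbent]
    if top != incumbent and r_top > (1.0 + config.family_switch_margin) * r_inc:
        patient.family_physician = top
    return patient.family_physician
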