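"""Discrete-event core: the chronological event loop driving all agents.

A run starts from an empty system state: no illnesses, no bookings, initial
ratings straight from distance and opening-hours overlap.  Events live in a
priority queue ordered by time, then a fixed kind priority for simultaneous
events (illness dynamics before arrivals before treatment completions before
end-of-buffer bookkeeping), then an insertion sequence number, which makes
every run bit-reproducible for a given (scenario, horizon, seed).

Event kinds and their processing:

* ``illness onset`` — the patient acquires a sampled acute illness, schedules
  its recovery, and immediately seeks care: up to two appointment requests in
  rating order, then the walk-in path as fallback.  An existing acute
  appointment inside the willingness window is reused (a patient never holds
  two acute appointments).
* ``recovery`` — the illness subsides; a booking that no longer serves any
  illness is cancelled with the age-class cancellation probability.
* ``arrival`` — an appointment holder (with a normal punctuality offset) or a
  walk-in (beta-positioned inside the targeted session) reaches the practice
  and faces the admission strategy.  Rejected walk-ins become emergencies and
  retry at the next-best (practice, session) pair until the willingness
  window is exhausted.
* ``treatment complete`` — all acute illnesses count as treated; persisting
  illnesses with more than a follow-up interval of remaining duration get a
  follow-up booking with the attending physician; chronic patients rebook
  their regular appointment with the family physician one follow-up interval
  ahead; the next waiting patient (priority FCFS) enters service.
* ``regular due`` / ``end of buffer`` — chronic booking triggers and the
  per-session admission-threshold learning step.

Randomness is split into named substreams derived from one root seed, so a
change in one concern (say service times) does not perturb the draws of any
other.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .agents import (
    PCP,
    Appointment,
    Experience,
    Patient,
    choose_appointment_targets,
    choose_walkin_target,
    haversine_km,
    initial_ratings,
    reevaluate_family_physician,
    update_rating,
)
from .illness import (
    Illness,
    expected_traits,
    sample_acute_illness,
    sample_onset_gap,
)
from .kpi import KpiAccumulator, KpiRecord
from .scenario import Scenario, validate
from .strategies import WaitingEntry, build_strategies
from .timebase import MINUTES_PER_DAY, Session, TimePoint, weekly_class

# Event kinds, in tie-break priority order for simultaneous events.
ONSET, RECOVERY, REGULAR_DUE, ARRIVAL, COMPLETE, BUFFER_END = range(6)
_PRIORITY = {ONSET: 1, RECOVERY: 1, REGULAR_DUE: 1, ARRIVAL: 2, COMPLETE: 3,
             BUFFER_END: 5}

_EPS = 1e-9


class ScenarioError(ValueError):
    """Raised when a scenario fails validation; carries all violations."""

    def __init__(self, violations: Sequence[str]):
        super().__init__("invalid scenario:\n" + "\n".join(violations))
        self.violations = list(violations)


@dataclass
class IllnessCase:
    """One active acute illness of a patient."""

    illness: Illness
    onset: float
    end: float


@dataclass
class WalkinIntent:
    """A planned walk-in visit (pending arrival)."""

    pcp_id: str
    session: Session
    deadline: float
    tried: set = field(default_factory=set)
    cancelled: bool = False


class PracticeState:
    """Per-run mutable state of one practice."""

    def __init__(self, pcp: PCP, config) -> None:
        self.pcp = pcp
        self.scheduling, self.treatment, self.admission = build_strategies(
            pcp, config
        )
        self.waiting: list[WaitingEntry] = []
        self.in_service: Optional[WaitingEntry] = None
        self.service_start = 0.0
        self.service_end = 0.0
        self.session_busy: dict[tuple[int, int], float] = {}
        self.buffer_days = config.buffer_hours / 24.0


class Simulation:
    """One simulation run over ``[0, horizon)`` with KPI window
    ``[warmup, horizon)``."""

    def __init__(
        self,
        scenario: Scenario,
        horizon: float,
        warmup: float = 0.0,
        seed: int = 0,
        yearly: bool = False,
        trace: Optional[Callable[[str], None]] = None,
        scripted_onsets: Optional[Sequence[tuple[float, int, Illness]]] = None,
        check_scenario: bool = True,
    ) -> None:
        if check_scenario:
            violations = validate(scenario)
            if violations:
                raise ScenarioError(violations)
        if not warmup < horizon:
            raise ValueError("warmup must be smaller than the horizon")
        self.scenario = scenario
        self.horizon = float(horizon)
        self.warmup = float(warmup)
        self.trace = trace
        self.clock = 0.0

        ss = np.random.SeedSequence([int(seed), 0x51CA]).spawn(5)
        self.rng_onsets = np.random.default_rng(ss[0])
        self.rng_illness = np.random.default_rng(ss[1])
        self.rng_service = np.random.default_rng(ss[2])
        self.rng_arrivals = np.random.default_rng(ss[3])
        self.rng_choices = np.random.default_rng(ss[4])

        self._heap: list = []
        self._seq = 0

        self.practices = {
            p.id: PracticeState(p, scenario.strategy) for p in scenario.pcps
        }
        self.patients: dict[int, Patient] = {}
        self.cases: dict[int, list[IllnessCase]] = {}
        self.intents: dict[int, WalkinIntent] = {}
        self.onset_rates: dict[int, float] = {}
        self.distance: dict[tuple[int, str], float] = {}
        self._build_patients()

        n_chronic = sum(1 for p in self.patients.values() if p.chronic)
        self.kpi = KpiAccumulator(
            scenario.pcps, len(self.patients), n_chronic,
            self.warmup, self.horizon, yearly=yearly,
        )

        self._schedule_buffer_ends()
        self._seed_initial_events(scripted_onsets)

    # ------------------------------------------------------------------
    # Initialization
    # ------------------------------------------------------------------

    def _build_patients(self) -> None:
        scn = self.scenario
        k = scn.behavior.consideration_size
        pcp_list = scn.pcps
        for spec in scn.patients:
            age = scn.age_classes[spec.age_class]
            chronic_illness = None
            if spec.chronic_family is not None:
                family = scn.families[spec.chronic_family]
                s = spec.chronic_seriousness
                _, exp_w, followup = expected_traits(family, s)
                chronic_illness = Illness(
                    family=family, seriousness=s,
                    willingness=age.willingness_factor * exp_w,
                    duration=None, followup_interval=followup,
                )
            patient = Patient(
                id=spec.id, lat=spec.lat, lon=spec.lon, health=spec.health,
                age_class=age, availabilities=spec.availabilities,
                chronic_illness=chronic_illness,
            )
            ranked = sorted(
                pcp_list,
                key=lambda p: (
                    haversine_km(patient.lat, patient.lon, p.lat, p.lon), p.id
                ),
            )[:k]
            patient.considered = tuple(p.id for p in ranked)
            for p in ranked:
                self.distance[(patient.id, p.id)] = haversine_km(
                    patient.lat, patient.lon, p.lat, p.lon
                )
            app, walk = initial_ratings(patient, ranked, scn.behavior)
            patient.appointment_ratings = app
            patient.walkin_ratings = walk
            if patient.chronic:
                patient.family_physician = choose_appointment_targets(patient)[0]
            self.patients[patient.id] = patient
            self.cases[patient.id] = []
            self.onset_rates[patient.id] = age.annual_illness_fn(patient.health)

    def _schedule_buffer_ends(self) -> None:
        for ps in self.practices.values():
            for day in range(int(math.ceil(self.horizon))):
                for half in (0, 1):
                    window = ps.pcp.opening_hours[2 * (day % 7) + half]
                    if window is None:
                        continue
                    t = day + window[1] + ps.buffer_days
                    if t < self.horizon:
                        self._push(t, BUFFER_END, (ps.pcp.id, Session(day, half)))

    def _seed_initial_events(self, scripted) -> None:
        for pid, patient in self.patients.items():
            rate = self.onset_rates[pid]
            if rate > 0 and scripted is None:
                gap = sample_onset_gap(rate, self.rng_onsets)
                if gap < self.horizon:
                    self._push(gap, ONSET, (pid,))
            if patient.chronic:
                nu = patient.chronic_illness.followup_interval
                if nu is None or nu <= 0:
                    continue
                first = (
                    0.5 * nu
                    if self.scenario.engine.deterministic
                    else float(self.rng_choices.uniform(0.0, nu))
                )
                if first < self.horizon:
                    self._push(first, REGULAR_DUE, (pid,))
        if scripted:
            for t, pid, illness in scripted:
                self._push(float(t), ONSET, (pid, illness))

    # ------------------------------------------------------------------
    # Event queue plumbing
    # ------------------------------------------------------------------

    def _push(self, t: float, kind: int, payload: tuple) -> None:
        self._seq += 1
        heapq.heappush(self._heap, (t, _PRIORITY[kind], self._seq, kind, payload))

    def _trace(self, t: float, message: str) -> None:
        if self.trace is not None:
            self.trace(f"{TimePoint.from_scalar(t)} {message}")

    # ------------------------------------------------------------------
    # Main loop
    # ------------------------------------------------------------------

    def run(self) -> KpiRecord:
        handlers = {
            ONSET: self._handle_onset,
            RECOVERY: self._handle_recovery,
            REGULAR_DUE: self._handle_regular_due,
            ARRIVAL: self._handle_arrival,
            COMPLETE: self._handle_complete,
            BUFFER_END: self._handle_buffer_end,
        }
        heap = self._heap
        while heap:
            t, _, _, kind, payload = heapq.heappop(heap)
            if t >= self.horizon:
                break
            assert t >= self.clock - _EPS, "clock must never decrease"
            self.clock = t
            handlers[kind](t, payload)
        return self.kpi.finalize()

    # ------------------------------------------------------------------
    # Illness dynamics
    # ------------------------------------------------------------------

    def _handle_onset(self, t: float, payload: tuple) -> None:
        pid = payload[0]
        patient = self.patients[pid]
        # recurring onset process (absent for scripted onsets)
        if len(payload) == 1:
            rate = self.onset_rates[pid]
            gap = sample_onset_gap(rate, self.rng_onsets)
            if t + gap < self.horizon:
                self._push(t + gap, ONSET, (pid,))
            illness = sample_acute_illness(
                patient.age_class, self.scenario.illness_dist,
                self.scenario.families, self.rng_illness,
                self.scenario.sampling,
            )
        else:
            illness = payload[1]
        case = IllnessCase(illness, t, t + illness.duration)
        self.cases[pid].append(case)
        patient.acute_illnesses.append(case)
        self.kpi.on_onset(t)
        self._trace(t, f"onset patient={pid} family={illness.family.icd_code}")
        if case.end < self.horizon:
            self._push(case.end, RECOVERY, (pid, case))
        self._seek_initial_care(patient, t, illness)

    def _seek_initial_care(self, patient: Patient, t: float, illness) -> None:
        deadline = t + illness.willingness
        appt = patient.acute_appointment
        if appt is not None and not appt.cancelled:
            if t < appt.time <= deadline:
                return  # reuse the held appointment; it treats all illnesses
            self._cancel_appointment(patient, appt)
        intent = self.intents.get(patient.id)
        if intent is not None and not intent.cancelled:
            window = self.practices[intent.pcp_id].pcp.session_window(
                intent.session
            )
            if window is not None and window[0] <= deadline:
                return  # a planned walk-in already covers this illness
            intent.cancelled = True
        if not self._request_appointment(patient, t, deadline, role="acute"):
            self._seek_walkin(patient, t, t, deadline, set())

    def _handle_recovery(self, t: float, payload: tuple) -> None:
        pid, case = payload
        patient = self.patients[pid]
        if case not in patient.acute_illnesses:
            return
        patient.acute_illnesses.remove(case)
        self.cases[pid].remove(case)
        self._trace(t, f"recovery patient={pid}")
        if patient.acute_illnesses:
            return
        p_cancel = patient.age_class.cancel_prob
        appt = patient.acute_appointment
        if appt is not None and not appt.cancelled:
            if self.rng_choices.random() < p_cancel:
                self._cancel_appointment(patient, appt)
                self.kpi.on_cancellation(t)
                self._trace(t, f"cancel patient={pid} pcp={appt.pcp_id}")
        intent = self.intents.get(pid)
        if intent is not None and not intent.cancelled:
            if self.rng_choices.random() < p_cancel:
                intent.cancelled = True
                patient.emergency = False

    def _cancel_appointment(self, patient: Patient, appt: Appointment) -> None:
        appt.cancelled = True
        self.practices[appt.pcp_id].scheduling.release(appt.session, appt.slot)
        if patient.acute_appointment is appt:
            patient.acute_appointment = None
        if patient.regular_appointment is appt:
            patient.regular_appointment = None

    # ------------------------------------------------------------------
    # Booking paths
    # ------------------------------------------------------------------

    def _request_appointment(
        self, patient: Patient, t: float, deadline: float, role: str
    ) -> bool:
        """Up-to-two appointment requests in rating order; True on success."""
        assert patient.acute_appointment is None
        for pcp_id in choose_appointment_targets(patient):
            ps = self.practices[pcp_id]
            offer = ps.scheduling.offer(t, deadline, patient.availabilities)
            if offer is None:
                update_rating(
                    patient, pcp_id, Experience.REQUEST_FAILED,
                    self.scenario.behavior,
                )
                continue
            self._book(patient, ps, offer, role, request=t, target=t)
            return True
        return False

    def _book(
        self,
        patient: Patient,
        ps: PracticeState,
        offer: tuple[float, Session, int],
        role: str,
        request: float,
        target: float,
    ) -> None:
        slot_time, session, slot = offer
        ps.scheduling.book(session, slot)
        appt = Appointment(
            time=slot_time, session=session, slot=slot, pcp_id=ps.pcp.id,
            patient_id=patient.id, role=role,
        )
        if role == "regular":
            patient.regular_appointment = appt
        else:
            patient.acute_appointment = appt
        update_rating(
            patient, ps.pcp.id, Experience.REQUEST_GRANTED, self.scenario.behavior
        )
        access = max(0.0, slot_time - max(request, target))
        self.kpi.on_booking(request, role if role == "regular" else "acute", access)
        self._trace(
            request,
            f"booked patient={patient.id} pcp={ps.pcp.id} role={role} "
            f"slot={TimePoint.from_scalar(slot_time)}",
        )
        arrival = max(self._appointment_arrival_time(ps, appt), request + _EPS)
        if arrival < self.horizon:
            self._push(arrival, ARRIVAL, (ps.pcp.id, patient.id, "appointment", appt))

    def _appointment_arrival_time(self, ps: PracticeState, appt) -> float:
        window = ps.pcp.session_window(appt.session)
        lo, hi = window
        if self.scenario.engine.deterministic:
            return appt.time
        offset = self.rng_arrivals.normal(
            0.0, self.scenario.engine.punctuality_sd_min / MINUTES_PER_DAY
        )
        return min(max(appt.time + offset, lo), hi - _EPS)

    def _walkin_candidates(
        self,
        patient: Patient,
        now: float,
        window_lo: float,
        window_hi: float,
        tried: set,
    ) -> list[tuple[str, Session, float]]:
        """(practice, session, arrival time) triples reachable in the window."""
        cfg = self.scenario.engine
        out = []
        for day in range(int(window_lo), int(window_hi) + 1):
            for half in (0, 1):
                session = Session(day, half)
                k = weekly_class(session).index
                if not patient.availabilities[k]:
                    continue
                for pcp_id in patient.considered:
                    if (pcp_id, session) in tried:
                        continue
                    window = self.practices[pcp_id].pcp.session_window(session)
                    if window is None:
                        continue
                    lo, hi = window
                    if lo > window_hi or hi <= max(now, window_lo):
                        continue
                    if lo >= now:
                        if cfg.deterministic:
                            arrival = (lo + hi) / 2.0
                        else:
                            frac = self.rng_arrivals.beta(
                                cfg.walkin_beta_a, cfg.walkin_beta_b
                            )
                            arrival = lo + frac * (hi - lo)
                    else:  # session already running: arrive after travel
                        arrival = now + cfg.retry_travel_min / MINUTES_PER_DAY
                        if arrival >= hi:
                            continue
                    out.append((pcp_id, session, arrival))
        return out

    #: Walk-in targeting extends day by day past the willingness window (up
    #: to two weekly cycles) before a patient gives up: patients who cannot
    #: get an appointment still seek treatment at the next feasible session.
    WALKIN_EXTENSION_DAYS = 14

    def _seek_walkin(
        self,
        patient: Patient,
        now: float,
        window_lo: float,
        window_hi: float,
        tried: set,
    ) -> bool:
        candidates = self._walkin_candidates(patient, now, window_lo, window_hi, tried)
        extension = 0
        while not candidates and extension < self.WALKIN_EXTENSION_DAYS:
            extension += 1
            candidates = self._walkin_candidates(
                patient, now, window_lo, window_hi + extension, tried
            )
        window_hi += extension
        choice = choose_walkin_target(
            patient, [(pcp_id, session) for pcp_id, session, _ in candidates]
        )
        if choice is None:
            patient.emergency = False
            self.kpi.on_forgo(now)
            self._trace(now, f"forgo patient={patient.id}")
            self.intents.pop(patient.id, None)
            return False
        pcp_id, session = choice
        arrival = next(
            a for p, s, a in candidates if p == pcp_id and s == session
        )
        intent = WalkinIntent(pcp_id, session, deadline=window_hi, tried=tried)
        self.intents[patient.id] = intent
        if arrival < self.horizon:
            self._push(arrival, ARRIVAL, (pcp_id, patient.id, "walkin", intent))
        self._trace(
            now, f"walkin-plan patient={patient.id} pcp={pcp_id} session={session}"
        )
        return True

    # ------------------------------------------------------------------
    # Arrivals, admission, treatment
    # ------------------------------------------------------------------

    def _handle_arrival(self, t: float, payload: tuple) -> None:
        pcp_id, pid, kind, ref = payload
        ps = self.practices[pcp_id]
        patient = self.patients[pid]
        if kind == "appointment":
            if ref.cancelled:
                return
            session, scheduled, role = ref.session, ref.time, ref.role
        else:
            if ref.cancelled or ref is not self.intents.get(pid):
                return
            session, scheduled, role = ref.session, None, None
        window = ps.pcp.session_window(session)
        if kind == "walkin" and (window is None or t >= window[1]):
            # retry pushed past closing: treat like a failed attempt
            self._retry_walkin(patient, ps, session, t, ref, rejected=False)
            return
        queue_len = len(ps.waiting) + (1 if ps.in_service is not None else 0)
        predicted = (
            queue_len + ps.scheduling.booked_after(session, t)
        ) * ps.treatment.mean_service_days(len(ps.waiting))
        admitted = ps.admission.admit(
            kind, patient.emergency, t, window[1], predicted
        )
        self.kpi.on_arrival(t, pcp_id, kind, admitted)
        if not admitted:
            self._trace(t, f"reject pcp={pcp_id} patient={pid}")
            update_rating(
                patient, pcp_id, Experience.REJECTED_AT_DOOR,
                self.scenario.behavior, session=session,
            )
            self._retry_walkin(patient, ps, session, t, ref, rejected=True)
            return
        # admitted
        if kind == "appointment":
            if ref.role == "regular":
                patient.regular_appointment = None
            else:
                patient.acute_appointment = None
            rank = 0
        else:
            self.intents.pop(pid, None)
            rank = 1 if patient.emergency else 2
        patient.emergency = False
        self._seq += 1
        entry = WaitingEntry(
            rank=rank, arrival=t, seq=self._seq, patient_id=pid, kind=kind,
            scheduled=scheduled, session=session, role=role,
        )
        ps.waiting.append(entry)
        self._trace(t, f"admit pcp={pcp_id} patient={pid} kind={kind}")
        if ps.in_service is None:
            self._start_service(ps, t)

    def _retry_walkin(
        self, patient, ps, session, t, intent, rejected: bool
    ) -> None:
        if rejected:
            patient.emergency = True
        tried = set(intent.tried)
        tried.add((ps.pcp.id, session))
        self.intents.pop(patient.id, None)
        self._seek_walkin(patient, t, t, intent.deadline, tried)

    def _start_service(self, ps: PracticeState, t: float) -> None:
        queue_len = len(ps.waiting)
        entry = ps.treatment.next_patient(ps.waiting)
        service = ps.treatment.service_time(queue_len, self.rng_service)
        ps.in_service = entry
        ps.service_start = t
        ps.service_end = t + service
        self._push(ps.service_end, COMPLETE, (ps.pcp.id, entry, t, service))
        # waiting-time experience and measurement
        patient = self.patients[entry.patient_id]
        if entry.kind == "appointment":
            wait_days = max(0.0, t - max(entry.arrival, entry.scheduled))
        else:
            wait_days = t - entry.arrival
        wait_min = wait_days * MINUTES_PER_DAY
        threshold = self.scenario.behavior.long_wait_threshold_min
        experience = (
            Experience.LONG_WAIT if wait_min > threshold else Experience.SHORT_WAIT
        )
        update_rating(
            patient, ps.pcp.id, experience, self.scenario.behavior,
            session=entry.session if entry.kind == "walkin" else None,
        )

    def _handle_complete(self, t: float, payload: tuple) -> None:
        pcp_id, entry, start, service = payload
        ps = self.practices[pcp_id]
        if ps.in_service is not entry:  # stale event (should not happen)
            return
        ps.in_service = None
        patient = self.patients[entry.patient_id]
        window = ps.pcp.session_window(entry.session)
        lo, hi = window
        buffer_end = hi + ps.buffer_days
        in_session = max(0.0, min(t, hi) - max(start, lo))
        key = (entry.session.day, entry.session.half)
        ps.session_busy[key] = ps.session_busy.get(key, 0.0) + in_session
        overtime = max(0.0, t - max(start, buffer_end))
        if entry.kind == "appointment":
            wait_min = max(0.0, start - max(entry.arrival, entry.scheduled)) \
                * MINUTES_PER_DAY
            on_time = (start - entry.scheduled) * MINUTES_PER_DAY <= 5.0
        else:
            wait_min = (start - entry.arrival) * MINUTES_PER_DAY
            on_time = None
        self.kpi.on_treatment(
            start=start, pcp_id=pcp_id, kind=entry.kind, role=entry.role,
            wait_min=wait_min, on_time=on_time,
            service_days=service, overtime_days=overtime,
            distance_km=self.distance[(entry.patient_id, pcp_id)],
        )
        self._trace(t, f"treated pcp={pcp_id} patient={entry.patient_id}")

        # follow-up care for persisting acute illnesses
        self._arrange_followup(patient, ps, t)
        # chronic patients rebook their regular appointment after a regular visit
        if entry.kind == "appointment" and entry.role == "regular" \
                and patient.chronic:
            reevaluate_family_physician(patient, self.scenario.behavior)
            nu = patient.chronic_illness.followup_interval
            if nu is not None and nu > 0:
                self._book_regular(patient, t, t + nu)
        if ps.waiting:
            self._start_service(ps, t)

    def _arrange_followup(self, patient: Patient, ps: PracticeState, t: float) -> None:
        if patient.acute_appointment is not None:
            return
        intent = self.intents.get(patient.id)
        if intent is not None and not intent.cancelled:
            return
        cfg = self.scenario.engine
        for case in sorted(patient.acute_illnesses, key=lambda c: c.onset):
            nu = case.illness.followup_interval
            if nu is None or nu <= 0:
                continue
            if case.end - t <= nu:
                continue  # illness will subside before follow-up falls due
            target = t + nu
            tol = nu * cfg.followup_tolerance_frac
            offer = ps.scheduling.offer(
                max(t, target - tol), target + tol, patient.availabilities
            )
            if offer is not None:
                self._book(patient, ps, offer, "acute", request=t, target=target)
            else:
                update_rating(
                    patient, ps.pcp.id, Experience.REQUEST_FAILED,
                    self.scenario.behavior,
                )
                self._seek_walkin(
                    patient, t, max(t, target - tol), target + tol, set()
                )
            return

    # ------------------------------------------------------------------
    # Chronic (regular) care
    # ------------------------------------------------------------------

    def _handle_regular_due(self, t: float, payload: tuple) -> None:
        pid = payload[0]
        patient = self.patients[pid]
        if patient.regular_appointment is not None:
            return
        self._book_regular(patient, t, t)

    def _book_regular(self, patient: Patient, now: float, target: float) -> None:
        if patient.regular_appointment is not None:
            return
        fam_id = patient.family_physician
        ps = self.practices.get(fam_id)
        if ps is None:  # roster changed between runs; re-anchor
            patient.family_physician = choose_appointment_targets(patient)[0]
            ps = self.practices[patient.family_physician]
        nu = patient.chronic_illness.followup_interval
        tol = nu * self.scenario.engine.followup_tolerance_frac
        offer = ps.scheduling.offer(
            max(now, target - tol), target + tol, patient.availabilities
        )
        if offer is None:  # widen: chronic care must continue
            offer = ps.scheduling.offer(
                max(now, target), target + nu, patient.availabilities
            )
        if offer is None:
            update_rating(
                patient, ps.pcp.id, Experience.REQUEST_FAILED,
                self.scenario.behavior,
            )
            retry = max(now, target) + 0.5 * nu
            if retry < self.horizon:
                self._push(retry, REGULAR_DUE, (patient.id,))
            return
        self._book(patient, ps, offer, "regular", request=now, target=target)

    # ------------------------------------------------------------------
    # Session bookkeeping
    # ------------------------------------------------------------------

    def _handle_buffer_end(self, t: float, payload: tuple) -> None:
        pcp_id, session = payload
        ps = self.practices[pcp_id]
        window = ps.pcp.session_window(session)
        lo, hi = window
        remaining = 0.0
        if ps.in_service is not None:
            remaining += max(0.0, ps.service_end - t)
        remaining += len(ps.waiting) * ps.treatment.mean_service_days(
            len(ps.waiting)
        )
        busy = ps.session_busy.pop((session.day, session.half), 0.0)
        idle_min = max(0.0, (hi - lo) - busy) * MINUTES_PER_DAY
        ps.admission.end_of_buffer_learning(
            overtime_min=remaining * MINUTES_PER_DAY,
            idle_min=idle_min if remaining <= _EPS else 0.0,
        )


def run(
    scenario: Scenario,
    horizon: float,
    warmup: float = 0.0,
    seed: int = 0,
    trace: Optional[Callable[[str], None]] = None,
    scripted_onsets: Optional[Sequence[tuple[float, int, Illness]]] = None,
) -> KpiRecord:
    """Execute one run and return its KPI record.

    ``horizon`` and ``warmup`` are in days; indicators accumulate only after
    the warm-up.  Output is bit-identical for identical
    (scenario, horizon, warmup, seed).
    """
    sim = Simulation(
        scenario, horizon, warmup, seed, trace=trace,
        scripted_onsets=scripted_onsets,
    )
    return sim.run()


def run_yearly(
    scenario: Scenario, years: int, seed: int = 0
):
    """Run for ``years`` simulated years collecting per-year KPI series
    (for warm-up truncation analysis).  Returns (KpiRecord, DataFrame)."""
    sim = Simulation(scenario, horizon=365.0 * years, warmup=0.0, seed=seed,
                     yearly=True)
    record = sim.run()
    return record, sim.kpi.yearly_series()


def run_experiment(
    scenario: Scenario,
    horizon: float,
    warmup: float,
    runs: int = 20,
    seed: int = 0,
) -> list[KpiRecord]:
    """Independent stochastic repetitions (seeds ``seed .. seed+runs-1``)."""
    return [
        run(scenario, horizon=horizon, warmup=warmup, seed=seed + r)
        for r in range(runs)
    ]
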