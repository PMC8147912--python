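"""Ratings, preference updates, and care-seeking choices of patient agents."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcsim import (
    PCP,
    BehaviorConfig,
    Experience,
    LinearFn,
    Patient,
    choose_appointment_targets,
    choose_walkin_target,
    haversine_km,
    initial_ratings,
    reevaluate_family_physician,
    update_rating,
)
from pcsim.agents import _availability_overlap
from pcsim.illness import AgeClass, Illness, IllnessFamily
from pcsim.timebase import Session, weekly_class

from conftest import full_week, weekday_mornings


def make_patient(avail=(True,) * 14, lat=50.0, lon=6.0) -> Patient:
    age = AgeClass("adult", LinearFn(0, 1))
    return Patient(
        id=0, lat=lat, lon=lon, health=0.5, age_class=age, availabilities=avail
    )


def make_pcp(pcp_id="a", lat=50.0, lon=6.0, opening=None) -> PCP:
    return PCP(
        id=pcp_id, lat=lat, lon=lon,
        opening_hours=opening or weekday_mornings(),
    )


def test_haversine_one_degree_latitude():
    assert haversine_km(50.0, 6.0, 51.0, 6.0) == pytest.approx(111.2, rel=0.01)


class TestInitialRatings:
    def test_more_overlap_beats_equal_distance(self):
        patient = make_patient()
        open_more = make_pcp("a", opening=full_week())
        open_less = make_pcp("b", opening=weekday_mornings())
        app, _ = initial_ratings(patient, [open_more, open_less])
        assert app["a"] > app["b"]

    def test_closed_sessions_have_zero_walkin_rating(self):
        # patient only available on weekends, practice only open weekdays
        avail = tuple(k >= 10 for k in range(14))
        patient = make_patient(avail=avail)
        pcp = make_pcp(opening=weekday_mornings())
        _, walk = initial_ratings(patient, [pcp])
        assert np.all(walk["a"] == 0.0)

    def test_identical_practices_rate_identically(self):
        patient = make_patient()
        a, b = make_pcp("a"), make_pcp("b")
        app, walk = initial_ratings(patient, [a, b])
        assert app["a"] == app["b"]
        assert np.array_equal(walk["a"], walk["b"])

    def test_nearer_practice_rates_higher(self):
        patient = make_patient()
        near = make_pcp("near", lat=50.01)
        far = make_pcp("far", lat=50.30)
        app, _ = initial_ratings(patient, [near, far])
        assert app["near"] > app["far"]

    def test_empty_consideration_set_rejected(self):
        with pytest.raises(ValueError):
            initial_ratings(make_patient(), [])

    def test_overlap_counts_open_available_sessions(self):
        patient = make_patient(avail=tuple(k < 4 for k in range(14)))
        # open in 2 of the patient's 4 available classes
        assert _availability_overlap(patient, make_pcp(opening=weekday_mornings())) \
            == pytest.approx(0.5)


class TestRatingUpdates:
    def _rated_patient(self, value=1.0):
        patient = make_patient()
        pcp = make_pcp()
        patient.appointment_ratings, patient.walkin_ratings = initial_ratings(
            patient, [pcp]
        )
        patient.appointment_ratings["a"] = value
        return patient

    def test_failed_request_scales_down(self):
        patient = self._rated_patient(1.0)
        update_rating(patient, "a", Experience.REQUEST_FAILED)
        assert patient.appointment_ratings["a"] == pytest.approx(0.8)

    def test_zero_rating_absorbs_negative_experiences(self):
        patient = self._rated_patient(0.0)
        update_rating(patient, "a", Experience.REJECTED_AT_DOOR)
        update_rating(patient, "a", Experience.REQUEST_FAILED)
        assert patient.appointment_ratings["a"] == 0.0

    def test_reciprocal_factors_round_trip(self):
        cfg = BehaviorConfig(
            factor_request_granted=1.25, factor_request_failed=0.8
        )
        patient = self._rated_patient(1.0)
        update_rating(patient, "a", Experience.REQUEST_GRANTED, cfg)
        update_rating(patient, "a", Experience.REQUEST_FAILED, cfg)
        assert patient.appointment_ratings["a"] == pytest.approx(1.0, abs=1e-12)

    def test_walkin_experience_touches_only_that_session(self):
        patient = self._rated_patient()
        before = patient.walkin_ratings["a"].copy()
        session = Session(0, 0)
        update_rating(
            patient, "a", Experience.LONG_WAIT, session=session
        )
        k = weekly_class(session).index
        assert patient.walkin_ratings["a"][k] < before[k]
        others = [i for i in range(14) if i != k]
        assert np.array_equal(patient.walkin_ratings["a"][others], before[others])

    def test_unknown_practice_rejected(self):
        with pytest.raises(ValueError):
            update_rating(self._rated_patient(), "zz", Experience.SHORT_WAIT)

    @given(st.lists(st.sampled_from(list(Experience)), max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_ratings_stay_in_bounds(self, experiences):
        cfg = BehaviorConfig()
        patient = self._rated_patient(1.0)
        for exp in experiences:
            update_rating(patient, "a", exp, cfg)
            assert 0.0 <= patient.appointment_ratings["a"] <= cfg.rating_cap


class TestAppointmentTargets:
    def _with_ratings(self, ratings):
        patient = make_patient()
        patient.appointment_ratings = dict(ratings)
        return patient

    def test_two_highest_in_descending_order(self):
        patient = self._with_ratings({"a": 3.0, "b": 2.0, "c": 1.0})
        assert choose_appointment_targets(patient) == ["a", "b"]

    def test_single_practice(self):
        patient = self._with_ratings({"only": 1.0})
        assert choose_appointment_targets(patient) == ["only"]

    def test_ties_break_lexicographically(self):
        patient = self._with_ratings({"b": 2.0, "a": 2.0, "c": 1.0})
        assert choose_appointment_targets(patient) == ["a", "b"]


class TestWalkinTarget:
    def _patient_with_walk_ratings(self, table):
        patient = make_patient()
        patient.walkin_ratings = {
            pcp_id: np.array(row, dtype=float) for pcp_id, row in table.items()
        }
        return patient

    def test_single_candidate_returned(self):
        patient = self._patient_with_walk_ratings({"a": [1.0] * 14})
        choice = choose_walkin_target(patient, [("a", Session(0, 0))])
        assert choice == ("a", Session(0, 0))

    def test_equal_ratings_prefer_earlier_session(self):
        patient = self._patient_with_walk_ratings({"a": [1.0] * 14})
        choice = choose_walkin_target(
            patient, [("a", Session(3, 0)), ("a", Session(1, 0))]
        )
        assert choice == ("a", Session(1, 0))

    def test_no_candidates_returns_none(self):
        patient = self._patient_with_walk_ratings({"a": [1.0] * 14})
        assert choose_walkin_target(patient, []) is None

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_matches_exhaustive_maximum(self, data):
        rng_rows = data.draw(
            st.dictionaries(
                st.sampled_from(["a", "b", "c"]),
                st.lists(
                    st.floats(0, 5, allow_nan=False), min_size=14, max_size=14
                ),
                min_size=1,
            )
        )
        patient = self._patient_with_walk_ratings(rng_rows)
        candidates = [
            (pcp_id, Session(day, half))
            for pcp_id in rng_rows
            for day in range(4)
            for half in (0, 1)
        ]
        choice = choose_walkin_target(patient, candidates)

        def rating(c):
            return patient.walkin_ratings[c[0]][weekly_class(c[1]).index]

        best = max(rating(c) for c in candidates)
        assert rating(choice) == best
        earliest = min(c[1] for c in candidates if rating(c) == best)
        assert choice[1] == earliest


class TestFamilyPhysician:
    def _chronic_patient(self, ratings, incumbent):
        patient = make_patient()
        family = IllnessFamily(
            "hbp", "I10", willingness_fn=LinearFn(0, 10),
            followup_fn=LinearFn(0, 90), chronic=True,
        )
        patient.chronic_illness = Illness(
            family=family, seriousness=0.3, willingness=10.0,
            followup_interval=90.0,
        )
        patient.appointment_ratings = dict(ratings)
        patient.family_physician = incumbent
        return patient

    def test_small_advantage_does_not_displace_incumbent(self):
        patient = self._chronic_patient({"inc": 1.0, "new": 1.1}, "inc")
        assert reevaluate_family_physician(patient) == "inc"

    def test_large_advantage_switches(self):
        patient = self._chronic_patient({"inc": 1.0, "new": 1.3}, "inc")
        assert reevaluate_family_physician(patient) == "new"

    def test_top_rated_incumbent_unchanged(self):
        patient = self._chronic_patient({"inc": 2.0, "new": 1.0}, "inc")
        assert reevaluate_family_physician(patient) == "inc"

    def test_non_chronic_patient_rejected(self):
        patient = make_patient()
        patient.appointment_ratings = {"a": 1.0}
        with pytest.raises(ValueError):
            reevaluate_family_physician(patient)
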