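"""Scenario schema round-trips, validation, synthetic generation, transformers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcsim import (
    SamplingConfig,
    apply_aging,
    apply_pcp_decline,
    read_scenario,
    scenario_from_dict,
    scenario_to_dict,
    validate,
    write_scenario,
)
from pcsim.synthetic import (
    AGING_MEDIUM_TERM,
    DEFAULT_AGE_DISTRIBUTION,
    MUNICIPALITIES,
    PopulationCell,
    case_study_scenario,
    default_age_classes,
    default_families,
    default_illness_distribution,
    exclude_minors,
    generate_patients,
    make_population_cells,
)

from conftest import small_stochastic_scenario


class TestExcludeMinors:
    def _cells(self, counts, municipality="m"):
        return [
            PopulationCell(50.0 + i * 1e-3, 6.0, c, municipality)
            for i, c in enumerate(counts)
        ]

    def test_case_study_counts(self):
        """The full-size population (35542 residents over 2754 cells, minus
        municipality child counts 1390/2383/1794) leaves 29975 adults."""
        rng = np.random.default_rng(0)
        cells = make_population_cells(MUNICIPALITIES, rng)
        assert len(cells) == 2754
        assert sum(c.count for c in cells) == 35542
        adults = exclude_minors(
            cells, {m: info["children"] for m, info in MUNICIPALITIES.items()},
            rng,
        )
        assert sum(c.count for c in adults) == 29975
        assert all(c.count >= 1 for c in adults)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_total_conserved_for_any_seed(self, seed):
        rng = np.random.default_rng(seed)
        cells = self._cells([5, 3, 9, 1, 7])
        adults = exclude_minors(cells, {"m": 8}, rng)
        assert sum(c.count for c in adults) == 25 - 8
        assert all(c.count >= 1 for c in adults)

    def test_zero_children_leave_population_unchanged(self):
        cells = self._cells([4, 2, 6])
        adults = exclude_minors(cells, {"m": 0}, np.random.default_rng(1))
        assert [c.count for c in adults] == [4, 2, 6]

    def test_infeasible_child_count_rejected(self):
        cells = self._cells([1, 1, 1])  # only fixed adults, nobody removable
        with pytest.raises(ValueError):
            exclude_minors(cells, {"m": 1}, np.random.default_rng(2))


@pytest.fixture(scope="module")
def population():
    rng = np.random.default_rng(123)
    n = 100_000
    cells = [PopulationCell(50.0, 6.0, n, "m")]
    return generate_patients(
        cells,
        default_age_classes(),
        DEFAULT_AGE_DISTRIBUTION,
        default_illness_distribution(),
        default_families(),
        SamplingConfig(),
        rng,
    )


class TestGeneratePatients:

    def test_health_condition_mean(self, population):
        """beta(25, 25) health conditions center on 0.5."""
        health = np.array([p.health for p in population])
        se = health.std(ddof=1) / math.sqrt(len(health))
        assert abs(health.mean() - 0.5) < 3 * se

    def test_age_class_mix(self, population):
        n = len(population)
        for name, p in DEFAULT_AGE_DISTRIBUTION.items():
            frac = sum(1 for q in population if q.age_class == name) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(frac - p) < 4 * se

    def test_elderly_chronic_fraction(self, population):
        elderly = [p for p in population if p.age_class == ">65"]
        frac = sum(1 for p in elderly if p.chronic_family) / len(elderly)
        se = math.sqrt(0.52 * 0.48 / len(elderly))
        assert abs(frac - 0.52) < 4 * se

    def test_locations_stay_inside_the_hectare(self, population):
        lats = np.array([p.lat for p in population[:1000]])
        assert np.all(np.abs(lats - 50.0) <= 50.0 / 111_320.0 + 1e-12)

    def test_chronic_patients_carry_a_seriousness(self, population):
        for p in population[:2000]:
            assert (p.chronic_family is None) == (p.chronic_seriousness is None)


class TestRoundTripAndValidation:
    def test_json_round_trip_is_structural_identity(self, tmp_path):
        scn = small_stochastic_scenario(n_patients=20, n_pcps=2, seed=1)
        path = tmp_path / "scenario.json"
        write_scenario(scn, path)
        again = read_scenario(path)
        assert scenario_to_dict(again) == scenario_to_dict(scn)
        assert validate(again) == []

    def test_generator_output_validates(self):
        scn = case_study_scenario(seed=2, scale=0.01)
        assert validate(scn) == []

    def test_generator_is_deterministic_in_the_seed(self):
        a = case_study_scenario(seed=5, scale=0.01)
        b = case_study_scenario(seed=5, scale=0.01)
        assert scenario_to_dict(a) == scenario_to_dict(b)

    def test_bad_probability_row_is_reported_with_age_class(self):
        scn = small_stochastic_scenario(n_patients=5, n_pcps=1, seed=0)
        data = scenario_to_dict(scn)
        data["acute_distribution"]["16-24"]["cold"] -= 0.1
        violations = validate(scenario_from_dict(data))
        assert any("16-24" in v for v in violations)

    def test_inverted_opening_window_is_reported(self):
        scn = small_stochastic_scenario(n_patients=5, n_pcps=1, seed=0)
        data = scenario_to_dict(scn)
        data["pcps"][0]["opening_hours"]["Mon-AM"] = [0.5, 0.4]
        violations = validate(scenario_from_dict(data))
        assert any("opening window" in v for v in violations)

    def test_all_violations_reported_not_just_first(self):
        scn = small_stochastic_scenario(n_patients=5, n_pcps=1, seed=0)
        data = scenario_to_dict(scn)
        data["pcps"][0]["opening_hours"]["Mon-AM"] = [0.5, 0.4]
        data["patients"][0]["health"] = 1.5
        assert len(validate(scenario_from_dict(data))) >= 2


@pytest.fixture(scope="module")
def base():
    return case_study_scenario(seed=3, scale=0.02, n_pcps=3)


class TestTransformers:

    def test_pcp_decline_keeps_patients(self, base):
        keep = [p.id for p in base.pcps[:-1]]
        reduced = apply_pcp_decline(base, keep)
        assert len(reduced.pcps) == len(base.pcps) - 1
        assert reduced.patients == base.patients

    def test_full_roster_is_identity(self, base):
        same = apply_pcp_decline(base, [p.id for p in base.pcps])
        assert same.pcps == base.pcps

    def test_empty_roster_rejected(self, base):
        with pytest.raises(ValueError):
            apply_pcp_decline(base, [])

    def test_unknown_physician_rejected(self, base):
        with pytest.raises(ValueError):
            apply_pcp_decline(base, ["nobody"])

    def test_aging_shifts_elderly_share(self):
        scn = case_study_scenario(seed=4, scale=0.2)
        aged = apply_aging(scn, AGING_MEDIUM_TERM, np.random.default_rng(0))
        n = len(aged.patients)
        share = sum(1 for p in aged.patients if p.age_class == ">65") / n
        p = AGING_MEDIUM_TERM[">65"]
        assert abs(share - p) < 4 * math.sqrt(p * (1 - p) / n)
        # locations and health preserved patient by patient
        for old, new in zip(scn.patients[:200], aged.patients[:200]):
            assert (old.lat, old.lon, old.health) == (new.lat, new.lon, new.health)

    def test_transformers_compose(self, base):
        keep = [p.id for p in base.pcps[:-1]]
        combined = apply_aging(
            apply_pcp_decline(base, keep),
            AGING_MEDIUM_TERM,
            np.random.default_rng(1),
        )
        assert len(combined.pcps) == len(base.pcps) - 1
        assert combined.age_class_distribution == AGING_MEDIUM_TERM
        assert validate(combined) == []

    def test_invalid_distribution_rejected(self, base):
        with pytest.raises(ValueError):
            apply_aging(base, {"16-24": 0.5, "25-65": 0.4},
                        np.random.default_rng(0))
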