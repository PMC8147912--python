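"""Illness families, trait evaluation, and the stochastic illness machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from pcsim import (
    AgeClass,
    AgeClassIllnessDistribution,
    ConfigurationError,
    IllnessFamily,
    LinearFn,
    SamplingConfig,
    annual_rate,
    expected_traits,
    sample_acute_illness,
    sample_chronic_illness,
)
from pcsim.illness import (
    sample_lognormal_mean,
    sample_onset_gap,
    sample_seriousness,
    sample_weibull_mean,
)
from pcsim.synthetic import (
    default_age_classes,
    default_families,
    default_illness_distribution,
)


class TestExpectedTraits:
    def test_worked_cold_example(self, cold_family):
        """A mild cold (s=0.2) has expected duration 5 d, willingness 2.4 d,
        and deterministic follow-up interval 6.6 d."""
        d, w, n = expected_traits(cold_family, 0.2)
        assert d == pytest.approx(5.0)
        assert w == pytest.approx(2.4)
        assert n == pytest.approx(6.6)

    def test_back_pain_willingness_at_extreme_seriousness(self):
        fam = default_families()["back pain"]  # W = -3s + 4
        _, w, _ = expected_traits(fam, 1.0)
        assert w == pytest.approx(1.0)

    def test_chronic_family_has_no_duration(self):
        fam = default_families()["high blood pressure"]
        d, _, _ = expected_traits(fam, 0.3)
        assert d is None

    def test_diabetes_followup_at_zero_seriousness(self):
        fam = default_families()["diabetes"]  # N = -10s + 90
        _, _, n = expected_traits(fam, 0.0)
        assert n == pytest.approx(90.0)

    def test_seriousness_outside_domain_rejected(self, cold_family):
        with pytest.raises(ValueError):
            expected_traits(cold_family, 1.2)

    def test_negative_evaluations_clamp_to_zero(self):
        assert LinearFn(-10, 1)(0.5) == 0.0


class TestAnnualRate:
    def test_healthy_young_patient(self):
        young = default_age_classes()["16-24"]  # I = 6c
        assert annual_rate(young, 0.0) == 0.0

    def test_elderly_midrange(self):
        elderly = default_age_classes()[">65"]  # I = 9c + 1
        assert annual_rate(elderly, 0.5) == pytest.approx(5.5)

    def test_onset_process_mean_matches_rate(self):
        """Exponential inter-onset gaps at rate 5.5/yr give 5.5 onsets per
        simulated patient-year on average (Poisson-process oracle)."""
        rng = np.random.default_rng(7)
        rate, reps = 5.5, 10_000
        counts = []
        for _ in range(reps):
            t, n = 0.0, 0
            while True:
                t += sample_onset_gap(rate, rng)
                if t >= 365.0:
                    break
                n += 1
            counts.append(n)
        se = np.std(counts, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(counts) - rate) < 3 * se

    def test_zero_rate_never_fires(self):
        assert sample_onset_gap(0.0, np.random.default_rng(0)) == math.inf


@pytest.fixture
def acute_setup(cold_family, adult_class):
    dist = AgeClassIllnessDistribution(acute={"adult": {cold_family.name: 1.0}})
    families = {cold_family.name: cold_family}
    return adult_class, dist, families


class TestAcuteSampling:
    def test_mean_duration_tracks_adjusted_trait(self, cold_family):
        """Monte-Carlo: sampled durations average to the age-adjusted
        expected trait (within 3 standard errors)."""
        age = AgeClass(
            "old", LinearFn(0, 1), duration_factor=1.2, willingness_factor=0.8
        )
        dist = AgeClassIllnessDistribution(acute={"old": {cold_family.name: 1.0}})
        fams = {cold_family.name: cold_family}
        rng = np.random.default_rng(3)
        cfg = SamplingConfig()
        samples = [
            sample_acute_illness(age, dist, fams, rng, cfg) for _ in range(20_000)
        ]
        # E[D_f(s)] under s ~ triangular(0, 0.3, 1): E[s] = 13/30
        exp_d = 1.2 * (10 * (0.0 + 0.3 + 1.0) / 3 + 3)
        exp_w = 0.8 * (-3 * (0.0 + 0.3 + 1.0) / 3 + 3)
        d = np.array([s.duration for s in samples])
        w = np.array([s.willingness for s in samples])
        assert abs(d.mean() - exp_d) < 3 * d.std(ddof=1) / math.sqrt(len(d))
        assert abs(w.mean() - exp_w) < 3 * w.std(ddof=1) / math.sqrt(len(w))

    def test_followup_is_deterministic_in_seriousness(self, acute_setup):
        age, dist, families = acute_setup
        rng = np.random.default_rng(5)
        for _ in range(200):
            illness = sample_acute_illness(age, dist, families, rng)
            assert illness.followup_interval == pytest.approx(
                -2 * illness.seriousness + 7
            )

    def test_samples_are_non_negative(self, acute_setup):
        age, dist, families = acute_setup
        rng = np.random.default_rng(11)
        for _ in range(500):
            illness = sample_acute_illness(age, dist, families, rng)
            assert illness.duration >= 0
            assert illness.willingness >= 0
            assert 0 <= illness.seriousness <= 1

    def test_acute_family_without_duration_rejected(self, adult_class):
        fam = IllnessFamily(
            "odd", "X99", willingness_fn=LinearFn(0, 1), duration_fn=None
        )
        dist = AgeClassIllnessDistribution(acute={"adult": {"odd": 1.0}})
        with pytest.raises(ConfigurationError):
            sample_acute_illness(
                adult_class, dist, {"odd": fam}, np.random.default_rng(0)
            )


class TestChronicSampling:
    def test_family_frequencies_match_young_column(self):
        """Chronic draws for the youngest class follow the configured
        (0.17, 0.33, 0.50) split."""
        age = default_age_classes()["16-24"]
        dist = default_illness_distribution()
        fams = default_families()
        rng = np.random.default_rng(9)
        n = 20_000
        draws = [
            sample_chronic_illness(age, dist, fams, rng).family.icd_code
            for _ in range(n)
        ]
        counts = {code: draws.count(code) / n for code in ("I10", "E11", "I25")}
        for code, p in (("I10", 0.17), ("E11", 0.33), ("I25", 0.5)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[code] - p) < 4 * se

    def test_chronic_draw_is_chronic_and_durationless(self, adult_class):
        dist = default_illness_distribution()
        rng = np.random.default_rng(2)
        age = default_age_classes()["25-65"]
        illness = sample_chronic_illness(age, dist, default_families(), rng)
        assert illness.family.chronic
        assert illness.duration is None

    def test_missing_chronic_table_rejected(self, acute_setup):
        age, dist, families = acute_setup
        with pytest.raises(ConfigurationError):
            sample_chronic_illness(age, dist, families, np.random.default_rng(0))


class TestDistributionConformance:
    """The configured parametric forms are actually what gets sampled."""

    N = 100_000
    ALPHA = 0.01

    def test_lognormal_duration_form(self):
        rng = np.random.default_rng(21)
        mean, cv = 5.0, 0.25
        x = np.array(
            [sample_lognormal_mean(mean, cv, rng) for _ in range(self.N)]
        )
        sigma2 = math.log1p(cv**2)
        mu = math.log(mean) - sigma2 / 2
        p = stats.kstest(x, "lognorm", args=(math.sqrt(sigma2), 0, math.exp(mu))).pvalue
        assert p > self.ALPHA

    def test_weibull_willingness_form(self):
        rng = np.random.default_rng(22)
        mean, k = 2.4, 2.0
        x = np.array([sample_weibull_mean(mean, k, rng) for _ in range(self.N)])
        scale = mean / math.gamma(1 + 1 / k)
        p = stats.kstest(x, "weibull_min", args=(k, 0, scale)).pvalue
        assert p > self.ALPHA

    def test_triangular_seriousness_form(self):
        rng = np.random.default_rng(23)
        cfg = SamplingConfig(seriousness_mode=0.3)
        x = np.array([sample_seriousness(cfg, rng) for _ in range(self.N)])
        p = stats.kstest(x, "triang", args=(0.3, 0, 1)).pvalue
        assert p > self.ALPHA

    def test_exponential_onset_gap_form(self):
        rng = np.random.default_rng(24)
        rate = 4.5
        x = np.array([sample_onset_gap(rate, rng) for _ in range(self.N)])
        p = stats.kstest(x, "expon", args=(0, 365.0 / rate)).pvalue
        assert p > self.ALPHA


def test_distribution_rows_must_sum_to_one():
    with pytest.raises(ConfigurationError):
        AgeClassIllnessDistribution(acute={"adult": {"a": 0.5, "b": 0.4}})


def test_acute_row_from_default_tables_sums_to_one():
    dist = default_illness_distribution()
    assert sum(dist.acute["16-24"].values()) == pytest.approx(1.0, abs=1e-9)
    for row in list(dist.acute.values()) + list(dist.chronic.values()):
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
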