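"""Shared fixtures: worked-example illness family, default tables, and
hand-buildable miniature scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from pcsim import (
    PCP,
    AgeClass,
    AgeClassIllnessDistribution,
    IllnessFamily,
    LinearFn,
    PatientSpec,
    SamplingConfig,
    Scenario,
)
from pcsim.scenario import EngineConfig
from pcsim.strategies import StrategyConfig


@pytest.fixture
def cold_family() -> IllnessFamily:
    """The illustrative 'common cold' family: D=10s+3, W=-3s+3, N=-2s+7."""
    return IllnessFamily(
        name="common cold",
        icd_code="X00",
        willingness_fn=LinearFn(-3, 3),
        duration_fn=LinearFn(10, 3),
        followup_fn=LinearFn(-2, 7),
    )


@pytest.fixture
def adult_class() -> AgeClass:
    return AgeClass("adult", LinearFn(7, 1), availability_prob=1.0)


def weekday_mornings() -> tuple:
    """Opening hours: Monday-Friday 8:00-12:00, afternoons/weekends closed."""
    opening = [None] * 14
    for wd in range(5):
        opening[2 * wd] = (8 / 24, 12 / 24)
    return tuple(opening)


def full_week() -> tuple:
    """Open every session 8:00-12:00 / 14:00-18:00 (stress configurations)."""
    opening = []
    for _ in range(7):
        opening += [(8 / 24, 12 / 24), (14 / 24, 18 / 24)]
    return tuple(opening)


@pytest.fixture
def single_practice_scenario(cold_family, adult_class) -> Scenario:
    """One fully deterministic patient/practice pair (for engine oracles)."""
    quiet = AgeClass("adult", LinearFn(0, 0))  # no spontaneous onsets
    return Scenario(
        families={cold_family.name: cold_family},
        age_classes={"adult": quiet},
        age_class_distribution={"adult": 1.0},
        illness_dist=AgeClassIllnessDistribution(
            acute={"adult": {cold_family.name: 1.0}}
        ),
        pcps=[
            PCP(id="pcp-0", lat=50.0, lon=6.0, opening_hours=weekday_mornings())
        ],
        patients=[
            PatientSpec(
                id=0, lat=50.0, lon=6.0, health=0.5, age_class="adult",
                availabilities=(True,) * 14,
            )
        ],
        sampling=SamplingConfig(deterministic=True),
        strategy=StrategyConfig(deterministic=True),
        engine=EngineConfig(deterministic=True),
    )


def small_stochastic_scenario(
    n_patients: int = 40, n_pcps: int = 2, seed: int = 0
) -> Scenario:
    """A small random scenario with the full default tables (fast runs)."""
    from pcsim import synthetic

    rng = np.random.default_rng(seed)
    families = synthetic.default_families()
    age_classes = synthetic.default_age_classes()
    dist = synthetic.default_illness_distribution()
    age_names = sorted(synthetic.DEFAULT_AGE_DISTRIBUTION)
    probs = np.array([synthetic.DEFAULT_AGE_DISTRIBUTION[a] for a in age_names])
    patients = []
    for pid in range(n_patients):
        age = age_names[int(rng.choice(len(age_names), p=probs))]
        avail, cf, cs = synthetic.draw_age_dependent_attributes(
            age_classes[age], dist, families, SamplingConfig(), rng
        )
        patients.append(
            PatientSpec(
                id=pid,
                lat=50.0 + rng.uniform(-0.05, 0.05),
                lon=6.0 + rng.uniform(-0.05, 0.05),
                health=float(rng.beta(25, 25)),
                age_class=age,
                availabilities=avail,
                chronic_family=cf,
                chronic_seriousness=cs,
            )
        )
    pcps = [
        PCP(
            id=f"pcp-{j}",
            lat=50.0 + rng.uniform(-0.05, 0.05),
            lon=6.0 + rng.uniform(-0.05, 0.05),
            opening_hours=synthetic.default_opening_hours(),
        )
        for j in range(n_pcps)
    ]
    return Scenario(
        families=families,
        age_classes=age_classes,
        age_class_distribution=dict(synthetic.DEFAULT_AGE_DISTRIBUTION),
        illness_dist=dist,
        pcps=pcps,
        patients=patients,
    )


@pytest.fixture(scope="session")
def desk_preset():
    """Scaled-down case-study scenario shared by the slower system tests."""
    from pcsim import synthetic

    return synthetic.desk_scenario(seed=1)
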