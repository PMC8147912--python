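"""Synthetic case-study scenario generator.

Rebuilds a rural three-municipality primary care system: a hectare-grid
population with one fixed adult per inhabited cell, an under-16 exclusion
step that removes municipality-level child counts uniformly from the
remaining residents, patient attributes drawn from age-specific tables
(age-class mix, session availabilities, chronic prevalence, beta-distributed
health conditions), and a physician roster with weekday two-session opening
hours, closed on weekends.

The default tables encode the study conditions: three age classes (16-24,
25-65, over 65), seven illness families identified by ICD-10 codes, and the
age-class-illness probability tables.  The practice coordinates of the real
system are confidential, so the roster here is synthetic: each practice sits
near a randomly chosen population cell.

The ``scale`` argument shrinks the system for desk-scale experiments while
preserving the patients-per-physician ratio (about 1500:1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .agents import PCP
from .illness import (
    AgeClass,
    AgeClassIllnessDistribution,
    IllnessFamily,
    LinearFn,
    SamplingConfig,
    sample_chronic_illness,
)
from .scenario import EngineConfig, PatientSpec, Scenario
from .strategies import StrategyConfig
from .timebase import WeeklySessionClass

# -- Illness families (ICD-10 coded). ---------------------------------------
# The vaccination family has no natural illness duration; it receives a
# synthetic nominal one-day duration so that it can participate in the acute
# sampling machinery (an acute episode that resolves almost immediately and
# never needs follow-up care).

def default_families() -> dict[str, IllnessFamily]:
    return {
        "high blood pressure": IllnessFamily(
            "high blood pressure", "I10",
            willingness_fn=LinearFn(-10, 20),
            followup_fn=LinearFn(-20, 100), chronic=True,
        ),
        "diabetes": IllnessFamily(
            "diabetes", "E11",
            willingness_fn=LinearFn(-4, 14),
            followup_fn=LinearFn(-10, 90), chronic=True,
        ),
        "ischemic heart disease": IllnessFamily(
            "ischemic heart disease", "I25",
            willingness_fn=LinearFn(-4, 10),
            followup_fn=LinearFn(-30, 100), chronic=True,
        ),
        "high cholesterol level": IllnessFamily(
            "high cholesterol level", "E78",
            willingness_fn=LinearFn(-5, 8),
            duration_fn=LinearFn(4, 8),
            followup_fn=LinearFn(-2, 11),
        ),
        "back pain": IllnessFamily(
            "back pain", "M54",
            willingness_fn=LinearFn(-3, 4),
            duration_fn=LinearFn(9, 5),
            followup_fn=LinearFn(-4, 11),
        ),
        "vaccination": IllnessFamily(
            "vaccination", "Z25",
            willingness_fn=LinearFn(0, 40),
            duration_fn=LinearFn(0, 1),  # synthetic nominal one-day episode
            followup_fn=None,
        ),
        "cold": IllnessFamily(
            "cold", "J06",
            willingness_fn=LinearFn(-2, 2),
            duration_fn=LinearFn(5, 4),
            followup_fn=LinearFn(-1, 6),
        ),
    }


def default_age_classes() -> dict[str, AgeClass]:
    return {
        "16-24": AgeClass(
            "16-24", LinearFn(6, 0),
            duration_factor=0.8, willingness_factor=1.2, cancel_prob=0.95,
            availability_prob=0.85, chronic_prob=0.12,
        ),
        "25-65": AgeClass(
            "25-65", LinearFn(7, 1),
            duration_factor=1.0, willingness_factor=1.0, cancel_prob=0.8,
            availability_prob=0.55, chronic_prob=0.33,
        ),
        ">65": AgeClass(
            ">65", LinearFn(9, 1),
            duration_factor=1.2, willingness_factor=0.8, cancel_prob=0.7,
            availability_prob=0.95, chronic_prob=0.52,
        ),
    }


def default_illness_distribution() -> AgeClassIllnessDistribution:
    return AgeClassIllnessDistribution(
        acute={
            "16-24": {"high cholesterol level": 0.02, "back pain": 0.32,
                      "vaccination": 0.14, "cold": 0.52},
            "25-65": {"high cholesterol level": 0.24, "back pain": 0.38,
                      "vaccination": 0.14, "cold": 0.24},
            ">65": {"high cholesterol level": 0.36, "back pain": 0.28,
                    "vaccination": 0.27, "cold": 0.09},
        },
        chronic={
            "16-24": {"high blood pressure": 0.17, "diabetes": 0.33,
                      "ischemic heart disease": 0.5},
            "25-65": {"high blood pressure": 0.65, "diabetes": 0.16,
                      "ischemic heart disease": 0.19},
            ">65": {"high blood pressure": 0.61, "diabetes": 0.2,
                    "ischemic heart disease": 0.19},
        },
    )


#: Baseline age-class mix of the adult population.
DEFAULT_AGE_DISTRIBUTION = {"16-24": 0.1196, "25-65": 0.6318, ">65": 0.2486}

#: Shifted age-class mixes for the aging-population what-if variants.
AGING_SHORT_TERM = {"16-24": 0.1051, "25-65": 0.6283, ">65": 0.2666}
AGING_MEDIUM_TERM = {"16-24": 0.1025, "25-65": 0.6033, ">65": 0.2942}

#: Health-condition beta shape (symmetric; expected condition 0.5).
HEALTH_SHAPE = (25.0, 25.0)

# Synthetic stand-in for the confidential region geometry: a rural bounding
# box of roughly 25 x 16 km split into three municipality strips.
REGION_BBOX = (50.50, 50.65, 6.10, 6.45)  # lat_lo, lat_hi, lon_lo, lon_hi

#: Municipality totals (residents, hectare cells, under-16 children).  The
#: grand totals (35542 residents over 2754 cells; 1390 + 2383 + 1794
#: children) follow the census figures of the modeled region; the per-
#: municipality resident/cell split is a synthetic reconstruction.
MUNICIPALITIES: dict[str, dict[str, int]] = {
    "muni-west": {"residents": 8500, "cells": 600, "children": 1390},
    "muni-central": {"residents": 15250, "cells": 1200, "children": 2383},
    "muni-east": {"residents": 11792, "cells": 954, "children": 1794},
}

#: Weekday opening hours: 8:00-12:00 and 14:00-17:00, Wednesday afternoon
#: and weekends closed (32 opening hours per week).
def default_opening_hours() -> tuple[Optional[tuple[float, float]], ...]:
    morning = (8 / 24, 12 / 24)
    afternoon = (14 / 24, 17 / 24)
    opening: list[Optional[tuple[float, float]]] = [None] * 14
    for weekday in range(5):
        opening[WeeklySessionClass(weekday, 0).index] = morning
        if weekday != 2:  # Wednesday afternoon closed
            opening[WeeklySessionClass(weekday, 1).index] = afternoon
    return tuple(opening)


@dataclass(frozen=True)
class PopulationCell:
    """One-hectare census cell: centroid, resident count, municipality."""

    lat: float
    lon: float
    count: int
    municipality: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("every populated cell holds at least one resident")


def make_population_cells(
    municipalities: Mapping[str, Mapping[str, int]],
    rng: np.random.Generator,
    bbox: tuple[float, float, float, float] = REGION_BBOX,
) -> list[PopulationCell]:
    """Scatter hectare cells over municipality strips of the bounding box and
    spread each municipality's residents over its cells (>= 1 per cell)."""
    lat_lo, lat_hi, lon_lo, lon_hi = bbox
    names = list(municipalities)
    strip = (lon_hi - lon_lo) / len(names)
    cells: list[PopulationCell] = []
    for j, name in enumerate(names):
        info = municipalities[name]
        n_cells, residents = info["cells"], info["residents"]
        if residents < n_cells:
            raise ValueError(f"{name}: fewer residents than cells")
        lats = rng.uniform(lat_lo, lat_hi, n_cells)
        lons = rng.uniform(lon_lo + j * strip, lon_lo + (j + 1) * strip, n_cells)
        # one resident per cell, remainder multinomially over cells
        extra = rng.multinomial(residents - n_cells, np.full(n_cells, 1.0 / n_cells))
        for lat, lon, e in zip(lats, lons, extra):
            cells.append(PopulationCell(float(lat), float(lon), int(1 + e), name))
    return cells


def exclude_minors(
    cells: Sequence[PopulationCell],
    child_counts: Mapping[str, int],
    rng: np.random.Generator,
) -> list[PopulationCell]:
    """Remove under-16 children from the cell population.

    One adult per cell is fixed (children do not live on their own); each
    municipality's child count is then drawn uniformly from the remaining
    residents of that municipality.  The adult total is exactly
    ``sum(residents) - sum(children)`` for every seed.
    """
    by_muni: dict[str, list[int]] = {}
    for idx, cell in enumerate(cells):
        by_muni.setdefault(cell.municipality, []).append(idx)
    result = list(cells)
    for muni, indices in by_muni.items():
        children = int(child_counts.get(muni, 0))
        residual = np.array([cells[i].count - 1 for i in indices])
        if children < 0 or children > residual.sum():
            raise ValueError(
                f"{muni}: cannot remove {children} children from "
                f"{residual.sum()} non-fixed residents"
            )
        removed = rng.multivariate_hypergeometric(residual, children)
        for i, r in zip(indices, removed):
            result[i] = replace(cells[i], count=cells[i].count - int(r))
    return result


def draw_age_dependent_attributes(
    age_class: AgeClass,
    dist: AgeClassIllnessDistribution,
    families: Mapping[str, IllnessFamily],
    sampling: SamplingConfig,
    rng: np.random.Generator,
) -> tuple[tuple[bool, ...], Optional[str], Optional[float]]:
    """Draw (availabilities, chronic family, chronic seriousness) for one
    patient of the given age class."""
    avail = tuple(bool(v) for v in rng.random(14) < age_class.availability_prob)
    if rng.random() < age_class.chronic_prob:
        illness = sample_chronic_illness(age_class, dist, families, rng, sampling)
        return avail, illness.family.name, illness.seriousness
    return avail, None, None


def generate_patients(
    cells: Sequence[PopulationCell],
    age_classes: Mapping[str, AgeClass],
    age_distribution: Mapping[str, float],
    dist: AgeClassIllnessDistribution,
    families: Mapping[str, IllnessFamily],
    sampling: SamplingConfig,
    rng: np.random.Generator,
    health_shape: tuple[float, float] = HEALTH_SHAPE,
) -> list[PatientSpec]:
    """One patient agent per adult resident.

    Locations are uniform within the one-hectare square of the home cell;
    health conditions are beta-distributed; the age class is categorical and
    availabilities, chronic status and the chronic illness follow from it.
    """
    age_names = sorted(age_distribution)
    age_probs = np.array([age_distribution[n] for n in age_names])
    age_probs = age_probs / age_probs.sum()
    patients: list[PatientSpec] = []
    pid = 0
    for cell in cells:
        half_lat = 50.0 / 111_320.0  # half hectare side, degrees latitude
        half_lon = 50.0 / (111_320.0 * math.cos(math.radians(cell.lat)))
        for _ in range(cell.count):
            lat = cell.lat + rng.uniform(-half_lat, half_lat)
            lon = cell.lon + rng.uniform(-half_lon, half_lon)
            health = float(rng.beta(*health_shape))
            age_name = age_names[int(rng.choice(len(age_names), p=age_probs))]
            avail, chronic_family, chronic_s = draw_age_dependent_attributes(
                age_classes[age_name], dist, families, sampling, rng
            )
            patients.append(
                PatientSpec(
                    id=pid, lat=lat, lon=lon, health=health, age_class=age_name,
                    availabilities=avail, chronic_family=chronic_family,
                    chronic_seriousness=chronic_s,
                )
            )
            pid += 1
    return patients


def generate_pcps(
    n: int,
    cells: Sequence[PopulationCell],
    rng: np.random.Generator,
) -> list[PCP]:
    """Synthetic physician roster: each practice near a random inhabited cell,
    with the default weekday opening hours."""
    if n < 1:
        raise ValueError("roster must contain at least one physician")
    anchors = rng.choice(len(cells), size=n, replace=False)
    opening = default_opening_hours()
    pcps = []
    for j, idx in enumerate(sorted(int(a) for a in anchors)):
        cell = cells[idx]
        pcps.append(
            PCP(
                id=f"pcp-{j:02d}",
                lat=cell.lat + float(rng.normal(0, 0.003)),
                lon=cell.lon + float(rng.normal(0, 0.003)),
                opening_hours=opening,
            )
        )
    return pcps


def _scaled_municipalities(scale: float) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for name, info in MUNICIPALITIES.items():
        cells = max(1, round(info["cells"] * scale))
        residents = max(cells, round(info["residents"] * scale))
        children = min(round(info["children"] * scale), residents - cells)
        out[name] = {"residents": residents, "cells": cells, "children": children}
    return out


def case_study_scenario(
    seed: int = 0,
    scale: float = 1.0,
    n_pcps: Optional[int] = None,
    sampling: SamplingConfig = SamplingConfig(),
    strategy: StrategyConfig = StrategyConfig(
        mean_service_min=7.0, slot_minutes=15.0
    ),
    engine: EngineConfig = EngineConfig(),
    age_distribution: Mapping[str, float] = DEFAULT_AGE_DISTRIBUTION,
) -> Scenario:
    """Build the full (scale 1: 20 practices, 29975 adults over 2754 cells)
    or a scaled-down case-study scenario preserving the ~1500 patients per
    physician ratio."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    munis = _scaled_municipalities(scale)
    cells = make_population_cells(munis, rng)
    child_counts = {name: info["children"] for name, info in munis.items()}
    adult_cells = exclude_minors(cells, child_counts, rng)
    families = default_families()
    age_classes = default_age_classes()
    dist = default_illness_distribution()
    patients = generate_patients(
        adult_cells, age_classes, age_distribution, dist, families, sampling, rng
    )
    if n_pcps is None:
        n_pcps = max(1, round(20 * scale))
    pcps = generate_pcps(n_pcps, adult_cells, rng)
    return Scenario(
        families=families,
        age_classes=age_classes,
        age_class_distribution=dict(age_distribution),
        illness_dist=dist,
        pcps=pcps,
        patients=patients,
        sampling=sampling,
        strategy=strategy,
        engine=engine,
        name=f"case-study-x{scale:g}",
    )


def desk_scenario(seed: int = 0, **kwargs) -> Scenario:
    """Scaled-down preset (3 practices, ~4500 patients) for desk experiments."""
    return case_study_scenario(seed=seed, scale=0.15, **kwargs)
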