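"""Scenario schema, JSON (de)serialization, validation, and what-if transformers.

A scenario bundles everything a simulation run needs: the illness families,
the age classes with their distributions, the physician roster with opening
hours and strategy names, the patient population (static attributes only —
preferences, ratings, consideration sets and family physicians are derived
at run initialization), and the tunable model parameters.  Scenarios are one
JSON document; ``validate`` checks every schema invariant and returns the
full list of violations rather than stopping at the first.

What-if transformers derive scenario variants: ``apply_pcp_decline`` removes
retired physicians (consideration sets and family physicians rebuild
automatically at run start), ``apply_aging`` redraws the age-dependent
patient attributes under a shifted age-class distribution while preserving
locations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .agents import PCP, BehaviorConfig
from .illness import (
    AgeClass,
    AgeClassIllnessDistribution,
    IllnessFamily,
    LinearFn,
    SamplingConfig,
)
from .strategies import StrategyConfig
from .timebase import ALL_WEEKLY_CLASSES


@dataclass(frozen=True)
class EngineConfig:
    """Behavioural parameters of the event engine itself."""

    punctuality_sd_min: float = 5.0       # SD of appointment arrival offset
    walkin_beta_a: float = 2.0            # beta shape of walk-in arrival time
    walkin_beta_b: float = 2.0
    followup_tolerance_frac: float = 0.25  # window half-width as fraction of ν
    retry_travel_min: float = 30.0        # delay before a same-session retry
    deterministic: bool = False           # zero punctuality, midpoint arrivals


@dataclass(frozen=True)
class PatientSpec:
    """Static, scenario-level attributes of one patient agent."""

    id: int
    lat: float
    lon: float
    health: float
    age_class: str
    availabilities: tuple[bool, ...]
    chronic_family: Optional[str] = None
    chronic_seriousness: Optional[float] = None


@dataclass
class Scenario:
    """A complete simulation setting."""

    families: dict[str, IllnessFamily]
    age_classes: dict[str, AgeClass]
    age_class_distribution: dict[str, float]
    illness_dist: AgeClassIllnessDistribution
    pcps: list[PCP]
    patients: list[PatientSpec]
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    name: str = "scenario"


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate(scenario: Scenario) -> list[str]:
    """Check every schema invariant; returns all violations (empty == ok)."""
    errors: list[str] = []
    if not scenario.pcps:
        errors.append("scenario has no physicians")
    if not scenario.patients:
        errors.append("scenario has no patients")

    for name, family in scenario.families.items():
        if family.chronic and family.duration_fn is not None:
            errors.append(f"chronic family {name!r} defines a duration")

    total = sum(scenario.age_class_distribution.values())
    if abs(total - 1.0) > 1e-9:
        errors.append(f"age class distribution sums to {total}, expected 1")
    for age in scenario.age_class_distribution:
        if age not in scenario.age_classes:
            errors.append(f"age class distribution names unknown class {age!r}")

    tables = [("acute", scenario.illness_dist.acute)]
    if scenario.illness_dist.chronic is not None:
        tables.append(("chronic", scenario.illness_dist.chronic))
    for label, table in tables:
        for age, row in table.items():
            if age not in scenario.age_classes:
                errors.append(f"{label} table names unknown age class {age!r}")
            row_sum = sum(row.values())
            if abs(row_sum - 1.0) > 1e-9:
                errors.append(
                    f"{label} table row for {age!r} sums to {row_sum}, expected 1"
                )
            for fam, p in row.items():
                if fam not in scenario.families:
                    errors.append(f"{label} table names unknown family {fam!r}")
                elif scenario.families[fam].chronic != (label == "chronic"):
                    errors.append(
                        f"family {fam!r} appears in the wrong ({label}) table"
                    )
                if not 0.0 <= p <= 1.0:
                    errors.append(f"{label} probability {p} for {fam!r} not in [0,1]")
    for age in scenario.age_classes:
        if age not in scenario.illness_dist.acute:
            errors.append(f"acute table has no row for age class {age!r}")

    seen_pcps = set()
    for pcp in scenario.pcps:
        if pcp.id in seen_pcps:
            errors.append(f"duplicate physician id {pcp.id!r}")
        seen_pcps.add(pcp.id)
        for k, window in enumerate(pcp.opening_hours):
            if window is not None and not 0.0 <= window[0] < window[1] <= 1.0:
                errors.append(
                    f"physician {pcp.id!r} has invalid opening window "
                    f"{window} in {ALL_WEEKLY_CLASSES[k]}"
                )
        if not any(w is not None for w in pcp.opening_hours):
            errors.append(f"physician {pcp.id!r} is never open")

    seen_patients = set()
    for p in scenario.patients:
        if p.id in seen_patients:
            errors.append(f"duplicate patient id {p.id}")
        seen_patients.add(p.id)
        if p.age_class not in scenario.age_classes:
            errors.append(f"patient {p.id} has unknown age class {p.age_class!r}")
        if not 0.0 <= p.health <= 1.0:
            errors.append(f"patient {p.id} health {p.health} not in [0,1]")
        if len(p.availabilities) != 14:
            errors.append(f"patient {p.id} availabilities must have 14 entries")
        if p.chronic_family is not None:
            fam = scenario.families.get(p.chronic_family)
            if fam is None or not fam.chronic:
                errors.append(
                    f"patient {p.id} chronic family {p.chronic_family!r} is "
                    "missing or not chronic"
                )
            if p.chronic_seriousness is None or not 0.0 <= p.chronic_seriousness <= 1.0:
                errors.append(f"patient {p.id} chronic seriousness invalid")
    return errors


# --------------------------------------------------------------------------
# JSON round-trip
# --------------------------------------------------------------------------

def _fn_to_json(fn: Optional[LinearFn]) -> Optional[list[float]]:
    return None if fn is None else [fn.slope, fn.intercept]


def _fn_from_json(data: Optional[Sequence[float]]) -> Optional[LinearFn]:
    return None if data is None else LinearFn(float(data[0]), float(data[1]))


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "name": scenario.name,
        "illness_families": {
            name: {
                "icd": f.icd_code,
                "willingness": _fn_to_json(f.willingness_fn),
                "duration": _fn_to_json(f.duration_fn),
                "followup": _fn_to_json(f.followup_fn),
                "chronic": f.chronic,
            }
            for name, f in scenario.families.items()
        },
        "age_classes": {
            name: {
                "annual_illnesses": _fn_to_json(a.annual_illness_fn),
                "duration_factor": a.duration_factor,
                "willingness_factor": a.willingness_factor,
                "cancel_prob": a.cancel_prob,
                "availability_prob": a.availability_prob,
                "chronic_prob": a.chronic_prob,
            }
            for name, a in scenario.age_classes.items()
        },
        "age_class_distribution": dict(scenario.age_class_distribution),
        "acute_distribution": {
            a: dict(row) for a, row in scenario.illness_dist.acute.items()
        },
        "chronic_distribution": (
            {a: dict(row) for a, row in scenario.illness_dist.chronic.items()}
            if scenario.illness_dist.chronic is not None
            else None
        ),
        "pcps": [
            {
                "id": p.id,
                "lat": p.lat,
                "lon": p.lon,
                "opening_hours": {
                    str(ALL_WEEKLY_CLASSES[k]): list(w)
                    for k, w in enumerate(p.opening_hours)
                    if w is not None
                },
                "scheduling_strategy": p.scheduling_strategy,
                "admission_strategy": p.admission_strategy,
                "treatment_strategy": p.treatment_strategy,
            }
            for p in scenario.pcps
        ],
        "patients": [
            {
                "id": p.id,
                "lat": p.lat,
                "lon": p.lon,
                "health": p.health,
                "age_class": p.age_class,
                "availabilities": [int(v) for v in p.availabilities],
                "chronic_family": p.chronic_family,
                "chronic_seriousness": p.chronic_seriousness,
            }
            for p in scenario.patients
        ],
        "parameters": {
            "behavior": dataclasses.asdict(scenario.behavior),
            "strategy": dataclasses.asdict(scenario.strategy),
            "sampling": dataclasses.asdict(scenario.sampling),
            "engine": dataclasses.asdict(scenario.engine),
        },
    }


def scenario_from_dict(data: Mapping) -> Scenario:
    class_by_name = {str(c): c for c in ALL_WEEKLY_CLASSES}
    families = {
        name: IllnessFamily(
            name=name,
            icd_code=f.get("icd", ""),
            willingness_fn=_fn_from_json(f["willingness"]),
            duration_fn=_fn_from_json(f.get("duration")),
            followup_fn=_fn_from_json(f.get("followup")),
            chronic=bool(f.get("chronic", False)),
        )
        for name, f in data["illness_families"].items()
    }
    age_classes = {
        name: AgeClass(
            name=name,
            annual_illness_fn=_fn_from_json(a["annual_illnesses"]),
            duration_factor=a.get("duration_factor", 1.0),
            willingness_factor=a.get("willingness_factor", 1.0),
            cancel_prob=a.get("cancel_prob", 0.0),
            availability_prob=a.get("availability_prob", 1.0),
            chronic_prob=a.get("chronic_prob", 0.0),
        )
        for name, a in data["age_classes"].items()
    }
    pcps = []
    for p in data["pcps"]:
        opening: list[Optional[tuple[float, float]]] = [None] * 14
        for key, window in p["opening_hours"].items():
            opening[class_by_name[key].index] = (float(window[0]), float(window[1]))
        pcps.append(
            PCP(
                id=p["id"],
                lat=p["lat"],
                lon=p["lon"],
                opening_hours=tuple(opening),
                scheduling_strategy=p.get("scheduling_strategy", "fixed_interval"),
                admission_strategy=p.get("admission_strategy", "priority_threshold"),
                treatment_strategy=p.get("treatment_strategy", "pfcfs"),
            )
        )
    patients = [
        PatientSpec(
            id=p["id"],
            lat=p["lat"],
            lon=p["lon"],
            health=p["health"],
            age_class=p["age_class"],
            availabilities=tuple(bool(v) for v in p["availabilities"]),
            chronic_family=p.get("chronic_family"),
            chronic_seriousness=p.get("chronic_seriousness"),
        )
        for p in data["patients"]
    ]
    params = data.get("parameters", {})
    return Scenario(
        families=families,
        age_classes=age_classes,
        age_class_distribution=dict(data["age_class_distribution"]),
        illness_dist=AgeClassIllnessDistribution(
            acute=data["acute_distribution"],
            chronic=data.get("chronic_distribution"),
            strict=False,
        ),
        pcps=pcps,
        patients=patients,
        behavior=BehaviorConfig(**params.get("behavior", {})),
        strategy=StrategyConfig(**params.get("strategy", {})),
        sampling=SamplingConfig(**params.get("sampling", {})),
        engine=EngineConfig(**params.get("engine", {})),
        name=data.get("name", "scenario"),
    )


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scenario_to_dict(scenario), indent=1))


def read_scenario(path: str | Path) -> Scenario:
    return scenario_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# What-if transformers
# --------------------------------------------------------------------------

def apply_pcp_decline(
    scenario: Scenario, retained_ids: Sequence[str], name: Optional[str] = None
) -> Scenario:
    """Scenario variant with only the retained physicians.

    Patients are untouched; their consideration sets, ratings and family
    physicians are rebuilt against the reduced roster at run initialization.
    """
    retained = set(retained_ids)
    known = {p.id for p in scenario.pcps}
    unknown = retained - known
    if unknown:
        raise ValueError(f"retained roster names unknown physicians: {unknown}")
    pcps = [p for p in scenario.pcps if p.id in retained]
    if not pcps:
        raise ValueError("retained roster is empty")
    return replace(
        scenario, pcps=pcps, name=name or f"{scenario.name}-pcp-decline"
    )


def apply_aging(
    scenario: Scenario,
    new_age_distribution: Mapping[str, float],
    rng: np.random.Generator,
    name: Optional[str] = None,
) -> Scenario:
    """Scenario variant with the patient population redrawn under a shifted
    age-class distribution; locations and health conditions are preserved."""
    total = sum(new_age_distribution.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"age distribution sums to {total}, expected 1")
    unknown = set(new_age_distribution) - set(scenario.age_classes)
    if unknown:
        raise ValueError(f"age distribution names unknown classes: {unknown}")

    from .synthetic import draw_age_dependent_attributes  # cycle-free helper

    names = sorted(new_age_distribution)
    probs = np.array([new_age_distribution[n] for n in names])
    patients = []
    for p in scenario.patients:
        age_name = names[int(rng.choice(len(names), p=probs / probs.sum()))]
        avail, chronic_family, chronic_s = draw_age_dependent_attributes(
            scenario.age_classes[age_name],
            scenario.illness_dist,
            scenario.families,
            scenario.sampling,
            rng,
        )
        patients.append(
            replace(
                p,
                age_class=age_name,
                availabilities=avail,
                chronic_family=chronic_family,
                chronic_seriousness=chronic_s,
            )
        )
    return replace(
        scenario,
        patients=patients,
        age_class_distribution=dict(new_age_distribution),
        name=name or f"{scenario.name}-aged",
    )
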