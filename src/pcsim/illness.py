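"""Illness families, illness instances, age classes, and their stochastics.

An illness *family* carries the constant traits shared by all of its
instances: linear functions of the seriousness ``s in [0, 1]`` giving the
expected duration ``D_f(s)``, the expected willingness to wait ``W_f(s)``,
and the deterministic follow-up interval ``N_f(s)``, plus a chronic flag.
An emerging illness *instance* samples its actual duration (log-normal) and
willingness to wait (Weibull) around the age-class-adjusted expected traits;
only the follow-up interval is deterministic.  Age classes modulate the
family means multiplicatively and drive the annual illness rate
``I_a(c)``, a linear function of the patient's health condition ``c``,
which feeds a homogeneous Poisson onset process (exponential inter-onset
times).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A scenario or model configuration violates a documented contract."""


@dataclass(frozen=True)
class LinearFn:
    """Linear trait function ``f(s) = slope * s + intercept`` on [0, 1].

    Evaluations are clamped at zero (with a warning) because printed trait
    coefficients can dip below zero near the ends of the seriousness range.
    """

    slope: float
    intercept: float

    def __call__(self, s: float) -> float:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"seriousness must lie in [0, 1], got {s}")
        value = self.slope * s + self.intercept
        if value < 0.0:
            logger.warning(
                "linear trait %r evaluates to %.3f at s=%.3f; clamping to 0",
                self, value, s,
            )
            return 0.0
        return value


@dataclass(frozen=True)
class IllnessFamily:
    """Constant traits of one illness family (e.g. cold, back pain)."""

    name: str
    icd_code: str
    willingness_fn: LinearFn
    duration_fn: Optional[LinearFn] = None  # None == "not applicable"
    followup_fn: Optional[LinearFn] = None
    chronic: bool = False

    def __post_init__(self) -> None:
        if self.chronic and self.duration_fn is not None:
            raise ConfigurationError(
                f"chronic family {self.name!r} must not define a duration"
            )


@dataclass(frozen=True)
class Illness:
    """One emerged illness instance.

    ``duration`` and ``willingness`` are in days; ``followup_interval`` is
    the deterministic ``N_f(s)`` (None when not applicable).  Chronic
    illnesses never carry a duration.
    """

    family: IllnessFamily
    seriousness: float
    willingness: float
    duration: Optional[float] = None
    followup_interval: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.seriousness <= 1.0:
            raise ValueError("seriousness must lie in [0, 1]")
        if self.family.chronic and self.duration is not None:
            raise ValueError("chronic illness must not carry a duration")


@dataclass(frozen=True)
class AgeClass:
    """Age-dependent patient characteristics."""

    name: str
    annual_illness_fn: LinearFn        # I_a: health condition -> illnesses/year
    duration_factor: float = 1.0       # multiplies D_f(s)
    willingness_factor: float = 1.0    # multiplies W_f(s)
    cancel_prob: float = 0.0           # P(cancel appointment after recovery)
    availability_prob: float = 1.0     # P(available) per weekly session
    chronic_prob: float = 0.0          # P(patient is chronically ill)

    def __post_init__(self) -> None:
        if self.duration_factor <= 0:
            raise ConfigurationError("duration_factor must be positive")
        if self.willingness_factor < 0:
            raise ConfigurationError("willingness_factor must be non-negative")
        for p_name in ("cancel_prob", "availability_prob", "chronic_prob"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{p_name} must lie in [0, 1], got {p}")


class AgeClassIllnessDistribution:
    """Probability tables over (age class, illness family).

    ``acute`` maps age-class name -> {family name: probability} over acute
    families; ``chronic`` is the optional counterpart over chronic families.
    Every row must sum to one.
    """

    def __init__(
        self,
        acute: Mapping[str, Mapping[str, float]],
        chronic: Optional[Mapping[str, Mapping[str, float]]] = None,
        strict: bool = True,
    ) -> None:
        self.acute = {a: dict(row) for a, row in acute.items()}
        self.chronic = (
            {a: dict(row) for a, row in chronic.items()} if chronic else None
        )
        if not strict:  # row sums reported later by scenario validation
            return
        for label, table in (("acute", self.acute), ("chronic", self.chronic)):
            if table is None:
                continue
            for age, row in table.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"{label} illness distribution for age class {age!r} "
                        f"sums to {total}, expected 1"
                    )


@dataclass(frozen=True)
class SamplingConfig:
    """Dispersion parameters of the illness-trait distributions.

    The trait means are fixed by family and age class; these parameters set
    the spread around them.  With ``deterministic=True`` every draw collapses
    onto its mean (used for hand-checkable runs).
    """

    seriousness_mode: float = 0.3   # mode of the triangular law on [0, 1]
    duration_cv: float = 0.25       # log-normal coefficient of variation
    willingness_shape: float = 2.0  # Weibull shape k
    deterministic: bool = False


def expected_traits(
    family: IllnessFamily, s: float
) -> tuple[Optional[float], float, Optional[float]]:
    """Evaluate (expected duration, expected willingness, follow-up) at ``s``.

    Inapplicable traits propagate as None.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"seriousness must lie in [0, 1], got {s}")
    duration = family.duration_fn(s) if family.duration_fn is not None else None
    willingness = family.willingness_fn(s)
    followup = family.followup_fn(s) if family.followup_fn is not None else None
    return duration, willingness, followup


def annual_rate(age_class: AgeClass, c: float) -> float:
    """Expected number of acute illnesses per year, ``I_a(c)``."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"health condition must lie in [0, 1], got {c}")
    return age_class.annual_illness_fn(c)


def sample_seriousness(config: SamplingConfig, rng: np.random.Generator) -> float:
    if config.deterministic:
        return config.seriousness_mode
    return float(rng.triangular(0.0, config.seriousness_mode, 1.0))


def sample_lognormal_mean(
    mean: float, cv: float, rng: np.random.Generator
) -> float:
    """Log-normal draw with the given mean and coefficient of variation."""
    if mean <= 0.0 or cv <= 0.0:
        return max(mean, 0.0)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def sample_weibull_mean(
    mean: float, shape: float, rng: np.random.Generator
) -> float:
    """Weibull draw with the given mean and shape ``k``."""
    if mean <= 0.0 or shape <= 0.0:
        return max(mean, 0.0)
    scale = mean / math.gamma(1.0 + 1.0 / shape)
    return float(scale * rng.weibull(shape))


def _pick_family(
    row: Mapping[str, float],
    families: Mapping[str, IllnessFamily],
    rng: np.random.Generator,
) -> IllnessFamily:
    names = sorted(row)
    probs = np.array([row[n] for n in names])
    idx = int(rng.choice(len(names), p=probs / probs.sum()))
    return families[names[idx]]


def sample_acute_illness(
    age_class: AgeClass,
    dist: AgeClassIllnessDistribution,
    families: Mapping[str, IllnessFamily],
    rng: np.random.Generator,
    config: SamplingConfig = SamplingConfig(),
) -> Illness:
    """Draw one acute illness for a patient of the given age class.

    The family comes from the acute distribution row, the seriousness from a
    triangular law, the duration from a log-normal and the willingness from a
    Weibull around the age-class-adjusted expected traits; the follow-up
    interval is the deterministic ``N_f(s)``.
    """
    family = _pick_family(dist.acute[age_class.name], families, rng)
    if family.chronic:
        raise ConfigurationError(
            f"family {family.name!r} in the acute table is chronic"
        )
    if family.duration_fn is None:
        raise ConfigurationError(
            f"acute family {family.name!r} has no duration function"
        )
    s = sample_seriousness(config, rng)
    exp_d, exp_w, followup = expected_traits(family, s)
    mean_d = age_class.duration_factor * exp_d
    mean_w = age_class.willingness_factor * exp_w
    if config.deterministic:
        duration, willingness = mean_d, mean_w
    else:
        duration = sample_lognormal_mean(mean_d, config.duration_cv, rng)
        willingness = sample_weibull_mean(mean_w, config.willingness_shape, rng)
    return Illness(
        family=family,
        seriousness=s,
        willingness=willingness,
        duration=duration,
        followup_interval=followup,
    )


def sample_chronic_illness(
    age_class: AgeClass,
    dist: AgeClassIllnessDistribution,
    families: Mapping[str, IllnessFamily],
    rng: np.random.Generator,
    config: SamplingConfig = SamplingConfig(),
) -> Illness:
    """Draw the unique chronic illness of a chronic patient.

    Mirrors the acute sampler except that chronic illnesses never heal (no
    duration) and the family comes from the chronic table.
    """
    if dist.chronic is None:
        raise ConfigurationError("scenario defines no chronic illness table")
    family = _pick_family(dist.chronic[age_class.name], families, rng)
    if not family.chronic:
        raise ConfigurationError(
            f"family {family.name!r} in the chronic table is not chronic"
        )
    s = sample_seriousness(config, rng)
    _, exp_w, followup = expected_traits(family, s)
    mean_w = age_class.willingness_factor * exp_w
    if config.deterministic:
        willingness = mean_w
    else:
        willingness = sample_weibull_mean(mean_w, config.willingness_shape, rng)
    return Illness(
        family=family,
        seriousness=s,
        willingness=willingness,
        duration=None,
        followup_interval=followup,
    )


def sample_onset_gap(rate_per_year: float, rng: np.random.Generator) -> float:
    """Days until the next acute illness onset (exponential inter-onset)."""
    if rate_per_year <= 0.0:
        return math.inf
    return float(rng.exponential(365.0 / rate_per_year))
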