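"""Key performance indicators, multi-run summaries, warm-up testing, sweeps.

The accumulator collects the per-run indicators inside the observation
window (after warm-up, before the horizon): treatment counts split by visit
type, service/overtime/utilization on the physician side, and access times,
access distances and waiting times on the patient side.  Waiting time for an
appointment holder runs from the later of arrival and the scheduled time to
the start of treatment; walk-in waiting runs from arrival.  Utilization is
total service time over the published opening hours of the window (the
post-session buffer does not count as available time, but work done there is
neither idle nor overtime; overtime is work performed after the buffer).

For experiments, ``summarize`` produces per-KPI means with two-sided
Student-t confidence intervals over independent runs.  Warm-up truncation is
decided with the Schruben-Singh-Tierney initialization-bias test on yearly
KPI series: a standardized partial-sum statistic whose scale is estimated by
batch means (5 batches over the last half of the series), compared
two-sidedly against a t distribution with (batches - 1) degrees of freedom.
``sensitivity_sweep`` varies one numeric scenario parameter over a relative
grid and reruns the experiment at every grid point with common seeds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agents import PCP
from .timebase import MINUTES_PER_DAY


def available_hours(
    pcps: Sequence[PCP], start_day: float, end_day: float
) -> dict[str, float]:
    """Published opening hours (h) per physician with session start inside
    ``[start_day, end_day)``; the post-session buffer is excluded."""
    out: dict[str, float] = {}
    for pcp in pcps:
        total = 0.0
        for day in range(int(math.floor(start_day)), int(math.ceil(end_day))):
            for half in (0, 1):
                window = pcp.opening_hours[2 * (day % 7) + half]
                if window is None:
                    continue
                open_t = day + window[0]
                if start_day <= open_t < end_day:
                    total += (window[1] - window[0]) * 24.0
        out[pcp.id] = total
    return out


def utilization(service_hours: float, open_hours: float) -> Optional[float]:
    """Service time over available working time; may exceed 1 under heavy
    overtime; None when no working time is available."""
    if open_hours <= 0:
        return None
    return service_hours / open_hours


@dataclass
class KpiRecord:
    """Aggregate indicators of one simulation run's observation window."""

    n_pcps: int = 0
    n_patients: int = 0
    n_chronic: int = 0
    window_days: float = 0.0
    treatments: int = 0
    walkins: int = 0                 # treated walk-in visits
    acute_appointments: int = 0      # attended acute appointments
    regular_appointments: int = 0    # attended regular appointments
    arrivals: int = 0
    admissions: int = 0
    rejected_walkins: int = 0
    rejected_appointment_holders: int = 0
    onsets: int = 0
    cancellations: int = 0
    forgone: int = 0
    bookings_acute: int = 0
    bookings_regular: int = 0
    service_hours: float = 0.0
    overtime_min: float = 0.0
    capacity_hours: float = 0.0
    access_time_acute_days: float = math.nan    # mean per arranged booking
    access_time_regular_days: float = math.nan
    access_distance_km: float = math.nan        # mean per treated visit
    wait_appointment_min: float = math.nan
    wait_walkin_min: float = math.nan
    on_time_fraction: float = math.nan
    utilization: float = math.nan               # mean over physicians
    overtime_weekly_min: float = math.nan       # mean per physician per week
    per_pcp: dict[str, dict[str, float]] = field(default_factory=dict)

    def scalar_fields(self) -> dict[str, float]:
        out = {}
        for f in dataclasses.fields(self):
            if f.name == "per_pcp":
                continue
            out[f.name] = float(getattr(self, f.name))
        return out


class KpiAccumulator:
    """Collects indicators inside the window; optionally bins yearly series."""

    YEARLY_KPIS = (
        "treatments",
        "access_time_acute_days",
        "wait_walkin_min",
        "overtime_weekly_min",
        "utilization",
    )

    def __init__(
        self,
        pcps: Sequence[PCP],
        n_patients: int,
        n_chronic: int,
        warmup: float,
        horizon: float,
        yearly: bool = False,
    ) -> None:
        self.warmup = warmup
        self.horizon = horizon
        self.pcp_ids = [p.id for p in pcps]
        self.capacity = available_hours(pcps, warmup, horizon)
        self.record = KpiRecord(
            n_pcps=len(pcps),
            n_patients=n_patients,
            n_chronic=n_chronic,
            window_days=horizon - warmup,
            capacity_hours=sum(self.capacity.values()),
        )
        self._per_pcp: dict[str, dict[str, float]] = {
            pid: {"treatments": 0.0, "service_hours": 0.0, "overtime_min": 0.0,
                  "rejected_walkins": 0.0}
            for pid in self.pcp_ids
        }
        self._sums = {
            "access_acute": [0.0, 0],
            "access_regular": [0.0, 0],
            "distance": [0.0, 0],
            "wait_app": [0.0, 0],
            "wait_walk": [0.0, 0],
            "on_time": [0.0, 0],
        }
        self.yearly = yearly
        if yearly:
            n_years = int(math.ceil(horizon / 365.0))
            self._year_sums: dict[str, np.ndarray] = {
                k: np.zeros(n_years) for k in
                ("treatments", "access_sum", "access_n", "wait_walk_sum",
                 "wait_walk_n", "overtime_min", "service_hours")
            }
            self._year_capacity = np.array(
                [
                    sum(
                        available_hours(
                            pcps, 365.0 * y, min(365.0 * (y + 1), horizon)
                        ).values()
                    )
                    for y in range(n_years)
                ]
            )

    # -- helpers -----------------------------------------------------------

    def _in_window(self, t: float) -> bool:
        return self.warmup <= t < self.horizon

    def _year(self, t: float) -> int:
        return int(t // 365.0)

    # -- event hooks -------------------------------------------------------

    def on_onset(self, t: float) -> None:
        if self._in_window(t):
            self.record.onsets += 1

    def on_booking(self, t: float, role: str, access_days: float) -> None:
        if self.yearly and role == "acute":
            y = self._year(t)
            self._year_sums["access_sum"][y] += access_days
            self._year_sums["access_n"][y] += 1
        if not self._in_window(t):
            return
        key = "access_acute" if role == "acute" else "access_regular"
        self._sums[key][0] += access_days
        self._sums[key][1] += 1
        if role == "acute":
            self.record.bookings_acute += 1
        else:
            self.record.bookings_regular += 1

    def on_arrival(
        self, t: float, pcp_id: str, kind: str, admitted: bool
    ) -> None:
        if not self._in_window(t):
            return
        self.record.arrivals += 1
        if admitted:
            self.record.admissions += 1
        elif kind == "walkin":
            self.record.rejected_walkins += 1
            self._per_pcp[pcp_id]["rejected_walkins"] += 1
        else:
            self.record.rejected_appointment_holders += 1

    def on_cancellation(self, t: float) -> None:
        if self._in_window(t):
            self.record.cancellations += 1

    def on_forgo(self, t: float) -> None:
        if self._in_window(t):
            self.record.forgone += 1

    def on_treatment(
        self,
        start: float,
        pcp_id: str,
        kind: str,                  # "walkin" | "appointment"
        role: Optional[str],        # appointment role: "acute" | "regular"
        wait_min: float,
        on_time: Optional[bool],
        service_days: float,
        overtime_days: float,
        distance_km: float,
    ) -> None:
        if self.yearly:
            y = min(self._year(start), len(self._year_sums["treatments"]) - 1)
            self._year_sums["treatments"][y] += 1
            self._year_sums["overtime_min"][y] += overtime_days * MINUTES_PER_DAY
            self._year_sums["service_hours"][y] += service_days * 24.0
            if kind == "walkin":
                self._year_sums["wait_walk_sum"][y] += wait_min
                self._year_sums["wait_walk_n"][y] += 1
        if not self._in_window(start):
            return
        rec = self.record
        rec.treatments += 1
        per = self._per_pcp[pcp_id]
        per["treatments"] += 1
        per["service_hours"] += service_days * 24.0
        per["overtime_min"] += overtime_days * MINUTES_PER_DAY
        rec.service_hours += service_days * 24.0
        rec.overtime_min += overtime_days * MINUTES_PER_DAY
        self._sums["distance"][0] += distance_km
        self._sums["distance"][1] += 1
        if kind == "walkin":
            rec.walkins += 1
            self._sums["wait_walk"][0] += wait_min
            self._sums["wait_walk"][1] += 1
        else:
            if role == "regular":
                rec.regular_appointments += 1
            else:
                rec.acute_appointments += 1
            self._sums["wait_app"][0] += wait_min
            self._sums["wait_app"][1] += 1
            if on_time is not None:
                self._sums["on_time"][0] += 1.0 if on_time else 0.0
                self._sums["on_time"][1] += 1

    # -- finalization ------------------------------------------------------

    @staticmethod
    def _mean(pair: list) -> float:
        return pair[0] / pair[1] if pair[1] else math.nan

    def finalize(self) -> KpiRecord:
        rec = self.record
        rec.access_time_acute_days = self._mean(self._sums["access_acute"])
        rec.access_time_regular_days = self._mean(self._sums["access_regular"])
        rec.access_distance_km = self._mean(self._sums["distance"])
        rec.wait_appointment_min = self._mean(self._sums["wait_app"])
        rec.wait_walkin_min = self._mean(self._sums["wait_walk"])
        rec.on_time_fraction = self._mean(self._sums["on_time"])
        utils = []
        weeks = rec.window_days / 7.0 if rec.window_days > 0 else math.nan
        weekly = []
        for pid in self.pcp_ids:
            per = self._per_pcp[pid]
            u = utilization(per["service_hours"], self.capacity[pid])
            per["utilization"] = math.nan if u is None else u
            per["overtime_weekly_min"] = (
                per["overtime_min"] / weeks if weeks else math.nan
            )
            if u is not None:
                utils.append(u)
            weekly.append(per["overtime_weekly_min"])
        rec.utilization = float(np.mean(utils)) if utils else 0.0
        rec.overtime_weekly_min = float(np.mean(weekly)) if weekly else math.nan
        rec.per_pcp = self._per_pcp
        return rec

    def yearly_series(self) -> pd.DataFrame:
        """Per-simulated-year KPI series (for warm-up truncation analysis)."""
        if not self.yearly:
            raise RuntimeError("accumulator was not collecting yearly series")
        ys = self._year_sums
        n_pcps = max(1, len(self.pcp_ids))
        with np.errstate(invalid="ignore", divide="ignore"):
            data = {
                "treatments": ys["treatments"] / n_pcps,
                "access_time_acute_days": ys["access_sum"]
                / np.where(ys["access_n"] > 0, ys["access_n"], np.nan),
                "wait_walkin_min": ys["wait_walk_sum"]
                / np.where(ys["wait_walk_n"] > 0, ys["wait_walk_n"], np.nan),
                "overtime_weekly_min": ys["overtime_min"] / n_pcps / (365.0 / 7.0),
                "utilization": ys["service_hours"]
                / np.where(self._year_capacity > 0, self._year_capacity, np.nan),
            }
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# Multi-run summaries
# --------------------------------------------------------------------------

def summarize(runs: Sequence[KpiRecord], level: float = 0.95) -> pd.DataFrame:
    """Per-KPI mean and two-sided Student-t confidence bounds over runs.

    With a single run the interval is undefined (NaN bounds).
    """
    if not runs:
        raise ValueError("no runs to summarize")
    frame = pd.DataFrame([r.scalar_fields() for r in runs])
    mean = frame.mean()
    if len(runs) >= 2:
        se = frame.std(ddof=1) / math.sqrt(len(runs))
        q = stats.t.ppf(0.5 + level / 2.0, df=len(runs) - 1)
        lo, hi = mean - q * se, mean + q * se
    else:
        lo = hi = mean * math.nan
    return pd.DataFrame({"mean": mean, "ci_lo": lo, "ci_hi": hi})


# --------------------------------------------------------------------------
# Initialization-bias (warm-up) testing
# --------------------------------------------------------------------------

N_BATCHES = 5


@dataclass(frozen=True)
class SstResult:
    statistic: float
    critical: float
    reject: bool
    truncation: int


def sst_warmup_test(
    series: Sequence[float], truncation: int = 0, alpha: float = 0.05
) -> SstResult:
    """Schruben-Singh-Tierney test for initialization bias in the mean.

    The truncated series' standardized partial-sum statistic

        T = sqrt(45) * n^(-3/2) * sum_k (1 - k/n) * k * (mean_n - mean_k) / s

    is asymptotically standard normal under the no-bias null; the scale ``s``
    is the square root of the batch-means estimate of the asymptotic variance
    computed from 5 batches over the last half of the series, so ``T`` is
    referred two-sidedly to a t distribution with 4 degrees of freedom.
    """
    y = np.asarray(series, dtype=float)[int(truncation):]
    n = len(y)
    if n < 2 * N_BATCHES:
        raise ValueError(
            f"series too short after truncation ({n} points; need >= {2 * N_BATCHES})"
        )
    if np.allclose(y, y[0]):
        crit = float(stats.t.ppf(1 - alpha / 2, N_BATCHES - 1))
        return SstResult(0.0, crit, False, int(truncation))
    k = np.arange(1, n + 1)
    cum_means = np.cumsum(y) / k
    numerator = np.sum((1.0 - k / n) * k * (cum_means[-1] - cum_means))
    half = y[n - (n // 2):]
    b = len(half) // N_BATCHES
    batches = half[len(half) - N_BATCHES * b:].reshape(N_BATCHES, b)
    batch_means = batches.mean(axis=1)
    var_hat = b * float(np.var(batch_means, ddof=1))
    if var_hat <= 0:
        crit = float(stats.t.ppf(1 - alpha / 2, N_BATCHES - 1))
        return SstResult(0.0, crit, False, int(truncation))
    statistic = math.sqrt(45.0) * numerator / (n ** 1.5 * math.sqrt(var_hat))
    critical = float(stats.t.ppf(1 - alpha / 2, N_BATCHES - 1))
    return SstResult(statistic, critical, abs(statistic) > critical, int(truncation))


def find_warmup(
    series_per_kpi: Mapping[str, Sequence[float]],
    step: int = 5,
    alpha: float = 0.05,
    min_length: int = 10,
) -> Optional[int]:
    """Smallest multiple of ``step`` (in series units, e.g. years) at which
    the initialization-bias null is not rejected for every tracked KPI;
    None when no admissible truncation exists within the series."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = min(len(s) for s in series_per_kpi.values())
    trunc = 0
    while n - trunc >= max(min_length, 2 * N_BATCHES):
        if all(
            not sst_warmup_test(s, truncation=trunc, alpha=alpha).reject
            for s in series_per_kpi.values()
        ):
            return trunc
        trunc += step
    return None


# --------------------------------------------------------------------------
# Sensitivity sweep
# --------------------------------------------------------------------------

_CONFIG_GROUPS = ("behavior", "strategy", "sampling", "engine")


def get_parameter(scenario, path: str) -> float:
    parts = path.split(".")
    if parts[0] in _CONFIG_GROUPS and len(parts) == 2:
        return float(getattr(getattr(scenario, parts[0]), parts[1]))
    if parts[0] == "age_classes" and len(parts) == 3:
        return float(getattr(scenario.age_classes[parts[1]], parts[2]))
    if path == "patients.health":
        return 1.0  # multiplicative scale on every patient's condition
    raise ValueError(f"unsupported parameter path {path!r}")


def set_parameter(scenario, path: str, value: float):
    """Return a scenario copy with the addressed numeric parameter replaced.

    Supported paths: ``behavior.*``, ``strategy.*``, ``sampling.*``,
    ``engine.*``, ``age_classes.<name>.<attr>``, and ``patients.health``
    (a multiplicative factor on every patient's health condition).
    """
    parts = path.split(".")
    if parts[0] in _CONFIG_GROUPS and len(parts) == 2:
        group = getattr(scenario, parts[0])
        current = getattr(group, parts[1])
        if isinstance(current, bool) or not isinstance(current, (int, float)):
            raise ValueError(f"parameter {path!r} is not numeric")
        return dataclasses.replace(
            scenario, **{parts[0]: dataclasses.replace(group, **{parts[1]: value})}
        )
    if parts[0] == "age_classes" and len(parts) == 3:
        classes = dict(scenario.age_classes)
        classes[parts[1]] = dataclasses.replace(
            classes[parts[1]], **{parts[2]: value}
        )
        return dataclasses.replace(scenario, age_classes=classes)
    if path == "patients.health":
        patients = [
            dataclasses.replace(p, health=min(1.0, max(0.0, p.health * value)))
            for p in scenario.patients
        ]
        return dataclasses.replace(scenario, patients=patients)
    raise ValueError(f"unsupported parameter path {path!r}")


def sensitivity_sweep(
    scenario,
    parameter_path: str,
    horizon: float,
    warmup: float,
    rel_range: float = 0.20,
    increment: float = 0.01,
    runs: int = 20,
    seed: int = 0,
    kpis: Sequence[str] = ("utilization", "rejected_walkins"),
) -> pd.DataFrame:
    """One-at-a-time sweep of a numeric parameter over a relative grid.

    The parameter varies between ``±rel_range`` of its base value in steps of
    ``increment`` (41 points for the default ±20 % / 1 %); every grid point is
    evaluated with ``runs`` independent simulation runs using the same seeds,
    so the zero-delta column reproduces the base experiment exactly.
    """
    from .engine import run as run_simulation  # deferred: avoids module cycle

    base = get_parameter(scenario, parameter_path)
    n_steps = int(round(rel_range / increment))
    deltas = [i * increment for i in range(-n_steps, n_steps + 1)]
    rows = []
    for delta in deltas:
        variant = set_parameter(scenario, parameter_path, base * (1.0 + delta))
        records = [
            run_simulation(variant, horizon=horizon, warmup=warmup, seed=seed + r)
            for r in range(runs)
        ]
        table = summarize(records)
        for kpi in kpis:
            rows.append(
                {
                    "parameter": parameter_path,
                    "delta": delta,
                    "kpi": kpi,
                    "mean": table.loc[kpi, "mean"],
                    "ci_lo": table.loc[kpi, "ci_lo"],
                    "ci_hi": table.loc[kpi, "ci_hi"],
                }
            )
    return pd.DataFrame(rows)
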