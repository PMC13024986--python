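"""Longitudinal area-based wound-healing metrics.

All metrics derive from the wound surface area A_t (cm²) measured at
scan day t, with day counted from the baseline scan (baseline = day 1
in the pilot-cohort convention):

* absolute area reduction       dA = A0 - A_last  (cm²)
* percentage area reduction     (A0 - A_t) / A0 * 100
* early-phase reduction         percent reduction at the first follow-up
* daily healing rate            (A0 - A_t) / (t - t0)  (cm²/day)
* Du Bois body surface area     BSA = 0.007184 * W^0.425 * H^0.725  (m²)
* TBSA%                         wound area / (BSA * 1e4) * 100
* dTBSA%                        sum of per-wound dA over BSA, as a %

Negative reductions (a wound that grew between scans) are legitimate and
propagate with their sign — clamping would hide deterioration.

The daily healing rate is the plain area change per elapsed day, with
units cm²/day; no additional scale factor is applied (a percentage-style
x100 on this quantity would be dimensionally inconsistent with its unit).
"""
from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError, InsufficientDataError

LOCATIONS = ("Torso", "RUL", "LUL", "RLL", "LLL")

#: Du Bois & Du Bois height-weight coefficient and exponents.
DU_BOIS_COEF = 0.007184
DU_BOIS_WEIGHT_EXP = 0.425
DU_BOIS_HEIGHT_EXP = 0.725


@dataclass(frozen=True)
class WoundObservation:
    """One wound-area measurement: patient, anatomical location, study day, cm²."""

    patient_id: str
    location: str
    day: int
    area_cm2: float

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}; expected one of {LOCATIONS}")
        if self.day < 1:
            raise ValueError("study day must be >= 1")
        if self.area_cm2 < 0:
            raise ValueError("wound area cannot be negative")


@dataclass(frozen=True)
class WoundSeries:
    """Time-ordered observations of one wound of one patient."""

    observations: tuple[WoundObservation, ...]

    def __post_init__(self):
        obs = tuple(self.observations)
        if not obs:
            raise ValueError("a wound series needs at least one observation")
        pid, loc = obs[0].patient_id, obs[0].location
        if any(o.patient_id != pid or o.location != loc for o in obs):
            raise ValueError("all observations in a series must share patient and location")
        days = [o.day for o in obs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("observation days must be strictly increasing")
        object.__setattr__(self, "observations", obs)

    @property
    def patient_id(self) -> str:
        return self.observations[0].patient_id

    @property
    def location(self) -> str:
        return self.observations[0].location

    @property
    def baseline(self) -> WoundObservation:
        return self.observations[0]

    @property
    def last(self) -> WoundObservation:
        return self.observations[-1]

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class PatientRecord:
    """Anthropometrics needed for Du Bois BSA."""

    patient_id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float

    def __post_init__(self):
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise DomainError("height and weight must be positive")

    @property
    def bsa_m2(self) -> float:
        return du_bois_bsa(self.weight_kg, self.height_cm)


@dataclass(frozen=True)
class WoundMetrics:
    """Bundle of longitudinal metrics for one wound series."""

    patient_id: str
    location: str
    baseline_area_cm2: float
    last_area_cm2: float
    delta_a_cm2: float
    percent_reduction: float
    early_phase_reduction_pct: float
    overall_rate_cm2_per_day: float
    interval_rates_cm2_per_day: tuple[float, ...]
    wound_grew: bool


@dataclass(frozen=True)
class PatientSummary:
    """Patient-level burn-burden summary on the TBSA scale."""

    patient_id: str
    bsa_m2: float
    n_wounds: int
    baseline_area_cm2: float
    tbsa_baseline_pct: float
    delta_tbsa_pct: float


def du_bois_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m²) from the Du Bois height-weight formula."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    return DU_BOIS_COEF * weight_kg**DU_BOIS_WEIGHT_EXP * height_cm**DU_BOIS_HEIGHT_EXP


def absolute_reduction(a0: float, at: float) -> float:
    """dA = A0 - A_t (cm²); negative when the wound grew."""
    if a0 < 0 or at < 0:
        raise DomainError("areas cannot be negative")
    return a0 - at


def percent_reduction(a0: float, at: float) -> float:
    """Percentage decrease in wound area relative to baseline."""
    if a0 <= 0:
        raise DomainError("baseline area must be positive for a percent reduction")
    return (a0 - at) / a0 * 100.0


def tbsa_percent(area_cm2: float, bsa_m2: float) -> float:
    """Express a wound area as a percentage of body surface area."""
    if bsa_m2 <= 0:
        raise DomainError("BSA must be positive")
    return area_cm2 / (bsa_m2 * 1e4) * 100.0


def delta_tbsa_percent(series_list, bsa_m2: float) -> float:
    """Overall drop in burned body fraction: sum of per-wound (A0 - A_last)
    over BSA (converted to cm²), as a percentage.

    Linear in the wounds: equals the sum of per-wound
    ``tbsa_percent(delta_a, bsa_m2)``.
    """
    series_list = list(series_list)
    if not series_list:
        raise DomainError("delta_tbsa_percent needs at least one wound series")
    total = sum(s.baseline.area_cm2 - s.last.area_cm2 for s in series_list)
    return tbsa_percent(total, bsa_m2)


def early_phase_reduction(series: WoundSeries) -> float:
    """Percent reduction from baseline to the first follow-up scan."""
    if len(series) < 2:
        raise InsufficientDataError("early-phase reduction needs a follow-up scan")
    return percent_reduction(series.baseline.area_cm2, series.observations[1].area_cm2)


def daily_healing_rate(series: WoundSeries, at_index: int | None = None) -> float:
    """Area change per elapsed day, baseline to the given follow-up (cm²/day).

    ``at_index`` indexes the observation list (>= 1); ``None`` uses the
    final scan (the overall rate).
    """
    if len(series) < 2:
        raise InsufficientDataError("a healing rate needs a follow-up scan")
    if at_index is None:
        at_index = len(series) - 1
    if not 1 <= at_index < len(series):
        raise DomainError(f"at_index must be in [1, {len(series) - 1}]")
    obs = series.observations[at_index]
    elapsed = obs.day - series.baseline.day
    if elapsed <= 0:
        raise DomainError("elapsed time must be positive")
    return (series.baseline.area_cm2 - obs.area_cm2) / elapsed


def wound_metrics(series: WoundSeries) -> WoundMetrics:
    """All per-wound metrics: baseline-vs-last, baseline-vs-first-follow-up,
    and the per-interval daily rates."""
    if len(series) < 2:
        raise InsufficientDataError("wound metrics need at least two observations")
    a0 = series.baseline.area_cm2
    alast = series.last.area_cm2
    delta = absolute_reduction(a0, alast)
    return WoundMetrics(
        patient_id=series.patient_id,
        location=series.location,
        baseline_area_cm2=a0,
        last_area_cm2=alast,
        delta_a_cm2=delta,
        percent_reduction=percent_reduction(a0, alast),
        early_phase_reduction_pct=early_phase_reduction(series),
        overall_rate_cm2_per_day=daily_healing_rate(series),
        interval_rates_cm2_per_day=tuple(
            daily_healing_rate(series, i) for i in range(1, len(series))
        ),
        wound_grew=delta < 0,
    )


def patient_summary(record: PatientRecord, series_list) -> PatientSummary:
    """Patient-level TBSA-scale summary across that patient's wounds."""
    series_list = list(series_list)
    if not series_list:
        raise DomainError("patient summary needs at least one wound series")
    if any(s.patient_id != record.patient_id for s in series_list):
        raise ValueError("series belong to a different patient")
    bsa = record.bsa_m2
    baseline_total = sum(s.baseline.area_cm2 for s in series_list)
    return PatientSummary(
        patient_id=record.patient_id,
        bsa_m2=bsa,
        n_wounds=len(series_list),
        baseline_area_cm2=baseline_total,
        tbsa_baseline_pct=tbsa_percent(baseline_total, bsa),
        delta_tbsa_pct=delta_tbsa_percent(series_list, bsa),
    )
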