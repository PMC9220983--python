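"""Screening policy, test model, and the screened (intervention) universe.

Screening is applied to the same life histories that produced the control
universe — the parallel-universe design.  At every attended screen before
death and before any diagnosis:

* an invasive tumor is screen-detected iff its current diameter has reached
  its screen-detectability diameter ``d_screen``, obtained by mapping the
  tumor's detectability quantile through the scenario's Weibull (median =
  the test's median detection size);
* a pre-clinical DCIS is detected with probability equal to the test's DCIS
  sensitivity, independently across rounds;
* a woman with no detectable cancer screens negative and accrues an expected
  false positive of (1 - specificity) (or a Bernoulli draw in ``bernoulli``
  mode).

A screen-detected tumor is re-staged at its detection diameter and cured iff
that diameter is still below the fatal diameter; otherwise the control
universe's breast-cancer death stands.  Women exit screening at diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    ONSET_DIAMETER,
    Cohort,
    crossing_ages,
    detection_threshold_from_quantile,
)
from .config import ConfigError, ContractViolation, substream
from .natural_history import (
    CAUSE_OTHER,
    MODE_SCREEN_DCIS,
    MODE_SCREEN_INVASIVE,
    CourseOutcomes,
    stage_at_diagnosis,
)


@dataclass(frozen=True)
class ScreeningPolicy:
    """A periodic screening schedule with optional partial attendance."""

    start_age: float = 50.0
    stop_age: float = 74.0
    interval: float = 2.0
    attendance: float = 1.0

    def validate(self) -> None:
        if not (self.start_age < self.stop_age or self.start_age == self.stop_age):
            raise ConfigError(f"policy: start_age must be <= stop_age, got {self.start_age} > {self.stop_age}")
        if not (self.interval > 0):
            raise ConfigError(f"policy: interval must be > 0, got {self.interval}")
        if not (0.0 <= self.attendance <= 1.0):
            raise ConfigError(f"policy: attendance must lie in [0, 1], got {self.attendance}")


@dataclass(frozen=True)
class TestCharacteristics:
    """One point of the scenario grid: what the screen test can do and costs."""

    dcis_sensitivity: float
    median_detect_size: float
    specificity: float
    price: float | None = None

    def validate(self) -> None:
        for name in ("dcis_sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"test.{name}: probability must lie in [0, 1], got {v}")
        if not (self.median_detect_size > 0):
            raise ConfigError(f"test.median_detect_size: must be > 0, got {self.median_detect_size}")


#: Digital mammography, the comparator strategy.
MAMMOGRAPHY = TestCharacteristics(dcis_sensitivity=0.91, median_detect_size=1.21, specificity=0.88, price=149.0)


def scheduled_ages(policy: ScreeningPolicy) -> np.ndarray:
    """The ordered screen ages: start, start+interval, ... up to stop (inclusive)."""
    policy.validate()
    n_rounds = int(np.floor((policy.stop_age - policy.start_age) / policy.interval + 1e-9)) + 1
    return policy.start_age + policy.interval * np.arange(n_rounds)


@dataclass
class ScreenedOutcome:
    """The screened universe plus the screening event ledger."""

    course: CourseOutcomes
    screen_ages: np.ndarray      # (R,) scheduled ages
    attended: np.ndarray         # (R, n) bool: woman alive, undiagnosed, attending
    fp_weight: np.ndarray        # (R, n) expected (or realised) false positives
    test: TestCharacteristics
    policy: ScreeningPolicy

    @property
    def negative(self) -> np.ndarray:
        """Attended screens that did not end in a detection."""
        detected_at = self.course.diagnosis_age  # NaN-safe compare below
        neg = self.attended.copy()
        screen_dx = np.isin(self.course.diagnosis_mode, (MODE_SCREEN_DCIS, MODE_SCREEN_INVASIVE))
        hit = screen_dx & np.isfinite(detected_at)
        # the detection round itself is not a negative screen
        neg[:, hit] &= self.screen_ages[:, None] != detected_at[hit][None, :]
        return neg

    @property
    def false_positives_per_woman(self) -> np.ndarray:
        return self.fp_weight.sum(axis=0)

    @property
    def screens_per_woman(self) -> np.ndarray:
        return self.attended.sum(axis=0)


def apply_screening(
    cohort: Cohort,
    control: CourseOutcomes,
    policy: ScreeningPolicy,
    test: TestCharacteristics,
    seed: int,
    fp_mode: str = "expected",
) -> ScreenedOutcome:
    """Run the screening universe for one test/policy on a prepared cohort.

    ``control`` must be the natural course of the same cohort: screening
    reuses its clinical-surfacing and death times for everything the screen
    does not change.  ``seed`` feeds the screening-only substreams (DCIS
    detection, attendance, Bernoulli false positives); natural-history draws
    are untouched, so scenarios sharing a cohort differ only through the
    test's characteristics.
    """
    if len(control) != len(cohort):
        raise ContractViolation(
            f"control universe has {len(control)} women but cohort has {len(cohort)}"
        )
    test.validate()
    policy.validate()
    if fp_mode not in ("expected", "bernoulli"):
        raise ConfigError(f"fp_mode: expected 'expected' or 'bernoulli', got {fp_mode!r}")

    n = len(cohort)
    ages = scheduled_ages(policy)
    n_rounds = len(ages)

    d_screen = detection_threshold_from_quantile(
        cohort.detect_quantile, test.median_detect_size, cohort.params.detect_threshold_shape
    )
    # age from which the invasive tumor is screen-detectable; thresholds at or
    # below the onset diameter make it detectable from the start of growth
    t_detect = crossing_ages(cohort, np.maximum(d_screen, ONSET_DIAMETER))
    invasive_start = cohort.invasive_start_age
    has_invasive_phase = ~np.isnan(invasive_start)

    # control-universe clinical surfacing (women exit screening at diagnosis)
    control_dx = np.where(np.isnan(control.diagnosis_age), np.inf, control.diagnosis_age)
    control_death = control.death_age

    dcis_start = cohort.age_at_onset
    dcis_end = cohort.age_at_onset + cohort.dcis_dwell  # NaN for non-DCIS

    rng_screen = substream(seed, "screening")
    rng_attend = substream(seed, "attendance")
    rng_fp = substream(seed, "fp")

    detect_age = np.full(n, np.nan)
    detect_is_dcis = np.zeros(n, dtype=bool)
    attended = np.zeros((n_rounds, n), dtype=bool)
    fp_weight = np.zeros((n_rounds, n))

    for k, a in enumerate(ages):
        # draw per-round uniforms unconditionally so the consumption pattern —
        # and hence every downstream draw — is identical across scenarios
        u_dcis = rng_screen.uniform(size=n)
        u_att = rng_attend.uniform(size=n)
        if fp_mode == "bernoulli":
            u_fp = rng_fp.uniform(size=n)

        undiagnosed = np.isnan(detect_age) & (a < control_dx)
        alive = a < control_death
        active = undiagnosed & alive
        attend = active & (u_att < policy.attendance)
        attended[k] = attend

        in_dcis_window = (
            cohort.starts_as_dcis
            & (dcis_start <= a)
            & np.where(np.isnan(dcis_end), False, a < dcis_end)
        )
        dcis_hit = attend & in_dcis_window & (u_dcis < test.dcis_sensitivity)

        with np.errstate(invalid="ignore"):
            inv_detectable = has_invasive_phase & (t_detect <= a)
        inv_hit = attend & inv_detectable & ~dcis_hit

        hit = dcis_hit | inv_hit
        detect_age[hit] = a
        detect_is_dcis[dcis_hit] = True

        negative = attend & ~hit
        if fp_mode == "expected":
            fp_weight[k][negative] = 1.0 - test.specificity
        else:
            fp_weight[k][negative & (u_fp < 1.0 - test.specificity)] = 1.0

    course = _resolve_screened_course(cohort, control, detect_age, detect_is_dcis)
    return ScreenedOutcome(
        course=course,
        screen_ages=ages,
        attended=attended,
        fp_weight=fp_weight,
        test=test,
        policy=policy,
    )


def _resolve_screened_course(
    cohort: Cohort,
    control: CourseOutcomes,
    detect_age: np.ndarray,
    detect_is_dcis: np.ndarray,
) -> CourseOutcomes:
    """Overlay screen detections on the control universe."""
    course = control.copy()
    detected = ~np.isnan(detect_age)

    # DCIS screen detections: diagnosed in situ and removed -> cured
    d = detected & detect_is_dcis
    course.diagnosis_age[d] = detect_age[d]
    course.diagnosis_mode[d] = MODE_SCREEN_DCIS
    course.stage[d] = stage_at_diagnosis(0.0, True)
    course.diagnosis_diameter[d] = np.nan
    course.bc_death_age[d] = np.nan
    course.death_age[d] = cohort.age_other_cause_death[d]
    course.death_cause[d] = CAUSE_OTHER

    # invasive screen detections: re-stage at the detection diameter; cured
    # iff caught below the fatal diameter
    i = detected & ~detect_is_dcis
    if i.any():
        start = cohort.invasive_start_age
        diam = ONSET_DIAMETER * np.exp(cohort.growth_rate[i] * (detect_age[i] - start[i]))
        course.diagnosis_age[i] = detect_age[i]
        course.diagnosis_mode[i] = MODE_SCREEN_INVASIVE
        course.stage[i] = stage_at_diagnosis(diam, False, cohort.params.stage_thresholds)
        course.diagnosis_diameter[i] = diam
        cured = np.zeros(len(cohort), dtype=bool)
        cured[i] = diam < cohort.d_fatal[i]
        cured &= i
        course.bc_death_age[cured] = np.nan
        course.death_age[cured] = cohort.age_other_cause_death[cured]
        course.death_cause[cured] = CAUSE_OTHER
        # not cured: the control universe's breast-cancer death stands

    return course


# ---------------------------------------------------------------------------
# Detection counting and the sensitivity conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionCounts:
    """Cancers diagnosed inside the counting window, by mode and pathology."""

    invasive_screen: int
    invasive_interval: int
    dcis_screen: int
    dcis_interval: int

    @property
    def total(self) -> int:
        return self.invasive_screen + self.invasive_interval + self.dcis_screen + self.dcis_interval


def classify_cancers(course: CourseOutcomes, window: tuple[float, float] = (50.0, 75.0)) -> DetectionCounts:
    """Count diagnosed cancers with diagnosis age in [window); default ages 50-74.

    Screen-detected cancers are those diagnosed at a screen; everything else
    diagnosed in the window (clinically surfacing, i.e. interval cancers for
    screened women) counts as interval/clinical.  False positives never enter
    these counts.
    """
    lo, hi = window
    in_window = np.isfinite(course.diagnosis_age) & (course.diagnosis_age >= lo) & (course.diagnosis_age < hi)
    mode = course.diagnosis_mode
    from .natural_history import MODE_CLINICAL_DCIS, MODE_CLINICAL_INVASIVE

    return DetectionCounts(
        invasive_screen=int((in_window & (mode == MODE_SCREEN_INVASIVE)).sum()),
        invasive_interval=int((in_window & (mode == MODE_CLINICAL_INVASIVE)).sum()),
        dcis_screen=int((in_window & (mode == MODE_SCREEN_DCIS)).sum()),
        dcis_interval=int((in_window & (mode == MODE_CLINICAL_DCIS)).sum()),
    )


def _pct(num: int, den: int) -> int:
    # round-half-up to integer percent, the convention of the published tables
    return int(np.floor(100.0 * num / den + 0.5)) if den > 0 else 0


def compute_sensitivities(counts: DetectionCounts) -> tuple[int, int, int]:
    """Convert detection counts into (DCIS, invasive, combined) screen-detected
    percentages, each rounded to integer percent.

    This is the conversion currency for comparing modalities: the share of
    cancers diagnosed at ages 50-74 that were found by screening.  A
    pathology with no cancers at all reports 0 for its own percentage.
    """
    if counts.total == 0:
        raise ValueError("no cancers in counts; sensitivities are undefined")
    dcis = _pct(counts.dcis_screen, counts.dcis_screen + counts.dcis_interval)
    invasive = _pct(counts.invasive_screen, counts.invasive_screen + counts.invasive_interval)
    combined = _pct(counts.dcis_screen + counts.invasive_screen, counts.total)
    return dcis, invasive, combined


def detection_table(counts: DetectionCounts, test: TestCharacteristics) -> pd.DataFrame:
    """One table row in the published detection-proportion layout."""
    dcis, invasive, combined = compute_sensitivities(counts)
    return pd.DataFrame(
        [
            {
                "dcis_sensitivity_pct": round(100 * test.dcis_sensitivity),
                "median_detect_size_cm": test.median_detect_size,
                "invasive_screen": counts.invasive_screen,
                "invasive_interval": counts.invasive_interval,
                "dcis_screen": counts.dcis_screen,
                "dcis_interval": counts.dcis_interval,
                "dcis_pct": dcis,
                "invasive_pct": invasive,
                "combined_pct": combined,
            }
        ]
    )
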