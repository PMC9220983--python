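"""Resolution of each life history in the no-screening (control) universe.

The cure mechanism is the fatal-diameter model: a tumor diagnosed while its
diameter is still below the woman's fatal diameter is cured (she dies of
other causes); a tumor that crosses its fatal diameter before diagnosis has
already sealed her fate — breast-cancer death follows the crossing by a
sampled survival time, censored only by other-cause death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    FATE_CLINICAL_DCIS,
    ONSET_DIAMETER,
    Cohort,
    LifeHistory,
    crossing_ages,
)
from .config import DomainError

# diagnosis modes
MODE_NONE = 0
MODE_CLINICAL_INVASIVE = 1
MODE_CLINICAL_DCIS = 2
MODE_SCREEN_INVASIVE = 3
MODE_SCREEN_DCIS = 4

MODE_NAMES = {
    MODE_NONE: "none",
    MODE_CLINICAL_INVASIVE: "clinical_invasive",
    MODE_CLINICAL_DCIS: "clinical_dcis",
    MODE_SCREEN_INVASIVE: "screen_invasive",
    MODE_SCREEN_DCIS: "screen_dcis",
}

# stages
STAGE_ABSENT = -1
STAGE_IN_SITU = 0
STAGE_LOCAL = 1
STAGE_REGIONAL = 2
STAGE_DISTANT = 3

STAGE_NAMES = {
    STAGE_ABSENT: "",
    STAGE_IN_SITU: "in_situ",
    STAGE_LOCAL: "local",
    STAGE_REGIONAL: "regional",
    STAGE_DISTANT: "distant",
}

CAUSE_OTHER = 0
CAUSE_BREAST_CANCER = 1


def stage_at_diagnosis(diameter, is_dcis=False, thresholds=(2.0, 5.0)):
    """Stage from diameter at diagnosis: in situ for DCIS, else T-size bins.

    Boundaries are half-open and lower-inclusive: diameter < lo -> local,
    lo <= diameter < hi -> regional, diameter >= hi -> distant.
    Scalar in, scalar out; arrays broadcast.
    """
    diameter = np.asarray(diameter, dtype=float)
    is_dcis = np.asarray(is_dcis)
    if np.any(~is_dcis & (diameter < 0)):
        raise DomainError("negative diameter")
    lo, hi = thresholds
    stage = np.full(np.broadcast(diameter, is_dcis).shape, STAGE_LOCAL, dtype=np.int8)
    stage = np.where(diameter >= lo, STAGE_REGIONAL, stage)
    stage = np.where(diameter >= hi, STAGE_DISTANT, stage)
    stage = np.where(is_dcis, STAGE_IN_SITU, stage)
    if stage.ndim == 0:
        return int(stage)
    return stage


@dataclass
class CourseOutcomes:
    """Per-woman outcome arrays for one universe (control or screened)."""

    diagnosis_age: np.ndarray       # NaN when never diagnosed
    diagnosis_mode: np.ndarray      # int8 MODE_* codes
    stage: np.ndarray               # int8 STAGE_* codes
    diagnosis_diameter: np.ndarray  # cm at diagnosis; NaN for DCIS / no diagnosis
    bc_death_age: np.ndarray        # NaN when no breast-cancer death
    death_age: np.ndarray
    death_cause: np.ndarray         # int8 CAUSE_* codes

    def __len__(self) -> int:
        return self.death_age.shape[0]

    @property
    def diagnosed(self) -> np.ndarray:
        return self.diagnosis_mode != MODE_NONE

    def copy(self) -> "CourseOutcomes":
        return CourseOutcomes(*(getattr(self, f).copy() for f in self.__dataclass_fields__))

    def to_frame(self, prefix: str = "") -> pd.DataFrame:
        mode = np.array([MODE_NAMES[m] for m in self.diagnosis_mode.tolist()], dtype=object)
        stage = np.array([STAGE_NAMES[s] for s in self.stage.tolist()], dtype=object)
        cause = np.where(self.death_cause == CAUSE_BREAST_CANCER, "breast_cancer", "other")
        return pd.DataFrame(
            {
                f"{prefix}diagnosis_age": self.diagnosis_age,
                f"{prefix}diagnosis_mode": mode,
                f"{prefix}stage": stage,
                f"{prefix}diagnosis_diameter": self.diagnosis_diameter,
                f"{prefix}bc_death_age": self.bc_death_age,
                f"{prefix}death_age": self.death_age,
                f"{prefix}death_cause": cause,
            }
        )


def natural_course(history_or_cohort) -> CourseOutcomes | dict:
    """Resolve the without-intervention universe.

    Accepts a full :class:`Cohort` (vectorised; returns
    :class:`CourseOutcomes`) or a single :class:`LifeHistory` (returns a
    plain dict with named fields, convenient in tests).
    """
    if isinstance(history_or_cohort, LifeHistory):
        return _single_course(history_or_cohort)
    return _cohort_course(history_or_cohort)


def _cohort_course(cohort: Cohort) -> CourseOutcomes:
    n = len(cohort)
    ocd = cohort.age_other_cause_death
    inf = np.inf

    # clinical surfacing age: invasive tumors surface at d_clinical, clinical
    # DCIS surfaces at the end of its dwell, regressing DCIS never surfaces
    t_clin = np.full(n, inf)
    t_clin_inv = crossing_ages(cohort, cohort.d_clinical)
    has_inv = ~np.isnan(t_clin_inv)
    t_clin[has_inv] = t_clin_inv[has_inv]
    is_clin_dcis = cohort.dcis_fate == FATE_CLINICAL_DCIS
    t_clin[is_clin_dcis] = (cohort.age_at_onset + cohort.dcis_dwell)[is_clin_dcis]

    # fatal crossing (invasive phase only)
    t_fatal = np.full(n, inf)
    t_fatal_inv = crossing_ages(cohort, cohort.d_fatal)
    t_fatal[has_inv] = t_fatal_inv[has_inv]

    # cure iff clinical diagnosis strictly precedes the fatal crossing
    fatal_first = np.isfinite(t_fatal) & (t_fatal <= t_clin)
    bc_death_raw = np.where(fatal_first, t_fatal + cohort.survival_after_fatal, inf)

    death_age = np.minimum(ocd, bc_death_raw)
    death_cause = np.where(bc_death_raw < ocd, CAUSE_BREAST_CANCER, CAUSE_OTHER).astype(np.int8)

    diagnosed = t_clin < death_age
    diagnosis_age = np.where(diagnosed, t_clin, np.nan)
    mode = np.where(diagnosed, np.where(is_clin_dcis, MODE_CLINICAL_DCIS, MODE_CLINICAL_INVASIVE), MODE_NONE).astype(np.int8)
    diam = np.where(diagnosed & ~is_clin_dcis, cohort.d_clinical, np.nan)

    stage = np.full(n, STAGE_ABSENT, dtype=np.int8)
    any_dx = diagnosed
    stage[any_dx] = stage_at_diagnosis(
        np.nan_to_num(diam[any_dx]), is_clin_dcis[any_dx], cohort.params.stage_thresholds
    )

    # censored by other-cause death: no BC death recorded if OCD comes first
    bc_death_age = np.where(death_cause == CAUSE_BREAST_CANCER, bc_death_raw, np.nan)

    return CourseOutcomes(
        diagnosis_age=diagnosis_age,
        diagnosis_mode=mode,
        stage=stage,
        diagnosis_diameter=diam,
        bc_death_age=bc_death_age,
        death_age=death_age,
        death_cause=death_cause,
    )


def _single_course(history: LifeHistory) -> dict:
    """Scalar resolution of one life history (reference path for tests)."""
    t = history.tumor
    out = {
        "diagnosis_age": None,
        "diagnosis_mode": "none",
        "stage_at_diagnosis": None,
        "bc_death_age": None,
        "death_age": history.age_other_cause_death,
        "death_cause": "other",
    }
    if t is None:
        return out
    import math

    ocd = history.age_other_cause_death
    t_clin = math.inf
    t_fatal = math.inf
    is_clin_dcis = False
    if t.starts_as_dcis and t.dcis_fate == "regress":
        return out
    if t.starts_as_dcis and t.dcis_fate == "clinical_dcis":
        t_clin = t.age_at_onset + t.dcis_dwell
        is_clin_dcis = True
    else:
        start = t.age_at_onset + (t.dcis_dwell if t.starts_as_dcis else 0.0)
        t_clin = start + math.log(t.d_clinical / ONSET_DIAMETER) / t.growth_rate
        t_fatal = start + math.log(t.d_fatal / ONSET_DIAMETER) / t.growth_rate

    bc_death_raw = t_fatal + t.survival_after_fatal if t_fatal <= t_clin else math.inf
    death_age = min(ocd, bc_death_raw)
    if bc_death_raw < ocd:
        out["death_cause"] = "breast_cancer"
        out["bc_death_age"] = bc_death_raw
    out["death_age"] = death_age
    if t_clin < death_age:
        out["diagnosis_age"] = t_clin
        out["diagnosis_mode"] = "clinical_dcis" if is_clin_dcis else "clinical_invasive"
        stage = stage_at_diagnosis(0.0 if is_clin_dcis else t.d_clinical, is_clin_dcis)
        out["stage_at_diagnosis"] = STAGE_NAMES[stage]
    return out


def export_paired_courses(control: CourseOutcomes, screened: CourseOutcomes) -> pd.DataFrame:
    """Side-by-side audit export of both universes, one row per woman."""
    frame = pd.concat([control.to_frame("control_"), screened.to_frame("screened_")], axis=1)
    frame.insert(0, "woman_id", np.arange(len(control)))
    return frame
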