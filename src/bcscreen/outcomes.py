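"""Health outcomes: discounted life-years, QALY decrements, overdiagnoses,
and the paired-universe benefit/harm summary per 1000 women.

Life-years run from age 30 (where outcome counting starts) to death and are
discounted at the economics layer's annual rate.  Quality adjustments are
additive decrements, (1 - utility) x duration: short events (a screen, a
diagnostic work-up, a false positive) are point-discounted at their event
age; care phases are accrued continuously over their interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import ConfigError, ContractViolation
from .economics import (
    DEFAULT_DISCOUNT_RATE,
    DEFAULT_REFERENCE_AGE,
    STAGE_ORDER,
    care_phase_durations,
    discount_factor,
    discounted_duration,
)
from .natural_history import (
    CAUSE_BREAST_CANCER,
    MODE_CLINICAL_DCIS,
    MODE_CLINICAL_INVASIVE,
    MODE_SCREEN_DCIS,
    MODE_SCREEN_INVASIVE,
    CourseOutcomes,
)
from .screening import ScreenedOutcome

WEEK = 1.0 / 52.0

QALY_COMPONENTS = ("screening", "tp_followup", "fp", "clinical_detection", "bc_care")


# ---------------------------------------------------------------------------
# Utility table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtilityTable:
    """Utility weights and durations for screening-pathway health states."""

    screening_utility: float = 0.994
    screening_weeks: float = 1.0
    workup_utility: float = 0.895
    workup_weeks: float = 5.0
    phase_utilities: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_PHASE_UTILITIES)
    )

    def validate(self) -> None:
        for name in ("screening_utility", "workup_utility"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"utility table: {name} must lie in (0, 1], got {v}")
        for stage in STAGE_ORDER:
            for phase in ("initial", "continuous", "terminal", "terminal_ocd"):
                key = (stage, phase)
                if key not in self.phase_utilities:
                    raise ConfigError(f"utility table: missing utility for {key}")
                u = self.phase_utilities[key]
                if not (0.0 < u <= 1.0):
                    raise ConfigError(f"utility table: utility for {key} must lie in (0, 1], got {u}")

    def phase(self, stage: str, phase: str) -> float:
        return self.phase_utilities[(stage, phase)]


_DEFAULT_PHASE_UTILITIES = {
    ("in_situ", "initial"): 0.90,
    ("in_situ", "continuous"): 0.93,
    ("in_situ", "terminal"): 0.49,
    ("in_situ", "terminal_ocd"): 0.93,
    ("local", "initial"): 0.90,
    ("local", "continuous"): 0.93,
    ("local", "terminal"): 0.49,
    ("local", "terminal_ocd"): 0.93,
    ("regional", "initial"): 0.75,
    ("regional", "continuous"): 0.78,
    ("regional", "terminal"): 0.49,
    ("regional", "terminal_ocd"): 0.78,
    ("distant", "initial"): 0.60,
    ("distant", "continuous"): 0.62,
    ("distant", "terminal"): 0.49,
    ("distant", "terminal_ocd"): 0.62,
}


def load_utility_table(path=None) -> UtilityTable:
    """Read the utility fixture CSV (columns: event, stage, phase, utility,
    duration_weeks)."""
    if path is None:
        with resources.files("bcscreen.data").joinpath("utilities.csv").open("rb") as fh:
            raw = pd.read_csv(fh, dtype={"stage": "string", "phase": "string"})
    else:
        raw = pd.read_csv(path, dtype={"stage": "string", "phase": "string"})

    def event_row(name: str):
        rows = raw[raw["event"] == name]
        if len(rows) != 1:
            raise ConfigError(f"utility table: expected one {name!r} row, found {len(rows)}")
        return float(rows["utility"].iloc[0]), float(rows["duration_weeks"].iloc[0])

    s_u, s_w = event_row("screening")
    w_u, w_w = event_row("workup")
    phases = {
        (str(r.stage), str(r.phase)): float(r.utility)
        for r in raw[raw["event"] == "care"].itertuples()
    }
    table = UtilityTable(
        screening_utility=s_u,
        screening_weeks=s_w,
        workup_utility=w_u,
        workup_weeks=w_w,
        phase_utilities=phases,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Life-years and QALYs
# ---------------------------------------------------------------------------


def life_years(
    course: CourseOutcomes,
    rate: float = DEFAULT_DISCOUNT_RATE,
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> float:
    """Population total of discounted life-years lived from the reference age."""
    return float(discounted_duration(reference_age, course.death_age, rate, reference_age).sum())


def qaly_components(
    course: CourseOutcomes,
    screened: Optional[ScreenedOutcome],
    utilities: UtilityTable,
    rate: float = DEFAULT_DISCOUNT_RATE,
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> dict:
    """Discounted QALY ledger (population totals, not per-1000).

    Returns life_years, the five decrement components, their sum
    ``total_decrement``, and ``qalys`` = life_years - total_decrement.
    ``screened`` is None for the no-screening universe (whose screening and
    false-positive decrements are zero by construction).
    """
    utilities.validate()
    n = len(course)
    ly = life_years(course, rate, reference_age)

    dec = {k: 0.0 for k in QALY_COMPONENTS}
    screen_loss = (1.0 - utilities.screening_utility) * utilities.screening_weeks * WEEK
    workup_loss = (1.0 - utilities.workup_utility) * utilities.workup_weeks * WEEK

    if screened is not None:
        df_round = discount_factor(screened.screen_ages, rate, reference_age)
        dec["screening"] = screen_loss * float((screened.attended.sum(axis=1) * df_round).sum())
        dec["fp"] = workup_loss * float((screened.fp_weight.sum(axis=1) * df_round).sum())

    dx = course.diagnosis_age
    diagnosed = np.isfinite(dx)
    if diagnosed.any():
        df_dx = discount_factor(np.maximum(np.nan_to_num(dx), reference_age), rate, reference_age)
        screen_dx = diagnosed & np.isin(course.diagnosis_mode, (MODE_SCREEN_DCIS, MODE_SCREEN_INVASIVE))
        clin_dx = diagnosed & np.isin(course.diagnosis_mode, (MODE_CLINICAL_DCIS, MODE_CLINICAL_INVASIVE))
        dec["tp_followup"] = workup_loss * float(df_dx[screen_dx].sum())
        dec["clinical_detection"] = workup_loss * float(df_dx[clin_dx].sum())

        _, initial, continuous, terminal = care_phase_durations(course)
        dxa = np.nan_to_num(dx)
        death = course.death_age
        bc_death = course.death_cause == CAUSE_BREAST_CANCER
        care = 0.0
        for code, stage in enumerate(STAGE_ORDER):
            sel = diagnosed & (course.stage == code)
            if not sel.any():
                continue
            u_init = utilities.phase(stage, "initial")
            u_cont = utilities.phase(stage, "continuous")
            loss_init = (1.0 - u_init) * discounted_duration(
                dxa[sel], dxa[sel] + initial[sel], rate, reference_age
            )
            loss_cont = (1.0 - u_cont) * discounted_duration(
                dxa[sel] + 1.0, dxa[sel] + 1.0 + continuous[sel], rate, reference_age
            )
            u_term = np.where(
                bc_death[sel], utilities.phase(stage, "terminal"), utilities.phase(stage, "terminal_ocd")
            )
            loss_term = (1.0 - u_term) * discounted_duration(
                death[sel] - terminal[sel], death[sel], rate, reference_age
            )
            care += float((loss_init + loss_cont + loss_term).sum())
        dec["bc_care"] = care

    total_dec = sum(dec.values())
    return {
        "life_years": ly,
        **dec,
        "total_decrement": total_dec,
        "qalys": ly - total_dec,
        "n": n,
    }


def qalys(
    course: CourseOutcomes,
    screened: Optional[ScreenedOutcome],
    utilities: UtilityTable,
    rate: float = DEFAULT_DISCOUNT_RATE,
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> float:
    """Population total of discounted quality-adjusted life-years."""
    return qaly_components(course, screened, utilities, rate, reference_age)["qalys"]


# ---------------------------------------------------------------------------
# Paired-universe benefits and harms
# ---------------------------------------------------------------------------


def count_bc_deaths(course: CourseOutcomes) -> int:
    return int((course.death_cause == CAUSE_BREAST_CANCER).sum())


def mortality_reduction(screened_deaths: int, control_deaths: int) -> float:
    """Percent reduction in breast-cancer deaths versus no screening."""
    if control_deaths <= 0:
        raise ValueError("mortality reduction undefined: no breast-cancer deaths in the control arm")
    return 100.0 * (1.0 - screened_deaths / control_deaths)


def count_overdiagnoses(control: CourseOutcomes, screened: CourseOutcomes, per: float = 1000.0) -> float:
    """Screen-initiated diagnoses of cancers that would never have surfaced.

    A diagnosis in the screened universe counts as an overdiagnosis when the
    same woman's unscreened history shows neither a clinical diagnosis nor a
    breast-cancer death before she dies of other causes — i.e. the cancer
    would not have caused symptoms or death.  Per 1000 women simulated.
    """
    if len(control) != len(screened):
        raise ContractViolation("control and screened universes must pair the same women")
    harmless_in_control = ~control.diagnosed & (control.death_cause != CAUSE_BREAST_CANCER)
    over = screened.diagnosed & harmless_in_control
    return float(over.sum()) * per / len(control)


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-1000-women benefits and harms of one screening scenario."""

    mortality_reduction_pct: float
    false_positives_per_1000: float
    overdiagnoses_per_1000: float
    life_years_gained_per_1000: float
    qalys_gained_per_1000: float
    decrements_per_1000: Mapping[str, float]  # screened-arm QALY decrements by component
    bc_deaths_control: int
    bc_deaths_screened: int


def summarize_outcomes(
    control: CourseOutcomes,
    screened: ScreenedOutcome,
    utilities: UtilityTable,
    rate: float = DEFAULT_DISCOUNT_RATE,
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> OutcomeSummary:
    """Aggregate one paired (control, screened) run into per-1000 outcomes."""
    n = len(control)
    per1000 = 1000.0 / n
    deaths_c = count_bc_deaths(control)
    deaths_s = count_bc_deaths(screened.course)

    q_control = qaly_components(control, None, utilities, rate, reference_age)
    q_screen = qaly_components(screened.course, screened, utilities, rate, reference_age)

    return OutcomeSummary(
        mortality_reduction_pct=mortality_reduction(deaths_s, deaths_c),
        false_positives_per_1000=float(screened.fp_weight.sum()) * per1000,
        overdiagnoses_per_1000=count_overdiagnoses(control, screened.course),
        life_years_gained_per_1000=(q_screen["life_years"] - q_control["life_years"]) * per1000,
        qalys_gained_per_1000=(q_screen["qalys"] - q_control["qalys"]) * per1000,
        decrements_per_1000={k: q_screen[k] * per1000 for k in QALY_COMPONENTS},
        bc_deaths_control=deaths_c,
        bc_deaths_screened=deaths_s,
    )
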