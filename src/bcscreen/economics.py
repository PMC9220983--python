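"""Costing, discounting, incremental cost-effectiveness, and threshold pricing.

All costs are 2020 USD from a federal payer perspective.  Events are
discounted at an annual rate (default 3%) to a fixed reference age (default
30, the age at which outcomes start being counted).  Per-test price enters
total cost affinely — total_cost(price) = total_cost(0) + price * S with S
the discounted screen count — which gives the threshold-price solver a
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import ConfigError, DomainError
from .natural_history import (
    CAUSE_BREAST_CANCER,
    MODE_CLINICAL_DCIS,
    MODE_CLINICAL_INVASIVE,
    MODE_SCREEN_DCIS,
    MODE_SCREEN_INVASIVE,
    STAGE_NAMES,
    CourseOutcomes,
)
from .screening import ScreenedOutcome

DEFAULT_DISCOUNT_RATE = 0.03
DEFAULT_REFERENCE_AGE = 30.0
DEFAULT_THRESHOLD = 50_000.0  # USD per QALY


# ---------------------------------------------------------------------------
# Discounting
# ---------------------------------------------------------------------------


def discount(amount, event_age, rate: float = DEFAULT_DISCOUNT_RATE, reference_age: float = DEFAULT_REFERENCE_AGE):
    """Present value at ``reference_age`` of ``amount`` incurred at ``event_age``.

    amount / (1 + rate)^(event_age - reference_age).  Scalars or arrays.
    """
    event_age = np.asarray(event_age, dtype=float)
    if np.any(event_age < reference_age - 1e-9):
        raise DomainError("event_age precedes reference_age")
    out = np.asarray(amount, dtype=float) * (1.0 + rate) ** -(event_age - reference_age)
    return float(out) if out.ndim == 0 else out


def discount_factor(event_age, rate: float = DEFAULT_DISCOUNT_RATE, reference_age: float = DEFAULT_REFERENCE_AGE):
    return (1.0 + rate) ** -(np.asarray(event_age, dtype=float) - reference_age)


def discounted_duration(start_age, end_age, rate: float = DEFAULT_DISCOUNT_RATE, reference_age: float = DEFAULT_REFERENCE_AGE):
    """∫ over [start, end] of the discount factor: the present value of one
    unit per year accrued continuously over the interval.  With rate 0 this
    is the raw duration."""
    start_age = np.asarray(start_age, dtype=float)
    end_age = np.asarray(end_age, dtype=float)
    if rate == 0.0:
        return np.maximum(end_age - start_age, 0.0)
    log1p = math.log1p(rate)
    f0 = discount_factor(np.maximum(start_age, reference_age), rate, reference_age)
    f1 = discount_factor(np.maximum(end_age, reference_age), rate, reference_age)
    return np.maximum(f0 - f1, 0.0) / log1p


# ---------------------------------------------------------------------------
# Cost table
# ---------------------------------------------------------------------------


AGE_BANDS = ((50.0, 65.0), (65.0, 75.0), (75.0, 101.0))


def _band_lookup(values: tuple[float, float, float], ages: np.ndarray) -> np.ndarray:
    """Map ages to the (50-64, 65-74, 75-100) banded values; ages below 50
    use the first band, above 100 the last."""
    ages = np.asarray(ages, dtype=float)
    out = np.full(ages.shape, values[0], dtype=float)
    out[ages >= AGE_BANDS[1][0]] = values[1]
    out[ages >= AGE_BANDS[2][0]] = values[2]
    return out


@dataclass(frozen=True)
class CostTable:
    """Event costs in 2020 USD, keyed as in the published cost inputs."""

    screen_cost: float = 149.0                       # comparator (mammography) per-test cost
    fp_imaging: float = 152.0                        # every false positive gets follow-up imaging
    fp_biopsy: tuple[float, float, float] = (1455.0, 1463.0, 1550.0)   # by age band
    fp_biopsy_fraction: float = 0.106                # share of FPs that also get a biopsy
    tp_diagnostics: tuple[float, float, float] = (2316.0, 2329.0, 1964.0)  # by age band
    care_costs: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_CARE_COSTS)
    )  # (stage, phase) -> USD; continuous is per year, the others are lump sums

    def validate(self) -> None:
        flat = [self.screen_cost, self.fp_imaging, self.fp_biopsy_fraction, *self.fp_biopsy, *self.tp_diagnostics]
        if any(v < 0 for v in flat):
            raise ConfigError("cost table: all costs must be non-negative")
        stages = [s for s in STAGE_NAMES.values() if s]
        for stage in stages:
            for phase in ("initial", "continuous", "terminal", "terminal_ocd"):
                if (stage, phase) not in self.care_costs:
                    raise ConfigError(f"cost table: missing care cost for ({stage}, {phase})")

    def care(self, stage: str, phase: str) -> float:
        try:
            return self.care_costs[(stage, phase)]
        except KeyError:
            raise ConfigError(f"cost table: no entry for stage={stage!r} phase={phase!r}") from None


_DEFAULT_CARE_COSTS = {
    ("in_situ", "initial"): 14_848.0,
    ("in_situ", "continuous"): 1_336.0,
    ("in_situ", "terminal"): 56_995.0,
    ("in_situ", "terminal_ocd"): 7_879.0,
    ("local", "initial"): 24_240.0,
    ("local", "continuous"): 2_306.0,
    ("local", "terminal"): 59_550.0,
    ("local", "terminal_ocd"): 6_332.0,
    ("regional", "initial"): 41_352.0,
    ("regional", "continuous"): 4_474.0,
    ("regional", "terminal"): 64_516.0,
    ("regional", "terminal_ocd"): 10_762.0,
    ("distant", "initial"): 55_985.0,
    ("distant", "continuous"): 19_212.0,
    ("distant", "terminal"): 81_656.0,
    ("distant", "terminal_ocd"): 20_081.0,
}


def load_cost_table(path=None) -> CostTable:
    """Read the cost fixture CSV (columns: item, stage, phase, age_group, value)."""
    if path is None:
        with resources.files("bcscreen.data").joinpath("costs.csv").open("rb") as fh:
            raw = pd.read_csv(fh, dtype={"stage": "string", "phase": "string", "age_group": "string"})
    else:
        raw = pd.read_csv(path, dtype={"stage": "string", "phase": "string", "age_group": "string"})

    def banded(item: str) -> tuple[float, float, float]:
        rows = raw[raw["item"] == item].set_index("age_group")["value"]
        return tuple(float(rows[g]) for g in ("50-64", "65-74", "75-100"))

    def scalar(item: str) -> float:
        rows = raw[raw["item"] == item]
        if len(rows) != 1:
            raise ConfigError(f"cost table: expected one {item!r} row, found {len(rows)}")
        return float(rows["value"].iloc[0])

    care = {
        (str(r.stage), str(r.phase)): float(r.value)
        for r in raw[raw["item"] == "care"].itertuples()
    }
    table = CostTable(
        screen_cost=scalar("screen"),
        fp_imaging=scalar("fp_imaging"),
        fp_biopsy=banded("fp_biopsy"),
        fp_biopsy_fraction=scalar("fp_biopsy_fraction"),
        tp_diagnostics=banded("tp_diagnostics"),
        care_costs=care,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Phase-of-care durations (shared with the QALY layer)
# ---------------------------------------------------------------------------


def care_phase_durations(course: CourseOutcomes):
    """Initial / continuous / terminal durations for every diagnosed woman.

    The initial phase is the first 12 months after diagnosis, the terminal
    phase the last 12 months of life, continuous the time between; for a
    survival shorter than two years the phases are truncated so that they
    always partition diagnosis-to-death exactly.
    """
    dx = course.diagnosis_age
    diagnosed = np.isfinite(dx)
    span = np.where(diagnosed, course.death_age - dx, 0.0)
    span = np.maximum(span, 0.0)
    initial = np.minimum(span, 1.0)
    terminal = np.clip(span - 1.0, 0.0, 1.0)
    continuous = np.maximum(span - 2.0, 0.0)
    return diagnosed, initial, continuous, terminal


# ---------------------------------------------------------------------------
# Total cost
# ---------------------------------------------------------------------------


STAGE_ORDER = ("in_situ", "local", "regional", "distant")


def total_cost(
    course: CourseOutcomes,
    screened: Optional[ScreenedOutcome],
    costs: CostTable,
    test_price: float,
    rate: float = DEFAULT_DISCOUNT_RATE,
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> dict:
    """Discounted cost ledger for one universe, per 1000 women simulated.

    Returns a dict with components {screening, fp, tp_followup,
    clinical_detection, bc_care}, their sum ``total``, and
    ``discounted_screens_per_1000`` (the slope of total cost in the per-test
    price).  ``screened`` is None for the no-screening universe.
    """
    costs.validate()
    n = len(course)
    per1000 = 1000.0 / n

    comp = {k: 0.0 for k in ("screening", "fp", "tp_followup", "clinical_detection", "bc_care")}
    discounted_screens = 0.0

    if screened is not None:
        ages = screened.screen_ages
        df_round = discount_factor(ages, rate, reference_age)
        n_att = screened.attended.sum(axis=1).astype(float)
        discounted_screens = float((n_att * df_round).sum())
        comp["screening"] = test_price * discounted_screens

        fp_per_round = screened.fp_weight.sum(axis=1)
        fp_unit = costs.fp_imaging + costs.fp_biopsy_fraction * _band_lookup(costs.fp_biopsy, ages)
        comp["fp"] = float((fp_per_round * fp_unit * df_round).sum())

    # diagnostic work-up at diagnosis, split screen-detected vs clinical
    dx = course.diagnosis_age
    mode = course.diagnosis_mode
    diagnosed = np.isfinite(dx)
    if diagnosed.any():
        diag_cost = _band_lookup(costs.tp_diagnostics, np.nan_to_num(dx)) * discount_factor(
            np.maximum(np.nan_to_num(dx), reference_age), rate, reference_age
        )
        screen_dx = diagnosed & np.isin(mode, (MODE_SCREEN_DCIS, MODE_SCREEN_INVASIVE))
        clin_dx = diagnosed & np.isin(mode, (MODE_CLINICAL_DCIS, MODE_CLINICAL_INVASIVE))
        comp["tp_followup"] = float(diag_cost[screen_dx].sum())
        comp["clinical_detection"] = float(diag_cost[clin_dx].sum())

    # stage- and phase-specific care costs
    diagnosed, initial, continuous, terminal = care_phase_durations(course)
    if diagnosed.any():
        dxa = np.nan_to_num(course.diagnosis_age)
        death = course.death_age
        bc_death = course.death_cause == CAUSE_BREAST_CANCER
        care = np.zeros(n)
        for code, stage in enumerate(STAGE_ORDER):
            sel = diagnosed & (course.stage == code)
            if not sel.any():
                continue
            init_cost = costs.care(stage, "initial") * discount_factor(dxa[sel], rate, reference_age)
            cont_cost = costs.care(stage, "continuous") * discounted_duration(
                dxa[sel] + 1.0, dxa[sel] + 1.0 + continuous[sel], rate, reference_age
            )
            term_price = np.where(bc_death[sel], costs.care(stage, "terminal"), costs.care(stage, "terminal_ocd"))
            term_cost = term_price * discount_factor(
                np.maximum(death[sel] - terminal[sel], reference_age), rate, reference_age
            )
            care[sel] = init_cost + cont_cost + term_cost
        comp["bc_care"] = float(care.sum())

    out = {k: v * per1000 for k, v in comp.items()}
    out["total"] = sum(out[k] for k in comp)
    out["discounted_screens_per_1000"] = discounted_screens * per1000
    return out


# ---------------------------------------------------------------------------
# ICER and threshold pricing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEAResult:
    """Discounted economics of one scenario, per 1000 women."""

    total_cost_per_1000: float
    qalys_per_1000: float
    discounted_screens_per_1000: float
    test_price: float
    cost_components: Mapping[str, float] = field(default_factory=dict)
    icer_vs_comparator: Optional[float] = None
    icer_classification: Optional[str] = None
    max_price: Optional[float] = None


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qalys: float
    value: Optional[float]  # USD per QALY; None when flagged
    classification: str     # "icer" | "dominant" | "dominated" | "equal"


def icer(scenario_cost: float, scenario_qalys: float, comparator_cost: float, comparator_qalys: float) -> ICERResult:
    """Incremental cost-effectiveness versus the comparator.

    Dominant: no dearer and more effective (or cheaper, no less effective).
    Dominated: no cheaper and less effective.  Equal arms are flagged rather
    than divided.
    """
    dc = scenario_cost - comparator_cost
    dq = scenario_qalys - comparator_qalys
    if dc == 0.0 and dq == 0.0:
        return ICERResult(dc, dq, None, "equal")
    if dc <= 0.0 and dq >= 0.0:
        return ICERResult(dc, dq, None, "dominant")
    if dc >= 0.0 and dq <= 0.0:
        return ICERResult(dc, dq, None, "dominated")
    return ICERResult(dc, dq, dc / dq, "icer")


def max_price(
    scenario: CEAResult,
    comparator: CEAResult,
    threshold: float = DEFAULT_THRESHOLD,
) -> Optional[float]:
    """Highest per-test price at which the scenario stays cost-effective.

    Exploits cost's affinity in price: with the scenario costed at its
    reference price P_ref, P* = P_ref + (threshold*ΔQ - ΔC(P_ref)) / S where
    S is the scenario's discounted screen count.  Returns None for scenarios
    with fewer QALYs than the comparator (no acceptable price exists at any
    cost; the published tables report prices only for alternatives with equal
    or greater QALYs).
    """
    dq = scenario.qalys_per_1000 - comparator.qalys_per_1000
    if dq < 0:
        return None
    s = scenario.discounted_screens_per_1000
    if s <= 0:
        raise ValueError("scenario has no discounted screens; price is undefined")
    dc_ref = scenario.total_cost_per_1000 - comparator.total_cost_per_1000
    return scenario.test_price + (threshold * dq - dc_ref) / s


def overdiagnosis_reduction(comparator_rate: float, scenario_rate: float) -> float:
    """Percent reduction in overdiagnoses relative to the comparator."""
    if comparator_rate <= 0:
        raise ValueError("comparator overdiagnosis rate must be positive")
    return 100.0 * (1.0 - scenario_rate / comparator_rate)
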