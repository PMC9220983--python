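"""Health outcomes: overdiagnosis, mortality reduction, discounted QALYs."""

import math

import numpy as np
import pytest

import bcscreen as b
from bcscreen.natural_history import (
    CAUSE_BREAST_CANCER,
    CAUSE_OTHER,
    MODE_CLINICAL_INVASIVE,
    MODE_NONE,
    MODE_SCREEN_DCIS,
    CourseOutcomes,
    STAGE_ABSENT,
    STAGE_IN_SITU,
    STAGE_LOCAL,
)
from bcscreen.outcomes import (
    QALY_COMPONENTS,
    life_years,
    qaly_components,
)
from bcscreen.economics import care_phase_durations
from conftest import SEED


def make_course(rows):
    """Build CourseOutcomes from per-woman dicts (test scaffolding)."""
    n = len(rows)
    course = CourseOutcomes(
        diagnosis_age=np.full(n, np.nan),
        diagnosis_mode=np.full(n, MODE_NONE, dtype=np.int8),
        stage=np.full(n, STAGE_ABSENT, dtype=np.int8),
        diagnosis_diameter=np.full(n, np.nan),
        bc_death_age=np.full(n, np.nan),
        death_age=np.zeros(n),
        death_cause=np.full(n, CAUSE_OTHER, dtype=np.int8),
    )
    for i, row in enumerate(rows):
        for key, value in row.items():
            getattr(course, key)[i] = value
    return course


UTIL = b.UtilityTable()


class TestOverdiagnosis:
    def test_identical_universes_mean_zero(self, control):
        assert b.count_overdiagnoses(control, control) == 0.0

    def test_constructed_trio(self):
        # woman 0: regressing DCIS screen-detected (overdiagnosis);
        # woman 1: interval cancer diagnosed in both universes; woman 2: healthy
        control = make_course(
            [
                {"death_age": 80.0},
                {
                    "diagnosis_age": 60.0,
                    "diagnosis_mode": MODE_CLINICAL_INVASIVE,
                    "stage": STAGE_LOCAL,
                    "death_age": 80.0,
                },
                {"death_age": 85.0},
            ]
        )
        screened = make_course(
            [
                {
                    "diagnosis_age": 62.0,
                    "diagnosis_mode": MODE_SCREEN_DCIS,
                    "stage": STAGE_IN_SITU,
                    "death_age": 80.0,
                },
                {
                    "diagnosis_age": 60.0,
                    "diagnosis_mode": MODE_CLINICAL_INVASIVE,
                    "stage": STAGE_LOCAL,
                    "death_age": 80.0,
                },
                {"death_age": 85.0},
            ]
        )
        assert b.count_overdiagnoses(control, screened) == pytest.approx(1000.0 / 3)

    def test_undiagnosed_fatal_cancer_is_not_overdiagnosis(self):
        # control universe: BC death without diagnosis; a screen detection of
        # that cancer is a (late) true positive, not an overdiagnosis
        control = make_course(
            [{"death_age": 70.0, "death_cause": CAUSE_BREAST_CANCER, "bc_death_age": 70.0}]
        )
        screened = make_course(
            [
                {
                    "diagnosis_age": 66.0,
                    "diagnosis_mode": MODE_CLINICAL_INVASIVE,
                    "stage": STAGE_LOCAL,
                    "death_age": 70.0,
                    "death_cause": CAUSE_BREAST_CANCER,
                    "bc_death_age": 70.0,
                }
            ]
        )
        assert b.count_overdiagnoses(control, screened) == 0.0


class TestMortalityReduction:
    def test_equal_deaths_zero(self):
        assert b.mortality_reduction(1000, 1000) == 0.0

    def test_arithmetic(self):
        assert b.mortality_reduction(750, 1000) == pytest.approx(25.0)

    def test_zero_control_deaths_signalled(self):
        with pytest.raises(ValueError):
            b.mortality_reduction(0, 0)

    def test_counter_matches_ledger_recount(self, control):
        # independent recount from the exported per-woman frame
        frame = control.to_frame()
        ledger_count = int((frame["death_cause"] == "breast_cancer").sum())
        from bcscreen.outcomes import count_bc_deaths

        assert count_bc_deaths(control) == ledger_count


class TestQalys:
    def test_single_screen_decrement_undiscounted(self):
        # one attended screen: (1 - 0.994) x 1/52 year
        course = make_course([{"death_age": 80.0}])
        policy = b.ScreeningPolicy(50, 50, 2)
        screened = b.ScreenedOutcome(
            course=course,
            screen_ages=np.array([50.0]),
            attended=np.array([[True]]),
            fp_weight=np.zeros((1, 1)),
            test=b.MAMMOGRAPHY,
            policy=policy,
        )
        comp = qaly_components(course, screened, UTIL, rate=0.0)
        assert comp["screening"] == pytest.approx(0.006 / 52)
        assert comp["fp"] == 0.0

    def test_terminal_phase_utility_is_049(self):
        for stage in ("in_situ", "local", "regional", "distant"):
            assert UTIL.phase(stage, "terminal") == 0.49

    def test_two_event_ledger_hand_summed(self):
        # one woman: local cancer diagnosed clinically at 40, BC death at 43;
        # hand-computed decrements with 3% discounting to age 30
        course = make_course(
            [
                {
                    "diagnosis_age": 40.0,
                    "diagnosis_mode": MODE_CLINICAL_INVASIVE,
                    "stage": STAGE_LOCAL,
                    "death_age": 43.0,
                    "death_cause": CAUSE_BREAST_CANCER,
                    "bc_death_age": 43.0,
                }
            ]
        )
        comp = qaly_components(course, None, UTIL, rate=0.03)

        log103 = math.log(1.03)

        def df(t):
            return 1.03 ** -(t - 30.0)

        def annuity(t0, t1):
            return (df(t0) - df(t1)) / log103

        ly = annuity(30, 43)
        workup = (1 - 0.895) * (5 / 52) * df(40)
        care = (
            (1 - 0.90) * annuity(40, 41)
            + (1 - 0.93) * annuity(41, 42)
            + (1 - 0.49) * annuity(42, 43)
        )
        assert comp["life_years"] == pytest.approx(ly, abs=1e-12)
        assert comp["clinical_detection"] == pytest.approx(workup, abs=1e-12)
        assert comp["bc_care"] == pytest.approx(care, abs=1e-12)
        assert comp["qalys"] == pytest.approx(ly - workup - care, abs=1e-12)

    def test_zero_rate_reproduces_raw_life_years(self, control):
        raw = np.maximum(control.death_age - 30.0, 0.0).sum()
        assert life_years(control, rate=0.0) == pytest.approx(raw)

    def test_decrement_additivity(self, control, comparator_screened):
        comp = qaly_components(comparator_screened.course, comparator_screened, UTIL)
        total = sum(comp[k] for k in QALY_COMPONENTS)
        assert comp["total_decrement"] == pytest.approx(total, abs=1e-9)
        assert comp["qalys"] == pytest.approx(comp["life_years"] - total, abs=1e-9)

    def test_phase_partition(self, comparator_screened):
        course = comparator_screened.course
        diagnosed, initial, continuous, terminal = care_phase_durations(course)
        span = course.death_age - course.diagnosis_age
        np.testing.assert_allclose(
            (initial + continuous + terminal)[diagnosed], span[diagnosed], atol=1e-12
        )

    def test_qalys_non_decreasing_in_specificity(self, cohort, control):
        gains = []
        for spec in (0.88, 0.96, 1.0):
            t = b.TestCharacteristics(0.91, 1.21, spec)
            s = b.apply_screening(cohort, control, b.ScreeningPolicy(), t, seed=SEED)
            summ = b.summarize_outcomes(control, s, UTIL)
            gains.append(summ.qalys_gained_per_1000)
        assert gains == sorted(gains)


class TestSummary:
    def test_summary_consistency(self, control, comparator_screened):
        summ = b.summarize_outcomes(control, comparator_screened, UTIL)
        n = len(control)
        assert summ.false_positives_per_1000 == pytest.approx(
            comparator_screened.fp_weight.sum() * 1000 / n
        )
        assert summ.overdiagnoses_per_1000 == b.count_overdiagnoses(
            control, comparator_screened.course
        )
        assert summ.mortality_reduction_pct == pytest.approx(
            100 * (1 - summ.bc_deaths_screened / summ.bc_deaths_control)
        )
        # screening benefits both mortality and life-years in this cohort
        assert summ.mortality_reduction_pct > 0
        assert summ.life_years_gained_per_1000 > 0

    def test_utility_fixture_matches_defaults(self):
        loaded = b.load_utility_table()
        assert loaded == UTIL
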