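"""Experiment orchestration: build one cohort, resolve its natural course
once, then run the comparator and every liquid-biopsy scenario on the same
histories with common screening random numbers.

Outputs mirror the published layouts: a detection-proportion table (counts
and screen-detected percentages per scenario), an outcomes table (mortality
reduction, false positives, overdiagnoses, QALYs gained, total costs,
maximum price), and ROC overlay points (FPR = 1 - specificity,
TPR = combined sensitivity).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, NaturalHistoryParams, sample_life_histories
from .config import ConfigError
from .economics import (
    DEFAULT_DISCOUNT_RATE,
    DEFAULT_REFERENCE_AGE,
    DEFAULT_THRESHOLD,
    CEAResult,
    CostTable,
    icer,
    load_cost_table,
    max_price,
    total_cost,
)
from .natural_history import CourseOutcomes, natural_course
from .outcomes import (
    OutcomeSummary,
    UtilityTable,
    load_utility_table,
    qaly_components,
    summarize_outcomes,
)
from .screening import (
    MAMMOGRAPHY,
    DetectionCounts,
    ScreeningPolicy,
    TestCharacteristics,
    apply_screening,
    classify_cancers,
    compute_sensitivities,
)

log = logging.getLogger("bcscreen")

#: Median detection sizes of the default liquid-biopsy grid: the ranged
#: sizes 1.03-1.39 cm in 0.06 steps plus the near-perfect 0.61 and 0.01 cm.
DEFAULT_GRID_SIZES = (1.03, 1.09, 1.15, 1.21, 1.27, 1.33, 1.39, 0.61, 0.01)
DEFAULT_GRID_DCIS = (0.91, 0.0)
DEFAULT_GRID_SPECIFICITIES = (0.88, 0.96, 1.00)


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    test: TestCharacteristics
    policy: ScreeningPolicy = ScreeningPolicy()
    is_comparator: bool = False


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    counts: DetectionCounts
    sensitivities: tuple[int, int, int]  # (dcis, invasive, combined) percent
    summary: OutcomeSummary
    cea: CEAResult
    roc_point: tuple[float, float]       # (FPR, TPR)
    runtime_s: float = 0.0


@dataclass
class RunConfig:
    """Full experiment configuration; loadable from YAML/JSON."""

    n: int = 1_000_000
    seed: int = 20_220_615
    params: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    policy: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    comparator_test: TestCharacteristics = MAMMOGRAPHY
    scenarios: Sequence[ScenarioSpec] = ()
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    reference_age: float = DEFAULT_REFERENCE_AGE
    threshold: float = DEFAULT_THRESHOLD
    fp_mode: str = "expected"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        for key in ("n", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("discount_rate", "reference_age", "threshold"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "fp_mode" in raw:
            kwargs["fp_mode"] = str(raw["fp_mode"])
        if "params" in raw:
            kwargs["params"] = NaturalHistoryParams.from_dict(raw["params"])
        if "policy" in raw:
            kwargs["policy"] = ScreeningPolicy(**{k: float(v) for k, v in raw["policy"].items()})
        if "comparator_test" in raw:
            kwargs["comparator_test"] = TestCharacteristics(**raw["comparator_test"])
        if "costs" in raw:
            kwargs["costs"] = load_cost_table(raw["costs"]) if isinstance(raw["costs"], str) else raw["costs"]
        if "utilities" in raw:
            kwargs["utilities"] = (
                load_utility_table(raw["utilities"]) if isinstance(raw["utilities"], str) else raw["utilities"]
            )
        cfg = cls(**kwargs)
        if "scenarios" in raw:
            specs = []
            for row in raw["scenarios"]:
                test = TestCharacteristics(
                    dcis_sensitivity=float(row["dcis_sensitivity"]),
                    median_detect_size=float(row["median_detect_size"]),
                    specificity=float(row["specificity"]),
                    price=row.get("price"),
                )
                specs.append(ScenarioSpec(label=str(row.get("label") or _grid_label(test)), test=test, policy=cfg.policy))
            cfg.scenarios = tuple(specs)
        else:
            cfg.scenarios = default_grid(cfg.policy)
        return cfg


def _grid_label(test: TestCharacteristics) -> str:
    return (
        f"lb_dcis{round(100 * test.dcis_sensitivity)}"
        f"_size{test.median_detect_size:g}"
        f"_spec{round(100 * test.specificity)}"
    )


def default_grid(policy: ScreeningPolicy = ScreeningPolicy()) -> tuple[ScenarioSpec, ...]:
    """The default liquid-biopsy grid: 2 DCIS sensitivities x 9 median
    detection sizes x 3 specificities (54 scenarios)."""
    specs = []
    for dcis in DEFAULT_GRID_DCIS:
        for size in DEFAULT_GRID_SIZES:
            for spec in DEFAULT_GRID_SPECIFICITIES:
                test = TestCharacteristics(
                    dcis_sensitivity=dcis, median_detect_size=size, specificity=spec, price=None
                )
                specs.append(ScenarioSpec(label=_grid_label(test), test=test, policy=policy))
    return tuple(specs)


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------


def run_scenario(
    spec: ScenarioSpec,
    cohort: Cohort,
    control: CourseOutcomes,
    config: RunConfig,
) -> ScenarioResult:
    """Run one scenario on a prepared cohort/control pair.

    Deterministic given (cohort seed, config seed): all scenarios share the
    cohort's natural history and the config-seeded screening streams, so two
    scenarios differ only through their test characteristics.
    """
    t0 = time.perf_counter()
    price = spec.test.price if spec.test.price is not None else 0.0
    screened = apply_screening(cohort, control, spec.policy, spec.test, config.seed, config.fp_mode)
    counts = classify_cancers(screened.course)
    sens = compute_sensitivities(counts)
    summary = summarize_outcomes(control, screened, config.utilities, config.discount_rate, config.reference_age)
    costs = total_cost(
        screened.course, screened, config.costs, price, config.discount_rate, config.reference_age
    )
    q = qaly_components(screened.course, screened, config.utilities, config.discount_rate, config.reference_age)
    cea = CEAResult(
        total_cost_per_1000=costs["total"],
        qalys_per_1000=summary.qalys_gained_per_1000,
        discounted_screens_per_1000=costs["discounted_screens_per_1000"],
        test_price=price,
        cost_components={k: costs[k] for k in ("screening", "fp", "tp_followup", "clinical_detection", "bc_care")},
    )
    result = ScenarioResult(
        spec=spec,
        counts=counts,
        sensitivities=sens,
        summary=summary,
        cea=cea,
        roc_point=(1.0 - spec.test.specificity, sens[2] / 100.0),
        runtime_s=time.perf_counter() - t0,
    )
    log.info(
        "scenario %s: n=%d seed=%d combined=%d%% mort_red=%.1f%% overdx=%.1f runtime=%.2fs",
        spec.label, len(cohort), config.seed, sens[2],
        summary.mortality_reduction_pct, summary.overdiagnoses_per_1000, result.runtime_s,
    )
    return result


@dataclass
class GridResult:
    comparator: ScenarioResult
    scenarios: list[ScenarioResult]
    config: RunConfig

    @property
    def all_results(self) -> list[ScenarioResult]:
        return [self.comparator, *self.scenarios]


def run_grid(config: RunConfig, cohort: Optional[Cohort] = None) -> GridResult:
    """Run the comparator and every configured scenario on one shared cohort.

    Scenario economics are computed at a reference price of 0 when a price is
    not supplied; the affine price identity then yields the maximum price at
    the cost-effectiveness threshold.  Scenarios with fewer QALYs than the
    comparator carry no maximum price.
    """
    labels = [s.label for s in config.scenarios]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ConfigError(f"duplicate scenario labels: {dupes}")

    if cohort is None:
        cohort = sample_life_histories(config.n, config.params, config.seed)
    control = natural_course(cohort)

    comparator_spec = ScenarioSpec(
        label="digital_mammography", test=config.comparator_test, policy=config.policy, is_comparator=True
    )
    comparator = run_scenario(comparator_spec, cohort, control, config)

    results = []
    for spec in config.scenarios:
        res = run_scenario(spec, cohort, control, config)
        ic = icer(
            res.cea.total_cost_per_1000,
            res.cea.qalys_per_1000,
            comparator.cea.total_cost_per_1000,
            comparator.cea.qalys_per_1000,
        )
        p_star = max_price(res.cea, comparator.cea, config.threshold)
        res.cea = replace(
            res.cea,
            icer_vs_comparator=ic.value,
            icer_classification=ic.classification,
            max_price=p_star,
        )
        results.append(res)
    return GridResult(comparator=comparator, scenarios=results, config=config)


# ---------------------------------------------------------------------------
# Published-table-shaped exports
# ---------------------------------------------------------------------------


def detection_proportion_table(grid: GridResult) -> pd.DataFrame:
    """Detection counts and screen-detected percentages, one row per scenario."""
    rows = []
    for res in grid.all_results:
        dcis, invasive, combined = res.sensitivities
        rows.append(
            {
                "label": res.spec.label,
                "dcis_sensitivity_pct": round(100 * res.spec.test.dcis_sensitivity),
                "median_detect_size_cm": res.spec.test.median_detect_size,
                "invasive_screen": res.counts.invasive_screen,
                "invasive_interval": res.counts.invasive_interval,
                "dcis_screen": res.counts.dcis_screen,
                "dcis_interval": res.counts.dcis_interval,
                "dcis_pct": dcis,
                "invasive_pct": invasive,
                "combined_pct": combined,
            }
        )
    return pd.DataFrame(rows)


def outcomes_table(grid: GridResult) -> pd.DataFrame:
    """Per-1000 outcomes with costs and the maximum cost-effective price.

    Matches the published outcome-table layout: scenarios that yield fewer
    QALYs than the comparator have no maximum price (NaN).
    """
    rows = []
    for res in grid.all_results:
        s = res.summary
        rows.append(
            {
                "label": res.spec.label,
                "combined_sensitivity_pct": res.sensitivities[2],
                "specificity_pct": round(100 * res.spec.test.specificity),
                "mortality_reduction_pct": round(s.mortality_reduction_pct, 1),
                "false_positives_per_1000": round(s.false_positives_per_1000, 1),
                "overdiagnoses_per_1000": round(s.overdiagnoses_per_1000, 1),
                "qalys_gained_per_1000": round(s.qalys_gained_per_1000, 1),
                "total_costs_usd_1000s": round(res.cea.total_cost_per_1000 / 1000.0, 1),
                "max_price_usd": (
                    np.nan
                    if res.spec.is_comparator or res.cea.max_price is None
                    else round(res.cea.max_price, 2)
                ),
            }
        )
    return pd.DataFrame(rows)


def export_roc_points(grid: GridResult) -> pd.DataFrame:
    """ROC overlay points per scenario for plotting against an external
    prediction-model curve.

    TPR is combined sensitivity as a fraction, FPR is 1 - specificity; the
    ``filled`` flag marks scenarios whose mortality reduction is at least the
    comparator's (the filled labels of the published figure).
    """
    comp_mort = grid.comparator.summary.mortality_reduction_pct
    rows = []
    for res in grid.all_results:
        rows.append(
            {
                "label": res.spec.label,
                "fpr": res.roc_point[0],
                "tpr": res.roc_point[1],
                "max_price_usd": np.nan if res.cea.max_price is None else round(res.cea.max_price, 2),
                "filled": bool(res.summary.mortality_reduction_pct >= comp_mort),
            }
        )
    return pd.DataFrame(rows)


def grid_summary_json(grid: GridResult) -> str:
    """Compact machine-readable run summary (seed, n, per-scenario key numbers)."""
    payload = {
        "n": grid.config.n,
        "seed": grid.config.seed,
        "threshold_usd_per_qaly": grid.config.threshold,
        "scenarios": [
            {
                "label": res.spec.label,
                "is_comparator": res.spec.is_comparator,
                "sensitivities_pct": list(res.sensitivities),
                "mortality_reduction_pct": res.summary.mortality_reduction_pct,
                "false_positives_per_1000": res.summary.false_positives_per_1000,
                "overdiagnoses_per_1000": res.summary.overdiagnoses_per_1000,
                "qalys_gained_per_1000": res.summary.qalys_gained_per_1000,
                "total_cost_per_1000": res.cea.total_cost_per_1000,
                "max_price_usd": res.cea.max_price,
                "runtime_s": res.runtime_s,
            }
            for res in grid.all_results
        ],
    }
    return json.dumps(payload, indent=2)
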