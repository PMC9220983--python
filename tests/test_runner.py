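"""Experiment orchestration: shared cohorts, the scenario grid, exports, CLI."""

import json

import numpy as np
import pytest
import yaml

import bcscreen as b
from bcscreen.config import ConfigError
from bcscreen.runner import (
    RunConfig,
    ScenarioSpec,
    default_grid,
    detection_proportion_table,
    export_roc_points,
    grid_summary_json,
    outcomes_table,
    run_grid,
    run_scenario,
)


@pytest.fixture(scope="module")
def small_config():
    return RunConfig.from_dict({"n": 8000, "seed": 5})


@pytest.fixture(scope="module")
def small_grid(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config)
    # a representative 8-scenario slice of the full grid keeps this module fast
    cfg.scenarios = tuple(
        s
        for s in default_grid()
        if s.test.median_detect_size in (1.21, 0.61)
        and s.test.specificity in (0.88, 1.0)
    )
    return run_grid(cfg)


class TestGridExecution:
    def test_rerun_is_identical(self, small_config):
        cohort = b.sample_life_histories(small_config.n, small_config.params, small_config.seed)
        control = b.natural_course(cohort)
        spec = ScenarioSpec(label="x", test=b.MAMMOGRAPHY)
        r1 = run_scenario(spec, cohort, control, small_config)
        r2 = run_scenario(spec, cohort, control, small_config)
        assert r1.counts == r2.counts
        assert r1.summary == r2.summary
        assert r1.cea.total_cost_per_1000 == r2.cea.total_cost_per_1000

    def test_default_grid_enumeration(self):
        grid = default_grid()
        assert len(grid) == 2 * 9 * 3
        assert len({s.label for s in grid}) == len(grid)

    def test_duplicate_labels_rejected(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config)
        spec = ScenarioSpec(label="dup", test=b.MAMMOGRAPHY)
        cfg.scenarios = (spec, spec)
        with pytest.raises(ConfigError, match="dup"):
            run_grid(cfg)

    def test_empty_grid_gives_comparator_only(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config)
        cfg.scenarios = ()
        grid = run_grid(cfg)
        assert grid.scenarios == []
        assert grid.comparator.spec.is_comparator

    def test_scenarios_share_natural_history(self, small_grid):
        # parallel-universe contract: control BC deaths identical across
        # scenarios; only screening effects differ
        controls = {r.summary.bc_deaths_control for r in small_grid.all_results}
        assert len(controls) == 1


class TestTables:
    def test_detection_table_schema(self, small_grid):
        tab = detection_proportion_table(small_grid)
        assert list(tab.columns) == [
            "label",
            "dcis_sensitivity_pct",
            "median_detect_size_cm",
            "invasive_screen",
            "invasive_interval",
            "dcis_screen",
            "dcis_interval",
            "dcis_pct",
            "invasive_pct",
            "combined_pct",
        ]
        assert len(tab) == len(small_grid.scenarios) + 1

    def test_outcomes_table_schema_and_price_filter(self, small_grid):
        tab = outcomes_table(small_grid)
        assert list(tab.columns) == [
            "label",
            "combined_sensitivity_pct",
            "specificity_pct",
            "mortality_reduction_pct",
            "false_positives_per_1000",
            "overdiagnoses_per_1000",
            "qalys_gained_per_1000",
            "total_costs_usd_1000s",
            "max_price_usd",
        ]
        # every row carrying a maximum price yielded at least comparator QALYs
        comp_q = small_grid.comparator.cea.qalys_per_1000
        priced = tab["max_price_usd"].notna()
        assert (tab.loc[priced, "qalys_gained_per_1000"] >= comp_q - 1e-9).all()
        for res in small_grid.scenarios:
            if res.cea.max_price is None:
                assert res.cea.qalys_per_1000 < comp_q

    def test_roc_points(self, small_grid):
        tab = export_roc_points(small_grid)
        for res, row in zip(small_grid.all_results, tab.itertuples()):
            assert row.fpr == pytest.approx(1.0 - res.spec.test.specificity)
            assert row.tpr == pytest.approx(res.sensitivities[2] / 100.0)
        # perfect specificity lands on the ROC y-axis
        perfect = tab[tab["label"].str.contains("spec100")]
        assert (perfect["fpr"] == 0.0).all()
        # filled flag: mortality reduction at least the comparator's
        comp_mort = small_grid.comparator.summary.mortality_reduction_pct
        for res, row in zip(small_grid.all_results, tab.itertuples()):
            assert row.filled == (res.summary.mortality_reduction_pct >= comp_mort)

    def test_summary_json_parses(self, small_grid):
        payload = json.loads(grid_summary_json(small_grid))
        assert payload["n"] == small_grid.config.n
        assert len(payload["scenarios"]) == len(small_grid.scenarios) + 1


class TestGoldenRun:
    """Frozen regression values for a 10^4-woman comparator run.

    Guards the whole pipeline (cohort draws, course resolution, screening,
    counting, summarising) against silent behavioural drift.
    """

    def test_comparator_golden_values(self):
        cohort = b.sample_life_histories(10_000, b.NaturalHistoryParams(), seed=101)
        control = b.natural_course(cohort)
        screened = b.apply_screening(
            cohort, control, b.ScreeningPolicy(), b.MAMMOGRAPHY, seed=101
        )
        counts = b.classify_cancers(screened.course)
        assert counts == b.DetectionCounts(550, 235, 173, 26)
        assert b.compute_sensitivities(counts) == (87, 70, 73)
        summary = b.summarize_outcomes(control, screened, b.UtilityTable())
        assert summary.false_positives_per_1000 == pytest.approx(1309.5)
        assert summary.overdiagnoses_per_1000 == pytest.approx(8.7)
        assert summary.mortality_reduction_pct == pytest.approx(37.311178, abs=1e-4)
        from bcscreen.economics import total_cost

        costed = total_cost(screened.course, screened, b.CostTable(), 149.0)
        assert costed["total"] == pytest.approx(4_141_271.15, rel=1e-6)
        assert costed["discounted_screens_per_1000"] == pytest.approx(4_471.539, rel=1e-6)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "n": 500,
                    "seed": 3,
                    "policy": {"start_age": 45, "stop_age": 54, "interval": 1},
                    "params": {
                        "lifetime_bc_risk": 0.1,
                        "growth_rate_distribution": {"kind": "lognormal", "median": 0.5, "sigma": 0.3},
                    },
                    "scenarios": [
                        {"dcis_sensitivity": 0.0, "median_detect_size": 1.21, "specificity": 1.0}
                    ],
                }
            )
        )
        cfg = RunConfig.from_yaml(cfg_path)
        assert cfg.n == 500
        assert cfg.policy.start_age == 45
        assert cfg.params.lifetime_bc_risk == 0.1
        assert len(cfg.scenarios) == 1
        grid = run_grid(cfg)
        assert len(grid.scenarios) == 1

    def test_bad_distribution_kind_errors(self):
        with pytest.raises(ConfigError, match="growth_rate_distribution"):
            RunConfig.from_dict(
                {"params": {"growth_rate_distribution": {"kind": "gaussian", "mean": 1.0}}}
            )


class TestCli:
    def test_grid_command_writes_outputs(self, tmp_path):
        from click.testing import CliRunner

        from bcscreen.cli import main

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            yaml.safe_dump(
                {
                    "n": 2000,
                    "seed": 1,
                    "scenarios": [
                        {"dcis_sensitivity": 0.91, "median_detect_size": 1.21, "specificity": 1.0}
                    ],
                }
            )
        )
        out = tmp_path / "out"
        runner = CliRunner()
        result = runner.invoke(main, ["grid", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        for name in ("detection_proportions.csv", "outcomes.csv", "roc_points.csv", "summary.json"):
            assert (out / name).exists()
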