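"""End-to-end model runs, sensitivity re-analysis, config and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from newborntypes import (
    CountryConfig,
    GeneratorConfig,
    NewbornTypeAnalysis,
    TYPE6,
    generate,
    scenario_paperlike,
    scenario_region_map,
    write_table,
)
from newborntypes.cli import main as cli_main
from newborntypes.config import load_run_config, run_from_config, validate_config
from newborntypes.io import ConfigurationError


@pytest.fixture(scope="module")
def small_scenario():
    config = scenario_paperlike(births_per_year=300)
    records, truth = generate(config)
    return config, records, truth


@pytest.fixture(scope="module")
def fitted(small_scenario):
    config, records, _ = small_scenario
    model = NewbornTypeAnalysis(
        records,
        config.standard(),
        region_map=scenario_region_map(),
        country_metadata={
            c.country: {"coverage_pct": c.coverage_pct, "facility_pct": c.facility_pct}
            for c in config.countries
        },
    )
    return model.fit()


class TestEndToEnd:
    def test_conservation_through_the_pipeline(self, small_scenario, fitted):
        _, records, _ = small_scenario
        flow = fitted.flow
        assert flow.n_input == len(records)
        assert flow.n_input == flow.n_included + flow.n_excluded
        assert fitted.counts6[list(TYPE6)].to_numpy().sum() == flow.n_included

    def test_ten_type_collapses_to_six(self, fitted):
        assert fitted.collapse_check

    def test_row_sums_to_one(self, fitted):
        prev = fitted.prevalence_country_year
        np.testing.assert_allclose(
            prev[list(TYPE6)].sum(axis=1), 1.0, atol=1e-9
        )

    def test_all_scenario_countries_eligible(self, fitted):
        assert fitted.eligibility["eligible"].all()

    def test_trends_limited_to_long_series(self, fitted):
        assert fitted.trends["country"].nunique() == 20

    def test_summary_text_mentions_key_numbers(self, fitted):
        text = fitted.summary()
        assert "small_composite" in text
        assert "23 national datasets" in text

    def test_fit_is_deterministic(self, small_scenario, fitted):
        config, records, _ = small_scenario
        again = NewbornTypeAnalysis(
            records, config.standard(), region_map=scenario_region_map()
        ).fit()
        pd.testing.assert_frame_equal(
            again.prevalence_national, fitted.prevalence_national
        )
        pd.testing.assert_frame_equal(again.trends, fitted.trends)


def test_sensitivity_reanalysis_excludes_flagged_country_years(toy_standard):
    config = GeneratorConfig(
        countries=[
            CountryConfig("AA", years=[2010, 2011], births_per_year=800),
            CountryConfig(
                "BB", years=[2010], births_per_year=800, missing_ga_rate=0.30
            ),
        ],
        seed=9,
    )
    records, _ = generate(config)
    results = NewbornTypeAnalysis(records, config.standard()).fit()
    assert results.sensitivity_flagged.to_dict("records") == [
        {"country": "BB", "year": 2010}
    ]
    sens = results.prevalence_national_sensitivity
    assert sens is not None
    assert set(sens["country"]) == {"AA"}


def test_manifest_records_the_decisions(fitted):
    manifest = fitted.model.manifest()
    assert manifest["quantile_rule"] == "linear"
    assert manifest["limits"]["combo_sd_multiplier"] == 5.0
    assert manifest["trend_threshold_pp"] == 0.5


def test_save_tables_writes_aggregates_only_by_default(fitted, tmp_path):
    written = fitted.save_tables(tmp_path / "out")
    names = {p.name for p in written}
    assert "prevalence_national.csv" in names
    assert "flow.csv" in names
    assert "manifest.json" in names
    assert "typed_records.csv" not in names  # disclosure-control default
    manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
    assert manifest["package"] == "newborntypes"


# -- run config and CLI -------------------------------------------------


def write_run_inputs(tmp_path, births_per_year=200):
    config = scenario_paperlike(births_per_year=births_per_year)
    records, _ = generate(config)
    registry = records.rename(
        columns={
            "country": "iso",
            "year": "yr",
            "ga_days": "gadays",
            "bw_grams": "bw",
            "sex": "sex",
        }
    )
    write_table(registry, tmp_path / "registry.csv")
    write_table(config.standard().to_frame(), tmp_path / "standard.csv")
    write_table(scenario_region_map().to_frame(), tmp_path / "regions.csv")
    run_config = {
        "registries": [
            {
                "path": "registry.csv",
                "ga_encoding": "days",
                "columns": {
                    "country": "iso",
                    "year": "yr",
                    "ga_days": "gadays",
                    "bw_grams": "bw",
                    "sex": "sex",
                },
            }
        ],
        "standard": {"path": "standard.csv"},
        "region_map": "regions.csv",
        "output_dir": "out",
    }
    cfg_path = tmp_path / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(run_config))
    return cfg_path


def test_run_from_config_end_to_end(tmp_path):
    cfg_path = write_run_inputs(tmp_path)
    config = load_run_config(cfg_path)
    assert validate_config(config) == []
    outdir = run_from_config(config)
    assert (outdir / "prevalence_national.csv").exists()
    nat = pd.read_csv(outdir / "prevalence_national.csv")
    assert len(nat) == 23


def test_validate_config_reports_all_problems(tmp_path):
    cfg_path = write_run_inputs(tmp_path)
    raw = yaml.safe_load(cfg_path.read_text())
    raw["standard"]["path"] = "missing.csv"
    raw["trend_threshold_pp"] = -1
    cfg_path.write_text(yaml.safe_dump(raw))
    problems = validate_config(load_run_config(cfg_path))
    assert len(problems) == 2
    assert any("missing.csv" in p for p in problems)
    assert any("threshold" in p for p in problems)
    with pytest.raises((ConfigurationError, RuntimeError)):
        run_from_config(load_run_config(cfg_path))


class TestCli:
    def test_simulate_then_validate_then_run(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(
            cli_main,
            ["simulate", "--out", str(tmp_path / "sim"), "--births-per-year", "50"],
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "sim" / "registry.csv").exists()
        assert (tmp_path / "sim" / "truth.csv").exists()

        cfg_path = write_run_inputs(tmp_path, births_per_year=100)
        ok = runner.invoke(cli_main, ["validate", str(cfg_path)])
        assert ok.exit_code == 0 and "valid" in ok.output
        run = runner.invoke(cli_main, ["run", str(cfg_path)])
        assert run.exit_code == 0, run.output
        assert (tmp_path / "out" / "flow.csv").exists()

    def test_validate_fails_on_bad_config(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("registries: []\n")
        runner = CliRunner()
        out = runner.invoke(cli_main, ["validate", str(tmp_path / "bad.yaml")])
        assert out.exit_code == 1
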