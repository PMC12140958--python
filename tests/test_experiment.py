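"""Study orchestration, reporting, and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from wallstrain.cli import main
from wallstrain.experiment import ExperimentPlan, run_experiment, run_pipeline, synthetic_contours
from wallstrain.phantom import generate_cine
from wallstrain.report import report, write_run_report


class TestExperimentPlan:
    def test_defaults_valid(self):
        plan = ExperimentPlan()
        assert plan.packing_levels == (100, 200, 300, 400)

    def test_damping_must_be_monotone_in_packing(self):
        with pytest.raises(ValueError):
            ExperimentPlan(
                conditions=("immediate",),
                damping_maps={"immediate": {100: 0.8, 200: 0.2, 300: 0.3, 400: 0.4}},
            )

    def test_damping_range_checked(self):
        with pytest.raises(ValueError):
            ExperimentPlan(
                conditions=("immediate",),
                damping_maps={"immediate": {100: 0.1, 200: 0.2, 300: 0.3, 400: 1.4}},
            )

    def test_immediate_expansion_clock(self):
        plan = ExperimentPlan(tau_minutes=5.0)
        d15 = plan.damping_at("immediate", 400, 15)
        d5 = plan.damping_at("immediate", 400, 5)
        final = plan.damping_maps["immediate"][400]
        assert d5 < d15 < final
        assert d15 == pytest.approx(final * (1 - np.exp(-3.0)))  # ~95% expanded

    def test_sequential_keeps_previous_levels_expanded(self):
        plan = ExperimentPlan(tau_minutes=5.0)
        dmap = plan.damping_maps["sequential"]
        d = plan.damping_at("sequential", 200, 5)
        assert d > dmap[100]  # the 100% load is already fully expanded
        assert d < dmap[200]

    def test_damping_non_decreasing_in_level_at_fixed_time(self):
        plan = ExperimentPlan()
        for cond in plan.conditions:
            for minute in plan.minutes:
                deltas = [plan.damping_at(cond, lvl, minute) for lvl in plan.packing_levels]
                assert all(b >= a for a, b in zip(deltas, deltas[1:]))


@pytest.fixture(scope="module")
def tiny_results(fast_config):
    plan = ExperimentPlan(
        conditions=("immediate",),
        packing_levels=(100, 400),
        minutes=(5, 15),
        damping_maps={"immediate": {100: 0.1, 400: 0.8}},
    )
    return run_experiment(plan, fast_config)


class TestRunExperiment:
    def test_table_shape_and_columns(self, tiny_results):
        assert len(tiny_results) == 4  # 1 condition x 2 levels x 2 minutes
        for col in ("condition", "packing_pct", "minute", "delta", "PP_mmHg",
                    "eps_max", "eps_norm_per_mmHg", "pct_change_vs_baseline"):
            assert col in tiny_results.columns

    def test_higher_packing_gives_lower_strain_change(self, tiny_results):
        at15 = tiny_results[tiny_results["minute"] == 15].set_index("packing_pct")
        assert (
            at15.loc[400, "pct_change_vs_baseline"]
            < at15.loc[100, "pct_change_vs_baseline"]
        )

    def test_undamped_level_matches_baseline(self, fast_config):
        plan = ExperimentPlan(
            conditions=("immediate",),
            packing_levels=(100,),
            minutes=(15,),
            damping_maps={"immediate": {100: 0.0}},
        )
        results = run_experiment(plan, fast_config)
        # delta = 0 reproduces the baseline run exactly (same seed, same speckle)
        assert results.loc[0, "pct_change_vs_baseline"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self, fast_config, tiny_results):
        plan = ExperimentPlan(
            conditions=("immediate",),
            packing_levels=(100, 400),
            minutes=(5, 15),
            damping_maps={"immediate": {100: 0.1, 400: 0.8}},
        )
        again = run_experiment(plan, fast_config)
        pd.testing.assert_frame_equal(tiny_results, again)


class TestReport:
    def test_outputs_written(self, tiny_results, tmp_path):
        paths = report(tiny_results, tmp_path)
        assert paths["results"].exists()
        assert paths["figure"].exists()
        assert paths["pulse_pressure_table"].exists()
        round_trip = pd.read_csv(paths["results"])
        assert len(round_trip) == len(tiny_results)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            report(pd.DataFrame(), tmp_path)

    def test_missing_baseline_column_rejected(self, tiny_results, tmp_path):
        broken = tiny_results.drop(columns=["pct_change_vs_baseline"])
        with pytest.raises(ValueError):
            report(broken, tmp_path)

    def test_run_report_json(self, tmp_path):
        path = write_run_report(tmp_path, {"a": 1}, seed=5)
        payload = json.loads(path.read_text())
        assert payload["seed"] == 5
        assert len(payload["config_sha256"]) == 64


@pytest.fixture(scope="module")
def cli_workspace(tmp_path_factory):
    """simulate -> mesh -> track -> strain on a miniature phantom."""
    root = tmp_path_factory.mktemp("cli")
    config = {
        "frames_per_cycle": 8,
        "image_size": 96,
        "pixel_spacing": 0.7,
        "scatterer_density": 30.0,
        "seed": 11,
    }
    cfg_path = root / "phantom.json"
    cfg_path.write_text(json.dumps(config))
    runner = CliRunner()
    sim = runner.invoke(main, ["simulate", "--config", str(cfg_path),
                               "--out-dir", str(root / "sim")])
    assert sim.exit_code == 0, sim.output
    return root


class TestCli:
    def test_simulate_outputs(self, cli_workspace):
        sim = cli_workspace / "sim"
        for name in ("cine.tiff", "contours.csv", "truth.json",
                     "truth_fields.npz", "run_report.json"):
            assert (sim / name).exists()

    def test_mesh_track_strain_chain(self, cli_workspace):
        runner = CliRunner()
        sim = cli_workspace / "sim"
        mesh = runner.invoke(main, ["mesh", "--contours", str(sim / "contours.csv"),
                                    "--out-dir", str(cli_workspace / "mesh")])
        assert mesh.exit_code == 0, mesh.output
        assert (cli_workspace / "mesh" / "mesh.txt").exists()

        track = runner.invoke(main, ["track", "--cine", str(sim / "cine.tiff"),
                                     "--contours", str(sim / "contours.csv"),
                                     "--out-dir", str(cli_workspace / "track")])
        assert track.exit_code == 0, track.output

        # pressure recording matching the default drive
        from wallstrain.hemodynamics import synth_waveform, write_pressure_csv
        lumen = synth_waveform(70, 130.4, 47.0, n_cycles=2, samples_per_cycle=100)
        sac = synth_waveform(70, 125.0, 48.0, n_cycles=2, samples_per_cycle=100,
                             site="sac")
        press = cli_workspace / "pressures.csv"
        write_pressure_csv(press, lumen, sac)
        strain = runner.invoke(main, ["strain",
                                      "--displacements",
                                      str(cli_workspace / "track" / "displacements.npz"),
                                      "--contours", str(sim / "contours.csv"),
                                      "--pressures", str(press),
                                      "--out-dir", str(cli_workspace / "strain")])
        assert strain.exit_code == 0, strain.output
        summary = json.loads((cli_workspace / "strain" / "strain_summary.json").read_text())
        assert summary["pp_mmhg"] == pytest.approx(83.4, abs=0.1)

    def test_report_command(self, tiny_results, tmp_path):
        results_path = tmp_path / "results.csv"
        tiny_results.to_csv(results_path, index=False)
        runner = CliRunner()
        rep = runner.invoke(main, ["report", "--results", str(results_path),
                                   "--out-dir", str(tmp_path / "report")])
        assert rep.exit_code == 0, rep.output
        assert (tmp_path / "report" / "strain_change.png").exists()


def test_run_pipeline_smoke(fast_config):
    cine, truth = generate_cine(fast_config)
    inner, outer = synthetic_contours(fast_config)
    result = run_pipeline(cine, inner, outer, pp=truth.pp)
    assert result.series.eps_norm is not None
    assert result.series.mean_strain[0] == pytest.approx(0.0, abs=1e-12)
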