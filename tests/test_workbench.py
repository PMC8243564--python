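"""Configuration, orchestration and the command-line interface."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from beamtune.cli import main
from beamtune.config import RunConfig
from beamtune.params import BeamParameters
from beamtune.pipeline import (
    build_training_data,
    fit_pca_models,
    plan_manifest,
    profile_sets_for_tuples,
    tune_beam,
)
from beamtune.profiles import ProfileSpec, write_profile
from beamtune.svr import train_svr, SearchGrid

TINY_AXES = ((5.6, 6.0, 6.4), (0.5,), (0.0, 0.4), (0.0, 3.0))


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=7, sigma_e_policy=0.5, step=0.2)
        path = tmp_path / "config.yaml"
        cfg.save(path)
        back = RunConfig.load(path)
        assert back.seed == 7
        assert back.fixed_sigma_e == 0.5
        assert back.step == 0.2
        assert [p.label() for p in back.profiles] == [p.label() for p in cfg.profiles]

    def test_default_selection_is_six_profiles(self):
        cfg = RunConfig()
        labels = [p.label() for p in cfg.profiles]
        assert labels == [
            "f10_depth", "f10_lat1.4", "f10_lat10",
            "f30_depth", "f30_lat1.4", "f30_lat10",
        ]

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            RunConfig(weights=[1.0, 2.0])

    def test_unknown_field_in_selection_rejected(self):
        specs = [ProfileSpec(field_size=3.0, kind="depth")]
        with pytest.raises(ValueError, match="fields"):
            RunConfig(profiles=specs, fields=(10.0, 30.0))


class TestTrainingDataBuild:
    def test_full_design_plans_900_dose_files(self):
        cfg = RunConfig()
        manifest = plan_manifest(cfg, fields=(3.0, 10.0, 30.0))
        assert len(manifest) == 900
        assert manifest["tuple_index"].nunique() == 300

    def test_scaled_down_grid_produces_expected_file_count(self):
        axes = ((5.8, 6.2), (0.5,), (0.1, 0.3), (1.0, 2.0))
        cfg = RunConfig(grid_axes=axes, seed=0, noise=False)
        training = build_training_data(cfg)
        assert len(training.manifest) == 16  # 8 nodes x 2 fields
        assert len(training.profile_sets) == 8

    def test_rerun_is_bit_identical(self):
        axes = ((5.8, 6.2), (0.5,), (0.1,), (1.0,))
        cfg = RunConfig(grid_axes=axes, seed=3)
        a = build_training_data(cfg)
        b = build_training_data(cfg)
        assert a.manifest.equals(b.manifest)
        for sa, sb in zip(a.profile_sets, b.profile_sets):
            for pa, pb in zip(sa, sb):
                assert np.array_equal(pa.doses, pb.doses)


@pytest.fixture(scope="module")
def tiny_trained(tmp_path_factory):
    """A complete tiny build: 12-node grid, PCA + SVR, no noise."""
    cfg = RunConfig(grid_axes=TINY_AXES, seed=0, noise=False)
    training = build_training_data(cfg)
    models = fit_pca_models(training, k=3)
    bundle = train_svr(
        models, training.grid, seed=0,
        search=SearchGrid(C=(100.0,), epsilon=(1e-3,), gamma_factors=(1.0,)),
    )
    return cfg, training, models, bundle


class TestTuneBeam:
    def test_recovers_known_parameters_from_noiseless_profiles(self, tiny_trained):
        cfg, training, models, bundle = tiny_trained
        truth = BeamParameters(6.1, 0.5, 0.22, 1.6)
        observed = profile_sets_for_tuples(cfg, [truth], seed_offset=9)[0]
        result = tune_beam(cfg, models, bundle, observed, grid=training.grid)
        est = result.optimum.as_array()
        assert abs(est[0] - truth.E) <= 0.05
        assert abs(est[2] - truth.s) <= 0.02
        assert abs(est[3] - truth.alpha) <= 0.15
        assert result.objective_optimum <= result.objective_start
        assert len(result.per_profile) == len(observed)
        for row in result.per_profile:
            assert row["gamma_pass_rate_pct"] >= 99.0
            assert row["mae_pct"] < 1.0

    def test_fixed_sigma_policy_passes_through(self, tiny_trained):
        cfg, training, models, bundle = tiny_trained
        cfg_fixed = RunConfig(
            grid_axes=TINY_AXES, seed=0, noise=False, sigma_e_policy=0.5
        )
        truth = BeamParameters(6.1, 0.5, 0.22, 1.6)
        observed = profile_sets_for_tuples(cfg, [truth], seed_offset=9)[0]
        result = tune_beam(cfg_fixed, models, bundle, observed, grid=training.grid)
        assert result.optimum.sigma_E == pytest.approx(0.5)


@pytest.fixture(scope="module")
def workdir(tmp_path_factory):
    root = tmp_path_factory.mktemp("cli")
    cfg = RunConfig(
        grid_axes=TINY_AXES, seed=0, noise=False,
        output_dir=str(root / "out"),
    )
    path = root / "config.yaml"
    cfg.save(path)
    return root, path, cfg


class TestCLI:
    def test_fit_pca_then_train_svr_then_tune(self, workdir):
        root, cfg_path, cfg = workdir
        runner = CliRunner()
        res = runner.invoke(main, ["fit-pca", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert (root / "out" / "pca" / "f10_depth.json").exists()

        res = runner.invoke(main, ["train-svr", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert (root / "out" / "svr_bundle.joblib").exists()

        truth = BeamParameters(6.15, 0.5, 0.18, 2.2)
        observed = profile_sets_for_tuples(cfg, [truth], seed_offset=5)[0]
        mdir = root / "measured"
        mdir.mkdir()
        files = []
        for prof in observed:
            f = mdir / f"{prof.spec.label()}.txt"
            write_profile(prof, f)
            files.append(str(f))
        res = runner.invoke(
            main,
            ["tune", "--config", str(cfg_path), "--fix-sigma-e", "0.5", *files],
        )
        assert res.exit_code == 0, res.output
        report = json.loads(
            (root / "out" / "tune_result_svr.json").read_text()
        )
        assert report["optimum"]["sigma_E"] == pytest.approx(0.5)
        assert abs(report["optimum"]["E"] - truth.E) <= 0.05
        assert (root / "out" / "reconstructed" / "f10_depth.txt").exists()
        assert (root / "out" / "resolved_config.yaml").exists()

    def test_stale_models_refused_after_selection_change(self, workdir, tmp_path):
        root, cfg_path, cfg = workdir
        changed = yaml.safe_load(cfg_path.read_text())
        changed["profiles"] = changed["profiles"][:3]  # drop the 30x30 profiles
        changed["weights"] = changed["weights"][:3]
        changed["fields"] = [10.0]
        new_cfg = tmp_path / "changed.yaml"
        new_cfg.write_text(yaml.safe_dump(changed))
        runner = CliRunner()
        res = runner.invoke(
            main, ["evaluate", "--config", str(new_cfg), "--out", str(root / "out")]
        )
        assert res.exit_code != 0
        assert "retrain" in res.output or "missing" in res.output

    def test_gamma_subcommand(self, tmp_path):
        from beamtune.profiles import DoseProfile

        spec = ProfileSpec(field_size=10.0, kind="depth", range_cm=(0.0, 5.0))
        a = DoseProfile(spec=spec, doses=np.full(spec.n_points, 100.0))
        b = DoseProfile(spec=spec, doses=np.full(spec.n_points, 102.0))
        fa, fb = tmp_path / "a.txt", tmp_path / "b.txt"
        write_profile(a, fa)
        write_profile(b, fb)
        runner = CliRunner()
        res = runner.invoke(main, ["gamma", str(fa), str(fb)])
        assert res.exit_code == 0, res.output
        assert "100.0%" in res.output
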