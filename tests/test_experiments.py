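"""Experiment orchestration, report bundles and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from brainprint import (CohortSpec, ExperimentConfig, compare_preprocessing,
                        make_cohort, run_experiment, session_pairs,
                        sweep_sample_size)
from brainprint.cli import main as cli_main
from brainprint.errors import ConfigError
from brainprint.simulate import degrade_cohort

TINY = dict(K=3, S=2, C=8, T=40, N=30)


def tiny_config(**kw):
    base = dict(kind="cross_session", cohort=dict(TINY), features=["sp"],
                n=10, R=3, seed=5, permutation_B=19)
    base.update(kw)
    return ExperimentConfig(**base)


class TestSessionPairs:
    def test_ordered_pair_counts(self):
        assert len(session_pairs(list("abc"), "cross_session")) == 6
        assert len(session_pairs(list("abcd"), "cross_session")) == 12
        assert session_pairs(list("ab"), "within") == [("a", "a"), ("b", "b")]

    def test_cross_excludes_diagonal(self):
        assert all(a != b for a, b in
                   session_pairs(list("abcd"), "cross_session"))


class TestConfig:
    def test_violations_listed(self):
        with pytest.raises(ConfigError, match="kind"):
            ExperimentConfig(kind="bogus")
        with pytest.raises(ConfigError, match="n_grid"):
            ExperimentConfig(kind="sweep")
        with pytest.raises(ConfigError, match="features"):
            ExperimentConfig(kind="within", features=["xx"])

    def test_from_yaml_with_overrides(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(dict(kind="within", n=5, R=2,
                                         cohort=dict(TINY))))
        cfg = ExperimentConfig.from_file(p, seed=9)
        assert cfg.kind == "within" and cfg.seed == 9 and cfg.n == 5

    def test_unknown_fields_rejected(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps(dict(kind="within", bogus_field=1)))
        with pytest.raises(ConfigError, match="bogus_field"):
            ExperimentConfig.from_file(p)


class TestRunExperiment:
    def test_cross_session_bundle(self, tmp_path):
        cfg = tiny_config(out_dir=str(tmp_path / "out"))
        out = run_experiment(cfg)
        acc = out["accuracy"]
        # 2 ordered cross-session pairs for S=2, one feature
        assert len(acc) == 2
        assert set(acc.source_session) == {"ses-00", "ses-01"}
        d = tmp_path / "out"
        assert (d / "accuracy.csv").exists()
        assert (d / "run_manifest.json").exists()
        assert (d / "significance.json").exists()
        assert len(list(d.glob("confusion_sp_*.csv"))) == 2
        # chance levels embedded alongside every accuracy
        assert np.allclose(acc.chance_identification, 1 / 3)

    def test_rerun_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            run_experiment(tiny_config(out_dir=str(tmp_path / d)))
        for name in ("accuracy.csv", "significance.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_within_uses_diagonal(self):
        out = run_experiment(tiny_config(kind="within"))
        acc = out["accuracy"]
        assert (acc.source_session == acc.target_session).all()

    def test_cross_task_runs_with_rest_sessions(self):
        out = run_experiment(tiny_config(kind="cross_task"))
        assert len(out["accuracy"]) == 2  # task<->rest, one feature

    def test_cross_modality_transfers_temporal_spectral_features(self):
        cfg = tiny_config(kind="cross_modality",
                          cohort=dict(K=4, S=1, C=12, T=60, N=40),
                          features=["sp", "tp", "fq"], n=25, R=4)
        out = run_experiment(cfg)
        acc = out["accuracy"]
        # sp is modality-bound (different sensor arrays) and is excluded
        assert set(acc.feature) == {"tp", "fq"}
        # shared temporal/spectral signatures transfer well above 1/K chance
        assert (acc.identification_accuracy > 0.5).all()


class TestSweep:
    def test_grid_cardinality_and_monotone_columns(self):
        cfg = tiny_config(kind="sweep", n_grid=[5, 10])
        table = run_experiment(cfg)["sweep"]
        assert len(table) == 2  # one feature x two n values
        assert set(table.n) == {5, 10}

    def test_equal_grid_points_give_identical_rows(self):
        cfg = tiny_config(kind="sweep", n_grid=[8, 8, 8])
        table = run_experiment(cfg)["sweep"]
        assert table.accuracy.nunique() == 1


class TestCompare:
    def test_identical_cohorts_null_result(self):
        cfg = tiny_config(kind="preproc_compare")
        cohort = make_cohort(cfg.spec())
        table = compare_preprocessing(cfg, cohort, cohort)
        assert (table.t == 0.0).all()
        assert np.allclose(table.p_value, 1.0)
        # vector length = ordered cross pairs x K
        assert (table.n_per_group == 2 * 3).all()

    def test_degraded_cohort_hurts_accuracy(self):
        spec = CohortSpec(K=4, S=2, C=12, T=60, N=40,
                          signature_strength=0.6, seed=3)
        clean = make_cohort(spec)
        raw = degrade_cohort(clean, noise_sd=6.0)
        cfg = tiny_config(kind="preproc_compare", features=["fq"], n=20, R=4,
                          cohort=dict(K=4, S=2, C=12, T=60, N=40))
        table = compare_preprocessing(cfg, raw, clean)
        assert (table.clean_mean >= table.raw_mean).all()


class TestCli:
    def test_simulate_and_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        r = runner.invoke(cli_main, [
            "simulate", "--seed", "1", "--out", str(out),
            "-k", "2", "-s", "1", "-n", "5"])
        assert r.exit_code == 0, r.output
        assert (out / "manifest.csv").exists()

    def test_identify_subcommand(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(dict(
            cohort=dict(TINY), features=["sp"], n=8, R=2,
            permutation_B=19)))
        runner = CliRunner()
        out = tmp_path / "res"
        r = runner.invoke(cli_main, [
            "identify", "--config", str(cfg_path), "--seed", "2",
            "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "accuracy.csv").exists()
        r2 = runner.invoke(cli_main, ["report", str(out)])
        assert r2.exit_code == 0, r2.output
        assert "accuracy" in r2.output
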