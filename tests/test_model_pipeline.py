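import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from chemosens import io
from chemosens.cli import main as cli_main
from chemosens.config import PipelineConfig
from chemosens.model import DrugResponseModel, run_pipeline
from chemosens.rfe import rfe_schedule


@pytest.fixture(scope="module")
def fitted(small_panel_module):
    spec, expr, responses, truth = small_panel_module
    model = DrugResponseModel(expr, responses, spec.drug_name)
    return model.fit(seed=5)


@pytest.fixture(scope="module")
def small_panel_module():
    from chemosens.simulate import SyntheticSpec, generate

    spec = SyntheticSpec(n_samples=40, n_probes=120, n_informative=8,
                        effect_size=2.0, seed=11)
    expr, responses, truth = generate(spec)
    return spec, expr, responses, truth


class TestModelFit:
    def test_trace_follows_schedule_and_floor(self, fitted, small_panel_module):
        spec = small_panel_module[0]
        assert [s.n_features for s in fitted.trace.steps] == rfe_schedule(spec.n_probes)
        assert len(fitted.model.probe_ids) >= 10

    def test_report_and_summary(self, fitted):
        assert fitted.report.accuracy >= 0.8  # strongly planted signal
        text = fitted.summary()
        assert "LOOCV" in text and "selected" in text

    def test_quadrant_accuracy_tracks_loocv(self, fitted):
        assert fitted.quadrant_accuracy() > 0.7

    def test_training_sensitive_sample_scores_positive(self, fitted, small_panel_module):
        _, expr, responses, _ = small_panel_module
        lv = fitted.label_vector
        sens = [s for s, l in zip(lv.sample_ids, lv.labels) if l == 1]
        pred = fitted.predict(expr[sens], normalize_queries=False)
        assert (pred["score"] > 0).mean() > 0.8

    def test_predict_normalized_cohort_and_rate(self, fitted, small_panel_module):
        _, expr, _, _ = small_panel_module
        # shift + rescale a few arrays: rank-based normalization undoes it exactly
        cohort = expr.iloc[:, :6] * 1.7 + 3.0
        pred = fitted.predict(cohort)
        base = fitted.predict(expr.iloc[:, :6])
        assert np.allclose(pred["score"], base["score"], atol=1e-9)
        rate = fitted.response_rate(cohort)
        assert rate == np.mean(pred["score"] > 0)

    def test_empty_query_rejected(self, fitted, small_panel_module):
        _, expr, _, _ = small_panel_module
        with pytest.raises(ValueError, match="empty"):
            fitted.predict(expr.iloc[:, :0])

    def test_missing_probes_listed(self, fitted, small_panel_module):
        _, expr, _, _ = small_panel_module
        missing_one = expr.drop(index=[fitted.model.probe_ids[0]])
        with pytest.raises((KeyError, ValueError)):
            fitted.predict(missing_one, normalize_queries=False)

    def test_unknown_drug_rejected(self, small_panel_module):
        _, expr, responses, _ = small_panel_module
        with pytest.raises(KeyError):
            DrugResponseModel(expr, responses, "nosuchdrug")

    def test_missing_gi50_excluded_per_drug(self, small_panel_module):
        _, expr, responses, _ = small_panel_module
        resp = responses.copy()
        resp.iloc[:3, 0] = np.nan
        model = DrugResponseModel(expr, resp, "drugA")
        assert model.expression.shape[1] == expr.shape[1] - 3


class TestConfig:
    def test_defaults_match_published_procedure(self):
        cfg = PipelineConfig(drug="x")
        assert (cfg.split_fraction, cfg.band_sd, cfg.feature_floor, cfg.block_size) == (
            0.75, 0.5, 10, 100,
        )

    def test_low_floor_requires_override(self):
        with pytest.raises(ValueError, match="allow_nonpaper"):
            PipelineConfig(drug="x", feature_floor=5)
        cfg = PipelineConfig(drug="x", feature_floor=5, allow_nonpaper=True)
        assert cfg.feature_floor == 5

    def test_fingerprint_stable_and_sensitive(self):
        a = PipelineConfig(drug="x").fingerprint()
        assert a == PipelineConfig(drug="x").fingerprint()
        assert a != PipelineConfig(drug="x", C=2.0).fingerprint()


class TestFilePipeline:
    @pytest.fixture()
    def panel_files(self, small_panel_module, tmp_path):
        _, expr, responses, _ = small_panel_module
        e, r = tmp_path / "expr.tsv", tmp_path / "gi50.tsv"
        io.write_expression_matrix(expr, e)
        io.write_response_table(responses, r)
        return e, r

    def test_emits_all_artifacts(self, panel_files, tmp_path):
        e, r = panel_files
        cfg = PipelineConfig(drug="drugA")
        out = run_pipeline(e, r, cfg, seed=3, outdir=tmp_path / "run1", query_path=e)
        assert set(out) == {"model", "trace", "report", "manifest", "predictions"}
        manifest = json.loads((tmp_path / "run1" / "drugA.manifest.json").read_text())
        assert manifest["seed"] == 3
        assert set(manifest["inputs"]) == {"expression", "responses"}

    def test_rerun_is_byte_identical(self, panel_files, tmp_path):
        e, r = panel_files
        cfg = PipelineConfig(drug="drugA")
        out1 = run_pipeline(e, r, cfg, seed=3, outdir=tmp_path / "a")
        out2 = run_pipeline(e, r, cfg, seed=3, outdir=tmp_path / "b")
        assert open(out1["model"], "rb").read() == open(out2["model"], "rb").read()

    def test_stage_error_removes_partial_outputs(self, panel_files, tmp_path):
        e, r = panel_files
        cfg = PipelineConfig(drug="drugA")
        bad_query = tmp_path / "bad.tsv"
        bad_query.write_text("probe\tS1\nP1\t1.0\nP2\t2.0\n")
        with pytest.raises(RuntimeError, match="stage 'predict'"):
            run_pipeline(e, r, cfg, seed=3, outdir=tmp_path / "c", query_path=bad_query)
        assert not any((tmp_path / "c").glob("*.model.txt"))

    def test_saved_model_round_trips_scores(self, fitted, tmp_path, small_panel_module):
        _, expr, _, _ = small_panel_module
        paths = fitted.save(tmp_path)
        reloaded = io.read_model(paths["model"])
        assert reloaded == fitted.model


class TestCli:
    def test_end_to_end_subcommands(self, tmp_path):
        runner = CliRunner()
        spec_yaml = tmp_path / "spec.yaml"
        spec_yaml.write_text(
            "n_samples: 40\nn_probes: 120\nn_informative: 8\neffect_size: 2.0\n"
        )
        fx = tmp_path / "fx"
        res = runner.invoke(
            cli_main, ["simulate", "--spec", str(spec_yaml), "--seed", "11",
                       "--outdir", str(fx)],
        )
        assert res.exit_code == 0, res.output

        res = runner.invoke(
            cli_main, ["label", "--responses", str(fx / "gi50.tsv"), "--drug", "drugA",
                       "--output", str(tmp_path / "labels.tsv")],
        )
        assert res.exit_code == 0, res.output
        assert "sensitive" in res.output

        run_dir = tmp_path / "run"
        res = runner.invoke(
            cli_main, ["train", "--expression", str(fx / "expression.tsv"),
                       "--responses", str(fx / "gi50.tsv"), "--drug", "drugA",
                       "--seed", "5", "--outdir", str(run_dir)],
        )
        assert res.exit_code == 0, res.output

        res = runner.invoke(
            cli_main, ["normalize", "--reference", str(fx / "expression.tsv"),
                       "--input", str(fx / "expression.tsv"),
                       "--output", str(tmp_path / "norm.tsv")],
        )
        assert res.exit_code == 0, res.output

        res = runner.invoke(
            cli_main, ["predict", "--model", str(run_dir / "drugA.model.txt"),
                       "--input", str(tmp_path / "norm.tsv"),
                       "--output", str(tmp_path / "pred.tsv")],
        )
        assert res.exit_code == 0, res.output
        assert "response rate" in res.output
        pred = pd.read_csv(tmp_path / "pred.tsv", sep="\t")
        assert {"sample_id", "drug", "score", "call"} <= set(pred.columns)

        res = runner.invoke(
            cli_main, ["evaluate", "--model", str(run_dir / "drugA.model.txt"),
                       "--expression", str(fx / "expression.tsv"),
                       "--responses", str(fx / "gi50.tsv"),
                       "--report", str(tmp_path / "report.tsv")],
        )
        assert res.exit_code == 0, res.output

    def test_train_rejects_low_floor_without_override(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        res = runner.invoke(cli_main, ["simulate", "--outdir", str(fx), "--spec",
                                       str(_tiny_spec(tmp_path))])
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main, ["train", "--expression", str(fx / "expression.tsv"),
                       "--responses", str(fx / "gi50.tsv"), "--drug", "drugA",
                       "--feature-floor", "5", "--outdir", str(tmp_path / "r")],
        )
        assert res.exit_code != 0
        assert "allow_nonpaper" in res.output


def _tiny_spec(tmp_path):
    p = tmp_path / "tiny.yaml"
    p.write_text("n_samples: 30\nn_probes: 60\nn_informative: 6\neffect_size: 2.0\n")
    return p
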