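"""Statsmodels-style front end: a DrugResponseModel built from an expression
matrix and a GI50 table, whose fit() runs bifurcation, stratified splitting,
SVM-RFE feature selection and LOOCV, returning a DrugResponseResults with the
trained classifier, the elimination trace, the evaluation report and a
summary() table. Prediction of new cohorts (with one-by-one normalization
against the training reference) hangs off the results object.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, io, labels, normalize, rfe, simulate, svm
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class DrugResponseModel:
    """Per-drug sensitivity classifier specification.

    Parameters
    ----------
    expression : DataFrame, probes x samples
        Log-scale intensities of the reference (training) panel.
    responses : DataFrame, samples x drugs
        GI50 values in molar concentration; missing entries allowed and
        excluded per drug.
    drug : str
        Column of ``responses`` to model.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        responses: pd.DataFrame,
        drug: str,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig(drug=drug)
        if self.config.drug and self.config.drug != drug:
            raise ValueError("config.drug disagrees with the drug argument")
        if not self.config.drug:
            self.config = PipelineConfig(**{**self.config.to_dict(), "drug": drug})
        self.drug = drug
        if drug not in responses.columns:
            raise KeyError(f"drug {drug!r} not in response table {list(responses.columns)}")
        expression = io.validate_expression_matrix(expression)

        gi50 = responses[drug]
        shared = [s for s in expression.columns if s in gi50.index and np.isfinite(gi50[s])]
        dropped = expression.shape[1] - len(shared)
        if dropped:
            logger.info("%s: excluding %d samples without a GI50 value", drug, dropped)
        if len(shared) < 3:
            raise ValueError(f"only {len(shared)} samples have both expression and GI50")
        expr = expression[shared]
        if self.config.gene_collapse == "mean":
            expr = simulate.collapse_to_gene(expr, mode="mean")
        if self.config.probe_filter is not None:
            keep = [p for p in expr.index if p in set(self.config.probe_filter)]
            if not keep:
                raise ValueError("probe_filter removed every probe")
            logger.info("probe filter retains %d/%d probes", len(keep), expr.shape[0])
            expr = expr.loc[keep]
        self.expression = expr
        self.gi50 = gi50[shared].astype(float)

    @classmethod
    def from_files(
        cls,
        expression_path,
        response_path,
        drug: str,
        config: PipelineConfig | None = None,
        transpose: bool = False,
    ) -> "DrugResponseModel":
        expr = io.read_expression_matrix(expression_path, transpose=transpose)
        resp = io.read_response_table(response_path)
        return cls(expr, resp, drug, config=config)

    def fit(self, seed: int = 0, loocv: bool = True) -> "DrugResponseResults":
        """Run the full learning procedure and evaluate the selected model.

        Stages: -log10(GI50) bifurcation into sensitive/indeterminate/
        resistant; exclusion of the indeterminate band from learning;
        stratified 75/25 train/validation split (seeded); SVM-RFE over the
        block-then-single elimination schedule; refit on the selected probes;
        LOOCV of the final probe set over all determinate samples.
        """
        cfg = self.config
        nlg = labels.neg_log_transform(self.gi50.to_numpy())
        lv = labels.bifurcate(nlg, sample_ids=self.gi50.index, band_sd=cfg.band_sd)
        mask = labels.learning_mask(lv)
        det_ids = [s for s, m in zip(lv.sample_ids, mask) if m]
        y_det = lv.labels[mask].astype(int)

        train_ids, val_ids = rfe.split_train_validation(
            det_ids, y_det, fraction=cfg.split_fraction, seed=seed
        )
        y_map = dict(zip(det_ids, y_det))
        X_train = self.expression[train_ids]
        X_val = self.expression[val_ids]
        y_train = np.array([y_map[s] for s in train_ids])
        y_val = np.array([y_map[s] for s in val_ids])

        schedule = rfe.rfe_schedule(
            X_train.shape[0], floor=cfg.feature_floor, block=cfg.block_size
        )
        trace = rfe.run_rfe(X_train, y_train, X_val, y_val, C=cfg.C, schedule=schedule)
        model = rfe.finalize_model(
            trace, X_train, y_train, C=cfg.C, drug=self.drug, fingerprint=cfg.fingerprint()
        )

        report = None
        if loocv:
            X_det = self.expression.loc[list(model.probe_ids), det_ids]
            report = evaluate.loocv(X_det, y_det, C=cfg.C, sample_ids=det_ids)

        reference = normalize.build_reference(self.expression, mode=cfg.reference_mode)
        return DrugResponseResults(
            spec=self,
            model=model,
            trace=trace,
            report=report,
            label_vector=lv,
            reference=reference,
            seed=seed,
        )


@dataclass
class DrugResponseResults:
    """Fitted classifier plus its selection trace and evaluation."""

    spec: DrugResponseModel
    model: svm.LinearModel
    trace: rfe.RFETrace
    report: evaluate.EvaluationReport | None
    label_vector: labels.LabelVector
    reference: normalize.ReferenceDistribution
    seed: int

    @property
    def selected_probes(self) -> tuple[str, ...]:
        return self.model.probe_ids

    def predict(self, queries: pd.DataFrame, normalize_queries: bool = True) -> pd.DataFrame:
        """Score a query cohort (probes x samples), one sample at a time.

        With ``normalize_queries`` each column is quantile-normalized against
        the training reference distribution before scoring. Returns a
        DataFrame (sample_id, drug, score, call).
        """
        if queries.shape[1] == 0:
            raise ValueError("empty query cohort")
        if normalize_queries:
            queries = normalize.normalize_cohort(queries, self.reference)
        missing = [p for p in self.model.probe_ids if p not in queries.index]
        if missing:
            raise KeyError(
                f"query lacks {len(missing)} model probes after normalization: {missing[:10]}"
            )
        scores = svm.decision_scores(self.model, queries)
        return pd.DataFrame(
            {
                "sample_id": list(queries.columns),
                "drug": self.spec.drug,
                "score": scores,
                "call": ["responder" if s > 0 else "non-responder" for s in scores],
            }
        )

    def response_rate(self, queries: pd.DataFrame, normalize_queries: bool = True) -> float:
        """Cohort response rate: fraction of query samples with positive score."""
        pred = self.predict(queries, normalize_queries=normalize_queries)
        return evaluate.response_rate(pred["score"].to_numpy())

    def quadrant_accuracy(self) -> float:
        """Concordance of LOOCV scores with -log10(GI50) around its mean."""
        if self.report is None:
            raise ValueError("fit with loocv=True to compute quadrant accuracy")
        order = {s: i for i, s in enumerate(self.label_vector.sample_ids)}
        nlg = np.array(
            [self.label_vector.neg_log_gi50[order[s]] for s in self.report.sample_ids]
        )
        return evaluate.quadrant_accuracy(self.report.scores, nlg)

    def summary(self) -> str:
        lv, sel = self.label_vector, self.trace.selected
        lines = [
            "Drug response model" + (f" — {self.spec.drug}" if self.spec.drug else ""),
            "=" * 54,
            f"samples: {len(lv.sample_ids)}  (sensitive {lv.n_sensitive}, "
            f"resistant {lv.n_resistant}, indeterminate {lv.n_indeterminate})",
            f"-log10(GI50): mean {lv.mean:.4f}, SD {lv.sd:.4f}, band ±{self.spec.config.band_sd}·SD",
            f"starting probes: {self.spec.expression.shape[0]}",
            f"RFE steps: {len(self.trace.steps)}; selected {sel.n_features} features "
            f"at validation accuracy {sel.accuracy:.3f}",
            f"C = {self.spec.config.C}, split = {self.spec.config.split_fraction:.0%}, "
            f"seed = {self.seed}",
        ]
        if self.report is not None:
            r = self.report
            lines += [
                "-" * 54,
                f"LOOCV (n={r.n_evaluated}): accuracy {r.accuracy:.3f}, "
                f"sensitivity {r.sensitivity:.3f}, specificity {r.specificity:.3f}, "
                f"AUC {r.auc:.3f}",
            ]
        lines += ["-" * 54, "top features (probe, weight):"]
        for pid, w in svm.feature_weights(self.model)[:10]:
            lines.append(f"  {pid:<16s} {w:+.4f}")
        return "\n".join(lines)

    def save(self, outdir, stem: str | None = None) -> dict[str, str]:
        """Write model, trace, report and manifest; returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = stem or (self.spec.drug or "model")
        paths = {
            "model": str(outdir / f"{stem}.model.txt"),
            "trace": str(outdir / f"{stem}.trace.tsv"),
            "report": str(outdir / f"{stem}.report.tsv"),
            "manifest": str(outdir / f"{stem}.manifest.json"),
        }
        io.write_model(self.model, paths["model"])
        self.trace.as_frame().to_csv(paths["trace"], sep="\t", index=False)
        if self.report is not None:
            self.report.as_frame().to_csv(paths["report"], sep="\t", index=False)
        manifest = {
            "drug": self.spec.drug,
            "seed": self.seed,
            "config": self.spec.config.to_dict(),
            "config_fingerprint": self.spec.config.fingerprint(),
            "n_probes": int(self.spec.expression.shape[0]),
            "n_samples": int(self.spec.expression.shape[1]),
            "selected_features": list(self.model.probe_ids),
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return paths


def run_pipeline(
    expression_path,
    response_path,
    config: PipelineConfig,
    seed: int = 0,
    outdir=".",
    query_path=None,
) -> dict[str, str]:
    """End-to-end file pipeline: load, fit, evaluate, save, optionally predict.

    Stages fail loudly with the stage name, and partially written outputs are
    removed so a crashed run leaves no ambiguous artifacts. Returns the output
    file map (plus 'predictions' when a query cohort was scored).
    """
    written: dict[str, str] = {}
    try:
        stage = "load"
        model_spec = DrugResponseModel.from_files(
            expression_path, response_path, config.drug, config=config
        )
        stage = "fit"
        results = model_spec.fit(seed=seed)
        stage = "save"
        written = results.save(outdir)
        # record input provenance in the manifest
        with open(written["manifest"]) as fh:
            manifest = json.load(fh)
        manifest["inputs"] = {
            "expression": io.sha256_file(expression_path),
            "responses": io.sha256_file(response_path),
        }
        with open(written["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if query_path is not None:
            stage = "predict"
            queries = io.read_expression_matrix(query_path)
            pred = results.predict(queries)
            pred_path = str(Path(outdir) / f"{config.drug or 'model'}.predictions.tsv")
            io.write_predictions(pred, pred_path)
            written["predictions"] = pred_path
        return written
    except Exception as exc:
        for path in written.values():
            Path(path).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
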