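"""Reusable design experiments on synthetic panels.

These functions instantiate the three training-set design questions the
platform is meant to probe — learning-set tissue diversity, probe-level vs
gene-averaged features, and biology-driven pre-filtering — plus the planted
signal-recovery benchmark. Each takes a seed and returns plain floats so that
tests and reproduction scripts can aggregate over seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import evaluate, labels, rfe, svm
from .config import PipelineConfig
from .model import DrugResponseModel
from .simulate import SyntheticSpec, generate, generate_tissue_panel

RECOVERY_SPEC = SyntheticSpec(n_samples=60, n_probes=2000, n_informative=20, effect_size=2.0)

TISSUE_SPEC = SyntheticSpec(
    n_samples=126, n_probes=300, n_informative=15, effect_size=2.0,
    n_tissues=9, tissue_sd=1.5, tissue_response_sd=0.8,
)

ISOFORM_SPEC = SyntheticSpec(
    n_samples=60, n_probes=600, n_informative=15, effect_size=1.0, probes_per_gene=3
)

PREFILTER_SPEC = SyntheticSpec(n_samples=60, n_probes=400, n_informative=12, effect_size=1.0)


def planted_recovery_experiment(seed: int, spec: SyntheticSpec = RECOVERY_SPEC) -> dict:
    """Fit the full pipeline on one planted panel; score signal recovery.

    Returns the fraction of planted probes in the top-k of the RFE
    elimination ranking (k = number planted), the LOOCV accuracy of the
    selected model, and the selected feature count.
    """
    expr, responses, truth = generate(replace(spec, seed=seed))
    model = DrugResponseModel(expr, responses, spec.drug_name)
    results = model.fit(seed=seed)
    recovery = rfe.ranking_recovery(results.trace, truth.planted_probes)
    return {
        "recovery": recovery,
        "loocv_accuracy": results.report.accuracy,
        "n_selected": len(results.model.probe_ids),
        "results": results,
        "truth": truth,
    }


def _fit_and_test(expr, lv, train_ids, test_ids, C=1.0, seed=0):
    """SVM-RFE on ``train_ids``, accuracy of the final model on ``test_ids``."""
    y = dict(zip(lv.sample_ids, lv.labels.astype(int)))
    y_train = np.array([y[s] for s in train_ids])
    tr, va = rfe.split_train_validation(train_ids, y_train, seed=seed)
    y_tr = np.array([y[s] for s in tr])
    y_va = np.array([y[s] for s in va])
    trace = rfe.run_rfe(expr[tr], y_tr, expr[va], y_va, C=C)
    model = rfe.finalize_model(trace, expr[tr], y_tr, C=C)
    scores = svm.decision_scores(model, expr[test_ids])
    truth = np.array([y[s] for s in test_ids])
    return float(np.mean(evaluate.calls_from_scores(scores) == truth))


def _take_with_class_guard(candidates, label_of, n_take):
    """First ``n_take`` candidates, extended as needed until both classes appear twice."""
    chosen = list(candidates[:n_take])
    rest = list(candidates[n_take:])
    while rest and (
        sum(label_of[s] == 1 for s in chosen) < 2 or sum(label_of[s] == -1 for s in chosen) < 2
    ):
        chosen.append(rest.pop(0))
    if sum(label_of[s] == 1 for s in chosen) < 2 or sum(label_of[s] == -1 for s in chosen) < 2:
        raise ValueError("candidate pool cannot provide 2 samples per class")
    return chosen


def tissue_diversity_experiment(seed: int, spec: SyntheticSpec = TISSUE_SPEC) -> dict:
    """Train on samples from 2 tissue blocks vs the same number spread over all
    blocks; test both models on a common held-out, all-tissue test set.

    The probe-level sensitivity signal is shared across tissues, but baseline
    expression and typical sensitivity both shift per tissue block. In a
    narrow (2-block) learning set, tissue identity therefore correlates with
    the response labels, and tissue-marker probes masquerade as predictive
    features that fail on held-out tissues; a diverse learning set averages
    that confounding away.
    """
    expr, responses, truth = generate_tissue_panel(replace(spec, seed=seed), spec.n_tissues)
    nlg = labels.neg_log_transform(responses[spec.drug_name].to_numpy())
    lv = labels.bifurcate(nlg, sample_ids=responses.index)
    label_of = dict(zip(lv.sample_ids, lv.labels.astype(int)))
    tissue_of = dict(zip(lv.sample_ids, truth.tissue_of_sample))
    det = [s for s in lv.sample_ids if label_of[s] != 0]

    # hold out the first 3 samples of every tissue as the common test set
    test_ids, seen = [], {}
    for s in lv.sample_ids:
        t = tissue_of[s]
        if seen.get(t, 0) < 3:
            seen[t] = seen.get(t, 0) + 1
            if label_of[s] != 0:
                test_ids.append(s)
    pool = [s for s in det if s not in set(test_ids)]

    narrow_candidates = sorted(pool, key=lambda s: (tissue_of[s], s))
    n_two = sum(1 for s in pool if tissue_of[s] < 2)
    narrow_ids = _take_with_class_guard(narrow_candidates, label_of, n_two)

    # round-robin over tissues for the diverse set of equal size
    by_tissue: dict[int, list] = {}
    for s in pool:
        by_tissue.setdefault(tissue_of[s], []).append(s)
    diverse_candidates = []
    depth = 0
    while len(diverse_candidates) < len(pool):
        for t in sorted(by_tissue):
            if depth < len(by_tissue[t]):
                diverse_candidates.append(by_tissue[t][depth])
        depth += 1
    diverse_ids = _take_with_class_guard(diverse_candidates, label_of, len(narrow_ids))

    return {
        "acc_diverse": _fit_and_test(expr, lv, diverse_ids, test_ids, seed=seed),
        "acc_narrow": _fit_and_test(expr, lv, narrow_ids, test_ids, seed=seed),
        "n_train": len(narrow_ids),
        "n_test": len(test_ids),
    }


def probe_vs_gene_experiment(seed: int, spec: SyntheticSpec = ISOFORM_SPEC) -> dict:
    """LOOCV accuracy with probe-level features vs gene-averaged features.

    Planted probes are isoform-specific (one informative probe among each
    informative gene's probes), so averaging a gene's probes dilutes the
    signal by the probes-per-gene factor.
    """
    expr, responses, _ = generate(replace(spec, seed=seed))
    drug = spec.drug_name
    acc_probe = DrugResponseModel(expr, responses, drug).fit(seed=seed).report.accuracy
    cfg = PipelineConfig(drug=drug, gene_collapse="mean")
    acc_gene = DrugResponseModel(expr, responses, drug, config=cfg).fit(seed=seed).report.accuracy
    return {"acc_probe": acc_probe, "acc_gene": acc_gene}


def prefilter_experiment(seed: int, spec: SyntheticSpec = PREFILTER_SPEC) -> dict:
    """LOOCV accuracy with the full probe set vs a pre-filtered starting set
    that excludes half of the planted (informative) probes — the cost of
    restricting learning to a preconceived gene list."""
    expr, responses, truth = generate(replace(spec, seed=seed))
    drug = spec.drug_name
    acc_full = DrugResponseModel(expr, responses, drug).fit(seed=seed).report.accuracy
    excluded = set(truth.planted_probes[: len(truth.planted_probes) // 2])
    keep = tuple(p for p in expr.index if p not in excluded)
    cfg = PipelineConfig(drug=drug, probe_filter=keep)
    acc_filt = DrugResponseModel(expr, responses, drug, config=cfg).fit(seed=seed).report.accuracy
    return {"acc_full": acc_full, "acc_filtered": acc_filt}
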