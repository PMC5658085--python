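"""Synthetic expression matrices and GI50 tables with known planted structure.

The generator emulates the statistical shape of a cell-line drug-sensitivity
panel: log-scale intensity matrices in which a small planted set of probes
tracks a latent per-sample sensitivity, GI50 values that are a noisy monotone
function of that latent (so -log10(GI50) is approximately normal), optional
tissue blocks that shift baseline expression, and optional multi-probe genes
where only one probe per gene is informative (isoform-specific signal).

Everything is reproducible from the seed, and the planted truth is returned
alongside the data so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic panel.

    Defaults mirror a 60-cell-line panel profiled on a few thousand probes:
    log2-intensity baselines around 8 +/- 1.5, unit probe-level noise, 20
    informative probes separating sensitive from resistant samples by 2 SD,
    and -log10(GI50) centred at 6 (micromolar potency) with slope 1 on the
    latent sensitivity and residual SD 0.3.
    """

    n_samples: int = 60
    n_probes: int = 2000
    n_informative: int = 20
    effect_size: float = 2.0
    gi50_noise_sd: float = 0.3
    gi50_intercept: float = 6.0
    gi50_slope: float = 1.0
    n_tissues: int = 1
    tissue_sd: float = 2.0
    tissue_response_sd: float = 0.0
    probes_per_gene: int = 1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    probe_noise_sd: float = 1.0
    drug_name: str = "drugA"
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative cannot exceed n_probes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be at least 1")
        if self.n_tissues > self.n_samples:
            raise ValueError("more tissue blocks than samples")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be at least 1")
        if min(self.gi50_noise_sd, self.baseline_sd, self.probe_noise_sd,
               self.tissue_sd, self.tissue_response_sd) < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth emitted beside every fixture."""

    planted_probes: tuple[str, ...]
    latent_sensitivity: np.ndarray = field(repr=False)
    tissue_of_sample: np.ndarray = field(repr=False)
    sample_ids: tuple[str, ...] = ()


def _probe_ids(spec: SyntheticSpec) -> list[str]:
    if spec.probes_per_gene == 1:
        return [f"P{i:05d}" for i in range(spec.n_probes)]
    ids = []
    for i in range(spec.n_probes):
        gene, iso = divmod(i, spec.probes_per_gene)
        ids.append(f"G{gene:05d}_p{iso + 1}")
    return ids


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, GI50 table, truth) for one panel.

    Latent sensitivity s ~ N(0,1) per sample. Informative probes read
    baseline + tissue offset + effect_size * s + noise; the rest are pure
    baseline + tissue offset + noise. With multi-probe genes, planted probes
    are spread one per gene (the isoform-specific case), so averaging a
    gene's probes dilutes the signal. GI50 = 10^-(a + b*s + eps), making the
    -log10 transform approximately normal.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.n_probes, spec.n_informative
    probe_ids = _probe_ids(spec)
    sample_ids = tuple(f"CL{j:03d}" for j in range(n))

    tissue = np.repeat(np.arange(spec.n_tissues), -(-n // spec.n_tissues))[:n]
    latent = rng.standard_normal(n)
    if spec.n_tissues > 1 and spec.tissue_response_sd > 0:
        # tissue-of-origin shifts the typical sensitivity, as in real cell-line
        # panels; the probe-level signal itself stays shared across tissues
        latent = latent + rng.normal(0.0, spec.tissue_response_sd, size=spec.n_tissues)[tissue]

    if spec.probes_per_gene > 1:
        # one informative probe per gene, so the gene average dilutes it
        n_genes = -(-p // spec.probes_per_gene)
        genes = rng.choice(n_genes, size=min(k, n_genes), replace=False)
        iso = rng.integers(0, spec.probes_per_gene, size=genes.size)
        planted_idx = np.minimum(genes * spec.probes_per_gene + iso, p - 1)
    else:
        planted_idx = rng.choice(p, size=k, replace=False)
    planted_idx = np.sort(planted_idx)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=p)
    values = baseline[:, None] + rng.normal(0.0, spec.probe_noise_sd, size=(p, n))
    if spec.n_tissues > 1:
        offsets = rng.normal(0.0, spec.tissue_sd, size=(p, spec.n_tissues))
        values += offsets[:, tissue]
    values[planted_idx, :] += spec.effect_size * latent[None, :]

    neg_log = spec.gi50_intercept + spec.gi50_slope * latent + rng.normal(
        0.0, spec.gi50_noise_sd, size=n
    )
    gi50 = np.power(10.0, -neg_log)

    expr = pd.DataFrame(values, index=probe_ids, columns=list(sample_ids))
    responses = pd.DataFrame({spec.drug_name: gi50}, index=list(sample_ids))
    responses.index.name = "sample"
    truth = SyntheticTruth(
        planted_probes=tuple(probe_ids[i] for i in planted_idx),
        latent_sensitivity=latent,
        tissue_of_sample=tissue,
        sample_ids=sample_ids,
    )
    return expr, responses, truth


def generate_tissue_panel(
    spec: SyntheticSpec, tissues: int
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a panel split into ``tissues`` baseline-shifted blocks.

    The drug-sensitivity signal is shared across tissues; only baseline
    expression differs per block, supporting training-set diversity
    experiments (train on a few blocks, test on held-out blocks).
    """
    if tissues < 2:
        raise ValueError("a tissue panel needs at least 2 blocks")
    return generate(replace(spec, n_tissues=tissues))


def collapse_to_gene(expr: pd.DataFrame, mode: str = "mean") -> pd.DataFrame:
    """Collapse multi-probe rows to one row per gene (probe IDs 'GENE_pN').

    Rows without the '_p' isoform suffix pass through unchanged.
    """
    if mode != "mean":
        raise ValueError(f"unsupported gene-collapse mode {mode!r}")
    genes = [pid.rsplit("_p", 1)[0] for pid in expr.index]
    out = expr.groupby(genes, sort=False).mean()
    out.index.name = expr.index.name
    return out


def write_truth(truth: SyntheticTruth, path) -> None:
    """Persist the planted truth as TSV (planted probes; per-sample latent/tissue)."""
    with open(path, "w") as fh:
        fh.write("# planted_probes: " + ",".join(truth.planted_probes) + "\n")
        fh.write("sample\tlatent_sensitivity\ttissue\n")
        for sid, s, t in zip(truth.sample_ids, truth.latent_sensitivity, truth.tissue_of_sample):
            fh.write(f"{sid}\t{float(s)!r}\t{t}\n")
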