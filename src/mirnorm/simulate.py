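"""Synthetic qPCR Cq tables with planted stable reference genes.

The generator emulates the curated expression tables the pipeline consumes:
a genes x samples matrix of quantification cycles in a realistic 15-35 cycle
window, with an additive structure

    Cq[g, s] = baseline[g] + sample_shift[s] + group_effect[g, group(s)] + noise

* ``baseline`` — each gene's mean abundance, uniform over the configured Cq
  range.
* ``sample_shift`` — a per-sample offset shared by all genes, mimicking RNA
  loading / input differences (exactly the nuisance a normalizer removes).
* ``group_effect`` — per-(gene, group) systematic shifts for non-stable genes
  when the design has sample groups; planted stable genes have none.
* ``noise`` — Gaussian on the Cq (log) scale; planted stable genes use a
  small common SD, the rest draw per-gene SDs from a configurable range.

Non-detects are inserted as missing values, uniformly at random by default or
biased toward high-Cq (low-abundance) cells on request.  The planted stable
genes are the ground truth against which recovery of the full pipeline is
measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset_io import RawDataset, curate_dataset
from .ranking import final_score

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "generate_dataset",
    "planted_recovery_rate",
    "write_dataset",
]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic qPCR dataset (all SD units: Cq cycles)."""

    n_genes: int = 200
    n_samples: int = 12
    n_groups: int = 1
    n_stable: int = 3
    baseline_cq_range: tuple[float, float] = (15.0, 35.0)
    stable_sd: float = 0.1
    unstable_sd_range: tuple[float, float] = (0.5, 3.0)
    group_effect_sd: float = 1.0
    sample_shift_sd: float = 0.5
    missing_rate: float = 0.0
    missing_mode: str = "random"  # or "high_cq"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be at least 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_groups < 1:
            raise ValueError("n_groups must be at least 1")
        if self.n_groups > self.n_samples // 2:
            raise ValueError("n_groups too large: each group needs at least 2 samples")
        if not 0 <= self.n_stable <= self.n_genes:
            raise ValueError("n_stable must lie in [0, n_genes]")
        if self.baseline_cq_range[0] > self.baseline_cq_range[1]:
            raise ValueError("baseline_cq_range must be (low, high)")
        if self.stable_sd < 0:
            raise ValueError("stable_sd must be >= 0")
        if self.unstable_sd_range[0] < 0 or self.unstable_sd_range[0] > self.unstable_sd_range[1]:
            raise ValueError("unstable_sd_range must be (low, high) with low >= 0")
        if self.group_effect_sd < 0:
            raise ValueError("group_effect_sd must be >= 0")
        if self.sample_shift_sd < 0:
            raise ValueError("sample_shift_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mode not in ("random", "high_cq"):
            raise ValueError("missing_mode must be 'random' or 'high_cq'")


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset."""

    stable_gene_ids: list[str]
    gene_sd: dict[str, float]
    group_effects: pd.DataFrame | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.gene_sd)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "true_sd": [self.gene_sd[g] for g in genes],
                "is_stable": [g in set(self.stable_gene_ids) for g in genes],
            }
        )


def generate_dataset(spec: SimulationSpec) -> tuple[RawDataset, GroundTruth]:
    """Draw one synthetic Cq table and its ground truth from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"miR-{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    sample_ids = [f"S{j:03d}" for j in range(1, spec.n_samples + 1)]

    stable_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_stable, replace=False))
    stable_mask = np.zeros(spec.n_genes, dtype=bool)
    stable_mask[stable_idx] = True

    gene_sd = rng.uniform(*spec.unstable_sd_range, size=spec.n_genes)
    gene_sd[stable_mask] = spec.stable_sd

    baseline = rng.uniform(*spec.baseline_cq_range, size=spec.n_genes)
    sample_shift = rng.normal(0.0, spec.sample_shift_sd, size=spec.n_samples)

    if spec.n_groups > 1:
        group_of_sample = np.arange(spec.n_samples) % spec.n_groups
        group_labels = [f"G{g + 1}" for g in group_of_sample]
        effects = rng.normal(0.0, spec.group_effect_sd, size=(spec.n_genes, spec.n_groups))
        effects[stable_mask] = 0.0
        group_term = effects[:, group_of_sample]
        effects_frame = pd.DataFrame(
            effects, index=gene_ids, columns=[f"G{g + 1}" for g in range(spec.n_groups)]
        )
    else:
        group_labels = None
        group_term = 0.0
        effects_frame = None

    noise = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_samples)) * gene_sd[:, None]
    values = baseline[:, None] + sample_shift[None, :] + group_term + noise

    if spec.missing_rate > 0:
        n_cells = values.size
        n_missing = int(round(spec.missing_rate * n_cells))
        if n_missing:
            if spec.missing_mode == "random":
                flat = rng.choice(n_cells, size=n_missing, replace=False)
            else:
                # bias non-detects toward high-Cq (low-abundance) reactions
                order = np.argsort(values, axis=None)
                weights = np.empty(n_cells)
                weights[order] = np.arange(1, n_cells + 1)
                weights /= weights.sum()
                flat = rng.choice(n_cells, size=n_missing, replace=False, p=weights)
            values.flat[flat] = np.nan

    raw = RawDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        group_labels=group_labels,
        source_tag=f"synthetic(seed={spec.seed})",
    )
    truth = GroundTruth(
        stable_gene_ids=[gene_ids[i] for i in stable_idx],
        gene_sd=dict(zip(gene_ids, gene_sd.tolist())),
        group_effects=effects_frame,
    )
    return raw, truth


def planted_recovery_rate(
    n_runs: int, spec: SimulationSpec, top_k: int
) -> float:
    """Fraction of simulated runs recovering every planted gene in the top k.

    Each run draws a fresh dataset (seed derived from ``spec.seed``), curates
    it, ranks all genes by final normalization score, and checks that all
    planted stable genes fall within the first ``top_k`` positions.
    """
    if top_k < spec.n_stable:
        raise ValueError("top_k must be at least n_stable")
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    base = 0 if spec.seed is None else spec.seed
    hits = 0
    for run in range(n_runs):
        run_spec = replace(spec, seed=(base + 10007 * run) % (2**31 - 1))
        raw, truth = generate_dataset(run_spec)
        curated = curate_dataset(raw)
        records = final_score(curated.to_expression_table())
        top = {r.entry_id for r in records[:top_k]}
        if set(truth.stable_gene_ids) <= top:
            hits += 1
    return hits / n_runs


def write_dataset(raw: RawDataset, truth: GroundTruth, matrix_path, truth_path=None) -> None:
    """Emit the table in the CSV dialect the loader reads, plus ground truth."""
    raw.to_frame().to_csv(matrix_path, index_label="gene_id")
    if truth_path is not None:
        truth.to_frame().to_csv(truth_path, index=False)
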