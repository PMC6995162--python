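"""Expression-stability scoring of candidate reference genes.

Three families of stability measures are computed on a complete Cq matrix,
each returning one non-negative value per gene where *lower means more
stable*:

* **GeNorm M** — the mean, over all other genes, of the standard deviation of
  the pairwise log2 expression ratio across samples.  On Cq input the log2
  ratio of gene *j* versus gene *k* in a sample is ``Cq_k - Cq_j`` (a Cq is
  approximately the negative log2 of relative template amount at
  amplification efficiency 2).  An iterative mode repeatedly discards the
  least stable gene and recomputes M until two genes remain.
* **NormFinder** — a model-based decomposition of each gene's variation into
  intergroup (systematic shift between sample groups) and intragroup (noise)
  components, combined into a single stability value.  An ungrouped variant
  scores the per-gene residual variation around additive gene + sample
  effects.
* **BestKeeper** — the standard deviation of each gene's Cq across samples.

All standard deviations use the n-1 (sample) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "StabilityScores",
    "genorm_scores",
    "normfinder_scores",
    "bestkeeper_scores",
    "bestkeeper_diagnostics",
    "scores_to_frame",
]


@dataclass
class ExpressionTable:
    """A complete (no missing values) Cq matrix ready for stability scoring."""

    gene_ids: list[str]
    sample_ids: list[str]
    cq: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        if self.cq.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("cq matrix shape does not match identifier lists")
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if not np.isfinite(self.cq).all():
            raise ValueError("expression table must be complete and finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if self.groups is not None and len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label per sample required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def has_groups(self) -> bool:
        return self.groups is not None and len(set(self.groups)) >= 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cq, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, groups=None) -> "ExpressionTable":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            cq=frame.to_numpy(dtype=float),
            groups=list(groups) if groups is not None else None,
        )

    def with_entry(self, entry_id: str, profile: np.ndarray) -> "ExpressionTable":
        """Return a copy augmented with one additional row (the base table is
        never mutated)."""
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (self.n_samples,):
            raise ValueError(
                f"profile length {profile.shape} does not match {self.n_samples} samples"
            )
        if entry_id in self.gene_ids:
            raise ValueError(f"entry id {entry_id!r} already present in the table")
        return ExpressionTable(
            gene_ids=[*self.gene_ids, entry_id],
            sample_ids=list(self.sample_ids),
            cq=np.vstack([self.cq, profile[None, :]]),
            groups=list(self.groups) if self.groups is not None else None,
        )


@dataclass
class StabilityScores:
    """Per-gene raw stability values from one algorithm (lower = more stable)."""

    algorithm: str
    score_by_gene: dict[str, float]
    exclusion_order: list[str] | None = field(default=None)


# ---------------------------------------------------------------------------
# GeNorm
# ---------------------------------------------------------------------------

def pairwise_ratio_sd(cq: np.ndarray) -> np.ndarray:
    """Matrix V with V[j, k] = sd over samples of the pairwise log2 ratio of
    genes j and k (zero diagonal).  On Cq input the ratio series is
    ``cq[k] - cq[j]``; its sd is symmetric in j, k."""
    diffs = cq[None, :, :] - cq[:, None, :]
    v = diffs.std(axis=2, ddof=1)
    np.fill_diagonal(v, 0.0)
    return v


def _m_values(cq: np.ndarray) -> np.ndarray:
    v = pairwise_ratio_sd(cq)
    n = cq.shape[0]
    return v.sum(axis=1) / (n - 1)


def genorm_scores(expr: ExpressionTable, mode: str = "single_pass") -> StabilityScores:
    """GeNorm stability value M for every gene.

    ``single_pass`` scores all genes on the full table.  ``iterative``
    additionally performs stepwise exclusion: the gene with the highest
    (worst) M is removed and M recomputed until two genes remain; each gene's
    score is its M at the iteration it was excluded, the final two sharing the
    last-iteration M.  Ties on the worst M are broken by excluding the
    lexicographically first tied gene id.
    """
    if mode not in ("single_pass", "iterative"):
        raise ValueError(f"unknown genorm mode {mode!r}")
    if expr.n_genes < 2:
        raise ValueError("genorm needs at least 2 genes")

    if mode == "single_pass":
        m = _m_values(expr.cq)
        return StabilityScores("genorm", dict(zip(expr.gene_ids, m.tolist())))

    if expr.n_genes < 3:
        raise ValueError("iterative genorm needs at least 3 genes")
    remaining = list(range(expr.n_genes))
    scores: dict[str, float] = {}
    excluded: list[str] = []
    while len(remaining) > 2:
        sub = expr.cq[remaining]
        m = _m_values(sub)
        worst_m = m.max()
        tied = [i for i, mv in zip(remaining, m) if mv == worst_m]
        drop = min(tied, key=lambda i: expr.gene_ids[i])
        scores[expr.gene_ids[drop]] = float(m[remaining.index(drop)])
        excluded.append(expr.gene_ids[drop])
        remaining.remove(drop)
    final_m = _m_values(expr.cq[remaining])
    for i, idx in enumerate(remaining):
        scores[expr.gene_ids[idx]] = float(final_m[i])
    return StabilityScores("genorm", scores, exclusion_order=excluded)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _group_slices(groups: list[str]) -> dict[str, np.ndarray]:
    labels: dict[str, list[int]] = {}
    for j, g in enumerate(groups):
        labels.setdefault(g, []).append(j)
    return {g: np.asarray(ix) for g, ix in sorted(labels.items())}


def _intragroup_variances(block: np.ndarray) -> np.ndarray:
    """Unbiased per-gene residual variances within one group.

    ``block`` is genes x samples for a single group.  The two-way centered
    residuals absorb gene means and per-sample (loading) effects; because the
    sample mean over k genes removes a 1/k share of every gene's own noise,
    the naive residual variance is deflated and contaminated by the other
    genes — the closed-form correction below inverts that exactly:
    ``var_i = k/(k-2) * (s2_i - mean(s2)/(k-1))``.  Negative estimates are
    clamped to zero.
    """
    k, n = block.shape
    if k < 3:
        raise ValueError("the model-based estimator needs at least 3 genes")
    if n < 2:
        raise ValueError("each group needs at least 2 samples")
    centered = (
        block
        - block.mean(axis=1, keepdims=True)
        - block.mean(axis=0, keepdims=True)
        + block.mean()
    )
    s2 = (centered**2).sum(axis=1) / (n - 1)
    var = (k / (k - 2)) * (s2 - s2.mean() / (k - 1))
    return np.maximum(var, 0.0)


def normfinder_scores(expr: ExpressionTable, use_groups: bool) -> StabilityScores:
    """NormFinder model-based stability values (lower = more stable).

    Grouped variant: per gene *i* and group *g* the intergroup difference
    ``d[i,g]`` (two-way centered gene-by-group mean) is shrunk toward zero by
    an empirical-Bayes factor ``gamma2 / (gamma2 + c[i,g])``, where ``c[i,g] =
    var[i,g]/n_g`` is its sampling variance and ``gamma2`` the estimated
    variance of the true intergroup differences across genes.  The per-group
    stability is ``|d_shrunk| + sqrt(posterior var of d + var[i,g]/n_g)`` —
    the magnitude of the systematic group effect plus the standard deviation
    of its uncertainty and the gene's own noise — averaged over groups.

    Ungrouped variant: the square root of the per-gene residual variance
    around additive gene + per-sample effects.
    """
    if use_groups:
        if expr.groups is None:
            raise ValueError("grouped NormFinder requires sample group labels")
        slices = _group_slices(expr.groups)
        if len(slices) < 2:
            raise ValueError("grouped NormFinder requires at least 2 groups")
        for g, ix in slices.items():
            if len(ix) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        k = expr.n_genes
        n_groups = len(slices)
        group_names = list(slices)

        var = np.empty((k, n_groups))
        means = np.empty((k, n_groups))
        sizes = np.empty(n_groups)
        for a, g in enumerate(group_names):
            block = expr.cq[:, slices[g]]
            var[:, a] = _intragroup_variances(block)
            means[:, a] = block.mean(axis=1)
            sizes[a] = len(slices[g])

        d = means - means.mean(axis=1, keepdims=True) - means.mean(axis=0, keepdims=True) + means.mean()
        c = var / sizes[None, :]
        gamma2 = max(0.0, (d**2).sum() / ((k - 1) * (n_groups - 1)) - c.mean())
        denom = gamma2 + c
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
        d_shrunk = d * shrink
        post_var = np.where(denom > 0, gamma2 * c / np.where(denom > 0, denom, 1.0), 0.0)
        rho = np.abs(d_shrunk) + np.sqrt(post_var + c)
        stability = rho.mean(axis=1)
        return StabilityScores("normfinder_grouped", dict(zip(expr.gene_ids, stability.tolist())))

    var = _intragroup_variances(expr.cq)
    return StabilityScores("normfinder_ungrouped", dict(zip(expr.gene_ids, np.sqrt(var).tolist())))


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper_scores(expr: ExpressionTable) -> StabilityScores:
    """BestKeeper stability: per-gene standard deviation of Cq across samples."""
    sd = expr.cq.std(axis=1, ddof=1)
    return StabilityScores("bestkeeper", dict(zip(expr.gene_ids, sd.tolist())))


def bestkeeper_diagnostics(expr: ExpressionTable) -> pd.DataFrame:
    """Optional BestKeeper-style diagnostics, not used in the normalization score.

    Returns, per gene: the Cq standard deviation and the Pearson correlation
    with the BestKeeper index (the per-sample mean Cq over all genes, i.e. the
    geometric mean on the linear scale).
    """
    index = expr.cq.mean(axis=0)
    sd = expr.cq.std(axis=1, ddof=1)
    centered = expr.cq - expr.cq.mean(axis=1, keepdims=True)
    idx_centered = index - index.mean()
    denom = np.sqrt((centered**2).sum(axis=1) * (idx_centered**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (centered @ idx_centered) / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(
        {"sd": sd, "r_vs_index": r},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def scores_to_frame(scores_list: list[StabilityScores]) -> pd.DataFrame:
    """Long-format export: one row per (gene, algorithm) stability value."""
    rows = [
        {"gene_id": gene, "algorithm": s.algorithm, "stability_value": value}
        for s in scores_list
        for gene, value in s.score_by_gene.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "algorithm", "stability_value"])
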