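"""Scoring multi-gene normalization factors by sequential dataset augmentation.

A combination of 2 or 3 genes is evaluated as a single normalization factor
by appending one extra entry to the dataset — the per-sample arithmetic mean
of the member genes' Cq values (the geometric mean of the underlying linear
quantities) — and rescoring the augmented table of N+1 entries with the full
stability suite.  Only one combination is ever present in the table at a
time: after its final score and place are recorded the entry is discarded, so
the base table is never perturbed by more than one synthetic row and scores
of different combinations never interact.

Exhaustive enumeration of all pairs and triples is the dominant cost of the
workflow, so a fast path caches every statistic of the base table that does
not involve the augmented entry (the GeNorm pairwise-SD row sums and the
BestKeeper SDs); per combination only the entry-vs-gene statistics are
computed.  The naive path (full recomputation on the stacked table) remains
available and the two are required to agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd

from .ranking import RankRecord, final_score, fractional_rank
from .stability import ExpressionTable, normfinder_scores, pairwise_ratio_sd

__all__ = [
    "GLOBAL_MEAN_SENTINEL",
    "CombinationRecord",
    "ComponentComparison",
    "DatasetScorer",
    "make_combination_profile",
    "score_augmented_entry",
    "enumerate_combinations",
    "global_mean_factor",
    "compare_to_components",
    "records_to_frame",
]

#: Member sentinel for the global-mean normalization factor (mean of all genes).
GLOBAL_MEAN_SENTINEL = "ALL"


@dataclass
class CombinationRecord:
    """One combination's final score and placement within its augmented dataset."""

    members: tuple[str, ...]
    dataset_id: str
    rank_by_algorithm: dict[str, float]
    final_score: float
    place: int

    @property
    def entry_id(self) -> str:
        return ";".join(self.members)


@dataclass
class ComponentComparison:
    """How combinations compare against their own component genes.

    ``counts_by_n_better[m]`` is the number of combinations for which exactly
    ``m`` component genes have a strictly lower (better) final score than the
    combination itself.  ``m = 0`` means the combination beat all of its
    components; ``m = k`` means every component beat it.
    """

    k: int
    counts_by_n_better: dict[int, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts_by_n_better.values())

    def category_counts(self) -> dict[str, int]:
        counts = {"better_than_all_components": 0, "better_than_some": 0, "worse_than_all_components": 0}
        for m, c in self.counts_by_n_better.items():
            if m == 0:
                counts["better_than_all_components"] += c
            elif m == self.k:
                counts["worse_than_all_components"] += c
            else:
                counts["better_than_some"] += c
        return counts

    def category_fractions(self) -> dict[str, float]:
        total = self.n_total
        return {k: v / total for k, v in self.category_counts().items()} if total else {}


def make_combination_profile(expr: ExpressionTable, members: tuple[str, ...]) -> np.ndarray:
    """Per-sample arithmetic mean of the member genes' Cq values."""
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [m for m in members if m not in index]
    if missing:
        raise KeyError(f"member gene(s) not in table: {missing}")
    rows = [index[m] for m in members]
    return expr.cq[rows].mean(axis=0)


class DatasetScorer:
    """Repeated augmented-entry scoring of one base table.

    Precomputes base-table statistics once; :meth:`score_entry` then scores a
    candidate profile as the (N+1)-th entry.  With ``naive=True`` every call
    recomputes all statistics on the stacked table instead of reusing the
    cache — the two modes must produce identical results.
    """

    def __init__(self, expr: ExpressionTable, dataset_id: str = "", naive: bool = False):
        self.expr = expr
        self.dataset_id = dataset_id
        self.naive = naive
        self._suite_algorithms = [s.algorithm for s in _augmented_suite_probe(expr)]
        if not naive:
            v = pairwise_ratio_sd(expr.cq)
            self._genorm_rowsum = v.sum(axis=1)
            self._bestkeeper_sd = expr.cq.std(axis=1, ddof=1)

    def score_entry(
        self, profile: np.ndarray, entry_id: str, members: tuple[str, ...]
    ) -> CombinationRecord:
        profile = np.asarray(profile, dtype=float)
        expr = self.expr
        if profile.shape != (expr.n_samples,):
            raise ValueError(
                f"profile length {profile.shape[0] if profile.ndim else 0} does not "
                f"match {expr.n_samples} samples"
            )
        if entry_id in expr.gene_ids:
            raise ValueError(f"entry id {entry_id!r} already present in the table")

        n = expr.n_genes
        aug_ids = [*expr.gene_ids, entry_id]

        if self.naive:
            aug = expr.with_entry(entry_id, profile)
            from .ranking import compute_stability_suite

            suite = compute_stability_suite(aug)
            score_maps = {s.algorithm: s.score_by_gene for s in suite}
        else:
            score_maps = {}
            # GeNorm: only the entry-vs-gene pairwise SDs are new.
            v_new = (expr.cq - profile[None, :]).std(axis=1, ddof=1)
            m_genes = (self._genorm_rowsum + v_new) / n
            m_entry = v_new.sum() / n
            score_maps["genorm"] = dict(zip(aug_ids, [*m_genes.tolist(), float(m_entry)]))
            # NormFinder: model fits involve all entries jointly; recompute on
            # the stacked matrix (linear cost, no pairwise structure to cache).
            if n + 1 >= 3:
                aug = ExpressionTable(
                    gene_ids=aug_ids,
                    sample_ids=list(expr.sample_ids),
                    cq=np.vstack([expr.cq, profile[None, :]]),
                    groups=list(expr.groups) if expr.groups is not None else None,
                )
                if "normfinder_grouped" in self._suite_algorithms:
                    score_maps["normfinder_grouped"] = normfinder_scores(aug, use_groups=True).score_by_gene
                score_maps["normfinder_ungrouped"] = normfinder_scores(aug, use_groups=False).score_by_gene
            # BestKeeper: per-gene SDs are independent of the entry.
            sd_entry = float(profile.std(ddof=1))
            score_maps["bestkeeper"] = dict(
                zip(aug_ids, [*self._bestkeeper_sd.tolist(), sd_entry])
            )

        per_alg = {alg: fractional_rank(m) for alg, m in score_maps.items()}
        finals = {
            e: float(np.mean([per_alg[a][e] for a in per_alg])) for e in aug_ids
        }
        entry_final = finals[entry_id]
        place = 1 + sum(1 for e, s in finals.items() if s < entry_final)
        return CombinationRecord(
            members=tuple(sorted(members)),
            dataset_id=self.dataset_id,
            rank_by_algorithm={a: per_alg[a][entry_id] for a in per_alg},
            final_score=entry_final,
            place=place,
        )


def _augmented_suite_probe(expr: ExpressionTable) -> list:
    """Which algorithms apply to this table once augmented (N+1 >= 3 genes)."""
    from .ranking import compute_stability_suite

    probe = ExpressionTable(
        gene_ids=[*expr.gene_ids, "\x00probe"],
        sample_ids=list(expr.sample_ids),
        cq=np.vstack([expr.cq, expr.cq[:1]]),
        groups=list(expr.groups) if expr.groups is not None else None,
    )
    return compute_stability_suite(probe)


def score_augmented_entry(
    expr: ExpressionTable,
    entry_profile: np.ndarray,
    entry_id: str,
    members: tuple[str, ...] | None = None,
    dataset_id: str = "",
    naive: bool = False,
) -> CombinationRecord:
    """Score one extra entry in the context of the whole dataset.

    Convenience wrapper constructing a :class:`DatasetScorer` for a single
    call; use the scorer directly for repeated scoring of the same table.
    """
    scorer = DatasetScorer(expr, dataset_id=dataset_id, naive=naive)
    return scorer.score_entry(entry_profile, entry_id, members or (entry_id,))


def enumerate_combinations(
    expr: ExpressionTable,
    k: int,
    candidate_pool: list[str] | None = None,
    dataset_id: str = "",
    naive: bool = False,
    progress: bool = False,
) -> list[CombinationRecord]:
    """Score every k-subset of the candidate pool as a normalization factor.

    ``k = 1`` reduces exactly to the plain single-gene ranking (no entry is
    appended — a duplicate row would perturb the scores of its twin).  For
    ``k`` of 2 or 3 each subset is scored by sequential augmentation; only
    one combination entry exists in the table at any time.  ``k > 3`` is
    rejected: the combinatorial cost grows too fast to be useful.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k={k} is not supported; combinations of at most 3 genes are scored")
    pool = list(candidate_pool) if candidate_pool is not None else list(expr.gene_ids)
    unknown = [g for g in pool if g not in set(expr.gene_ids)]
    if unknown:
        raise KeyError(f"candidate pool gene(s) not in table: {unknown}")
    if len(pool) < k:
        raise ValueError(f"candidate pool of {len(pool)} genes is smaller than k={k}")
    pool = sorted(set(pool))

    if k == 1:
        singles = {r.entry_id: r for r in final_score(expr)}
        return [
            CombinationRecord(
                members=(g,),
                dataset_id=dataset_id,
                rank_by_algorithm=dict(singles[g].rank_by_algorithm),
                final_score=singles[g].final_score,
                place=singles[g].place,
            )
            for g in pool
        ]

    scorer = DatasetScorer(expr, dataset_id=dataset_id, naive=naive)
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    records = []
    combos = list(iter_combinations(pool, k))
    iterator = combos
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(combos, desc=f"{dataset_id or 'dataset'} k={k}")
        except ImportError:
            pass
    for members in iterator:
        rows = [index[m] for m in members]
        profile = expr.cq[rows].mean(axis=0)
        records.append(scorer.score_entry(profile, ";".join(members), members))
    return records


def global_mean_factor(
    expr: ExpressionTable, dataset_id: str = "", naive: bool = False
) -> CombinationRecord:
    """Score the per-sample mean of all genes as a single normalization factor."""
    profile = expr.cq.mean(axis=0)
    record = score_augmented_entry(
        expr,
        profile,
        entry_id=f"{GLOBAL_MEAN_SENTINEL}:{expr.n_genes}",
        members=(GLOBAL_MEAN_SENTINEL,),
        dataset_id=dataset_id,
        naive=naive,
    )
    return record


def compare_to_components(
    records: list[CombinationRecord], singles: list[RankRecord] | dict[str, float]
) -> ComponentComparison:
    """Classify combinations by how many of their components outrank them.

    For every combination, count the component genes whose single-gene final
    score is strictly lower (better) than the combination's.  The counts
    partition the combinations into ``better_than_all_components`` (0),
    intermediate, and ``worse_than_all_components`` (all k).
    """
    if not records:
        raise ValueError("no combination records to compare")
    ks = {len(r.members) for r in records}
    if len(ks) != 1:
        raise ValueError(f"records mix combination sizes {sorted(ks)}")
    k = ks.pop()
    if k < 2:
        raise ValueError("component comparison is defined for combinations of >= 2 genes")
    if isinstance(singles, dict):
        single_scores = singles
    else:
        single_scores = {r.entry_id: r.final_score for r in singles}
    counts: dict[int, int] = {m: 0 for m in range(k + 1)}
    for r in records:
        missing = [m for m in r.members if m not in single_scores]
        if missing:
            raise KeyError(f"no single-gene score for component(s) {missing}")
        n_better = sum(1 for m in r.members if single_scores[m] < r.final_score)
        counts[n_better] += 1
    return ComponentComparison(k=k, counts_by_n_better=counts)


def records_to_frame(records: list[CombinationRecord]) -> pd.DataFrame:
    """CSV-ready table: members (semicolon-joined), ranks, final score, place."""
    algorithms = sorted({a for r in records for a in r.rank_by_algorithm})
    rows = []
    for r in records:
        row = {"members": r.entry_id, "dataset_id": r.dataset_id}
        for a in algorithms:
            row[f"rank_{a}"] = r.rank_by_algorithm.get(a, np.nan)
        row["final_score"] = r.final_score
        row["place"] = r.place
        rows.append(row)
    return pd.DataFrame(rows)
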