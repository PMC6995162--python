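"""Fractional ranking of stability values and cross-dataset aggregation.

Each stability algorithm produces raw values on its own scale; to combine
them, every gene receives a fractional rank within its dataset:

    rank = (place in the ascending sort - 1) / (number of entries)

which lies in [0, 1) with 0 for the most stable entry.  The final
normalization score of an entry is the arithmetic mean of its fractional
ranks over the applicable algorithms; entries are then ordered ascending
(lower = better normalizer).  Rankings from several datasets are combined by
an unweighted mean over the datasets that contain the entry, restricted to
entries present in more than a threshold fraction of datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stability import (
    ExpressionTable,
    StabilityScores,
    bestkeeper_scores,
    genorm_scores,
    normfinder_scores,
)

__all__ = [
    "RankRecord",
    "CombinedRanking",
    "fractional_rank",
    "compute_stability_suite",
    "final_score",
    "rank_table",
    "aggregate_across_datasets",
    "summarize_factor_classes",
]


@dataclass
class RankRecord:
    """Per-entry fractional ranks per algorithm and their mean (final score)."""

    entry_id: str
    rank_by_algorithm: dict[str, float]
    final_score: float
    place: int | None = field(default=None)


@dataclass
class CombinedRanking:
    """Cross-dataset consensus: mean final score per entry plus its presence."""

    scores: dict[str, float]
    presence_fraction: dict[str, float]
    n_datasets: int

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.scores.items(), key=lambda kv: (kv[1], kv[0]))
        return pd.DataFrame(
            {
                "entry_id": [e for e, _ in rows],
                "combined_score": [s for _, s in rows],
                "presence_fraction": [self.presence_fraction[e] for e, _ in rows],
            }
        )


def fractional_rank(scores: dict[str, float]) -> dict[str, float]:
    """Map stability values to fractional ranks (place - 1) / n in [0, 1).

    Lower stability values receive lower ranks.  Tied values receive the mean
    of the fractional ranks they would occupy, so the rank multiset sum is
    unchanged by ties.
    """
    if not scores:
        raise ValueError("cannot rank an empty score map")
    entries = list(scores)
    values = np.asarray([scores[e] for e in entries], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("stability values must be finite")
    n = len(entries)
    ranks = (rankdata(values, method="average") - 1.0) / n
    return dict(zip(entries, ranks.tolist()))


def compute_stability_suite(expr: ExpressionTable) -> list[StabilityScores]:
    """Run every applicable stability algorithm on a table.

    Always GeNorm (single pass) and BestKeeper; NormFinder ungrouped when the
    table has at least 3 genes (the model-based estimator is undefined for
    2); NormFinder grouped additionally when valid group labels are present
    (>= 2 groups of >= 2 samples).  Tables with groups therefore contribute 4
    algorithm rankings, ungrouped tables 3.
    """
    suite = [genorm_scores(expr, mode="single_pass")]
    if expr.n_genes >= 3:
        if expr.has_groups:
            counts = pd.Series(expr.groups).value_counts()
            if (counts >= 2).all():
                suite.append(normfinder_scores(expr, use_groups=True))
        suite.append(normfinder_scores(expr, use_groups=False))
    suite.append(bestkeeper_scores(expr))
    return suite


def _records_from_suite(suite: list[StabilityScores]) -> list[RankRecord]:
    per_alg = {s.algorithm: fractional_rank(s.score_by_gene) for s in suite}
    entries = list(suite[0].score_by_gene)
    records = []
    for entry in entries:
        ranks = {alg: per_alg[alg][entry] for alg in per_alg}
        records.append(
            RankRecord(
                entry_id=entry,
                rank_by_algorithm=ranks,
                final_score=float(np.mean(list(ranks.values()))),
            )
        )
    records.sort(key=lambda r: (r.final_score, r.entry_id))
    finals = np.asarray([r.final_score for r in records])
    for r in records:
        r.place = int(np.sum(finals < r.final_score)) + 1
    return records


def final_score(expr: ExpressionTable) -> list[RankRecord]:
    """Final normalization scores for every gene of a curated table.

    Runs the applicable stability algorithms, fractional-ranks each, and
    averages the ranks per gene.  The result is sorted ascending by final
    score (ties by gene id); ``place`` is the 1-based competition rank, so
    entries tied at the minimum all hold place 1.
    """
    return _records_from_suite(compute_stability_suite(expr))


def rank_table(records: list[RankRecord]) -> pd.DataFrame:
    """Tabular export of a ranking: one row per entry, one column per algorithm."""
    algorithms = sorted({a for r in records for a in r.rank_by_algorithm})
    rows = []
    for r in records:
        row = {"entry_id": r.entry_id}
        for a in algorithms:
            row[f"rank_{a}"] = r.rank_by_algorithm.get(a, np.nan)
        row["final_score"] = r.final_score
        row["place"] = r.place
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_across_datasets(
    per_dataset: list[tuple[str, list[RankRecord]]],
    presence_threshold: float = 0.80,
) -> CombinedRanking:
    """Average final scores over datasets, keeping widely measured entries.

    An entry is retained only when present in strictly more than
    ``presence_threshold`` of the datasets; its combined score is the
    unweighted mean of its final scores from the datasets containing it.
    """
    if not per_dataset:
        raise ValueError("need at least one dataset to aggregate")
    n = len(per_dataset)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for _, records in per_dataset:
        for r in records:
            sums[r.entry_id] = sums.get(r.entry_id, 0.0) + r.final_score
            counts[r.entry_id] = counts.get(r.entry_id, 0) + 1
    scores = {}
    presence = {}
    for entry, cnt in counts.items():
        frac = cnt / n
        if frac > presence_threshold:
            scores[entry] = sums[entry] / cnt
            presence[entry] = frac
    return CombinedRanking(scores=scores, presence_fraction=presence, n_datasets=n)


def summarize_factor_classes(
    scores_by_class: dict[str, dict[str, list[float]]],
) -> pd.DataFrame:
    """Descriptive summary of final scores per normalization-factor class.

    ``scores_by_class`` maps a class name (e.g. ``"single"``, ``"pair"``,
    ``"triple"``, ``"global_mean"``) to ``{dataset_id: [final scores]}``.
    Returns one row per (class, dataset) with mean, sd (NaN when a class has
    a single member) and member count.  Purely descriptive; no hypothesis
    testing is performed.
    """
    rows = []
    for cls, by_dataset in scores_by_class.items():
        for ds, values in by_dataset.items():
            if not values:
                raise ValueError(f"class {cls!r} is empty in dataset {ds!r}")
            arr = np.asarray(values, dtype=float)
            rows.append(
                {
                    "factor_class": cls,
                    "dataset_id": ds,
                    "mean_final_score": float(arr.mean()),
                    "sd_final_score": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
                    "n": int(arr.size),
                }
            )
    return pd.DataFrame(rows)
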