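"""Monte-Carlo validation of a candidate reference-gene set.

A candidate set of genes (default size 13) is judged by the mean final
normalization score of every triple that can be built from it.  To calibrate
that mean, the same quantity is computed for many random same-size gene sets
drawn from the dataset's gene pool; the fraction of random sets whose mean is
strictly greater than the candidate's (``fraction_surpassed``) is the
empirical percentile of the candidate — the complement of a Monte-Carlo
p-value.  A ``fraction_surpassed`` near 1 means the candidate builds more
stable triples than essentially any random set of the same size.

Triple scores are deterministic given the dataset, so they are cached across
replicates: each distinct triple is scored once regardless of how many random
sets contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd

from .combinations import DatasetScorer
from .stability import ExpressionTable

__all__ = [
    "McDistribution",
    "McResult",
    "TripleScoreCache",
    "candidate_mean_ranking",
    "random_set_distribution",
    "percentile_of_candidate",
    "histogram_frame",
]


@dataclass
class McDistribution:
    """Empirical distribution of mean triple scores over random gene sets."""

    replicate_means: list[float]
    set_size: int
    n_replicates: int
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.replicate_means) != self.n_replicates:
            raise ValueError("length of replicate_means must equal n_replicates")


@dataclass
class McResult:
    """Placement of a candidate set within the random-set distribution."""

    candidate_mean: float
    fraction_surpassed: float
    n_replicates: int
    seed: int | None = field(default=None)


class TripleScoreCache:
    """Lazily scores triples of one dataset, each distinct triple once."""

    def __init__(self, expr: ExpressionTable, naive: bool = False):
        self.expr = expr
        self._scorer = DatasetScorer(expr, naive=naive)
        self._index = {g: i for i, g in enumerate(expr.gene_ids)}
        self._cache: dict[tuple[str, ...], float] = {}

    def score(self, members: tuple[str, ...]) -> float:
        members = tuple(sorted(members))
        if members not in self._cache:
            rows = [self._index[m] for m in members]
            profile = self.expr.cq[rows].mean(axis=0)
            record = self._scorer.score_entry(profile, ";".join(members), members)
            self._cache[members] = record.final_score
        return self._cache[members]

    def mean_over_triples(self, genes: list[str]) -> float:
        triples = list(iter_combinations(sorted(genes), 3))
        return float(np.mean([self.score(t) for t in triples]))


def candidate_mean_ranking(
    expr: ExpressionTable,
    candidate: set[str] | list[str],
    cache: TripleScoreCache | None = None,
) -> float:
    """Mean final score of all triples derivable from the candidate set.

    Genes absent from the dataset are ignored; at least 3 candidate genes
    must be present.
    """
    present = sorted(set(candidate) & set(expr.gene_ids))
    if len(present) < 3:
        raise ValueError(
            f"only {len(present)} candidate gene(s) present in the table; need >= 3"
        )
    if cache is None:
        cache = TripleScoreCache(expr)
    return cache.mean_over_triples(present)


def random_set_distribution(
    expr: ExpressionTable,
    set_size: int = 13,
    n_replicates: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cache: TripleScoreCache | None = None,
) -> McDistribution:
    """Distribution of mean triple scores for random gene sets.

    Each replicate draws ``set_size`` distinct genes uniformly without
    replacement from the dataset's pool and records the mean final score of
    all its triples.  Reproducible for a fixed seed.
    """
    if set_size < 3:
        raise ValueError("set_size must be at least 3")
    if set_size > expr.n_genes:
        raise ValueError(
            f"set_size {set_size} exceeds the {expr.n_genes} genes in the table"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if cache is None:
        cache = TripleScoreCache(expr)
    pool = np.asarray(sorted(expr.gene_ids))
    means = []
    for _ in range(n_replicates):
        genes = rng.choice(pool, size=set_size, replace=False)
        means.append(cache.mean_over_triples(genes.tolist()))
    return McDistribution(
        replicate_means=means, set_size=set_size, n_replicates=n_replicates, seed=seed
    )


def percentile_of_candidate(dist: McDistribution, candidate_mean: float) -> McResult:
    """Fraction of random-set means strictly greater than the candidate's.

    Ties count as not surpassed (conservative for the candidate).
    """
    if not dist.replicate_means:
        raise ValueError("empty Monte-Carlo distribution")
    arr = np.asarray(dist.replicate_means)
    fraction = float((arr > candidate_mean).mean())
    return McResult(
        candidate_mean=float(candidate_mean),
        fraction_surpassed=fraction,
        n_replicates=dist.n_replicates,
        seed=dist.seed,
    )


def histogram_frame(dist: McDistribution, bins: int = 40) -> pd.DataFrame:
    """Histogram of the replicate means as CSV-ready bin edges and counts."""
    counts, edges = np.histogram(dist.replicate_means, bins=bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
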