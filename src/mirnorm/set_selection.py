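"""Choosing a small reference-gene set from per-dataset combination rankings.

After every pair and triple has been scored in every dataset, the question
becomes: which *small* set of genes suffices to build a first-place
normalization factor in every dataset?  Because each combination is scored in
isolation, several combinations can tie at the minimum final score and all of
them hold place 1; the first-place index collects those tuples per dataset.
An exact branch-and-bound search then finds the smallest gene set containing
at least one first-place pair of every dataset, the candidate set is
validated against the first-place triples, and a dataset-normalized pairwise
co-occurrence ("normalizing affinity") matrix summarizes which genes tend to
build the best triples together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd

from .combinations import GLOBAL_MEAN_SENTINEL, CombinationRecord

__all__ = [
    "FirstPlaceIndex",
    "CoverResult",
    "collect_first_place",
    "minimal_cover_set",
    "validate_set_with_triples",
    "pair_affinity_matrix",
]


@dataclass
class FirstPlaceIndex:
    """Per-dataset lists of member tuples that placed first, split by size k."""

    by_k: dict[int, dict[str, list[tuple[str, ...]]]] = field(default_factory=dict)

    def datasets(self, k: int) -> list[str]:
        return sorted(self.by_k.get(k, {}))

    def tuples(self, k: int, dataset_id: str) -> list[tuple[str, ...]]:
        return self.by_k.get(k, {}).get(dataset_id, [])


@dataclass
class CoverResult:
    """All minimal gene sets covering one first-place pair per dataset."""

    feasible: bool
    size: int | None
    sets: list[tuple[str, ...]]


def collect_first_place(records_by_dataset: dict[str, list[CombinationRecord]]) -> FirstPlaceIndex:
    """Index every place-1 combination per dataset and combination size.

    Ties at the minimum final score all count as first place.  Global-mean
    sentinel entries are excluded (they name no concrete gene set).
    """
    index = FirstPlaceIndex()
    for ds, records in records_by_dataset.items():
        for r in records:
            if GLOBAL_MEAN_SENTINEL in r.members:
                continue
            if r.place == 1:
                k = len(r.members)
                index.by_k.setdefault(k, {}).setdefault(ds, []).append(tuple(sorted(r.members)))
    for k in index.by_k:
        for ds in index.by_k[k]:
            index.by_k[k][ds] = sorted(set(index.by_k[k][ds]))
    return index


def minimal_cover_set(
    index: FirstPlaceIndex, k: int = 2, max_size: int | None = None
) -> CoverResult:
    """Smallest gene set containing a first-place k-tuple of every dataset.

    Exact search: iterative deepening on the set size with branch-and-bound —
    at each node the search branches on the uncovered dataset with the fewest
    remaining options and adds one of its first-place tuples' missing genes.
    All distinct sets of the minimal size are returned, sorted.  When no set
    within ``max_size`` exists, the result is flagged infeasible.
    """
    per_dataset = index.by_k.get(k, {})
    if not per_dataset:
        raise ValueError(f"first-place index holds no k={k} entries")
    empty = [ds for ds, tuples in per_dataset.items() if not tuples]
    if empty:
        raise ValueError(f"dataset(s) without any first-place k={k} tuple: {empty}")

    datasets = sorted(per_dataset)
    options = {ds: [frozenset(t) for t in per_dataset[ds]] for ds in datasets}
    universe = sorted({g for opts in options.values() for s in opts for g in s})
    cap = max_size if max_size is not None else len(universe)

    def covered(ds: str, chosen: frozenset) -> bool:
        return any(s <= chosen for s in options[ds])

    solutions: set[frozenset] = set()

    def search(chosen: frozenset, budget: int) -> None:
        uncovered = [ds for ds in datasets if not covered(ds, chosen)]
        if not uncovered:
            solutions.add(chosen)
            return
        if budget <= 0:
            return
        # branch on the most constrained dataset
        ds = min(uncovered, key=lambda d: len(options[d]))
        tried: set[frozenset] = set()
        for tup in options[ds]:
            new = tup - chosen
            if not new or len(new) > budget:
                continue
            nxt = chosen | new
            if nxt in tried:
                continue
            tried.add(nxt)
            search(nxt, budget - len(new))

    for target in range(k, cap + 1):
        search(frozenset(), target)
        if solutions:
            minimal = min(len(s) for s in solutions)
            sets = sorted(tuple(sorted(s)) for s in solutions if len(s) == minimal)
            return CoverResult(feasible=True, size=minimal, sets=sets)
    return CoverResult(feasible=False, size=None, sets=[])


def validate_set_with_triples(
    candidate: set[str] | list[str], index: FirstPlaceIndex
) -> tuple[dict[str, bool], bool]:
    """Does the candidate set contain a first-place triple of every dataset?

    Returns the per-dataset coverage vector and the overall verdict.
    """
    per_dataset = index.by_k.get(3, {})
    if not per_dataset:
        raise ValueError("first-place index holds no k=3 entries")
    s = set(candidate)
    coverage = {
        ds: any(set(t) <= s for t in tuples) for ds, tuples in sorted(per_dataset.items())
    }
    return coverage, all(coverage.values())


def pair_affinity_matrix(
    index: FirstPlaceIndex, k: int = 3, mode: str = "per_dataset_total"
) -> pd.DataFrame:
    """Dataset-normalized pairwise co-occurrence within first-place triples.

    For every dataset and every first-place triple, each of the triple's
    three unordered gene pairs gains a weight; weights are summed over
    datasets into a symmetric, zero-diagonal matrix.  Normalization modes:

    * ``"per_dataset_total"`` (default): weight = 1 / (number of first-place
      k-tuples in the dataset), so every dataset contributes the same total
      mass regardless of how many combinations tied at first place.
    * ``"containing_pair"``: weight = 1 / (number of the dataset's
      first-place k-tuples containing that pair), an alternative reading of
      the normalization.
    """
    if mode not in ("per_dataset_total", "containing_pair"):
        raise ValueError(f"unknown affinity mode {mode!r}")
    per_dataset = index.by_k.get(k, {})
    if not per_dataset:
        raise ValueError(f"first-place index holds no k={k} entries")
    genes = sorted({g for tuples in per_dataset.values() for t in tuples for g in t})
    pos = {g: i for i, g in enumerate(genes)}
    matrix = np.zeros((len(genes), len(genes)))
    for ds, tuples in per_dataset.items():
        total = len(tuples)
        if total == 0:
            continue
        if mode == "containing_pair":
            pair_counts: dict[tuple[str, str], int] = {}
            for t in tuples:
                for a, b in iter_combinations(sorted(t), 2):
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
        for t in tuples:
            for a, b in iter_combinations(sorted(t), 2):
                if mode == "per_dataset_total":
                    w = 1.0 / total
                else:
                    w = 1.0 / pair_counts[(a, b)]
                matrix[pos[a], pos[b]] += w
                matrix[pos[b], pos[a]] += w
    return pd.DataFrame(matrix, index=genes, columns=genes)
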