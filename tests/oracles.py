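"""Independent reference implementations used as oracles by the tests.

Deliberately written with plain-Python loops and the stdlib ``statistics``
module (no numpy vectorization, no code shared with the package) so that
agreement with the package is a meaningful cross-check rather than a
tautology.
"""

from __future__ import annotations

import statistics
from math import sqrt


def genorm_m_bruteforce(rows: list[list[float]]) -> list[float]:
    """GeNorm M per gene: mean over partners of stdev of pairwise Cq differences."""
    n = len(rows)
    m = []
    for j in range(n):
        sds = []
        for k in range(n):
            if k == j:
                continue
            series = [rows[k][s] - rows[j][s] for s in range(len(rows[j]))]
            sds.append(statistics.stdev(series))
        m.append(sum(sds) / (n - 1))
    return m


def genorm_exclusion_bruteforce(rows: list[list[float]], ids: list[str]):
    """Stepwise exclusion with full recomputation; lexicographic tie-break.

    Returns (exclusion_order, score_by_gene) with the final two genes sharing
    the last-iteration M.
    """
    remaining = list(range(len(rows)))
    order: list[str] = []
    scores: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m_bruteforce([rows[i] for i in remaining])
        worst = max(m)
        tied = [remaining[i] for i, v in enumerate(m) if v == worst]
        drop = min(tied, key=lambda i: ids[i])
        scores[ids[drop]] = m[remaining.index(drop)]
        order.append(ids[drop])
        remaining.remove(drop)
    final = genorm_m_bruteforce([rows[i] for i in remaining])
    for pos, i in enumerate(remaining):
        scores[ids[i]] = final[pos]
    return order, scores


def _two_way_residual_variances(block: list[list[float]]) -> list[float]:
    """Per-gene unbiased residual variances in one group (plain loops)."""
    k = len(block)
    n = len(block[0])
    row_mean = [sum(r) / n for r in block]
    col_mean = [sum(block[i][j] for i in range(k)) / k for j in range(n)]
    grand = sum(row_mean) / k
    s2 = []
    for i in range(k):
        acc = 0.0
        for j in range(n):
            r = block[i][j] - row_mean[i] - col_mean[j] + grand
            acc += r * r
        s2.append(acc / (n - 1))
    s2_bar = sum(s2) / k
    return [max((k / (k - 2)) * (x - s2_bar / (k - 1)), 0.0) for x in s2]


def normfinder_ungrouped_bruteforce(rows: list[list[float]]) -> list[float]:
    """Stability = sqrt of the per-gene residual variance (single group)."""
    return [sqrt(v) for v in _two_way_residual_variances(rows)]


def normfinder_grouped_bruteforce(rows: list[list[float]], groups: list[str]) -> list[float]:
    """Model-based grouped stability value, coded independently with loops.

    Intergroup differences from the two-way centered gene x group mean table,
    empirical-Bayes shrinkage by gamma2 / (gamma2 + c), stability per group =
    |shrunk d| + sqrt(posterior variance + intragroup variance / group size),
    averaged over groups.
    """
    names = sorted(set(groups))
    k = len(rows)
    n_groups = len(names)
    var: dict[str, list[float]] = {}
    gmean: dict[str, list[float]] = {}
    size: dict[str, int] = {}
    for g in names:
        cols = [j for j, label in enumerate(groups) if label == g]
        block = [[rows[i][j] for j in cols] for i in range(k)]
        var[g] = _two_way_residual_variances(block)
        gmean[g] = [sum(r) / len(cols) for r in block]
        size[g] = len(cols)

    m = [[gmean[g][i] for g in names] for i in range(k)]
    row_mean = [sum(r) / n_groups for r in m]
    col_mean = [sum(m[i][a] for i in range(k)) / k for a in range(n_groups)]
    grand = sum(row_mean) / k
    d = [[m[i][a] - row_mean[i] - col_mean[a] + grand for a in range(n_groups)] for i in range(k)]
    c = [[var[names[a]][i] / size[names[a]] for a in range(n_groups)] for i in range(k)]

    sum_d2 = sum(d[i][a] ** 2 for i in range(k) for a in range(n_groups))
    c_bar = sum(c[i][a] for i in range(k) for a in range(n_groups)) / (k * n_groups)
    gamma2 = max(0.0, sum_d2 / ((k - 1) * (n_groups - 1)) - c_bar)

    stability = []
    for i in range(k):
        acc = 0.0
        for a in range(n_groups):
            denom = gamma2 + c[i][a]
            if denom > 0:
                d_shrunk = d[i][a] * gamma2 / denom
                post_var = gamma2 * c[i][a] / denom
            else:
                d_shrunk = 0.0
                post_var = 0.0
            acc += abs(d_shrunk) + sqrt(post_var + c[i][a])
        stability.append(acc / n_groups)
    return stability


def minimal_cover_bruteforce(options_by_dataset: dict[str, list[tuple[str, ...]]]):
    """All smallest gene sets covering one tuple per dataset, by exhaustive
    enumeration of subsets of the universe (feasible for <= ~12 genes)."""
    from itertools import combinations

    universe = sorted({g for tuples in options_by_dataset.values() for t in tuples for g in t})
    for size in range(1, len(universe) + 1):
        found = []
        for subset in combinations(universe, size):
            s = set(subset)
            if all(
                any(set(t) <= s for t in tuples)
                for tuples in options_by_dataset.values()
            ):
                found.append(tuple(subset))
        if found:
            return size, sorted(found)
    return None, []
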