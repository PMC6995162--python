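# Methods

This note documents the models and estimators implemented in `mirnorm`, the
numerical conventions, the design choices made where the design was genuinely
open, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Input model and curation

The unit of analysis is a complete genes × samples matrix of quantification
cycles (Cq/Ct). A Cq is treated as approximately −log2 of relative template
abundance at amplification efficiency 2; no efficiency calibration is
attempted (none is available for the array-style panels this targets).
Curation removes, in order: control probes (identifier patterns), duplicate
gene identifiers (first occurrence kept — a deterministic, order-stable rule;
how discordant duplicate probes should be merged is genuinely undecidable
without platform metadata), and every gene carrying at least one missing
value. Non-detects are missing values; an optional Cq detection ceiling can
convert high-cycle measurements to non-detects, but is off by default because
instruments and exports differ in where (or whether) they truncate.

Dataset-level inclusion requires ≥ 170 genes, ≥ 5 samples and a missing
fraction strictly below 20% (all configurable). Inclusion is a screen for
whether a dataset should inform a cross-dataset consensus; the CLI therefore
warns rather than refuses by default (`--strict` upgrades it to an error).

## Stability scores

All standard deviations throughout the package use the sample (n−1)
estimator, chosen once for consistency.

**GeNorm.** `M_j = mean_{k≠j} sd_s(Cq_ks − Cq_js)`. The single-pass mode
scores all genes on the full table and is what enters the final normalization
score; the iterative mode (worst gene excluded, M recomputed, down to two
genes) is available for the classical stepwise protocol. The final two genes
cannot be separated by the procedure and share the last-iteration M; ties on
the worst M are resolved by excluding the lexicographically first tied
identifier, for reproducibility.

**NormFinder, grouped.** Model: `Cq_igj = α_ig + β_gj + ε_igj` with gene *i*,
group *g* (size n_g), sample *j*, Var(ε_igj) = σ²_ig, k genes, G groups.

1. Within each group, two-way centering absorbs gene means and per-sample
   loading effects; with `s²_ig = Σ_j r²_igj / (n_g − 1)` the unbiased
   heteroscedastic intragroup variance is
   `σ̂²_ig = (k/(k−2)) · (s²_ig − s̄²_g/(k−1))`, clamped at 0.
   (The sample mean over k genes removes a 1/k share of each gene's own
   noise and mixes in the others'; the closed form inverts that exactly —
   derivable from E[s²_ig] = σ²_ig(k−2)/k + σ̄²_g/k.)
2. Intergroup differences `d̂_ig` are the two-way centered gene × group mean
   table (groups unweighted). Their sampling variance is approximated by
   `c_ig = σ̂²_ig / n_g`; the variance of the true differences across genes
   is `γ̂² = max(0, Σ d̂²/((k−1)(G−1)) − c̄)`.
3. Empirical-Bayes shrinkage `d̃ = d̂ · γ̂²/(γ̂² + c)` and per-group stability
   `ρ_ig = |d̃_ig| + sqrt(γ̂²c_ig/(γ̂²+c_ig) + c_ig)` — the magnitude of the
   systematic group effect plus one standard deviation of its combined
   uncertainty — averaged over groups into the gene's stability value.

The simplified closed-form estimator (rather than a full Bayesian fit) is
used deliberately: it reduces the model to the single per-gene value the
ranking needs. The k/(k−2) correction makes k = 2 undefined, so NormFinder
requires ≥ 3 genes; 2-gene tables are scored by GeNorm and BestKeeper only.
`c_ig` neglects the small covariance induced by the two-way centering of the
group-mean table; the same approximation is used consistently in the
independent loop-coded oracle the tests compare against.

**NormFinder, ungrouped.** The same bias-corrected residual variance with a
single group; stability is its square root (a residual SD in cycles).

**BestKeeper.** Per-gene SD of Cq across samples. The index-correlation
diagnostics (per-sample mean Cq as the "BestKeeper index", Pearson r of each
gene against it) are exposed separately but do not enter the normalization
score: the SD criterion is the part that ranks genes, and the original
index machinery has no published reference output to validate against.

## Ranking and aggregation

Per algorithm, entries are sorted ascending by stability value and ranked
`(place − 1)/n ∈ [0, 1)`. Tied stability values receive the mean of the
fractional ranks they would occupy, keeping the rank-sum invariant (the
classical formulation does not address ties). The final normalization score
is the unweighted mean of the available algorithm ranks — 4 with valid sample
groups (≥ 2 groups of ≥ 2), else 3; averaging only defined ranks is preferred
over imputing a grouped rank that has no meaning without groups. Output is
sorted ascending, ties broken lexicographically; `place` is the competition
rank (1 + number of strictly better entries), so all entries tied at the
minimum hold place 1.

Cross-dataset consensus averages an entry's final scores over the datasets
containing it, unweighted by dataset size, and retains entries present in
strictly more than 80% of datasets (both configurable).

## Combinations by sequential augmentation

A combination's per-sample profile is the arithmetic mean of the member Cq
values — the geometric mean of the underlying linear-scale quantities, the
natural average for log-scale data. Each combination is appended as one extra
entry, the N+1-entry table is fully rescored, and the entry is removed before
the next combination is scored: appending all combinations at once would let
the (combinatorially many) synthetic entries dominate the variance structure
that GeNorm and NormFinder estimate. The combination's place is computed
among all N+1 entries — it is scored in the context of the whole dataset, not
of other combinations. `k = 1` bypasses augmentation entirely and returns the
plain single-gene ranking (a duplicate row would perturb its twin's scores).
`k > 3` is rejected: the enumeration cost explodes and averaging ever more
genes converges on the global-mean factor, which is itself scored separately
via the `ALL` sentinel.

The fast path caches the base table's pairwise-SD row sums (GeNorm) and
per-gene SDs (BestKeeper); per combination only the entry-versus-gene
statistics are new. NormFinder is recomputed on the stacked matrix (its model
couples all entries; the cost is linear). The naive full-recompute mode
remains available (`naive=True` / `--naive`) and the test suite requires the
two modes to agree to 1e-12 with identical orderings — bit-exact equality is
not promised because float summation order differs between the cached and
stacked reductions.

## Reference-set selection

All place-1 pairs and triples are indexed per dataset (ties at the minimum
all count as first). The smallest gene set containing at least one
first-place pair of every dataset is found by exact iterative-deepening
branch-and-bound (branching on the most constrained dataset); all minimal
solutions are returned in deterministic order, and a size cap turns an
impossible instance into an explicit infeasibility result rather than a
near-miss. Triples validate the chosen set per dataset. The affinity matrix
weights each pair inside a first-place triple by 1/(number of first-place
triples in that dataset), so every dataset contributes total mass 3
regardless of how many combinations tied at first; an alternative reading —
dividing by the number of first-place triples containing the pair — is
available as a mode flag. Exclusion of genes known to be disease-labile is a
manual input (an exclusion list file), not an algorithm: that judgment
requires literature, not Cq values.

## Monte-Carlo validation

A candidate set is summarized by the mean final score of all C(m,3) triples
built from its members present in the validation table. The null reference
is the same statistic for random same-size gene sets (default size 13,
default 2000 replicates, all randomness from one explicitly passed seeded
generator). `fraction_surpassed` counts replicates *strictly* above the
candidate mean — ties count against the candidate, the conservative
direction. Triple scores are cached across replicates (scoring is
deterministic), which changes nothing numerically and makes the default
replicate count cheap.

## Synthetic data

`Cq[g,s] = baseline_g + shift_s + effect_{g,group(s)} + ε`, with baselines
uniform on 15–35 cycles, per-sample loading shifts N(0, 0.5²), per-gene
Gaussian noise on the Cq (log) scale — the standard qPCR error model — and,
in grouped designs, N(0, 1²) per-(gene, group) systematic effects on
non-stable genes. Planted stable genes have zero group effect and SD 0.1
cycles against unstable SDs uniform on 0.5–3.0 cycles; 1 cycle ≈ a 2-fold
expression change, so the planted/unstable contrast mimics genuinely
housekeeping-like candidates inside a disease-responsive panel. Defaults for
the effect scales: a 0.5-cycle loading SD corresponds to typical input
variability in serum preps, and 1-cycle group effects to ~2-fold disease
dysregulation. Non-detects are missing-at-random by default; a high-Cq-biased
mode reflects the reality that low-abundance reactions fail first, but is off
by default to keep missingness orthogonal to the planted structure.

What the generator does **not** emulate: correlated co-regulation between
genes (noise is independent per gene), platform-specific probe effects,
amplification-efficiency differences, batch structure beyond the global
sample shift, and heavy-tailed or censored noise. Passing recovery tests
therefore demonstrate that the pipeline identifies low-variance, group-inert
genes under an additive Gaussian model — not that any particular real panel
will behave as cleanly.

Problem sizes in the test suite and acceptance study (200-gene single
datasets, a 5 × 30-gene combination panel, 200 Monte-Carlo replicates, 20
recovery runs) are the package's chosen desk-scale study conditions; the
pipeline itself has no size limits beyond memory and patience.

## Numerical conventions and degenerate inputs

* SDs: ddof = 1 everywhere.
* Negative variance estimates from the NormFinder corrections are clamped to
  0; a zero shrinkage denominator (γ̂² + c = 0) yields a zero intergroup term.
* Ties: mean fractional rank within algorithms; lexicographic entry order in
  reports; competition places (ties share the best place).
* Tables must hold ≥ 2 genes and ≥ 2 samples; NormFinder needs ≥ 3 genes;
  grouped NormFinder needs ≥ 2 groups of ≥ 2 samples; iterative GeNorm needs
  ≥ 3 genes.
* Fixed seeds make every stochastic output byte-identical.

## Known limitations

* BestKeeper's SD — and therefore the final ranking that averages it in — is
  *not* invariant to per-sample loading shifts; GeNorm and NormFinder cancel
  them exactly. This is inherent to scoring absolute per-gene spread and is
  precisely why multi-algorithm consensus is used. A global constant shift of
  the whole table leaves everything invariant.
* The grouped NormFinder estimator uses the simplified closed form with an
  approximate sampling variance for the intergroup differences; exact parity
  with other implementations of the model is not guaranteed, and the test
  oracle is an independently coded implementation of the formulas above.
* Amplification efficiency is fixed at 2; panels with strongly divergent
  probe efficiencies violate the Cq-as-log2 reading.
* The minimal-cover search is exact and exponential in the worst case; for
  pathological first-place indexes far larger than real panels produce, the
  size cap is the safety valve.
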