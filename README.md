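# mirnorm

Selection of stable endogenous reference genes (normalizers) from
high-throughput RT-qPCR expression tables, with a focus on circulating
(serum/plasma) miRNA panels.

## The problem

Relative quantification by qPCR reports every target as a ratio against a
reference gene that is assumed to be stably expressed. In biofluids no single
universally stable miRNA is known, and a badly chosen normalizer biases every
downstream fold change. `mirnorm` screens a Cq/Ct matrix (genes × samples)
for the most stable entries, scores *combinations* of 2–3 genes used jointly
as one normalization factor, aggregates evidence across independent datasets,
and validates a candidate reference set against random sets of the same size.

## Method

Four stability scores are computed per entry, lower = more stable:

* **GeNorm M** — for gene *j*, the pairwise log2 expression-ratio series
  against gene *k* across samples is `A_jk = Cq_k − Cq_j` (a Cq is ≈ −log2 of
  relative template amount at amplification efficiency 2);
  `M_j = mean_{k≠j} sd(A_jk)`. An iterative mode repeatedly excludes the
  worst-M gene down to the final two.
* **NormFinder** (grouped) — a model-based decomposition
  `Cq_igj = α_ig + β_gj + ε_igj` per gene *i*, sample group *g*: intragroup
  variances σ²_ig are estimated with a closed-form bias correction, the
  intergroup differences d_ig are shrunk by an empirical-Bayes factor, and the
  stability value combines |d| with the standard deviation of its uncertainty
  plus the gene's own noise, averaged over groups.
* **NormFinder** (ungrouped) — the residual standard deviation around additive
  gene + sample effects.
* **BestKeeper** — the standard deviation of a gene's Cq across samples.

Raw scores are made commensurable by the **fractional dataset ranking**
`rank = (place − 1) / n ∈ [0, 1)` per algorithm; the **final normalization
score** of an entry is the arithmetic mean of its fractional ranks (4
algorithms when sample groups exist, 3 otherwise). Combinations of 2–3 genes
are scored by **sequential augmentation**: the per-sample arithmetic mean of
the member Cq values is appended as a single extra entry, the augmented
N+1-entry table is rescored, the combination's score and place are recorded,
and the entry is discarded before the next combination — so only one
combination ever perturbs the table. Rankings from several datasets are
averaged over datasets containing the entry (presence > 80% required);
first-place pairs drive an exact minimal-cover search for a small reference
set, first-place triples validate it and yield a pairwise "normalizing
affinity" matrix. A Monte-Carlo procedure locates a candidate set's mean
derived-triple ranking within the distribution over random same-size sets.

## Worked example

Simulate a 60-gene serum-like panel with 3 planted stable genes, rank it and
validate the planted set (the library API mirrors every step; the CLI is a
thin wrapper):

```
$ mirnorm simulate --genes 60 --samples 10 --stable 3 --seed 11 --outdir sim
wrote synthetic dataset (60 genes x 10 samples) -> sim

$ mirnorm rank sim/synthetic_matrix.csv --outdir rank
ranked 60 genes -> rank/single_gene_ranking.csv

$ head -4 rank/single_gene_ranking.csv
entry_id,rank_bestkeeper,rank_genorm,rank_normfinder_ungrouped,final_score,place
miR-0008,0.03333333333333333,0.0,0.008333333333333333,0.013888888888888888,1
miR-0059,0.05,0.016666666666666666,0.008333333333333333,0.025000000000000005,2
miR-0048,0.016666666666666666,0.03333333333333333,0.03333333333333333,0.027777777777777776,3
```

The three planted reference genes (miR-0008, miR-0048, miR-0059 in this run)
occupy places 1–3: each row shows the fractional rank a gene received from
BestKeeper, GeNorm and ungrouped NormFinder and their mean, the final
normalization score. Scoring all 1770 pairs and validating the planted set:

```
$ mirnorm combos sim/synthetic_matrix.csv --k 2 --outdir combos
scored 1770 combinations -> combos

$ mirnorm mc-validate sim/synthetic_matrix.csv --candidate cand.txt \
    --set-size 3 --replicates 500 --seed 11 --outdir mc
candidate mean ranking 0.0219; surpasses 99.8% of 500 random sets -> mc
```

A candidate mean ranking of 0.0219 means the triple built from the planted
genes sits, on average, in the best ~2% of the augmented ranking; 99.8% of
random 3-gene sets produced a worse (higher) mean ranking, so the planted set
is a far better normalizer source than chance.

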