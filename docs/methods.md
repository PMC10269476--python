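# Methods

## The replicate-overlap statistic

For one sample sequenced as *n* technical replicates over a common feature
space, each feature's prevalence *k* ∈ {1..n} is the number of replicates
where its count is positive. The overlap decomposition assigns:

- occurrence mode: level *k* receives `k · N_k / Σ_i S_i × 100`, where
  `N_k` is the number of prevalence-*k* features and `S_i` the richness of
  replicate *i*;
- abundance mode: level *k* receives the share of all sequences (summed
  over replicates) carried by prevalence-*k* features.

The generic form `P = n · N_shared / N_total × 100%` is ambiguous about
`N_total` (union vs summed richness) and about what "shared sequences"
means. We adopt the unique reading under which (a) identical replicates
score exactly 100% at level *n*, and (b) the levels partition to exactly
100% (`Σ_k k·N_k = Σ_i S_i` for occurrence; every sequence belongs to one
prevalence class for abundance). "Shared by two of three" means prevalence
exactly 2, not at-least-2 — the at-least reading double-counts the
all-shared class and cannot partition. Presence means count > 0 after
whatever rarefaction/filtering preceded the call; there is no hidden
minimum-count presence threshold.

Per-stratum summaries (mean ± SD over samples) never pool samples with
different *n*; 2- and 3-replicate designs are reported separately.

## Alpha diversity and PRR

Richness is the count of positive entries; Shannon is `H = −Σ p_j ln p_j`
in nats (natural log is the default of the common ecology implementations;
bases 2 and 10 are options). The variability statistic is the percent
relative range, `PRR = (max − min)/mean × 100`, over the replicates of one
sample. PRR is scale-invariant and 0 iff all values agree. A value set that
is identically zero (all-zero dissimilarities of identical replicates) has
a 0/0 PRR; batch summaries report it as 0 with a degenerate flag rather
than failing, so noise-free inputs produce complete tables.

## Beta diversity

Abundance-mode Bray-Curtis applies `ln(1 + x)` to the counts first
(compressing the dominance of abundant features), occurrence mode uses raw
presence/absence — the log1p transform concerns sequence numbers, and on
0/1 vectors any positive scaling cancels, so binarisation order is
irrelevant. On presence/absence Bray-Curtis equals Sørensen dissimilarity
`1 − 2a/(2a + b + c)`, which the tests exploit as an independent oracle.
`dissimilarity_summary` reports within-sample means, the PRR of the three
pair values for 3-replicate samples (undefined and omitted for pairs), the
all-pair mean over every unordered replicate pair (within-sample pairs
included), and a between-sample-only mean used by the significance test.
Unequal library sizes trigger a warning: rarefy first.

## Rarefaction

`rarefy` draws each library's subsample without replacement — a
multivariate hypergeometric draw — so each rarefied total equals the depth
exactly and no cell exceeds its original count. The expected richness at
depth *d* has the closed form `E[S(d)] = Σ_j (1 − C(T−c_j, d)/C(T, d))`;
the implementation evaluates the binomial ratio as a cumulative sum of log
ratios `Π_{i<c_j}(T−d−i)/(T−i)`, exact to float rounding, and the Monte
Carlo law is verified against it in the tests. Repeated rarefaction (100
iterations by default, iteration seeds spawned deterministically from the
report seed) quantifies how much alpha-diversity variability the random
draw itself contributes; under the calibrated study conditions it is well
under a tenth of the variability between distinct replicates, which is the
justification for the pipeline's default one-time rarefaction to the
data-set minimum depth.

## Robustness and agreement statistics

- **Replicate-split Spearman.** Each of 999 repeats draws, per sample, an
  ordered pair of two distinct replicates (for 2-replicate samples this is
  a random assignment of the pair; for 3-replicate samples the unused
  replicate varies per repeat), forms two across-sample vectors, and
  computes Spearman's rho with midranks and the t-approximation p-value
  (an exact-permutation p is infeasible at realistic sample counts). On a
  2-replicate design the procedure has exactly 2^n_samples distinct
  splits, which the tests enumerate as an oracle.
- **Within vs between.** The claim "replicates are closer than samples" is
  tested one-sidedly with Mann-Whitney U on the two sets of pairwise
  dissimilarities (exact null for small groups — up to 10 within and 60
  between pairs — normal approximation with tie correction beyond).
  Because dissimilarity pairs are not independent, a label-permutation
  variant (replicate-to-sample assignment shuffled, difference of group
  means, add-one p) is provided alongside.
- **OTU/ASV agreement.** Alpha indices of the two views are compared by
  OLS with `adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2)`. Community
  structure is compared by Hellinger transform (row-wise square root of
  relative abundance), Euclidean distances, classical-scaling PCoA, and a
  symmetric Procrustes fit on the first two axes (configurable): both
  configurations centred and scaled to unit sum of squares, optimal
  rotation from the SVD, `M² = 1 − (Σ singular values)²`. Significance is
  Monte Carlo by row permutation of one configuration with the add-one
  convention `p = (1 + #{M²_perm ≤ M²_obs})/(1 + permutations)`, so 0.001
  is the attainable minimum at 999 permutations. Negative PCoA eigenvalues
  are dropped with a warning (no Cailliez/Lingoes correction — the
  simplest defensible default); Procrustes configurations of unequal axis
  counts are zero-padded.
- **Overlap-mean comparison.** One-way ANOVA plus Tukey HSD adjusted
  pairwise p-values, run separately per mode and per stratum.

All scipy-backed steps (Spearman, Mann-Whitney, ANOVA/Tukey, OLS, pairwise
Bray-Curtis) sit behind the package's own interfaces; PCoA and Procrustes
are implemented here (control over eigenvalue handling and a fast
permutation loop) and cross-checked in the tests against scikit-bio's
ordination and scipy's Procrustes disparity.

## Synthetic replicate studies

The generator works at the feature-count level (no reads, no error models)
and emulates the regime of a deep-sea sediment replicate survey:

| parameter | default | meaning |
|---|---|---|
| `depth_range` | 57,000–68,000 | per-replicate sequencing depth (uniform) |
| `richness_log_mean/sd` | 5.6 / 0.75 | lognormal true per-sample richness, clipped to 50–2,500 |
| `abundance_log_sd` | 1.8 | lognormal spread of true relative abundances |
| `heterogeneity` | 120 | Dirichlet total concentration of replicate drift |
| `heterogeneity_log_sd` | 0.8 | per-replicate lognormal spread of that concentration |
| `spurious_rate` | 60 | expected replicate-private artifact features (counts 1–5) |
| `between_sample_turnover` | 0.3 | fraction of a sample's abundances resampled from scratch |
| `pool_size` | 6,000 | regional feature pool |

Each sample draws its features from a shared regional pool with lognormal
base abundances; each replicate perturbs the sample's proportions with a
Dirichlet draw and samples counts multinomially at its depth. Two design
choices matter:

- *Per-replicate concentration spread.* With a fixed Dirichlet
  concentration, replicate richness is far too stable (PRR ≈ 8%) and
  split-Spearman rho saturates near 1 — unlike real replicate data, where
  richness PRR reaches tens of percent. Letting the concentration itself
  vary lognormally across replicates (aliquots differ in how faithfully
  they sample the community) reproduces both the large richness PRR and
  sub-0.95 rho values.
- *Spurious features are replicate-private.* Artifacts never recur across
  replicates — the worst case for occurrence overlap and consistent with
  unshared features carrying a tiny fraction of sequences.

The noise defaults were fixed by the bracketing procedure in
`scripts/calibrate_generator.py`: at the study condition used throughout
(50 samples × 3 replicates, depth 20,000), mean occurrence level-3 overlap
must fall in (20, 40)% and mean abundance level-3 overlap in (75, 92)%.
With the defaults the generator lands near 35% and 84%, with richness PRR
≈ 25–30% against Shannon PRR ≈ 11–13%, split-Spearman mean rho ≈ 0.65–0.8
(all 999 splits significant), and within-sample Bray-Curtis ≈ 0.5 against
an all-pair mean ≈ 0.98.

What the generator does *not* emulate: taxonomic structure, chimeras and
their upstream filtering, depth-richness covariation, spatial gradients
between samples, or realized richness spanning the full 50–2,500 range
(the defaults realize roughly 70–700 at depth 20,000). Passing tests
therefore validate the statistical machinery and the qualitative
replicate-noise regime, not any quantitative claim about a particular
sediment community.

## Problem sizes and numerical choices

The study condition exercised by the tests and the acceptance script is 50
samples × 3 replicates at depth 20,000 — large enough that every
qualitative signature is stable across seeds, small enough to run the
whole battery in seconds. Counts are exact integers; fractional input is
an error, not rounded, since every downstream statistic assumes sequence
counts. The minimum-count filter defaults to data-set-total scope
(features with fewer than the threshold sequences summed over all
replicates are removed), with a per-replicate cell-zeroing variant as an
option; a cell-wise filter can legitimately empty a replicate, which the
container permits in that path only. Zero-feature tables are allowed so
header-only files round-trip. Permutation p-values use the add-one
convention throughout. Master seeds expand to per-stage seeds through a
fixed, append-only spawn order, so reports are byte-reproducible and
adding a stage cannot shift earlier stages' draws.

## Known limitations

- The abundance-mode overlap's `N_shared` could in principle be read as
  pooled or minimum counts instead of the summed-fraction reading used
  here; the summed reading is the only one that partitions to 100%, and it
  is the only mode exposed.
- The Mann-Whitney within/between test treats dissimilarity pairs as
  exchangeable observations; they share replicates and are not
  independent. The permutation variant is the safer instrument when the
  conclusion is borderline.
- No phylogenetic (UniFrac) or Hill-number diversity, no
  PERMANOVA/ANOSIM/Mantel, no coverage-based normalisation alternatives,
  and no read-level simulation.
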