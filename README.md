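# repliscope

Technical-replicate reproducibility analysis for amplicon (16S rRNA gene)
feature tables.

When the same DNA sample is sequenced two or three times, the resulting
OTU/ASV tables disagree far more than users expect: most low-abundance
features appear in only one library, even though the libraries agree almost
perfectly on where the sequences went. `repliscope` quantifies this, for
studies that sequenced technical replicates of each sample, and answers the
question that matters downstream: *are the diversity patterns across samples
robust to the replicate-level noise?*

## What it computes

Given an integer count table of replicate libraries × features and a design
that groups replicates into samples:

- **Overlap by sharing level.** For a sample with *n* replicates, every
  feature has a prevalence *k* = number of replicates that contain it. The
  overlap statistic is `P = n · N_shared / N_total × 100%`, where in
  occurrence mode `N_shared` counts features present in all *n* replicates
  and `N_total` is the summed per-replicate richness; in abundance mode the
  levels partition the sequences instead of the incidences. Levels sum to
  100% and identical replicates score 100% at level *n*.
- **Alpha-diversity variability.** Observed richness and Shannon index
  (natural log) per replicate, summarised per sample by the percent relative
  range, `PRR = (max − min)/mean × 100`.
- **Beta-diversity variability.** Bray-Curtis dissimilarity on
  log1p-transformed counts (abundance) or presence/absence, where it equals
  Sørensen dissimilarity (occurrence); within-sample means vs the all-pair
  mean, plus a one-sided Mann-Whitney test of within < between.
- **Rarefaction.** Subsampling without replacement (multivariate
  hypergeometric) to a common depth, the analytic expected-richness
  rarefaction curve, and a repeated-rarefaction diagnostic that measures how
  much alpha-diversity variability the rarefaction draw itself contributes.
- **Robustness of diversity patterns.** Replicate-split Spearman
  resampling: 999 times, pick one replicate per sample for each of two
  groups and correlate the groups across samples.
- **Method agreement (OTU vs ASV).** OLS regression of alpha indices with
  adjusted R², and Hellinger transform → PCoA → symmetric Procrustes M²
  with a Monte Carlo permutation test, comparing two feature-calling views
  of the same libraries; one-way ANOVA + Tukey HSD compares overlap means
  between views.
- **Synthetic studies.** A generator that emulates this data regime
  (lognormal abundances with a long rare tail, Dirichlet replicate drift,
  spurious replicate-private features, multinomial depth sampling) with
  full ground truth, for validation and power exploration.

## Worked example

Simulate a small study and analyse it:

```sh
repliscope simulate --n-samples 8 --replicates 3 --depth 5000 5000 \
    --seed 42 --out demo
repliscope overlap --table demo/table.tsv --design demo/design.tsv \
    --mode both --seed 42 --out demo/overlap.tsv
repliscope alpha --table demo/table.tsv --design demo/design.tsv \
    --seed 42 --out demo/alpha.tsv
repliscope beta --table demo/table.tsv --design demo/design.tsv \
    --seed 42 --out demo/beta.json
```

prints

```
wrote 24 replicates x 2564 features to demo
occurrence n=3: level-3 mean 30.49 ± 6.31 % over 8 samples (depth 5128)
abundance n=3: level-3 mean 77.13 ± 10.30 % over 8 samples (depth 5128)
mean PRR richness 28.0% shannon 9.0%
abundance: within mean 0.541  all-pair mean 0.946
```

Read: only ~30% of the incidence pool is shared by all three replicates,
yet those shared features carry ~77% of the sequences — the unshared
features are almost all rare. Richness is about three times as variable
across replicates as the Shannon index (PRR 28% vs 9%), because dropout of
rare features changes the feature count but hardly moves an
abundance-weighted index. Replicates of the same sample (mean Bray-Curtis
0.54) are still far more similar than arbitrary library pairs (0.95), so
between-sample structure dominates the technical noise.

`repliscope report` runs every stage at once and writes a `report.json`
bundle plus Table-shaped TSVs; `repliscope robustness` and
`repliscope agreement` expose the Spearman-resampling and OTU/ASV-agreement
stages separately. The same functionality is importable
(`repliscope.run_report`, `repliscope.overlap_table`, ...).

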