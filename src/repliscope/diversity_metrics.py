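"""Alpha and beta diversity with replicate-variability summaries.

Alpha diversity is observed richness and the Shannon index; variability
across the technical replicates of a sample is summarised by the percent
relative range, PRR = (max - min) / mean x 100. Beta diversity is
Bray-Curtis dissimilarity either on log1p-transformed counts (abundance
mode) or on presence/absence (occurrence mode, where Bray-Curtis reduces to
the Sørensen dissimilarity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .tables_io import FeatureTable, ReplicateDesign

__all__ = [
    "richness",
    "shannon",
    "prr",
    "bray_curtis",
    "alpha_summary",
    "dissimilarity_matrix",
    "dissimilarity_summary",
    "AlphaSummary",
    "BetaSummary",
]


def richness(counts) -> int:
    """Observed number of features: entries with count > 0."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def shannon(counts, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_j log p_j over features with count > 0.

    Natural log by default (nats); ``base`` may be 2 or 10 for bits/bans.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base != math.e:
        h /= math.log(base)
    # clip the -0.0 that a single-feature vector produces
    return max(h, 0.0)


def prr(values) -> float:
    """Percent relative range: (max - min) / mean x 100.

    The variability statistic used to compare technical replicates; 0 iff
    all values are equal.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("PRR requires at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("PRR undefined for zero-mean values")
    return float((v.max() - v.min()) / m * 100.0)


def _prr_or_zero(values) -> tuple[float, bool]:
    """PRR, with the all-zero degenerate case reported as (0, True)."""
    v = np.asarray(values, dtype=float)
    if v.mean() == 0:
        return 0.0, True
    return float((v.max() - v.min()) / v.mean() * 100.0), False


def bray_curtis(x, y, mode: str = "abundance") -> float:
    """Pairwise Bray-Curtis dissimilarity between two count vectors.

    Abundance mode applies the log1p transform to the counts first:
    BC = sum|x' - y'| / sum(x' + y') with x' = ln(1 + x). Occurrence mode
    uses 0/1 presence vectors, which makes BC equal to the Sørensen
    dissimilarity 1 - 2a/(2a + b + c).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share one feature space")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("Bray-Curtis undefined for a zero-total vector")
    if mode == "abundance":
        xt, yt = np.log1p(x), np.log1p(y)
    elif mode == "occurrence":
        xt, yt = (x > 0).astype(float), (y > 0).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.abs(xt - yt).sum() / (xt + yt).sum())


@dataclass
class AlphaSummary:
    """Per-replicate alpha indices and per-sample PRR variability."""

    per_replicate: pd.DataFrame   # index replicate_id; columns richness, shannon
    per_sample_prr: pd.DataFrame  # index sample_id; columns n, prr_richness, prr_shannon

    def stats(self) -> pd.DataFrame:
        """Min/Mean/Max/SD of each column over replicates and samples."""
        frames = {}
        for name, df in (("replicate", self.per_replicate),
                         ("sample_prr", self.per_sample_prr.drop(columns="n"))):
            frames[name] = df.agg(["min", "mean", "max", "std"])
        return pd.concat(frames, axis=1)


@dataclass
class BetaSummary:
    """Within-sample and all-pair Bray-Curtis summaries for one mode.

    ``within_sample`` holds, per sample, the mean pairwise dissimilarity
    among its replicates and (for 3-replicate samples) the PRR of those
    three pair values. ``all_m`` is the mean over every unordered replicate
    pair in the table, within-sample pairs included; ``between_m`` averages
    only pairs that span two samples.
    """

    mode: str
    pairwise: pd.DataFrame        # square symmetric, index/columns replicate_id
    within_sample: pd.DataFrame   # index sample_id; n, mean_dissimilarity, prr, prr_degenerate
    stats: dict                   # min/mean/max/sd of within-sample means
    prr_m: float | None           # mean within-sample PRR (3-replicate samples only)
    all_m: float                  # mean pairwise dissimilarity, all pairs
    between_m: float              # mean pairwise dissimilarity, between-sample pairs


def alpha_summary(table: FeatureTable, design: ReplicateDesign,
                  shannon_base: float = math.e) -> AlphaSummary:
    """Richness and Shannon per replicate plus per-sample PRR of each."""
    design.check_against(table)
    rows = {}
    for rid in table.replicate_ids:
        c = table.row(rid)
        rows[rid] = {"richness": richness(c), "shannon": shannon(c, base=shannon_base)}
    per_rep = pd.DataFrame.from_dict(rows, orient="index")

    prr_rows = {}
    for sample, reps in design.groups.items():
        rich = per_rep.loc[reps, "richness"].to_numpy(dtype=float)
        shan = per_rep.loc[reps, "shannon"].to_numpy(dtype=float)
        pr, _ = _prr_or_zero(rich)
        ps, _ = _prr_or_zero(shan)
        prr_rows[sample] = {"n": len(reps), "prr_richness": pr, "prr_shannon": ps}
    return AlphaSummary(per_rep, pd.DataFrame.from_dict(prr_rows, orient="index"))


def dissimilarity_matrix(table: FeatureTable, mode: str = "abundance") -> pd.DataFrame:
    """Square symmetric Bray-Curtis matrix over all replicates."""
    if mode == "abundance":
        X = np.log1p(table.counts.astype(float))
    elif mode == "occurrence":
        X = (table.counts > 0).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("zero-total replicate in table")
    # Bray-Curtis via vectorised pdist-equivalent on the transformed rows
    from scipy.spatial.distance import pdist

    d = pdist(X, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero pair cannot occur after the guard
    return pd.DataFrame(squareform(d), index=table.replicate_ids,
                        columns=table.replicate_ids)


def dissimilarity_summary(table: FeatureTable, design: ReplicateDesign,
                          mode: str = "abundance",
                          warn_unequal_totals: bool = True) -> BetaSummary:
    """Within-sample vs all-pair Bray-Curtis summary for one mode.

    Intended to run on a rarefied table; a warning is emitted when library
    sizes are unequal. For 2-replicate samples the within-sample mean is the
    single pair value and PRR is undefined (left as NaN). A 3-replicate
    sample whose three pair values are all zero has PRR 0 with the
    ``prr_degenerate`` flag set.
    """
    design.check_against(table)
    if warn_unequal_totals and len(set(table.totals().tolist())) > 1:
        import warnings

        warnings.warn("library sizes are unequal; rarefy before comparing "
                      "dissimilarities", stacklevel=2)
    D = dissimilarity_matrix(table, mode=mode)
    within_rows = {}
    within_pair_mask = np.zeros((table.n_replicates, table.n_replicates), bool)
    ridx = {r: i for i, r in enumerate(table.replicate_ids)}
    prr_values = []
    for sample, reps in design.groups.items():
        idx = [ridx[r] for r in reps]
        pair_vals = [D.iat[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]]
        for a, i in enumerate(idx):
            for j in idx[a + 1:]:
                within_pair_mask[i, j] = within_pair_mask[j, i] = True
        row = {"n": len(reps), "mean_dissimilarity": float(np.mean(pair_vals)),
               "prr": np.nan, "prr_degenerate": False}
        if len(reps) >= 3:
            val, degen = _prr_or_zero(pair_vals)
            row["prr"], row["prr_degenerate"] = val, degen
            prr_values.append(val)
        within_rows[sample] = row
    within = pd.DataFrame.from_dict(within_rows, orient="index")

    Dv = D.to_numpy()
    iu = np.triu_indices_from(Dv, k=1)
    all_vals = Dv[iu]
    between_vals = Dv[iu][~within_pair_mask[iu]]
    wmeans = within["mean_dissimilarity"]
    stats = {"min": float(wmeans.min()), "mean": float(wmeans.mean()),
             "max": float(wmeans.max()),
             "sd": float(wmeans.std(ddof=1)) if len(wmeans) > 1 else 0.0}
    return BetaSummary(
        mode=mode, pairwise=D, within_sample=within, stats=stats,
        prr_m=float(np.mean(prr_values)) if prr_values else None,
        all_m=float(all_vals.mean()),
        between_m=float(between_vals.mean()) if between_vals.size else float("nan"),
    )
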