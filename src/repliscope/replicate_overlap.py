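"""Occurrence- and abundance-based overlap among technical replicates.

For a sample with n technical replicates, every feature has a prevalence
level k: the number of replicates (1..n) in which it appears with a positive
count. The overlap statistic partitions the sample's total incidence
(occurrence mode) or its total sequences (abundance mode) across prevalence
levels:

- occurrence: level k gets k x N_k / sum_i S_i x 100, where N_k is the
  number of features with prevalence k and S_i the richness of replicate i
  (so the n x N_shared / N_total overlap formula is the k = n entry, with
  N_total the summed per-replicate richness);
- abundance: level k gets the fraction of all sequences (summed over
  replicates) that belong to prevalence-k features, x 100.

In both modes the levels partition to exactly 100%, and two identical
replicates score 100% at level n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import FeatureTable, ReplicateDesign

__all__ = [
    "occurrence_overlap",
    "abundance_overlap",
    "overlap_table",
    "summarize_overlap",
    "OverlapResult",
]


@dataclass
class OverlapResult:
    """Per-sample overlap percentages by prevalence level."""

    sample_id: str
    n: int
    mode: str
    percent_by_level: dict  # k in 1..n -> percentage

    @property
    def percent_all_shared(self) -> float:
        """The level-n entry: percentage shared by all n replicates."""
        return self.percent_by_level[self.n]


def _as_matrix(replicate_counts) -> np.ndarray:
    M = np.asarray(replicate_counts, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need n >= 2 replicate count vectors over a common "
                         "feature set")
    if (M < 0).any():
        raise ValueError("counts must be non-negative")
    if M.sum() == 0:
        raise ValueError("all-zero input")
    return M


def occurrence_overlap(replicate_counts) -> dict:
    """Percent of total incidence at each prevalence level.

    ``replicate_counts`` is an (n x F) matrix over a common feature set.
    Returns {k: percent} for k = 1..n; entries sum to 100 because each of
    the sum_i S_i incidences belongs to exactly one prevalence class.
    """
    M = _as_matrix(replicate_counts)
    n = M.shape[0]
    present = M > 0
    prevalence = present.sum(axis=0)
    total_incidence = int(present.sum())
    out = {}
    for k in range(1, n + 1):
        n_k = int((prevalence == k).sum())
        out[k] = 100.0 * k * n_k / total_incidence
    return out


def abundance_overlap(replicate_counts) -> dict:
    """Percent of total sequences carried by features at each prevalence level."""
    M = _as_matrix(replicate_counts)
    n = M.shape[0]
    prevalence = (M > 0).sum(axis=0)
    grand_total = M.sum()
    out = {}
    for k in range(1, n + 1):
        out[k] = float(100.0 * M[:, prevalence == k].sum() / grand_total)
    return out


_MODES = {"occurrence": occurrence_overlap, "abundance": abundance_overlap}


def overlap_table(table: FeatureTable, design: ReplicateDesign,
                  mode: str = "occurrence"):
    """Per-sample overlap plus per-stratum mean/SD summaries.

    Returns ``(results, summaries)`` where ``results`` is a list of
    :class:`OverlapResult` (one per sample) and ``summaries`` maps each
    replicate-group size n present in the design to a DataFrame of mean and
    SD per level. Samples with different n are never pooled: 2-replicate
    and 3-replicate samples are summarised as separate strata.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    design.check_against(table)
    fn = _MODES[mode]
    results = []
    for sample, reps in design.groups.items():
        sub = table.subset(reps)
        results.append(OverlapResult(sample, len(reps), mode, fn(sub.counts)))
    summaries = {}
    for n in sorted({r.n for r in results}):
        stratum = [r for r in results if r.n == n]
        summaries[n] = summarize_overlap(stratum)
    return results, summaries


def summarize_overlap(results) -> pd.DataFrame:
    """Mean and SD of each prevalence level over samples with equal n."""
    if not results:
        raise ValueError("no results to summarize")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"mixed replicate counts {sorted(ns)} in one summary; "
                         "summarize strata separately")
    n = ns.pop()
    mat = np.array([[r.percent_by_level[k] for k in range(1, n + 1)]
                    for r in results])
    return pd.DataFrame(
        {"mean": mat.mean(axis=0),
         "sd": mat.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(n)},
        index=pd.Index(range(1, n + 1), name="level"),
    )


def overlap_long_table(results) -> pd.DataFrame:
    """Long-format view (sample_id, mode, n, level, percent) for TSV export."""
    rows = []
    for r in results:
        for k, pct in r.percent_by_level.items():
            rows.append({"sample_id": r.sample_id, "mode": r.mode, "n": r.n,
                         "level": k, "percent": pct})
    return pd.DataFrame.from_records(rows)
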