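"""Library-size normalisation by rarefaction (subsampling without replacement).

``rarefy`` draws, for each replicate library, a uniform random subsample of
its sequences at a fixed depth — a multivariate hypergeometric draw over the
feature counts, matching the semantics of classic rarefaction tools.
``repeated_rarefaction`` quantifies how much of the replicate-to-replicate
variability in alpha diversity could be explained by the rarefaction draw
itself, and ``rarefaction_curve`` gives the analytic expected richness at
any depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity_metrics import richness, shannon, _prr_or_zero
from .tables_io import FeatureTable

__all__ = [
    "min_depth",
    "rarefy",
    "repeated_rarefaction",
    "rarefaction_curve",
    "RarefactionReport",
]


def min_depth(table: FeatureTable) -> int:
    """Minimum library size over replicates — the default rarefaction depth."""
    if table.n_replicates == 0:
        raise ValueError("empty table")
    return int(table.totals().min())


def _rarefy_row(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    total = int(row.sum())
    if depth == total:
        return row.copy()
    return rng.multivariate_hypergeometric(row, depth).astype(np.int64)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every replicate to exactly ``depth`` sequences.

    Sampling is without replacement (each replicate's rarefied counts follow
    a multivariate hypergeometric law), so rarefied counts never exceed the
    originals and each library total equals ``depth`` exactly. A fixed seed
    gives a bit-identical table.
    """
    totals = table.totals()
    short = np.flatnonzero(totals < depth)
    if short.size:
        raise ValueError(
            f"depth {depth} exceeds total count {int(totals[short[0]])} of "
            f"replicate {table.replicate_ids[short[0]]!r}"
        )
    rng = np.random.default_rng(seed)
    new = np.vstack([_rarefy_row(table.counts[i], depth, rng)
                     for i in range(table.n_replicates)])
    return FeatureTable(list(table.replicate_ids), list(table.feature_ids), new,
                        feature_kind=table.feature_kind, taxonomy=table.taxonomy)


@dataclass
class RarefactionReport:
    """Alpha-diversity variability across repeated rarefaction draws."""

    depth: int
    iterations: int
    per_iteration_alpha: pd.DataFrame   # replicate_id, iteration, richness, shannon
    prr_across_iterations: pd.DataFrame  # index replicate_id; prr_richness, prr_shannon

    def write_tsv(self, path) -> None:
        self.per_iteration_alpha.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "depth": self.depth,
            "iterations": self.iterations,
            "mean_prr_richness": float(self.prr_across_iterations["prr_richness"].mean()),
            "mean_prr_shannon": float(self.prr_across_iterations["prr_shannon"].mean()),
        }


def repeated_rarefaction(table: FeatureTable, depth: int,
                         iterations: int = 100, seed: int = 0) -> RarefactionReport:
    """Rarefy ``iterations`` times and track richness/Shannon per draw.

    Each iteration uses a seed derived deterministically from ``(seed,
    iteration)``, so the report is reproducible while iterations stay
    independent. The PRR of each index across iterations measures the
    variability attributable to the rarefaction draw alone.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(iterations)
    records = []
    for it, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        for i, rid in enumerate(table.replicate_ids):
            row = table.counts[i]
            if depth > row.sum():
                raise ValueError(
                    f"depth {depth} exceeds total count of replicate {rid!r}")
            sub = _rarefy_row(row, depth, rng)
            records.append({"replicate_id": rid, "iteration": it,
                            "richness": richness(sub), "shannon": shannon(sub)})
    alpha = pd.DataFrame.from_records(records)
    prr_rows = {}
    for rid, grp in alpha.groupby("replicate_id", sort=False):
        pr, _ = _prr_or_zero(grp["richness"].to_numpy(float))
        ps, _ = _prr_or_zero(grp["shannon"].to_numpy(float))
        prr_rows[rid] = {"prr_richness": pr, "prr_shannon": ps}
    prr_df = pd.DataFrame.from_dict(prr_rows, orient="index")
    return RarefactionReport(depth, iterations, alpha, prr_df)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Analytic expected richness E[S(d)] for each subsampling depth.

    For a library with feature counts c_j summing to T, the probability that
    feature j is missed entirely by a without-replacement subsample of size
    d is C(T - c_j, d) / C(T, d), so

        E[S(d)] = sum_j (1 - C(T - c_j, d) / C(T, d)).

    Monotone non-decreasing in d, with E[S(T)] equal to observed richness.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    T = int(c.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths > T).any():
        raise ValueError(f"depth {int(depths.max())} exceeds library total {T}")
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")
    out = np.empty(depths.shape, dtype=float)
    cmax = int(c.max()) if c.size else 0
    for k, d in enumerate(depths):
        # miss prob C(T-c_j, d)/C(T, d) = prod_{i<c_j} (T-d-i)/(T-i),
        # accumulated in log space via a shared cumulative sum
        i = np.arange(cmax, dtype=float)
        num = T - d - i
        with np.errstate(divide="ignore"):
            ratio_logs = np.where(num > 0, np.log(np.maximum(num, 1e-300))
                                  - np.log(T - i), -np.inf)
        cum = np.concatenate([[0.0], np.cumsum(ratio_logs)])
        log_miss = cum[c]
        out[k] = float(np.sum(1.0 - np.exp(log_miss)))
    return out
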