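"""End-to-end reproducibility report over one or two feature tables.

``run_report`` chains the stages in their canonical order — optional
minimum-count filter, rarefaction to the data-set minimum, overlap in both
modes, alpha diversity with PRR, Bray-Curtis summaries, replicate-split
Spearman resampling, within- vs between-sample testing, and (when both an
OTU and an ASV table are given) OTU/ASV agreement via regression,
Procrustes, and ANOVA + Tukey of overlap means. Samples with 2 and with 3
technical replicates are always summarised as separate strata; no statistic
pools across group sizes.

Seeds: a single master seed is expanded through a fixed, named spawn order
(see ``_STAGE_SEEDS``), so adding a stage never shifts the draws of
earlier stages and the whole report is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (anova_tukey, linear_regression, pcoa,
                          procrustes_test, replicate_split_resample,
                          within_between_test, hellinger)
from .diversity_metrics import alpha_summary, dissimilarity_summary
from .rarefaction import min_depth, rarefy
from .replicate_overlap import overlap_long_table, overlap_table
from .tables_io import FeatureTable, ReplicateDesign, filter_min_count

__all__ = ["ReportBundle", "run_report"]

# fixed spawn order of per-stage seeds; append-only
_STAGE_SEEDS = ("rarefy_primary", "rarefy_secondary", "spearman",
                "within_between", "procrustes", "reserved_0", "reserved_1")


def _stage_seeds(master_seed: int) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGE_SEEDS))
    return {name: int(c.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            for name, c in zip(_STAGE_SEEDS, children)}


def _table_hash(table: FeatureTable) -> str:
    h = hashlib.sha256()
    h.update("\t".join(table.replicate_ids).encode())
    h.update("\t".join(table.feature_ids).encode())
    h.update(np.ascontiguousarray(table.counts).tobytes())
    return h.hexdigest()[:16]


@dataclass
class ReportBundle:
    """All per-stage outputs of one report run, JSON-serialisable."""

    options: dict
    provenance: dict
    overlap: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    robustness: dict = field(default_factory=dict)
    agreement: dict = field(default_factory=dict)
    # long-format frames kept for TSV export
    frames: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {"options": self.options, "provenance": self.provenance,
                "overlap": self.overlap, "alpha": self.alpha,
                "beta": self.beta, "robustness": self.robustness,
                "agreement": self.agreement}

    def write(self, outdir) -> None:
        """Write TSV/JSON outputs into one run directory."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.frames.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
        if self.agreement:
            with open(outdir / "agreement.json", "w") as fh:
                json.dump(self.agreement, fh, indent=2)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
        with open(outdir / "log.txt", "w") as fh:
            fh.write(f"repliscope {__version__}\n")
            for k, v in self.provenance.items():
                fh.write(f"{k}: {v}\n")


def _overlap_stage(table, design, kind):
    out = {}
    frames = []
    for mode in ("occurrence", "abundance"):
        results, summaries = overlap_table(table, design, mode=mode)
        long = overlap_long_table(results)
        long.insert(0, "table", kind)
        frames.append(long)
        out[mode] = {
            str(n): {"mean": {str(k): v for k, v in summ["mean"].items()},
                     "sd": {str(k): v for k, v in summ["sd"].items()}}
            for n, summ in summaries.items()
        }
    return out, pd.concat(frames, ignore_index=True)


def _alpha_values(alpha, design, index: str) -> dict:
    return {s: {r: float(alpha.per_replicate.loc[r, index])
                for r in design.groups[s]}
            for s in design.groups}


def _stratum_design(design: ReplicateDesign, n: int) -> ReplicateDesign:
    return ReplicateDesign({s: design.groups[s]
                            for s in design.samples_with_n(n)})


def run_report(table: FeatureTable, design: ReplicateDesign,
               secondary_table: FeatureTable | None = None,
               min_count: int = 0, min_count_scope: str = "table_total",
               depth: int | None = None, repeats: int = 999,
               permutations: int = 999, procrustes_axes: int = 2,
               seed: int = 0) -> ReportBundle:
    """Run the full reproducibility analysis.

    Parameters
    ----------
    table : FeatureTable
        The primary (e.g. OTU-based) table.
    design : ReplicateDesign
        Sample grouping; must be resolvable in every provided table.
    secondary_table : FeatureTable, optional
        A second view of the same libraries (e.g. ASV-based). When given,
        the OTU/ASV agreement stage (regressions, Procrustes, ANOVA+Tukey
        on overlap means) runs as well.
    min_count : int
        Optional minimum-sequence filter applied before rarefaction.
    depth : int, optional
        Rarefaction depth; defaults to each table's minimum library size.
    repeats, permutations : int
        Resampling effort for split-Spearman and the Procrustes test.
    seed : int
        Master seed; all stage seeds derive from it.
    """
    design.check_against(table)
    if secondary_table is not None:
        design.check_against(secondary_table)
    seeds = _stage_seeds(seed)
    options = {"min_count": min_count, "min_count_scope": min_count_scope,
               "depth": depth, "repeats": repeats,
               "permutations": permutations,
               "procrustes_axes": procrustes_axes, "seed": seed}
    provenance = {"seed": seed, "version": __version__,
                  "table_hash": _table_hash(table)}
    if secondary_table is not None:
        provenance["secondary_table_hash"] = _table_hash(secondary_table)
    bundle = ReportBundle(options=options, provenance=provenance)

    tables = {"primary": table}
    if secondary_table is not None:
        tables["secondary"] = secondary_table

    rarefied = {}
    for i, (kind, tab) in enumerate(tables.items()):
        if min_count:
            tab = filter_min_count(tab, min_count, scope=min_count_scope)
        d = depth if depth is not None else min_depth(tab)
        rarefied[kind] = rarefy(tab, d, seeds[f"rarefy_{kind}"])
        bundle.provenance[f"depth_{kind}"] = d

    overlap_frames = []
    alphas = {}
    for kind, tab in rarefied.items():
        bundle.overlap[kind], frame = _overlap_stage(tab, design, kind)
        overlap_frames.append(frame)
        al = alpha_summary(tab, design)
        alphas[kind] = al
        bundle.alpha[kind] = {
            "per_sample_prr_mean": {
                "richness": float(al.per_sample_prr["prr_richness"].mean()),
                "shannon": float(al.per_sample_prr["prr_shannon"].mean()),
            },
            "stats": json.loads(al.stats().to_json()),
        }
        beta = {}
        for mode in ("occurrence", "abundance"):
            bs = dissimilarity_summary(tab, design, mode=mode,
                                       warn_unequal_totals=False)
            stat, p, means = within_between_test(bs.pairwise, design)
            beta[mode] = {"stats": bs.stats, "prr_m": bs.prr_m,
                          "all_m": bs.all_m, "between_m": bs.between_m,
                          "within_between": {"statistic": stat, "p": p,
                                             **means}}
            if kind == "primary" and mode == "abundance":
                bundle.frames["beta_pairwise"] = bs.pairwise
        bundle.beta[kind] = beta
        bundle.frames[f"alpha_prr_{kind}"] = al.per_sample_prr

        rob = {}
        for n, samples in design.strata().items():
            if len(samples) < 3:
                continue
            sub = _stratum_design(design, n)
            stratum = {}
            for index in ("richness", "shannon"):
                res = replicate_split_resample(
                    _alpha_values(al, sub, index), repeats=repeats,
                    seed=seeds["spearman"])
                stratum[index] = {**res.summary,
                                  "all_significant": res.all_significant()}
            rob[str(n)] = stratum
        bundle.robustness[kind] = rob
    bundle.frames["overlap"] = pd.concat(overlap_frames, ignore_index=True)

    if secondary_table is not None:
        agreement: dict = {"regression": {}, "procrustes": {},
                           "anova_tukey": {}}
        a1, a2 = alphas["primary"], alphas["secondary"]
        common = [r for r in a1.per_replicate.index
                  if r in set(a2.per_replicate.index)]
        for index in ("richness", "shannon"):
            slope, intercept, r2, adj = linear_regression(
                a1.per_replicate.loc[common, index],
                a2.per_replicate.loc[common, index])
            agreement["regression"][index] = {
                "slope": slope, "intercept": intercept, "r2": r2,
                "adjusted_r2": adj}
        for n, samples in design.strata().items():
            sub = _stratum_design(design, n)
            reps = sub.replicate_ids
            coords = []
            for kind in ("primary", "secondary"):
                tab = rarefied[kind].subset(reps)
                H = hellinger(tab)
                from scipy.spatial.distance import pdist, squareform

                D = squareform(pdist(H, metric="euclidean"))
                c, _ = pcoa(D, k=procrustes_axes)
                coords.append(c)
            res = procrustes_test(coords[0], coords[1],
                                  permutations=permutations,
                                  seed=seeds["procrustes"])
            agreement["procrustes"][str(n)] = {
                "m2": res.m2, "correlation": res.correlation,
                "p": res.p_value, "permutations": res.permutations,
                "axes": res.axes_used}
        for mode in ("occurrence", "abundance"):
            for n in design.strata():
                groups = {}
                for kind in ("primary", "secondary"):
                    results, _ = overlap_table(
                        rarefied[kind], _stratum_design(design, n), mode=mode)
                    groups[kind] = [r.percent_all_shared for r in results]
                if min(len(v) for v in groups.values()) < 2:
                    continue
                try:
                    F, p, pairwise = anova_tukey(groups)
                except ValueError:
                    continue
                agreement["anova_tukey"][f"{mode}_n{n}"] = {
                    "F": F, "p": p,
                    "tukey": {f"{a}|{b}": v for (a, b), v in pairwise.items()}}
        bundle.agreement = agreement
    return bundle
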