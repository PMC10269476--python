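"""Feature tables, replicate designs, and their on-disk formats.

The central container is :class:`FeatureTable`: an integer count matrix of
replicate libraries (rows) by OTU/ASV features (columns). Two dialects are
supported on disk — the QIIME-classic tab-separated table (features as rows,
first header cell ``#OTU ID``, optional trailing ``taxonomy`` column) and
BIOM-format 1.0 JSON (sparse or dense). A :class:`ReplicateDesign` groups
replicate library IDs into samples of 2 or 3 technical replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "FeatureTable",
    "ReplicateDesign",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "filter_min_count",
]


class FormatError(ValueError):
    """Raised when an input file or table violates the format contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class FeatureTable:
    """Integer count matrix of replicate libraries x features.

    Parameters
    ----------
    replicate_ids : list of str
        Ordered, unique identifiers of the replicate libraries (rows).
    feature_ids : list of str
        Ordered, unique identifiers of the OTUs/ASVs (columns).
    counts : ndarray of int, shape (n_replicates, n_features)
        ``counts[i, j]`` is the number of sequences of feature j observed in
        replicate i. Non-negative integers.
    feature_kind : str
        Label for the clustering method that produced the features, by
        convention ``"OTU"`` or ``"ASV"``. Metadata only.
    taxonomy : dict, optional
        feature_id -> taxonomy string, carried through I/O but never used in
        any computation.

    Notes
    -----
    Every replicate must contain at least one sequence; an all-zero library
    carries no information and is rejected (except in the degenerate
    zero-feature table, which is permitted so that header-only files
    round-trip). Features with all-zero counts are retained: they can occur
    on read and may matter when taking feature-set unions.
    """

    replicate_ids: list
    feature_ids: list
    counts: np.ndarray
    feature_kind: str = "OTU"
    taxonomy: dict | None = field(default=None, repr=False)
    #: a cell-wise filter can legitimately empty a replicate; such tables
    #: are constructed with the check disabled
    allow_empty_replicates: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.replicate_ids = [str(r) for r in self.replicate_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.replicate_ids), len(self.feature_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.replicate_ids)} replicates x {len(self.feature_ids)} features"
            )
        if counts.dtype.kind not in "iu":
            rounded = np.rint(counts)
            bad = np.argwhere(~np.isclose(counts, rounded, rtol=0, atol=1e-9))
            if bad.size:
                i, j = bad[0]
                raise FormatError(
                    f"non-integral count {counts[i, j]!r} for replicate "
                    f"{self.replicate_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count {counts[i, j]} for replicate "
                f"{self.replicate_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        _check_unique(self.replicate_ids, "replicate_id")
        _check_unique(self.feature_ids, "feature_id")
        if self.n_features > 0 and not self.allow_empty_replicates:
            empties = np.flatnonzero(counts.sum(axis=1) == 0)
            if empties.size:
                raise FormatError(
                    f"replicate {self.replicate_ids[empties[0]]!r} has zero total count"
                )
        self.counts = counts

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def totals(self) -> np.ndarray:
        """Per-replicate library sizes (row sums)."""
        return self.counts.sum(axis=1)

    def replicate_index(self, replicate_id: str) -> int:
        try:
            return self.replicate_ids.index(replicate_id)
        except ValueError:
            raise KeyError(f"replicate {replicate_id!r} not in table") from None

    def row(self, replicate_id: str) -> np.ndarray:
        return self.counts[self.replicate_index(replicate_id)]

    def subset(self, replicate_ids) -> "FeatureTable":
        """Row-subset preserving the full feature space."""
        idx = [self.replicate_index(r) for r in replicate_ids]
        return FeatureTable(
            [self.replicate_ids[i] for i in idx],
            list(self.feature_ids),
            self.counts[idx],
            feature_kind=self.feature_kind,
            taxonomy=self.taxonomy,
        )

    def drop_empty_features(self) -> "FeatureTable":
        keep = np.flatnonzero(self.counts.sum(axis=0) > 0)
        tax = None
        if self.taxonomy is not None:
            tax = {self.feature_ids[j]: self.taxonomy[self.feature_ids[j]]
                   for j in keep if self.feature_ids[j] in self.taxonomy}
        return FeatureTable(
            list(self.replicate_ids),
            [self.feature_ids[j] for j in keep],
            self.counts[:, keep],
            feature_kind=self.feature_kind,
            taxonomy=tax,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.replicate_ids,
                            columns=self.feature_ids)

    def __eq__(self, other):
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (self.replicate_ids == other.replicate_ids
                and self.feature_ids == other.feature_ids
                and np.array_equal(self.counts, other.counts))


@dataclass
class ReplicateDesign:
    """Grouping of replicate library IDs into samples.

    ``groups`` maps sample_id -> ordered list of replicate_ids. Each
    replicate belongs to exactly one sample and every sample has at least
    two technical replicates.
    """

    groups: dict

    def __post_init__(self):
        self.groups = {str(s): [str(r) for r in reps]
                       for s, reps in self.groups.items()}
        seen = {}
        for sample, reps in self.groups.items():
            for r in reps:
                if r in seen:
                    raise FormatError(
                        f"replicate {r!r} assigned to both samples "
                        f"{seen[r]!r} and {sample!r}"
                    )
                seen[r] = sample
        for sample, reps in self.groups.items():
            if len(reps) < 2:
                raise FormatError(
                    f"sample {sample!r} has {len(reps)} replicate(s); "
                    "at least 2 are required"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.groups)

    @property
    def replicate_ids(self) -> list:
        return [r for reps in self.groups.values() for r in reps]

    @property
    def n_replicates(self) -> dict:
        """Per-sample group size."""
        return {s: len(reps) for s, reps in self.groups.items()}

    def samples_with_n(self, n: int) -> list:
        """Sample IDs with exactly n technical replicates (one stratum)."""
        return [s for s, reps in self.groups.items() if len(reps) == n]

    def strata(self) -> dict:
        """Group sizes present -> list of sample IDs, e.g. {2: [...], 3: [...]}."""
        out: dict = {}
        for s, reps in self.groups.items():
            out.setdefault(len(reps), []).append(s)
        return dict(sorted(out.items()))

    def check_against(self, table: FeatureTable) -> None:
        known = set(table.replicate_ids)
        for s, reps in self.groups.items():
            for r in reps:
                if r not in known:
                    raise FormatError(
                        f"replicate {r!r} of sample {s!r} not present in table"
                    )


# ---------------------------------------------------------------------------
# QIIME-classic TSV dialect

_QIIME_HEADER = "#OTU ID"


def _read_qiime_tsv(path: Path) -> FeatureTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = None
    for ln in lines:
        if ln.startswith(_QIIME_HEADER):
            header = ln
            break
        if not ln.startswith("#"):
            raise FormatError(
                f"{path}: expected a header line starting with {_QIIME_HEADER!r}"
            )
    if header is None:
        raise FormatError(f"{path}: no {_QIIME_HEADER!r} header found")
    cols = header.split("\t")
    has_taxonomy = bool(cols) and cols[-1].strip().lower() == "taxonomy"
    replicate_ids = cols[1:-1] if has_taxonomy else cols[1:]
    body = [ln for ln in lines if not ln.startswith("#")]
    feature_ids, rows, taxonomy = [], [], {}
    for ln in body:
        parts = ln.split("\t")
        expected = 1 + len(replicate_ids) + (1 if has_taxonomy else 0)
        if len(parts) != expected:
            raise FormatError(
                f"{path}: row {parts[0]!r} has {len(parts)} fields, expected {expected}"
            )
        fid = parts[0]
        vals = parts[1:1 + len(replicate_ids)]
        row = []
        for rep, v in zip(replicate_ids, vals):
            try:
                x = float(v)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric count {v!r} at feature {fid!r}, "
                    f"replicate {rep!r}"
                ) from None
            if not float(x).is_integer():
                raise FormatError(
                    f"{path}: non-integral count {v!r} at feature {fid!r}, "
                    f"replicate {rep!r}"
                )
            if x < 0:
                raise FormatError(
                    f"{path}: negative count {v!r} at feature {fid!r}, "
                    f"replicate {rep!r}"
                )
            row.append(int(x))
        feature_ids.append(fid)
        rows.append(row)
        if has_taxonomy:
            taxonomy[fid] = parts[-1]
    counts = (np.array(rows, dtype=np.int64).T if rows
              else np.zeros((len(replicate_ids), 0), dtype=np.int64))
    return FeatureTable(replicate_ids, feature_ids, counts,
                        taxonomy=taxonomy or None)


def _write_qiime_tsv(table: FeatureTable, path: Path) -> None:
    has_tax = table.taxonomy is not None
    with open(path, "w") as fh:
        cols = [_QIIME_HEADER] + list(table.replicate_ids)
        if has_tax:
            cols.append("taxonomy")
        fh.write("\t".join(cols) + "\n")
        for j, fid in enumerate(table.feature_ids):
            row = [fid] + [str(int(c)) for c in table.counts[:, j]]
            if has_tax:
                row.append(table.taxonomy.get(fid, ""))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BIOM 1.0 JSON dialect (observations = features as rows; columns = libraries)

def _read_biom_json(path: Path) -> FeatureTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: invalid JSON ({e})") from None
    for key in ("rows", "columns", "shape", "matrix_type", "data"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM document missing {key!r}")
    n_feat, n_rep = doc["shape"]
    feature_ids = [r["id"] for r in doc["rows"]]
    replicate_ids = [c["id"] for c in doc["columns"]]
    if len(feature_ids) != n_feat or len(replicate_ids) != n_rep:
        raise FormatError(f"{path}: shape does not match rows/columns lists")
    dense = np.zeros((n_feat, n_rep))
    if doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            i, j, v = entry
            dense[int(i), int(j)] = v
    elif doc["matrix_type"] == "dense":
        if len(doc["data"]) != n_feat:
            raise FormatError(f"{path}: dense data has wrong row count")
        dense = np.asarray(doc["data"], dtype=float)
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        if isinstance(md, dict) and "taxonomy" in md:
            tx = md["taxonomy"]
            taxonomy[r["id"]] = "; ".join(tx) if isinstance(tx, list) else str(tx)
    kind = (doc.get("type") or "").upper()
    feature_kind = "ASV" if "ASV" in kind else "OTU"
    return FeatureTable(replicate_ids, feature_ids, dense.T,
                        feature_kind=feature_kind, taxonomy=taxonomy or None)


def _write_biom_json(table: FeatureTable, path: Path) -> None:
    dense = table.counts.T  # features x replicates
    data = [[int(i), int(j), int(dense[i, j])]
            for i, j in zip(*np.nonzero(dense))]
    rows = []
    for fid in table.feature_ids:
        md = None
        if table.taxonomy is not None and fid in table.taxonomy:
            md = {"taxonomy": table.taxonomy[fid]}
        rows.append({"id": fid, "metadata": md})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "repliscope",
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_features, table.n_replicates],
        "rows": rows,
        "columns": [{"id": r, "metadata": None} for r in table.replicate_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


_READERS = {"qiime_tsv": _read_qiime_tsv, "biom_json": _read_biom_json}
_WRITERS = {"qiime_tsv": _write_qiime_tsv, "biom_json": _write_biom_json}


def read_feature_table(path, format: str = "qiime_tsv") -> FeatureTable:
    """Read and validate a feature table.

    Parameters
    ----------
    path : path-like
    format : {"qiime_tsv", "biom_json"}
    """
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; use one of {sorted(_READERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[format](path)


def write_feature_table(table: FeatureTable, path, format: str = "qiime_tsv") -> None:
    """Write a feature table; the file re-reads to an identical table."""
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; use one of {sorted(_WRITERS)}")
    _WRITERS[format](table, Path(path))


# ---------------------------------------------------------------------------
# Replicate design I/O

def read_design(path) -> ReplicateDesign:
    """Read a two-column TSV (sample_id, replicate_id) into a design.

    Groups are built preserving file order. A header line
    ``sample_id<TAB>replicate_id`` is accepted and skipped.
    """
    path = Path(path)
    groups: dict = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            sample, rep = parts
            if lineno == 1 and (sample, rep) == ("sample_id", "replicate_id"):
                continue
            groups.setdefault(sample, []).append(rep)
    if not groups:
        raise FormatError(f"{path}: empty design")
    return ReplicateDesign(groups)


def write_design(design: ReplicateDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\treplicate_id\n")
        for sample, reps in design.groups.items():
            for r in reps:
                fh.write(f"{sample}\t{r}\n")


# ---------------------------------------------------------------------------
# Minimum-count filtering

def filter_min_count(table: FeatureTable, threshold: int,
                     scope: str = "table_total") -> FeatureTable:
    """Remove low-count features, as in minimum-sequence-number filtering.

    Parameters
    ----------
    table : FeatureTable
    threshold : int
        Minimum number of sequences a feature needs to be kept. 0 is the
        identity.
    scope : {"table_total", "per_replicate"}
        ``table_total`` drops features whose count summed over all replicates
        is below the threshold. ``per_replicate`` zeroes every cell below the
        threshold, then drops features that became all-zero; the replicate
        set is unchanged either way.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if scope not in ("table_total", "per_replicate"):
        raise ValueError(f"unknown scope {scope!r}")
    if threshold == 0:
        return table
    counts = table.counts
    if scope == "table_total":
        keep = counts.sum(axis=0) >= threshold
        new_counts = counts[:, keep]
    else:
        new_counts = np.where(counts >= threshold, counts, 0)
        keep = new_counts.sum(axis=0) > 0
        new_counts = new_counts[:, keep]
    keep_idx = np.flatnonzero(keep)
    feature_ids = [table.feature_ids[j] for j in keep_idx]
    tax = None
    if table.taxonomy is not None:
        tax = {f: table.taxonomy[f] for f in feature_ids if f in table.taxonomy}
    return FeatureTable(list(table.replicate_ids), feature_ids, new_counts,
                        feature_kind=table.feature_kind, taxonomy=tax,
                        allow_empty_replicates=True)
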