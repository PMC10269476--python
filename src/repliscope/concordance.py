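"""Robustness and agreement statistics for replicate studies.

Four questions, four tools:

- Do technical replicates rank samples the same way? Replicate-split
  Spearman resampling: repeatedly pick one replicate per sample for each of
  two groups and correlate the groups across samples.
- Are replicates of a sample more alike than different samples?
  One-sided Mann-Whitney U on within- vs between-sample dissimilarities
  (with a label-permutation alternative, since dissimilarity pairs are not
  independent).
- Do two feature-calling methods (OTU vs ASV) agree on alpha diversity?
  Ordinary least-squares regression with adjusted R².
- Do they agree on community structure? Hellinger transform, principal
  coordinates, and a symmetric Procrustes rotation test with a Monte Carlo
  permutation p-value (protest-style M²).

Group means of overlap statistics are compared with one-way ANOVA plus
Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "spearman",
    "replicate_split_resample",
    "SpearmanResampleResult",
    "within_between_test",
    "linear_regression",
    "hellinger",
    "pcoa",
    "procrustes_m2",
    "procrustes_test",
    "ProcrustesResult",
    "anova_tukey",
]


def spearman(x, y):
    """Spearman rank correlation with midranks for ties.

    Returns (rho, p) with p from the t-distribution approximation on
    n - 2 degrees of freedom. Raises on a constant vector, whose ranks
    have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SpearmanResampleResult:
    """999-fold (by default) replicate-split Spearman resampling outcome."""

    rho_values: np.ndarray
    p_values: np.ndarray
    repeats: int

    @property
    def summary(self) -> dict:
        r = self.rho_values
        return {"min": float(r.min()), "mean": float(r.mean()),
                "max": float(r.max()), "sd": float(r.std(ddof=1))}

    def all_significant(self, alpha: float = 0.05) -> bool:
        return bool((self.p_values < alpha).all())


def replicate_split_resample(alpha_values: dict, repeats: int = 999,
                             seed: int = 0) -> SpearmanResampleResult:
    """Split each sample's replicates into two groups and correlate.

    ``alpha_values`` maps sample_id -> {replicate_id: value}. Each repeat
    draws, per sample, an ordered pair of two distinct replicates uniformly
    at random (for a 2-replicate sample this is a random assignment of the
    pair; for 3 replicates the unused one varies per repeat), builds the two
    across-sample vectors, and computes the Spearman correlation between
    them.
    """
    samples = list(alpha_values)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    per_sample = []
    for s in samples:
        vals = np.asarray(list(alpha_values[s].values()), dtype=float)
        if vals.size < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 replicate values")
        per_sample.append(vals)
    rng = np.random.default_rng(seed)
    rhos = np.empty(repeats)
    ps = np.empty(repeats)
    for t in range(repeats):
        a = np.empty(len(samples))
        b = np.empty(len(samples))
        for i, vals in enumerate(per_sample):
            ia, ib = rng.choice(vals.size, size=2, replace=False)
            a[i], b[i] = vals[ia], vals[ib]
        rhos[t], ps[t] = spearman(a, b)
    return SpearmanResampleResult(rhos, ps, repeats)


def _within_between_values(pairwise, design):
    import pandas as pd

    if isinstance(pairwise, pd.DataFrame):
        ids = list(pairwise.index)
        D = pairwise.to_numpy()
    else:
        raise TypeError("pairwise must be a labelled DataFrame")
    idx = {r: i for i, r in enumerate(ids)}
    mask = np.zeros_like(D, dtype=bool)
    for reps in design.groups.values():
        ii = [idx[r] for r in reps]
        for a, i in enumerate(ii):
            for j in ii[a + 1:]:
                mask[i, j] = mask[j, i] = True
    iu = np.triu_indices_from(D, k=1)
    within = D[iu][mask[iu]]
    between = D[iu][~mask[iu]]
    return within, between


def within_between_test(pairwise, design, method: str = "mannwhitney",
                        permutations: int = 9999, seed: int = 0):
    """Test whether within-sample dissimilarities are lower than between.

    One-sided (alternative: within < between). ``method="mannwhitney"``
    uses the Mann-Whitney U test (exact for small groups, normal
    approximation with tie correction otherwise). ``method="permutation"``
    shuffles replicate-to-sample labels and compares the difference of group
    means — provided because dissimilarity pairs are not independent.

    Returns ``(statistic, p, group_means)`` with group means keyed
    ``within``/``between``.
    """
    within, between = _within_between_values(pairwise, design)
    if within.size == 0 or between.size == 0:
        raise ValueError("need at least one within-sample and one "
                         "between-sample pair")
    means = {"within": float(within.mean()), "between": float(between.mean())}
    if method == "mannwhitney":
        # exact null distribution for small groups; otherwise the normal
        # approximation with tie correction
        how = ("exact" if within.size <= 10 and between.size <= 60
               else "asymptotic")
        res = stats.mannwhitneyu(within, between, alternative="less",
                                 method=how)
        return float(res.statistic), float(res.pvalue), means
    if method == "permutation":
        rng = np.random.default_rng(seed)
        D = pairwise.to_numpy()
        ids = list(pairwise.index)
        sizes = [len(reps) for reps in design.groups.values()]
        obs = means["within"] - means["between"]
        iu = np.triu_indices_from(D, k=1)
        hits = 0
        n = len(ids)
        for _ in range(permutations):
            perm = rng.permutation(n)
            mask = np.zeros_like(D, dtype=bool)
            start = 0
            for sz in sizes:
                ii = perm[start:start + sz]
                start += sz
                for a in range(sz):
                    for b in range(a + 1, sz):
                        mask[ii[a], ii[b]] = mask[ii[b], ii[a]] = True
            w = D[iu][mask[iu]].mean()
            btw = D[iu][~mask[iu]].mean()
            if w - btw <= obs:
                hits += 1
        p = (1 + hits) / (1 + permutations)
        return float(obs), float(p), means
    raise ValueError(f"unknown method {method!r}")


def linear_regression(x, y):
    """OLS fit y = slope*x + intercept with R² and adjusted R².

    adjusted R² = 1 - (1 - R²)(n - 1)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    n = x.size
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return float(res.slope), float(res.intercept), float(r2), float(adj)


def hellinger(table) -> np.ndarray:
    """Row-wise Hellinger transform: sqrt of relative abundances.

    Accepts a FeatureTable or a counts matrix; each output row's squared
    values sum to 1.
    """
    M = np.asarray(getattr(table, "counts", table), dtype=float)
    totals = M.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("zero-total row")
    return np.sqrt(M / totals)


def pcoa(dissimilarity, k: int | None = None):
    """Principal coordinates (classical scaling) of a dissimilarity matrix.

    Gower-centres -D²/2, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt eigenvalue, sorted by descending
    eigenvalue) on the positive-eigenvalue axes only; negative eigenvalues
    are dropped with a warning. ``k`` truncates to the first k axes.
    """
    D = np.asarray(getattr(dissimilarity, "values", dissimilarity), dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-12
    if (vals < -tol).any():
        warnings.warn("negative eigenvalues dropped (non-Euclidean "
                      "dissimilarities)", stacklevel=2)
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    eigvals = vals[pos]
    if k is not None:
        coords = coords[:, :k]
        eigvals = eigvals[:k]
    return coords, eigvals


def _standardize(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    norm = np.sqrt((X ** 2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration (all points identical)")
    return X / norm


def procrustes_m2(X, Y) -> float:
    """Symmetric Procrustes M²: residual sum of squares after optimal fit.

    Both configurations are centred and scaled to unit sum of squares; the
    optimal rotation gives M² = 1 - (sum of singular values of XᵀY)².
    0 means a perfect similarity transform maps one onto the other.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    # pad the narrower configuration with zero axes
    kmax = max(X.shape[1], Y.shape[1])
    X = np.pad(X, ((0, 0), (0, kmax - X.shape[1])))
    Y = np.pad(Y, ((0, 0), (0, kmax - Y.shape[1])))
    Xs, Ys = _standardize(X), _standardize(Y)
    s = np.linalg.svd(Xs.T @ Ys, compute_uv=False).sum()
    return float(max(1.0 - s * s, 0.0))


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p_value: float
    permutations: int
    axes_used: int


def procrustes_test(X, Y, permutations: int = 999, seed: int = 0) -> ProcrustesResult:
    """Procrustes rotation test with Monte Carlo significance.

    Rows of X and Y must be aligned by identity (same replicate in the same
    row). The null distribution permutes the rows of Y; the p-value uses the
    add-one convention (1 + #{M²_perm <= M²_obs}) / (1 + permutations), so
    the attainable minimum at 999 permutations is 0.001.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    m2_obs = procrustes_m2(X, Y)
    kmax = max(X.shape[1], Y.shape[1])
    Xs = _standardize(np.pad(X, ((0, 0), (0, kmax - X.shape[1]))))
    Ys = _standardize(np.pad(Y, ((0, 0), (0, kmax - Y.shape[1]))))
    rng = np.random.default_rng(seed)
    hits = 0
    n = Xs.shape[0]
    for _ in range(permutations):
        perm = rng.permutation(n)
        Yp = Ys[perm]
        Yp = Yp - Yp.mean(axis=0)  # re-centre: permutation preserves it, cheap safety
        s = np.linalg.svd(Xs.T @ Yp, compute_uv=False).sum()
        if 1.0 - s * s <= m2_obs:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return ProcrustesResult(m2=m2_obs, correlation=float(np.sqrt(1 - m2_obs)),
                            p_value=float(p), permutations=permutations,
                            axes_used=kmax)


def anova_tukey(groups: dict):
    """One-way ANOVA F test plus Tukey HSD pairwise adjusted p-values.

    ``groups`` maps label -> list of values (each group >= 2 values).
    Returns ``(F, p, pairwise)`` with ``pairwise`` keyed by label pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate: all values identical")
    F, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise[(labels[i], labels[j])] = float(hsd.pvalue[i, j])
    return float(F), float(p), pairwise
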