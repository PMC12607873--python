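"""Beta-diversity machinery: Bray-Curtis, PCoA, PERMANOVA, PERMDISP.

Everything here is implemented from first principles rather than wrapped
from an ecology package, because the permutation scheme, the pseudo-F
decomposition, and the negative-eigenvalue correction are the load-bearing
statistics of the analysis and need to be auditable against their formulas.

Conventions
-----------
* Bray-Curtis: ``d(x, y) = sum|x_t - y_t| / sum(x_t + y_t)`` over the shared
  taxon index; scale-invariant when both columns are rescaled together.
* Permutation p-values use the ``(1 + b) / (1 + m)`` estimator, so p is never
  zero and always >= 1/(m+1).
* Every permutation test takes an explicit seed; there is no hidden global
  RNG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hma_fidelity.tables import PairingMap, SampleMeta, TaxonTable

logger = logging.getLogger(__name__)

EIG_TOL = 1e-12


@dataclass
class DistMatrix:
    """Symmetric dissimilarity matrix over an ordered id list."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} ids")
        if not np.isfinite(self.d).all():
            raise ValueError("dissimilarities must be finite")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    def loc(self, i: str, j: str) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def write_dist_matrix(dist: DistMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class Ordination:
    """Principal-coordinate embedding of a dissimilarity matrix."""

    ids: list[str]
    coordinates: np.ndarray        # n x k, axes ordered by eigenvalue
    eigenvalues: np.ndarray        # length n, sorted descending
    proportion_explained: np.ndarray  # per-axis fraction of the positive-eigenvalue sum

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    r_squared: float | None = None


@dataclass
class GroupedDissimilarities:
    """Off-diagonal dissimilarities partitioned into comparison categories.

    Categories: donor_donor, mouse_mouse, donor_paired_recipient (a donor
    against its own recipient group), donor_other_recipient (a donor against
    another donor's recipient group).  Each unordered pair contributes to
    exactly one category.
    """

    categories: dict[str, list[float]] = field(default_factory=dict)

    def means(self) -> dict[str, float]:
        return {
            k: float(np.mean(v)) for k, v in self.categories.items() if v
        }


@dataclass
class GroupComparisonResult:
    """Omnibus statistic + pairwise adjusted p-values for >=2 groups."""

    method: str
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float]


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(table: TaxonTable) -> DistMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    ``d[i, j] = sum_t |x_ti - x_tj| / sum_t (x_ti + x_tj)``.  Requires every
    column to carry some abundance (all-zero columns have an undefined
    self-dissimilarity structure and are rejected upstream by renormalize).
    """
    x = table.values
    sums = x.sum(axis=0)
    if (sums <= 0).any():
        bad = [s for s, z in zip(table.samples, sums <= 0) if z]
        raise ValueError(f"all-zero sample column(s): {bad}")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i:i + 1] - x[:, i + 1:]).sum(axis=0)
        tot = (x[:, i:i + 1] + x[:, i + 1:]).sum(axis=0)
        row = diff / tot
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return DistMatrix(ids=table.samples, d=d)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def _double_centered(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistMatrix, k: int | None = None) -> Ordination:
    """Classical metric scaling (Gower's PCoA).

    Double-centers ``-d^2/2``, eigendecomposes, and scales eigenvectors by
    the square root of positive eigenvalues; axes with eigenvalue <= 1e-12
    contribute zero coordinates.  ``proportion_explained`` is each positive
    eigenvalue over the positive-eigenvalue sum (zero for the rest).
    """
    n = len(dist.ids)
    if k is None:
        k = n
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    b = _double_centered(dist.d)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    coords = np.zeros((n, k))
    positive = eigval > EIG_TOL
    for j in range(k):
        if positive[j]:
            coords[:, j] = eigvec[:, j] * np.sqrt(eigval[j])

    pos_sum = eigval[positive].sum()
    prop = np.zeros(n)
    if pos_sum > 0:
        prop[positive] = eigval[positive] / pos_sum
    return Ordination(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_indices(groups) -> tuple[list[str], list[np.ndarray]]:
    labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    return uniq, [np.flatnonzero(labels == g) for g in uniq]


def _permanova_f(d2: np.ndarray, idx_by_group: list[np.ndarray]) -> tuple[float, float]:
    """Pseudo-F and R^2 from the squared-dissimilarity decomposition."""
    n = d2.shape[0]
    a = len(idx_by_group)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = sum(
        d2[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)].sum() / len(idx)
        for idx in idx_by_group
    )
    ss_between = ss_total - ss_within
    if n - a <= 0:
        raise ValueError("PERMANOVA needs more samples than groups")
    denom = ss_within / (n - a)
    f = np.inf if denom == 0 else (ss_between / (a - 1)) / denom
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def _permuted_withins(d2: np.ndarray, sizes: list[int], perms: np.ndarray) -> np.ndarray:
    """SS_within for each permutation, vectorized over permutations.

    ``perms`` is (m, n): each row a permutation of sample indices; group g of
    size ``sizes[g]`` takes the next block of each row.  For an indicator
    block M (m x n), the within-group sum of squared dissimilarities is
    ``(M @ d2 * M).sum(1) / 2``.
    """
    m, n = perms.shape
    ss_within = np.zeros(m)
    start = 0
    for size in sizes:
        block = perms[:, start:start + size]
        ind = np.zeros((m, n))
        np.put_along_axis(ind, block, 1.0, axis=1)
        ss_within += (ind @ d2 * ind).sum(axis=1) / (2.0 * size)
        start += size
    return ss_within


def permanova(
    dist: DistMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way PERMANOVA pseudo-F test on a dissimilarity matrix.

    ``SS_total = sum_{i<j} d2_ij / n``; ``SS_within`` sums the analogous
    within-group terms; ``F = (SS_between/(a-1)) / (SS_within/(n-a))``.  The
    p-value permutes group labels ``n_perm`` times with the given seed and
    applies the ``(1+b)/(1+m)`` estimator.
    """
    if seed is None:
        raise ValueError("permanova requires an explicit seed")
    labels = np.asarray(groups)
    n = len(dist.ids)
    if labels.shape != (n,):
        raise ValueError("groups must align with the distance-matrix ids")
    uniq, idx_by_group = _group_indices(labels)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = dist.d ** 2
    f_obs, r2 = _permanova_f(d2, idx_by_group)

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    sizes = [len(idx) for idx in idx_by_group]
    # order columns so group blocks are contiguous under the identity map
    base = np.concatenate(idx_by_group)
    perms = base[perms]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = _permuted_withins(d2, sizes, perms)
    a = len(uniq)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    f_perm = np.where(np.isnan(f_perm), np.inf, f_perm)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(
        statistic=f_obs, p_value=p, n_permutations=n_perm, seed=seed, r_squared=r2
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def dispersion_distances(dist: DistMatrix, groups) -> np.ndarray:
    """Per-sample distance to its group centroid in corrected PCoA space.

    Both positive- and negative-eigenvalue axes are embedded; the squared
    distance to the centroid is the real-axis contribution minus the
    imaginary-axis contribution, floored at zero (the standard correction
    for semi-metric dissimilarities such as Bray-Curtis).
    """
    labels = np.asarray(groups)
    n = len(dist.ids)
    b = _double_centered(dist.d)
    eigval, eigvec = np.linalg.eigh(b)
    pos = eigval > EIG_TOL
    neg = eigval < -EIG_TOL
    x_real = eigvec[:, pos] * np.sqrt(eigval[pos])
    x_imag = eigvec[:, neg] * np.sqrt(-eigval[neg])

    dists = np.zeros(n)
    for g in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        c_real = x_real[idx].mean(axis=0)
        c_imag = x_imag[idx].mean(axis=0)
        sq = ((x_real[idx] - c_real) ** 2).sum(axis=1)
        sq -= ((x_imag[idx] - c_imag) ** 2).sum(axis=1)
        dists[idx] = np.sqrt(np.maximum(sq, 0.0))
    return dists


def _embed_corrected(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real- and imaginary-axis coordinates of the full PCoA embedding."""
    b = _double_centered(d)
    eigval, eigvec = np.linalg.eigh(b)
    pos = eigval > EIG_TOL
    neg = eigval < -EIG_TOL
    x_real = eigvec[:, pos] * np.sqrt(eigval[pos])
    x_imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return x_real, x_imag


def _dispersion_f(
    x_real: np.ndarray,
    x_imag: np.ndarray,
    sizes: list[int],
    perms: np.ndarray,
) -> np.ndarray:
    """ANOVA F on centroid distances, recomputed under each permutation.

    ``perms`` is (m, n) with group g occupying the columns of its block;
    centroids are recomputed from the permuted membership, so the statistic
    is fully exchangeable under the null.
    """
    m, n = perms.shape
    a = len(sizes)
    dists = np.zeros((m, n))
    start = 0
    for size in sizes:
        block = perms[:, start:start + size]
        xr = x_real[block]                      # (m, size, k_real)
        xi = x_imag[block]
        sq = ((xr - xr.mean(axis=1, keepdims=True)) ** 2).sum(axis=2)
        sq -= ((xi - xi.mean(axis=1, keepdims=True)) ** 2).sum(axis=2)
        dists[:, start:start + size] = np.sqrt(np.maximum(sq, 0.0))
        start += size
    grand = dists.mean(axis=1)
    ss_between = np.zeros(m)
    ss_within = np.zeros(m)
    start = 0
    for size in sizes:
        block = dists[:, start:start + size]
        gmean = block.mean(axis=1)
        ss_between += size * (gmean - grand) ** 2
        ss_within += ((block - gmean[:, None]) ** 2).sum(axis=1)
        start += size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return np.where(np.isnan(f), np.inf, f)


def permdisp(
    dist: DistMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Samples are embedded once in corrected PCoA space; the statistic is the
    one-way ANOVA F on distances to group centroids, and group labels are
    permuted with the centroids (and hence the distances) recomputed for
    every permuted labeling, keeping the permutation distribution
    exchangeable under the null.
    """
    if seed is None:
        raise ValueError("permdisp requires an explicit seed")
    labels = np.asarray(groups)
    uniq, idx_by_group = _group_indices(labels)
    if len(uniq) < 2:
        raise ValueError("PERMDISP needs at least two groups")
    for g, idx in zip(uniq, idx_by_group):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    x_real, x_imag = _embed_corrected(dist.d)
    sizes = [len(idx) for idx in idx_by_group]
    base = np.concatenate(idx_by_group)
    n = len(base)
    f_obs = float(_dispersion_f(x_real, x_imag, sizes, base[np.newaxis, :])[0])

    rng = np.random.default_rng(seed)
    perms = base[np.argsort(rng.random((n_perm, n)), axis=1)]
    f_perm = _dispersion_f(x_real, x_imag, sizes, perms)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(
        statistic=f_obs, p_value=p, n_permutations=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# Group-wise dissimilarity extraction and comparison
# ---------------------------------------------------------------------------

def extract_group_dissimilarities(
    dist: DistMatrix,
    meta: list[SampleMeta],
    pairing: PairingMap,
) -> GroupedDissimilarities:
    """Partition every off-diagonal pair of a replicate-averaged matrix.

    Ids in ``dist`` must be either human sample ids or recipient-group ids
    from the pairing.  Each unordered pair lands in exactly one of
    donor_donor, mouse_mouse, donor_paired_recipient, donor_other_recipient.
    """
    humans = {m.sample_id for m in meta if m.host == "human"}
    groups = set(pairing.recipient_group_members)
    paired = set(pairing.pairs)

    kind = {}
    for sid in dist.ids:
        if sid in humans:
            kind[sid] = "donor"
        elif sid in groups:
            kind[sid] = "group"
        else:
            raise ValueError(
                f"id {sid!r} is neither a human sample nor a recipient group"
            )

    out = {
        "donor_donor": [],
        "mouse_mouse": [],
        "donor_paired_recipient": [],
        "donor_other_recipient": [],
    }
    n = len(dist.ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dist.ids[i], dist.ids[j]
            value = float(dist.d[i, j])
            if kind[a] == "donor" and kind[b] == "donor":
                out["donor_donor"].append(value)
            elif kind[a] == "group" and kind[b] == "group":
                out["mouse_mouse"].append(value)
            else:
                donor, group = (a, b) if kind[a] == "donor" else (b, a)
                if (donor, group) in paired:
                    out["donor_paired_recipient"].append(value)
                else:
                    out["donor_other_recipient"].append(value)
    return GroupedDissimilarities(categories=out)


def _dunn_pairwise(values_by_group: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc z-tests on pooled midranks, Bonferroni-adjusted."""
    names = sorted(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in names])
    sizes = {g: len(values_by_group[g]) for g in names}
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)

    mean_rank = {}
    start = 0
    for g in names:
        mean_rank[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            var = base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2])
            if var <= 0:
                pairwise[(g1, g2)] = 1.0
                continue
            z = (mean_rank[g1] - mean_rank[g2]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
            pairwise[(g1, g2)] = min(1.0, p * k)
    return pairwise


def compare_groups(
    values_by_group: dict[str, list[float]],
    method: str = "kruskal_dunn",
) -> GroupComparisonResult:
    """Omnibus + post-hoc comparison of >=2 groups of values.

    ``kruskal_dunn``: Kruskal-Wallis H (midranks, tie-corrected) followed by
    Dunn's pairwise z-tests with Bonferroni adjustment.  ``anova_tukey``:
    one-way ANOVA F followed by Tukey's HSD.  If every value is identical
    across all groups the omnibus statistic is reported as 0 with p = 1.
    """
    if method not in ("kruskal_dunn", "anova_tukey"):
        raise ValueError(f"unknown method {method!r}")
    names = sorted(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across groups; statistic undefined")
        pairwise = {
            (g1, g2): 1.0
            for i, g1 in enumerate(names)
            for g2 in names[i + 1:]
        }
        return GroupComparisonResult(method, 0.0, 1.0, pairwise)

    if method == "kruskal_dunn":
        stat, p = stats.kruskal(*arrays)
        pairwise = _dunn_pairwise(dict(zip(names, [a.tolist() for a in arrays])))
    else:
        stat, p = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pairwise = {}
        for i, g1 in enumerate(names):
            for jj, g2 in enumerate(names):
                if jj > i:
                    pairwise[(g1, g2)] = float(tukey.pvalue[i, jj])
    return GroupComparisonResult(method, float(stat), float(p), pairwise)
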