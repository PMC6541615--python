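"""Assemblage composition: Bray-Curtis, ANOSIM and non-metric MDS.

Dissimilarity between sampling units is Bray-Curtis on (by default)
square-root transformed abundances.  ANOSIM contrasts the mean rank of
between-group against within-group dissimilarities,

    R = (r̄_between - r̄_within) / (M / 2),   M = n(n-1)/2,

tested by label permutation: complete enumeration of all distinct label
arrangements when their number is small enough (the observed arrangement is
part of the enumeration, so p is the plain fraction), otherwise seeded random
permutations with the observed arrangement added to the denominator.
Pairwise follow-up tests recompute ranks within each pair's submatrix and
carry no multiplicity adjustment.  The ordination is non-metric MDS
minimising Kruskal stress-1, restarted from several random configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "DissimilarityMatrix",
    "AnosimResult",
    "OrdinationResult",
    "bray_curtis",
    "anosim",
    "pairwise_anosim",
    "nmds",
    "kruskal_stress",
    "centroid_overlay",
]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    labels: list  # sample ids
    groups: list  # level labels, parallel to labels

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, keep) -> "DissimilarityMatrix":
        keep = np.asarray(keep)
        return DissimilarityMatrix(
            values=self.values[np.ix_(keep, keep)],
            labels=[self.labels[i] for i in keep],
            groups=[self.groups[i] for i in keep],
        )


def bray_curtis(abund, transform: str = "sqrt") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between sampling units.

    ``transform`` is "sqrt" (the default used throughout the pipeline) or
    "none".  An all-zero row has no defined dissimilarity and raises.
    """
    X = abund.counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 sampling units")
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        bad = [abund.counts.index[i] for i in zero]
        raise ValueError(f"all-zero abundance row(s): {bad}")
    if transform == "sqrt":
        X = np.sqrt(X)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(
        values=d,
        labels=list(abund.counts.index),
        groups=list(abund.meta["level"]),
    )


@dataclass
class AnosimResult:
    R: float
    p: float
    scheme: str  # "exact" | "sampled"
    n_arrangements: int  # enumeration size, or permutation count
    seed: int | None
    groups: tuple  # the group labels compared
    group_sizes: tuple


def _r_stat(ranks, within, M):
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (M / 2.0)


def _n_arrangements(sizes) -> int:
    n = sum(sizes)
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(s)
    return out


def anosim(
    d: DissimilarityMatrix,
    max_exact: int = 200_000,
    n_perm: int = 9_999,
    seed: int = 0,
) -> AnosimResult:
    """One-way ANOSIM of ``d.groups`` with exact or sampled permutation p.

    Requires >= 2 groups of >= 2 samples each (within-group ranks are
    undefined for singletons).  Ties in dissimilarity take midranks.
    """
    labels = np.asarray(d.groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1: {small}")
    n = d.n
    M = n * (n - 1) // 2
    ranks = rankdata(d.condensed())
    iu, ju = np.triu_indices(n, k=1)

    codes = np.searchsorted(uniq, labels)
    within_obs = codes[iu] == codes[ju]
    r_obs = _r_stat(ranks, within_obs, M)

    total = _n_arrangements(counts)
    if total <= max_exact:
        count_ge = 0
        for perm in multiset_permutations(codes.tolist()):
            p = np.asarray(perm)
            within = p[iu] == p[ju]
            if _r_stat(ranks, within, M) >= r_obs - 1e-12:
                count_ge += 1
        pval = count_ge / total
        return AnosimResult(
            R=float(r_obs), p=float(pval), scheme="exact",
            n_arrangements=total, seed=None,
            groups=tuple(uniq.tolist()), group_sizes=tuple(int(c) for c in counts),
        )
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        p = rng.permutation(codes)
        within = p[iu] == p[ju]
        if _r_stat(ranks, within, M) >= r_obs - 1e-12:
            count_ge += 1
    pval = (1 + count_ge) / (1 + n_perm)
    return AnosimResult(
        R=float(r_obs), p=float(pval), scheme="sampled",
        n_arrangements=n_perm, seed=seed,
        groups=tuple(uniq.tolist()), group_sizes=tuple(int(c) for c in counts),
    )


def pairwise_anosim(
    d: DissimilarityMatrix,
    max_exact: int = 200_000,
    n_perm: int = 9_999,
    seed: int = 0,
) -> list:
    """ANOSIM for every unordered pair of groups.

    Each pair's submatrix is extracted first and its dissimilarities
    re-ranked (subsetting then ranking, not the reverse).  No multiplicity
    adjustment is applied.
    """
    labels = np.asarray(d.groups)
    uniq = np.unique(labels)
    out = []
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            keep = np.flatnonzero((labels == uniq[i]) | (labels == uniq[j]))
            out.append(anosim(d.subset(keep), max_exact, n_perm, seed))
    return out


def kruskal_stress(d: DissimilarityMatrix, X: np.ndarray) -> float:
    """Kruskal stress-1 of configuration ``X`` against dissimilarities ``d``.

    Disparities are the isotonic (pool-adjacent-violators) regression of the
    configuration distances on the dissimilarity ranks; stress-1 =
    sqrt(sum (dist - disp)^2 / sum dist^2).
    """
    delta = d.condensed()
    dist = pdist(X)
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    disp_sorted = iso.fit_transform(np.arange(delta.size), dist[order])
    disp = np.empty_like(dist)
    disp[order] = disp_sorted
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # sample x axis, centred, principal-axis rotated
    stress: float  # Kruskal stress-1 of the returned configuration
    n_starts: int
    converged: bool


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS (SMACOF with isotonic disparities) in ``k`` dimensions.

    The best of ``n_starts`` random starts is centred, rotated to its
    principal axes, and reported with its Kruskal stress-1 (recomputed
    independently of the optimiser's internal criterion).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    X = model.fit_transform(d.values)
    X = X - X.mean(axis=0)
    # rotate to principal axes; fix sign so the largest-|loading| entry is +
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for a in range(X.shape[1]):
        if X[np.argmax(np.abs(X[:, a])), a] < 0:
            X[:, a] = -X[:, a]
    stress = kruskal_stress(d, X)
    coords = pd.DataFrame(
        X, index=pd.Index(d.labels, name="sample"),
        columns=[f"axis{a + 1}" for a in range(k)],
    )
    coords.insert(0, "level", d.groups)
    converged = model.n_iter_ < max_iter
    return OrdinationResult(coords=coords, stress=stress,
                            n_starts=n_starts, converged=bool(converged))


def centroid_overlay(ordination: OrdinationResult) -> pd.DataFrame:
    """Arithmetic mean coordinates of each level's replicates."""
    axes = [c for c in ordination.coords.columns if c.startswith("axis")]
    return ordination.coords.groupby("level")[axes].mean()
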