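"""Validation and community statistics: Pearson correlation with Fisher-z
confidence intervals, Bray-Curtis distances, NMDS ordination, permutation
tests for beta dispersion and PERMANOVA (pseudo-F on a distance matrix), and
the frequency-of-occurrence contingency chi-square.

Permutation p-values follow the (1 + #{extreme}) / (n_perm + 1) convention
and are therefore never exactly zero; all permutation tests are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __post_init__(self):
        if not (self.ci_low - 1e-12 <= self.r <= self.ci_high + 1e-12):
            raise ValueError("confidence interval does not bracket r")


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p: float
    n_perm: int
    df: float | None = None
    mean_squares: dict | None = None


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_with_ci(x, y) -> CorrelationResult:
    """Sample Pearson r with a Fisher-z 95% CI and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(xm @ ym / math.sqrt((xm @ xm) * (ym @ ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo, hi = r, r
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, p=p, n=n)


# ---------------------------------------------------------------------------
# Bray-Curtis distance
# ---------------------------------------------------------------------------

def bray_curtis(matrix, unit_ids: list[str] | None = None) -> np.ndarray:
    """Pairwise Bray-Curtis distances d(u,v) = sum|u-v| / sum(u+v) between
    the rows of a units x taxa count matrix."""
    m = np.asarray(matrix, dtype=float)
    if (m < 0).any():
        raise ValueError("counts must be >= 0")
    zero = np.flatnonzero(m.sum(axis=1) == 0)
    if zero.size:
        name = unit_ids[zero[0]] if unit_ids else f"row {zero[0]}"
        raise ValueError(f"unit {name} has all-zero counts")
    return squareform(pdist(m, metric="braycurtis"))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def nmds(
    dist: np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Nonmetric multidimensional scaling into ``k`` dimensions.

    Runs ``n_starts`` random starts of isotonic-regression NMDS and keeps
    the configuration with the lowest Kruskal stress-1; coordinates are
    centered.  Returns (coordinates, stress)."""
    from sklearn.manifold import MDS

    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 0:
        raise ValueError("dist must be a symmetric distance matrix, zero diagonal")
    if n < k + 2:
        raise ValueError("need at least k + 2 points")
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_starts,
        init="random",
        max_iter=max_iter,
        metric="precomputed",
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    coords = model.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    return coords, float(model.stress_)


def kruskal_stress(dist: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration: sqrt(sum (d_hat - d_conf)^2 / sum
    d_conf^2) with disparities from isotonic regression of configuration
    distances on the input dissimilarity ranks."""
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(dist.shape[0], 1)
    d_obs = dist[iu]
    d_conf = squareform(pdist(coords))[iu]
    order = np.argsort(d_obs, kind="stable")
    disparities = np.empty_like(d_conf)
    disparities[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), d_conf[order]
    )
    return float(
        math.sqrt(((disparities - d_conf) ** 2).sum() / (d_conf ** 2).sum())
    )


# ---------------------------------------------------------------------------
# Beta dispersion and PERMANOVA
# ---------------------------------------------------------------------------

def _check_groups(groups, min_size: int = 2) -> np.ndarray:
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < min_size:
        raise ValueError(f"every group needs at least {min_size} members")
    return g

def _pcoa_coords(dist: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding (positive eigenvalues retained)."""
    d2 = np.asarray(dist, float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    keep = vals > 1e-10
    return vecs[:, keep] * np.sqrt(vals[keep])


def _dispersion_f(coords: np.ndarray, g: np.ndarray) -> float:
    """F ratio of between/within mean squares of distances to group centroids."""
    dists = np.empty(len(g))
    for lab in np.unique(g):
        idx = g == lab
        centroid = coords[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    grand = dists.mean()
    labels = np.unique(g)
    ss_between = sum(
        (g == lab).sum() * (dists[g == lab].mean() - grand) ** 2 for lab in labels
    )
    ss_within = sum(
        ((dists[g == lab] - dists[g == lab].mean()) ** 2).sum() for lab in labels
    )
    df1, df2 = labels.size - 1, len(g) - labels.size
    if ss_within == 0:
        return 0.0 if ss_between == 0 else math.inf
    return (ss_between / df1) / (ss_within / df2)


def permutest_dispersion(
    dist: np.ndarray, groups, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Distances to group centroids are computed in principal-coordinate space;
    the observed F of those distances is compared with its distribution
    under group-label permutation."""
    g = _check_groups(groups)
    coords = _pcoa_coords(dist)
    observed = _dispersion_f(coords, g)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _dispersion_f(coords, rng.permutation(g)) >= observed
    return PermutationTestResult(
        statistic=float(observed),
        p=(1 + hits) / (n_perm + 1),
        n_perm=n_perm,
    )


def _permanova_f(dist: np.ndarray, g: np.ndarray) -> tuple[float, dict]:
    n = len(g)
    d2 = dist ** 2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    labels = np.unique(g)
    for lab in labels:
        idx = np.flatnonzero(g == lab)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df1, df2 = labels.size - 1, n - labels.size
    ms = {
        "group": ss_between / df1,
        "residual": ss_within / df2,
        "ss_group": ss_between,
        "ss_residual": ss_within,
    }
    f = math.inf if ms["residual"] == 0 else ms["group"] / ms["residual"]
    return f, ms


def permanova(
    dist: np.ndarray, groups, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """One-way PERMANOVA: pseudo-F from the partition of squared distances,
    p-value by group-label permutation.  Reports group and residual mean
    squares."""
    g = _check_groups(groups)
    d = np.asarray(dist, dtype=float)
    observed, ms = _permanova_f(d, g)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f, _ = _permanova_f(d, rng.permutation(g))
        hits += f >= observed
    return PermutationTestResult(
        statistic=float(observed),
        p=(1 + hits) / (n_perm + 1),
        n_perm=n_perm,
        df=float(len(np.unique(g)) - 1),
        mean_squares=ms,
    )


# ---------------------------------------------------------------------------
# FOO contingency chi-square
# ---------------------------------------------------------------------------

def foo_contingency_chisq(
    foo_a: dict[str, int], foo_b: dict[str, int], min_foo: int = 3
) -> PermutationTestResult:
    """Pearson chi-square (no continuity correction) on the 2 x T
    contingency table of two FOO vectors, restricted to taxa occurring at
    least ``min_foo`` times in at least one of the two."""
    taxa = sorted(
        t
        for t in set(foo_a) | set(foo_b)
        if max(foo_a.get(t, 0), foo_b.get(t, 0)) >= min_foo
    )
    if len(taxa) < 2:
        raise ValueError("fewer than 2 taxa after the min_foo restriction")
    obs = np.array(
        [[foo_a.get(t, 0) for t in taxa], [foo_b.get(t, 0) for t in taxa]],
        dtype=float,
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count in contingency table")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(taxa) - 1
    return PermutationTestResult(
        statistic=stat,
        p=float(chi2_dist.sf(stat, df)),
        n_perm=0,
        df=float(df),
    )
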