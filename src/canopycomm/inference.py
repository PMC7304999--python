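"""Permutation and rank-based inference for community comparisons.

PERMANOVA partitions the sum of squared inter-sample dissimilarities among
a-priori groups and tests the pseudo-F ratio by permuting group labels.  With
squared dissimilarities d2_ij over N samples in a groups:

    SS_T = (1/N) sum_{i<j} d2_ij
    SS_W = sum_g (1/n_g) sum_{i<j in g} d2_ij
    F    = (SS_A / (a-1)) / (SS_W / (N-a)),   SS_A = SS_T - SS_W

With a Euclidean distance on univariate data the pseudo-F reduces exactly to
the classical one-way ANOVA F, which serves as an oracle in the test suite.
Permutation p-values use the (1 + b) / (n_perm + 1) convention throughout.

"Sorensen distance on densities" is interpreted as the quantitative Sorensen
dissimilarity, which coincides with Bray-Curtis; the binary (presence-based)
Sorensen is available as ``metric="sorensen_binary"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermanovaResult",
    "bray_curtis",
    "permanova",
    "kruskal_dunn",
    "spearman_rank",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    df_among: int
    df_within: int
    p: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None


def bray_curtis(matrix: np.ndarray) -> np.ndarray:
    """Condensed Bray-Curtis (quantitative Sorensen) distances between rows."""
    return pdist(np.asarray(matrix, dtype=float), metric="braycurtis")


def _distance_matrix(data: np.ndarray, metric: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 2 and data.shape[0] == data.shape[1] and \
            np.allclose(data, data.T) and np.allclose(np.diag(data), 0):
        return data  # already a square distance matrix
    if metric in ("braycurtis", "sorensen", "bray_curtis"):
        return squareform(pdist(data, metric="braycurtis"))
    if metric == "sorensen_binary":
        return squareform(pdist(data > 0, metric="dice"))
    if metric == "euclidean":
        return squareform(pdist(data, metric="euclidean"))
    raise ValueError(f"unknown metric {metric!r}")


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, k=1)].sum() / n
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_a = ss_t - ss_w
    df_a, df_w = n_groups - 1, n - n_groups
    if ss_w <= 0:
        return math.inf if ss_a > 0 else 0.0
    return (ss_a / df_a) / (ss_w / df_w)


def permanova(data, groups, metric: str = "braycurtis",
              n_permutations: int = 9999, seed: int | None = None,
              pairwise: bool = False) -> PermanovaResult:
    """Permutational multivariate ANOVA on a samples x species matrix.

    ``data`` may also be a precomputed square symmetric distance matrix.
    ``pairwise=True`` additionally runs the two-group statistic on every group
    pair (permuting labels within the pair only), reporting t = sqrt(F) and
    Benjamini-Hochberg adjusted p-values.
    """
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = labels[np.argmin(sizes)]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    d = _distance_matrix(np.asarray(data, dtype=float), metric)
    if d.shape[0] != groups.size:
        raise ValueError("group labels do not match the number of samples")
    d2 = d ** 2
    n = d2.shape[0]
    if d2[np.triu_indices(n, k=1)].sum() == 0:
        raise ValueError("no variation: all samples are identical")

    rng = np.random.default_rng(seed)
    f_obs = _permanova_f(d2, codes, labels.size)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, labels.size) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)

    pw = None
    if pairwise:
        rows = []
        for a, b in itertools.combinations(range(labels.size), 2):
            idx = np.nonzero((codes == a) | (codes == b))[0]
            sub2 = d2[np.ix_(idx, idx)]
            sub_codes = (codes[idx] == b).astype(int)
            f_ab = _permanova_f(sub2, sub_codes, 2)
            ex = 0
            for _ in range(n_permutations):
                if _permanova_f(sub2, rng.permutation(sub_codes), 2) >= f_ab:
                    ex += 1
            rows.append({"group_a": labels[a], "group_b": labels[b],
                         "t": math.sqrt(f_ab),
                         "p_raw": (1 + ex) / (n_permutations + 1)})
        pw = pd.DataFrame(rows)
        pw["p_adj"] = benjamini_hochberg(pw["p_raw"].to_numpy())

    return PermanovaResult(pseudo_f=f_obs, df_among=labels.size - 1,
                           df_within=n - labels.size, p=p,
                           n_permutations=n_permutations, pairwise=pw)


def kruskal_dunn(values, groups) -> dict:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z-tests.

    Dunn's statistic for groups i, j uses the mean midranks over the full
    pooled ranking:

        z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Pairwise p-values
    are two-sided and Benjamini-Hochberg adjusted.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty group")

    if np.all(values == values[0]):
        h, p = 0.0, 1.0
    else:
        h, p = kruskal(*samples)

    n = values.size
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n - 1))
    rows = []
    for a, b in itertools.combinations(range(labels.size), 2):
        ra = ranks[groups == labels[a]]
        rb = ranks[groups == labels[b]]
        se2 = (n * (n + 1) / 12.0 - tie_term) * (1 / ra.size + 1 / rb.size)
        z = (ra.mean() - rb.mean()) / math.sqrt(se2) if se2 > 0 else 0.0
        rows.append({"group_a": labels[a], "group_b": labels[b], "z": z,
                     "p_raw": 2.0 * norm.sf(abs(z))})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = benjamini_hochberg(pw["p_raw"].to_numpy())
    return {"H": float(h), "p": float(p), "pairwise": pw}


def spearman_rank(x, y) -> dict:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
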