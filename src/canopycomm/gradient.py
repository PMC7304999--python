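"""Canopy-response curves, the rank-averaged conservation composite, and
spatial eigenvectors.

Community responses along a canopy-cover gradient are typically hump-shaped:
richness, abundance and conservation value rise from open grassland, peak at
some intermediate cover, and fall toward closed forest.  Each response is fit
with both a cubic polynomial and a three-parameter Gaussian peak

    y = b0 + b1 x + b2 x^2 + b3 x^3        (cubic)
    y = a exp(-0.5 ((x - x0) / b)^2)       (gaussian_peak)

and the better model (lower AICc) supplies the peak location — the canopy
cover at the curve's maximum, restricted to the observed canopy range
(extrapolated cubic maxima are refused).

The composite conservation outcome ranks every site from 1 (worst: lowest
richness, density, CVI) to n (best) on each of the three responses with
midranks for ties, and averages the three ranks per site.

Moran spatial eigenvectors (a.k.a. spatial eigenvector mapping / PCNM) supply
synthetic spatial predictors: the inter-site distance matrix is truncated at
the longest minimum-spanning-tree edge, double-centered, and decomposed; the
eigenvectors with positive eigenvalues describe spatial patterns from broad
trends (first vectors) to fine-grained structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .community import site_metrics
from .detection import (apportion_unidentified, estimate_densities,
                        fit_detection_groups)

__all__ = [
    "PeakFitResult",
    "fit_peak_model",
    "rank_composite",
    "spatial_eigenvectors",
    "report",
]


@dataclass(frozen=True)
class PeakFitResult:
    model: str                    # "cubic" or "gaussian_peak"
    parameters: tuple[float, ...]
    r_squared: float
    aicc: float
    peak_x: float                 # within the observed x range
    peak_y: float
    aicc_alternative: float | None = None


def _aicc(rss: float, n: int, k: int) -> float:
    # k counts the error variance as a parameter
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return float(aic)


def _gaussian(x, a, x0, b):
    return a * np.exp(-0.5 * ((x - x0) / b) ** 2)


def _cubic_peak(coeffs: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """Argmax of b0 + b1 x + b2 x^2 + b3 x^3 over [lo, hi]."""
    b0, b1, b2, b3 = coeffs
    deriv = np.polynomial.polynomial.Polynomial([b1, 2 * b2, 3 * b3])
    candidates = [lo, hi]
    for rt in deriv.roots():
        if abs(rt.imag) < 1e-9 and lo <= rt.real <= hi:
            candidates.append(float(rt.real))
    poly = np.polynomial.polynomial.Polynomial(coeffs)
    values = [float(poly(c)) for c in candidates]
    i = int(np.argmax(values))
    return candidates[i], values[i]


def fit_peak_model(x, y) -> PeakFitResult:
    """Fit cubic and Gaussian-peak canopy-response models; keep the better.

    Needs at least 5 points with x in [0, 100].  The Gaussian fit is
    initialized at a = max(y), x0 = argmax(y), b = range(x)/4.  Model choice
    is by AICc; the reported peak is the winning curve's maximum within the
    observed x range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 (x, y) points")
    if np.any((x < 0) | (x > 100)):
        raise ValueError("x must be canopy cover in [0, 100]")
    lo, hi = float(x.min()), float(x.max())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n = x.size

    fits = {}
    # cubic: linear least squares, always available
    coeffs = np.polynomial.polynomial.polyfit(x, y, 3)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    rss_c = float((resid ** 2).sum())
    peak_x, peak_y = _cubic_peak(coeffs, lo, hi)
    fits["cubic"] = (tuple(coeffs), rss_c, _aicc(rss_c, n, 5), peak_x, peak_y)

    # gaussian peak: iterative
    try:
        p0 = [float(y.max()), float(x[np.argmax(y)]), (hi - lo) / 4 or 1.0]
        popt, _ = curve_fit(_gaussian, x, y, p0=p0, maxfev=10000)
        a, x0, b = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        rss_g = float(((y - _gaussian(x, a, x0, b)) ** 2).sum())
        if a >= 0:
            gx = min(max(x0, lo), hi)
        else:  # inverted bell: maximum at the range end farthest from x0
            gx = lo if abs(lo - x0) > abs(hi - x0) else hi
        fits["gaussian_peak"] = ((a, x0, b), rss_g, _aicc(rss_g, n, 4),
                                 gx, float(_gaussian(gx, a, x0, b)))
    except RuntimeError:
        pass

    if not fits:
        raise RuntimeError("neither canopy-response model converged")
    winner = min(fits, key=lambda m: fits[m][2])
    params, rss, aicc, px, py = fits[winner]
    other = [m for m in fits if m != winner]
    return PeakFitResult(
        model=winner, parameters=params,
        r_squared=1.0 - rss / ss_tot if ss_tot > 0 else 0.0,
        aicc=aicc, peak_x=px, peak_y=py,
        aicc_alternative=fits[other[0]][2] if other else None)


def rank_composite(site_table: pd.DataFrame) -> pd.DataFrame:
    """Average of per-metric site ranks (1 = least desirable outcome).

    ``site_table`` must carry ``site_id`` plus ``richness``, ``density`` and
    ``cvi`` columns (any per-site flavour of each).  Ascending midranks are
    assigned per metric and averaged into ``average_rank``.
    """
    required = {"richness", "density", "cvi"}
    missing = required - set(site_table.columns)
    if missing:
        raise KeyError(f"site table missing metric column(s) {sorted(missing)}")
    out = site_table[["site_id"]].copy() if "site_id" in site_table.columns \
        else pd.DataFrame(index=site_table.index)
    for metric in ("richness", "density", "cvi"):
        out[f"rank_{metric}"] = rankdata(site_table[metric].to_numpy())
    out["average_rank"] = out[[f"rank_{m}" for m in
                               ("richness", "density", "cvi")]].mean(axis=1)
    return out


def spatial_eigenvectors(coordinates, truncation: float | None = None):
    """Moran spatial eigenvectors of a set of site coordinates.

    Pairwise distances beyond the truncation (default: the longest edge of
    the minimum spanning tree, the smallest threshold keeping all sites
    connected) are replaced by 4x the truncation; the resulting matrix is
    double-centered via -d^2/2 and decomposed.  Returns ``(vectors, values)``
    with only the positive-eigenvalue vectors, ordered by decreasing
    eigenvalue.  Vectors are zero-mean and mutually orthogonal.
    """
    xy = np.asarray(coordinates, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 3:
        raise ValueError("need at least 3 sites with (x, y) coordinates")
    d = squareform(pdist(xy))
    off = d[np.triu_indices(len(xy), k=1)]
    if np.any(off == 0):
        raise ValueError("duplicate coordinates collapse the connectivity graph")
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst[mst > 0].max())
    dt = np.where(d <= truncation, d, 4.0 * truncation)
    np.fill_diagonal(dt, 0.0)
    a = -0.5 * dt ** 2
    n = len(xy)
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9 * max(vals.max(), 1.0)
    return vecs[:, keep], vals[keep]


def report(observations: pd.DataFrame, sites: pd.DataFrame,
           traits: pd.DataFrame, reversed_ranks: pd.Series | dict,
           min_detections: int = 30,
           surveys: pd.DataFrame | None = None) -> dict:
    """End-to-end gradient summary: peak canopy covers of the responses.

    Chains apportionment -> pooled detection fits -> density table -> per-site
    metrics -> canopy-response peak fits for richness (ACE), mean density,
    mean CVI, and the rank-averaged composite.  Returns a JSON-serializable
    dict with a ``peaks`` entry mapping each response to its peak canopy
    cover (%).
    """
    obs = apportion_unidentified(observations, traits)
    fits = fit_detection_groups(obs, traits, min_detections=min_detections)
    dens = estimate_densities(obs, sites, fits, surveys=surveys)
    per_site = site_metrics(dens, obs, reversed_ranks)
    merged = per_site.merge(
        sites[["site_id", "canopy_cover_pct"]], on="site_id")
    canopy = merged["canopy_cover_pct"].to_numpy()

    responses = {
        "richness": merged["ace_richness"].to_numpy(),
        "density": merged["mean_density"].to_numpy(),
        "cvi": merged["mean_cvi"].to_numpy(),
    }
    comp = rank_composite(merged.rename(columns={
        "ace_richness": "richness", "mean_density": "density",
        "mean_cvi": "cvi"}))
    responses["composite"] = comp["average_rank"].to_numpy()

    out = {"n_sites": int(len(merged)), "peaks": {}, "models": {}}
    for name, yvals in responses.items():
        fit = fit_peak_model(canopy, yvals)
        out["peaks"][f"{name}_peak_canopy"] = fit.peak_x
        out["models"][name] = {"model": fit.model,
                               "r_squared": fit.r_squared,
                               "peak_y": fit.peak_y}
    return out
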