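"""Composition analytics: principal-curve ordination, IndVal, predictive CoCA.

Three complementary views of multivariate community structure:

* **One-dimensional principal-curve ordination** fits a smooth curve through
  the samples in species space and scores each sample by its arc-length
  position along the curve, capturing a single dominant — possibly strongly
  nonlinear — compositional gradient.  The fit alternates between smoothing
  each species' (transformed) abundance against the current scores with a
  fixed-df cubic spline and re-projecting every sample onto the nearest point
  of the resulting multivariate curve, starting from the first correspondence
  analysis axis.

* **Indicator species analysis (IndVal)** scores each species for each site
  group as 100 x specificity x fidelity, where specificity A_sg is the share
  of the species' mean abundance found in group g and fidelity B_sg is the
  fraction of g's sites occupied.  Significance of a species' maximum IndVal
  is assessed by permuting the site-to-group assignment (group sizes
  preserved) with Benjamini-Hochberg correction across species.

* **Predictive co-correspondence analysis (CoCA)** asks how well the
  composition of one community (e.g. plants in flower) predicts another
  (butterflies) sampled at the same sites.  Both matrices are reduced to row
  profiles with chi-square-style scaling under site weights taken from the
  response's row totals, and axes are extracted by weighted partial least
  squares, each maximizing the covariance of weighted-averaging sample scores
  and orthogonal to its predecessors.  Predictive skill is the leave-one-out
  cross-validated fit, which is negative when the predictor community carries
  no information about the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import svd

from .core import HABITATS
from .inference import benjamini_hochberg

__all__ = [
    "PrincipalCurveResult",
    "principal_curve_ordination",
    "IndValResult",
    "indicator_values",
    "CoCAResult",
    "predictive_coca",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# principal curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrincipalCurveResult:
    scores: np.ndarray            # per sample, rescaled to [0, 1]
    variance_explained: float     # 1 - SS_res / SS_tot
    fitted: np.ndarray            # per-sample fitted species values
    n_iterations: int
    converged: bool


def _apply_transform(m: np.ndarray, transform: str) -> np.ndarray:
    if transform in (None, "none"):
        return m.copy()
    if transform == "sqrt":
        return np.sqrt(m)
    if transform == "log":
        return np.log(m + 0.5)
    raise ValueError(f"unknown transform {transform!r}")


def _ca_first_axis(m: np.ndarray) -> np.ndarray:
    """Row scores on the first correspondence-analysis axis (zero rows -> 0)."""
    total = m.sum()
    if total <= 0:
        raise ValueError("correspondence analysis needs positive entries")
    p = m / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep = c > 0
    pc = p[:, keep]
    cc = c[keep]
    rs = np.where(r > 0, r, 1.0)
    s = (pc - np.outer(r, cc)) / np.sqrt(np.outer(rs, cc))
    u, sv, _ = svd(s, full_matrices=False)
    scores = u[:, 0] * sv[0] / np.sqrt(rs)
    scores[r == 0] = 0.0
    return scores


def _spline_basis(scores: np.ndarray, df: int, grid: np.ndarray):
    """Cubic B-spline design matrices at the sample scores and on a grid.

    ``df`` is the number of basis functions beyond the intercept, so df=4
    gives five cubic basis functions (one interior knot at the median score).
    """
    k = 3
    n_basis = df + 1
    n_interior = max(n_basis - (k + 1), 0)
    lo, hi = float(scores.min()), float(scores.max())
    if hi <= lo:
        raise ValueError("degenerate scores: all equal")
    if n_interior:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(scores, qs)
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (k + 1), np.sort(interior), [hi] * (k + 1)])
    x = np.clip(scores, lo, hi)
    b = BSpline.design_matrix(x, t, k).toarray()
    bg = BSpline.design_matrix(np.clip(grid, lo, hi), t, k).toarray()
    return b, bg


def principal_curve_ordination(matrix, transform: str = "none", df: int = 4,
                               canopy=None, max_iter: int = 50,
                               tol: float = 1e-6,
                               grid_size: int = 201) -> PrincipalCurveResult:
    """One-dimensional principal-curve ordination of a samples x species matrix.

    Parameters
    ----------
    matrix : samples x species abundances (DataFrame or array), >= 2 samples.
    transform : "none", "sqrt", or "log" (ln(x + 0.5)), applied before fitting.
    df : effective degrees of freedom of the per-species spline smoother.
    canopy : optional per-sample covariate used only to orient the axis
        (scores are made to correlate positively with it); without it the
        orientation follows the correspondence-analysis initialization.

    Returns scores rescaled to [0, 1] and the fraction of total variance
    (about species means, after transformation) explained by the curve.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    z = _apply_transform(m, transform)
    center = z - z.mean(axis=0)
    ss_tot = float((center ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant matrix: no compositional variation")

    if m.shape[0] == 2:
        scores = np.array([0.0, 1.0])
        return PrincipalCurveResult(scores=_orient(scores, canopy, scores),
                                    variance_explained=1.0, fitted=z.copy(),
                                    n_iterations=0, converged=True)

    init = _ca_first_axis(np.clip(m, 0, None)) if (m >= 0).all() \
        else z @ svd(center, full_matrices=False)[2][0]
    scores = _rescale(init)
    grid = np.linspace(0.0, 1.0, grid_size)

    ss_res_prev = np.inf
    converged = False
    fitted = z.copy()
    for it in range(1, max_iter + 1):
        b, bg = _spline_basis(scores, df, grid)
        coef, *_ = np.linalg.lstsq(b, z, rcond=None)
        curve = bg @ coef                      # grid x species
        d2 = ((z[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        # re-parameterize by arc length along the fitted curve, refining the
        # nearest grid point to an exact projection on the adjacent segments
        seg = np.sqrt(((np.diff(curve, axis=0)) ** 2).sum(axis=1))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        fitted, new_scores, ss_res = _project_local(z, curve, arc, nearest)
        if new_scores.max() == new_scores.min():
            logger.warning("principal curve collapsed to a point at iteration %d", it)
            break
        scores = _rescale(new_scores)
        if abs(ss_res_prev - ss_res) / ss_tot < tol:
            converged = True
            ss_res_prev = ss_res
            break
        ss_res_prev = ss_res
    else:
        it = max_iter
        logger.warning("principal curve did not converge in %d iterations", max_iter)

    ve = max(0.0, 1.0 - ss_res_prev / ss_tot)
    return PrincipalCurveResult(scores=_orient(scores, canopy, init),
                                variance_explained=ve, fitted=fitted,
                                n_iterations=it, converged=converged)


def _project_local(z: np.ndarray, curve: np.ndarray, arc: np.ndarray,
                   nearest: np.ndarray):
    """Exact orthogonal projection onto the polyline segments adjacent to the
    nearest grid point of each sample.  Returns fitted points, arc-length
    scores, and the residual sum of squares."""
    n = len(z)
    best_d2 = np.full(n, np.inf)
    best_fit = curve[nearest].copy()
    best_arc = arc[nearest].copy()
    for a_idx, b_idx in ((nearest - 1, nearest), (nearest, nearest + 1)):
        a = np.clip(a_idx, 0, len(curve) - 1)
        bb = np.clip(b_idx, 0, len(curve) - 1)
        valid = a != bb
        v = curve[bb] - curve[a]
        vv = (v ** 2).sum(axis=1)
        vv[vv == 0] = 1.0
        t = np.clip(((z - curve[a]) * v).sum(axis=1) / vv, 0.0, 1.0)
        proj = curve[a] + t[:, None] * v
        d2 = ((z - proj) ** 2).sum(axis=1)
        improve = valid & (d2 < best_d2)
        best_d2[improve] = d2[improve]
        best_fit[improve] = proj[improve]
        seg_len = arc[bb] - arc[a]
        best_arc[improve] = (arc[a] + t * seg_len)[improve]
    # fall back to the grid point itself where no segment applied
    grid_d2 = ((z - curve[nearest]) ** 2).sum(axis=1)
    worse = grid_d2 < best_d2
    best_d2[worse] = grid_d2[worse]
    best_fit[worse] = curve[nearest][worse]
    best_arc[worse] = arc[nearest][worse]
    return best_fit, best_arc, float(best_d2.sum())


def _rescale(s: np.ndarray) -> np.ndarray:
    return (s - s.min()) / (s.max() - s.min())


def _orient(scores: np.ndarray, canopy, fallback: np.ndarray) -> np.ndarray:
    ref = np.asarray(canopy, dtype=float) if canopy is not None else fallback
    if np.std(ref) > 0 and np.corrcoef(scores, ref)[0, 1] < 0:
        return 1.0 - scores
    return scores


# ---------------------------------------------------------------------------
# indicator species analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndValResult:
    indval: pd.DataFrame          # species x groups, values in [0, 100]
    summary: pd.DataFrame         # per species: max_group, indval_max, p_raw, p_adj
    n_permutations: int


def _group_order(labels: np.ndarray) -> list:
    labs = list(pd.unique(labels))
    if set(labs) <= set(HABITATS):
        return [h for h in HABITATS if h in labs]
    return sorted(labs)


def _indval_matrix(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """IndVal (groups x species): 100 * specificity * fidelity."""
    sizes = masks.sum(axis=1)[:, None]
    means = (masks @ x) / sizes
    denom = means.sum(axis=0, keepdims=True)
    denom[denom == 0] = 1.0
    a = means / denom
    b = (masks @ (x > 0)) / sizes
    return 100.0 * a * b


def indicator_values(matrix, groups, n_permutations: int = 4999,
                     seed: int | None = None) -> IndValResult:
    """Dufrene-Legendre indicator values with a permutation test.

    ``matrix`` is sites x species abundances; ``groups`` assigns each site to
    a habitat class.  Each species' p-value is the permutation probability of
    a maximum IndVal at least as large as observed under random reassignment
    of sites to groups with sizes preserved, using the (1+b)/(n_perm+1)
    convention, Benjamini-Hochberg adjusted across species.  Ties in the
    maximum group resolve to the first group in gradient order
    (open, savanna, woodland, scrub, forest) and are logged.
    """
    x = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    if x.shape[0] != groups.size:
        raise ValueError("group labels do not match the number of sites")
    order = _group_order(groups)
    if len(order) < 2:
        raise ValueError("need at least two groups")
    masks = np.stack([(groups == g) for g in order]).astype(float)
    if (masks.sum(axis=1) == 0).any():
        raise ValueError("a group has zero sites")

    iv = _indval_matrix(x, masks)              # groups x species
    max_idx = iv.argmax(axis=0)
    obs_max = iv.max(axis=0)
    n_ties = int(((iv == obs_max[None, :]).sum(axis=0) > 1).sum())
    if n_ties:
        logger.info("%d species had tied maximum IndVal; first gradient-order "
                    "group reported", n_ties)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    for _ in range(n_permutations):
        perm = rng.permutation(x.shape[0])
        piv = _indval_matrix(x[perm], masks)
        exceed += piv.max(axis=0) >= obs_max
    p_raw = (1.0 + exceed) / (n_permutations + 1.0)

    species = (list(matrix.columns) if isinstance(matrix, pd.DataFrame)
               else [f"sp{i}" for i in range(x.shape[1])])
    iv_df = pd.DataFrame(iv.T, index=species, columns=order)
    summary = pd.DataFrame({
        "max_group": [order[i] for i in max_idx],
        "indval_max": obs_max,
        "p_raw": p_raw,
        "p_adj": benjamini_hochberg(p_raw),
    }, index=species)
    return IndValResult(indval=iv_df, summary=summary,
                        n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# predictive co-correspondence analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoCAResult:
    n_axes: int
    cv_fit: np.ndarray               # cumulative LOO CV fit (%) per axis count
    variance_explained: np.ndarray   # cumulative % of response inertia
    site_scores: np.ndarray          # samples x axes (predictor-side scores)
    singular_values: np.ndarray
    axis_p: np.ndarray | None = None


def _coca_prepare(y: np.ndarray, x: np.ndarray):
    ry = y.sum(axis=1)
    rx = x.sum(axis=1)
    if (ry <= 0).any() or (rx <= 0).any():
        raise ValueError("all-zero sample row in response or predictor")
    r = ry / ry.sum()                         # site weights from the response
    qy = y / ry[:, None]
    cy = r @ qy
    keep_y = cy > 0
    yc = (qy[:, keep_y] - cy[keep_y]) / np.sqrt(cy[keep_y])
    qx = x / rx[:, None]
    cx = r @ qx
    keep_x = cx > 0
    xc = (qx[:, keep_x] - cx[keep_x]) / np.sqrt(cx[keep_x])
    return r, yc, xc, cy[keep_y], cx[keep_x], keep_y, keep_x


def _wpls_fit(xc: np.ndarray, yc: np.ndarray, r: np.ndarray, n_axes: int):
    """Weighted PLS: axes maximizing covariance in the site-weight metric."""
    xd, yd = xc.copy(), yc.copy()
    ws, ps, qs, ts, norms, svals = [], [], [], [], [], []
    for _ in range(n_axes):
        m = xd.T @ (r[:, None] * yd)
        u, s, _ = svd(m, full_matrices=False)
        if s[0] < 1e-12:
            break
        w = u[:, 0]
        t = xd @ w
        nrm = float(np.sqrt(np.sum(r * t * t)))
        if nrm < 1e-12:
            break
        t = t / nrm
        p = xd.T @ (r * t)
        q = yd.T @ (r * t)
        xd = xd - np.outer(t, p)
        yd = yd - np.outer(t, q)
        ws.append(w); ps.append(p); qs.append(q); ts.append(t)
        norms.append(nrm); svals.append(float(s[0]))
    return ws, ps, qs, ts, norms, svals


def _wpls_predict(xc_row: np.ndarray, ws, ps, qs, norms, n_axes: int) -> np.ndarray:
    xrow = xc_row.copy()
    yhat = np.zeros(qs[0].shape[0]) if qs else np.zeros(0)
    for a in range(min(n_axes, len(ws))):
        t = float(xrow @ ws[a]) / norms[a]
        xrow = xrow - t * ps[a]
        yhat = yhat + t * qs[a]
    return yhat


def predictive_coca(response, predictor, max_axes: int = 4,
                    n_permutations: int = 0,
                    seed: int | None = None) -> CoCAResult:
    """Predictive co-correspondence analysis of two community matrices.

    ``response`` (Y) and ``predictor`` (X) are samples x species abundance
    matrices over the same samples, nonnegative with no all-zero rows.  Axes
    are extracted by weighted PLS on chi-square-scaled row profiles (site
    weights from Y's row totals).  The leave-one-out cross-validated fit for
    k axes is

        100 * (1 - PRESS_k / PRESS_0)

    with PRESS the weighted squared error of predicted left-out response
    profiles; zero axes predict the (training) mean profile, so useless
    predictors give fits <= 0.  ``n_permutations > 0`` additionally tests each
    axis by permuting the sample rows of X and comparing singular values.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.ndim != 2 or x.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("response and predictor must share the same samples")
    if (y < 0).any() or (x < 0).any():
        raise ValueError("community matrices must be nonnegative")
    n = y.shape[0]
    max_axes = int(min(max_axes, n - 2, x.shape[1], y.shape[1]))
    if max_axes < 1:
        raise ValueError("too few samples or species for even one axis")

    r, yc, xc, cy, cx, keep_y, keep_x = _coca_prepare(y, x)
    ws, ps, qs, ts, norms, svals = _wpls_fit(xc, yc, r, max_axes)
    k = len(ws)
    total_inertia = float(np.sum(r[:, None] * yc ** 2))
    explained = np.cumsum([float(np.sum(q ** 2)) for q in qs])
    variance_explained = 100.0 * explained / total_inertia

    # leave-one-out cross-validation
    press = np.zeros(k + 1)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        ri, yci, xci, cyi, cxi, ky, kx = _coca_prepare(y[keep], x[keep])
        wsi, psi, qsi, tsi, normsi, _ = _wpls_fit(xci, yci, ri, k)
        # transform the left-out row with the training centering/scaling
        xprof = x[i] / x[i].sum()
        xrow = (xprof[kx] - cxi) / np.sqrt(cxi)
        yprof = y[i] / y[i].sum()
        ytrue = (yprof[ky] - cyi) / np.sqrt(cyi)
        wt = y[i].sum()
        press[0] += wt * float(ytrue @ ytrue)
        for kk in range(1, k + 1):
            yhat = _wpls_predict(xrow, wsi, psi, qsi, normsi, kk)
            press[kk] += wt * float(np.sum((ytrue - yhat) ** 2))
    cv_fit = 100.0 * (1.0 - press[1:] / press[0])

    axis_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(k)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            rp, ycp, xcp, *_ = _coca_prepare(y, x[perm])
            _, _, _, _, _, sv_p = _wpls_fit(xcp, ycp, rp, k)
            sv_p = np.asarray(sv_p + [0.0] * (k - len(sv_p)))
            exceed += sv_p >= np.asarray(svals)
        axis_p = (1.0 + exceed) / (n_permutations + 1.0)

    return CoCAResult(n_axes=k, cv_fit=cv_fit,
                      variance_explained=variance_explained,
                      site_scores=np.column_stack(ts) if ts else np.zeros((n, 0)),
                      singular_values=np.asarray(svals), axis_p=axis_p)
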