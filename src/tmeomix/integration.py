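"""Cross-layer correlation and regression analyses.

Two questions are answered here: which genes co-vary (positively or
negatively) with a focal gene across all samples, and how protein abundance
tracks transcript abundance overall.  Protein and transcript layers have
different replicate plans and no stated sample-to-sample correspondence, so
gene–protein pairing is done at the (cell type, condition) group-mean level.
The protein-vs-gene fit is available as ordinary least squares, Tukey
bisquare IRLS (robust), or total least squares (orthogonal, via the
principal axis of the centered 2-D cloud, with signed perpendicular
residuals and a binned residual-bias profile along the fitted axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .io_formats import ExpressionTable, UsageError
from .preprocess import SampleDesign, group_means


@dataclass
class CorrelationRanking:
    """Pearson correlation of every gene with a focal gene, plus top lists."""

    focal: str
    correlations: pd.Series  # per gene, focal excluded; NaN-free
    top_positive: list[str]
    top_negative: list[str]
    undefined: list[str]  # zero-variance genes, excluded from ranking


def focal_correlation(
    table: ExpressionTable, focal: str, k: int = 50
) -> CorrelationRanking:
    """Rank genes by Pearson correlation with the focal gene across all
    samples (controls, TME and tumor groups alike)."""
    if focal not in table.data.index:
        raise UsageError(f"focal gene {focal!r} absent from the table")
    X = table.values
    f = table.data.loc[focal].to_numpy()
    if np.isnan(f).any() or np.isnan(X).any():
        raise UsageError("correlation ranking requires complete rows")
    fc = f - f.mean()
    f_ss = float(fc @ fc)
    if f_ss == 0:
        raise UsageError(f"focal gene {focal!r} has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ fc) / np.sqrt(ss * f_ss)
    series = pd.Series(r, index=table.molecule_ids)
    undefined = sorted(series.index[ss == 0])
    series = series.drop(index=undefined).drop(index=[focal], errors="ignore")
    ranked = series.sort_values(ascending=False)
    return CorrelationRanking(
        focal=focal,
        correlations=series,
        top_positive=list(ranked.index[:k]),
        top_negative=list(ranked.index[::-1][:k]),
        undefined=undefined,
    )


def match_gene_protein(
    genes: ExpressionTable,
    proteins: ExpressionTable,
    design: SampleDesign,
    groups=None,
) -> pd.DataFrame:
    """Pair gene and protein expression by shared official symbol.

    Values are paired at the group-mean level per (cell type, condition);
    the result has one row per (symbol, group) with columns ``gene`` and
    ``protein`` (NaN protein group means are dropped).
    """
    shared = sorted(set(genes.molecule_ids) & set(proteins.molecule_ids))
    if not shared:
        raise UsageError("no shared official symbols between gene and protein tables")
    gm = group_means(genes, design, groups)
    pm = group_means(proteins, design, groups)
    common_groups = [g for g in gm.columns if g in pm.columns]
    rows = []
    for sym in shared:
        for g in common_groups:
            pv = pm.loc[sym, g]
            if np.isnan(pv):
                continue
            rows.append({"symbol": sym, "group": g, "gene": gm.loc[sym, g], "protein": pv})
    return pd.DataFrame(rows, columns=["symbol", "group", "gene", "protein"])


@dataclass
class RegressionFit:
    """A protein-vs-gene line fit with the Pearson correlation of the cloud."""

    slope: float
    intercept: float
    pearson_r: float
    n_points: int
    method: str
    iterations: int = 0
    projections: np.ndarray | None = None  # positions along the fitted axis
    residuals: np.ndarray | None = None  # signed orthogonal residuals
    bias_profile: pd.DataFrame | None = field(default=None, repr=False)


def fit_regression(pairs: pd.DataFrame, method: str = "robust") -> RegressionFit:
    """Fit protein (y) against gene (x) expression.

    ``ordinary``: least squares.  ``robust``: iteratively reweighted least
    squares with Tukey bisquare weights (tuning constant 4.685, MAD scale,
    convergence |Δslope| < 1e-8, at most 100 iterations).  ``orthogonal``:
    total least squares via the principal axis of the centered cloud; also
    reports per-point projections, signed perpendicular residuals and the
    mean signed residual in 10 equal-count bins along the axis.
    """
    x = pairs["gene"].to_numpy(dtype=float)
    y = pairs["protein"].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UsageError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise UsageError("all gene values identical; slope undefined")
    r = float(st.pearsonr(x, y)[0]) if np.ptp(y) > 0 else 0.0

    if method == "ordinary":
        slope, intercept = _ols(x, y, np.ones_like(x))
        return RegressionFit(slope, intercept, r, x.size, method)
    if method == "robust":
        slope, intercept, iters = _bisquare_irls(x, y)
        return RegressionFit(slope, intercept, r, x.size, method, iterations=iters)
    if method == "orthogonal":
        return _orthogonal_fit(x, y, r)
    raise UsageError(f"unknown regression method {method!r}")


def _ols(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise UsageError("weighted x spread collapsed to zero")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(slope), float(ym - slope * xm)


def _bisquare_irls(
    x: np.ndarray, y: np.ndarray, c: float = 4.685, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, float, int]:
    slope, intercept = _ols(x, y, np.ones_like(x))
    iters = 0
    for iters in range(1, max_iter + 1):
        resid = y - (slope * x + intercept)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6745
        if scale == 0:  # exact fit for >half the points
            break
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0 or np.ptp(x[w > 0]) == 0:
            break
        new_slope, new_intercept = _ols(x, y, w)
        converged = abs(new_slope - slope) < tol
        slope, intercept = new_slope, new_intercept
        if converged:
            break
    return float(slope), float(intercept), iters


def _orthogonal_fit(x: np.ndarray, y: np.ndarray, r: float) -> RegressionFit:
    xm, ym = x.mean(), y.mean()
    cloud = np.column_stack([x - xm, y - ym])
    cov = cloud.T @ cloud / (x.size - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    axis = eigvec[:, np.argmax(eigval)]  # principal direction
    if axis[0] < 0:
        axis = -axis
    if axis[0] == 0:
        raise UsageError("orthogonal fit degenerate: principal axis is vertical")
    slope = float(axis[1] / axis[0])
    intercept = float(ym - slope * xm)
    normal = np.array([-axis[1], axis[0]])
    projections = cloud @ axis
    residuals = cloud @ normal
    fit = RegressionFit(
        slope,
        intercept,
        r,
        x.size,
        "orthogonal",
        projections=projections,
        residuals=residuals,
    )
    fit.bias_profile = residual_bias_profile(projections, residuals)
    return fit


def residual_bias_profile(
    projections: np.ndarray, residuals: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Mean signed orthogonal residual in equal-count bins along the fitted
    axis — a systematic deviation from zero in middle bins indicates an
    expression-dependent bias of protein vs transcript abundance."""
    order = np.argsort(projections, kind="mergesort")
    bins = np.array_split(order, min(n_bins, projections.size))
    rows = [
        {
            "bin": i,
            "n": idx.size,
            "projection_mean": float(projections[idx].mean()),
            "residual_mean": float(residuals[idx].mean()),
        }
        for i, idx in enumerate(bins)
        if idx.size
    ]
    return pd.DataFrame(rows)
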