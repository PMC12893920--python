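"""Axis-variable gene detection by negative-binomial spline regression.

Expression of each gene is modelled as a smooth function of the axis
coordinate s in [0, 1], treated analogously to pseudotime: counts are
NB-distributed with log link, linear predictor = intercept + cubic
B-spline basis in s (knots at axis quantiles) + ln(size factor) offset.
The gene-level dispersion is estimated once by a Pearson moment estimator
on the fitted full model and then held fixed; axis association is a
likelihood-ratio test of the spline terms against an intercept-only fit,
with p from chi-square on ``spline_df`` degrees of freedom.

A gene's effect size is the log2 amplitude of the fitted curve
(max - min of the fitted log2 mean over the axis); the detection
criterion is p < 0.001 and log2 amplitude > 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import chi2

from .axis import AxisAssignment, bin_axis
from .errors import AxisTkError
from .io import normalize_log_cpm100

logger = logging.getLogger(__name__)

_GRID_SIZE = 100
_DISPERSION_FLOOR = 1e-8
_MAX_IRLS_ITER = 100


@dataclass(eq=False)
class GeneAxisModel:
    """Fitted NB spline model of one gene's expression along the axis."""

    gene_id: str
    spline_df: int
    coefficients: np.ndarray
    dispersion: float
    grid: np.ndarray
    fitted_log_mean: np.ndarray  # natural-log mean at size factor 1
    loglik: float
    null_loglik: float
    lrt_stat: float
    p_value: float
    log2_amplitude: float
    converged: bool
    n_units: int
    q_value: float | None = None


def bspline_basis(x: np.ndarray, df: int, *, knots: np.ndarray | None = None):
    """Cubic B-spline design matrix with ``df`` columns (no constant).

    A full basis of ``df + 1`` functions is built (degree min(3, df),
    interior knots at quantiles of ``x``) and its first column dropped,
    so the span together with an intercept is the usual spline space.
    For ``df = 1`` the single remaining degree-1 function is the linear
    ramp, making the model an ordinary log-linear NB regression.
    """
    if df < 1:
        raise ValueError("spline_df must be >= 1")
    x = np.asarray(x, dtype=float)
    degree = min(3, df)
    n_interior = df - degree
    lo, hi = 0.0, 1.0
    if knots is None:
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
            interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
            interior = np.maximum.accumulate(interior)  # keep non-decreasing
        else:
            interior = np.array([])
        knots = np.concatenate(
            [[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        )
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return B[:, 1:], knots


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Pearson moment estimator of the NB2 dispersion.

    Under NB2, E[(y - mu)^2 / mu] = 1 + alpha * mu; equating the Poisson
    Pearson statistic to its NB expectation gives
    alpha = (X^2 - (n - p)) / sum(mu).
    """
    n = y.shape[0]
    x2 = np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12))
    alpha = (x2 - (n - n_params)) / np.sum(mu)
    return float(max(alpha, _DISPERSION_FLOOR))


def fit_gene_axis_model(
    counts_g: np.ndarray,
    axis: np.ndarray,
    size_factors: np.ndarray,
    spline_df: int = 5,
    *,
    gene_id: str = "",
    dispersion: float | None = None,
) -> GeneAxisModel:
    """Fit the NB spline model for one gene and test axis association.

    Parameters
    ----------
    counts_g
        Integer counts per unit.
    axis
        Axis coordinate per unit in [0, 1] (no missing values).
    size_factors
        Positive per-unit depth factors, entering as a log offset.
    spline_df
        Number of spline basis functions (test degrees of freedom).
    dispersion
        Fix the NB dispersion instead of estimating it.

    All-zero genes return a flat model with statistic 0 and p = 1.
    Fits that have not converged after 100 IRLS iterations are flagged
    (``converged=False``) and excluded from q-value computation.
    """
    y = np.asarray(counts_g, dtype=float)
    if sp.issparse(counts_g):
        y = np.asarray(counts_g.todense()).ravel()
    s = np.asarray(axis, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    if np.isnan(s).any():
        raise ValueError("axis contains missing values; mask them first")
    n = y.shape[0]
    if n < 10 * spline_df:
        raise ValueError(f"need >= {10 * spline_df} units for spline_df={spline_df}")
    grid = np.linspace(0.0, 1.0, _GRID_SIZE)

    if y.sum() == 0:
        return GeneAxisModel(
            gene_id=gene_id,
            spline_df=spline_df,
            coefficients=np.zeros(spline_df + 1),
            dispersion=_DISPERSION_FLOOR,
            grid=grid,
            fitted_log_mean=np.full(_GRID_SIZE, -np.inf),
            loglik=0.0,
            null_loglik=0.0,
            lrt_stat=0.0,
            p_value=1.0,
            log2_amplitude=0.0,
            converged=True,
            n_units=n,
        )

    B, knots = bspline_basis(s, spline_df)
    X = np.column_stack([np.ones(n), B])
    offset = np.log(sf)

    if dispersion is None:
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
            maxiter=_MAX_IRLS_ITER
        )
        alpha = _moment_dispersion(y, pois.mu, X.shape[1])
    else:
        alpha = max(float(dispersion), _DISPERSION_FLOOR)

    fam = sm.families.NegativeBinomial(alpha=alpha)
    full = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=_MAX_IRLS_ITER)
    null = sm.GLM(y, np.ones((n, 1)), family=fam, offset=offset).fit(
        maxiter=_MAX_IRLS_ITER
    )

    Bg, _ = bspline_basis(grid, spline_df, knots=knots)
    Xg = np.column_stack([np.ones(_GRID_SIZE), Bg])
    fitted_log_mean = Xg @ full.params

    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(chi2.sf(lrt, df=spline_df)) if lrt > 0 else 1.0
    amp = float((fitted_log_mean.max() - fitted_log_mean.min()) / np.log(2.0))
    return GeneAxisModel(
        gene_id=gene_id,
        spline_df=spline_df,
        coefficients=np.asarray(full.params),
        dispersion=alpha,
        grid=grid,
        fitted_log_mean=fitted_log_mean,
        loglik=float(full.llf),
        null_loglik=float(null.llf),
        lrt_stat=float(lrt),
        p_value=p,
        log2_amplitude=amp,
        converged=bool(getattr(full, "converged", True)),
        n_units=n,
    )


def association_test(model: GeneAxisModel, null_model: GeneAxisModel | None = None):
    """Likelihood-ratio test of the spline terms.

    With ``null_model`` given (an intercept-only fit of the same gene on
    the same units and offsets), the statistic is recomputed from the two
    log-likelihoods; otherwise the statistic stored in ``model`` is
    returned. Returns (lrt_stat, p_value).
    """
    if null_model is not None:
        if null_model.n_units != model.n_units:
            raise AxisTkError("full and null fits are on different unit sets")
        lrt = max(0.0, 2.0 * (model.loglik - null_model.loglik))
    else:
        lrt = model.lrt_stat
    p = float(chi2.sf(lrt, df=model.spline_df)) if lrt > 0 else 1.0
    return lrt, p


def default_size_factors(adata: ad.AnnData) -> np.ndarray:
    """Total counts scaled to mean 1 (so fitted means stay at count scale)."""
    totals = np.asarray(sp.csr_matrix(adata.X).sum(axis=1), dtype=float).ravel()
    return totals / totals.mean()


def detect_spatially_variable_genes(
    adata: ad.AnnData,
    axis: AxisAssignment | pd.Series,
    p_max: float = 0.001,
    min_log2fc: float = 0.5,
    spline_df: int = 5,
    min_expr_frac: float = 0.01,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the axis model for every sufficiently expressed gene.

    Genes detected in at least ``min_expr_frac`` of units are fitted;
    a gene passes when p < ``p_max`` and log2 amplitude > ``min_log2fc``
    (the raw p is thresholded; BH q-values are reported alongside).
    The table is sorted by the LRT statistic, descending.
    """
    axis_values = (
        axis.to_series() if isinstance(axis, AxisAssignment) else pd.Series(axis)
    )
    axis_values = axis_values.reindex(adata.obs_names)
    keep = ~axis_values.isna().to_numpy()
    if cell_mask is not None:
        keep &= np.asarray(cell_mask, dtype=bool)
    sub = adata[keep]
    s = axis_values.to_numpy(dtype=float)[keep]
    X = sp.csc_matrix(sub.X)
    sf = default_size_factors(sub)
    det_frac = np.asarray((X > 0).sum(axis=0)).ravel() / sub.n_obs
    test_idx = np.flatnonzero(det_frac >= min_expr_frac)
    if test_idx.size == 0:
        logger.warning("no genes pass the %.1f%% expression floor", 100 * min_expr_frac)
        return pd.DataFrame(
            columns=["gene_id", "lrt_stat", "p_value", "q_value",
                     "log2_amplitude", "pattern", "converged", "pass"]
        ).set_index("gene_id")

    rows = []
    models = []
    for j in test_idx:
        y = np.asarray(X[:, j].todense()).ravel()
        m = fit_gene_axis_model(
            y, s, sf, spline_df=spline_df, gene_id=str(sub.var_names[j])
        )
        models.append(m)
        rows.append(
            {
                "gene_id": m.gene_id,
                "lrt_stat": m.lrt_stat,
                "p_value": m.p_value,
                "log2_amplitude": m.log2_amplitude,
                "pattern": classify_pattern(m, min_log2fc=min_log2fc),
                "converged": m.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    table["q_value"] = np.nan
    conv = table["converged"].to_numpy()
    if conv.any():
        table.loc[conv, "q_value"] = _bh_adjust(table.loc[conv, "p_value"].to_numpy())
    table["pass"] = (
        (table["p_value"] < p_max)
        & (table["log2_amplitude"] > min_log2fc)
        & table["converged"]
    )
    table = table.sort_values("lrt_stat", ascending=False)
    table.attrs["models"] = {m.gene_id: m for m in models}
    return table[
        ["lrt_stat", "p_value", "q_value", "log2_amplitude", "pattern",
         "converged", "pass"]
    ]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def binned_minmax_profiles(
    adata: ad.AnnData,
    axis: AxisAssignment | pd.Series,
    gene_list: list[str],
    n_bins: int = 20,
    *,
    use_fitted: bool = False,
    models: dict[str, GeneAxisModel] | None = None,
) -> pd.DataFrame:
    """Min-max normalized expression profiles over axis bins (gene x bin).

    Per bin, the mean depth-normalized expression (or the fitted model
    value at the bin centre with ``use_fitted``); each gene's row is then
    scaled to [0, 1]. Constant rows are all zeros by convention. Empty
    bins are NaN unless filled from the fitted curve.
    """
    missing = [g for g in gene_list if g not in set(adata.var_names)]
    if missing:
        raise AxisTkError(f"genes absent from dataset: {missing}")
    assignment = (
        axis
        if isinstance(axis, AxisAssignment)
        else AxisAssignment(unit_ids=np.asarray(axis.index), value=axis.to_numpy())
    )
    bins = bin_axis(assignment, n_bins=n_bins).reindex(adata.obs_names)
    centres = (np.arange(n_bins) + 0.5) / n_bins
    prof = np.full((len(gene_list), n_bins), np.nan)
    if use_fitted:
        if models is None:
            raise AxisTkError("use_fitted requires fitted models")
        for i, g in enumerate(gene_list):
            m = models[g]
            prof[i] = np.interp(centres, m.grid, m.fitted_log_mean)
    else:
        # depth-normalize on the full gene universe, then subset columns
        norm = normalize_log_cpm100(adata)
        col_idx = pd.Index(adata.var_names).get_indexer(gene_list)
        dense = np.asarray(norm[:, col_idx].todense())
        for b in range(n_bins):
            mask = (bins == b).to_numpy(dtype=bool)
            if mask.any():
                prof[:, b] = dense[mask].mean(axis=0)
    lo = np.nanmin(prof, axis=1, keepdims=True)
    hi = np.nanmax(prof, axis=1, keepdims=True)
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(rng > 0, (prof - lo) / np.where(rng == 0, 1, rng), 0.0)
    scaled = np.where(np.isnan(prof), np.nan, scaled)
    return pd.DataFrame(
        scaled, index=pd.Index(gene_list, name="gene_id"),
        columns=[f"bin{b}" for b in range(n_bins)],
    )


def classify_pattern(model: GeneAxisModel, min_log2fc: float = 0.5) -> str:
    """Classify the fitted profile: flat (amplitude at or below the
    threshold), else rostral / middle / caudal by the position of the
    fitted maximum (argmax in [0, 1/3), [1/3, 2/3], (2/3, 1])."""
    if model.log2_amplitude <= min_log2fc:
        return "flat"
    peak = model.grid[int(np.argmax(model.fitted_log_mean))]
    if peak < 1.0 / 3.0:
        return "rostral"
    if peak <= 2.0 / 3.0:
        return "middle"
    return "caudal"
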