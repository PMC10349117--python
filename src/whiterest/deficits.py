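"""Cohort statistics linking lesion impact scores to clinical deficits.

A deficit is summarised from its battery of clinical scores by the first
principal component of the standardised columns, min-max normalised to
[0, 1] (0 = minimum, 1 = maximum deficit in the cohort).  The deficit is
then related to the per-patient DiscROver score of the matching network by
Pearson correlation and ordinary least-squares fit, with a covariate-
corrected coefficient of determination (squared partial correlation
controlling for age, sex and chronicity) and a bootstrap confidence band
around the fitted line (percentile interval, 1000 resamples by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA

__all__ = [
    "DeficitScores",
    "LinearFit",
    "deficit_score",
    "fit_linear",
    "corrected_r2",
    "bootstrap_band",
    "dual_impact_select",
]


@dataclass
class DeficitScores:
    """Per-patient deficit in [0, 1] plus the first-PC variance share."""

    scores: np.ndarray
    variance_explained: float


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int


def _as_matrix(scores) -> np.ndarray:
    x = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if x.ndim != 2:
        raise ValueError("clinical scores must be a 2D table (patients x scores)")
    if np.isnan(x).any():
        raise ValueError("clinical scores contain missing values")
    return x


def deficit_score(scores) -> DeficitScores:
    """First-principal-component deficit score, min-max scaled to [0, 1].

    Columns are standardised (correlation-matrix PCA) since clinical scales
    differ in units.  The component sign is oriented so the score correlates
    non-negatively with the mean of the standardised columns, making larger
    values consistently mean larger deficit for deficit-oriented batteries.
    """
    x = _as_matrix(scores)
    n, p = x.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 patients and 2 score columns")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance clinical score column")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=min(n, p))
    proj = pca.fit_transform(z)[:, 0]
    if np.corrcoef(proj, z.mean(axis=1))[0, 1] < 0:
        proj = -proj
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        raise ValueError("degenerate first component (constant scores)")
    return DeficitScores(
        scores=(proj - lo) / (hi - lo),
        variance_explained=float(pca.explained_variance_ratio_[0]),
    )


def fit_linear(x, y) -> LinearFit:
    """OLS line, Pearson r, R^2 = r^2, and the exact two-sided t-test p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = scipy.stats.linregress(x, y)
    r, p = scipy.stats.pearsonr(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(r),
        r2=float(r) ** 2,
        p=float(p),
        n=len(x),
    )


def _residualise(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), cov])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def corrected_r2(x, y, covariates, method: str = "partial") -> float:
    """Covariate-corrected coefficient of determination (R^2-c).

    ``method="partial"`` (default): residualise both x and y on the
    covariates (with intercept) and square the Pearson correlation of the
    residuals.  ``method="semipartial"``: hierarchical increment, the R^2 of
    y ~ covariates + x minus the R^2 of y ~ covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if len(x) != len(y) or len(x) != len(cov):
        raise ValueError("x, y and covariates must have the same length")
    design = np.column_stack([np.ones(len(x)), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if method == "partial":
        rx = _residualise(x, cov)
        ry = _residualise(y, cov)
        if np.allclose(rx, 0) or np.allclose(ry, 0):
            return 0.0
        return float(np.corrcoef(rx, ry)[0, 1] ** 2)
    if method == "semipartial":
        def ssr(design_):
            beta, *_ = np.linalg.lstsq(design_, y, rcond=None)
            resid = y - design_ @ beta
            return 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)

        full = np.column_stack([design, x])
        return float(ssr(full) - ssr(design))
    raise ValueError(f"unknown method {method!r}")


def bootstrap_band(
    x,
    y,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> dict:
    """Percentile bootstrap confidence band for the OLS line.

    Patients (x, y rows) are resampled with replacement ``n_boot`` times and
    the line refit; the band at each grid point is the percentile interval
    at ``level``.  Degenerate resamples (constant x) are redrawn and counted.
    Deterministic given the seed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, float)
    preds = np.empty((n_boot, len(grid)))
    n = len(x)
    n_degenerate = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            xb = x[idx]
            if np.ptp(xb) > 0:
                break
            n_degenerate += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        yb = y[idx]
        slope, intercept = np.polyfit(xb, yb, 1)
        preds[b] = intercept + slope * grid
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(preds, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return {
        "grid": grid,
        "low": lo,
        "high": hi,
        "level": level,
        "n_boot": n_boot,
        "n_degenerate_redrawn": n_degenerate,
    }


def dual_impact_select(
    score_table: pd.DataFrame,
    rsn_a: str,
    rsn_b: str,
    threshold: float = 33.0,
) -> pd.DataFrame:
    """Patients whose lesion impacts both networks above the threshold.

    Selection is strict (> threshold) on both DiscROver columns, mirroring
    the "at least a third of both networks impacted" criterion.
    """
    for col in (rsn_a, rsn_b):
        if col not in score_table.columns:
            raise KeyError(f"missing DiscROver column {col!r}")
    sel = (score_table[rsn_a] > threshold) & (score_table[rsn_b] > threshold)
    return score_table.loc[sel]
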