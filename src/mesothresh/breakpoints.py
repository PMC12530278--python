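"""Linear vs. single-breakpoint piecewise fits and environment PC1.

The piecewise model is OLS on the hinge basis {1, x, (x - c)+} profiled over
the breakpoint c: every interior observed x is a grid candidate, and the
winner is refined by golden-section search on the (continuous) profile RSS
between its neighboring candidates. The model-selection rule compares the
piecewise fit to the nested straight line with an F test charging the
breakpoint two parameters (slope change + breakpoint location), selecting
the piecewise model when p < alpha (default 0.01). Because the breakpoint is
profiled, the F(2, n-4) reference is approximate and slightly liberal under
the null; the calibration is measured, not assumed, in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ENV_VARIABLES


@dataclass
class LinearFit:
    intercept: float
    slope: float
    rss: float
    df_resid: int
    fitted: np.ndarray


@dataclass
class BreakpointFit:
    intercept: float
    slope_below: float
    slope_above: float
    breakpoint_estimate: float
    rss: float
    df_resid: int
    fitted: np.ndarray


@dataclass
class ModelComparison:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    selected: str                 # "linear" | "piecewise"
    alpha: float = 0.01


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares y ~ x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("fit_linear needs n >= 3")
    if np.std(x) == 0:
        raise ValueError("fit_linear: x is constant")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return LinearFit(float(beta[0]), float(beta[1]), rss, n - 2, fitted)


def _hinge_rss(x: np.ndarray, y: np.ndarray, c: float):
    X = np.column_stack([np.ones_like(x), x, np.clip(x - c, 0.0, None)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2)), beta, fitted


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(fun, lo: float, hi: float, tol: float) -> float:
    a, b = lo, hi
    c1 = b - _GOLDEN * (b - a)
    c2 = a + _GOLDEN * (b - a)
    f1, f2 = fun(c1), fun(c2)
    while b - a > tol:
        if f1 <= f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - _GOLDEN * (b - a)
            f1 = fun(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + _GOLDEN * (b - a)
            f2 = fun(c2)
    return 0.5 * (a + b)


def fit_piecewise(x, y, grid=None) -> BreakpointFit:
    """Single-breakpoint piecewise-linear OLS with profiled breakpoint.

    ``grid`` defaults to the observed interior x values (>= 2 points strictly
    on each side); the best grid candidate is refined by golden-section
    search between its neighbors. Residual df is n - 4: intercept, slope,
    slope change, and the breakpoint each consume one parameter.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 5:
        raise ValueError("fit_piecewise needs n >= 5")
    xs = np.unique(x)
    if grid is None:
        grid = [c for c in xs if (x < c).sum() >= 2 and (x > c).sum() >= 2]
    else:
        grid = [c for c in np.asarray(grid, float)
                if (x < c).sum() >= 2 and (x > c).sum() >= 2]
    if not grid:
        raise ValueError(
            "fit_piecewise: no admissible breakpoint candidate "
            "(need >= 2 points strictly on each side)")
    grid = np.asarray(sorted(grid))
    rss_grid = np.array([_hinge_rss(x, y, c)[0] for c in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[i - 1] if i > 0 else grid[i]
    hi = grid[i + 1] if i < len(grid) - 1 else grid[i]
    span = x.max() - x.min()
    best_c = float(grid[i])
    if hi > lo:
        refined = _golden_section(lambda c: _hinge_rss(x, y, c)[0],
                                  float(lo), float(hi),
                                  tol=max(span * 1e-12, 1e-14))
        if (_hinge_rss(x, y, refined)[0] <= rss_grid[i] and
                (x < refined).sum() >= 2 and (x > refined).sum() >= 2):
            best_c = float(refined)
    rss, beta, fitted = _hinge_rss(x, y, best_c)
    return BreakpointFit(
        intercept=float(beta[0]), slope_below=float(beta[1]),
        slope_above=float(beta[1] + beta[2]),
        breakpoint_estimate=best_c, rss=rss, df_resid=n - 4, fitted=fitted)


def compare_models(linear: LinearFit, piecewise: BreakpointFit,
                   alpha: float = 0.01) -> ModelComparison:
    """ANOVA-style comparison of the nested linear and piecewise fits."""
    if piecewise.rss > linear.rss + 1e-8 * max(1.0, linear.rss):
        raise RuntimeError(
            "piecewise RSS exceeds linear RSS; fits are inconsistent")
    df2 = piecewise.df_resid
    if piecewise.rss <= 0:
        f = np.inf
        p = 0.0
    else:
        f = ((linear.rss - piecewise.rss) / 2.0) / (piecewise.rss / df2)
        p = float(stats.f.sf(f, 2, df2))
    selected = "piecewise" if p < alpha else "linear"
    return ModelComparison(float(f), 2, df2, p, selected, alpha)


def select_breakpoint_model(x, y, alpha: float = 0.01):
    """Convenience wrapper: fit both models and apply the selection rule."""
    lin = fit_linear(x, y)
    pw = fit_piecewise(x, y)
    return lin, pw, compare_models(lin, pw, alpha=alpha)


def environment_pc1(env: pd.DataFrame, orient_by=None) -> pd.Series:
    """First principal-coordinate axis of the standardized environment table.

    Variables are z-scored and the axis comes from classical scaling of
    Euclidean distances (equivalently, PCA scores on the correlation scale).
    Zero-variance variables are dropped with a warning. ``orient_by`` flips
    the sign so the correlation with the supplied covariate (e.g. loading)
    is non-negative.
    """
    missing = [v for v in ENV_VARIABLES if v not in env.columns]
    if missing:
        raise ValueError(f"environment table missing variable(s): {missing}")
    x = env[list(ENV_VARIABLES)].astype(float)
    sd = x.std(ddof=0)
    dead = list(sd.index[sd == 0])
    if dead:
        warnings.warn(f"environment_pc1: dropping zero-variance {dead}")
        x = x.drop(columns=dead)
        sd = sd.drop(dead)
    z = (x - x.mean()) / sd
    # PCoA on Euclidean distances of z == PCA: take top eigenvector of z z^T
    m = z.to_numpy()
    m = m - m.mean(axis=0)
    gram = m @ m.T
    vals, vecs = np.linalg.eigh(gram)
    v1 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    scores = pd.Series(v1, index=env.index, name="env_pc1")
    if orient_by is not None:
        cov = np.asarray(pd.Series(orient_by).to_numpy(), float)
        c = cov - cov.mean()
        if c.std() > 0 and float(scores.to_numpy() @ c) < 0:
            scores = -scores
    return scores
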