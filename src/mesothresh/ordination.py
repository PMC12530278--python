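"""Ordination: classical scaling (PCoA), non-metric MDS, and vector fitting.

PCoA is the exact eigendecomposition of the Gower-centered matrix; NMDS
minimizes Kruskal stress-1 by alternating isotonic regression (monotone
fitted distances) with Guttman majorization steps, initialized from PCoA.
``envfit`` projects external variables onto ordination scores with a
permutation test on the OLS R^2, mirroring the vegan convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .diversity import DissimilarityMatrix


@dataclass
class Ordination:
    sample_ids: list
    scores: np.ndarray                  # n x k, centered per axis
    method: str                         # "pcoa" | "nmds"
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    stress_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def pcoa(d: DissimilarityMatrix, k: int = 2) -> Ordination:
    """Classical (metric) scaling.

    Eigenvalues are reported in decreasing order, negatives included; scores
    use only positive-eigenvalue axes, so ``k`` may not exceed their count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _gower_center(d.values)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10
    n_pos = int(np.sum(vals > tol))
    if k > n_pos:
        raise ValueError(
            f"requested k={k} axes but only {n_pos} positive eigenvalues")
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    scores = scores - scores.mean(axis=0)
    return Ordination(list(d.sample_ids), scores, "pcoa", eigenvalues=vals)


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _isotonic_disparities(dvec: np.ndarray, dist: np.ndarray) -> np.ndarray:
    # Primary (weak) tie treatment: within tied dissimilarities the fitted
    # values may differ, so ties are pre-sorted by the current configuration
    # distances before the monotone fit.
    order = np.lexsort((dist, dvec))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return dhat


def nmds(d: DissimilarityMatrix, k: int = 2, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-7) -> Ordination:
    """Kruskal non-metric MDS of a dissimilarity matrix.

    Initialized from the PCoA configuration; the recorded stress trace is
    non-increasing by construction (an iteration that would raise stress-1 is
    rejected and iteration stops).
    """
    n = d.n
    if n < k + 2:
        raise ValueError(f"nmds needs at least k+2={k+2} samples, got {n}")
    rng = np.random.default_rng(seed)
    try:
        x = pcoa(d, k).scores
    except ValueError:
        x = rng.normal(0.0, 1.0, (n, k))  # degenerate input; random start
    dvec = squareform(d.values, checks=False)
    iu = np.triu_indices(n, 1)

    def distances(conf):
        return pdist(conf)

    dist = distances(x)
    dhat = _isotonic_disparities(dvec, dist)
    stress = _stress1(dist, dhat)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        # Guttman transform toward the current disparities
        dd = np.zeros((n, n))
        dd[iu] = dist
        dd += dd.T
        ratio = np.zeros((n, n))
        nz = dd > 0
        dh = np.zeros((n, n))
        dh[iu] = dhat
        dh += dh.T
        ratio[nz] = dh[nz] / dd[nz]
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = (b @ x) / n
        x_new -= x_new.mean(axis=0)
        dist_new = distances(x_new)
        dhat_new = _isotonic_disparities(dvec, dist_new)
        stress_new = _stress1(dist_new, dhat_new)
        if stress_new > stress:      # never report an increasing trace
            converged = True
            break
        x, dist, dhat = x_new, dist_new, dhat_new
        trace.append(stress_new)
        if stress - stress_new < tol:
            stress = stress_new
            converged = True
            break
        stress = stress_new
    if not converged:
        warnings.warn(f"nmds did not converge in {max_iter} iterations "
                      f"(stress {stress:.4g})")
    return Ordination(list(d.sample_ids), x, "nmds", stress=stress,
                      stress_trace=trace, converged=converged)


def orient_axes(ordination: Ordination, covariate) -> Ordination:
    """Flip each axis so its correlation with ``covariate`` is >= 0."""
    cov = np.asarray(covariate, dtype=float)
    if cov.std() == 0:
        warnings.warn("orient_axes: zero-variance covariate; no-op")
        return ordination
    scores = ordination.scores.copy()
    c = cov - cov.mean()
    for j in range(scores.shape[1]):
        if float(scores[:, j] @ c) < 0:
            scores[:, j] = -scores[:, j]
    out = Ordination(ordination.sample_ids, scores, ordination.method,
                     eigenvalues=ordination.eigenvalues,
                     stress=ordination.stress,
                     stress_trace=list(ordination.stress_trace),
                     converged=ordination.converged)
    return out


@dataclass
class EnvFitResult:
    """Per-variable direction cosines, r^2 and permutation p on an ordination."""

    table: pd.DataFrame  # index=variable; axis1..axisk, r_squared, p_value
    n_permutations: int

    def __getitem__(self, var: str) -> pd.Series:
        return self.table.loc[var]


def envfit(ordination: Ordination, variables: pd.DataFrame,
           n_perm: int = 999, seed: int = 0) -> EnvFitResult:
    """Least-squares fit of each variable onto ordination scores.

    r^2 is the OLS coefficient of determination of the centered variable on
    the score matrix; p = (exceedances + 1) / (n_perm + 1) under row
    permutation of the variable.
    """
    scores = ordination.scores
    n, k = scores.shape
    if list(variables.index) != list(ordination.sample_ids):
        variables = variables.loc[ordination.sample_ids]
    rng = np.random.default_rng(seed)
    s = scores - scores.mean(axis=0)
    # projection onto score space for fast permuted r^2
    sts_inv = np.linalg.pinv(s.T @ s)
    rows = {}
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    for var in variables.columns:
        v = variables[var].to_numpy(dtype=float)
        vc = v - v.mean()
        tss = float(vc @ vc)
        if tss == 0:
            warnings.warn(f"envfit: variable {var!r} is constant; r^2=0, p=1")
            rows[var] = [0.0] * k + [0.0, 1.0]
            continue
        coef = sts_inv @ (s.T @ vc)
        r2 = float(coef @ (s.T @ vc)) / tss
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else np.zeros(k)
        vp = vc[perms]                       # n_perm x n
        proj = vp @ s                        # n_perm x k
        r2_perm = np.einsum("ij,jk,ik->i", proj, sts_inv, proj) / tss
        p = (np.sum(r2_perm >= r2 - 1e-12) + 1) / (n_perm + 1)
        rows[var] = list(direction) + [r2, float(p)]
    cols = [f"axis{i+1}" for i in range(k)] + ["r_squared", "p_value"]
    return EnvFitResult(pd.DataFrame.from_dict(rows, orient="index",
                                               columns=cols), n_perm)
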