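"""PERMANOVA variance partitioning and the binary loading-threshold scan.

The partition is sequential (Type-I): terms enter in the order given, each
charged the increase in explained sum of squares of the Gower-centered
dissimilarity decomposition. p-values come from free permutation of sample
labels (rows/columns of the dissimilarity matrix permuted jointly), with the
same permutations reused across terms; an exhaustive-enumeration mode exists
for small designs. The threshold scan fits a one-term PERMANOVA for every
binary split "loading <= t vs > t" over observed loading values and reports
the R^2/p profile and its argmax — the compositional transition point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .diversity import DissimilarityMatrix


class DesignError(ValueError):
    """Raised for singular or degenerate PERMANOVA designs."""


@dataclass
class PermanovaResult:
    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    r_squared: dict[str, float]
    pseudo_f: dict[str, float]
    p_value: dict[str, float]
    residual_df: int
    residual_ss: float
    total_df: int
    total_ss: float
    n_permutations: int
    method: str = "permutation"

    def to_table(self) -> pd.DataFrame:
        """Source/df/SS/R2/F/p table (residual and total rows included)."""
        rows = []
        for t in self.terms:
            rows.append((t, self.df[t], self.ss[t], self.r_squared[t],
                         self.pseudo_f[t], self.p_value[t]))
        rows.append(("Residual", self.residual_df, self.residual_ss,
                     self.residual_ss / self.total_ss, np.nan, np.nan))
        rows.append(("Total", self.total_df, self.total_ss, 1.0,
                     np.nan, np.nan))
        return pd.DataFrame(rows, columns=["Source", "df", "SS", "R2", "F",
                                           "p"])


def gower_matrix(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -(1/2) J D^2 J."""
    a = -0.5 * np.asarray(d, float) ** 2
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def _term_columns(values, name: str) -> np.ndarray:
    """Centered model-matrix columns for one term (factor or covariate)."""
    v = np.asarray(pd.Series(values).to_numpy())
    if v.dtype.kind in "OUSb" or isinstance(v[0], str):
        levels = pd.unique(v)
        if len(levels) < 2:
            raise DesignError(f"factor {name!r} has a single level")
        counts = pd.Series(v).value_counts()
        if counts.min() < 2:
            thin = list(counts.index[counts < 2])
            raise DesignError(
                f"factor {name!r} has level(s) with < 2 samples: {thin}")
        cols = np.column_stack([(v == lv).astype(float)
                                for lv in levels[1:]])
    else:
        x = v.astype(float)
        if np.std(x) == 0:
            raise DesignError(f"covariate {name!r} is constant")
        cols = x[:, None]
    return cols - cols.mean(axis=0)


def _sequential_bases(term_items: list[tuple[str, np.ndarray]], n: int):
    """Orthonormal bases of each term's sequential contribution."""
    bases = []
    q_full = np.ones((n, 1)) / np.sqrt(n)  # intercept
    for name, cols in term_items:
        resid = cols - q_full @ (q_full.T @ cols)
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
        q = q[:, keep]
        if q.shape[1] == 0:
            raise DesignError(
                f"term {name!r} is confounded with earlier terms "
                f"(no additional degrees of freedom)")
        bases.append((name, q))
        q_full = np.column_stack([q_full, q])
    return bases


def _explained(q: np.ndarray, g: np.ndarray) -> float:
    return float(np.einsum("ij,jk,ki->", q.T, g, q))


def permanova(d: DissimilarityMatrix, terms: dict[str, object],
              n_perm: int = 999, seed: int = 0,
              method: str = "permutation",
              strata=None) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a dissimilarity matrix.

    Parameters
    ----------
    terms
        Ordered mapping term name -> per-sample values (strings/categorical
        -> factor; numeric -> centered covariate). Order of entry defines the
        Type-I partition.
    method
        ``"permutation"`` (default) or ``"exact"`` (exhaustive enumeration of
        distinct sample relabelings; small n only).
    strata
        Optional per-sample grouping; permutations are then restricted to
        shuffle samples only within each stratum.
    """
    n = d.n
    g = gower_matrix(d.values)
    total_ss = float(np.trace(g))
    term_items = [(name, _term_columns(vals, name))
                  for name, vals in terms.items()]
    bases = _sequential_bases(term_items, n)
    dfs = {name: q.shape[1] for name, q in bases}
    model_df = sum(dfs.values())
    resid_df = n - 1 - model_df
    if resid_df < 1:
        raise DesignError("design leaves no residual degrees of freedom")

    ss = {}
    for name, q in bases:
        ss[name] = _explained(q, g)
    resid_ss = total_ss - sum(ss.values())
    f_obs = {name: (ss[name] / dfs[name]) / (resid_ss / resid_df)
             for name in ss}

    if method == "exact":
        perms = _distinct_relabelings(term_items, strata)
        m = len(perms)
        exceed = {name: 0 for name in ss}
        for p in perms:
            # relabel: design rows permuted against the fixed Gower matrix
            bases_p = _sequential_bases(
                [(name, cols[p]) for name, cols in term_items], n)
            ss_p = {name: _explained(q, g) for name, q in bases_p}
            resid_p = total_ss - sum(ss_p.values())
            for name in ss:
                f_p = (ss_p[name] / dfs[name]) / (resid_p / resid_df)
                if f_p >= f_obs[name] - 1e-12:
                    exceed[name] += 1
        p_vals = {name: exceed[name] / m for name in ss}
        n_used = m
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perms = _random_permutations(rng, n, n_perm, strata)
        exceed = {name: 0 for name in ss}
        for p in perms:
            gp = g[np.ix_(p, p)]
            ss_p = {name: _explained(q, gp) for name, q in bases}
            resid_p = total_ss - sum(ss_p.values())
            for name in ss:
                f_p = (ss_p[name] / dfs[name]) / (resid_p / resid_df)
                if f_p >= f_obs[name] - 1e-12:
                    exceed[name] += 1
        p_vals = {name: (exceed[name] + 1) / (n_perm + 1) for name in ss}
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    r2 = {name: ss[name] / total_ss for name in ss}
    return PermanovaResult(
        terms=[name for name, _ in bases], df=dfs, ss=ss, r_squared=r2,
        pseudo_f=f_obs, p_value=p_vals, residual_df=resid_df,
        residual_ss=resid_ss, total_df=n - 1, total_ss=total_ss,
        n_permutations=n_used, method=method)


def _random_permutations(rng, n, n_perm, strata):
    if strata is None:
        return [rng.permutation(n) for _ in range(n_perm)]
    strata = np.asarray(pd.Series(strata).to_numpy())
    groups = [np.flatnonzero(strata == lv) for lv in pd.unique(strata)]
    perms = []
    for _ in range(n_perm):
        p = np.arange(n)
        for idx in groups:
            p[idx] = idx[rng.permutation(len(idx))]
        perms.append(p)
    return perms


def _distinct_relabelings(term_items, strata):
    """All sample orderings that produce distinct joint label vectors."""
    if strata is not None:
        raise ValueError("exact enumeration does not support strata")
    cols = np.column_stack([c for _, c in term_items])
    n = cols.shape[0]
    labels = [tuple(np.round(cols[i], 12)) for i in range(n)]
    seen = set()
    perms = []
    for p in iter_permutations(range(n)):
        key = tuple(labels[i] for i in p)
        if key in seen:
            continue
        seen.add(key)
        perms.append(np.asarray(p))
    return perms


@dataclass
class ThresholdScanResult:
    candidates: np.ndarray          # grams
    r_squared: np.ndarray
    p_values: np.ndarray
    best_threshold: float
    best_r_squared: float
    best_p: float
    tie: bool = False
    best_p_max_corrected: float | None = None
    n_permutations: int = 0

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_g": self.candidates,
                             "r_squared": self.r_squared,
                             "p_value": self.p_values})


def threshold_scan(d: DissimilarityMatrix, loading,
                   n_perm: int = 999, seed: int = 0,
                   max_statistic_correction: bool = False
                   ) -> ThresholdScanResult:
    """Scan binary loading splits for the one maximizing PERMANOVA R^2.

    Candidates are the observed loading values with at least two samples on
    each side. Ties on R^2 break toward the smaller threshold (flagged). The
    reported best p is the raw per-candidate permutation p; an optional
    max-statistic correction re-uses the same permutations to build the null
    distribution of the scan's maximum R^2.
    """
    loading = np.asarray(pd.Series(loading).to_numpy(), dtype=float)
    n = d.n
    if len(loading) != n:
        raise ValueError("loading length must match dissimilarity matrix")
    g = gower_matrix(d.values)
    total_ss = float(np.trace(g))
    uniq = np.unique(loading)
    cands = [t for t in uniq
             if (loading <= t).sum() >= 2 and (loading > t).sum() >= 2]
    if not cands:
        raise DesignError("no loading split leaves >= 2 samples per side")
    cands = np.asarray(cands, dtype=float)

    def split_ss(u_centered):
        return float(u_centered @ g @ u_centered) / float(
            u_centered @ u_centered)

    r2 = np.empty(len(cands))
    f_obs = np.empty(len(cands))
    ucs = []
    for i, t in enumerate(cands):
        u = (loading <= t).astype(float)
        uc = u - u.mean()
        ss_b = split_ss(uc)
        r2[i] = ss_b / total_ss
        f_obs[i] = ss_b / ((total_ss - ss_b) / (n - 2))
        ucs.append(uc)

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    p_vals = np.empty(len(cands))
    r2_perm_max = np.zeros(n_perm)
    for i, uc in enumerate(ucs):
        up = uc[perm_idx]                       # n_perm x n
        qf = np.einsum("ij,jk,ik->i", up, g, up) / float(uc @ uc)
        f_p = qf / ((total_ss - qf) / (n - 2))
        p_vals[i] = (np.sum(f_p >= f_obs[i] - 1e-12) + 1) / (n_perm + 1)
        np.maximum(r2_perm_max, qf / total_ss, out=r2_perm_max)

    best_r2 = r2.max()
    tied = np.flatnonzero(np.isclose(r2, best_r2, rtol=0, atol=1e-12))
    best_idx = int(tied.min())
    corrected = None
    if max_statistic_correction:
        corrected = float(
            (np.sum(r2_perm_max >= best_r2 - 1e-12) + 1) / (n_perm + 1))
    return ThresholdScanResult(
        candidates=cands, r_squared=r2, p_values=p_vals,
        best_threshold=float(cands[best_idx]),
        best_r_squared=float(r2[best_idx]),
        best_p=float(p_vals[best_idx]),
        tie=len(tied) > 1,
        best_p_max_corrected=corrected,
        n_permutations=n_perm)
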