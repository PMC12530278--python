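"""Alpha/beta diversity primitives and cross-microbiome similarity analysis.

Bray-Curtis is computed on rarefied counts (rarefy-then-dissimilarity), the
order the analysis pipeline assumes throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, ValidationError


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarities with sample ids."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity matrix must have zero diagonal")
        object.__setattr__(self, "values", 0.5 * (v + v.T))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def submatrix(self, ids) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return DissimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


def write_dissimilarity(d: DissimilarityMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_dissimilarity(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return DissimilarityMatrix(list(df.index), df.to_numpy())


def rarefy(table: CountTable, depth: int | None = None,
           seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    ``depth=None`` uses the minimum per-sample total.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    totals = table.totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    keep, rows = [], []
    dropped = []
    for sid, row in zip(table.sample_ids, table.counts):
        tot = int(row.sum())
        if tot < depth:
            dropped.append(sid)
            continue
        if tot == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        keep.append(sid)
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) below depth {depth}: "
            f"{dropped}")
    if not keep:
        raise ValueError("rarefy: no sample reaches the requested depth")
    return CountTable(pd.DataFrame(np.vstack(rows), index=keep,
                                   columns=table.taxon_ids))


def bray_curtis(table: CountTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = sum|x-y| / sum(x+y)."""
    x = table.counts.astype(float)
    zero = np.flatnonzero(x.sum(axis=1) == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(table.sample_ids, d)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (natural-log units)."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("shannon: sample has no reads")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: CountTable) -> pd.Series:
    return pd.Series([shannon(r) for r in table.counts],
                     index=table.sample_ids, name="shannon")


@dataclass
class PairwiseWilcoxonResult:
    p_values: pd.DataFrame          # symmetric group x group p matrix
    letters: dict[str, str]         # significance letter display
    alpha: float


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("pairwise_wilcoxon: constant pooled data; p = 1")
        return 1.0
    method = "exact" if (len(a) <= 10 and len(b) <= 10
                         and len(np.unique(pooled)) == len(pooled)) \
        else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _letter_display(groups: list[str], ns_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display: letters = maximal cliques of the
    not-significantly-different graph."""
    adj = {g: {g} for g in groups}
    for pair in ns_pairs:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)
    cliques: list[set] = []
    # groups are few; enumerate subsets largest-first
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            s = set(combo)
            if any(s <= c for c in cliques):
                continue
            if all(b in adj[a] for a, b in itertools.combinations(combo, 2)):
                cliques.append(s)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, c in enumerate(cliques):
        for g in groups:
            if g in c:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def pairwise_wilcoxon(groups: dict[str, np.ndarray],
                      alpha: float = 0.01,
                      holm: bool = False) -> PairwiseWilcoxonResult:
    """All-pairs rank-sum tests plus a significance letter display.

    Exact enumeration when both group sizes are <= 10 (and no ties);
    tie-corrected normal approximation otherwise. No multiplicity correction
    by default; ``holm=True`` applies Holm step-down before lettering.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("pairwise_wilcoxon needs >= 2 groups")
    for g, v in groups.items():
        if len(np.asarray(v)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                        columns=names)
    pairs = list(itertools.combinations(names, 2))
    raw = [_mann_whitney(np.asarray(groups[a], float),
                         np.asarray(groups[b], float)) for a, b in pairs]
    if holm and raw:
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx]))
            adj[idx] = running
        raw = list(adj)
    ns = set()
    for (a, b), p in zip(pairs, raw):
        pmat.loc[a, b] = pmat.loc[b, a] = p
        if p >= alpha:
            ns.add(frozenset((a, b)))
    return PairwiseWilcoxonResult(pmat, _letter_display(names, ns), alpha)


@dataclass
class SimilarityFit:
    pairs: pd.DataFrame          # loading_g, similarity, source_pair, ...
    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    smooth_edf: float
    smooth_f: float
    smooth_p: float
    smooth_preferred: bool
    model: str = "linear"


def build_similarity_pairs(table_a: CountTable, table_b: CountTable,
                           meta: pd.DataFrame,
                           within_treatment_only: bool = False
                           ) -> pd.DataFrame:
    """1 - Bray-Curtis between samples of two sources at identical loading."""
    rows = []
    meta_a = meta.loc[table_a.sample_ids]
    meta_b = meta.loc[table_b.sample_ids]
    xa = table_a.counts.astype(float)
    xb = table_b.data[table_a.taxon_ids].to_numpy().astype(float)
    for i, sa in enumerate(table_a.sample_ids):
        for j, sb in enumerate(table_b.sample_ids):
            if sa == sb:
                continue
            la, lb = meta_a["loading_g"].iloc[i], meta_b["loading_g"].iloc[j]
            if la != lb:
                continue
            ta, tb = meta_a["treatment"].iloc[i], meta_b["treatment"].iloc[j]
            if within_treatment_only and ta != tb:
                continue
            num = np.abs(xa[i] - xb[j]).sum()
            den = (xa[i] + xb[j]).sum()
            bc = num / den if den > 0 else 0.0
            rows.append((float(la),
                         f"{meta_a['source'].iloc[i]}-{meta_b['source'].iloc[j]}",
                         1.0 - bc, f"{ta}-{tb}", sa, sb))
    return pd.DataFrame(rows, columns=["loading_g", "source_pair",
                                       "similarity", "treatment_pair",
                                       "sample_a", "sample_b"])


def _gcv_spline(x: np.ndarray, y: np.ndarray):
    """Penalized B-spline smoother, penalty weight chosen by GCV."""
    from statsmodels.gam.api import BSplines, GLMGam
    df = int(min(8, max(4, np.unique(x).size - 1)))
    bs = BSplines(x[:, None], df=[df], degree=[3], include_intercept=False)
    exog = np.ones((len(x), 1))
    model = GLMGam(y, exog=exog, smoother=bs, alpha=1.0)
    model.fit()  # primes model.scale for select_penweight
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = model.select_penweight(criterion="gcv")[0]
        res = GLMGam(y, exog=exog, smoother=bs, alpha=alpha).fit()
    rss = float(np.sum((y - res.fittedvalues) ** 2))
    edf = float(np.sum(res.edf))
    return rss, edf, res


def similarity_vs_loading(table_a: CountTable, table_b: CountTable,
                          meta: pd.DataFrame,
                          within_treatment_only: bool = False,
                          alpha: float = 0.05) -> SimilarityFit:
    """Fit similarity ~ loading by OLS and by a GCV-penalized cubic spline,
    and test whether the smooth term improves on the straight line."""
    pairs = build_similarity_pairs(table_a, table_b, meta,
                                   within_treatment_only)
    levels = pairs["loading_g"].nunique()
    if levels < 3:
        raise ValueError(
            f"similarity_vs_loading needs >= 3 shared loading levels, "
            f"got {levels}")
    x = pairs["loading_g"].to_numpy(float)
    y = pairs["similarity"].to_numpy(float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss_lin = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss_lin / tss if tss > 0 else 0.0
    se = np.sqrt(rss_lin / (n - 2)
                 * np.linalg.inv(X.T @ X)[1, 1]) if n > 2 else np.inf
    slope_p = float(2 * stats.t.sf(abs(beta[1] / se), n - 2)) if se > 0 else 1.0

    rss_sm, edf, _ = _gcv_spline(x, y)
    df1 = max(edf - 2.0, 1e-8)
    df2 = max(n - edf, 1.0)
    if rss_sm < rss_lin and edf > 2.0 + 1e-6:
        f = ((rss_lin - rss_sm) / df1) / (rss_sm / df2)
        p_sm = float(stats.f.sf(f, df1, df2))
    else:
        f, p_sm = 0.0, 1.0
    preferred = p_sm < alpha
    return SimilarityFit(pairs, float(beta[1]), float(beta[0]), r2, slope_p,
                         edf, float(f), p_sm, preferred,
                         model="smooth" if preferred else "linear")
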