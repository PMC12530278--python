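"""Community-weighted genome traits and loading-differential pathways.

Traits are per-taxon predicted genome characteristics (genome size in bp,
coding-sequence count, growth rate = ln 2 / doubling time, relative genomic
plasticity). The community-weighted mean (CWM) renormalizes relative
abundances over trait-complete taxa. Pathway differential abundance fits
log2(size-factor-normalized abundance + pseudocount) against loading scaled
to unit SD, so a slope ("log2 fold change") of +2 means a pathway is 4x more
abundant one SD above the mean loading than at the mean; inference is a
permutation test on the slope, and the headline filter keeps pathways with
p < 0.01, |log2FC| > 2 and at least five member taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable, ValidationError

TRAIT_COLUMNS = ("genome_size_bp", "n_coding_sequences", "growth_rate_per_h",
                 "plasticity")


def growth_rate_from_doubling_time(doubling_time_h) -> np.ndarray:
    """Exponential growth rate r = ln 2 / doubling time (per hour)."""
    dt = np.asarray(doubling_time_h, float)
    if np.any(dt <= 0):
        raise ValueError("doubling times must be > 0")
    return np.log(2.0) / dt


def relative_genomic_plasticity(d_gene: pd.DataFrame,
                                d_proteome: pd.DataFrame,
                                signed: bool = True,
                                flip_sign: bool = False) -> pd.Series:
    """Per-taxon mean difference between marker-gene and proteome
    dissimilarity to all other taxa.

    plasticity(i) = mean_{j != i} (d_gene(i,j) - d_proteome(i,j)).

    The literal definition is mean(gene - proteome); ``flip_sign`` gives the
    opposite convention (proteome divergence beyond phylogenetic expectation
    positive), and ``signed=False`` returns absolute differences. Either way,
    larger magnitude means functional divergence decoupled from the marker
    gene phylogeny.
    """
    if list(d_gene.index) != list(d_proteome.index) or \
            list(d_gene.columns) != list(d_proteome.columns):
        raise ValidationError("gene and proteome matrices index mismatch")
    g = d_gene.to_numpy(float)
    p = d_proteome.to_numpy(float)
    n = g.shape[0]
    if n < 2 or g.shape != (n, n):
        raise ValidationError("need square matrices over >= 2 taxa")
    for name, m in (("gene", g), ("proteome", p)):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError(f"{name} dissimilarity must be symmetric")
    diff = g - p
    np.fill_diagonal(diff, 0.0)
    vals = diff.sum(axis=1) / (n - 1)
    if not signed:
        adiff = np.abs(g - p)
        np.fill_diagonal(adiff, 0.0)
        vals = adiff.sum(axis=1) / (n - 1)
    if flip_sign:
        vals = -vals
    return pd.Series(vals, index=d_gene.index, name="plasticity")


@dataclass
class CommunityWeightedTraits:
    values: pd.DataFrame       # sample x trait CWMs (NaN where no coverage)
    coverage: pd.DataFrame     # fraction of reads on trait-complete taxa


def community_weighted_traits(table: CountTable, traits: pd.DataFrame
                              ) -> CommunityWeightedTraits:
    """Relative-abundance-weighted trait means per sample.

    For each trait, weights are renormalized over the taxa with a non-missing
    value; the retained read fraction is reported as coverage. A sample with
    no trait-complete taxon gets NaN with a warning.
    """
    shared = [t for t in table.taxon_ids if t in traits.index]
    if not shared:
        raise ValidationError("no taxa shared between counts and traits")
    counts = table.data[shared].to_numpy(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    tr = traits.loc[shared]
    cols = [c for c in tr.columns if np.issubdtype(tr[c].dtype, np.number)]
    out, cov = {}, {}
    for c in cols:
        v = tr[c].to_numpy(float)
        ok = np.isfinite(v)
        w = rel[:, ok]
        wsum = w.sum(axis=1)
        cwm = np.full(len(table.sample_ids), np.nan)
        nz = wsum > 0
        cwm[nz] = (w[nz] @ v[ok]) / wsum[nz]
        if np.any(~nz):
            bad = [table.sample_ids[i] for i in np.flatnonzero(~nz)]
            warnings.warn(f"CWM of {c!r} undefined for sample(s) {bad}")
        out[c] = cwm
        cov[c] = wsum
    idx = pd.Index(table.sample_ids, name="sample_id")
    return CommunityWeightedTraits(pd.DataFrame(out, index=idx),
                                   pd.DataFrame(cov, index=idx))


def pathway_abundance(table: CountTable, incidence: pd.DataFrame
                      ) -> pd.DataFrame:
    """Pathway x sample abundance: summed counts of member taxa.

    ``incidence`` is pathway x taxon binary membership. Pathways with no
    member among the counted taxa are excluded with a warning.
    """
    inc = incidence.reindex(columns=table.taxon_ids, fill_value=0)
    m = (inc.to_numpy(float) > 0).astype(float)
    empty = np.flatnonzero(m.sum(axis=1) == 0)
    if empty.size:
        warnings.warn(
            f"pathway_abundance: excluding memberless pathway(s) "
            f"{[incidence.index[i] for i in empty]}")
    ab = m @ table.counts.T.astype(float)
    out = pd.DataFrame(ab, index=incidence.index, columns=table.sample_ids)
    return out.drop(index=[incidence.index[i] for i in empty])


def median_of_ratios_size_factors(abundance: pd.DataFrame) -> pd.Series:
    """Per-sample size factors from the median-of-ratios normalization."""
    a = abundance.to_numpy(float)
    with np.errstate(divide="ignore"):
        loga = np.log(a)
    ref = loga.mean(axis=1)                      # geometric mean per pathway
    usable = np.isfinite(ref)
    if not usable.any():
        # fall back to library-size scaling when every pathway hits a zero
        tot = a.sum(axis=0)
        return pd.Series(tot / np.exp(np.mean(np.log(tot))),
                         index=abundance.columns, name="size_factor")
    logratios = loga[usable] - ref[usable, None]
    sf = np.exp(np.median(logratios, axis=0))
    return pd.Series(sf, index=abundance.columns, name="size_factor")


@dataclass
class PathwayFilters:
    p_threshold: float = 0.01
    min_abs_log2fc: float = 2.0
    min_taxa: int = 5


@dataclass
class DifferentialPathwayResult:
    table: pd.DataFrame        # pathway, log2_fold_change, p_value, n_member_taxa, passes_filters
    filters: PathwayFilters
    n_permutations: int

    def significant(self) -> list:
        t = self.table
        return list(t.index[t["passes_filters"]])


def differential_pathways(abundance: pd.DataFrame, loading,
                          n_member_taxa: pd.Series,
                          n_perm: int = 999, seed: int = 0,
                          filters: PathwayFilters | None = None,
                          pseudocount: float = 1.0
                          ) -> DifferentialPathwayResult:
    """Loading-differential pathway abundance with the three-clause filter.

    The response is log2(normalized abundance + pseudocount); the predictor
    is loading centered and scaled to unit SD, so the slope is the log2 fold
    change per SD of loading. p-values come from permutation of the loading
    labels. Constant pathway rows are skipped (flagged NaN).
    """
    filters = filters or PathwayFilters()
    loading = np.asarray(pd.Series(loading).to_numpy(), float)
    n = abundance.shape[1]
    if len(loading) != n:
        raise ValueError("loading length must match abundance columns")
    if n < 6:
        raise ValueError("differential_pathways needs >= 6 samples")
    if np.unique(loading).size < 2:
        raise ValueError("loading must take more than one value")
    sf = median_of_ratios_size_factors(abundance)
    norm = abundance.to_numpy(float) / sf.to_numpy()[None, :]
    y = np.log2(norm + pseudocount)              # pathways x samples
    x = (loading - loading.mean()) / loading.std(ddof=0)
    xx = float(x @ x)
    slopes = (y @ x) / xx
    const = y.std(axis=1) == 0

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    xp = x[perms]                                # n_perm x n
    slopes_perm = (y @ xp.T) / xx                # pathways x n_perm
    exceed = (np.abs(slopes_perm) >= np.abs(slopes)[:, None] - 1e-12).sum(axis=1)
    p = (exceed + 1) / (n_perm + 1)

    taxa = n_member_taxa.reindex(abundance.index)
    tab = pd.DataFrame({
        "log2_fold_change": slopes,
        "p_value": p,
        "n_member_taxa": taxa.to_numpy(),
    }, index=abundance.index)
    tab.loc[const, ["log2_fold_change", "p_value"]] = np.nan
    tab["skipped_constant"] = const
    tab["passes_filters"] = (
        (tab["p_value"] < filters.p_threshold)
        & (tab["log2_fold_change"].abs() > filters.min_abs_log2fc)
        & (tab["n_member_taxa"] >= filters.min_taxa)
    ).fillna(False)
    return DifferentialPathwayResult(tab, filters, n_perm)


def categorize_by_day(early: set | list, late: set | list) -> pd.DataFrame:
    """Partition significant pathway sets into only-early / only-late / both."""
    a, b = set(early), set(late)
    rows = [(p, "both" if p in a and p in b
             else "only_early" if p in a else "only_late")
            for p in sorted(a | b)]
    return pd.DataFrame(rows, columns=["pathway_id", "category"]
                        ).set_index("pathway_id")
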