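"""Diversity primitives: rarefaction, Bray-Curtis, Shannon, Wilcoxon,
similarity-vs-loading."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mesothresh import (CountTable, SyntheticExperimentConfig, bray_curtis,
                        generate_experiment, pairwise_wilcoxon, rarefy,
                        shannon, similarity_vs_loading)
from mesothresh.diversity import build_similarity_pairs
from mesothresh.tables import ValidationError

from conftest import random_count_table


def table_of(rows, samples=None, taxa=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestBrayCurtis:
    @pytest.mark.parametrize("a,b,expected", [
        ((2, 2, 0), (2, 2, 0), 0.0),        # identical
        ((3, 0, 0), (0, 0, 7), 1.0),        # disjoint supports
        ((2, 2, 0), (0, 2, 2), 0.5),        # 4/8 by hand
    ])
    def test_hand_cases(self, a, b, expected):
        d = bray_curtis(table_of([a, b]))
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_common_pair_scaling(self):
        d1 = bray_curtis(table_of([(2, 2, 0), (0, 2, 2)])).values[0, 1]
        d2 = bray_curtis(table_of([(20, 20, 0), (0, 20, 20)])).values[0, 1]
        assert d1 == pytest.approx(d2)

    def test_metric_identity_and_symmetry(self, rng):
        table = random_count_table(rng)
        d = bray_curtis(table)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)
        assert d.values.min() >= 0 and d.values.max() <= 1

    def test_all_zero_sample_rejected_by_container(self):
        with pytest.raises(ValidationError, match="no positive counts"):
            table_of([(0, 0), (1, 1)])


class TestShannon:
    def test_uniform_equals_log_richness(self):
        assert shannon([5] * 10) == pytest.approx(np.log(10))

    def test_single_taxon_zero(self):
        assert shannon([0, 9, 0]) == 0.0

    def test_hand_case(self):
        assert shannon([1, 2, 3]) == pytest.approx(1.0114, abs=5e-5)

    def test_bounded_by_log_richness(self, rng):
        for _ in range(20):
            c = rng.integers(1, 30, size=rng.integers(2, 10))
            h = shannon(c)
            assert 0 <= h <= np.log(len(c)) + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestRarefy:
    def test_row_sums_equal_depth_and_bounded_by_input(self, rng):
        table = random_count_table(rng, n_samples=5, n_taxa=10, max_count=80)
        out = rarefy(table, depth=30, seed=1)
        assert (out.totals() == 30).all()
        assert (out.data.to_numpy()
                <= table.data.loc[out.sample_ids].to_numpy()).all()

    def test_sample_at_exact_depth_unchanged(self):
        table = table_of([np.array([5000, 258])])
        out = rarefy(table, depth=5258, seed=0)
        assert out.data.iloc[0].tolist() == [5000, 258]

    def test_single_taxon_sample(self):
        out = rarefy(table_of([(10, 0, 0)]), depth=5, seed=0)
        assert out.data.iloc[0].tolist() == [5, 0, 0]

    def test_shallow_samples_dropped_with_warning(self):
        table = table_of([(100, 100), (3, 2)])
        with pytest.warns(UserWarning, match="s1"):
            out = rarefy(table, depth=50, seed=0)
        assert out.sample_ids == ["s0"]

    def test_hypergeometric_mean(self):
        # (60, 40) rarefied to 50: first-taxon count ~ Hypergeom(100, 60, 50)
        rng = np.random.default_rng(0)
        draws = np.array([rng.multivariate_hypergeometric([60, 40], 50)[0]
                          for _ in range(10_000)])
        var = 50 * 0.6 * 0.4 * (100 - 50) / 99
        se_mean = np.sqrt(var / 10_000)
        assert abs(draws.mean() - 30.0) < 3 * se_mean

    def test_invalid_depth(self, small_table):
        with pytest.raises(ValueError):
            rarefy(small_table, depth=0)


class TestPairwiseWilcoxon:
    def test_identical_groups_p_one(self):
        res = pairwise_wilcoxon({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.p_values.loc["a", "b"] == pytest.approx(1.0)

    def test_exact_small_sample(self):
        res = pairwise_wilcoxon({"a": [1, 2, 3], "b": [10, 11, 12]})
        assert res.p_values.loc["a", "b"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 7), rng.integers(3, 7)
        pool = rng.permutation(40)[:na + nb].astype(float)  # unique values
        a, b = pool[:na], pool[na:]
        res = pairwise_wilcoxon({"a": a, "b": b})
        # oracle: enumerate all assignments of the pooled values to group a
        u_obs = sum((x > y) for x in a for y in b)
        n_extreme = 0
        total = 0
        for combo in itertools.combinations(range(na + nb), na):
            aa = pool[list(combo)]
            bb = pool[[i for i in range(na + nb) if i not in combo]]
            u = sum((x > y) for x in aa for y in bb)
            total += 1
            if abs(u - na * nb / 2) >= abs(u_obs - na * nb / 2):
                n_extreme += 1
        assert res.p_values.loc["a", "b"] == pytest.approx(
            n_extreme / total, abs=1e-12)

    def test_constant_pooled_data_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            res = pairwise_wilcoxon({"a": [2, 2], "b": [2, 2]})
        assert res.p_values.loc["a", "b"] == 1.0

    def test_all_nonsignificant_share_a_letter(self, rng):
        groups = {k: rng.normal(0, 1, 8) for k in ("g1", "g2", "g3")}
        res = pairwise_wilcoxon(groups, alpha=0.01)
        assert res.letters["g1"] == res.letters["g2"] == res.letters["g3"]

    def test_separated_groups_get_distinct_letters(self):
        res = pairwise_wilcoxon({
            "lo": np.arange(8, dtype=float),
            "hi": np.arange(100, 108, dtype=float)}, alpha=0.01)
        assert set(res.letters["lo"]).isdisjoint(res.letters["hi"])


def _two_source_experiment(slope=0.0, seed=0):
    cfg = SyntheticExperimentConfig(
        n_taxa=60, depth_mean=4000.0, days=(10,), rng_seed=seed,
        include_hosts=True,
        host_water_affinity={"daphnia": 0.5},
        host_affinity_loading_slope=slope)
    return generate_experiment(cfg)


class TestSimilarityVsLoading:
    def test_pairs_only_at_identical_loading(self):
        exp = _two_source_experiment()
        meta = exp.metadata
        water_ids = meta.index[meta["source"] == "water"]
        daph_ids = meta.index[meta["source"] == "daphnia"]
        table = exp.counts_by_day[10]
        pairs = build_similarity_pairs(table.select_samples(water_ids),
                                       table.select_samples(daph_ids), meta)
        assert len(pairs) > 0
        for _, row in pairs.iterrows():
            la = meta.loc[row["sample_a"], "loading_g"]
            lb = meta.loc[row["sample_b"], "loading_g"]
            assert la == lb == row["loading_g"]
        assert pairs["similarity"].between(0, 1).all()

    def test_affinity_slope_sign_recovered(self):
        # mixing weight toward water increases with loading -> similarity
        # between daphnia and water microbiomes rises with loading
        exp = _two_source_experiment(slope=0.002, seed=1)
        meta = exp.metadata
        table = exp.counts_by_day[10]
        water = table.select_samples(meta.index[meta["source"] == "water"])
        daph = table.select_samples(meta.index[meta["source"] == "daphnia"])
        fit = similarity_vs_loading(water, daph, meta)
        assert fit.slope > 0
        assert fit.slope_p < 0.05

    def test_constant_similarity_prefers_line(self, rng):
        # two identical-composition sources: similarity flat in loading
        exp = _two_source_experiment(slope=0.0, seed=2)
        meta = exp.metadata
        table = exp.counts_by_day[10]
        water = table.select_samples(meta.index[meta["source"] == "water"])
        daph = table.select_samples(meta.index[meta["source"] == "daphnia"])
        fit = similarity_vs_loading(water, daph, meta)
        assert not fit.smooth_preferred or fit.smooth_p >= 0.01

    def test_too_few_shared_levels(self):
        exp = _two_source_experiment()
        meta = exp.metadata.copy()
        table = exp.counts_by_day[10]
        water = table.select_samples(meta.index[meta["source"] == "water"])
        daph = table.select_samples(meta.index[meta["source"] == "daphnia"])
        meta["loading_g"] = 100.0  # collapse to one level
        with pytest.raises(ValueError, match="loading levels"):
            similarity_vs_loading(water, daph, meta)


# property-based invariants over arbitrary small count tables
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=40, deadline=None, derandomize=True)
@given(counts=arrays(np.int64, (5, 7), elements=st.integers(0, 200)))
def test_braycurtis_rarefy_shannon_invariants(counts):
    counts = counts.copy()
    counts[:, 0] += 1  # every sample keeps at least one read
    table = CountTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(5)],
        columns=[f"t{j}" for j in range(7)]))
    d = bray_curtis(table)
    assert np.all(d.values >= 0) and np.all(d.values <= 1)
    assert np.allclose(d.values, d.values.T)
    depth = int(table.totals().min())
    out = rarefy(table, depth=depth, seed=0)
    assert (out.totals() == depth).all()
    assert (out.data.to_numpy() <= table.data.loc[out.sample_ids]
            .to_numpy()).all()
    for row in table.counts:
        h = shannon(row)
        assert 0.0 <= h <= np.log(np.count_nonzero(row)) + 1e-9
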