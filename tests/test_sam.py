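"""SAM statistics, fudge factor, permutation FDR, hierarchy driver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fibrosig.sam import (ComparisonSpec, DEError, fold_change,
                          fold_change_multiclass, hierarchy_counts,
                          permutation_fdr, run_comparison,
                          sam_statistic_multiclass, sam_statistic_two_class,
                          select_s0)
from fibrosig.simulate import SimulationConfig, generate_expression
from .conftest import make_dataset


def two_groups(n1=6, n2=6):
    return np.array(["A"] * n1 + ["B"] * n2)


class TestTwoClassStatistic:
    def test_hand_computed_example(self):
        """{1,2,3} vs {4,5,6}: d = 3 / sqrt(2/3) with s0 = 0."""
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        d = sam_statistic_two_class(values, two_groups(3, 3), s0=0.0)
        assert d[0] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-12)

    def test_equal_means_give_zero(self):
        values = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        d = sam_statistic_two_class(values, two_groups(3, 3), s0=0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_equals_pooled_t_on_random_matrices(self):
        """d at s0=0 is the classical pooled-variance t (200 genes)."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=(200, 12))
        groups = two_groups(6, 6)
        d = sam_statistic_two_class(values, groups, s0=0.0)
        t, _ = stats.ttest_ind(values[:, 6:].T, values[:, :6].T)
        np.testing.assert_allclose(d, t, atol=1e-10)

    def test_large_s0_shrinks_towards_zero(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(50, 10))
        groups = two_groups(5, 5)
        d = sam_statistic_two_class(values, groups, s0=1e9)
        assert np.abs(d).max() < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(DEError):
            sam_statistic_two_class(np.ones((3, 3)),
                                    np.array(["A", "A", "B"]), 0.0)


class TestMulticlassStatistic:
    def three_groups(self):
        return np.array(["A"] * 5 + ["B"] * 5 + ["C"] * 5)

    def test_equal_group_means_give_zero(self):
        block = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        values = np.concatenate([block, block, block])[None, :]
        d = sam_statistic_multiclass(values, self.three_groups(), s0=0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_rank_identical_to_one_way_f(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(100, 15))
        groups = self.three_groups()
        d = sam_statistic_multiclass(values, groups, s0=0.0)
        f = np.array([
            stats.f_oneway(row[:5], row[5:10], row[10:]).statistic
            for row in values
        ])
        # d^2 = (K-1) F exactly, hence identical ranking
        np.testing.assert_allclose(d**2, 2 * f, rtol=1e-9)
        assert (np.argsort(d) == np.argsort(f)).all()

    def test_k2_reduces_to_absolute_two_class(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(60, 11))
        groups = np.array(["A"] * 5 + ["B"] * 6)
        d2 = sam_statistic_two_class(values, groups, s0=0.0)
        from fibrosig.sam import (_contrast_parts, _safe_ratio,
                                  _multiclass_parts, _group_indicator)
        r, s = _contrast_parts(values, groups, ["A", "B"])
        # route the same data through the multiclass formula with K=2
        rm, sm = _multiclass_parts(values, _group_indicator(groups, ["A", "B"]))
        np.testing.assert_allclose(rm, np.abs(r), atol=1e-10)
        np.testing.assert_allclose(sm, s, atol=1e-10)
        np.testing.assert_allclose(_safe_ratio(rm, sm), np.abs(d2), atol=1e-10)

    def test_planted_shift_ranks_first(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(80, 15))
        values[17, 10:] += 25.0
        d = sam_statistic_multiclass(values, self.three_groups(), s0=0.0)
        assert np.argmax(d) == 17


class TestSelectS0:
    def test_all_s_equal_returns_common_value(self):
        # identical within-group spread, gene-specific group difference
        within = np.array([0.0, 1.0, 2.0])
        deltas = np.linspace(-2, 2, 20)
        values = np.array([np.concatenate([within, within + d])
                           for d in deltas])
        s0 = select_s0(values, two_groups(3, 3))
        from fibrosig.sam import _contrast_parts
        _, s = _contrast_parts(values, two_groups(3, 3), ["A", "B"])
        assert s0 == pytest.approx(s[0])

    def test_reduces_dispersion_cv_versus_zero(self):
        """On variance-heterogeneous data the chosen s0 stabilizes d."""
        rng = np.random.default_rng(10)
        sds = rng.uniform(0.05, 3.0, 500)
        values = rng.normal(0, 1, (500, 12)) * sds[:, None]
        groups = two_groups(6, 6)
        s0 = select_s0(values, groups)
        assert s0 > 0

        def window_cv(s0_val):
            from fibrosig.sam import _contrast_parts, _safe_ratio
            r, s = _contrast_parts(values, groups, ["A", "B"])
            d = _safe_ratio(r, s + s0_val)
            edges = np.quantile(s, np.linspace(0, 1, 26))
            win = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 24)
            spread = np.array([
                np.median(np.abs(d[win == w] - np.median(d[win == w]))) / 0.64
                for w in range(25) if (win == w).any()
            ])
            return spread.std() / spread.mean()

        assert window_cv(s0) <= window_cv(0.0) + 1e-9

    def test_fixed_s0_bypasses_selection(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(30, 10))
        groups = two_groups(5, 5)
        d_fixed = sam_statistic_two_class(values, groups, s0=0.25)
        from fibrosig.sam import _contrast_parts, _safe_ratio
        r, s = _contrast_parts(values, groups, ["A", "B"])
        np.testing.assert_allclose(d_fixed, _safe_ratio(r, s + 0.25))

    def test_constant_matrix_gives_zero(self):
        s0 = select_s0(np.full((10, 8), 3.0), two_groups(4, 4))
        assert s0 == 0.0


class TestFoldChange:
    @pytest.mark.parametrize("delta, expected", [(0.0, 1.0), (1.0, 2.0),
                                                 (-2.0, 0.25)])
    def test_log2_semantics(self, delta, expected):
        values = np.array([[0.0, 0.0, delta, delta]])
        fc = fold_change(values, two_groups(2, 2))
        assert fc[0] == pytest.approx(expected)

    def test_multiclass_is_max_pairwise(self):
        values = np.array([[0.0, 0.0, 1.0, 1.0, 3.0, 3.0]])
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        fc = fold_change_multiclass(values, groups)
        assert fc[0] == pytest.approx(2.0 ** 3)


class TestPermutationFdr:
    def test_planted_gene_has_smallest_q(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(300, 12))
        values[42, 6:] += 10.0
        groups = two_groups(6, 6)
        d = sam_statistic_two_class(values, groups, s0=0.0)
        q, _ = permutation_fdr(values, groups, d, n_perm=200, seed=0)
        assert q[42] == q.min()
        assert q[42] < 0.01

    def test_null_q_rarely_below_threshold(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=(1000, 12))
        groups = two_groups(6, 6)
        d = sam_statistic_two_class(values, groups, s0=0.0)
        q, info = permutation_fdr(values, groups, d, n_perm=200, seed=1)
        assert (q <= 0.05).mean() <= 0.05 * info["pi0"] + 0.01
        assert ((q >= 0) & (q <= 1)).all()

    def test_q_monotone_in_absolute_d(self):
        rng = np.random.default_rng(14)
        values = rng.normal(size=(200, 10))
        values[:20, 5:] += rng.uniform(1, 5, (20, 5))
        groups = two_groups(5, 5)
        d = sam_statistic_two_class(values, groups, s0=0.0)
        q, _ = permutation_fdr(values, groups, d, n_perm=150, seed=2)
        order = np.argsort(-np.abs(d))
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_invariant_under_gene_permutation(self):
        rng = np.random.default_rng(15)
        values = rng.normal(size=(150, 10))
        groups = two_groups(5, 5)
        d = sam_statistic_two_class(values, groups, s0=0.0)
        q, _ = permutation_fdr(values, groups, d, n_perm=150, seed=3)
        perm = rng.permutation(150)
        q_p, _ = permutation_fdr(values[perm], groups, d[perm],
                                 n_perm=150, seed=3)
        np.testing.assert_allclose(q_p, q[perm])

    def test_identity_labels_reproduce_observed_statistic(self):
        """The permutation code path on unpermuted labels equals d_obs."""
        from fibrosig.sam import _contrast_parts, _safe_ratio, _permuted_labels
        rng = np.random.default_rng(16)
        values = rng.normal(size=(40, 8))
        groups = two_groups(4, 4)
        d_obs = sam_statistic_two_class(values, groups, s0=0.0)
        identity = next(
            p for p in _permuted_labels(groups, 100, seed=0, strata=None)
            if (np.asarray(p) == groups).all()
        )
        r, s = _contrast_parts(values, np.asarray(identity), ["A", "B"])
        np.testing.assert_allclose(_safe_ratio(r, s), d_obs, atol=1e-12)

    def test_doubling_permutations_is_stable_on_null(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(500, 16))
        groups = two_groups(8, 8)
        d = sam_statistic_two_class(values, groups, s0=0.0)
        q1, _ = permutation_fdr(values, groups, d, n_perm=500, seed=4)
        q2, _ = permutation_fdr(values, groups, d, n_perm=1000, seed=4)
        assert np.abs(q1 - q2).mean() < 0.02

    def test_strata_respected(self):
        """Within-stratum shuffles keep the stratum composition intact."""
        from fibrosig.sam import _permuted_labels
        groups = np.array(["A", "A", "B", "B", "A", "B", "B", "B"])
        strata = np.array(["x", "x", "x", "x", "y", "y", "y", "y"])
        for perm in _permuted_labels(groups, 200, seed=5, strata=strata):
            assert sorted(perm[:4]) == ["A", "A", "B", "B"]
            assert sorted(perm[4:]) == ["A", "B", "B", "B"]


class TestComparisonDriver:
    def test_called_flag_consistent(self, small_data):
        dataset, _ = small_data
        spec = ComparisonSpec("serum", ("low", "high"))
        res = run_comparison(dataset, spec, n_perm=150, seed=6)
        t = res.table
        expected = (t["q_value"] <= 0.05) & (
            (t["fold_change"] >= 2) | (t["fold_change"] <= 0.5))
        assert (t["called"] == expected).all()

    def test_sample_relabeling_within_group_irrelevant(self, small_data):
        dataset, _ = small_data
        spec = ComparisonSpec("serum", ("low", "high"))
        res = run_comparison(dataset, spec, n_perm=150, seed=7)
        shuffled = dataset.annotation.copy()
        # swap two same-serum samples' order
        cols = list(dataset.values.columns)
        low = [c for c in cols if shuffled.loc[c, "serum"] == "low"]
        i, j = cols.index(low[0]), cols.index(low[1])
        cols[i], cols[j] = cols[j], cols[i]
        permuted = dataset.subset_samples(cols)
        res2 = run_comparison(permuted, spec, n_perm=150, seed=7)
        assert res.called_genes == res2.called_genes

    def test_hierarchy_ordering_on_small_generator(self, small_data):
        dataset, truth = small_data
        hc = hierarchy_counts(dataset, n_perm=150, seed=8)
        assert hc.top_level["site"] > hc.top_level["serum"] > hc.top_level["disease"]
        assert hc.disease_within.loc["synovium", "low"] >= \
            10 * max(hc.disease_within.loc["synovium", "high"], 1)

    def test_null_generator_counts_near_zero(self):
        config = SimulationConfig(
            n_genes=400, n_ra_patients=4, n_oa_patients=4,
            n_site_genes=90, n_serum_genes=40, n_disease_genes=20,
            n_oa_synovium_genes=15,
            effect_size_site=0, effect_size_serum=0, effect_size_disease=0,
            effect_size_oa_synovium=0, seed=23,
        )
        dataset, _ = generate_expression(config)
        hc = hierarchy_counts(dataset, n_perm=150, seed=9)
        assert all(v <= 400 * 0.05 for v in hc.top_level.values())

    def test_insufficient_cell_marked_unavailable(self):
        rng = np.random.default_rng(18)
        # one OA sample only in synovium/low: the RA-vs-OA cell is unavailable
        annot = {
            "tissue": ["synovium"] * 6,
            "serum": ["low"] * 6,
            "disease": ["RA", "RA", "RA", "RA", "RA", "OA"],
            "patient": [f"p{i}" for i in range(6)],
        }
        data = make_dataset(rng.normal(size=(50, 6)), annot=annot)
        hc = hierarchy_counts(data, n_perm=150, seed=10)
        assert np.isnan(hc.disease_within.loc["synovium", "low"])


@given(st.integers(0, 50))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_two_class_t_equivalence_property(seed):
    """d(s0=0) == pooled t for arbitrary random matrices and sizes."""
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 7, 2)
    values = rng.normal(size=(20, n1 + n2))
    groups = np.array(["A"] * n1 + ["B"] * n2)
    d = sam_statistic_two_class(values, groups, s0=0.0)
    t, _ = stats.ttest_ind(values[:, n1:].T, values[:, :n1].T)
    np.testing.assert_allclose(d, t, atol=1e-10)
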