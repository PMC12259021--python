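import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stagehet as sh
from stagehet.heterogeneity import StageNMIResult
from conftest import make_adata


# -- independent brute-force oracle (joint count table, direct formula) ------

def mi_brute(x, y):
    n = len(x)
    cj, cx, cy = Counter(zip(x, y)), Counter(x), Counter(y)
    return sum(
        (c / n) * math.log((c / n) / ((cx[a] / n) * (cy[b] / n)))
        for (a, b), c in cj.items()
    )


def entropy_brute(x):
    n = len(x)
    return -sum((c / n) * math.log(c / n) for c in Counter(x).values())


def nmi_brute(x, y):
    hx, hy = entropy_brute(x), entropy_brute(y)
    if hx == 0 or hy == 0:
        return 0.0
    return mi_brute(x, y) / math.sqrt(hx * hy)


profiles = st.integers(2, 50).flatmap(
    lambda L: st.tuples(
        st.lists(st.integers(0, 9), min_size=L, max_size=L),
        st.lists(st.integers(0, 9), min_size=L, max_size=L),
    )
)


class TestMutualInformation:
    def test_identical_two_level_profile_gives_ln2(self):
        x = [0, 0, 1, 1]
        assert sh.mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-15)

    def test_independent_pair_gives_zero(self):
        assert sh.mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-15)

    def test_three_bin_case_matches_bruteforce(self):
        x, y = [0, 0, 1, 2], [0, 1, 1, 2]
        assert sh.mutual_information(x, y) == pytest.approx(mi_brute(x, y), abs=1e-12)
        assert sh.nmi(x, y) == pytest.approx(
            mi_brute(x, y) / math.sqrt(entropy_brute(x) * entropy_brute(y)), abs=1e-12
        )

    def test_matches_bruteforce_on_200_random_pairs(self, rng):
        for _ in range(200):
            L = rng.integers(2, 51)
            x = rng.integers(0, rng.integers(2, 11), L)
            y = rng.integers(0, rng.integers(2, 11), L)
            assert sh.mutual_information(x, y) == pytest.approx(mi_brute(tuple(x), tuple(y)), abs=1e-12)
            if sh.entropy(x) > 0 and sh.entropy(y) > 0:
                assert sh.nmi(x, y) == pytest.approx(nmi_brute(tuple(x), tuple(y)), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        """Cross-check against sklearn's contingency-based MI/NMI."""
        from sklearn.metrics import mutual_info_score, normalized_mutual_info_score

        for _ in range(25):
            x = rng.integers(0, 6, 40)
            y = rng.integers(0, 6, 40)
            assert sh.mutual_information(x, y) == pytest.approx(
                mutual_info_score(x, y), abs=1e-10
            )
            assert sh.nmi(x, y) == pytest.approx(
                normalized_mutual_info_score(x, y, average_method="geometric"), abs=1e-10
            )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(profiles)
    def test_bounds_and_symmetry(self, xy):
        x, y = xy
        I = sh.mutual_information(x, y)
        hx, hy = sh.entropy(x), sh.entropy(y)
        assert -1e-12 <= I <= min(hx, hy) + 1e-12
        assert I == pytest.approx(sh.mutual_information(y, x), abs=1e-12)
        if hx > 0 and hy > 0:
            v = sh.nmi(x, y)
            assert -1e-12 <= v <= 1 + 1e-12
            assert v == sh.nmi(y, x)

    def test_self_nmi_is_one(self):
        assert sh.nmi([0, 1, 2, 3], [0, 1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-entropy"):
            assert sh.nmi([1, 1, 1], [0, 1, 2]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sh.mutual_information([0, 1], [0, 1, 2])

    def test_bin_shuffling_noise_never_raises_expected_nmi(self, rng):
        """Data-processing sanity: randomizing a fraction of y's bins
        cannot increase NMI in expectation."""
        x = rng.integers(0, 5, 200)
        y = (x + rng.integers(0, 2, 200)) % 5  # correlated with x
        base = np.mean([sh.nmi(x, y) for _ in range(1)])
        noised = []
        for _ in range(100):
            yy = y.copy()
            mask = rng.random(200) < 0.5
            yy[mask] = rng.integers(0, 5, mask.sum())
            noised.append(sh.nmi(x, yy))
        assert np.mean(noised) < base


class TestPairwiseNMI:
    def test_matches_scalar_nmi_loop(self, rng):
        bins = rng.integers(0, 7, size=(12, 60))
        M = sh.pairwise_nmi(bins, 7)
        for i in range(12):
            for j in range(i + 1, 12):
                assert M[i, j] == pytest.approx(sh.nmi(bins[i], bins[j]), abs=1e-8)
        assert np.allclose(M, M.T)

    def test_zero_entropy_row_gets_zero(self):
        bins = np.array([[1, 1, 1, 1], [0, 1, 2, 3], [0, 0, 1, 1]])
        with pytest.warns(UserWarning):
            expected = sh.nmi(bins[0], bins[1])
        M = sh.pairwise_nmi(bins, 4)
        assert M[0, 1] == expected == 0.0
        assert M[1, 2] > 0


class TestDiscretize:
    def test_constant_gene_maps_to_bin_zero(self):
        norm = make_adata(np.full((5, 1), 3.3))
        d = sh.discretize(norm, ["G0000"], n_bins=10)
        assert (d.bins == 0).all()

    def test_exact_grid_values(self):
        norm = make_adata(np.arange(10.0)[:, None])
        d = sh.discretize(norm, ["G0000"], n_bins=10)
        assert d.bins.ravel().tolist() == list(range(10))

    def test_two_bin_edge_at_half(self):
        norm = make_adata(np.array([0.0, 0.49, 0.51, 1.0])[:, None])
        d = sh.discretize(norm, ["G0000"], n_bins=2)
        assert d.bins.ravel().tolist() == [0, 0, 1, 1]

    def test_maximum_maps_to_top_bin(self, rng):
        norm = make_adata(rng.random((30, 4)))
        d = sh.discretize(norm, [f"G{i:04d}" for i in range(4)], n_bins=10)
        assert (d.bins.max(axis=0) == 9).all()
        assert d.bins.min() >= 0

    def test_quantile_scheme_balances_occupancy(self, rng):
        norm = make_adata(rng.normal(size=(1000, 1)))
        d = sh.discretize(norm, ["G0000"], n_bins=10, scheme="quantile")
        occ = np.bincount(d.bins.ravel(), minlength=10)
        assert occ.min() >= 80

    def test_errors(self, rng):
        norm = make_adata(rng.random((5, 3)))
        with pytest.raises(ValueError, match="empty"):
            sh.discretize(norm, [])
        with pytest.raises(ValueError, match="n_bins"):
            sh.discretize(norm, ["G0000"], n_bins=1)
        with pytest.raises(ValueError, match="absent"):
            sh.discretize(norm, ["NOPE"])


class TestRankMarkers:
    @staticmethod
    def _adata(X, clusters):
        a = make_adata(X)
        a.obs["cluster"] = clusters
        return a

    def test_exclusively_expressed_gene_ranks_first(self, rng):
        X = rng.random((10, 5)) * 0.1
        X[:5, 2] += 5.0  # gene G0002 only in cluster A
        a = self._adata(X, ["A"] * 5 + ["B"] * 5)
        markers = sh.rank_markers(a, top_m=3)
        assert markers["A"][0] == "G0002"

    def test_identically_distributed_gene_ranks_last(self, rng):
        X = rng.random((12, 4))
        X[:6, 0] += 3
        X[6:, 1] += 3
        X[:, 3] = np.tile([0.1, 0.9], 6)  # same in both clusters
        a = self._adata(X, ["A"] * 6 + ["B"] * 6)
        markers = sh.rank_markers(a, top_m=4)
        assert markers["A"][-1] == "G0003"

    def test_ranking_matches_exact_rank_sum_enumeration(self):
        """On a tie-free fixture the ranking reproduces the exact
        permutation null of the rank-sum statistic."""
        import itertools
        import scipy.stats

        X = np.array(
            [  # 4 cells cluster A, 4 cluster B; 5 genes, all values distinct
                [9.1, 0.11, 5.1, 1.01, 2.6],
                [8.7, 0.22, 5.9, 1.52, 0.7],
                [9.9, 0.35, 4.6, 2.03, 2.9],
                [8.1, 0.41, 5.5, 0.54, 0.3],
                [1.1, 7.15, 5.2, 1.27, 2.8],
                [0.9, 8.28, 4.9, 1.76, 0.5],
                [1.8, 7.33, 5.7, 0.88, 2.7],
                [0.2, 6.49, 4.4, 1.39, 0.6],
            ]
        )
        a = self._adata(X, ["A"] * 4 + ["B"] * 4)

        def exact_p(col):
            obs = X[:4, col].sum()
            ranks = scipy.stats.rankdata(X[:, col])
            ra = ranks[:4].sum()
            null = [
                sum(ranks[list(c)]) for c in itertools.combinations(range(8), 4)
            ]
            null = np.array(null)
            mu = null.mean()
            return np.mean(np.abs(null - mu) >= abs(ra - mu) - 1e-12)

        ps = [exact_p(j) for j in range(5)]
        lfc = np.abs(X[:4].mean(0) - X[4:].mean(0))
        order = sorted(range(5), key=lambda j: (ps[j], -lfc[j], f"G{j:04d}"))
        expected = [f"G{j:04d}" for j in order]
        assert sh.rank_markers(a, top_m=5)["A"] == expected

    def test_tiny_cluster_skipped_with_warning(self, rng):
        X = rng.random((5, 3))
        a = self._adata(X, ["A", "A", "B", "B", "C"])
        with pytest.warns(UserWarning, match="skipped"):
            markers = sh.rank_markers(a, top_m=2)
        assert "C" not in markers

    def test_single_cluster_rejected(self, rng):
        a = self._adata(rng.random((4, 3)), ["A"] * 4)
        with pytest.raises(ValueError, match="2 clusters"):
            sh.rank_markers(a)


class TestBuildPanel:
    def test_identical_lists_deduplicate(self):
        p = sh.build_panel({"a": ["g1", "g2"], "b": ["g1", "g2"]})
        assert p.genes == ["g1", "g2"]

    def test_disjoint_union_size(self):
        loadings = pd.DataFrame(
            [[0.9, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.8],
             [0.0, 0.0, 0.0, 0.0, 0.0, 0.7, 0.6, 0.0]],
            index=["PC1", "PC2"],
            columns=[f"c{i}" for i in range(8)],
        )
        p = sh.build_panel(
            {"k1": ["m1", "m2", "m3"], "k2": ["m4", "m5", "m6"]},
            loadings, top_k=2, n_components=2,
        )
        assert len(p) == 10

    def test_overlapping_union_order(self):
        loadings = pd.DataFrame(
            [[0.0, 0.0, 0.9, 0.0, 0.5]],
            index=["PC1"],
            columns=["a", "b", "c", "d", "e"],
        )
        p = sh.build_panel({"k1": ["a", "b", "c"], "k2": ["b", "d"]},
                           loadings, top_k=2, n_components=1)
        assert p.genes == ["a", "b", "c", "d", "e"]
        assert len(p) == 5

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sh.build_panel({})


class TestStageHeterogeneity:
    @staticmethod
    def _disc(bins, barcodes):
        from stagehet.heterogeneity import DiscretizedMatrix

        return DiscretizedMatrix(
            bins=np.asarray(bins), genes=[f"g{i}" for i in range(np.asarray(bins).shape[1])],
            cell_index=pd.Index(barcodes), n_bins=int(np.asarray(bins).max()) + 1,
        )

    def test_identical_cells_give_all_medians_one(self):
        bins = np.tile([0, 1, 2, 3, 0, 1], (6, 1))
        disc = self._disc(bins, [f"c{i}" for i in range(6)])
        stages = pd.Series(["s"] * 6, index=disc.cell_index)
        with pytest.warns(UserWarning, match="using all"):
            res = sh.stage_heterogeneity(disc, stages, n_cells=100, n_draws=20, seed=0)
        assert np.allclose(res.medians["s"], 1.0)

    def test_deterministic_under_seed(self, two_stage_norm):
        disc = sh.discretize(two_stage_norm, list(two_stage_norm.var_names[:80]))
        r1 = sh.stage_heterogeneity(disc, two_stage_norm.obs["stage"], n_cells=30,
                                    n_draws=10, seed=5)
        r2 = sh.stage_heterogeneity(disc, two_stage_norm.obs["stage"], n_cells=30,
                                    n_draws=10, seed=5)
        for st in r1.medians:
            assert np.array_equal(r1.medians[st], r2.medians[st])

    def test_noisier_stage_has_lower_median_nmi(self, two_stage_norm):
        """The generator's jitter ordering is the oracle: the high-noise
        stage must show lower within-stage median NMI."""
        disc = sh.discretize(two_stage_norm, list(two_stage_norm.var_names))
        res = sh.stage_heterogeneity(disc, two_stage_norm.obs["stage"], n_cells=50,
                                     n_draws=50, seed=5)
        assert np.median(res.medians["low"]) > np.median(res.medians["high"])

    def test_tiny_stage_excluded(self):
        bins = np.array([[0, 1, 2], [2, 1, 0], [0, 2, 1]])
        disc = self._disc(bins, ["c0", "c1", "c2"])
        stages = pd.Series(["a", "a", "b"], index=disc.cell_index)
        with pytest.warns(UserWarning):
            res = sh.stage_heterogeneity(disc, stages, n_cells=2, n_draws=5, seed=0)
        assert "b" not in res.medians and "a" in res.medians

    def test_missing_stage_labels_rejected(self):
        disc = self._disc(np.zeros((3, 4), int), ["c0", "c1", "c2"])
        stages = pd.Series(["a", "a"], index=["c0", "c1"])
        with pytest.raises(ValueError, match="missing"):
            sh.stage_heterogeneity(disc, stages)


class TestCompareStages:
    @staticmethod
    def _result(**medians):
        return StageNMIResult(
            medians={k: np.asarray(v, float) for k, v in medians.items()},
            n_cells=10, n_draws=len(next(iter(medians.values()))), seed=0,
            stage_order=list(medians),
        )

    def test_identical_vectors_give_p_one(self):
        v = [0.1, 0.2, 0.3, 0.4, 0.5]
        out = sh.compare_stages(self._result(a=v, b=v))
        assert out.loc[0, "pvalue"] == pytest.approx(1.0)
        assert out.loc[0, "statistic"] == pytest.approx(0.0)

    def test_mannwhitney_exact_matches_permutation_null(self):
        out = sh.compare_stages(
            self._result(a=[1, 1, 1, 1, 1], b=[0, 0, 0, 0, 0]),
            method="mannwhitney", mw_method="exact",
        )
        assert out.loc[0, "statistic"] == 25
        assert out.loc[0, "pvalue"] == pytest.approx(2 / 252, abs=1e-15)
        assert out.loc[0, "direction"] == "a>b"

    def test_caveat_is_surfaced(self):
        out = sh.compare_stages(self._result(a=[0.1, 0.2, 0.3], b=[0.4, 0.5, 0.6]))
        assert "not independent" in out.loc[0, "caveat"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            sh.compare_stages(self._result(a=[1, 2], b=[3, 4]), method="anova")

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sh.compare_stages(self._result(a=[1, 2, 3]))
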