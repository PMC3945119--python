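import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plast.analysis import (
    DivergenceTable,
    annotation_baseline_search,
    annotation_match_fraction,
    classify_divergence,
    cluster_profiles,
    compare_methods,
    enrichment_test,
    function_divergence_table,
    permutation_test,
    preference_sweep,
    sample_null_pairs,
    subunit_search,
)
from plast.errors import InsufficientDataError, ParameterError, PlastError


def toy_dp_matrix(n=20, seed=0, complex_ids=("P0", "P1", "P2", "P3", "P4")):
    """Proteins P0..P4 form a tight cluster; the rest are diffuse."""
    rng = np.random.default_rng(seed)
    vecs = {}
    for i in range(n):
        pid = f"P{i}"
        base = np.array([1.0, 0.0, 0.0]) if pid in complex_ids else rng.normal(size=3)
        vecs[pid] = base + rng.normal(0, 0.05, 3)
    ids = list(vecs)
    M = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            ha, hb = vecs[a], vecs[b]
            M[i, j] = 1 - ha @ hb / (np.linalg.norm(ha) * np.linalg.norm(hb))
    np.fill_diagonal(M, 0.0)
    return pd.DataFrame((M + M.T) / 2, index=ids, columns=ids)


class TestSubunitSearch:
    def test_perfect_cluster_reaches_f1_one(self):
        dmat = toy_dp_matrix()
        res = subunit_search(["P0", "P1"], dmat, truth=["P0", "P1", "P2", "P3", "P4"])
        assert res.max_f1 == 1.0
        assert set(res.ranking.head(3)["protein"]) == {"P2", "P3", "P4"}

    def test_precision_recall_formula(self):
        # TP=8, FP=2, FN=2 -> P=R=F1=0.8
        tp, fp, fn = 8, 2, 2
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        dmat = toy_dp_matrix(n=30, complex_ids=tuple(f"P{i}" for i in range(11)))
        res = subunit_search(["P0"], dmat, truth=[f"P{i}" for i in range(11)])
        # at rank 10 the curve obeys the formula identities
        k = 9
        tp_k = res.ranking["is_truth"][: k + 1].sum()
        assert res.precision[k] == pytest.approx(tp_k / (k + 1))
        assert res.recall[k] == pytest.approx(tp_k / 10)
        if res.precision[k] + res.recall[k] > 0:
            f1 = 2 * res.precision[k] * res.recall[k] / (res.precision[k] + res.recall[k])
            assert res.f1[k] == pytest.approx(f1)

    def test_curve_invariants(self):
        dmat = toy_dp_matrix(seed=3)
        res = subunit_search(["P0"], dmat, truth=["P1", "P2", "P3"])
        assert np.all(np.diff(res.recall) >= -1e-12)
        assert res.precision[0] in (0.0, 1.0)

    def test_unknown_query_raises(self):
        with pytest.raises(ParameterError):
            subunit_search(["missing"], toy_dp_matrix(), truth=["P1"])


class TestAnnotationBaseline:
    def test_shared_category_recovers_truth(self):
        annotations = {f"P{i}": {"ribosome"} for i in range(8)}
        annotations.update({f"Q{i}": {"nucleus"} for i in range(5)})
        res = annotation_baseline_search(["P0", "P1"], annotations, truth=[f"P{i}" for i in range(8)])
        assert res.max_f1 == 1.0

    def test_tie_breaks_lexicographically(self):
        annotations = {"q": {"b_cat", "a_cat"}, "x": {"a_cat"}, "y": {"b_cat"}}
        res = annotation_baseline_search(["q"], annotations, truth=["x"])
        assert set(res.ranking["protein"]) == {"x"}  # a_cat wins the tie

    def test_category_bleed_matches_set_arithmetic(self):
        truth = {f"P{i}" for i in range(10)}
        annotations = {f"P{i}": {"c"} for i in range(5)}  # half the truth annotated c
        annotations.update({f"X{i}": {"c"} for i in range(5)})  # plus 5 outsiders
        res = annotation_baseline_search(["P0"], annotations, truth=truth)
        predicted = {p for p in annotations if p != "P0" and "c" in annotations[p]}
        tp = len(predicted & (truth - {"P0"}))
        prec = tp / len(predicted)
        rec = tp / len(truth - {"P0"})
        assert res.max_f1 == pytest.approx(2 * prec * rec / (prec + rec))

    def test_unannotated_query_flagged(self):
        with pytest.raises(InsufficientDataError):
            annotation_baseline_search(["nope"], {"x": {"c"}}, truth=["x"])


class TestCompareMethods:
    def test_identical_methods_give_half_p(self):
        f1 = pd.DataFrame({"A": [0.5, 0.6, 0.7], "B": [0.5, 0.6, 0.7]})
        out = compare_methods(f1)
        assert (out["p"] == 0.5).all()

    def test_constant_improvement_detected(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.4, 0.6, 20)
        f1 = pd.DataFrame({"A": b + 0.1, "B": b})
        out = compare_methods(f1).set_index(["method_a", "method_b"])
        assert out.loc[("A", "B"), "p"] < 0.001
        # closed-form paired t oracle
        t, p = stats.ttest_rel(b + 0.1, b, alternative="greater")
        assert out.loc[("A", "B"), "t"] == pytest.approx(t)
        assert out.loc[("A", "B"), "p_adj"] == pytest.approx(min(1.0, p * 2))


class TestPermutationTest:
    def test_identical_split_gives_p_one(self):
        x = np.arange(10.0)
        assert permutation_test(x, x.copy(), n_perm=200, seed=0) == 1.0

    def test_strong_difference_below_resolution(self):
        rng = np.random.default_rng(1)
        p = permutation_test(rng.normal(0, 1, 50), rng.normal(5, 1, 50), n_perm=2000, seed=2)
        assert p == 0.0  # below 1/n_perm resolution

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        p_xy = permutation_test(x, y, n_perm=4000, seed=4)
        p_yx = permutation_test(y, x, n_perm=4000, seed=4)
        assert abs(p_xy - p_yx) < 0.03

    def test_median_statistic_supported(self):
        rng = np.random.default_rng(5)
        p = permutation_test(rng.normal(0, 1, 40), rng.normal(3, 1, 40), stat="median_diff", n_perm=500, seed=6)
        assert p < 0.01

    def test_validation(self):
        with pytest.raises(ParameterError):
            permutation_test([], [1.0])
        with pytest.warns(UserWarning):
            permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=50, seed=0)


class TestDivergence:
    def _setup(self, seed=0):
        dmat = toy_dp_matrix(n=40, seed=seed, complex_ids=())
        dups = [("P0", "P1"), ("P2", "P3"), ("P4", "P5")]
        nulls = sample_null_pairs(dmat.index, dups, n_pairs=200, seed=seed)
        return dmat, dups, nulls

    def test_percentile_zero_makes_all_dl(self):
        dmat, dups, nulls = self._setup()
        table = classify_divergence(dups, nulls, dmat, percentile=0.0)
        assert (table.pairs["cls"] == "DL").all()

    def test_null_pair_dl_fraction_identity(self):
        dmat, dups, nulls = self._setup()
        for q in (10.0, 50.0):
            table = classify_divergence(nulls, nulls, dmat, percentile=q)
            frac_dl = (table.pairs["cls"] == "DL").mean()
            assert frac_dl == pytest.approx(1 - q / 100, abs=0.02)

    def test_dl_fraction_monotone_in_percentile(self):
        dmat, dups, nulls = self._setup()
        fracs = [
            (classify_divergence(dups, nulls, dmat, percentile=q).pairs["cls"] == "DL").mean()
            for q in (0, 25, 50, 75, 100)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_missing_profile_skipped_with_warning(self):
        dmat, dups, nulls = self._setup()
        with pytest.warns(UserWarning):
            table = classify_divergence([("P0", "ZZZ")] + dups, nulls, dmat, percentile=10)
        assert len(table.pairs) == len(dups)

    def test_small_null_sample_rejected(self):
        dmat, dups, _ = self._setup()
        with pytest.raises(ParameterError):
            classify_divergence(dups, [("P0", "P1")] * 50, dmat)

    def test_null_pairs_exclude_duplicates_and_selfs(self):
        dmat, dups, nulls = self._setup()
        dupset = {frozenset(d) for d in dups}
        for a, b in nulls:
            assert a != b
            assert frozenset((a, b)) not in dupset


class TestFunctionDivergence:
    def test_match_fraction_arithmetic(self):
        assert annotation_match_fraction({"a", "b", "c", "d"}, {"a", "b", "c", "e"}) == 0.75

    def test_degenerate_table_p_one(self):
        pairs = pd.DataFrame(
            {"idA": ["a", "c"], "idB": ["b", "d"], "dp": [0.1, 0.2], "shared_ratio": np.nan,
             "n_compartments_union": np.nan, "cls": ["SL", "SL"]}
        )
        table = DivergenceTable(pairs=pairs, percentile=10, threshold=0.5)
        annotations = {k: {"t1"} for k in "abcd"}
        tab, p = function_divergence_table(table, annotations)
        assert p == 1.0
        assert tab.loc["SL", "similar"] == 2

    def test_planted_association_detected(self):
        rng = np.random.default_rng(7)
        rows, annotations = [], {}
        for i in range(200):
            cls = "DL" if i % 2 else "SL"
            dissim_p = 0.75 if cls == "DL" else 0.25
            a, b = f"a{i}", f"b{i}"
            annotations[a] = {"t1", "t2", "t3", "t4"}
            if rng.random() < dissim_p:
                annotations[b] = {"x1", "x2", "t1", "x3"}  # 1/4 match: dissimilar
            else:
                annotations[b] = {"t1", "t2", "t3", "x1"}  # 3/4 match: similar
            rows.append({"idA": a, "idB": b, "dp": 0.5, "shared_ratio": np.nan,
                         "n_compartments_union": np.nan, "cls": cls})
        table = DivergenceTable(pairs=pd.DataFrame(rows), percentile=10, threshold=0.5)
        _, p = function_divergence_table(table, annotations)
        assert p < 0.05

    def test_unannotated_pairs_error(self):
        pairs = pd.DataFrame({"idA": ["a"], "idB": ["b"], "dp": [0.1], "shared_ratio": np.nan,
                              "n_compartments_union": np.nan, "cls": ["SL"]})
        table = DivergenceTable(pairs=pairs, percentile=10, threshold=0.5)
        with pytest.raises(PlastError):
            function_divergence_table(table, {})


class TestClustering:
    def test_ward_recovers_two_blobs(self):
        from plast.segmentation import LabeledMask, rand_error

        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        from scipy.spatial.distance import cdist

        dmat = pd.DataFrame(cdist(pts, pts), index=[f"p{i}" for i in range(20)], columns=[f"p{i}" for i in range(20)])
        labels, _ = cluster_profiles(dmat, "hierarchical_ward", k=2)
        truth = np.array([1] * 10 + [2] * 10)
        assert rand_error(LabeledMask(truth.reshape(1, -1)), LabeledMask(labels.reshape(1, -1))) == 0.0

    def test_identical_points_single_cluster(self):
        n = 8
        dmat = pd.DataFrame(np.zeros((n, n)), index=range(n), columns=range(n))
        labels, _ = cluster_profiles(dmat, "hierarchical_ward", k=1)
        assert len(np.unique(labels)) == 1

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ParameterError):
            cluster_profiles(pd.DataFrame(M), "affinity_propagation")

    def test_ap_preference_sweep_recovers_three_classes(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(c, 0.05, (6, 2)) for c in ((0, 0), (3, 0), (0, 3))])
        from scipy.spatial.distance import cdist

        ids = [f"p{i}" for i in range(18)]
        dmat = pd.DataFrame(cdist(pts, pts), index=ids, columns=ids)
        sweep = preference_sweep(dmat, preferences=np.linspace(-8, -1, 8), seed=0)
        counts = sweep["n_clusters"].tolist()
        assert counts.count(3) >= 4  # plateau at the true cluster count


class TestEnrichment:
    def test_cluster_equals_category_closed_form(self):
        universe = [f"u{i}" for i in range(30)]
        cluster = set(universe[:6])
        p = enrichment_test(cluster, cluster, universe)
        # drawing all 6 category members in 6 draws: 1 / C(30,6)
        from math import comb

        assert p == pytest.approx(1 / comb(30, 6))

    def test_disjoint_category_not_enriched(self):
        universe = [f"u{i}" for i in range(30)]
        p = enrichment_test(set(universe[:5]), set(universe[10:15]), universe)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_tail_sum_matches_brute_force(self):
        p = enrichment_test({f"u{i}" for i in range(10)}, {f"u{i}" for i in range(5, 15)}, [f"u{i}" for i in range(100)])
        brute = sum(stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert p == pytest.approx(brute, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            enrichment_test(set(), set(), set())
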