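"""Residual-feature clustering: matrix, distances, agglomeration, Newick."""

import datetime as dt
import itertools

import numpy as np
import pytest

import uveprof as uv
from uveprof.annotate import TermMention
from uveprof.cohort import AnalysisWindow


def _mention(pid, concept, date):
    return TermMention(pid, f"{pid}-N", date, "t", concept, 0, 1, False, False)


def _window(pid, end=dt.date(2006, 1, 1)):
    return AnalysisWindow(pid, end)


# --------------------------------------------------------------------------
# binary matrix
# --------------------------------------------------------------------------

class TestBinaryMatrix:
    def test_mention_after_window_is_absent(self):
        mat = uv.build_matrix([_mention("P1", "cough", dt.date(2007, 5, 1)),
                               _mention("P2", "cough", dt.date(2005, 5, 1))],
                              ["P1", "P2"])
        bm = uv.build_binary_matrix(mat, [_window("P1"), _window("P2")], frozenset())
        assert bm.frame().loc["P1", "cough"] == 0
        assert bm.frame().loc["P2", "cough"] == 1

    def test_excluded_concepts_removed(self):
        mat = uv.build_matrix([_mention("P1", "psoriasis", dt.date(2005, 1, 1)),
                               _mention("P2", "cough", dt.date(2005, 1, 1))],
                              ["P1", "P2"])
        bm = uv.build_binary_matrix(mat, [_window("P1"), _window("P2")],
                                    frozenset({"psoriasis"}))
        assert bm.concepts == ["cough"]

    def test_empty_input_no_error(self):
        mat = uv.build_matrix([], ["P1", "P2"])
        bm = uv.build_binary_matrix(mat, [_window("P1"), _window("P2")], frozenset())
        assert bm.concepts == []
        assert bm.values.shape == (2, 0)


class TestDistances:
    def test_binary_disagreement_count(self):
        m = uv.BinaryConceptMatrix(["a", "b", "c"], ["x", "y", "z"],
                                   np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]]))
        d = uv.euclidean_distances(m)
        assert d[0, 1] == pytest.approx(np.sqrt(2))
        assert d[0, 2] == 0.0
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_brute_force_pairwise(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, (5, 4))
        m = uv.BinaryConceptMatrix([f"p{i}" for i in range(5)],
                                   [f"c{j}" for j in range(4)], vals)
        d = uv.euclidean_distances(m)
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(
                    np.sqrt(np.sum((vals[i] - vals[j]) ** 2)))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 2, (8, 6))
        d = uv.euclidean_distances(
            uv.BinaryConceptMatrix([str(i) for i in range(8)],
                                   [str(j) for j in range(6)], vals))
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_single_patient_rejected(self):
        m = uv.BinaryConceptMatrix(["a"], ["x"], np.array([[1]]))
        with pytest.raises(uv.ClusterError):
            uv.euclidean_distances(m)


# --------------------------------------------------------------------------
# agglomeration
# --------------------------------------------------------------------------

def linkage_oracle(d: np.ndarray, linkage: str = "complete"):
    """Naive oracle: recompute every inter-cluster linkage from scratch at
    each step over explicit member lists."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pairs = [d[i, j] for i in clusters[a] for j in clusters[b]]
            val = max(pairs) if linkage == "complete" else min(pairs)
            key = (val, a, b)
            if best is None or key < best:
                best = key
        val, a, b = best
        merges.append((a, b, val))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestAgglomerate:
    def test_three_points_merges_closest_first(self):
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        dendro = uv.agglomerate(d)
        assert dendro.merges[0] == (0, 1, 1.0)
        assert dendro.merges[1] == (2, 3, 3.0)  # complete linkage: max(3, 2)

    def test_equidistant_tie_goes_to_lowest_indices(self):
        d = np.ones((3, 3)) - np.eye(3)
        dendro = uv.agglomerate(d)
        assert dendro.merges[0][:2] == (0, 1)

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pts = rng.normal(size=(6, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dendro = uv.agglomerate(d)
            assert dendro.merges == [
                (a, b, pytest.approx(h)) for a, b, h in linkage_oracle(d)]

    def test_merge_heights_match_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(12, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dendro = uv.agglomerate(d)
        ours = sorted(h for _, _, h in dendro.merges)
        scipys = sorted(linkage(squareform(d, checks=False), "complete")[:, 2])
        assert np.allclose(ours, scipys)

    def test_heights_nondecreasing_to_root(self):
        rng = np.random.default_rng(13)
        vals = rng.integers(0, 2, (10, 5))
        m = uv.BinaryConceptMatrix([str(i) for i in range(10)],
                                   [str(j) for j in range(5)], vals)
        dendro = uv.agglomerate(uv.euclidean_distances(m))
        heights = dendro.heights()
        for node, (a, b) in dendro.children().items():
            assert heights[node] >= heights.get(a, 0.0) - 1e-12
            assert heights[node] >= heights.get(b, 0.0) - 1e-12

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(uv.ClusterError):
            uv.agglomerate(d)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(14)
        vals = rng.integers(0, 2, (9, 5))
        ids = [f"p{i}" for i in range(9)]
        m1 = uv.BinaryConceptMatrix(ids, list("abcde"), vals)
        perm = rng.permutation(9)
        m2 = uv.BinaryConceptMatrix([ids[i] for i in perm], list("abcde"), vals[perm])
        d1 = uv.agglomerate(uv.euclidean_distances(m1), leaf_ids=m1.patients)
        d2 = uv.agglomerate(uv.euclidean_distances(m2), leaf_ids=m2.patients)
        assert sorted(h for *_, h in d1.merges) == pytest.approx(
            sorted(h for *_, h in d2.merges))
        labels = {pid: ("case" if i % 3 == 0 else "control")
                  for i, pid in enumerate(ids)}
        mem1, *_ = uv.find_main_cluster(d1, labels, min_size=3)
        mem2, *_ = uv.find_main_cluster(d2, labels, min_size=3)
        assert mem1 == mem2


# --------------------------------------------------------------------------
# main cluster & influence
# --------------------------------------------------------------------------

class TestMainCluster:
    def _two_clades(self):
        # 5 cases identical to each other, 5 controls identical, far apart
        vals = np.array([[1, 1, 0, 0]] * 5 + [[0, 0, 1, 1]] * 5)
        ids = [f"case{i}" for i in range(5)] + [f"ctrl{i}" for i in range(5)]
        labels = {pid: ("case" if pid.startswith("case") else "control")
                  for pid in ids}
        m = uv.BinaryConceptMatrix(ids, list("wxyz"), vals)
        dendro = uv.agglomerate(uv.euclidean_distances(m), leaf_ids=ids)
        return m, dendro, labels

    def test_pure_case_clade_selected(self):
        _, dendro, labels = self._two_clades()
        members, n_cases, n_ctrl, p = uv.find_main_cluster(dendro, labels)
        assert members == {f"case{i}" for i in range(5)}
        assert (n_cases, n_ctrl) == (5, 0)

    def test_single_class_rejected(self):
        _, dendro, _ = self._two_clades()
        with pytest.raises(uv.ClusterError):
            uv.find_main_cluster(dendro, {pid: "case" for pid in dendro.leaf_ids})

    def test_feature_influence_vs_hand_tables(self):
        m, dendro, labels = self._two_clades()
        members, *_ = uv.find_main_cluster(dendro, labels)
        infl = uv.feature_influence(m, members)
        # concept 'w': present in all 5 inside, none of 5 outside
        expected = uv.fisher_exact_2x2([[5, 0], [0, 5]])
        assert infl.set_index("concept").loc["w", "p"] == pytest.approx(expected)

    def test_constant_column_uninformative(self):
        vals = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        m = uv.BinaryConceptMatrix(list("abcd"), ["k", "l"], vals)
        infl = uv.feature_influence(m, {"a", "b"})
        assert infl.set_index("concept").loc["k", "p"] == 1.0


class TestNewick:
    def test_two_leaf_shape(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        dendro = uv.agglomerate(d, leaf_ids=["P1", "P2"])
        s = uv.export_newick(dendro, {"P1": "case", "P2": "control"})
        assert s == "(case_P1:2,ctrl_P2:2);"

    def test_round_trip_through_dendropy(self):
        import dendropy
        rng = np.random.default_rng(15)
        vals = rng.integers(0, 2, (7, 4))
        ids = [f"P{i}" for i in range(7)]
        m = uv.BinaryConceptMatrix(ids, list("abcd"), vals)
        dendro = uv.agglomerate(uv.euclidean_distances(m), leaf_ids=ids)
        labels = {pid: "case" for pid in ids}
        s = uv.export_newick(dendro, labels)
        tree = dendropy.Tree.get(data=s, schema="newick",
                                 preserve_underscores=True)
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == {f"case_{pid}" for pid in ids}

    def test_branch_lengths_positive_for_increasing_heights(self):
        d = np.array([[0.0, 1.0, 4.0, 6.0],
                      [1.0, 0.0, 5.0, 6.5],
                      [4.0, 5.0, 0.0, 2.0],
                      [6.0, 6.5, 2.0, 0.0]])
        dendro = uv.agglomerate(d)
        s = uv.export_newick(dendro)
        lengths = [float(x.split(")")[0].split(",")[0])
                   for x in s.split(":")[1:]]
        assert all(l > 0 for l in lengths)
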