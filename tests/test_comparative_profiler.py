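"""Profile matrix, Pearson distance and UPGMA against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from rumenmt.comparative_profiler import (
    build_profile_matrix,
    cophenetic_distances,
    default_reference_profiles,
    gh_only,
    pearson_distance,
    to_newick,
    upgma,
)


class TestProfileMatrix:
    def test_row_normalized_percents(self):
        m = build_profile_matrix({"s": {"GH5": 1, "GH6": 1}}, ["GH5", "GH6"])
        assert m.percents.tolist() == [[50.0, 50.0]]

    def test_missing_family_fills_zero_column(self):
        m = build_profile_matrix({"s": {"GH5": 4}}, ["GH5", "GH6"])
        assert m.counts.tolist() == [[4, 0]]
        assert m.family_ids == ["GH5", "GH6"]

    def test_all_zero_row_flagged_and_excluded(self):
        m = build_profile_matrix(
            {"a": {"GH5": 1, "GH6": 3}, "b": {}, "c": {"GH5": 3, "GH6": 1}},
            ["GH5", "GH6"])
        assert m.empty_rows == ["b"]
        ids, _ = pearson_distance(m)
        assert ids == ["a", "c"]

    def test_rows_sum_to_100(self):
        m = build_profile_matrix(default_reference_profiles(),
                                 gh_only(["GH1", "GH2", "GH3", "GH5", "GH6",
                                          "GH9", "GH10", "GH11", "GH13",
                                          "GH43", "GH45", "GH48"]))
        assert np.allclose(m.percents.sum(axis=1), 100.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            build_profile_matrix({"s": {"GH5": -1}}, ["GH5"])


class TestPearsonDistance:
    def _dist(self, rows, fams=None):
        fams = fams or [f"GH{i}" for i in range(1, len(rows[0]) + 1)]
        prof = {f"s{i}": dict(zip(fams, r)) for i, r in enumerate(rows)}
        return pearson_distance(build_profile_matrix(prof, fams))

    def test_identical_rows_have_zero_distance(self):
        _, d = self._dist([[10, 20, 30], [10, 20, 30]])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_have_distance_two(self):
        _, d = self._dist([[80, 20], [20, 80]])
        assert d[0, 1] == pytest.approx(2.0)

    def test_hand_computed_covariance_example(self):
        # percents [60,30,10] vs [10,30,60]: deviations (80,-10,-70)/3 and
        # (-70,-10,80)/3 give r = -11100/11400 = -37/38, so d = 75/38
        _, d = self._dist([[60, 30, 10], [10, 30, 60]])
        assert d[0, 1] == pytest.approx(75 / 38, abs=1e-12)

    def test_scale_invariance_of_count_rows(self):
        _, d1 = self._dist([[6, 3, 1], [1, 5, 9]])
        _, d2 = self._dist([[60, 30, 10], [1, 5, 9]])
        assert np.allclose(d1, d2)

    def test_zero_variance_row_error_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            self._dist([[10, 20, 30], [25, 25, 25]])

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 50, size=(5, 8)) + 1
        _, d = self._dist(rows.tolist())
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 2


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        root = upgma(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        assert root.height == pytest.approx(0.2)
        assert root.members == ("a", "b")

    def test_three_leaf_hand_executed_example(self):
        d = np.array([[0.0, 0.2, 0.6],
                      [0.2, 0.0, 0.6],
                      [0.6, 0.6, 0.0]])
        root = upgma(d, ["a", "b", "c"])
        assert root.height == pytest.approx(0.3)
        inner = [c for c in root.children if not c.is_leaf][0]
        assert inner.members == ("a", "b") and inner.height == pytest.approx(0.1)

    def test_heights_non_decreasing_rootward(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            d = _random_distance(rng, n)
            root = upgma(d, [f"l{i}" for i in range(n)])

            def check(node):
                for c in node.children:
                    assert c.height <= node.height + 1e-12
                    check(c)

            check(root)

    def test_tie_break_is_label_deterministic(self):
        # equilateral triangle: every pair ties; smallest id pair merges first
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        root = upgma(d, ["b", "a", "c"])
        inner = [c for c in root.children if not c.is_leaf][0]
        assert inner.members == ("a", "b")

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma(d, ["a", "b"])

    def test_matches_scipy_average_linkage_cophenet(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            d = _random_distance(rng, n)
            labels = [f"l{i}" for i in range(n)]
            ours = cophenetic_distances(upgma(d, labels))
            ref = squareform(cophenet(linkage(squareform(d), method="average")))
            for i, j in itertools.combinations(range(n), 2):
                assert ours[frozenset((labels[i], labels[j]))] == pytest.approx(
                    ref[i, j], abs=1e-9)

    def test_newick_output_parses_and_is_ultrametric(self):
        rng = np.random.default_rng(31)
        d = _random_distance(rng, 6)
        labels = [f"l{i}" for i in range(6)]
        root = upgma(d, labels)
        tree = TreeNode.read([to_newick(root)])
        tips = sorted(t.name for t in tree.tips())
        assert tips == labels
        depths = {t.name: tree.distance(t) for t in tree.tips()}
        assert max(depths.values()) - min(depths.values()) < 1e-5


def _random_distance(rng, n):
    m = rng.uniform(0.05, 2.0, size=(n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def test_planted_profiles_split_into_expected_clades():
    """Cellulolytic-like and oligosaccharide-like profiles separate at the root."""
    profiles = default_reference_profiles()
    universe = gh_only(sorted({f for p in profiles.values() for f in p}))
    m = build_profile_matrix(profiles, universe)
    ids, d = pearson_distance(m)
    root = upgma(d, ids)
    clades = [set(c.members) for c in root.children]
    assert {"cellulolytic_A", "cellulolytic_B"} in clades
    assert {"oligosaccharide_A", "oligosaccharide_B"} in clades
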