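import itertools

import numpy as np
import pandas as pd
import pytest

from bloodsig.diversity import (
    _kruskal_safe,
    alpha_diversity,
    compare_alpha,
    faith_pd,
    observed_richness,
    pcoa,
    rarefy,
    unweighted_unifrac,
    unweighted_unifrac_pair,
)
from bloodsig.io import FeatureTable, read_newick
from bloodsig.synth import generate_tree


def table(data, samples, taxa):
    return FeatureTable(pd.DataFrame(data, index=samples, columns=taxa))


# --- independent brute-force oracle for Faith's PD -------------------------


def faith_pd_bruteforce(present, tree):
    """Union of root-paths of the present tips; sum of edge lengths."""
    edges = set()
    for tip in tree.tips():
        if tip.name in present:
            node = tip
            while node.parent is not None:
                edges.add(id(node))
                node = node.parent
    by_id = {id(n): n for n in tree.traverse(include_self=False)}
    return sum(by_id[e].length for e in edges)


class TestRarefy:
    def test_insufficient_depth_excluded(self):
        ft = table([[1500]], ["a"], ["G1"])
        out, excluded = rarefy(ft, 2000)
        assert excluded == ["a"]
        assert out.counts.shape[0] == 0

    def test_exact_depth_passthrough(self):
        ft = table([[1200, 800]], ["a"], ["G1", "G2"])
        out, excluded = rarefy(ft, 2000)
        assert excluded == []
        assert out.counts.loc["a"].tolist() == [1200, 800]

    def test_single_taxon_forced_outcome(self):
        ft = table([[4000, 0]], ["a"], ["G1", "G2"])
        out, _ = rarefy(ft, 2000)
        assert out.counts.loc["a"].tolist() == [2000, 0]

    def test_totals_zeros_and_richness(self, rng):
        counts = rng.integers(0, 200, size=(6, 10))
        counts[:, 3] = 0
        ft = table(counts, [f"s{i}" for i in range(6)], [f"G{i}" for i in range(10)])
        depth = int(min(counts.sum(axis=1)))
        out, excluded = rarefy(ft, depth, seed=1)
        assert excluded == []
        assert (out.sample_totals() == depth).all()
        assert (out.counts["G3"] == 0).all()
        assert (observed_richness(out) <= observed_richness(ft)).all()

    def test_reproducible_under_seed(self):
        ft = table([[500, 700, 900]], ["a"], ["G1", "G2", "G3"])
        a, _ = rarefy(ft, 1000, seed=9)
        b, _ = rarefy(ft, 1000, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestObservedRichness:
    @pytest.mark.parametrize("counts, expected", [([3, 0, 1], 2), ([0, 0, 0], 0)])
    def test_examples(self, counts, expected):
        assert observed_richness(counts) == expected

    def test_agrees_with_bruteforce_on_random_tables(self, rng):
        counts = rng.integers(0, 3, size=(5, 8))
        df = pd.DataFrame(counts, index=[f"s{i}" for i in range(5)])
        expected = [sum(1 for v in row if v > 0) for row in counts]
        assert observed_richness(df).tolist() == expected


class TestFaithPD:
    @pytest.mark.parametrize(
        "present, expected",
        [({"A"}, 2.0), ({"A", "B"}, 3.0), ({"A", "B", "C"}, 5.0)],
    )
    def test_toy_tree_values(self, toy_tree, present, expected):
        assert faith_pd(present, toy_tree) == pytest.approx(expected)

    def test_missing_taxon_named_in_error(self, toy_tree):
        with pytest.raises(ValueError, match="Zeta"):
            faith_pd({"A", "Zeta"}, toy_tree)

    def test_matches_bruteforce_on_random_trees(self, rng):
        taxa = [f"T{i}" for i in range(12)]
        for seed in range(5):
            tree = generate_tree(taxa, seed=seed)
            present = set(rng.choice(taxa, size=rng.integers(1, 12), replace=False))
            assert faith_pd(present, tree) == pytest.approx(
                faith_pd_bruteforce(present, tree)
            )

    def test_monotone_in_presence(self, rng):
        taxa = [f"T{i}" for i in range(10)]
        tree = generate_tree(taxa, seed=3)
        present = set()
        last = 0.0
        for t in rng.permutation(taxa):
            present.add(t)
            value = faith_pd(present, tree)
            assert value >= last - 1e-12
            last = value


class TestUnweightedUniFrac:
    def test_toy_tree_pair(self, toy_tree):
        # branches: A(1), B(1), internal(1), C(2); {A} vs {B}: unique A+B=2
        # over observed A+B+internal=3
        assert unweighted_unifrac_pair({"A"}, {"B"}, toy_tree) == pytest.approx(2 / 3)

    def test_identity_on_equal_presence(self, toy_tree):
        assert unweighted_unifrac_pair({"A", "C"}, {"A", "C"}, toy_tree) == 0.0

    def test_disjoint_lineages_are_maximal(self, toy_tree):
        assert unweighted_unifrac_pair({"A"}, {"C"}, toy_tree) == pytest.approx(1.0)

    def test_empty_sample_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            unweighted_unifrac_pair(set(), {"A"}, toy_tree)

    def test_metric_axioms_on_exhaustive_small_tree(self):
        tree = read_newick("(((A:0.5,B:1.2):0.3,C:0.9):0.4,(D:0.7,E:0.2):1.1);")
        taxa = ["A", "B", "C", "D", "E"]
        subsets = [
            frozenset(c)
            for r in range(1, 6)
            for c in itertools.combinations(taxa, r)
        ]
        d = {
            (i, j): unweighted_unifrac_pair(subsets[i], subsets[j], tree)
            for i in range(len(subsets))
            for j in range(i, len(subsets))
        }

        def dist(i, j):
            return d[(i, j)] if i <= j else d[(j, i)]

        n = len(subsets)
        for i in range(n):
            assert dist(i, i) == 0.0
            for j in range(i + 1, n):
                assert dist(i, j) >= 0
                if subsets[i] != subsets[j]:
                    assert dist(i, j) > 0
        # triangle inequality over sampled triples (full cube is large)
        rng = np.random.default_rng(0)
        for _ in range(300):
            i, j, k = rng.integers(0, n, size=3)
            assert dist(i, k) <= dist(i, j) + dist(j, k) + 1e-12

    def test_matrix_form_matches_pairs(self, toy_tree):
        ft = table([[1, 0, 0], [0, 1, 0], [1, 1, 1]], ["x", "y", "z"], ["A", "B", "C"])
        dm = unweighted_unifrac(ft, toy_tree)
        assert dm["x", "y"] == pytest.approx(2 / 3)
        assert dm["x", "z"] == pytest.approx(
            unweighted_unifrac_pair({"A"}, {"A", "B", "C"}, toy_tree)
        )


class TestPCoA:
    def test_collinear_points_recovered_exactly(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = pcoa(d)
        axis1 = res.samples.iloc[:, 0].to_numpy()
        for i in range(3):
            for j in range(3):
                assert abs(axis1[i] - axis1[j]) == pytest.approx(d[i, j], abs=1e-10)
        positive = res.eigvals[res.eigvals > 1e-10]
        assert len(positive) == 1

    def test_all_zero_distances_give_zero_coordinates(self):
        res = pcoa(np.zeros((4, 4)))
        assert np.allclose(res.samples.to_numpy(), 0.0)

    def test_euclidean_inputs_reproduced_within_tolerance(self, rng):
        points = rng.normal(size=(6, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        res = pcoa(d)
        coords = res.samples.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(recon, d, atol=1e-8)

    def test_non_symmetric_matrix_rejected(self):
        bad = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(Exception):
            pcoa(bad)


class TestCompareAlpha:
    def make_alpha(self, values, groups, studies=None):
        n = len(values)
        studies = studies or ["S1"] * n
        ids = [f"s{i}" for i in range(n)]
        alpha = pd.DataFrame({"observed_richness": values}, index=ids)
        md = pd.DataFrame(
            {
                "sample_id": ids,
                "study_id": studies,
                "group": groups,
                "cohort_label": "x",
            }
        )
        return alpha, md

    def test_hand_computed_h_statistic(self):
        alpha, md = self.make_alpha([1, 2, 3, 4, 5, 6], ["Ct"] * 3 + ["NCt"] * 3)
        out = compare_alpha(alpha, md)
        assert out["H"] == pytest.approx(3.857, abs=5e-4)

    def test_identical_groups_give_zero_h(self):
        assert _kruskal_safe([5, 5], [5, 5]) == (0.0, 1.0)

    def test_control_mean_normalization(self):
        alpha, md = self.make_alpha([2, 4, 6], ["Ct", "Ct", "NCt"])
        out = compare_alpha(alpha, md)
        assert out["normalized"].loc["s2"] == pytest.approx(2.0)

    def test_study_without_controls_skipped(self):
        alpha, md = self.make_alpha(
            [1, 2, 3, 4],
            ["Ct", "NCt", "NCt", "NCt"],
            ["S1", "S1", "S2", "S2"],
        )
        out = compare_alpha(alpha, md)
        assert out["studies_without_controls"] == ["S2"]
        assert np.isnan(out["normalized"].loc["s2"])


def test_alpha_diversity_bounds(small_dataset):
    """Richness never exceeds the taxon count and Faith's PD never exceeds
    the tree's total branch length."""
    from bloodsig.io import total_branch_length
    from bloodsig.qc import filter_low_depth

    ds = small_dataset
    ft, _ = filter_low_depth(ds["table"], 100)
    rt, _ = rarefy(ft, 2000, seed=0)
    sub = FeatureTable(rt.counts.iloc[:10])
    al = alpha_diversity(sub, ds["tree"])
    assert (al["observed_richness"] <= len(sub.taxon_ids)).all()
    assert (al["faith_pd"] <= total_branch_length(ds["tree"]) + 1e-9).all()
    assert (al["faith_pd"] >= 0).all()
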