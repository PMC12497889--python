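"""Phylogenetic and Raup–Crick null models, process classification."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from lakeassembly import (
    AbundanceMatrix,
    NeutralSimConfig,
    bmntd,
    bnti_pairwise,
    classify_process,
    cophenetic,
    rc_bray,
    simulate_neutral,
    simulate_tree,
    summarize_processes,
)
from lakeassembly.exceptions import FormatError, InvalidInputError
from lakeassembly.phylonull import classify_pairs


def brute_force_bmntd(x, y, d, weighted=True):
    """Nested-loop oracle for the mean nearest-taxon distance."""
    ix = [i for i in range(len(x)) if x[i] > 0]
    iy = [j for j in range(len(y)) if y[j] > 0]
    fx = [x[i] for i in ix]
    fy = [y[j] for j in iy]
    if not weighted:
        fx = [1.0] * len(ix)
        fy = [1.0] * len(iy)
    sx, sy = sum(fx), sum(fy)
    acc_x = sum(
        (w / sx) * min(d[i][j] for j in iy) for i, w in zip(ix, fx)
    )
    acc_y = sum(
        (w / sy) * min(d[i][j] for i in ix) for j, w in zip(iy, fy)
    )
    return 0.5 * (acc_x + acc_y)


class TestCophenetic:
    def test_two_tip_path_sum(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:2);"))
        ids, d = cophenetic(tree)
        assert d[ids.index("A"), ids.index("B")] == pytest.approx(3.0)

    def test_ultrametric_tips_equidistant_from_root(self):
        tree = simulate_tree(12, seed=2)
        depths = {tip.name: tip.accumulate_to_ancestor(tree) for tip in tree.tips()}
        vals = np.array(list(depths.values()))
        np.testing.assert_allclose(vals, vals[0], rtol=1e-9)

    def test_triangle_inequality_on_small_yule_trees(self):
        for seed in range(6):
            tree = simulate_tree(8, seed=seed)
            _, d = cophenetic(tree)
            n = d.shape[0]
            for i, j, k in itertools.permutations(range(n), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_branch_length_rejected(self):
        tree = TreeNode.read(io.StringIO("(A:1,(B,C:1):2);"))
        with pytest.raises(FormatError):
            cophenetic(tree)


class TestBmntd:
    def test_identical_supports_zero(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert bmntd([0.3, 0.7], [0.5, 0.5], d) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_pair(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert bmntd([1, 0], [0, 1], d) == pytest.approx(2.0)

    def test_hand_worked_three_taxon_case(self):
        # x={A}, y={B:0.5, C:0.5}; D(A,B)=2, D(A,C)=4, D(B,C)=4
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        assert bmntd([1, 0, 0], [0, 0.5, 0.5], d) == pytest.approx(2.5)

    def test_empty_community_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(InvalidInputError):
            bmntd([0, 0], [1, 0], d)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 9)
            d = rng.uniform(0.1, 5.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for weighted in (True, False):
                assert bmntd(x, y, d, weighted) == pytest.approx(
                    brute_force_bmntd(x, y, d.tolist(), weighted), abs=1e-12
                )


class TestBnti:
    def test_identical_communities_undefined(self, small_tree):
        taxa = [t.name for t in small_tree.tips()]
        row = np.arange(1, len(taxa) + 1)
        m = AbundanceMatrix(np.vstack([row, row]), ["a", "b"], taxa)
        with pytest.warns(UserWarning, match="zero null spread"):
            df = bnti_pairwise(m, small_tree, n_null=49, seed=1)
        assert not df["defined"].iloc[0]
        assert np.isnan(df["bnti"].iloc[0])

    def test_branch_length_scale_invariance(self, small_tree, neutral_matrix):
        taxa = [t.name for t in small_tree.tips()]
        sub = AbundanceMatrix(
            neutral_matrix.counts[:6, : len(taxa)], neutral_matrix.sample_ids[:6], taxa
        )
        a = bnti_pairwise(sub, small_tree, n_null=99, seed=3)
        scaled = small_tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 7.5
        b = bnti_pairwise(sub, scaled, n_null=99, seed=3)
        np.testing.assert_allclose(a["bnti"], b["bnti"], rtol=1e-9)

    def test_neutral_calibration_modest(self, neutral_matrix):
        # phylogeny-free community: |bNTI| > 2 should be rare
        tree = simulate_tree(neutral_matrix.n_taxa, seed=21)
        m = AbundanceMatrix(
            neutral_matrix.counts, neutral_matrix.sample_ids,
            [t.name for t in tree.tips()],
        )
        df = bnti_pairwise(m, tree, n_null=199, seed=5)
        assert df["defined"].all()
        assert (df["bnti"].abs() > 2).mean() <= 0.15


class TestRcBray:
    def test_identical_pair_strongly_negative(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 50, 30)
        counts = np.vstack([base, base, rng.integers(0, 50, 30)])
        m = AbundanceMatrix(counts, ["a", "b", "c"], [f"t{i}" for i in range(30)])
        df = rc_bray(m, n_null=199, seed=2)
        pair = df[(df.sample_i == "a") & (df.sample_j == "b")]["rc"].iloc[0]
        assert pair <= -0.95

    def test_single_taxon_all_ties_give_zero(self):
        m = AbundanceMatrix(np.array([[10], [20]]), ["a", "b"], ["t"])
        df = rc_bray(m, n_null=99, seed=0)
        assert df["rc"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance_and_determinism(self, neutral_matrix):
        sub = AbundanceMatrix(
            neutral_matrix.counts[:5], neutral_matrix.sample_ids[:5], neutral_matrix.taxon_ids
        )
        a = rc_bray(sub, n_null=99, seed=4)
        b = rc_bray(sub, n_null=99, seed=4)
        pd.testing.assert_frame_equal(a, b)
        perm = np.random.default_rng(0).permutation(sub.n_taxa)
        shuffled = AbundanceMatrix(
            sub.counts[:, perm], sub.sample_ids, [sub.taxon_ids[i] for i in perm]
        )
        c = rc_bray(shuffled, n_null=99, seed=4)
        np.testing.assert_allclose(a["bc_obs"], c["bc_obs"], atol=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti, rc, expected",
        [
            (3.1, None, "variable_selection"),
            (-2.5, None, "homogeneous_selection"),
            (-1.0, 0.97, "dispersal_limitation"),
            (1.2, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.5, "undominated"),  # boundary: 2 is not > 2
        ],
    )
    def test_thresholds(self, bnti, rc, expected):
        assert classify_process(bnti, rc) == expected

    def test_rc_required_in_stochastic_range(self):
        with pytest.raises(InvalidInputError):
            classify_process(0.5, None)

    def test_summary_fractions(self):
        pairs = pd.DataFrame(
            {
                "group": ["g"] * 4,
                "process": ["undominated", "undominated", "variable_selection", None],
            }
        )
        out = summarize_processes(pairs, "group")
        row = out.iloc[0]
        assert row["undominated"] == pytest.approx(2 / 3)
        assert row["variable_selection"] == pytest.approx(1 / 3)
        assert row["n_undefined"] == 1
        procs = ["variable_selection", "homogeneous_selection", "dispersal_limitation",
                 "homogenizing_dispersal", "undominated"]
        assert row[procs].sum() == pytest.approx(1.0, abs=1e-12)

    def test_classify_pairs_joins_tables(self):
        bnti_df = pd.DataFrame(
            {"sample_i": ["a"], "sample_j": ["b"], "bmntd_obs": [1.0], "bnti": [0.0],
             "defined": [True]}
        )
        rc_df = pd.DataFrame({"sample_i": ["a"], "sample_j": ["b"], "bc_obs": [0.4], "rc": [0.99]})
        merged = classify_pairs(bnti_df, rc_df)
        assert merged["process"].iloc[0] == "dispersal_limitation"
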