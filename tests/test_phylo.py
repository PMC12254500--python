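"""Newick handling, leaf-to-root distances, monophyly, and the test statistics.

The Welch, Benjamini–Hochberg and paired-t implementations are cross-checked
against independent textbook-formula oracles implemented here from scratch.
"""

import math

import numpy as np
import pytest
from scipy import stats as sps

from nrbpkit.phylo import (
    compare_clade_distances,
    is_monophyletic,
    leaf_root_distances,
    paired_score_test,
    parse_newick,
    root_at_outgroup,
)


# ---------------------------------------------------------------------------
# independent textbook oracles
# ---------------------------------------------------------------------------

def welch_oracle(x, y):
    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(pvalues):
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def paired_oracle(diffs):
    n = len(diffs)
    m = sum(diffs) / n
    sd = math.sqrt(sum((d - m) ** 2 for d in diffs) / (n - 1))
    t = m / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


class TestNewick:
    def test_parse_counts_nodes(self):
        tree = parse_newick("((A:1,B:2):0.5,C:3);")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == {"A", "B", "C"}
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internals) == 2

    def test_internal_label_read_as_support(self):
        tree = parse_newick("((A:1,B:1)100:1,C:1);")
        mono, support = is_monophyletic(tree, {"A", "B"})
        assert mono and support == 100.0

    def test_malformed_input_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_newick("((A:1,B:2):0.5,C:3")

    def test_reroot_splits_outgroup_branch_equally(self):
        tree = root_at_outgroup(parse_newick("((A:1,B:2):0.5,C:3);"), "C")
        d = leaf_root_distances(tree)
        assert d["C"] == pytest.approx(1.5)
        assert d["A"] == pytest.approx(3.0)
        assert d["B"] == pytest.approx(4.0)

    def test_missing_outgroup_errors(self):
        with pytest.raises(ValueError, match="not found"):
            root_at_outgroup(parse_newick("(A:1,B:2);"), "Z")


class TestDistances:
    @pytest.mark.parametrize("newick,expected", [
        ("(A:1,B:2);", {"A": 1.0, "B": 2.0}),
        ("((A:0.1,B:0.2):0.3,C:0.4);", {"A": 0.4, "B": 0.5, "C": 0.4}),
    ])
    def test_hand_path_sums(self, newick, expected):
        d = leaf_root_distances(parse_newick(newick))
        assert d == pytest.approx(expected)

    def test_zero_length_branches_do_not_change_distances(self):
        d = leaf_root_distances(parse_newick("((A:1,B:2):0.0,C:3);"))
        assert d == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_invariant_to_child_rotation(self):
        d1 = leaf_root_distances(parse_newick("((A:1,B:2):0.5,C:3);"))
        d2 = leaf_root_distances(parse_newick("(C:3,(B:2,A:1):0.5);"))
        assert d1 == pytest.approx(d2)

    def test_missing_branch_length_names_node(self):
        with pytest.raises(ValueError, match="branch length"):
            leaf_root_distances(parse_newick("(A:1,B);"))


class TestMonophyly:
    def test_non_clade_returns_false(self):
        tree = parse_newick("((A:1,B:1)95:1,C:1);")
        assert is_monophyletic(tree, {"A", "C"}) == (False, None)

    def test_whole_leaf_set_is_monophyletic(self):
        tree = parse_newick("((A:1,B:1)95:1,C:1);")
        mono, _ = is_monophyletic(tree, {"A", "B", "C"})
        assert mono

    def test_unknown_leaf_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(parse_newick("(A:1,B:1);"), {"A", "Z"})


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        rep = compare_clade_distances(
            {f"x{i}": v for i, v in enumerate([1.0, 2.0, 3.0])}
            | {f"y{i}": v for i, v in enumerate([1.0, 2.0, 3.0])},
            {f"x{i}": "X" for i in range(3)} | {f"y{i}": "Y" for i in range(3)},
            [("X", "Y")],
        )
        row = rep.tests.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_textbook_example(self):
        distances = {f"x{i}": v for i, v in enumerate([2.0, 4.0, 6.0])}
        distances |= {f"y{i}": v for i, v in enumerate([1.0, 2.0, 3.0])}
        assignment = {f"x{i}": "X" for i in range(3)} | {f"y{i}": "Y" for i in range(3)}
        rep = compare_clade_distances(distances, assignment, [("X", "Y")])
        row = rep.tests.iloc[0]
        assert row["t"] == pytest.approx(1.549, abs=1e-3)
        assert row["df"] == pytest.approx(2.941, abs=1e-3)

    def test_small_clade_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_clade_distances(
                {"a": 1.0, "b": 2.0, "c": 3.0},
                {"a": "X", "b": "Y", "c": "Y"},
                [("X", "Y")],
            )

    def test_matches_textbook_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, size=2)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=n1)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=n2)
            distances = {f"x{i}": v for i, v in enumerate(x)}
            distances |= {f"y{i}": v for i, v in enumerate(y)}
            assignment = {f"x{i}": "X" for i in range(n1)}
            assignment |= {f"y{i}": "Y" for i in range(n2)}
            rep = compare_clade_distances(distances, assignment, [("X", "Y")])
            row = rep.tests.iloc[0]
            t, df, p = welch_oracle(list(x), list(y))
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["df"] == pytest.approx(df, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-10)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        assert bh_oracle([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        distances = {}
        assignment = {}
        rng = np.random.default_rng(0)
        for clade in "ABCD":
            for i in range(5):
                distances[f"{clade}{i}"] = float(rng.normal(ord(clade), 1))
                assignment[f"{clade}{i}"] = clade
        rep = compare_clade_distances(
            distances, assignment, [("A", "B"), ("A", "C"), ("A", "D")]
        )
        assert rep.tests["p_adjusted"].tolist() == pytest.approx(
            bh_oracle(rep.tests["p"].tolist())
        )

    def test_adjusted_p_properties(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 12))
            p = rng.uniform(0, 1, size=m)
            adj = bh_oracle(list(p))
            from statsmodels.stats.multitest import multipletests

            package_adj = multipletests(p, method="fdr_bh")[1]
            assert package_adj == pytest.approx(adj, abs=1e-10)
            assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))
            assert all(a <= 1.0 for a in adj)
            if m == 1:
                assert adj[0] == pytest.approx(p[0])


class TestPairedScore:
    def test_constant_positive_differences_flagged_degenerate(self):
        res = paired_score_test([(2.0, 1.0), (3.0, 2.0), (4.0, 3.0), (5.0, 4.0)])
        assert res["degenerate"] and res["p"] == 0.0 and res["t"] == math.inf
        assert res["fraction_favoring_ref1"] == 1.0

    def test_symmetric_differences_give_t0_p1(self):
        res = paired_score_test([(1.0, 0.0), (0.0, 1.0), (1.0, 0.0), (0.0, 1.0)])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_textbook_example(self):
        res = paired_score_test([(2.0, 0.0), (3.0, 0.0), (4.0, 0.0)])
        t, p = paired_oracle([2.0, 3.0, 4.0])
        assert res["t"] == pytest.approx(t) and res["t"] == pytest.approx(3 * math.sqrt(3))
        assert res["p"] == pytest.approx(p)
        assert res["df"] == 2

    def test_matches_textbook_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a = rng.normal(0, 1, size=n)
            b = rng.normal(0.3, 1, size=n)
            res = paired_score_test(np.column_stack([a, b]))
            t, p = paired_oracle(list(a - b))
            assert res["t"] == pytest.approx(t, abs=1e-10)
            assert res["p"] == pytest.approx(p, abs=1e-10)
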