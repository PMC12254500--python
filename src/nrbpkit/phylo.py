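"""Divergence statistics on rooted phylogenies.

Branch lengths are amino acid substitutions per site, so the sum of branch
lengths from the root to a leaf measures how many substitutions that lineage
accumulated since the family's ancestor.  Clades (e.g. the NRBP1-like and the
faster-evolving NRBP2-like paralog clades) are compared by two-sided Welch's
t-tests on their leaf-to-root distances with Benjamini–Hochberg correction
across the tested pairs; a paired t-test compares per-sequence bit scores
against two alternative references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DivergenceReport",
    "parse_newick",
    "root_at_outgroup",
    "leaf_root_distances",
    "node_support",
    "is_monophyletic",
    "compare_clade_distances",
    "paired_score_test",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Internal-node labels are preserved (they hold bootstrap support values by
    the usual tree-inference convention).  Malformed input raises
    ``ValueError`` carrying the parser's position information.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return tree


def root_at_outgroup(tree: dendropy.Tree, outgroup_leaf: str) -> dendropy.Tree:
    """Reroot so the outgroup leaf is sister to everything else.

    The outgroup's branch length is split equally across the two child edges
    of the new root.
    """
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == outgroup_leaf:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup leaf {outgroup_leaf!r} not found in tree")
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def leaf_root_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Sum of branch lengths on the unique root-to-leaf path, per leaf."""
    distances: dict[str, float] = {}
    root = tree.seed_node

    def walk(node, acc: float) -> None:
        for child in node.child_nodes():
            if child.edge.length is None:
                label = child.taxon.label if child.taxon else (child.label or "<internal>")
                raise ValueError(f"missing branch length on edge to node {label!r}")
            d = acc + child.edge.length
            if child.is_leaf():
                distances[child.taxon.label] = d
            else:
                walk(child, d)

    walk(root, 0.0)
    return distances


def node_support(node) -> float | None:
    """Support value from an internal-node label, if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def is_monophyletic(
    tree: dendropy.Tree, leaf_labels: set[str]
) -> tuple[bool, float | None]:
    """Whether some node's descendant leaves are exactly ``leaf_labels``.

    Returns the subtending node's support value (parsed from its label) when
    monophyletic, else ``None``.
    """
    if not leaf_labels:
        raise ValueError("leaf set is empty")
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = leaf_labels - all_leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    mrca = tree.mrca(taxon_labels=list(leaf_labels))
    descendants = {l.taxon.label for l in mrca.leaf_iter()}
    if descendants == set(leaf_labels):
        return True, node_support(mrca)
    return False, None


@dataclass
class DivergenceReport:
    """Per-clade distance summaries and pairwise Welch tests with BH correction."""

    clade_stats: pd.DataFrame  # clade, n, mean, sd
    tests: pd.DataFrame  # clade_a, clade_b, t, df, p, p_adjusted, degenerate
    distances: dict[str, list[float]]


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Welch t, Welch–Satterthwaite df, two-sided p; degenerate flag."""
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0, True
        # constant but different samples: infinitely strong evidence
        return math.copysign(math.inf, x.mean() - y.mean()), float(
            len(x) + len(y) - 2
        ), 0.0, True
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue), False


def compare_clade_distances(
    distances: dict[str, float],
    assignment: dict[str, str],
    clade_pairs: list[tuple[str, str]],
) -> DivergenceReport:
    """Welch's t-tests between clade leaf-to-root distance samples.

    ``assignment`` maps leaf label to clade label; only leaves with a defined
    distance are used.  Two-sided p-values are Benjamini–Hochberg adjusted
    across the tested pairs.
    """
    samples: dict[str, list[float]] = {}
    for leaf, clade in assignment.items():
        if leaf in distances:
            samples.setdefault(clade, []).append(distances[leaf])

    stats_rows = [
        {
            "clade": clade,
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        }
        for clade, vals in sorted(samples.items())
    ]

    rows = []
    for a, b in clade_pairs:
        for clade in (a, b):
            if clade not in samples:
                raise ValueError(f"clade {clade!r} has no leaves with distances")
            if len(samples[clade]) < 2:
                raise ValueError(f"clade {clade!r} has fewer than 2 members")
        x = np.asarray(samples[a], dtype=float)
        y = np.asarray(samples[b], dtype=float)
        t, df, p, degen = _welch(x, y)
        rows.append(
            {
                "clade_a": a, "clade_b": b,
                "mean_a": float(x.mean()), "mean_b": float(y.mean()),
                "t": t, "df": df, "p": p, "degenerate": degen,
            }
        )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adjusted"] = multipletests(tests["p"], method="fdr_bh")[1]
    else:
        tests["p_adjusted"] = []
    return DivergenceReport(
        clade_stats=pd.DataFrame(stats_rows), tests=tests, distances=samples
    )


def paired_score_test(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> dict[str, float | bool]:
    """Two-sided paired t-test on per-sequence (reference1, reference2) scores.

    Returns the mean within-pair difference (ref1 − ref2), t, df = n − 1, the
    two-sided p, and the fraction of pairs favoring reference1.  All-zero
    differences give the conventional t=0, p=1; non-zero constant differences
    are flagged degenerate with p reported as 0.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (score1, score2) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    n = len(diffs)
    result: dict[str, float | bool] = {
        "n": n,
        "mean_difference": float(diffs.mean()),
        "fraction_favoring_ref1": float((diffs > 0).mean()),
        "df": float(n - 1),
        "degenerate": False,
    }
    if diffs.var(ddof=1) == 0:
        result["degenerate"] = True
        if diffs.mean() == 0:
            result["t"], result["p"] = 0.0, 1.0
        else:
            result["t"] = math.copysign(math.inf, diffs.mean())
            result["p"] = 0.0
        return result
    res = stats.ttest_rel(arr[:, 0], arr[:, 1])
    result["t"], result["p"] = float(res.statistic), float(res.pvalue)
    return result
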