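"""Independent oracles used to cross-check treekit's implementations.

These deliberately avoid treekit's own tree structures: newick is parsed
with dendropy and splits are enumerated by plain recursion over its nodes,
so agreement with the package is evidence, not tautology.
"""

from __future__ import annotations

import math

import dendropy


def _splits_of(newick: str, universe: frozenset) -> set[frozenset]:
    """All nontrivial splits of one tree, restricted to ``universe``, each as
    a frozenset of the two frozenset sides (brute-force enumeration)."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    out: set[frozenset] = set()

    def rec(node) -> set:
        if node.is_leaf():
            return {node.taxon.label}
        labels: set = set()
        for child in node.child_nodes():
            labels |= rec(child)
        if node.parent_node is not None:
            a = frozenset(x for x in labels if x in universe)
            b = universe - a
            if len(a) >= 2 and len(b) >= 2:
                out.add(frozenset({a, b}))
        return labels

    rec(tree.seed_node)
    return out


def brute_force_rf(newick_a: str, newick_b: str) -> tuple[int, int]:
    """(rf, max_rf) on the shared leaf universe by explicit enumeration."""
    leaves_a = {
        t.label for t in dendropy.Tree.get(
            data=newick_a, schema="newick",
            preserve_underscores=True).taxon_namespace}
    leaves_b = {
        t.label for t in dendropy.Tree.get(
            data=newick_b, schema="newick",
            preserve_underscores=True).taxon_namespace}
    universe = frozenset(leaves_a & leaves_b)
    sa = _splits_of(newick_a, universe)
    sb = _splits_of(newick_b, universe)
    return len(sa ^ sb), len(sa) + len(sb)


def chi2_sf_by_integration(d: float, df: int) -> float:
    """Upper tail of the chi-square distribution by numerical integration of
    the density written out from the gamma function (no scipy.stats)."""
    from scipy.integrate import quad

    if d <= 0:
        return 1.0

    def pdf(x):
        return (x ** (df / 2.0 - 1.0) * math.exp(-x / 2.0)
                / (2.0 ** (df / 2.0) * math.gamma(df / 2.0)))

    lower, _ = quad(pdf, 0, d, limit=200)
    return 1.0 - lower
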