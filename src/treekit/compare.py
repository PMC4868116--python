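"""Duplication-aware tree comparison.

This module implements the comparison engine: the species-overlap rule for
labeling gene-tree nodes as speciation or duplication events, the recursive
decomposition of a gene tree into all maximal duplication-free ("pruned")
subtrees, and three distances computed in one pass —

* the Robinson–Foulds distance (count of nontrivial splits present in exactly
  one tree, on the shared leaf universe),
* a branch congruence percentage per tree (shared splits / own splits), and
* the speciation distance between duplicated gene trees: a weighted mean of
  normalized RF over all comparable pairs of pruned subtrees from the two
  decompositions.

Trees of different size are handled by restricting to the shared leaf
universe; low-support branches can be filtered symmetrically in both trees
before any split is computed.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ComparisonError, DecompositionError, TreeError
from .tree import (Bipartition, TreeNode, collapse_low_support,
                   get_bipartitions)

#: annotation keys written by :func:`detect_duplications`
EVOL_EVENT_KEY = "evoltype"
OVERLAP_KEY = "species_overlap"


class SpeciesMap:
    """Maps gene-tree leaf labels to species labels.

    The default convention takes the substring before the first ``_`` (so
    ``HUMAN_p53a`` maps to species ``HUMAN``); labels without the delimiter
    map to themselves. An explicit table (dict or two-column TSV file)
    overrides the delimiter rule entirely.
    """

    def __init__(self, delimiter: str = "_",
                 table: dict[str, str] | None = None):
        self.delimiter = delimiter
        self.table = dict(table) if table is not None else None

    @classmethod
    def from_tsv(cls, path) -> "SpeciesMap":
        table = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise TreeError(
                        f"species map line {ln} needs two tab-separated "
                        f"columns: {line!r}")
                table[parts[0]] = parts[1]
        return cls(table=table)

    def __call__(self, leaf_label: str) -> str:
        if self.table is not None:
            try:
                return self.table[leaf_label]
            except KeyError:
                raise TreeError(
                    f"leaf {leaf_label!r} missing from species map") from None
        head, _, _ = leaf_label.partition(self.delimiter)
        return head or leaf_label


# ---------------------------------------------------------------------------
# Duplication detection and TreeKO decomposition
# ---------------------------------------------------------------------------

def detect_duplications(root: TreeNode, smap: SpeciesMap | None = None,
                        overlap_threshold: float = 0.0) -> TreeNode:
    """Annotate internal nodes as speciation ("S") or duplication ("D").

    An internal node is a duplication iff the species-overlap score — the
    Jaccard overlap ``|S(a) ∩ S(b)| / |S(a) ∪ S(b)|`` between the species
    sets under two of its children — exceeds ``overlap_threshold`` for at
    least one child pair (for binary nodes this is simply the left/right
    overlap). The default threshold 0.0 flags any shared species as a
    duplication. Returns an annotated copy; the input is untouched.
    """
    smap = smap or SpeciesMap()
    work = root.copy()
    species: dict[int, frozenset] = {}
    for node in work.traverse("postorder"):
        if node.is_leaf:
            species[id(node)] = frozenset({smap(node.name)})
            continue
        sets = [species[id(c)] for c in node.children]
        species[id(node)] = frozenset().union(*sets)
        score = 0.0
        for sa, sb in itertools.combinations(sets, 2):
            inter = len(sa & sb)
            if inter:
                score = max(score, inter / len(sa | sb))
        node.annotations[OVERLAP_KEY] = score
        node.annotations[EVOL_EVENT_KEY] = \
            "D" if score > overlap_threshold else "S"
    return work


def count_pruned_trees(root: TreeNode, smap: SpeciesMap | None = None,
                       overlap_threshold: float = 0.0) -> int:
    """Number of duplication-free subtrees the decomposition would produce,
    without materializing them (product at speciations, sum at duplications).
    """
    labeled = detect_duplications(root, smap, overlap_threshold)
    return _count(labeled)


def _count(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    counts = [_count(c) for c in node.children]
    if node.annotations.get(EVOL_EVENT_KEY) == "D":
        return sum(counts)
    prod = 1
    for c in counts:
        prod *= c
    return prod


def treeko_decompose(root: TreeNode, smap: SpeciesMap | None = None,
                     overlap_threshold: float = 0.0,
                     max_subtrees: int = 1000) -> list[TreeNode]:
    """Split a gene tree into all maximal duplication-free subtrees.

    The recursion: a leaf yields itself; a speciation node yields every
    combination of one pruned subtree per child, joined under a copy of the
    node (cartesian product); a duplication node yields the union of its
    children's pruned subtrees, each inheriting the duplication node's branch
    length so path lengths are preserved. At the default threshold 0 every
    returned subtree carries at most one leaf per species and re-testing it
    for duplications finds none.

    The product rule makes the count exponential in nested duplications, so
    enumeration is refused with an explicit error when it would exceed
    ``max_subtrees``.
    """
    if root is None:
        raise DecompositionError("cannot decompose an empty tree")
    labeled = detect_duplications(root, smap, overlap_threshold)
    total = _count(labeled)
    if total > max_subtrees:
        raise DecompositionError(
            f"decomposition would produce {total} subtrees "
            f"(> max_subtrees={max_subtrees}); raise the overlap threshold "
            f"or the limit")

    def build(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            leaf = TreeNode(node.name, node.dist)
            leaf.annotations = dict(node.annotations)
            return [leaf]
        parts = [build(c) for c in node.children]
        if node.annotations.get(EVOL_EVENT_KEY) == "D":
            out: list[TreeNode] = []
            for sub_list in parts:
                for sub in sub_list:
                    sub.dist += node.dist  # absorb the duplication edge
                    out.append(sub)
            return out
        out = []
        for combo in itertools.product(*parts):
            joined = TreeNode(node.name, node.dist, node.support)
            for sub in combo:
                joined.add_child(sub.copy())
            out.append(joined)
        return out

    pruned = build(labeled)
    for t in pruned:
        t.dist = 1.0  # subtree roots have no parent edge
        t.up = None
    return pruned


def relabel_to_species(root: TreeNode,
                       smap: SpeciesMap | None = None) -> TreeNode:
    """Copy of the tree with every leaf renamed to its species label."""
    smap = smap or SpeciesMap()
    work = root.copy()
    for leaf in work.iter_leaves():
        leaf.name = smap(leaf.name)
    return work


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Everything one tree-pair comparison produces.

    ``congruence_src``/``congruence_ref`` are percentages of each tree's own
    nontrivial splits found in the other tree; a tree contributing zero
    nontrivial splits gets ``None`` (reported as NA — agreement cannot be
    claimed from vacuity). ``treeko_speciation_dist`` is filled only by
    :func:`speciation_distance`-aware callers.
    """

    rf: int
    max_rf: int
    norm_rf: float
    congruence_src: float | None
    congruence_ref: float | None
    effective_leaves: int
    shared_splits: list[Bipartition] = field(default_factory=list)
    src_only_splits: list[Bipartition] = field(default_factory=list)
    ref_only_splits: list[Bipartition] = field(default_factory=list)
    treeko_speciation_dist: float | None = None


def _sorted_splits(splits: Iterable[Bipartition]) -> list[Bipartition]:
    return sorted(splits, key=lambda b: (tuple(sorted(b.side_a)),
                                         tuple(sorted(b.side_b))))


def rf_distance(src: TreeNode, ref: TreeNode, min_support: float = 0.0,
                universe_policy: str = "shared") -> ComparisonResult:
    """Robinson–Foulds distance and split lists on the shared leaf universe.

    Both trees are first (optionally) filtered with
    :func:`collapse_low_support` — symmetrically, the same threshold on both
    — then restricted to the intersection of their leaf sets (``shared``
    policy). ``strict`` policy instead errors on unequal leaf sets.
    Requires at least 3 shared leaves; with fewer there is no nontrivial
    split arithmetic to do.
    """
    if universe_policy not in ("shared", "strict"):
        raise ComparisonError(f"unknown universe policy: {universe_policy!r}")
    if min_support > 0:
        src = collapse_low_support(src, min_support)
        ref = collapse_low_support(ref, min_support)
    src_leaves = src.leaf_names()
    ref_leaves = ref.leaf_names()
    for name, leaves in (("source", src_leaves), ("reference", ref_leaves)):
        dupes = [n for n, c in Counter(leaves).items() if c > 1]
        if dupes:
            raise ComparisonError(
                f"duplicate leaf labels in {name} tree "
                f"({', '.join(sorted(dupes)[:5])}); map to species and use "
                f"the duplication-aware decomposition path instead")
    a, b = set(src_leaves), set(ref_leaves)
    if universe_policy == "strict" and a != b:
        raise ComparisonError(
            "strict policy: leaf sets differ "
            f"(source-only: {sorted(a - b)[:5]}, "
            f"reference-only: {sorted(b - a)[:5]})")
    universe = a & b
    if len(universe) < 3:
        raise ComparisonError(
            f"only {len(universe)} shared leaves; at least 3 are required")
    s_splits = get_bipartitions(src, universe)
    r_splits = get_bipartitions(ref, universe)
    shared = s_splits & r_splits
    src_only = s_splits - r_splits
    ref_only = r_splits - s_splits
    rf = len(src_only) + len(ref_only)
    max_rf = len(s_splits) + len(r_splits)
    norm_rf = rf / max_rf if max_rf else 0.0
    c_src = 100.0 * len(shared) / len(s_splits) if s_splits else None
    c_ref = 100.0 * len(shared) / len(r_splits) if r_splits else None
    return ComparisonResult(
        rf=rf, max_rf=max_rf, norm_rf=norm_rf,
        congruence_src=c_src, congruence_ref=c_ref,
        effective_leaves=len(universe),
        shared_splits=_sorted_splits(shared),
        src_only_splits=_sorted_splits(src_only),
        ref_only_splits=_sorted_splits(ref_only))


def branch_congruence(src: TreeNode, ref: TreeNode,
                      min_support: float = 0.0
                      ) -> tuple[float | None, float | None]:
    """Percentage of each tree's nontrivial splits found in the other.

    Both are 100 exactly when the normalized RF distance is 0; a tree with no
    nontrivial splits on the shared universe reports ``None``.
    """
    res = rf_distance(src, ref, min_support=min_support)
    return res.congruence_src, res.congruence_ref


@dataclass
class PairDetail:
    """One comparable pruned-subtree pair inside a speciation distance."""

    src_subtree: int
    ref_subtree: int
    n_shared_species: int
    norm_rf: float
    weight: float


@dataclass
class SpeciationDistanceResult:
    distance: float | None
    n_comparisons: int
    detail: list[PairDetail]
    reason: str | None = None


def speciation_distance(src: TreeNode, ref: TreeNode,
                        smap: SpeciesMap | None = None,
                        overlap_threshold: float = 0.0,
                        max_subtrees: int = 1000,
                        min_support: float = 0.0,
                        weighting: str = "shared"
                        ) -> SpeciationDistanceResult:
    """Speciation distance between two (possibly duplicated) gene trees.

    Both trees are decomposed into duplication-free subtrees and every leaf
    relabeled to its species. For each pair (one pruned subtree from each
    side) sharing at least 3 species, the normalized RF distance on the
    shared species is computed; the distance is the weighted mean over those
    pairs, with weights proportional to the pair's shared-species count
    (``weighting="uniform"`` switches to equal weights). Pairs with fewer
    than 3 shared species — or with a repeated species inside one subtree, as
    can happen above threshold 0 — carry no split information and are
    excluded from both the sum and the normalizer.
    """
    if weighting not in ("shared", "uniform"):
        raise ComparisonError(f"unknown weighting: {weighting!r}")
    smap = smap or SpeciesMap()
    if min_support > 0:
        src = collapse_low_support(src, min_support)
        ref = collapse_low_support(ref, min_support)
    src_parts = [relabel_to_species(t, smap) for t in treeko_decompose(
        src, smap, overlap_threshold, max_subtrees)]
    ref_parts = [relabel_to_species(t, smap) for t in treeko_decompose(
        ref, smap, overlap_threshold, max_subtrees)]

    detail: list[PairDetail] = []
    num = den = 0.0
    for (i, g), (j, s) in itertools.product(enumerate(src_parts),
                                            enumerate(ref_parts)):
        g_sp, s_sp = g.leaf_names(), s.leaf_names()
        if len(set(g_sp)) != len(g_sp) or len(set(s_sp)) != len(s_sp):
            continue  # repeated species: no unambiguous splits
        shared = set(g_sp) & set(s_sp)
        if len(shared) < 3:
            continue
        res = rf_distance(g, s)
        w = float(len(shared)) if weighting == "shared" else 1.0
        num += w * res.norm_rf
        den += w
        detail.append(PairDetail(i, j, len(shared), res.norm_rf, w))
    if not detail:
        return SpeciationDistanceResult(
            distance=None, n_comparisons=0, detail=[],
            reason="no pruned-subtree pair shares >= 3 species")
    for d in detail:
        d.weight /= den
    return SpeciationDistanceResult(
        distance=num / den, n_comparisons=len(detail), detail=detail)


# ---------------------------------------------------------------------------
# Gene-tree signal on a species tree
# ---------------------------------------------------------------------------

@dataclass
class BranchSupportRecord:
    """Gene-tree support summary for one reference-tree branch."""

    branch_id: int
    split: Bipartition
    support_fraction: float | None
    n_informative: float


def map_gene_tree_support(ref_species_tree: TreeNode,
                          gene_trees: Sequence[TreeNode],
                          smap: SpeciesMap | None = None,
                          min_support: float = 0.0,
                          overlap_threshold: float = 0.0,
                          max_subtrees: int = 1000
                          ) -> tuple[list[BranchSupportRecord], TreeNode]:
    """Summarize the phylogenetic signal of many gene trees on a species tree.

    Every gene tree is decomposed into duplication-free subtrees and
    relabeled to species. For each nontrivial split of the reference species
    tree, a pruned subtree is *informative* iff restricting the split to the
    subtree's species leaves at least two species on each side; among
    informative subtrees, the support fraction is the weighted share whose
    own topology contains the restricted split. Subtrees from one gene tree
    share that tree's unit weight (1/number of its subtrees), so every gene
    family contributes total weight 1 regardless of how many duplications it
    carries.

    Returns the per-branch table and a copy of the reference tree whose
    internal nodes carry ``gt_support`` / ``gt_n_informative`` annotations.
    """
    if not gene_trees:
        raise ComparisonError("gene tree list must be non-empty")
    smap = smap or SpeciesMap()
    ref = ref_species_tree.copy()
    ref_universe = set(ref.leaf_names())
    if len(ref_universe) != len(ref.leaf_names()):
        raise ComparisonError("reference species tree must be single-copy")

    weighted_parts: list[tuple[TreeNode, frozenset, float]] = []
    for gt in gene_trees:
        if min_support > 0:
            gt = collapse_low_support(gt, min_support)
        parts = treeko_decompose(gt, smap, overlap_threshold, max_subtrees)
        w = 1.0 / len(parts)
        for p in parts:
            sp_tree = relabel_to_species(p, smap)
            names = sp_tree.leaf_names()
            if len(set(names)) != len(names):
                continue
            weighted_parts.append(
                (sp_tree, frozenset(names) & frozenset(ref_universe), w))

    # stable branch ids: preorder index over internal non-root nodes
    records: list[BranchSupportRecord] = []
    branch_nodes: list[TreeNode] = []
    for node in ref.traverse("preorder"):
        if node.up is not None and not node.is_leaf:
            branch_nodes.append(node)
    seen_splits: dict[Bipartition, BranchSupportRecord] = {}
    for bid, node in enumerate(branch_nodes):
        side_a = frozenset(node.leaf_names())
        side_b = frozenset(ref_universe) - side_a
        if len(side_a) < 2 or len(side_b) < 2:
            continue
        split = Bipartition.make(side_a, side_b)
        if split in seen_splits:
            # the other edge of a degree-2 root: same unrooted split, one
            # record — but the node still gets the annotations
            prev = seen_splits[split]
            node.annotations["gt_support"] = prev.support_fraction
            node.annotations["gt_n_informative"] = prev.n_informative
            continue
        num = den = 0.0
        for sp_tree, species, w in weighted_parts:
            ra, rb = side_a & species, side_b & species
            if len(ra) < 2 or len(rb) < 2:
                continue
            den += w
            target = Bipartition.make(ra, rb)
            if target in get_bipartitions(sp_tree, universe=ra | rb):
                num += w
        frac = num / den if den > 0 else None
        record = BranchSupportRecord(
            branch_id=bid, split=split,
            support_fraction=frac, n_informative=den)
        records.append(record)
        seen_splits[split] = record
        node.annotations["gt_support"] = frac
        node.annotations["gt_n_informative"] = den
    return records, ref
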