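"""Rooted phylogenetic trees, newick I/O and topology operations.

:class:`TreeNode` is the container every other module operates on: a rooted
tree whose nodes carry a name, a branch length to the parent (``dist``), an
optional support value for the edge above internal nodes, and a free-form
``annotations`` mapping used by the taxonomy and selection-analysis layers.

Newick reading supports three dialects that differ only in how a *bare label
on an internal node* is interpreted:

``default``
    a bare numeric label in [0, 1] is read as branch support, anything else
    (including any quoted label) as the node name;
``named-internal``
    internal labels are always names;
``support-as-label``
    internal labels are parsed as support whenever they are numeric.

Branch lengths default to 1.0 when no ``:x`` suffix is present; support is
*absent* (``None``) when no label is present — absent is deliberately distinct
from 0 or 1. NHX-style comments (``[&&NHX:key=value:...]``) are parsed into
``annotations`` and can be written back out.

All topology operations (:func:`prune`, :func:`set_outgroup`,
:func:`collapse_low_support`) are pure: they return a new tree and leave the
input untouched.
"""

from __future__ import annotations

import random
import re
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import NewickError, TreeError

DIALECTS = ("default", "named-internal", "support-as-label")

#: characters that force a label to be quoted on output
_UNSAFE = set("()[]{},;:'\" \t\r\n=")

_NUMBER_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


class TreeNode:
    """One node of a rooted tree; the root is simply a node with ``up is None``.

    Children are kept in an ordered list; child order is stable under a
    serialization round-trip. Leaves are nodes with an empty child list.
    """

    __slots__ = ("name", "dist", "support", "children", "up", "annotations")

    def __init__(self, name: str = "", dist: float = 1.0,
                 support: float | None = None):
        if dist < 0:
            raise TreeError(f"branch length must be non-negative, got {dist}")
        self.name = name
        self.dist = float(dist)
        self.support = None if support is None else float(support)
        self.children: list[TreeNode] = []
        self.up: TreeNode | None = None
        self.annotations: dict = {}

    # -- structure ---------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.up is None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.up = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> "TreeNode":
        self.children.remove(child)
        child.up = None
        return child

    def copy(self) -> "TreeNode":
        """Deep copy of the subtree rooted here (annotations included)."""
        clone = TreeNode(self.name, self.dist, self.support)
        clone.annotations = dict(self.annotations)
        for c in self.children:
            clone.add_child(c.copy())
        return clone

    # -- traversal ---------------------------------------------------------

    def traverse(self, order: str = "preorder") -> Iterator["TreeNode"]:
        """Yield every node exactly once in ``preorder``, ``postorder`` or
        ``levelorder``."""
        if order == "preorder":
            stack = [self]
            while stack:
                node = stack.pop()
                yield node
                stack.extend(reversed(node.children))
        elif order == "postorder":
            stack: list[tuple[TreeNode, bool]] = [(self, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    yield node
                else:
                    stack.append((node, True))
                    for c in reversed(node.children):
                        stack.append((c, False))
        elif order == "levelorder":
            queue = deque([self])
            while queue:
                node = queue.popleft()
                yield node
                queue.extend(node.children)
        else:
            raise TreeError(f"unknown traversal order: {order!r}")

    def iter_leaves(self) -> Iterator["TreeNode"]:
        for node in self.traverse("preorder"):
            if node.is_leaf:
                yield node

    def get_leaves(self) -> list["TreeNode"]:
        return list(self.iter_leaves())

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.iter_leaves()]

    def iter_ancestors(self) -> Iterator["TreeNode"]:
        node = self.up
        while node is not None:
            yield node
            node = node.up

    def search_nodes(self, name: str) -> list["TreeNode"]:
        return [n for n in self.traverse("preorder") if n.name == name]

    # -- queries -----------------------------------------------------------

    def get_common_ancestor(self, names: Iterable[str]) -> "TreeNode":
        """Most recent common ancestor of the named leaves (or named nodes)."""
        names = list(names)
        targets: list[TreeNode] = []
        for nm in names:
            hits = self.search_nodes(nm)
            if not hits:
                raise TreeError(f"label not found in tree: {nm!r}")
            targets.extend(hits)
        return _mrca(targets)

    def get_distance(self, other: "TreeNode") -> float:
        """Sum of branch lengths on the path between two nodes of one tree."""
        upstream: dict[int, float] = {}
        d = 0.0
        node: TreeNode | None = self
        while node is not None:
            upstream[id(node)] = d
            d += node.dist
            node = node.up
        d = 0.0
        node = other
        while id(node) not in upstream:
            d += node.dist
            node = node.up
            if node is None:  # pragma: no cover - different trees
                raise TreeError("nodes do not share a common ancestor")
        return d + upstream[id(node)]

    def write(self, dialect: str = "default",
              annotations: Sequence[str] | bool | None = None) -> str:
        return write_newick(self, dialect=dialect, annotations=annotations)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)} children"
        return f"<TreeNode {self.name!r} ({kind})>"


def _mrca(nodes: Sequence[TreeNode]) -> TreeNode:
    if not nodes:
        raise TreeError("cannot take the MRCA of zero nodes")
    if len(nodes) == 1:
        return nodes[0]
    paths = []
    for n in nodes:
        path = [n, *n.iter_ancestors()]
        path.reverse()  # root .. node
        paths.append(path)
    depth = 0
    limit = min(len(p) for p in paths)
    while depth < limit and all(p[depth] is paths[0][depth] for p in paths):
        depth += 1
    if depth == 0:
        raise TreeError("nodes do not share a common ancestor")
    return paths[0][depth - 1]


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a leaf-label universe induced by one internal edge.

    Equality and hashing use the two label sets only; ``support`` is carried
    along for reporting but never compared. The lexicographically smaller side
    is always stored as ``side_a`` so equality is plain label-set equality.
    """

    side_a: frozenset
    side_b: frozenset
    support: float | None = field(default=None, compare=False)

    @staticmethod
    def make(a: Iterable[str], b: Iterable[str],
             support: float | None = None) -> "Bipartition":
        fa, fb = frozenset(a), frozenset(b)
        if fa & fb:
            raise TreeError("bipartition sides must be disjoint")
        if tuple(sorted(fa)) > tuple(sorted(fb)):
            fa, fb = fb, fa
        return Bipartition(fa, fb, support)

    def restrict(self, universe: Iterable[str]) -> "Bipartition":
        u = set(universe)
        return Bipartition.make(self.side_a & u, self.side_b & u, self.support)

    def __str__(self) -> str:
        return ("{" + ",".join(sorted(self.side_a)) + "} | {"
                + ",".join(sorted(self.side_b)) + "}")


def get_bipartitions(root: TreeNode,
                     universe: Iterable[str] | None = None) -> set[Bipartition]:
    """Nontrivial splits induced by the internal edges of ``root``.

    Each internal (non-root) edge contributes the split of the leaf universe
    into the labels below it versus the rest, *after* restriction to
    ``universe`` (default: the tree's own leaf set). Splits with fewer than
    two labels on either side are trivial and dropped. A degree-2 root's two
    edges induce the same unrooted split, so they contribute once: RF between
    differently rooted copies of one topology is 0.
    """
    leaves = root.leaf_names()
    if universe is not None:
        universe = set(universe)
        restricted = [n for n in leaves if n in universe]
    else:
        restricted = leaves
    dupes = [n for n, c in Counter(restricted).items() if c > 1]
    if dupes:
        raise TreeError(
            "duplicate leaf labels prevent split computation: "
            + ", ".join(sorted(dupes)))
    full = frozenset(restricted)
    below: dict[int, frozenset] = {}
    splits: set[Bipartition] = set()
    for node in root.traverse("postorder"):
        if node.is_leaf:
            below[id(node)] = frozenset({node.name}) if node.name in full \
                else frozenset()
        else:
            acc: set[str] = set()
            for c in node.children:
                acc |= below[id(c)]
            below[id(node)] = frozenset(acc)
            if node.up is not None:
                side = below[id(node)]
                other = full - side
                if len(side) >= 2 and len(other) >= 2:
                    splits.add(Bipartition.make(side, other, node.support))
    return splits


# ---------------------------------------------------------------------------
# Topology operations
# ---------------------------------------------------------------------------

def prune(root: TreeNode, keep: Iterable[str]) -> TreeNode:
    """Restrict a tree to the leaves in ``keep``.

    Unary internal nodes left behind are contracted with branch lengths
    summed, so leaf-to-leaf path lengths among kept leaves are preserved.
    Annotations on surviving nodes are preserved; annotations on contracted
    nodes are dropped.
    """
    keep = set(keep)
    if not keep:
        raise TreeError("keep set must contain at least one leaf label")
    present = set(root.leaf_names())
    missing = sorted(keep - present)
    if missing:
        raise TreeError("labels not found in tree: " + ", ".join(missing))

    work = root.copy()

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return node if node.name in keep else None
        survivors = [s for s in (rec(c) for c in node.children)
                     if s is not None]
        if not survivors:
            return None
        if len(survivors) == 1:
            child = survivors[0]
            child.dist += node.dist
            child.up = None
            return child
        node.children = []
        for s in survivors:
            node.add_child(s)
        return node

    if work.is_leaf:
        return work
    survivors = [s for s in (rec(c) for c in work.children) if s is not None]
    if len(survivors) == 1:
        # root contraction: the root's own dist is not part of any path
        new_root = survivors[0]
        new_root.up = None
        return new_root
    work.children = []
    for s in survivors:
        work.add_child(s)
    return work


def set_outgroup(root: TreeNode,
                 outgroup: str | Iterable[str]) -> TreeNode:
    """Re-root a tree on the edge above ``outgroup``.

    ``outgroup`` is a single node label or an iterable of leaf labels (the
    MRCA of which becomes the outgroup node). The new root splits the
    outgroup's edge at its midpoint. Leaf set, pairwise leaf-path lengths and
    the unrooted split set are all preserved.
    """
    work = root.copy()
    if isinstance(outgroup, str):
        hits = work.search_nodes(outgroup)
        if not hits:
            raise TreeError(f"outgroup not found in tree: {outgroup!r}")
        node = hits[0]
    else:
        node = work.get_common_ancestor(outgroup)
    if node is work:
        raise TreeError("cannot use the current root as outgroup")

    path = [node.up, *node.up.iter_ancestors()]  # parent .. old root
    node.up.children.remove(node)

    new_root = TreeNode(dist=1.0)
    half = node.dist / 2.0
    node.dist = half
    node.up = new_root
    new_root.children.append(node)

    prev = new_root
    carry_dist, carry_support = half, node.support
    for p in path:
        parent = p.up
        if parent is not None:
            parent.children.remove(p)
        next_dist, next_support = p.dist, p.support
        p.dist, p.support = carry_dist, carry_support
        p.up = prev
        prev.children.append(p)
        carry_dist, carry_support = next_dist, next_support
        prev = p

    old_root = path[-1]
    if len(old_root.children) == 1:
        # the old degree-2 root is now unary: merge its two incident edges
        child = old_root.children[0]
        parent = old_root.up
        child.dist += old_root.dist
        if child.support is None:
            child.support = old_root.support
        idx = parent.children.index(old_root)
        parent.children[idx] = child
        child.up = parent
    return new_root


def collapse_low_support(root: TreeNode, min_support: float) -> TreeNode:
    """Contract every internal edge whose support is below ``min_support``.

    Children of a collapsed node are lifted into its parent (forming a
    polytomy) with the collapsed branch length added to theirs, preserving
    path lengths. Edges with *absent* support are never collapsed: missing
    data is not evidence of weakness.
    """
    if not 0.0 <= min_support <= 1.0:
        raise TreeError(f"min_support must be in [0, 1], got {min_support}")
    work = root.copy()
    for node in list(work.traverse("postorder")):
        if (node.up is not None and not node.is_leaf
                and node.support is not None and node.support < min_support):
            parent = node.up
            idx = parent.children.index(node)
            for c in node.children:
                c.dist += node.dist
                c.up = parent
            parent.children[idx:idx + 1] = node.children
            node.children = []
            node.up = None
    return work


def check_monophyly(root: TreeNode, labels: Iterable[str],
                    by: str = "name") -> tuple[bool, TreeNode, set[str]]:
    """Test whether the leaves matching ``labels`` form a clean clade.

    ``by`` selects the leaf attribute matched against ``labels``: ``"name"``
    (default) or any annotation key. Returns ``(is_monophyletic, mrca_node,
    intruder_leaf_names)``; the MRCA is reported even when the group is not
    monophyletic.
    """
    labels = set(labels)
    if not labels:
        raise TreeError("labels set must be non-empty")

    def value(leaf: TreeNode):
        return leaf.name if by == "name" else leaf.annotations.get(by)

    leaves = root.get_leaves()
    targets = [lf for lf in leaves if value(lf) in labels]
    missing = labels - {value(lf) for lf in targets}
    if missing:
        raise TreeError("labels not found in tree: "
                        + ", ".join(sorted(map(str, missing))))
    mrca = _mrca(targets)
    intruders = {lf.name for lf in mrca.iter_leaves()
                 if value(lf) not in labels}
    return (not intruders, mrca, intruders)


def ladderize(root: TreeNode, ascending: bool = True) -> TreeNode:
    """Return a copy with children sorted by clade size (opt-in cosmetic)."""
    work = root.copy()
    size: dict[int, int] = {}
    for node in work.traverse("postorder"):
        size[id(node)] = 1 if node.is_leaf else \
            sum(size[id(c)] for c in node.children)
        node.children.sort(
            key=lambda c: (size[id(c)], c.name), reverse=not ascending)
    return work


def random_tree(n_leaves: int, seed: int = 0,
                label_prefix: str = "t") -> TreeNode:
    """Reproducible random rooted binary tree.

    Leaves are labeled ``<prefix>1..<prefix>n``; topology is built by random
    sequential joins; branch lengths are exponential with mean 0.1; internal
    supports are uniform on [0, 1]. The same seed always yields the same
    newick string.
    """
    if n_leaves < 1:
        raise TreeError(f"n_leaves must be >= 1, got {n_leaves}")
    rng = random.Random(seed)
    pool = [TreeNode(name=f"{label_prefix}{i + 1}",
                     dist=round(rng.expovariate(10.0), 6))
            for i in range(n_leaves)]
    while len(pool) > 1:
        a = pool.pop(rng.randrange(len(pool)))
        b = pool.pop(rng.randrange(len(pool)))
        parent = TreeNode(dist=round(rng.expovariate(10.0), 6),
                          support=round(rng.random(), 4))
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    root = pool[0]
    root.dist = 1.0
    root.support = None
    return root


def trees_equal(a: TreeNode, b: TreeNode, dist_tol: float = 1e-9) -> bool:
    """Structural equality: topology, names, supports, dists (to tolerance).

    The dist of the two *root* nodes is not compared: a root has no parent
    edge, so its dist is not part of any path.
    """
    if a.name != b.name or len(a.children) != len(b.children):
        return False
    if (a.up is not None or b.up is not None) and abs(a.dist - b.dist) > dist_tol:
        return False
    if (a.support is None) != (b.support is None):
        return False
    if a.support is not None and abs(a.support - b.support) > dist_tol:
        return False
    return all(trees_equal(ca, cb, dist_tol)
               for ca, cb in zip(a.children, b.children))


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str, dialect: str):
        self.s = text
        self.i = 0
        self.dialect = dialect

    def error(self, message: str):
        raise NewickError(message, self.i)

    def peek(self) -> str:
        while self.i < len(self.s) and self.s[self.i] in " \t\r\n":
            self.i += 1
        return self.s[self.i] if self.i < len(self.s) else ""

    def parse(self) -> TreeNode:
        root = self.parse_clade()
        if self.peek() != ";":
            self.error("expected ';' at end of newick statement")
        self.i += 1
        if self.peek():
            self.error("trailing characters after ';'")
        return root

    def parse_clade(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.i += 1
            node.add_child(self.parse_clade())
            while self.peek() == ",":
                self.i += 1
                node.add_child(self.parse_clade())
            if self.peek() != ")":
                self.error("unbalanced parentheses: expected ')'")
            self.i += 1
        label, quoted = self.parse_label()
        self.parse_comment(node)
        if self.peek() == ":":
            self.i += 1
            node.dist = self.parse_number("branch length")
            if node.dist < 0:
                self.error("negative branch length")
        self.parse_comment(node)
        _assign_label(node, label, quoted, self.dialect)
        return node

    def parse_label(self) -> tuple[str, bool]:
        c = self.peek()
        if c == "'":
            start = self.i
            self.i += 1
            out = []
            while True:
                if self.i >= len(self.s):
                    self.i = start
                    self.error("unterminated quoted label")
                ch = self.s[self.i]
                if ch == "'":
                    if self.i + 1 < len(self.s) and self.s[self.i + 1] == "'":
                        out.append("'")
                        self.i += 2
                        continue
                    self.i += 1
                    break
                out.append(ch)
                self.i += 1
            return "".join(out), True
        out = []
        while self.i < len(self.s) and self.s[self.i] not in "()[]{},;:'\" \t\r\n":
            out.append(self.s[self.i])
            self.i += 1
        return "".join(out), False

    def parse_number(self, what: str) -> float:
        self.peek()
        m = _NUMBER_RE.match(self.s, self.i)
        if not m:
            self.error(f"expected a number for {what}")
        self.i = m.end()
        return float(m.group())

    def parse_comment(self, node: TreeNode):
        if self.peek() != "[":
            return
        start = self.i
        end = self.s.find("]", self.i)
        if end < 0:
            self.error("unterminated comment")
        body = self.s[self.i + 1:end]
        self.i = end + 1
        if body.startswith("&&NHX"):
            for pair in body[5:].split(":"):
                if not pair:
                    continue
                if "=" not in pair:
                    self.i = start
                    self.error("malformed NHX tag")
                key, _, value = pair.partition("=")
                node.annotations[key] = value


def _assign_label(node: TreeNode, label: str, quoted: bool, dialect: str):
    if not label:
        return
    if node.is_leaf or quoted or dialect == "named-internal":
        node.name = label
        return
    try:
        value = float(label)
    except ValueError:
        node.name = label
        return
    if dialect == "support-as-label":
        node.support = value
    elif 0.0 <= value <= 1.0:
        node.support = value
    else:
        node.name = label


def parse_newick(text: str, dialect: str = "default") -> TreeNode:
    """Parse a single newick statement (must end with ``;``).

    Errors (unbalanced parentheses, empty input, trailing garbage) report the
    character offset of the problem.
    """
    if dialect not in DIALECTS:
        raise TreeError(f"unknown newick dialect: {dialect!r}")
    if not text or not text.strip():
        raise NewickError("empty newick string", 0)
    return _Parser(text, dialect).parse()


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def _quote_label(label: str) -> str:
    if label and not (_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _sanitize_nhx(value) -> str:
    if isinstance(value, (list, tuple)):
        value = "|".join(str(v) for v in value)
    text = str(value)
    for ch in ":=[]":
        text = text.replace(ch, "_")
    return text


def write_newick(root: TreeNode, dialect: str = "default",
                 annotations: Sequence[str] | bool | None = None) -> str:
    """Serialize a tree back to newick.

    Under the ``default`` dialect an internal node's support (when present) is
    written as its label, falling back to the name; ``named-internal`` writes
    names; ``support-as-label`` writes supports only. Floats are rendered with
    shortest round-tripping precision. ``annotations`` selects annotation keys
    to emit as an NHX comment (``True`` = all, in sorted key order).
    """
    if dialect not in DIALECTS:
        raise TreeError(f"unknown newick dialect: {dialect!r}")

    def label_of(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote_label(node.name) if node.name else ""
        if dialect == "named-internal":
            return _quote_label(node.name) if node.name else ""
        if dialect == "support-as-label":
            return _fmt_num(node.support) if node.support is not None else ""
        if node.support is not None:
            return _fmt_num(node.support)
        return _quote_label(node.name) if node.name else ""

    def nhx_of(node: TreeNode) -> str:
        if not annotations or not node.annotations:
            return ""
        keys = sorted(node.annotations) if annotations is True else \
            [k for k in annotations if k in node.annotations]
        if not keys:
            return ""
        body = ":".join(f"{k}={_sanitize_nhx(node.annotations[k])}"
                        for k in keys)
        return f"[&&NHX:{body}]"

    def rec(node: TreeNode) -> str:
        if node.children:
            inner = "(" + ",".join(rec(c) for c in node.children) + ")"
        else:
            inner = ""
        out = inner + label_of(node)
        if node.up is not None:
            out += ":" + _fmt_num(node.dist)
        return out + nhx_of(node)

    return rec(root) + ";"


def read_newick(path, dialect: str = "default") -> TreeNode:
    """Read a single-tree newick file."""
    with open(path) as fh:
        return parse_newick(fh.read(), dialect=dialect)


def iter_newick_file(path, dialect: str = "default") -> Iterator[TreeNode]:
    """Lazily yield trees from a one-newick-per-line file (blank lines and
    ``#`` comment lines skipped)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                yield parse_newick(line, dialect=dialect)
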