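"""Local taxonomy database built from NCBI taxdump-format files.

The taxdump dialect is the one NCBI distributes: fields separated by
``\\t|\\t``, rows terminated by ``\\t|``. ``nodes.dmp`` supplies the tree
(taxid, parent taxid, rank); ``names.dmp`` supplies names, with the
``scientific name`` class authoritative and every other class indexed as a
synonym; ``merged.dmp`` supplies redirects from retired taxids to their
replacements (chains are collapsed at build time, so any lookup follows at
most one hop).

All queries run against the in-memory store; an optional single-file JSON
persistence (deterministic byte-for-byte serialization) lets pipelines build
the database once and reuse it. Batch translators treat unknown ids/names as
soft failures; single-subject queries (lineage, descendants, topology on an
empty set) fail hard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import TaxonomyError
from .tree import TreeNode

_SEP = "\t|\t"


def _parse_dmp_line(line: str) -> list[str]:
    line = line.rstrip("\n").rstrip("\r")
    if line.endswith("\t|"):
        line = line[:-2]
    return line.split(_SEP)


@dataclass(frozen=True)
class TaxonRecord:
    taxid: int
    parent: int
    rank: str
    sci_name: str
    synonyms: tuple[str, ...] = ()


def _normalize(name: str) -> str:
    return " ".join(name.split()).lower()


class TaxonomyDB:
    """In-memory taxonomy store with lineage/topology query methods."""

    def __init__(self, records: dict[int, TaxonRecord],
                 merged: dict[int, int]):
        self.records = records
        self.merged = merged
        self.root = next(t for t, r in records.items() if r.parent == t)
        self.name_index: dict[str, set[int]] = {}
        for rec in records.values():
            self.name_index.setdefault(
                _normalize(rec.sci_name), set()).add(rec.taxid)
            for syn in rec.synonyms:
                self.name_index.setdefault(
                    _normalize(syn), set()).add(rec.taxid)
        self._children: dict[int, list[int]] | None = None

    # -- plumbing ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, taxid: int) -> int | None:
        """Follow a merge redirect (at most one hop); None if unknown."""
        if taxid in self.records:
            return taxid
        return self.merged.get(taxid)

    def _children_index(self) -> dict[int, list[int]]:
        if self._children is None:
            idx: dict[int, list[int]] = {}
            for tid, rec in self.records.items():
                if rec.parent != tid:
                    idx.setdefault(rec.parent, []).append(tid)
            for kids in idx.values():
                kids.sort()
            self._children = idx
        return self._children

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Deterministic single-file JSON store (stable bytes per content)."""
        payload = {
            "format": "treekit-taxdb",
            "version": 1,
            "records": {
                str(t): [r.parent, r.rank, r.sci_name, sorted(r.synonyms)]
                for t, r in sorted(self.records.items())},
            "merged": {str(o): n for o, n in sorted(self.merged.items())},
        }
        Path(path).write_text(
            json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, path) -> "TaxonomyDB":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "treekit-taxdb":
            raise TaxonomyError(f"{path}: not a treekit taxonomy store")
        records = {
            int(t): TaxonRecord(int(t), parent, rank, sci, tuple(syn))
            for t, (parent, rank, sci, syn) in payload["records"].items()}
        merged = {int(o): int(n) for o, n in payload["merged"].items()}
        return cls(records, merged)

    # -- queries -----------------------------------------------------------

    def get_lineage(self, taxid: int) -> tuple[list[int], dict[int, str]]:
        """Full lineage root→taxid plus a taxid→rank map for its elements."""
        resolved = self.resolve(taxid)
        if resolved is None:
            raise TaxonomyError(f"unknown taxid: {taxid}")
        lineage = [resolved]
        seen = {resolved}
        node = resolved
        while True:
            parent = self.records[node].parent
            if parent == node:
                break
            if parent in seen:
                raise TaxonomyError(f"cycle in taxonomy at taxid {parent}")
            lineage.append(parent)
            seen.add(parent)
            node = parent
        lineage.reverse()
        ranks = {t: self.records[t].rank for t in lineage}
        return lineage, ranks

    def translate_taxids(self, taxids: Iterable[int]
                         ) -> tuple[dict[int, str], list[int]]:
        """taxid→scientific-name map plus the list of unknown ids (soft)."""
        out: dict[int, str] = {}
        missing: list[int] = []
        for tid in taxids:
            resolved = self.resolve(tid)
            if resolved is None:
                missing.append(tid)
            else:
                out[tid] = self.records[resolved].sci_name
        return out, missing

    def translate_names(self, names: Iterable[str]
                        ) -> tuple[dict[str, list[int]], list[str]]:
        """Case-insensitive exact name→taxids map plus unmatched names."""
        out: dict[str, list[int]] = {}
        missing: list[str] = []
        for name in names:
            hits = self.name_index.get(_normalize(name))
            if hits:
                out[name] = sorted(hits)
            else:
                missing.append(name)
        return out, missing

    def get_descendants(self, taxid: int,
                        rank_filter: str | None = None) -> list[int]:
        """All strict descendants, ascending, optionally filtered by rank."""
        resolved = self.resolve(taxid)
        if resolved is None:
            raise TaxonomyError(f"unknown taxid: {taxid}")
        idx = self._children_index()
        out: list[int] = []
        stack = list(idx.get(resolved, []))
        while stack:
            tid = stack.pop()
            out.append(tid)
            stack.extend(idx.get(tid, []))
        if rank_filter is not None:
            out = [t for t in out if self.records[t].rank == rank_filter]
        return sorted(out)

    def get_topology(self, taxids: Iterable[int],
                     collapse_intermediate: bool = True
                     ) -> tuple[TreeNode, list[int]]:
        """Minimal spanning topology of the given taxids in the taxonomy.

        Leaves are the input taxids; an input taxid that is an ancestor of
        another input appears as an annotated *internal* node, not a
        duplicated leaf. Intermediate single-child taxa are contracted unless
        ``collapse_intermediate=False``. Unknown taxids are skipped (returned
        in the second element); it is an error for all of them to be unknown.
        """
        wanted: list[int] = []
        unknown: list[int] = []
        for tid in taxids:
            resolved = self.resolve(tid)
            if resolved is None:
                unknown.append(tid)
            elif resolved not in wanted:
                wanted.append(resolved)
        if not wanted:
            raise TaxonomyError("none of the requested taxids are known")
        lineages = [self.get_lineage(t)[0] for t in wanted]
        # root the result at the deepest shared lineage prefix (the LCA)
        depth = 0
        limit = min(len(ln) for ln in lineages)
        while depth < limit and len({ln[depth] for ln in lineages}) == 1:
            depth += 1
        lca_depth = depth - 1

        nodes: dict[int, TreeNode] = {}
        wanted_set = set(wanted)

        def make_node(tid: int) -> TreeNode:
            rec = self.records[tid]
            node = TreeNode(name=rec.sci_name)
            node.annotations.update(
                taxid=tid, sci_name=rec.sci_name, rank=rec.rank)
            return node

        root_tid = lineages[0][lca_depth]
        nodes[root_tid] = make_node(root_tid)
        for ln in lineages:
            for parent_tid, child_tid in zip(ln[lca_depth:], ln[lca_depth + 1:]):
                if child_tid not in nodes:
                    nodes[child_tid] = make_node(child_tid)
                    nodes[parent_tid].add_child(nodes[child_tid])
        root = nodes[root_tid]
        if collapse_intermediate:
            for node in list(root.traverse("postorder")):
                if (node.up is not None and len(node.children) == 1
                        and node.annotations["taxid"] not in wanted_set):
                    child = node.children[0]
                    child.dist += node.dist
                    parent = node.up
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.up = parent
            while (len(root.children) == 1
                   and root.annotations["taxid"] not in wanted_set):
                root = root.children[0]
                root.up = None
        return root, unknown

    def annotate_tree(self, root: TreeNode,
                      leaf_attr: str = "name") -> TreeNode:
        """Annotate a user tree with taxonomic data.

        Leaves are resolved from ``leaf_attr``: the leaf name (numeric names
        are taken as taxids, anything else looked up as a scientific name or
        synonym) or an annotation key holding a taxid. Resolvable leaves gain
        ``taxid``/``sci_name``/``rank``/``lineage``/``named_lineage``
        annotations; every internal node gains the lowest common ancestor of
        its resolvable leaves. Unresolvable leaves are annotated
        ``unresolved`` and skipped — only a tree with *zero* resolvable
        leaves is an error.
        """
        work = root.copy()
        lineages: dict[int, list[int]] = {}
        n_resolved = 0
        for leaf in work.iter_leaves():
            if leaf_attr == "name":
                raw = leaf.name
            else:
                raw = leaf.annotations.get(leaf_attr)
            tid: int | None = None
            if raw is not None:
                try:
                    tid = self.resolve(int(raw))
                except (TypeError, ValueError):
                    hits = self.name_index.get(_normalize(str(raw)))
                    if hits:
                        tid = min(hits)
                        if len(hits) > 1:
                            leaf.annotations["ambiguous_name"] = True
            if tid is None:
                leaf.annotations["unresolved"] = True
                continue
            n_resolved += 1
            rec = self.records[tid]
            lineage, _ = self.get_lineage(tid)
            lineages[id(leaf)] = lineage
            leaf.annotations.update(
                taxid=tid, sci_name=rec.sci_name, rank=rec.rank,
                lineage=list(lineage),
                named_lineage=[self.records[t].sci_name for t in lineage])
        if n_resolved == 0:
            raise TaxonomyError("no leaf could be resolved to a taxid")
        for node in work.traverse("postorder"):
            if node.is_leaf:
                continue
            member_lineages = [lineages[id(lf)] for lf in node.iter_leaves()
                               if id(lf) in lineages]
            if not member_lineages:
                continue
            depth = 0
            limit = min(len(ln) for ln in member_lineages)
            while depth < limit and len(
                    {ln[depth] for ln in member_lineages}) == 1:
                depth += 1
            lca = member_lineages[0][depth - 1]
            rec = self.records[lca]
            node.annotations.update(
                taxid=lca, sci_name=rec.sci_name, rank=rec.rank)
        return work


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def build_taxdb(nodes_file, names_file, merged_file=None,
                store_path=None) -> TaxonomyDB:
    """Build a :class:`TaxonomyDB` from taxdump-format dump files.

    Validates referential integrity (every parent must exist; every taxid
    must carry a scientific name) and collapses merge chains so redirects are
    single-hop. When ``store_path`` is given the database is also persisted
    as a deterministic JSON store; rebuilding from identical inputs yields a
    byte-identical file.
    """
    raw_nodes: dict[int, tuple[int, str]] = {}
    with open(nodes_file) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes.dmp row: {line!r}")
            raw_nodes[int(fields[0])] = (int(fields[1]), fields[2])
    if not raw_nodes:
        raise TaxonomyError(f"{nodes_file}: no taxon rows found")
    orphans = sorted(t for t, (p, _) in raw_nodes.items()
                     if p not in raw_nodes)
    if orphans:
        raise TaxonomyError(
            "parent taxid missing from nodes for: "
            + ", ".join(map(str, orphans[:10])))

    sci: dict[int, str] = {}
    synonyms: dict[int, list[str]] = {}
    with open(names_file) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 4:
                raise TaxonomyError(f"malformed names.dmp row: {line!r}")
            tid, name, _unique, name_class = (int(fields[0]), fields[1],
                                              fields[2], fields[3])
            if tid not in raw_nodes:
                continue
            if name_class == "scientific name":
                sci[tid] = name
            else:
                synonyms.setdefault(tid, []).append(name)
    unnamed = sorted(set(raw_nodes) - set(sci))
    if unnamed:
        raise TaxonomyError("taxids without a scientific name: "
                            + ", ".join(map(str, unnamed[:10])))

    merged: dict[int, int] = {}
    if merged_file is not None:
        with open(merged_file) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _parse_dmp_line(line)
                merged[int(fields[0])] = int(fields[1])
        # collapse chains so every redirect is one hop
        for old in list(merged):
            target = merged[old]
            hops = 0
            while target in merged:
                target = merged[target]
                hops += 1
                if hops > len(merged):
                    raise TaxonomyError(f"merge cycle involving taxid {old}")
            if target not in raw_nodes:
                raise TaxonomyError(
                    f"merge target {target} (from {old}) not in nodes")
            merged[old] = target

    records = {
        tid: TaxonRecord(tid, parent, rank, sci[tid],
                         tuple(sorted(synonyms.get(tid, ()))))
        for tid, (parent, rank) in raw_nodes.items()}
    db = TaxonomyDB(records, merged)
    # cycle check: every lineage must terminate
    for tid in records:
        db.get_lineage(tid)
    if store_path is not None:
        db.save(store_path)
    return db


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

#: 5-taxon fixture used throughout the test suite and documentation:
#: root(1) → Bacteria(2), Eukaryota(3) → Homo(4) → Homo sapiens(5);
#: retired taxid 6 redirects to 5.
CANONICAL_TAXA = [
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Bacteria"),
    (3, 1, "superkingdom", "Eukaryota"),
    (4, 3, "genus", "Homo"),
    (5, 4, "species", "Homo sapiens"),
]
CANONICAL_MERGES = [(6, 5)]


def synthetic_taxdump(taxa: Sequence[tuple[int, int, str, str]],
                      merges: Sequence[tuple[int, int]] = (),
                      out_dir=".") -> tuple[Path, Path, Path]:
    """Write ``nodes.dmp``/``names.dmp``/``merged.dmp`` in the exact taxdump
    dialect :func:`build_taxdb` consumes.

    ``taxa`` rows are ``(taxid, parent, rank, scientific name)``; exactly one
    row must be the root (parent == taxid) and every other row must be
    reachable from it (cycles or unknown parents are errors).
    """
    if not taxa:
        raise TaxonomyError("taxa must contain at least the root taxon")
    ids = {row[0] for row in taxa}
    if len(ids) != len(taxa):
        raise TaxonomyError("duplicate taxids in taxa")
    roots = [row[0] for row in taxa if row[1] == row[0]]
    if len(roots) != 1:
        raise TaxonomyError(
            f"taxa must contain exactly one root (parent == taxid), "
            f"found {len(roots)}")
    parent_of = {row[0]: row[1] for row in taxa}
    for tid in ids:
        if parent_of[tid] not in ids:
            raise TaxonomyError(f"unknown parent {parent_of[tid]} for {tid}")
        seen = set()
        node = tid
        while parent_of[node] != node:
            if node in seen:
                raise TaxonomyError(f"cycle in taxa at taxid {node}")
            seen.add(node)
            node = parent_of[node]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes_path = out / "nodes.dmp"
    names_path = out / "names.dmp"
    merged_path = out / "merged.dmp"
    with open(nodes_path, "w") as fh:
        for taxid, parent, rank, _name in taxa:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid, _parent, _rank, name in taxa:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    with open(merged_path, "w") as fh:
        for old, new in merges:
            fh.write(f"{old}\t|\t{new}\t|\n")
    return nodes_path, names_path, merged_path


def canonical_taxdump(out_dir) -> tuple[Path, Path, Path]:
    """Write the canonical 5-taxon fixture into ``out_dir``."""
    return synthetic_taxdump(CANONICAL_TAXA, CANONICAL_MERGES, out_dir)
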