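# treekit

A Python library and command-line tool for everyday phylogenomics at scale:
comparing phylogenetic trees (including gene trees that differ in size or
contain duplications), querying an NCBI-style taxonomy entirely offline,
running likelihood-ratio tests over fitted codon models with a
selective-pressure classification scheme, and building supermatrices from
per-gene alignments.

## What it computes

**Tree comparison.** For a pair of trees restricted to their shared leaf set,
`treekit` reports three measures in one pass:

- the **Robinson–Foulds distance** `RF = |A Δ B|`, where `A` and `B` are the
  sets of nontrivial bipartitions (splits) induced by each tree's internal
  edges, normalized by `maxRF = |A| + |B|`;
- a **branch congruence** percentage per tree, `100·|A ∩ B| / |A|`;
- the **speciation distance** for duplicated gene trees: each tree is first
  decomposed into all maximal duplication-free subtrees (duplication nodes
  are detected with the species-overlap rule — a node is a duplication iff
  its children's species sets overlap; the decomposition multiplies
  alternatives at speciation nodes and adds them at duplication nodes), and
  the distance is the shared-species-weighted mean of normalized RF over all
  subtree pairs sharing ≥ 3 species.

Alongside the numbers you get the full list of shared and conflicting
splits, optional filtering of branches below a support threshold, and a
summarizer that maps the agreement of a heterogeneous set of gene trees
(duplications included) onto each branch of a reference species tree.

**Taxonomy.** `build_taxdb` parses taxdump-format dumps (`nodes.dmp`,
`names.dmp`, `merged.dmp`) into a local store supporting taxid ↔ name
translation, full lineage tracks, rank-filtered descendants, minimal
spanning topologies of a taxon set, and annotation of user trees with
lineages and per-node LCA taxa — no network access, ever.

**Selection statistics.** Fitted codon models are compared with likelihood
ratio tests (`D = 2ΔlnL` vs χ², df = Δ parameters, Bonferroni-adjusted
across pairs) and estimates are classified for display: branch ω < 0.2
purifying, 0.2–1 relaxed, > 1 positive, ∞ saturated; site p-values < 0.01
strong, < 0.05 moderate.

**Supermatrix.** `concat_alignments` concatenates gene alignments with exact
species matching, `?`-padding for missing species, and a RAxML-style
partition table.

## Worked example

```sh
$ printf '(((a_1,b_1),(a_2,b_2)),(c_1,d_1));\n' > gene.nw
$ printf '((a_1,(b_1,c_1)),d_1);\n' > species.nw
$ treekit compare gene.nw species.nw --treeko
src_index  ref_index  effective_leaves  rf  max_rf  norm_rf  congruence_src  congruence_ref  treeko_dist  n_treeko_comparisons
0          0          4                 2   2       1        0               0               1            2
```

(columns tab-separated). The plain RF columns treat the 4 leaf labels the
two files share as the comparison universe: each restricted tree carries one
nontrivial split, they disagree, so `rf = max_rf = 2` and both congruence
percentages are 0. `--treeko` adds the duplication-aware view: the gene tree
decomposes into two duplication-free subtrees (one per `a/b` copy, each
keeping the `c_1,d_1` outgroup), both conflict with the reference topology
on their shared species, and the shared-species-weighted mean over the 2
comparable pairs is 1.

```sh
$ treekit generate taxdump --out-dir tax/      # 5-taxon demo taxonomy
$ treekit ncbiquery --taxdb tax.json --build --nodes tax/nodes.dmp \
    --names tax/names.dmp --merged tax/merged.dmp
$ treekit ncbiquery --taxdb tax.json --lineage 5
subject  lineage  named_lineage
5        1,3,4,5  root,Eukaryota,Homo,Homo sapiens
```

The lineage runs root → Eukaryota → Homo → *Homo sapiens*; retired taxid 6
resolves to 5 through the merge table.

From Python:

```python
>>> import treekit as tk
>>> res = tk.rf_distance(tk.parse_newick("((a,b),(c,d));"),
...                      tk.parse_newick("((a,c),(b,d));"))
>>> res.rf, res.max_rf, res.norm_rf
(2, 2, 1.0)
```

Two four-leaf trees in maximal conflict: each has one nontrivial split, none
shared, so the normalized distance is 1.

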