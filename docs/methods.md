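# Methods

This note documents the models and procedures treekit implements, the
choices made where conventions are genuinely open, and what the synthetic
data used by the test suite does and does not establish.

## Trees and newick dialects

Trees are rooted, ordered (child order is preserved as parsed), with a
branch length `dist` on the edge above each node (default 1.0 when the
newick carries no `:x`) and an optional support value on internal edges.
Support is *absent*, not 0 or 1, when no label is present: "unstated" and
"maximal" must stay distinguishable, and an edge with absent support is
never collapsed by the support filter — missing data is not evidence of
weakness.

Newick leaves the meaning of a bare internal label ambiguous (name vs
support). The `default` dialect reads a bare numeric internal label in
[0, 1] as support and anything else as a name, matching the most common
practice for bootstrap-annotated trees; `named-internal` and
`support-as-label` override in either direction. Quoted labels are always
names, verbatim (underscores included — no space substitution). Floats are
serialized with shortest round-tripping precision, so parse∘write is the
identity on tree values; this is property-tested on random trees of 1–64
leaves.

Duplicate leaf labels are legal in storage — gene trees have them after
species mapping — but any split-based operation rejects them loudly; the
comparison layer directs the caller to the duplication-aware path instead.

## Bipartitions and Robinson–Foulds distance

Removing one internal edge splits the leaf universe in two; splits with
fewer than two labels on a side are trivial and ignored. Splits are
computed in unrooted semantics: the two edges incident to a degree-2 root
induce the same split and count once, so RF between differently rooted
copies of one topology is 0. Trees of different size are compared on the
intersection of their leaf sets (each tree's splits are restricted to that
universe before counting); at least 3 shared leaves are required, since
smaller universes admit no nontrivial split. A `strict` policy that errors
on unequal leaf sets is available for pipelines that must not prune
silently.

`rf = |A Δ B|`, `max_rf = |A| + |B|`, `norm_rf = rf / max_rf` (0 when both
trees are stars). Branch congruence is `100·|A ∩ B| / |A|` per tree; a tree
contributing zero nontrivial splits reports NA rather than 100 — agreement
cannot be claimed from vacuity. When a support threshold is given, both
trees are filtered symmetrically before any split is computed; collapsing
can only remove splits, so `max_rf` is non-increasing in the threshold
(checked on random trees).

The implementation is cross-checked against two independent brute-force
split enumerators (one over dendropy's node structure in the test suite,
one over raw parenthesis nesting in the acceptance script).

## Species-overlap duplication detection and decomposition

Leaf labels map to species by the common `SPECIES_gene` prefix convention
(configurable delimiter, or an explicit two-column table). An internal node
is called a duplication iff the Jaccard overlap of its children's species
sets, `|S_L ∩ S_R| / |S_L ∪ S_R|`, exceeds a threshold (default 0: any
shared species implies a duplication). A polytomy is a duplication iff any
pair of its children overlaps — the consistent generalization of the binary
rule.

The decomposition into duplication-free subtrees follows the recursion
P(leaf) = {leaf}; at a speciation node, P = all combinations of one member
per child (cartesian product, joined under a copy of the node); at a
duplication node, P = the union over children, each subtree absorbing the
duplication edge's length. The subtree count therefore multiplies at
speciations and adds at duplications, which the tests verify by independent
recounting; at threshold 0 every output subtree provably carries at most
one leaf per species and re-tests duplication-free. The product rule is
exponential in nested duplications, so enumeration refuses to run (hard
error, never silent truncation) when the count would exceed
`max_subtrees = 1000` — truncation would bias any downstream distance.

## Speciation distance

Both trees are decomposed, leaves relabeled to species, and every
cross-pair of subtrees sharing at least 3 species contributes its
normalized RF on the shared species. Pairs below 3 shared species, or with
a repeated species inside a subtree (possible above threshold 0), carry no
split information and are excluded from both the numerator and the
normalizer. The distance is the weighted mean with weights proportional to
each pair's shared-species count: larger overlaps carry more topological
information. This weighting is one defensible choice among several; it is
isolated behind a `weighting` switch (`"uniform"` gives the unweighted
mean) so the convention is explicit rather than baked in. The result is
symmetric, 0 for identical single-copy trees, and reported as absent — with
the reason — when no pair qualifies.

## Gene-tree support on a species tree

To summarize the signal of a heterogeneous gene-tree sample on a reference
species tree, every gene tree is decomposed and species-relabeled; for each
nontrivial reference split, a subtree is *informative* iff restricting the
split to the subtree's species leaves ≥ 2 species per side, and supports it
iff its own topology contains the restricted split. Subtrees inherit
1/(subtrees of their gene tree) of that tree's weight, so each gene family
contributes exactly unit weight no matter how many duplications it carries;
the reported fraction is supporting weight over informative weight, with
the informative weight reported alongside so poorly sampled branches are
visible.

## Taxonomy store

The store parses the taxdump dialect exactly as NCBI ships it (fields
`\t|\t`, rows `\t|`): bit-level compatibility with real dumps while all
tests run on synthetic ones written by the same module. The `scientific
name` class is authoritative and unique per taxid; every other name class
is indexed as a synonym. Name lookup is case-insensitive with internal
whitespace collapsed — no fuzzy matching, by design. Merge chains are
collapsed at build time so every redirect is one hop. Referential integrity
(parents exist, lineages terminate, every taxid named) is enforced at build
with errors listing the offenders.

Persistence is a single JSON file with fully sorted keys and fixed
separators, so rebuilding from identical inputs is byte-identical — the
locality requirement (all queries offline) only needs an embedded store,
and a deterministic text format keeps the artifact diffable and
dependency-free.

Topology extraction returns the minimal spanning tree of the requested
taxids: intermediate single-child taxa are contracted (opt-out), and an
input taxid ancestral to another input appears as an annotated internal
node rather than a duplicated leaf. Batch translators treat unknown
ids/names as soft failures (pipelines must survive partial data);
single-subject queries fail hard. Tree annotation resolves numeric leaf
names as taxids and other names via the name index (ambiguous names take
the smallest taxid and are flagged), attaches lineage tracks to leaves and
LCA taxa to internal nodes, and only errors when *no* leaf resolves.

## Likelihood-ratio tests and classification

`D = 2(lnL_alt − lnL_null)` is referred to a χ² with df equal to the
parameter-count difference. The df is derived automatically only for pairs
in a registered nesting table (M0/M3, M1/M2, M7/M8, M0/free-ratio,
M0/b_free, b_neut/b_free, bsA1/bsA, M1/bsC); unknown pairs require an
explicit df so accidental non-nested comparisons fail loudly. Negative D —
routine optimizer noise in real fits — is clamped to 0 with a warning, not
an error. The default null distribution is the plain χ², which is
conservative for boundary nulls; a `boundary_mixture` flag applies the
50:50 point-mass/χ² mixture where appropriate. Across multiple pairs the
raw p-values are reported alongside Bonferroni-adjusted ones (simplest
defensible correction; capped at 1), and the best-fit flag uses the raw p
against α = 0.05 by default. p-values are verified to 1e-8 against a
numerical-integration oracle over df 1–10 and D 0–20, and at (D=4, df=1)
against the closed form erfc(√2) ≈ 0.0455.

Branch ω classes follow the display convention: < 0.2 purifying, [0.2, 1]
relaxed (both boundaries inclusive — "between 0.2 and 1" read as the closed
interval, documented here as the tie-break), > 1 positive, ∞ saturated
(dS ≈ 0). Site significance: p < 0.01 strong, p < 0.05 moderate, else ns.

Running CodeML/SLR and parsing their native outputs is out of scope; fits
enter through a versioned three-section TSV (header, per-branch ω with an
`inf` token, strictly increasing per-site records) whose reader reports
line numbers on every malformed row.

## Supermatrix

Species are matched across partitions by exact label only. Missing species
under the union policy are padded with `?`, not `-`: downstream inference
tools distinguish "no data" from "alignment gap". Partition ranges are
1-based inclusive, contiguous by construction, and written as RAxML-style
lines or TSV. Conservation laws (total length, per-species characters,
contiguous coverage) are property-tested on randomized inputs. The
intersection policy errors on an empty species intersection, and mixing
nucleotide with amino-acid partitions is an error rather than a coercion.

## Synthetic data and what the tests show

All fixtures are generated in code: random binary trees (sequential random
joins; exponential branch lengths with mean 0.1, a typical substitutions
per-site scale for single-gene trees; uniform supports), random gene trees
(random species assignment over 3–7 species with up to ~32 leaves), the
canonical 5-taxon taxonomy (root; Bacteria; Eukaryota → Homo → *Homo
sapiens*; retired taxid 6 → 5), random taxonomies up to 2,000 nodes, and
randomized alignments. These exercise the combinatorial machinery
exhaustively at small size, where brute-force oracles are feasible, and the
problem sizes keep the whole suite under a few seconds. They do not emulate
real estimation noise: supports are not bootstrap-derived, branch lengths
are independent of topology, and model fits are constructed rather than
optimized — so passing tests certify the combinatorics and the statistics
on stated inputs, not the behavior of upstream inference tools.

## Known limitations

- NEXUS/phyloXML I/O, tree drawing and branch-length re-estimation are out
  of scope; newick (with NHX annotation tags) is the only tree format.
- The speciation-distance weighting and the <3-shared-species exclusion are
  this package's documented conventions; other implementations of the same
  family of distances may choose differently.
- The branch-score / quartet distances and a strict variant of the
  duplication-aware distance are not implemented.
- Name matching in the taxonomy is exact (case/whitespace-normalized);
  misspelled taxa do not resolve.
- The parser is recursive; pathological trees nested deeper than ~900
  levels would need a raised recursion limit.
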