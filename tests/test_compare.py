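"""Duplication detection, decomposition and distance tests."""

import random

import pytest

import _oracles
from treekit import (ComparisonError, DecompositionError, SpeciesMap,
                     branch_congruence, count_pruned_trees,
                     detect_duplications, map_gene_tree_support,
                     parse_newick, random_tree,
                     rf_distance, speciation_distance, treeko_decompose,
                     trees_equal, write_newick)
from treekit.compare import EVOL_EVENT_KEY, OVERLAP_KEY


def events(tree):
    return {tuple(sorted(n.leaf_names())): n.annotations[EVOL_EVENT_KEY]
            for n in tree.traverse("preorder") if not n.is_leaf}


class TestSpeciesMap:
    def test_default_prefix_rule(self):
        smap = SpeciesMap()
        assert smap("HUMAN_p53") == "HUMAN"
        assert smap("nodelimiter") == "nodelimiter"

    def test_explicit_table_overrides(self):
        smap = SpeciesMap(table={"g1": "human"})
        assert smap("g1") == "human"
        with pytest.raises(Exception, match="missing"):
            smap("unmapped")

    def test_tsv_table(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("g1\thuman\ng2\tmouse\n")
        smap = SpeciesMap.from_tsv(p)
        assert smap("g2") == "mouse"


class TestDetectDuplications:
    def test_root_duplication_children_speciations(self):
        t = detect_duplications(parse_newick("((a_1,b_1),(a_2,b_2));"))
        ev = events(t)
        assert ev[("a_1", "a_2", "b_1", "b_2")] == "D"
        assert ev[("a_1", "b_1")] == "S" and ev[("a_2", "b_2")] == "S"
        root = next(n for n in t.traverse("preorder") if n.is_root)
        assert root.annotations[OVERLAP_KEY] == pytest.approx(1.0)

    def test_single_copy_tree_has_no_duplications(self):
        t = detect_duplications(parse_newick("((a_1,b_1),(c_1,d_1));"))
        assert set(events(t).values()) == {"S"}

    def test_nested_duplication_below_speciation_root(self):
        t = detect_duplications(parse_newick("(((a_1,b_1),(a_2,b_2)),c_1);"))
        ev = events(t)
        assert ev[("a_1", "a_2", "b_1", "b_2", "c_1")] == "S"
        assert ev[("a_1", "a_2", "b_1", "b_2")] == "D"

    def test_overlap_threshold_raises_duplication_bar(self):
        # root overlap 1/3 (shares a; union a,b,c)
        nwk = "((a_1,b_1),(a_2,c_1));"
        assert events(detect_duplications(nwk_t := parse_newick(nwk)))[
            ("a_1", "a_2", "b_1", "c_1")] == "D"
        t = detect_duplications(nwk_t, overlap_threshold=0.5)
        assert events(t)[("a_1", "a_2", "b_1", "c_1")] == "S"

    def test_polytomy_any_pair_overlap(self):
        t = detect_duplications(parse_newick("(a_1,b_1,(x_1,x_2));"))
        ev = events(t)
        assert ev[("a_1", "b_1", "x_1", "x_2")] == "S"
        assert ev[("x_1", "x_2")] == "D"

    def test_input_not_mutated(self):
        t = parse_newick("((a_1,b_1),(a_2,b_2));")
        detect_duplications(t)
        assert all(EVOL_EVENT_KEY not in n.annotations
                   for n in t.traverse("preorder"))


class TestTreekoDecompose:
    def test_root_duplication_splits_in_two(self):
        parts = treeko_decompose(parse_newick("((a_1,b_1),(a_2,b_2));"))
        assert sorted(sorted(p.leaf_names()) for p in parts) == [
            ["a_1", "b_1"], ["a_2", "b_2"]]

    def test_single_copy_identity(self):
        t = parse_newick("((a_1:1,b_1:2)0.9:1,(c_1:1,d_1:1)0.8:2);")
        parts = treeko_decompose(t)
        assert len(parts) == 1
        assert trees_equal(parts[0], t)

    def test_duplication_under_speciation_copies_outgroup(self):
        parts = treeko_decompose(parse_newick("(((a_1,b_1),(a_2,b_2)),c_1);"))
        assert sorted(sorted(p.leaf_names()) for p in parts) == [
            ["a_1", "b_1", "c_1"], ["a_2", "b_2", "c_1"]]

    @pytest.mark.parametrize("seed", range(5))
    def test_count_law_product_at_speciation_sum_at_duplication(self, seed):
        gt = _random_gene_tree(seed, n_leaves=16, n_species=5)
        labeled = detect_duplications(gt)

        def recount(node):
            if node.is_leaf:
                return 1
            vals = [recount(c) for c in node.children]
            if node.annotations[EVOL_EVENT_KEY] == "D":
                return sum(vals)
            out = 1
            for v in vals:
                out *= v
            return out

        expected = recount(labeled)
        assert count_pruned_trees(gt) == expected
        if expected <= 1000:
            assert len(treeko_decompose(gt)) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_every_pruned_tree_is_duplication_free(self, seed):
        gt = _random_gene_tree(seed + 50, n_leaves=12, n_species=4)
        if count_pruned_trees(gt) > 1000:
            pytest.skip("explosive fixture")
        for p in treeko_decompose(gt):
            relabeled = detect_duplications(p)
            assert "D" not in events(relabeled).values()
            species = [SpeciesMap()(x) for x in p.leaf_names()]
            assert len(species) == len(set(species))

    def test_explosion_guard(self):
        # 8 stacked two-copy duplications of a 3-species core: counts multiply
        core = "((a_1,b_1),c_1)"
        nwk = core
        for _ in range(8):
            nwk = f"({nwk},{nwk})"
        with pytest.raises(DecompositionError, match="max_subtrees"):
            treeko_decompose(parse_newick(nwk + ";"), max_subtrees=100)

    def test_branch_lengths_retained(self):
        t = parse_newick("((a_1:1,b_1:2)0.7:3,(a_2:4,b_2:5)0.6:6);")
        parts = treeko_decompose(t)
        by_leaf = {p.leaf_names()[0]: p for p in parts}
        first = by_leaf["a_1"]
        assert first.search_nodes("a_1")[0].dist == 1.0
        assert first.search_nodes("b_1")[0].dist == 2.0


def _random_gene_tree(seed, n_leaves, n_species):
    """Random topology whose leaves are random species copies."""
    rng = random.Random(seed)
    t = random_tree(n_leaves, seed=seed)
    counters = {}
    for leaf in t.iter_leaves():
        sp = f"sp{rng.randrange(n_species)}"
        counters[sp] = counters.get(sp, 0) + 1
        leaf.name = f"{sp}_{counters[sp]}"
    return t


class TestRFDistance:
    def test_identity(self):
        t = parse_newick("((a,b),(c,(d,e)));")
        res = rf_distance(t, t)
        assert (res.rf, res.norm_rf) == (0, 0.0)
        assert res.congruence_src == res.congruence_ref == 100.0
        assert res.src_only_splits == res.ref_only_splits == []

    def test_maximally_different_quartets(self):
        res = rf_distance(parse_newick("((a,b),(c,d));"),
                          parse_newick("((a,c),(b,d));"))
        assert (res.rf, res.max_rf, res.norm_rf) == (2, 2, 1.0)
        assert res.congruence_src == res.congruence_ref == 0.0

    def test_different_sizes_use_shared_universe(self):
        src = parse_newick("(((a,b),c),(d,e));")     # 5 leaves
        ref = parse_newick("((a,b),(c,d));")         # 4 leaves
        res = rf_distance(src, ref)
        assert res.effective_leaves == 4
        # src restricted to {a,b,c,d} has the single split ab|cd: identical
        assert res.rf == 0 and res.max_rf == 2

    def test_symmetry(self):
        a = parse_newick("(((a,b),c),(d,e));")
        b = parse_newick("((a,(b,c)),(d,e));")
        r1, r2 = rf_distance(a, b), rf_distance(b, a)
        assert r1.rf == r2.rf and r1.max_rf == r2.max_rf
        assert r1.congruence_src == r2.congruence_ref
        assert r1.src_only_splits == r2.ref_only_splits

    def test_strict_policy_requires_equal_leaf_sets(self):
        with pytest.raises(ComparisonError, match="strict"):
            rf_distance(parse_newick("(((a,b),c),d);"),
                        parse_newick("((a,b),(c,e));"),
                        universe_policy="strict")

    def test_fewer_than_three_shared_leaves(self):
        with pytest.raises(ComparisonError, match="shared leaves"):
            rf_distance(parse_newick("((a,b),(x,y));"),
                        parse_newick("((a,b),(p,q));"))

    def test_duplicate_labels_direct_caller_to_decomposition(self):
        with pytest.raises(ComparisonError, match="duplication-aware"):
            rf_distance(parse_newick("((a,a),(b,c));"),
                        parse_newick("((a,b),(c,d));"))

    def test_min_support_filter_applied_to_both_trees(self):
        src = parse_newick("(((a,b)0.2,c)0.9,(d,e)0.9);")
        ref = parse_newick("(((a,c)0.3,b)0.9,(d,e)0.9);")
        noisy = rf_distance(src, ref)
        filtered = rf_distance(src, ref, min_support=0.5)
        assert noisy.rf == 2
        assert filtered.rf == 0       # the conflicting splits are collapsed
        assert filtered.max_rf < noisy.max_rf

    @pytest.mark.parametrize("pair_seed", range(30))
    def test_matches_brute_force_oracle(self, pair_seed):
        n1 = 4 + pair_seed % 5
        n2 = 4 + (pair_seed // 5) % 5
        a = random_tree(n1, seed=pair_seed)
        b = random_tree(n2, seed=1000 + pair_seed)
        res = rf_distance(a, b)
        rf, max_rf = _oracles.brute_force_rf(write_newick(a),
                                             write_newick(b))
        assert (res.rf, res.max_rf) == (rf, max_rf)


class TestBranchCongruence:
    def test_identical_trees(self):
        t = parse_newick("((a,b),(c,d));")
        assert branch_congruence(t, t) == (100.0, 100.0)

    def test_disjoint_quartets(self):
        assert branch_congruence(parse_newick("((a,b),(c,d));"),
                                 parse_newick("((a,c),(b,d));")) == (0.0, 0.0)

    def test_half_agreement(self):
        src = parse_newick("((((a,b),c),d),e);")
        ref = parse_newick("((((a,b),d),c),e);")
        assert branch_congruence(src, ref) == (50.0, 50.0)

    def test_star_tree_reports_undefined(self):
        star = parse_newick("(a,b,c,d);")
        ref = parse_newick("((a,b),(c,d));")
        c_src, c_ref = branch_congruence(star, ref)
        assert c_src is None and c_ref == 0.0


class TestSpeciationDistance:
    def test_identity_single_copy(self):
        t = parse_newick("((a_1,b_1),(c_1,d_1));")
        res = speciation_distance(t, t)
        assert res.distance == 0.0 and res.n_comparisons == 1

    def test_no_comparable_pair_reports_reason(self):
        src = parse_newick("((a_1,b_1),(a_2,b_2));")
        ref = parse_newick("(a_1,b_1);")
        res = speciation_distance(src, ref)
        assert res.distance is None and res.n_comparisons == 0
        assert "3 species" in res.reason

    def test_weighted_mean_over_pruned_pairs(self):
        src = parse_newick("(((a_1,b_1),c_1),((a_2,c_2),b_2));")
        ref = parse_newick("((a_1,b_1),c_1);")
        res = speciation_distance(src, ref)
        # two pruned trees: ((a,b),c) agrees (norm_rf 0, rooted triplet has
        # one nontrivial rooted... on 3 species there are no nontrivial
        # splits, so both pairs give norm_rf 0
        assert res.n_comparisons == 2
        assert res.distance == pytest.approx(0.0)

    def test_conflicting_quartets_give_distance_one(self):
        src = parse_newick("((a_1,b_1),(c_1,d_1));")
        ref = parse_newick("((a_1,c_1),(b_1,d_1));")
        res = speciation_distance(src, ref)
        assert res.distance == pytest.approx(1.0)

    def test_symmetry(self):
        src = parse_newick("(((a_1,b_1),(a_2,b_2)),(c_1,d_1));")
        ref = parse_newick("((a_1,(b_1,c_1)),d_1);")
        r1 = speciation_distance(src, ref)
        r2 = speciation_distance(ref, src)
        assert r1.n_comparisons == r2.n_comparisons
        assert r1.distance == pytest.approx(r2.distance)

    def test_shared_weighting_versus_uniform(self):
        # one pruned pair shares 4 species (conflict), another shares 3
        # (agreement): shared-weighting must weight the conflict 4/7
        src = parse_newick("(((a_1,b_1),(c_1,d_1)),((a_2,c_2),b_2));")
        ref = parse_newick("((a_1,c_1),(b_1,d_1));")
        shared = speciation_distance(src, ref)
        uniform = speciation_distance(src, ref, weighting="uniform")
        assert shared.n_comparisons == uniform.n_comparisons == 2
        assert shared.distance == pytest.approx(4 / 7)
        assert uniform.distance == pytest.approx(0.5)

    def test_weights_sum_to_one(self):
        src = parse_newick("(((a_1,b_1),(a_2,b_2)),(c_1,d_1));")
        ref = parse_newick("((a_1,b_1),(c_1,d_1));")
        res = speciation_distance(src, ref)
        assert sum(d.weight for d in res.detail) == pytest.approx(1.0)


class TestMapGeneTreeSupport:
    REF = "((a,b),(c,d));"

    def test_perfect_agreement(self):
        ref = parse_newick(self.REF)
        genes = [parse_newick("((a_1,b_1),(c_1,d_1));")] * 3
        records, annotated = map_gene_tree_support(ref, genes)
        assert records and all(
            r.support_fraction == pytest.approx(1.0) for r in records)
        internal = [n for n in annotated.traverse("preorder")
                    if not n.is_leaf and n.up is not None]
        assert all(n.annotations["gt_support"] == pytest.approx(1.0)
                   for n in internal)

    def test_split_agreement_fraction(self):
        ref = parse_newick(self.REF)
        genes = [parse_newick("((a_1,b_1),(c_1,d_1));"),
                 parse_newick("((a_1,c_1),(b_1,d_1));")]
        records, _ = map_gene_tree_support(ref, genes)
        (rec,) = [r for r in records
                  if r.split.side_a in ({"a", "b"}, {"c", "d"})]
        assert rec.support_fraction == pytest.approx(0.5)
        assert rec.n_informative == pytest.approx(2.0)

    def test_missing_species_excluded_from_denominator(self):
        ref = parse_newick("((a,b),(c,d));")
        genes = [parse_newick("((a_1,b_1),(c_1,d_1));"),
                 parse_newick("((a_1,b_1),d_1);")]  # lacks c, side {c,d}<2
        records, _ = map_gene_tree_support(ref, genes)
        (rec,) = records
        assert rec.n_informative == pytest.approx(1.0)
        assert rec.support_fraction == pytest.approx(1.0)

    def test_duplicated_family_contributes_unit_weight(self):
        ref = parse_newick("((a,b),(c,d));")
        dup = parse_newick("(((a_1,b_1),(c_1,d_1)),((a_2,c_2),(b_2,d_2)));")
        records, _ = map_gene_tree_support(ref, [dup])
        (rec,) = records
        # two pruned subtrees with weight 1/2 each: one agrees, one conflicts
        assert rec.n_informative == pytest.approx(1.0)
        assert rec.support_fraction == pytest.approx(0.5)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ComparisonError, match="non-empty"):
            map_gene_tree_support(parse_newick(self.REF), [])
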