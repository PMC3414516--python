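"""Trees, duplicate pairs, ancestral lineages, mechanisms and fates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpsevol import (
    PhyloTree,
    ProteinAlignment,
    bootstrap_support,
    classify_duplicate_fate,
    classify_duplication_mechanism,
    count_ancestral_lineages,
    find_species_duplicate_pairs,
    jtt_distance,
    jtt_distance_matrix,
    nj_tree,
    simulate_expression_matrix,
)
from tpsevol.errors import TpsEvolError, TreeDataMismatchError
from tpsevol.family import DuplicatePair, _jtt


class TestJTTDistance:
    def test_identical_sequences(self):
        assert jtt_distance("MKVLANW", "MKVLANW") == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        aa = "ARNDCQEGHILKMFPSTWYV"
        s1 = "".join(rng.choice(list(aa), 150))
        s2 = "".join(
            c if rng.random() > 0.2 else rng.choice(list(aa))
            for c in s1
        )
        # agreement to the optimizer's own tolerance
        assert jtt_distance(s1, s2) == pytest.approx(
            jtt_distance(s2, s1), abs=1e-6
        )

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        aa = "ARNDCQEGHILKMFPSTWYV"
        s1 = "".join(rng.choice(list(aa), 200))
        s2 = "".join(
            c if rng.random() > 0.25 else rng.choice(list(aa))
            for c in s1
        )
        est = jtt_distance(s1, s2)
        model = _jtt()
        ai = np.array([aa.index(c) for c in s1])
        bi = np.array([aa.index(c) for c in s2])
        grid = np.arange(1e-4, 2.0, 1e-4)
        nll = [
            -np.log(model.P(t)[ai, bi]).sum() for t in grid
        ]
        t_grid = grid[int(np.argmin(nll))]
        assert est == pytest.approx(t_grid, abs=2e-4)

    def test_no_comparable_columns_raises(self):
        with pytest.raises(TpsEvolError):
            jtt_distance("M---", "-KVL")


class TestNJ:
    def test_additive_quartet_recovered(self):
        # tree ((a:2,b:3):1,(c:4,d:5)); path distances are additive
        ids = list("abcd")
        D = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        t = nj_tree(D, ids)
        assert t.bipartition_sets() == {frozenset("ab")}
        lengths = {
            lf.taxon.label: lf.edge.length
            for lf in t.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)

    def test_three_taxon_closed_form(self):
        D = np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float
        )
        t = nj_tree(D, list("abc"))
        lengths = {
            lf.taxon.label: lf.edge.length
            for lf in t.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    @given(st.permutations(list(range(5))))
    @settings(max_examples=20, deadline=None)
    def test_input_order_invariance(self, perm):
        """Permuting taxa must not change the unrooted topology."""
        # caterpillar (((a:1,b:1):1,c:2):1,(d:1,e:1):1) path metric
        ids = list("abcde")
        D0 = np.array(
            [
                [0, 2, 4, 5, 5],
                [2, 0, 4, 5, 5],
                [4, 4, 0, 5, 5],
                [5, 5, 5, 0, 2],
                [5, 5, 5, 2, 0],
            ],
            dtype=float,
        )
        ref = nj_tree(D0, ids).bipartition_sets()
        pids = [ids[i] for i in perm]
        Dp = D0[np.ix_(perm, perm)]
        assert nj_tree(Dp, pids).bipartition_sets() == ref

    def test_rejects_bad_input(self):
        with pytest.raises(TpsEvolError):
            nj_tree(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["a", "b"])


@pytest.fixture(scope="module")
def treelike_alignment():
    """Protein data simulated on a 6-taxon tree with long branches:
    clean signal, so every split should reach 100% support."""
    from tpsevol import SimulationSpec, simulate_codon_alignment
    from tpsevol.simulate import balanced_tree
    from tpsevol._codons import CODON_TO_AA

    tree = balanced_tree(6, depth=0.8)
    ca, _ = simulate_codon_alignment(
        SimulationSpec(
            tree=tree, kappa=2.0,
            omega_by_class={"background": 0.5},
            n_codons=400, seed=13,
        )
    )
    return ProteinAlignment(
        ids=list(ca.ids),
        rows=["".join(CODON_TO_AA[c] for c in r) for r in ca.rows],
    )


class TestBootstrap:
    def test_clean_signal_gives_full_support(self, treelike_alignment):
        t = bootstrap_support(treelike_alignment, n_reps=20, seed=1)
        supports = [
            int(n.label)
            for n in t.tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_support_binary(self, treelike_alignment):
        t = bootstrap_support(treelike_alignment, n_reps=1, seed=5)
        supports = [
            int(n.label)
            for n in t.tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert set(supports) <= {0, 100}

    def test_same_seed_same_supports(self, treelike_alignment):
        def supports(seed):
            t = bootstrap_support(treelike_alignment, n_reps=5, seed=seed)
            return [
                n.label
                for n in t.tree.preorder_node_iter()
                if not n.is_leaf()
            ]

        assert supports(7) == supports(7)


class TestDuplicatePairs:
    def test_no_same_species_cherries(self):
        t = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        pairs, _ = find_species_duplicate_pairs(
            t, {"a": "s1", "b": "s2", "c": "s1", "d": "s2"}
        )
        assert pairs == []

    def test_single_cherry_found(self):
        t = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        pairs, _ = find_species_duplicate_pairs(
            t, {"a": "s1", "b": "s1", "c": "s2"}
        )
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]

    def test_polytomy_reported_unresolved(self):
        t = PhyloTree.from_newick("((a:1,b:1,c:1):1,d:1);")
        pairs, unresolved = find_species_duplicate_pairs(
            t, {"a": "s1", "b": "s1", "c": "s1", "d": "s2"}
        )
        assert pairs == []
        assert unresolved == [["a", "b", "c"]]

    def test_invariant_to_rotation(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        t2 = PhyloTree.from_newick("(c:1,(b:1,a:1):1);")
        sp = {"a": "s1", "b": "s1", "c": "s2"}
        p1, _ = find_species_duplicate_pairs(t1, sp)
        p2, _ = find_species_duplicate_pairs(t2, sp)
        assert [(p.gene_a, p.gene_b) for p in p1] == [
            (p.gene_a, p.gene_b) for p in p2
        ]


class TestAncestralLineages:
    SIDES = {"r1": "monocot", "r2": "monocot", "r3": "monocot",
             "d1": "dicot", "d2": "dicot", "d3": "dicot"}

    def test_two_orthologous_groups(self):
        t = PhyloTree.from_newick("((r1:1,d1:1):1,(r2:1,d2:1):1);")
        n, groups = count_ancestral_lineages(t, self.SIDES)
        assert n == 2
        assert sorted(g["members"] for g in groups) == [
            ["d1", "r1"], ["d2", "r2"]
        ]

    def test_single_side_tree_one_group(self):
        t = PhyloTree.from_newick("((r1:1,r2:1):1,r3:1);")
        assert count_ancestral_lineages(t, self.SIDES)[0] == 1

    def test_one_sided_subclade_counts_separately(self):
        # dicot-only clade sister to a mixed clade: the dicot-only clade
        # is its own ancestral lineage (gene lost on the monocot side)
        t = PhyloTree.from_newick(
            "(((r1:1,d1:1):1,(d2:1,d3:1):1):1,r2:2);"
        )
        n, _ = count_ancestral_lineages(t, self.SIDES)
        assert n == 3

    def test_outgroup_excluded(self):
        t = PhyloTree.from_newick("(((r1:1,d1:1):1,r2:1):1,OtsA:3);")
        n, _ = count_ancestral_lineages(
            t, self.SIDES, outgroup="OtsA"
        )
        assert n == 2

    def test_unmapped_leaf_raises(self):
        t = PhyloTree.from_newick("((r1:1,d1:1):1,zzz:1);")
        with pytest.raises(TreeDataMismatchError):
            count_ancestral_lineages(t, self.SIDES)

    def test_pruning_a_group_reduces_count_by_one(self):
        t = PhyloTree.from_newick("((r1:1,d1:1):1,(r2:1,d2:1):1);")
        n_full, groups = count_ancestral_lineages(t, self.SIDES)
        drop = set(groups[0]["members"])
        pruned = t.subtree_for_leaves(
            [x for x in t.leaf_ids if x not in drop]
        )
        n_pruned, _ = count_ancestral_lineages(pruned, self.SIDES)
        assert n_pruned == n_full - 1


class TestMechanism:
    GT = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "species": ["p"] * 5,
            "side": ["dicot"] * 5,
            "chromosome": ["chr1", "chr1", "chr2", "chr9", "chr14"],
            "start": [10_000, 25_000, 500_000, 100_000, 200_000],
            "end": [15_000, 30_000, 505_000, 105_000, 205_000],
            "strand": ["+"] * 5,
            "class": ["I"] * 5,
        }
    )

    def test_tandem_call(self):
        p = DuplicatePair("g1", "g2", "p")
        assert classify_duplication_mechanism(p, self.GT) == "tandem"

    def test_block_table_call(self):
        p = DuplicatePair("g4", "g5", "p")
        blocks = [
            {
                "regionA": ("chr9", 1, 1_000_000),
                "regionB": ("chr14", 1, 1_000_000),
            }
        ]
        assert (
            classify_duplication_mechanism(p, self.GT, blocks)
            == "whole_genome_block"
        )
        blocks[0]["kind"] = "segmental"
        assert (
            classify_duplication_mechanism(p, self.GT, blocks)
            == "segmental"
        )

    def test_no_evidence_unknown(self):
        p = DuplicatePair("g1", "g3", "p")
        assert classify_duplication_mechanism(p, self.GT) == "unknown"

    def test_missing_coordinates_unknown(self):
        gt = self.GT.copy()
        gt.loc[0, "chromosome"] = None
        p = DuplicatePair("g1", "g2", "p")
        assert classify_duplication_mechanism(p, gt) == "unknown"


class TestFates:
    CONDS = [f"c{i}" for i in range(5)]

    def _em(self, a_on, b_on):
        calls = {}
        for g, on in (("ga", a_on), ("gb", b_on)):
            calls[g] = {
                c: ("expressed" if c in on else "not_expressed")
                for c in self.CONDS
            }
        from tpsevol import ExpressionMatrix

        return ExpressionMatrix(["ga", "gb"], self.CONDS, calls)

    def pair(self):
        return DuplicatePair("ga", "gb", "p")

    def test_both_everywhere_shared(self):
        em = self._em(set(self.CONDS), set(self.CONDS))
        assert classify_duplicate_fate(self.pair(), em) == "shared_expression"

    def test_one_silent_nonfunctionalization(self):
        em = self._em(set(self.CONDS), set())
        assert (
            classify_duplicate_fate(self.pair(), em)
            == "nonfunctionalization_candidate"
        )

    def test_broad_vs_subset_subfunctionalization(self):
        em = self._em(set(self.CONDS), {"c0"})
        assert (
            classify_duplicate_fate(self.pair(), em)
            == "subfunctionalization_candidate"
        )

    def test_incomparable_patterns_divergent(self):
        em = self._em({"c0", "c1"}, {"c2", "c3"})
        assert classify_duplicate_fate(self.pair(), em) == "divergent"

    def test_absent_gene_unknown(self):
        em = self._em(set(self.CONDS), set(self.CONDS))
        assert (
            classify_duplicate_fate(DuplicatePair("ga", "zz", "p"), em)
            == "unknown"
        )

    def test_noise_free_generator_closed_loop(self):
        fates = [
            "shared_expression",
            "nonfunctionalization_candidate",
            "subfunctionalization_candidate",
            "divergent",
        ]
        pairs = [(f"a{i}", f"b{i}", f) for i, f in enumerate(fates)]
        em = simulate_expression_matrix(pairs, self.CONDS, noise=0.0, seed=2)
        for (ga, gb, fate) in pairs:
            assert (
                classify_duplicate_fate(DuplicatePair(ga, gb, "p"), em)
                == fate
            )
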