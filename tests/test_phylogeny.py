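"""Parsimony machinery: Fitch counting, tree search vs brute force,
bootstrap behaviour, branch annotation, RF distance."""

import itertools

import numpy as np
import pytest

from crcevo.model import Effect, MutationCall, RegionSample, TissueClass
from crcevo.parsimony import (
    FitchScorer,
    canonical_newick,
    enumerate_topologies,
    nni_neighbors,
    search_tree,
    topology_to_phylotree,
)
from crcevo.phylogeny import (
    BinaryCharacterMatrix,
    annotate_branches,
    apply_support,
    bootstrap_support,
    build_character_matrix,
    fitch_score,
    search_mp_tree,
)
from crcevo.tree import PhyloTree, rf_distance


def _sample(sid, tissue=TissueClass.CARCINOMA):
    return RegionSample(sid, "P1", tissue)


def _call(sid, pos, vaf=0.4, gene="", effect=Effect.OTHER):
    return MutationCall(sid, "chr1", pos, "C", "T", gene=gene, effect=effect, vaf=vaf)


class TestCharacterMatrix:
    def test_shared_and_private_patterns(self):
        calls = [_call("A", 1), _call("B", 1), _call("A", 2), _call("B", 3)]
        m = build_character_matrix(calls, [_sample("A"), _sample("B")])
        assert m.values.shape == (3, 3)
        patterns = {mid: tuple(m.values[1:, j]) for j, mid in enumerate(m.mutation_ids)}
        assert sorted(patterns.values()) == [(0, 1), (1, 0), (1, 1)]

    def test_subthreshold_call_is_absent(self):
        calls = [_call("A", 1, vaf=0.01), _call("B", 1, vaf=0.4)]
        m = build_character_matrix(calls, [_sample("A"), _sample("B")])
        assert m.values[1:, 0].tolist() == [0, 1]

    def test_noiseless_matrix_equals_simulator_truth(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        t = clean_patient.truth_matrix()
        obs = {mid: frozenset(s for i, s in enumerate(m.sample_ids) if m.values[i, j])
               for j, mid in enumerate(m.mutation_ids)}
        exp = {mid: frozenset(s for i, s in enumerate(t.sample_ids) if t.values[i, j])
               for j, mid in enumerate(t.mutation_ids)}
        assert obs == exp

    def test_no_variable_columns_is_error(self):
        with pytest.raises(ValueError):
            build_character_matrix([_call("A", 1, vaf=0.0)],
                                   [_sample("A"), _sample("B")],
                                   detection_threshold=0.5)


def _matrix(rows, sample_ids=None, genes=None, effects=None):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    sample_ids = sample_ids or ["germline"] + [f"S{i}" for i in range(1, n)]
    mids = [f"m{j}" for j in range(rows.shape[1])]
    return BinaryCharacterMatrix(sample_ids, mids, rows,
                                 genes or [], effects or [])


class TestFitchScore:
    def test_truncal_character_needs_one_change(self):
        # Present in all four cancer leaves, absent outgroup: s=1 on any shape.
        m = _matrix([[0], [1], [1], [1], [1]])
        for topo in enumerate_topologies([1, 2, 3, 4]):
            scorer = FitchScorer(m.values)
            assert scorer.score(topo) == 1

    def test_hand_run_incompatible_pattern(self):
        # A=C=1, B=D=0 on tree ((A,B),(C,D)) + outgroup: two gains.
        m = _matrix([[0], [1], [0], [1], [0]],
                    sample_ids=["germline", "A", "B", "C", "D"])
        tree = PhyloTree.from_newick("(germline:0,((A:1,B:0):0,(C:1,D:0):0):0);")
        stats = fitch_score(tree, m)
        assert stats.per_char_changes.tolist() == [2]
        assert stats.consistency_index == 0.5
        assert stats.homoplasy_index == 0.5

    def test_simulator_truth_tree_has_zero_homoplasy(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        assert fitch_score(clean_patient.truth_tree, m).homoplasy_index == 0.0


class TestSearch:
    def test_star_like_for_identical_samples(self):
        m = _matrix([[0] * 3, [1] * 3, [1] * 3, [1] * 3, [1] * 3])
        tree, stats = search_mp_tree(m)
        assert stats.score == 3
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert all(lengths[s] == 0 for s in ["S1", "S2", "S3", "S4"])

    def test_heuristic_matches_exhaustive_on_random_matrices(self, rng):
        """Stepwise+NNI with restarts finds the exhaustive optimum on
        5-taxon matrices (brute force over all 15 shapes)."""
        names = ["out", "A", "B", "C", "D", "E"]
        for rep in range(25):
            values = rng.integers(0, 2, size=(6, 20))
            values[0] = 0
            scorer = FitchScorer(values)
            best = min(scorer.score(t) for t in enumerate_topologies([1, 2, 3, 4, 5]))
            _, heur = search_tree(scorer, names, exhaustive_limit=0,
                                  restarts=20, seed=rep)
            assert heur == best

    def test_recovers_truth_topology_noiseless(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        tree, stats = search_mp_tree(m)
        assert rf_distance(tree, clean_patient.truth_tree) == 0
        assert stats.homoplasy_index == 0.0

    def test_branch_lengths_sum_to_score(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        tree, stats = search_mp_tree(m)
        total = sum(n.length for n in tree.preorder() if n is not tree.root)
        assert total == stats.score

    def test_deterministic_tie_break(self):
        m = _matrix([[0, 0], [1, 0], [1, 0], [0, 1], [0, 1]])
        t1, _ = search_mp_tree(m, seed=0)
        t2, _ = search_mp_tree(m, seed=99)
        assert t1.to_newick() == t2.to_newick()

    def test_too_few_samples_rejected(self):
        m = _matrix([[0], [1], [1]])
        with pytest.raises(ValueError):
            search_mp_tree(m)

    def test_conflicting_column_strictly_increases_score(self, rng):
        values = rng.integers(0, 2, size=(6, 12))
        values[0] = 0
        values[:, 0] = [0, 1, 1, 0, 0, 0]
        m = _matrix(values)
        tree, stats = search_mp_tree(m)
        # add a column conflicting with the S1,S2 split
        conflict = np.array([0, 1, 0, 1, 0, 0], dtype=np.int8)[:, None]
        m2 = _matrix(np.hstack([values, conflict]))
        _, stats2 = search_mp_tree(m2)
        assert stats2.score > stats.score


class TestBootstrap:
    def test_single_replicate_supports_binary(self):
        m = _matrix(np.array([[0] * 6, [1, 1, 0, 0, 0, 0], [1, 1, 0, 0, 1, 1],
                              [0, 0, 1, 1, 1, 1], [0, 0, 1, 1, 0, 0]]))
        supports = bootstrap_support(m, b=1, seed=0)
        assert all(v in (0.0, 100.0) for v in supports.values())

    def test_fixed_seed_reproducible(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        s1 = bootstrap_support(m, b=25, seed=5)
        s2 = bootstrap_support(m, b=25, seed=5)
        assert s1 == s2

    def test_column_permutation_invariance(self, rng, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        perm = rng.permutation(len(m.mutation_ids))
        m2 = m.subset_columns(perm.tolist())
        assert bootstrap_support(m, b=20, seed=3) == bootstrap_support(m2, b=20, seed=3)

    def test_strong_signal_gives_high_support(self, rng):
        # 50 clean characters per branch: every true clade near 100%.
        values = np.zeros((6, 150), dtype=np.int8)
        values[1, :50] = values[2, :50] = 1  # S1+S2 clade
        values[3, 50:100] = values[4, 50:100] = 1  # S3+S4 clade
        values[1, 100:] = 1  # private
        m = _matrix(values)
        tree, _ = search_mp_tree(m)
        supports = bootstrap_support(m, b=100, seed=0)
        apply_support(tree, supports)
        internal = [n.support for n in tree.preorder()
                    if not n.is_leaf and n.support is not None]
        assert internal and min(internal) >= 95


class TestAnnotation:
    def test_truncal_driver_on_trunk_and_private_on_leaf(self):
        samples = [_sample(s) for s in ["A", "B", "C"]]
        calls = ([_call(s, 1, gene="TP53", effect=Effect.MISSENSE) for s in "ABC"]
                 + [_call("A", 2, gene="KRAS", effect=Effect.MISSENSE)]
                 + [_call(s, i + 10) for i, s in enumerate("ABC")])
        m = build_character_matrix(calls, samples)
        tree, _ = search_mp_tree(m)
        annotate_branches(tree, m, ["TP53", "KRAS"])
        trunk_labels = [a for n in tree.preorder() for a in n.annotations
                        if {l.name for l in PhyloTree(n).leaves()} >= {"A", "B", "C"}]
        assert any("TP53" in a for a in trunk_labels)
        leaf_a = tree.find("A")
        assert any("KRAS" in a for a in leaf_a.annotations)

    def test_homoplastic_driver_flagged_on_both_gains(self):
        values = np.array([
            [0, 0, 0], [1, 1, 0], [1, 1, 0], [1, 0, 1], [1, 0, 1],
        ], dtype=np.int8)
        # column 0: present in all but forced homoplastic? no - truncal.
        # make column 0 conflict: A=D=1, B=C=0
        values[:, 0] = [0, 1, 0, 0, 1]
        m = _matrix(values, genes=["BRAF", "", ""],
                    effects=[Effect.MISSENSE, None, None])
        tree, _ = search_mp_tree(m)
        annotate_branches(tree, m, ["BRAF"])
        labels = [a for n in tree.preorder() for a in n.annotations]
        assert sum("BRAF" in a for a in labels) == 2
        assert all("homoplastic" in a for a in labels if "BRAF" in a)


class TestRFDistance:
    def test_identical_trees(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(t, t.copy()) == 0

    def test_four_leaf_single_split_difference(self):
        a = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(a, b) == 2

    def test_caterpillar_vs_balanced_matches_split_enumeration(self):
        cat = PhyloTree.from_newick("(A:1,(B:1,(C:1,(D:1,(E:1,F:1):1):1):1):1);")
        bal = PhyloTree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")

        def splits(tree):
            leaves = frozenset(tree.leaf_names())
            ref = min(leaves)
            out = set()
            for s in tree.splits():
                out.add(s if ref not in s else leaves - s)
            return out

        expected = len(splits(cat) ^ splits(bal))
        assert rf_distance(cat, bal) == expected
        assert rf_distance(cat, bal) > 0

    def test_leaf_mismatch_rejected(self):
        a = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        b = PhyloTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError):
            rf_distance(a, b)


class TestTopologyPrimitives:
    def test_topology_counts(self):
        # (2m-3)!! rooted shapes over m leaves
        assert len(enumerate_topologies([1, 2, 3])) == 3
        assert len(enumerate_topologies([1, 2, 3, 4])) == 15
        assert len(enumerate_topologies([1, 2, 3, 4, 5])) == 105

    def test_nni_neighbors_are_distinct_topologies(self):
        names = ["o", "A", "B", "C", "D", "E"]
        tree = ((1, 2), (3, (4, 5)))
        base = canonical_newick(tree, names)
        neigh = {canonical_newick(t, names) for t in nni_neighbors(tree)}
        assert base not in neigh
        assert len(neigh) >= 4
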