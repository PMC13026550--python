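import random

import dendropy
import numpy as np
import pytest

from intronscape._seq import mutate, random_seq
from intronscape.phylo import (
    DistanceMatrix,
    MaskedAlignment,
    UndefinedDistanceError,
    bootstrap_support,
    build_nj_tree,
    center_star_align,
    compute_distances,
    mask_regions,
    rf_distance,
)
from intronscape.phylo import test_monophyly as is_monophyletic


class TestMasking:
    def test_empty_spec_is_identity(self):
        ma = mask_regions({"a": "ACGU", "b": "ACGA", "c": "ACGU"}, [])
        assert ma.retained == 4

    def test_masking_everything_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            mask_regions({"a": "ACGU", "b": "ACGA"}, [("all", 1, 4)])

    def test_region_outside_alignment_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            mask_regions({"a": "ACGU", "b": "ACGA"}, [("r", 2, 9)])

    def test_retained_columns_are_the_set_complement(self):
        rng = np.random.default_rng(0)
        rows = {f"s{i}": random_seq(rng, 50) for i in range(4)}
        regions = [("r1", 5, 10), ("r2", 30, 40)]
        ma = mask_regions(rows, regions)
        expected = [i for i in range(50) if not (4 <= i <= 9 or 29 <= i <= 39)]
        assert ma.kept_columns == expected
        assert ma.rows[0] == "".join(rows["s0"][i] for i in expected)

    def test_overlapping_regions_merge_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            ma = mask_regions({"a": "ACGUACGU", "b": "ACGUACGA", "c": "ACGUUCGA"},
                              [("r1", 1, 4), ("r2", 3, 6)])
        assert ma.retained == 2

    def test_masking_constant_columns_preserves_mismatches_and_topology(self):
        """Dropping invariant sites keeps pairwise mismatch counts (and hence
        the NJ topology); only the per-site normalisation shifts."""
        rng = np.random.default_rng(1)
        var = {f"s{i}": mutate(random_seq(rng, 200), 0.2, rng) for i in range(5)}
        const = "A" * 50
        aln = {k: v + const for k, v in var.items()}
        d0 = compute_distances(aln, "p")
        ma = mask_regions(aln, [("const", 201, 250)])
        d1 = compute_distances(ma, "p")
        assert np.allclose(d0.matrix * 250, d1.matrix * 200)
        assert rf_distance(build_nj_tree(d0), build_nj_tree(d1)) == 0


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        d = compute_distances({"a": "ACGU" * 5, "b": "ACGU" * 5, "c": "ACGU" * 5}, "p")
        assert np.allclose(d.matrix, 0)

    def test_p_distance_counts_mismatches_over_compared_sites(self):
        d = compute_distances(
            {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC", "c": "AAAAAAAAAA"}, "p"
        )
        assert d.matrix[0, 1] == pytest.approx(0.1)

    def test_jc69_closed_form(self):
        d = compute_distances(
            {"a": "A" * 9 + "C", "b": "A" * 10, "c": "G" + "A" * 9}, "jc69"
        )
        assert d.matrix[0, 1] == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))

    def test_jc69_is_monotone_in_p(self):
        ps = np.linspace(0.01, 0.74, 40)
        ds = -0.75 * np.log(1 - 4 * ps / 3)
        assert np.all(np.diff(ds) > 0)

    def test_saturated_pairs_are_flagged_infinite(self):
        d = compute_distances({"a": "AAAA", "b": "CCCC", "c": "AAAA"}, "jc69")
        assert np.isinf(d.matrix[0, 1])

    def test_gap_only_pair_raises_undefined_distance(self):
        with pytest.raises(UndefinedDistanceError, match="a.*b"):
            compute_distances({"a": "--AA", "b": "AA--", "c": "AAAA"}, "p")


class TestNeighborJoining:
    def test_three_taxon_branch_lengths_match_closed_form(self):
        dm = DistanceMatrix(
            ["t1", "t2", "t3"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        tree = build_nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["t1"] == pytest.approx(0.05)
        assert lengths["t2"] == pytest.approx(0.15)
        assert lengths["t3"] == pytest.approx(0.25)

    def test_four_taxon_additive_matrix_recovers_split(self):
        D = np.array(
            [[0, 0.2, 0.4, 0.4], [0.2, 0, 0.4, 0.4], [0.4, 0.4, 0, 0.2], [0.4, 0.4, 0.2, 0]]
        )
        tree = build_nj_tree(DistanceMatrix(list("ABCD"), D))
        ref = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        assert rf_distance(tree, ref) == 0

    def test_additive_matrices_are_reconstructed_exactly(self):
        """NJ is consistent: patristic matrices of random trees come back RF=0."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 11))
            src = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=random.Random(seed),
            )
            for k, leaf in enumerate(src.leaf_node_iter()):
                leaf.taxon.label = f"x{k}"
            for e in src.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.uniform(0.05, 0.5))
            taxa = list(src.taxon_namespace)
            pdm = src.phylogenetic_distance_matrix()
            M = np.array(
                [[0 if a is b else pdm.patristic_distance(a, b) for b in taxa] for a in taxa]
            )
            nj = build_nj_tree(DistanceMatrix([t.label for t in taxa], M))
            hits += rf_distance(nj, src) == 0
        assert hits == 100

    def test_agrees_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        rows = {f"s{i}": mutate(random_seq(rng, 500), 0.1, rng) for i in range(7)}
        dm = compute_distances(rows, "p")
        ours = build_nj_tree(dm)
        theirs_nwk = str(skbio_nj(SkbioDM(dm.matrix, ids=dm.labels)).write([]).pop())
        theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick")
        assert rf_distance(ours, theirs) == 0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_nj_tree(
                DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))
            )


class TestBootstrap:
    def _two_cluster_alignment(self, seed, n_cols=2000):
        rng = np.random.default_rng(seed)
        anc1 = random_seq(rng, n_cols)
        anc2 = mutate(anc1, 0.3, rng)
        rows = {}
        for i in range(4):
            rows[f"a{i}"] = mutate(anc1, 0.01, rng)
        for i in range(4):
            rows[f"b{i}"] = mutate(anc2, 0.01, rng)
        return rows

    def test_separated_clusters_get_high_central_support(self):
        for seed in range(5):
            rows = self._two_cluster_alignment(seed)
            tree = bootstrap_support(rows, "p", n_reps=100, seed=seed)
            tree.encode_bipartitions()
            a_side = frozenset(f"a{i}" for i in range(4))
            central = None
            for e in tree.preorder_edge_iter():
                if e.head_node.parent_node is None or e.head_node.is_leaf():
                    continue
                below = frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                if below in (a_side, frozenset(rows) - a_side):
                    central = float(e.head_node.label)
            assert central is not None and central >= 95

    def test_same_seed_gives_identical_supports(self):
        rows = self._two_cluster_alignment(11, n_cols=400)
        t1 = bootstrap_support(rows, "p", n_reps=50, seed=5)
        t2 = bootstrap_support(rows, "p", n_reps=50, seed=5)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestTreeComparison:
    def test_identical_topologies_have_rf_zero(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,(D,E)));", schema="newick")
        t2 = dendropy.Tree.get(data="(((D,E),C),(B,A));", schema="newick")
        assert rf_distance(t1, t2) == 0

    def test_conflicting_quartets_have_rf_two(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        assert rf_distance(t1, t2) == 2

    def test_rf_is_symmetric_for_random_trees(self):
        for seed in range(30):
            t1 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
                rng=random.Random(seed),
            )
            t2 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
                rng=random.Random(seed + 1000),
            )
            for t in (t1, t2):
                for k, leaf in enumerate(t.leaf_node_iter()):
                    leaf.taxon.label = f"x{k}"
            assert rf_distance(t1, t2) == rf_distance(t2, t1)

    def test_leaf_set_mismatch_raises(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
        with pytest.raises(ValueError, match="differ"):
            rf_distance(t1, t2)

    def test_monophyly_on_caterpillar(self):
        t = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")
        assert is_monophyletic(t, {"A", "B"}, "E") is True
        assert is_monophyletic(t, {"A", "C"}, "E") is False

    def test_monophyly_of_everything_warns_trivially_true(self):
        t = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")
        with pytest.warns(UserWarning, match="trivially"):
            assert is_monophyletic(t, {"A", "B", "C", "D"}, "E") is True


class TestCenterStar:
    def test_prealigned_input_returned_unchanged(self):
        seqs = {"a": "ACGU", "b": "ACGA"}
        assert center_star_align(seqs) == seqs

    def test_high_identity_set_alignment_has_equal_rows(self):
        rng = np.random.default_rng(9)
        base = random_seq(rng, 300)
        seqs = {
            "a": base,
            "b": base[:100] + base[110:],  # deletion
            "c": base[:200] + "ACGUA" + base[200:],  # insertion
        }
        aligned = center_star_align(seqs)
        assert len({len(v) for v in aligned.values()}) == 1
        for k in seqs:
            assert aligned[k].replace("-", "") == seqs[k]
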