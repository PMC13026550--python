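import hashlib

import numpy as np
import pytest

from intronscape._seq import matches_iupac
from intronscape.simulate import (
    FamilySpec,
    SimConfig,
    SimulationError,
    build_family_templates,
    build_intron_template,
    demo_families,
    emit_cohort,
    evolve_cohort,
    simulate_cohort,
    simulate_species_tree,
)
from intronscape.structure import parse_domains


class TestSpeciesTree:
    def test_three_taxa_tree_is_fully_bifurcating(self):
        t = simulate_species_tree(3, 1.0, seed=1)
        assert len(t.leaf_nodes()) == 3
        assert sum(1 for _ in t.preorder_node_iter()) == 5  # 2n-1

    def test_same_seed_gives_identical_newick(self):
        a = simulate_species_tree(8, 1.0, seed=7).as_string(schema="newick")
        b = simulate_species_tree(8, 1.0, seed=7).as_string(schema="newick")
        assert a == b

    def test_node_count_and_ultrametricity_at_n50(self):
        t = simulate_species_tree(50, 1.0, seed=3)
        assert len(t.leaf_nodes()) == 50
        assert sum(1 for _ in t.preorder_node_iter()) == 99
        depths = []
        for leaf in t.leaf_node_iter():
            d, n = 0.0, leaf
            while n.parent_node is not None:
                d += n.edge.length
                n = n.parent_node
            depths.append(d)
        assert np.allclose(depths, 1.0)

    def test_too_few_species_rejected(self):
        with pytest.raises(SimulationError):
            simulate_species_tree(2, 1.0, seed=0)


class TestTemplates:
    def test_iia1_template_has_canonical_ends_and_bvga_junction(self):
        seq, db, truth = build_intron_template(FamilySpec("cox1", 686, "IIA1", "RTM"), seed=1)
        assert seq.startswith("GUGCGA")
        assert seq[-2] == "A" and seq[-1] in "CU"
        layout = parse_domains(seq, db)
        assert set(layout.domains) == {"DI", "DII", "DIII", "DIV", "DV", "DVI"}
        assert layout.dv_length == 34
        tet = seq[layout.domains["DII"][1] : layout.domains["DII"][1] + 4]
        assert matches_iupac(tet, "BVGA") and not matches_iupac(tet, "RRGA")

    def test_iib1_lhe_linker_template_loses_branchpoint(self):
        spec = FamilySpec(
            "rns", 420, "IIB1", "LHE",
            degenerations=frozenset({"linker", "no_branchpoint_A"}),
        )
        seq, db, truth = build_intron_template(spec, seed=2)
        assert 2 <= truth["linker_len"] <= 10
        assert seq[truth["linker_len"] : truth["linker_len"] + 6] == "GUGCGA"
        assert truth["branchpoint"] == -1
        # no unpaired A 6-10 nt from the 3' end
        L = len(seq)
        window = [i for i in range(L) if 6 <= L - i <= 10 and db[i] == "."]
        assert all(seq[i] != "A" for i in window)

    def test_diiia_template_has_seven_top_level_stems(self):
        spec = FamilySpec("atp1", 990, "IIA1", "RTM", degenerations=frozenset({"add_DIIIa"}))
        seq, db, truth = build_intron_template(spec, seed=3)
        layout = parse_domains(seq, db)
        assert len(layout.helices) == 7
        assert "DIIIa" in layout.accessories
        a, b = layout.accessories["DIIIa"]
        assert layout.domains["DIII"][1] < a and b < layout.domains["DIV"][0]

    def test_contradictory_flags_rejected(self):
        with pytest.raises(SimulationError):
            FamilySpec(
                "cox1", 10, "IIA1", "RTM", degenerations=frozenset({"linker"})
            ).validate()
        with pytest.raises(SimulationError):
            FamilySpec("cox1", 10, "IIB1", "LHE", degenerations=frozenset({"linker"})).validate()
        with pytest.raises(SimulationError):
            FamilySpec("cox1", 10, "IIA1", "LHE").validate()


class TestCohortEvolution:
    def test_zero_rate_copies_identical_to_template(self, clean_cohort):
        templates = clean_cohort.cohort.templates
        for it in clean_cohort.cohort.introns:
            assert it.sequence == templates[it.family].sequence

    def test_full_presence_probability_yields_all_species(self, clean_cohort):
        n = clean_cohort.cfg.n_species
        counts = {}
        for it in clean_cohort.cohort.introns:
            counts[it.family] = counts.get(it.family, 0) + 1
        assert all(c == n for c in counts.values())

    def test_presence_counts_follow_binomial_expectation(self):
        """Bernoulli(0.5) presence over 44 species: mean count near 22."""
        fams = (FamilySpec("cox1", 686, "IIB2", "RTM", presence_prob=0.5),)
        templates, _, _ = build_family_templates(
            SimConfig(n_species=44, seed=1, families=fams)
        )
        counts = []
        for seed in range(200):
            cfg = SimConfig(n_species=44, seed=seed, families=fams)
            tree = simulate_species_tree(44, 1.0, seed=123)
            cohort = evolve_cohort(templates, tree, cfg)
            counts.append(len(cohort.introns))
        sigma = np.sqrt(44 * 0.25)
        assert abs(np.mean(counts) - 22) <= 3 * sigma

    def test_linker_families_always_lack_branchpoint(self, rich_cohort):
        truth = rich_cohort.data.truth
        coupled = truth[truth.linker_len > 0]
        assert len(coupled) > 0
        assert (coupled.branchpoint == -1).all()


class TestEmission:
    def test_emission_is_byte_identical_for_fixed_config(self, tmp_path):
        cfg = SimConfig(
            n_species=4, seed=9, subst_rate_rna=0.03, subst_rate_orf=0.03,
            families=demo_families()[:4],
        )
        hashes = []
        for run in range(2):
            out = tmp_path / f"run{run}"
            paths = emit_cohort(simulate_cohort(cfg), str(out))
            digest = hashlib.md5()
            for name in sorted(paths):
                digest.update(open(paths[name], "rb").read())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]

    def test_truth_rows_match_presence_totals(self, clean_cohort):
        truth = clean_cohort.data.truth
        assert len(truth) == len(clean_cohort.cohort.introns)
        assert len(truth) == 12 * 20  # presence_prob 1 everywhere

    def test_gff_intron_intervals_match_fasta_lengths(self, clean_cohort):
        from Bio import SeqIO

        lengths = {
            r.id: len(r.seq)
            for r in SeqIO.parse(clean_cohort.paths["introns.fasta"], "fasta")
        }
        n = 0
        for line in open(clean_cohort.paths["genes.gff3"]):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "intron":
                continue
            iid = dict(kv.split("=") for kv in f[8].split(";"))["ID"]
            assert int(f[4]) - int(f[3]) + 1 == lengths[iid]
            n += 1
        assert n == len(lengths)
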