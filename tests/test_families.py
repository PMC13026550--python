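import numpy as np
import pandas as pd
import pytest

from intronscape._seq import mutate, random_seq
from intronscape.families import (
    PresenceMatrix,
    UnmappableSiteError,
    assign_families,
    build_presence_matrix,
    map_insertion_site,
    occurrence_frequency,
    pairwise_identity,
    search_family_members,
)
from intronscape.model import IntronRecord


def _intron(iid, seq, up, down="ACGUACGUACGUACGUACGU", gene="cox1"):
    return IntronRecord(
        id=iid, genome_id="g", host_gene=gene, site=None,
        sequence=seq, upstream_flank=up, downstream_flank=down,
    )


class TestSiteMapping:
    def test_exact_flank_maps_to_reference_coordinate(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 800, "ACGT")
        flank = ref[666:686]
        m = map_insertion_site(_intron("i1", "A" * 200, flank), ref)
        assert m.site == 686
        assert m.identity == 1.0

    def test_five_prime_mismatch_still_anchors_three_prime_end(self):
        """Oracle: best gap-free local alignment over all offsets."""
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 700, "ACGT")
        flank = list(ref[666:686])
        flank[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[flank[0]]
        flank = "".join(flank)

        # brute-force oracle: score every ungapped placement
        best = None
        for off in range(len(ref) - 20 + 1):
            sc = sum(2 if ref[off + k] == flank[k] else -3 for k in range(20))
            if best is None or sc > best[0]:
                best = (sc, off + 20)
        m = map_insertion_site(_intron("i1", "A" * 200, flank), ref)
        assert m.site == best[1] == 686

    def test_unrelated_flank_is_unmappable(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 500, "GC")
        with pytest.raises(UnmappableSiteError):
            map_insertion_site(_intron("i1", "A" * 200, "A" * 20), ref)


class TestFamilyAssignment:
    def _refs(self, rng):
        return {"cox1": random_seq(rng, 900, "ACGT")}

    def test_homologous_same_site_introns_share_a_family(self):
        rng = np.random.default_rng(3)
        refs = self._refs(rng)
        base = random_seq(rng, 1000)
        var = mutate(base, 0.05, rng)  # ~95% identity
        flank = refs["cox1"][666:686]
        introns = [_intron("a", base, flank), _intron("b", var, flank)]
        fams, un = assign_families(introns, refs)
        assert len(fams) == 1 and not un
        assert fams[0].family_id == "cox1-686"
        assert fams[0].members == ["a", "b"]

    def test_cosited_nonhomologous_introns_get_suffixed_families(self):
        rng = np.random.default_rng(4)
        refs = self._refs(rng)
        flank = refs["cox1"][666:686]
        introns = [
            _intron("a", random_seq(rng, 1000), flank),
            _intron("b", random_seq(rng, 1000), flank),
        ]
        fams, _ = assign_families(introns, refs)
        assert sorted(f.family_id for f in fams) == ["cox1-686", "cox1-686.2"]

    def test_identical_sequence_at_different_sites_splits_families(self):
        rng = np.random.default_rng(5)
        refs = self._refs(rng)
        seq = random_seq(rng, 1000)
        introns = [
            _intron("a", seq, refs["cox1"][666:686]),
            _intron("b", seq, refs["cox1"][280:300]),
        ]
        fams, _ = assign_families(introns, refs)
        assert sorted(f.family_id for f in fams) == ["cox1-300", "cox1-686"]

    def test_zero_mutation_cohort_recovers_truth_partition(self, clean_cohort):
        from sklearn.metrics import rand_score

        from intronscape.io import load_reference_genes

        refs = load_reference_genes(clean_cohort.paths["reference_genes.fasta"])
        fams, un = assign_families(clean_cohort.data.introns, refs)
        assert not un
        pred = {m: f.family_id for f in fams for m in f.members}
        truth = dict(
            zip(clean_cohort.data.truth.intron_id, clean_cohort.data.truth.family)
        )
        ids = sorted(pred)
        assert rand_score(
            [truth[i] for i in ids], [pred[i] for i in ids]
        ) == pytest.approx(1.0)
        assert all(pred[i] == truth[i] for i in ids)


class TestHomologySearch:
    def test_exact_probe_yields_full_coverage_hit(self):
        rng = np.random.default_rng(6)
        genome = random_seq(rng, 10000, "ACGT")
        hits = search_family_members(genome[4000:4500], genome)
        assert hits[0].percent_identity == 100.0
        assert hits[0].query_coverage == 1.0
        assert hits[0].interval == (4001, 4500)

    def test_random_probe_finds_nothing_at_cutoff(self):
        misses = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            genome = random_seq(rng, 10000, "ACGT")
            probe = random_seq(rng, 500, "ACGT")
            misses += len(search_family_members(probe, genome)) == 0
        assert misses == 20

    def test_mutated_probe_recovered_with_matching_identity(self):
        rng = np.random.default_rng(7)
        genome = random_seq(rng, 10000, "ACGT")
        probe = mutate(genome[2000:2500], 0.05, rng, alphabet="ACGT")
        ident, cov = pairwise_identity(probe, genome[2000:2500])
        hits = search_family_members(probe, genome)
        assert hits
        assert hits[0].percent_identity == pytest.approx(100 * ident, abs=2.0)
        assert abs(hits[0].percent_identity - 95.0) <= 2.0

    def test_short_probe_rejected(self):
        with pytest.raises(ValueError):
            search_family_members("ACGTACGT", "ACGT" * 100)


class TestOccurrence:
    @pytest.mark.parametrize(
        "count,total,percent,cls",
        [
            (23, 44, 52.3, "broad"),
            (23, 47, 48.9, "broad"),
            (7, 44, 15.9, "intermediate"),
            (0, 44, 0.0, "narrow"),
            (2, 44, 4.5, "narrow"),
        ],
    )
    def test_printed_percentages_and_classes(self, count, total, percent, cls):
        row = [True] * count + [False] * (total - count)
        pm = PresenceMatrix(
            pd.DataFrame([row], index=["fam"], columns=[f"g{i}" for i in range(total)])
        )
        out = occurrence_frequency(pm)
        assert out.loc[0, "percent"] == percent
        assert out.loc[0, "class"] == cls

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            nf, ng = rng.integers(1, 8), rng.integers(1, 50)
            mat = rng.random((nf, ng)) < 0.4
            pm = PresenceMatrix(
                pd.DataFrame(
                    mat,
                    index=[f"f{i}" for i in range(nf)],
                    columns=[f"g{i}" for i in range(ng)],
                )
            )
            out = occurrence_frequency(pm).set_index("family")
            for i in range(nf):
                k = sum(bool(x) for x in mat[i])
                assert out.loc[f"f{i}", "count"] == k
                assert out.loc[f"f{i}", "percent"] == round(100 * k / ng, 1)

    def test_empty_matrix_rejected(self):
        pm = PresenceMatrix(pd.DataFrame(index=["f"], columns=[], dtype=bool))
        with pytest.raises(ValueError):
            occurrence_frequency(pm)

    def test_presence_matrix_from_assignments(self, clean_cohort):
        from intronscape.io import load_reference_genes

        refs = load_reference_genes(clean_cohort.paths["reference_genes.fasta"])
        fams, _ = assign_families(clean_cohort.data.introns, refs)
        genome_ids = [g["id"] for g in clean_cohort.cohort.genomes]
        member_genome = {r.id: r.genome_id for r in clean_cohort.data.introns}
        pm = build_presence_matrix(fams, genome_ids, member_genome)
        out = occurrence_frequency(pm)
        assert (out["percent"] == 100.0).all()  # presence_prob = 1 roster
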