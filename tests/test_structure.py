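import collections

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from intronscape._seq import as_rna
from intronscape.simulate import FamilySpec, build_intron_template
from intronscape.structure import (
    DomainLayout,
    StructureError,
    StructureFeatures,
    annotate_intron,
    build_consensus,
    classify_subgroup,
    detect_branchpoint,
    detect_ebs_ibs,
    detect_terminal_elements,
    extract_junctions,
    parse_domains,
)


class TestParseDomains:
    def test_layout_matches_generator_truth_intervals(self, clean_cohort):
        for fam, t in clean_cohort.cohort.templates.items():
            layout = parse_domains(t.sequence, t.dot_bracket)
            truth = dict(
                item.split(":") for item in t.truth["domains"].split(";")
            )
            for dom, iv in truth.items():
                if dom == "DIIIa":
                    continue
                s, e = (int(x) for x in iv.split("-"))
                assert layout.domains[dom] == (s, e), (fam, dom)

    def test_seven_helix_layout_flags_diiia(self):
        spec = FamilySpec("nad5", 1057, "IIA1", "RTM", degenerations=frozenset({"add_DIIIa"}))
        seq, db, _ = build_intron_template(spec, seed=5)
        layout = parse_domains(seq, db)
        assert "DIIIa" in layout.accessories
        assert set(layout.domains) == {"DI", "DII", "DIII", "DIV", "DV", "DVI"}

    def test_single_helix_is_a_layout_error(self):
        with pytest.raises(StructureError, match="1"):
            parse_domains("GGGGAAACCCC", "((((...))))")

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(StructureError, match="unbalanced"):
            parse_domains("GGAA", "((..")


class TestConsensus:
    def test_identical_rows_reproduce_the_sequence(self):
        c = build_consensus(["ACGU", "ACGU", "ACGU"])
        assert c.representative == "ACGU" and not c.tie_columns

    def test_majority_symbol_wins(self):
        assert build_consensus(["AAG", "AAG", "AGG"]).representative == "AAG"

    def test_two_row_tie_breaks_alphabetically_and_is_flagged(self):
        c = build_consensus(["AC", "GC"])
        assert c.representative == "AC"
        assert c.tie_columns == {0}

    def test_gap_majority_columns_are_dropped(self):
        c = build_consensus(["A-C", "--C", "-GC"])
        assert c.representative == "C"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])

    @given(
        st.integers(2, 6).flatmap(
            lambda n: st.lists(
                st.text(alphabet="ACGU-", min_size=8, max_size=8),
                min_size=n,
                max_size=n,
            )
        )
    )
    def test_matches_column_count_oracle(self, rows):
        """Independent oracle: per-column Counter with alphabetical ties."""
        expected = []
        for col in zip(*rows):
            counts = collections.Counter(col)
            gap = counts.pop("-", 0)
            best = max(counts.values()) if counts else 0
            if gap > best:
                continue
            expected.append(min(b for b in counts if counts[b] == best))
        assert build_consensus(rows).representative == "".join(expected)


class TestTerminalElements:
    def test_canonical_motif_with_au_end(self):
        seq = "GUGCGA" + "C" * 60 + "AU"
        assert detect_terminal_elements(seq) == ("canonical", 0, True)

    def test_linker_offsets_the_motif(self):
        seq = "CA" + "GUGCGA" + "C" * 60 + "AC"
        assert detect_terminal_elements(seq) == ("canonical", 2, True)

    def test_aa_end_is_not_ay(self):
        seq = "GUGCGA" + "C" * 60 + "AA"
        motif, linker, ay = detect_terminal_elements(seq)
        assert motif == "canonical" and ay is False

    def test_single_mismatch_is_variant(self):
        seq = "GAGCGA" + "C" * 60 + "AU"
        motif, _, _ = detect_terminal_elements(seq)
        assert motif == "variant:GAGCGA"


class TestBranchpoint:
    def test_unpaired_a_outside_window_is_absent(self):
        # bulged A only 3 nt from the 3' end: outside the 6-10 window
        seq = "GGGGGGG" + "UUUU" + "CCCCCCC" + "AAU"
        db = "(((((((" + "...." + ")))))))" + "..."
        layout = DomainLayout(domains={"DVI": (1, len(seq))}, dot_bracket=db)
        assert detect_branchpoint(layout, seq) == ("absent", None)

    def test_missing_dvi_is_not_assessable(self):
        layout = DomainLayout(domains={}, dot_bracket="....")
        assert detect_branchpoint(layout, "ACGU")[0] == "not_assessable"

    def test_generator_truth_round_trip(self, rich_cohort):
        truth = rich_cohort.data.truth.drop_duplicates("family")
        recs = {r.id: r for r in rich_cohort.data.introns}
        for _, row in truth.iterrows():
            r = recs[row.intron_id]
            layout = parse_domains(r.sequence, r.structure)
            status, pos = detect_branchpoint(layout, r.sequence)
            assert (status == "present") == (row.branchpoint != -1)


class TestEbsIbs:
    def _layout(self, db):
        return DomainLayout(domains={"DI": (1, len(db))}, dot_bracket=db)

    def test_hand_oracle_six_of_six_watson_crick(self):
        # IBS1 CUUCAG pairs EBS1 CUGAAG (reverse complement)
        seq = "GGGG" + "CUGAAG" + "CCCC"
        db = "((((" + "......" + "))))"
        rep = detect_ebs_ibs(self._layout(db), seq, "AAAAAA" + "CUUCAG", "G")
        assert rep.ebs1.status == "found"
        assert rep.ebs1.sequence == "CUGAAG"
        assert rep.ebs1.matches == 6

    def test_wobble_pairs_only_count_when_enabled(self):
        # IBS1 GUUCAG vs loop CUGAAU: position pairing U:G needs wobble
        seq = "GGGG" + "CUGAAU" + "CCCC"
        db = "((((" + "......" + "))))"
        up = "AAAAAA" + "GUUCAG"
        strict = detect_ebs_ibs(self._layout(db), seq, up, "G")
        wob = detect_ebs_ibs(self._layout(db), seq, up, "G", allow_wobble=True)
        assert strict.ebs1.matches == 5
        assert wob.ebs1.matches == 6 and wob.wobble_used

    def test_short_flanks_not_assessable(self):
        seq = "GGGG" + "CUGAAG" + "CCCC"
        db = "((((" + "......" + "))))"
        rep = detect_ebs_ibs(self._layout(db), seq, "CAG", "")
        assert rep.ebs1.status == "not_assessable"
        assert rep.ebs2.status == "not_assessable"
        assert rep.ebs3.status == "not_assessable"

    def test_found_sites_always_meet_thresholds(self, rich_cohort):
        """Re-verify every reported EBS against its IBS partner."""
        from intronscape._seq import is_complementary

        for r in rich_cohort.data.introns:
            layout = parse_domains(r.sequence, r.structure)
            rep = detect_ebs_ibs(
                layout, r.sequence, r.upstream_flank, r.downstream_flank
            )
            for site, thr, ibs in (
                (rep.ebs1, 5, r.upstream_flank[-6:]),
                (rep.ebs2, 4, r.upstream_flank[-12:-6]),
            ):
                if site.status != "found":
                    continue
                w = site.sequence
                matches = sum(
                    is_complementary(w[k], ibs[len(ibs) - 1 - k]) for k in range(len(w))
                )
                assert matches >= thr

    def test_zero_mutation_cohort_recovers_truth(self, clean_cohort):
        truth = clean_cohort.data.truth.set_index("intron_id")
        for r in clean_cohort.data.introns:
            layout = parse_domains(r.sequence, r.structure)
            rep = detect_ebs_ibs(layout, r.sequence, r.upstream_flank, r.downstream_flank)
            row = truth.loc[r.id]
            assert rep.ebs1.status == row.ebs1_status == "found"
            assert rep.ebs1.sequence == row.ebs1_seq
            assert rep.ebs2.status == row.ebs2_status == "found"
            assert rep.ebs3.status == row.ebs3_status == "found"

    def test_lose_ebs2_families_report_ebs2_lost(self, rich_cohort):
        truth = rich_cohort.data.truth
        lost = truth[truth.family.isin(["rnl-2698", "rns-670", "infA-62"])]
        assert (lost.ebs2_status == "lost").all()
        assert (lost.ebs1_status == "found").all()


def _features(tet=None, dim=None, length=1500, motif="canonical", bp=("present", 5), ebs=None):
    return StructureFeatures(
        length=length,
        five_prime_motif=motif,
        linker_len=0,
        three_prime_AY=True,
        branchpoint=bp,
        junction_DII_DIII=tet,
        junction_DIV_DV=dim,
        ebs=ebs,
        accessories={},
    )


class TestSubgroupLogic:
    @pytest.mark.parametrize(
        "tet,expected",
        [("CAGA", "IIA1"), ("GGGA", "ambiguous-IIA"), ("AAGA", "IIA2"), ("CCGA", "IIA1")],
    )
    def test_tetramer_iupac_decisions(self, tet, expected):
        assert classify_subgroup(_features(tet=tet)) == expected

    @pytest.mark.parametrize("dim,expected", [("UA", "IIB1"), ("GG", "IIB2"), ("AG", "IIB2"), ("CU", "IIB1")])
    def test_dimer_iupac_decisions(self, dim, expected):
        assert classify_subgroup(_features(tet="UUCU", dim=dim)) == expected

    def test_ambiguous_iia_resolved_by_prior(self):
        assert classify_subgroup(_features(tet="GGGA"), iia_prior="IIA2") == "IIA2"

    def test_iib_like_needs_short_iepless_degenerate_scaffold(self):
        f = _features(tet="UUCU", dim="CC", length=600, motif="canonical", bp=("absent", None))
        # only one core feature missing -> unclassified
        assert classify_subgroup(f) == "unclassified"
        f2 = _features(tet="UUCU", dim="CC", length=600, motif="absent", bp=("absent", None))
        assert classify_subgroup(f2) == "IIB-like"
        f3 = _features(tet="UUCU", dim="CC", length=1500, motif="absent", bp=("absent", None))
        assert classify_subgroup(f3) == "unclassified"  # too long

    def test_subgroup_accuracy_tolerates_moderate_divergence(self):
        """>= 90% subgroup recovery at 0.05 substitutions/site (20 seeds)."""
        from intronscape.iep import annotate_iep
        from intronscape.simulate import SimConfig, demo_families, simulate_cohort

        ok = n = 0
        for seed in range(20):
            cfg = SimConfig(
                n_species=5, seed=seed, subst_rate_rna=0.05, subst_rate_orf=0.05,
                families=demo_families(),
            )
            cohort = simulate_cohort(cfg)
            templates = cohort.templates
            for it in cohort.introns:
                layout, feats = annotate_intron(
                    it.sequence, it.dot_bracket, it.upstream_flank, it.downstream_flank
                )
                iep = annotate_iep(it.sequence, layout)
                n += 1
                ok += classify_subgroup(feats, layout, iep) == templates[it.family].spec.subgroup
        assert ok / n >= 0.90

    def test_full_cohort_subgroups_recover_truth(self, rich_cohort):
        from intronscape.iep import annotate_iep

        truth = rich_cohort.data.truth.set_index("intron_id")
        for r in rich_cohort.data.introns:
            layout, feats = annotate_intron(
                r.sequence, r.structure, r.upstream_flank, r.downstream_flank
            )
            iep = annotate_iep(r.sequence, layout)
            assert classify_subgroup(feats, layout, iep) == truth.loc[r.id, "subgroup"]


class TestAccessories:
    def test_accessory_labels_recover_truth_flags(self, rich_cohort):
        truth = rich_cohort.data.truth.set_index("intron_id")
        for r in rich_cohort.data.introns:
            _, feats = annotate_intron(
                r.sequence, r.structure, r.upstream_flank, r.downstream_flank
            )
            row = truth.loc[r.id]
            for acc in ("Ia", "IC2", "ID2", "ID2a", "IE", "DIIIa"):
                assert (acc in feats.accessories) == bool(row[f"has_{acc}"]), (r.id, acc)
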