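"""Synthetic organellar group II intron cohorts with full ground truth.

The generator emulates the statistical and structural properties the
comparative pipeline assumes:

* canonical six-domain (DI-DVI) architecture over a dot-bracket structure,
  with subgroup-diagnostic junction motifs (DII-DIII tetramer BVGA/RRGA for
  IIA1/IIA2; DIV-DV dimer YW/RG for IIB1/IIB2);
* EBS1/EBS2/EBS3 loops in DI complementary to the IBS windows of the flanking
  exons of the (reference) host gene;
* conserved terminal motifs (5' GUGCGA ... 3' AY), a fixed ~34-nt catalytic
  DV, and a bulged branch-point adenosine 8 nt from the 3' end of DVI;
* DIV-embedded ORFs: reverse transcriptase/maturase (RT/M, 450 codons with
  the catalytic YADD motif plus an upstream RT block) or LAGLIDADG homing
  endonuclease (LHE, 200 codons with two LAGLIDADG copies ~105 aa apart);
* lineage-specific degenerations: 5' linker insertion (coupled with loss of
  the branch-point adenosine), EBS2 erosion, IC2/ID2 loss, ID2a/IE/DIIIa
  accessory insertions, premature-stop or absent ORFs;
* per-family Bernoulli presence/absence across species, and coevolving
  RNA/ORF divergence: family templates descend from ancestral segment
  sequences evolved along a family guide tree whose topology mirrors the
  subgroup structure, and LHE ORFs are introduced as independent invasion
  events (one ancestral LHE per invasion lineage), producing the dual-origin
  signal; within families, copies evolve along a Yule species tree.

Every emitted intron has exactly one ground-truth row; EBS truth is recorded
from the package's own detector run on the pre-mutation template, so truth
always describes the emitted object.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._seq import (
    as_dna,
    as_rna,
    draw_from_pattern,
    jc_subst_prob,
    mutate,
    random_seq,
    revcomp_rna,
)
from .naming import name_intron

__all__ = [
    "FamilySpec",
    "SimConfig",
    "SimulationError",
    "simulate_species_tree",
    "family_guide_tree",
    "build_intron_template",
    "build_family_templates",
    "evolve_cohort",
    "simulate_cohort",
    "emit_cohort",
    "demo_families",
    "family_scaffold_alignment",
    "scaffold_hotspot_regions",
    "family_orf_proteins",
]

SUBGROUPS = ("IIA1", "IIA2", "IIB1", "IIB2", "IIB-like")
IEP_TYPES = ("RTM", "LHE", "none")
DEGENERATION_FLAGS = frozenset(
    {
        "linker",
        "no_branchpoint_A",
        "lose_EBS2",
        "lose_IC2",
        "lose_ID2",
        "add_ID2a",
        "add_IE",
        "add_DIIIa",
        "orf_premature_stop",
        "orf_absent",
    }
)

FIVE_PRIME_MOTIF = "GUGCGA"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
RTM_LEN = 450  # codons
LHE_LEN = 200
RTM_CATALYTIC = "YADD"  # matches the [YF]xDD RT catalytic pattern
RTM_SUPPORT = "LPQG"  # RT block pattern [LIV]PQG
LHE_MOTIF = "LAGLIDADG"
RTM_MOTIF_POS = {150: RTM_SUPPORT, 300: RTM_CATALYTIC}
LHE_MOTIF_POS = {30: LHE_MOTIF, 135: LHE_MOTIF}


class SimulationError(ValueError):
    """Invalid simulator configuration."""


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FamilySpec:
    """One intron family: host locus, subgroup, IEP and degeneration flags."""

    host_gene: str
    site: int
    subgroup: str
    iep: str
    presence_prob: float = 1.0
    degenerations: frozenset = frozenset()
    invasion_donor: str | None = None

    @property
    def family_id(self) -> str:
        return name_intron(self.host_gene, self.site)

    def validate(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise SimulationError(f"{self.family_id}: unknown subgroup {self.subgroup}")
        if self.iep not in IEP_TYPES:
            raise SimulationError(f"{self.family_id}: unknown IEP type {self.iep}")
        if self.site < 1:
            raise SimulationError(f"{self.family_id}: site must be >= 1")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise SimulationError(f"{self.family_id}: presence_prob outside [0,1]")
        bad = set(self.degenerations) - DEGENERATION_FLAGS
        if bad:
            raise SimulationError(f"{self.family_id}: unknown degeneration flags {sorted(bad)}")
        flags = self.degenerations
        if self.subgroup in ("IIA1", "IIA2"):
            # all IIA introns carry an intact RT/M
            if self.iep != "RTM":
                raise SimulationError(f"{self.family_id}: IIA introns must encode RT/M")
            if "linker" in flags:
                raise SimulationError(f"{self.family_id}: 5' linker is restricted to IIB introns")
        if "linker" in flags:
            if self.subgroup not in ("IIB1", "IIB2"):
                raise SimulationError(
                    f"{self.family_id}: linker requires subgroup IIB1 or IIB2"
                )
            if "no_branchpoint_A" not in flags:
                raise SimulationError(
                    f"{self.family_id}: linker is coupled with branch-point loss "
                    "(set no_branchpoint_A jointly)"
                )
        if self.iep == "none" and ("orf_premature_stop" in flags):
            raise SimulationError(f"{self.family_id}: orf_premature_stop needs an IEP type")
        if self.invasion_donor is not None and self.iep != "LHE":
            raise SimulationError(f"{self.family_id}: invasion_donor only applies to LHE families")


@dataclass(frozen=True)
class SimConfig:
    n_species: int
    organelle: str = "mt"
    seed: int = 0
    birth_rate: float = 1.0
    subst_rate_rna: float = 0.0  # expected subs/site across tree depth
    subst_rate_orf: float = 0.0
    families: tuple = ()
    exon_len: int = 60
    family_divergence: float = 0.2  # root-to-tip subs/site on the family guide tree
    scaffold_extra: int = 0  # extra DI padding helix (nt), for long-scaffold cohorts
    translation_table: int = 1

    def validate(self) -> None:
        if self.n_species < 3:
            raise SimulationError("n_species must be >= 3")
        if self.organelle not in ("mt", "cp"):
            raise SimulationError("organelle must be 'mt' or 'cp'")
        if self.birth_rate <= 0:
            raise SimulationError("birth_rate must be positive")
        if self.subst_rate_rna < 0 or self.subst_rate_orf < 0:
            raise SimulationError("substitution rates must be >= 0")
        if self.exon_len < 20:
            raise SimulationError("exon_len must be >= 20")
        if not self.families:
            raise SimulationError("at least one FamilySpec required")
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate family ids")
        for f in self.families:
            f.validate()
            if f.invasion_donor is not None and f.invasion_donor not in ids:
                raise SimulationError(f"{f.family_id}: unknown invasion donor {f.invasion_donor}")


# --------------------------------------------------------------------------
# species tree (Yule)


def simulate_species_tree(n_species: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth (Yule) species tree.

    Leaves are labelled ``sp1..spN`` and edge lengths are rescaled so the
    root-to-tip depth is 1.0 (substitution rates are therefore expressed as
    expected substitutions/site across the whole tree depth).
    """
    if n_species < 3:
        raise SimulationError("n_species must be >= 3")
    if birth_rate <= 0:
        raise SimulationError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.birth_time = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    for c in (c1, c2):
        c.birth_time = 0.0
        root.add_child(c)
    active = [c1, c2]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active[i]
        k1, k2 = dendropy.Node(), dendropy.Node()
        for k in (k1, k2):
            k.birth_time = t
            node.add_child(k)
        active[i] = k1
        active.append(k2)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    if t_end <= 0:
        t_end = 1.0

    idx = 0
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = 0.0
            continue
        end = t_end if node.is_leaf() else min(c.birth_time for c in node.child_nodes())
        node.edge.length = (end - node.birth_time) / t_end
        if node.is_leaf():
            idx += 1
            node.taxon = tns.new_taxon(label=f"sp{idx}")
    return tree


# --------------------------------------------------------------------------
# family guide tree


def _ladder(names: list[str]) -> str | None:
    if not names:
        return None
    if len(names) == 1:
        return names[0]
    return f"({names[0]},{_ladder(names[1:])})"


def _join(*parts) -> str | None:
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(parts) + ")"


def family_guide_tree(families, divergence: float) -> dendropy.Tree:
    """Fixed cladogram over families mirroring the subgroup structure.

    Topology: (IIB-like, (IIA1, IIA2), ((IIB1-RT/M, IIB1-LHE),
    (IIB2-RT/M, IIB2-LHE))); within IIA1, DIIIa-carrying families form their
    own subclade. Every edge gets equal length such that the deepest leaf sits
    at ``divergence`` substitutions/site from the root.
    """
    def ids(subgroup, iep=None, diiia=None):
        out = []
        for f in families:
            if f.subgroup != subgroup:
                continue
            if iep is not None and f.iep != iep:
                continue
            if diiia is not None and (("add_DIIIa" in f.degenerations) != diiia):
                continue
            out.append(f.family_id)
        return out

    iia1 = _join(_ladder(ids("IIA1", diiia=True)), _ladder(ids("IIA1", diiia=False)))
    iia = _join(iia1, _ladder(ids("IIA2")))
    iib1 = _join(_ladder(ids("IIB1", iep="RTM")),
                 _join(_ladder(ids("IIB1", iep="LHE")), _ladder(ids("IIB1", iep="none"))))
    iib2 = _join(_ladder(ids("IIB2", iep="RTM")),
                 _join(_ladder(ids("IIB2", iep="LHE")), _ladder(ids("IIB2", iep="none"))))
    iib = _join(iib1, iib2)
    newick = _join(_ladder(ids("IIB-like")), iia, iib)
    if newick is None:
        raise SimulationError("no families")
    if "(" not in newick:
        newick = f"({newick})"
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    depth = max(
        sum(1 for _ in leaf.ancestor_iter()) for leaf in tree.leaf_node_iter()
    )
    el = divergence / max(depth, 1)
    for edge in tree.preorder_edge_iter():
        edge.length = el if edge.head_node.parent_node is not None else 0.0
    return tree


def _evolve_on_tree(tree, root_seq, rng, protected=None, alphabet="ACGU"):
    """Evolve ``root_seq`` along ``tree`` (edge lengths = subs/site); leaf map."""
    out = {}

    def rec(node, seq):
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            s2 = mutate(seq, jc_subst_prob(d), rng, protected=protected, alphabet=alphabet)
            if child.is_leaf():
                out[child.taxon.label] = s2
            else:
                rec(child, s2)

    rec(tree.seed_node, root_seq)
    return out


# --------------------------------------------------------------------------
# codon machinery


def _codon_map(table_id: int):
    table = CodonTable.unambiguous_rna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    stops = sorted(table.stop_codons)
    return by_aa, stops


def _backtranslate(aa_seq: str, rng, table_id: int) -> str:
    by_aa, _ = _codon_map(table_id)
    return "".join(
        by_aa[aa][rng.integers(0, len(by_aa[aa]))] for aa in aa_seq
    )


def translate_rna(seq: str, table_id: int = 1) -> str:
    """Translate an RNA sequence (length trimmed to a codon multiple); '*' = stop."""
    n = len(seq) - len(seq) % 3
    return str(Seq(as_dna(seq[:n])).translate(table=table_id))


def _repair_stops(orf_rna: str, table_id: int) -> str:
    """Replace internal stop codons introduced by mutation with sense codons."""
    _, stops = _codon_map(table_id)
    fix = {"UAA": "CAA", "UAG": "CAG", "UGA": "CGA"}
    codons = [orf_rna[i : i + 3] for i in range(0, len(orf_rna) - 3, 3)]
    codons = [fix.get(c, c) if c in stops else c for c in codons]
    return "".join(codons) + orf_rna[len(codons) * 3 :]


def _make_orf(kind: str, rng, table_id: int):
    """Ancestral IEP ORF (RNA incl. terminal stop) + protected-position mask."""
    n_aa = RTM_LEN if kind == "RTM" else LHE_LEN
    motifs = RTM_MOTIF_POS if kind == "RTM" else LHE_MOTIF_POS
    aa = ["M"] + [AA_ALPHABET[rng.integers(0, 20)] for _ in range(n_aa - 1)]
    for pos, motif in motifs.items():
        aa[pos : pos + len(motif)] = list(motif)
    rna = _backtranslate("".join(aa), rng, table_id) + "UAA"
    protected = np.zeros(len(rna), dtype=bool)
    protected[0:3] = True  # start codon
    protected[-3:] = True  # terminal stop
    for pos, motif in motifs.items():
        protected[pos * 3 : (pos + len(motif)) * 3] = True
    return rna, protected


# --------------------------------------------------------------------------
# segment skeleton

#: canonical accessory sub-helix sizes (stem, loop); total sizes are distinct
#: so positional labelling can fingerprint them.
DI_CHILD_SIZES = {
    "Ia": (4, 4),  # 12 nt
    "IC2": (5, 5),  # 15 nt
    "ID2": (6, 4),  # 16 nt
    "ID2a": (5, 6),  # 16 nt (distinguished from ID2 by stem/loop split)
    "IE": (7, 4),  # 18 nt
}

# DI children in canonical 5'->3' order (optional ones marked by flags)
DI_CHILD_ORDER = ["Ia", "pad", "EBS2h", "IC2", "ID2", "ID2a", "IE", "EBS1h", "EBS3h"]


@dataclass
class Segment:
    label: str  # unique slot id (also the element name used for masking)
    seq: str
    db: str
    protected: bool = False  # excluded from family-level evolution

    def __post_init__(self):
        if len(self.seq) != len(self.db):
            raise SimulationError(f"segment {self.label}: seq/db length mismatch")


def _hairpin(rng, stem: int, loop: int | str) -> tuple[str, str]:
    loop_seq = loop if isinstance(loop, str) else random_seq(rng, loop)
    s5 = random_seq(rng, stem)
    seq = s5 + loop_seq + revcomp_rna(s5)
    db = "(" * stem + "." * len(loop_seq) + ")" * stem
    return seq, db


def _build_skeleton(rng, scaffold_extra: int, table_id: int):
    """Ancestral (root) sequence for every segment slot a family may carry."""
    seg: dict[str, Segment] = {}

    def put(label, seq, db=None, protected=False):
        seg[label] = Segment(label, seq, "." * len(seq) if db is None else db, protected)

    put("motif5", FIVE_PRIME_MOTIF, protected=True)
    # DI outer stem
    di5 = random_seq(rng, 8)
    put("DI_stem5", di5, "(" * 8)
    for name in DI_CHILD_ORDER:
        put(f"jd_{name}", random_seq(rng, 1))
        if name == "pad":
            if scaffold_extra > 0:
                stem = max((scaffold_extra - 8) // 2, 4)
                s, d = _hairpin(rng, stem, 8)
                put("pad", s, d)
            continue
        if name == "EBS2h":
            s5 = random_seq(rng, 4)
            put("EBS2h_5", s5, "((((")
            put("EBS2", random_seq(rng, 6))  # overridden per family
            put("EBS2h_3", revcomp_rna(s5), "))))")
        elif name == "EBS1h":
            s5 = random_seq(rng, 4)
            put("EBS1h_5", s5, "((((")
            put("EBS1", random_seq(rng, 6))
            put("EBS1h_3", revcomp_rna(s5), "))))")
        elif name == "EBS3h":
            s5 = random_seq(rng, 4)
            put("EBS3h_5", s5, "((((")
            put("EBS3", random_seq(rng, 3))
            put("EBS3h_3", revcomp_rna(s5), "))))")
        else:
            stem, loop = DI_CHILD_SIZES[name]
            s, d = _hairpin(rng, stem, loop)
            put(name, s, d)
    put("jd_end", random_seq(rng, 1))
    put("DI_stem3", revcomp_rna(di5), ")" * 8)

    put("j12", random_seq(rng, 2))
    s, d = _hairpin(rng, 7, 5)
    put("DII", s, d)
    put("j23", random_seq(rng, 4))  # subgroup-diagnostic tetramer, overridden
    s, d = _hairpin(rng, 6, 4)
    put("DIII", s, d)
    put("j3a", random_seq(rng, 2))
    s, d = _hairpin(rng, 5, 4)
    put("DIIIa", s, d)
    put("j3b", random_seq(rng, 2))

    div5 = random_seq(rng, 8)
    put("DIV_stem5", div5, "(" * 8)
    put("DIV_pre", random_seq(rng, 3))
    # ORF slots (ancestral RT/M; LHE ancestors are drawn per invasion event)
    orf, prot = _make_orf("RTM", rng, table_id)
    put("ORF_RTM", orf)
    seg["ORF_RTM"].orf_protected = prot
    put("DIV_plain", random_seq(rng, 12))
    put("DIV_post", random_seq(rng, 3))
    put("DIV_stem3", revcomp_rna(div5), ")" * 8)

    put("j45", random_seq(rng, 2))  # subgroup-diagnostic dimer, overridden
    dv5 = "GAGCGGUCUAACGC"
    put("DV", dv5 + "UUAAGC" + revcomp_rna(dv5), "(" * 14 + "." * 6 + ")" * 14, protected=True)
    put("j56", random_seq(rng, 2))
    # DVI: 7-bp stem, UUCG loop, bulged branch-point A 8 nt from the intron 3' end
    dvi5 = random_seq(rng, 7)
    rc = revcomp_rna(dvi5)
    put("DVI", dvi5 + "UUCG" + rc[:2] + "A" + rc[2:], "(" * 7 + "...." + "))" + "." + ")" * 5)
    bp_mask = np.zeros(19, dtype=bool)
    # the loop and the bulged branch-point adenosine are conserved unless
    # flagged (keeps the unpaired DVI content under generator control)
    bp_mask[7:11] = True
    bp_mask[13] = True
    seg["DVI"].orf_protected = bp_mask
    put("term3", "AU", protected=True)
    return seg


def _family_slot_list(spec: FamilySpec, scaffold_extra: int) -> list[str]:
    """Ordered segment slots making up one family's template."""
    flags = spec.degenerations
    slots: list[str] = []
    if "linker" in flags:
        slots.append("linker")
    slots.append("motif5")
    slots.append("DI_stem5")

    def child(name):
        nonlocal slots
        slots.append(f"jd_{name}")
        if name == "EBS2h":
            slots += ["EBS2h_5", "EBS2", "EBS2h_3"]
        elif name == "EBS1h":
            slots += ["EBS1h_5", "EBS1", "EBS1h_3"]
        elif name == "EBS3h":
            slots += ["EBS3h_5", "EBS3", "EBS3h_3"]
        else:
            slots.append(name)

    if spec.subgroup == "IIB2":
        child("Ia")
    # the IIB-like lineage has a drastically reduced scaffold: no DI padding
    if scaffold_extra > 0 and spec.subgroup != "IIB-like":
        child("pad")
    child("EBS2h")
    if "lose_IC2" not in flags:
        child("IC2")
    if "lose_ID2" not in flags:
        child("ID2")
    if "add_ID2a" in flags:
        child("ID2a")
    if "add_IE" in flags:
        child("IE")
    child("EBS1h")
    child("EBS3h")
    slots += ["jd_end", "DI_stem3", "j12", "DII", "j23", "DIII"]
    if "add_DIIIa" in flags:
        slots += ["j3a", "DIIIa", "j3b"]
    else:
        slots += ["j3a"]
    slots += ["DIV_stem5", "DIV_pre"]
    if "orf_absent" in flags or spec.iep == "none":
        slots.append("DIV_plain")
    elif spec.iep == "RTM":
        slots.append("ORF_RTM")
    else:
        slots.append("ORF_LHE")  # resolved to the event-specific sequence
    slots += ["DIV_post", "DIV_stem3", "j45", "DV", "j56", "DVI", "term3"]
    return slots


#: segment labels that belong to core domains, for layout truth
_DOMAIN_OF = {}
for _l in ("DI_stem5", "DI_stem3", "jd_end"):
    _DOMAIN_OF[_l] = "DI"
for _l in DI_CHILD_ORDER + [f"jd_{n}" for n in DI_CHILD_ORDER] + [
    "EBS2h_5", "EBS2", "EBS2h_3", "EBS1h_5", "EBS1", "EBS1h_3",
    "EBS3h_5", "EBS3", "EBS3h_3",
]:
    _DOMAIN_OF[_l] = "DI"
_DOMAIN_OF.update({"DII": "DII", "DIII": "DIII", "DIIIa": "DIIIa", "DV": "DV", "DVI": "DVI"})
for _l in ("DIV_stem5", "DIV_pre", "ORF_RTM", "ORF_LHE", "DIV_plain", "DIV_post", "DIV_stem3"):
    _DOMAIN_OF[_l] = "DIV"


@dataclass
class FamilyTemplate:
    """Pre-mutation template for one family, with full ground truth."""

    spec: FamilySpec
    segments: list  # list[(label, seq, db)]
    reference_gene: str  # DNA, root copy of the host gene
    truth: dict = field(default_factory=dict)

    @property
    def family_id(self) -> str:
        return self.spec.family_id

    @property
    def sequence(self) -> str:
        return "".join(s for _, s, _ in self.segments)

    @property
    def dot_bracket(self) -> str:
        return "".join(d for _, _, d in self.segments)

    def segment_intervals(self) -> dict[str, tuple[int, int]]:
        """1-based inclusive interval per segment label."""
        out, pos = {}, 0
        for label, s, _ in self.segments:
            out[label] = (pos + 1, pos + len(s))
            pos += len(s)
        return out

    def domain_intervals(self) -> dict[str, tuple[int, int]]:
        segs = self.segment_intervals()
        out: dict[str, tuple[int, int]] = {}
        for label, iv in segs.items():
            dom = _DOMAIN_OF.get(label)
            if dom is None:
                continue
            if dom in out:
                out[dom] = (min(out[dom][0], iv[0]), max(out[dom][1], iv[1]))
            else:
                out[dom] = iv
        return out

    def orf_interval(self) -> tuple[int, int] | None:
        segs = self.segment_intervals()
        for label in ("ORF_RTM", "ORF_LHE"):
            if label in segs:
                return segs[label]
        return None

    def upstream_exon(self, exon_len: int) -> str:
        gene = self.reference_gene
        return gene[max(0, self.spec.site - exon_len) : self.spec.site]

    def downstream_exon(self, exon_len: int) -> str:
        gene = self.reference_gene
        return gene[self.spec.site : self.spec.site + exon_len]


def _iupac_junction(rng, spec: FamilySpec) -> tuple[str, str]:
    """Subgroup-diagnostic (DII-DIII tetramer, DIV-DV dimer)."""
    sg = spec.subgroup
    if sg == "IIA1":
        # BVGA, avoiding G at position 1 so the draw cannot also match RRGA
        tet = draw_from_pattern(rng, "BVGA", forbid={0: {"G"}})
        dim = "CC"
    elif sg == "IIA2":
        # RRGA with A at position 1 (unambiguous vs BVGA)
        tet = "A" + draw_from_pattern(rng, "RGA")
        dim = "CC"
    else:
        # non-IIA: tetramer must match neither BVGA nor RRGA (position 3 != G)
        tet = draw_from_pattern(rng, "NNNN", forbid={2: {"G"}})
        if sg == "IIB1":
            dim = draw_from_pattern(rng, "YW")
        elif sg == "IIB2":
            dim = draw_from_pattern(rng, "RG")
        else:  # IIB-like: matches neither YW nor RG
            dim = "CC"
    return tet, dim


def _apply_leaf_overrides(
    spec: FamilySpec,
    slots: list[str],
    seqs: dict[str, str],
    dbs: dict[str, str],
    ref_gene: str,
    rng,
    table_id: int,
):
    """Family-specific sequence for diagnostic/EBS/degeneration slots."""
    flags = spec.degenerations
    site = spec.site
    ibs1 = as_rna(ref_gene[site - 6 : site])
    ibs2 = as_rna(ref_gene[site - 12 : site - 6])
    ibs3 = as_rna(ref_gene[site : site + 1])

    tet, dim = _iupac_junction(rng, spec)
    seqs["j23"], seqs["j45"] = tet, dim
    seqs["EBS1"] = revcomp_rna(ibs1)
    seqs["EBS2"] = revcomp_rna(ibs2)
    mid = revcomp_rna(ibs3)
    flank = [b for b in "ACGU" if b != mid]
    seqs["EBS3"] = flank[rng.integers(0, 3)] + mid + flank[rng.integers(0, 3)]
    if "linker" in flags:
        n = int(rng.integers(2, 11))
        seqs["linker"] = random_seq(rng, n)
        dbs["linker"] = "." * n
    if "no_branchpoint_A" in flags:
        # remove the bulged A (position 14 of the 19-nt DVI)
        s, d = seqs["DVI"], dbs["DVI"]
        seqs["DVI"], dbs["DVI"] = s[:13] + s[14:], d[:13] + d[14:]
    if "ORF_LHE" in slots and "orf_premature_stop" in flags:
        s = seqs["ORF_LHE"]
        stop_at = 100 * 3
        seqs["ORF_LHE"] = s[:stop_at] + "UAA" + s[stop_at + 3 :]
    if "ORF_RTM" in slots and "orf_premature_stop" in flags:
        s = seqs["ORF_RTM"]
        stop_at = 199 * 3  # internal stop at codon 200
        seqs["ORF_RTM"] = s[:stop_at] + "UAA" + s[stop_at + 3 :]


def _verify_truth(template: FamilyTemplate, exon_len: int, table_id: int, rng) -> None:
    """Record detector-verified ground truth on the pre-mutation template.

    For ``lose_EBS2`` the EBS2 loop is rejection-resampled until the detector
    reports the site as lost (so truth always matches the emitted template).
    """
    from .structure import (
        detect_branchpoint,
        detect_ebs_ibs,
        detect_terminal_elements,
        parse_domains,
    )
    from .iep import annotate_iep

    spec = template.spec
    flags = spec.degenerations

    if "lose_EBS2" in flags:
        for _ in range(60):
            layout = parse_domains(template.sequence, template.dot_bracket)
            rep = detect_ebs_ibs(
                layout,
                template.sequence,
                as_rna(template.upstream_exon(exon_len)),
                as_rna(template.downstream_exon(exon_len)),
            )
            if rep.ebs2.status != "found":
                break
            for i, (label, s, d) in enumerate(template.segments):
                if label == "EBS2":
                    template.segments[i] = (label, random_seq(rng, 6), d)
                    break

    seq, db = template.sequence, template.dot_bracket
    layout = parse_domains(seq, db)
    rep = detect_ebs_ibs(
        layout, seq, as_rna(template.upstream_exon(exon_len)),
        as_rna(template.downstream_exon(exon_len)),
    )
    motif, linker_len, ay = detect_terminal_elements(seq)
    bp = detect_branchpoint(layout, seq)
    iep = annotate_iep(seq, layout, translation_table=table_id)

    segs = template.segment_intervals()
    template.truth = {
        "family": spec.family_id,
        "host_gene": spec.host_gene,
        "site": spec.site,
        "subgroup": spec.subgroup,
        "iep_type": iep.type,
        "iep_status": iep.status,
        "length": len(seq),
        "linker_len": linker_len,
        "branchpoint": bp[1] if bp[0] == "present" else -1,
        "ebs1_status": rep.ebs1.status,
        "ebs1_seq": rep.ebs1.sequence or "",
        "ebs2_status": rep.ebs2.status,
        "ebs2_seq": rep.ebs2.sequence or "",
        "ebs3_status": rep.ebs3.status,
        "ebs3_seq": rep.ebs3.sequence or "",
        "has_Ia": int("Ia" in segs),
        "has_IC2": int("IC2" in segs),
        "has_ID2": int("ID2" in segs),
        "has_ID2a": int("ID2a" in segs),
        "has_IE": int("IE" in segs),
        "has_DIIIa": int("DIIIa" in segs),
        "orf_start": (template.orf_interval() or (-1, -1))[0],
        "orf_end": (template.orf_interval() or (-1, -1))[1],
        "domains": ";".join(
            f"{d}:{a}-{b}" for d, (a, b) in sorted(template.domain_intervals().items())
        ),
    }


def _invasion_events(families) -> list[list[str]]:
    """Group LHE families into invasion events via invasion_donor links."""
    lhe = [f for f in families if f.iep == "LHE"]
    parent = {f.family_id: f.family_id for f in lhe}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for f in lhe:
        if f.invasion_donor is not None and f.invasion_donor in parent:
            parent[find(f.family_id)] = find(f.invasion_donor)
    groups: dict[str, list[str]] = {}
    for f in lhe:
        groups.setdefault(find(f.family_id), []).append(f.family_id)
    return [groups[k] for k in sorted(groups)]


def build_family_templates(config: SimConfig):
    """Build all family templates (and reference genes) for a configuration.

    Returns ``(templates, guide_tree, reference_genes)`` where ``templates``
    maps family id -> :class:`FamilyTemplate` and ``reference_genes`` maps
    host gene -> root DNA sequence.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    keys = ["skeleton", "genes", "famevo", "events", "leaves", "verify"]
    streams = dict(zip(keys, [np.random.default_rng(s) for s in ss.spawn(len(keys))]))

    skeleton = _build_skeleton(streams["skeleton"], config.scaffold_extra, config.translation_table)
    guide = family_guide_tree(config.families, config.family_divergence)

    # reference host genes (shared by co-hosted families)
    gene_rng = streams["genes"]
    ref_genes: dict[str, str] = {}
    for spec in config.families:
        need = spec.site + config.exon_len
        if spec.host_gene not in ref_genes or len(ref_genes[spec.host_gene]) < need:
            ref_genes[spec.host_gene] = random_seq(gene_rng, need + 10, "ACGT")

    # family-level evolution of every shared slot
    fam_rng = streams["famevo"]
    evolved: dict[str, dict[str, str]] = {}
    for label in sorted(skeleton):
        seg = skeleton[label]
        if seg.protected:
            evolved[label] = {
                leaf.taxon.label: seg.seq for leaf in guide.leaf_node_iter()
            }
        else:
            protected = getattr(seg, "orf_protected", None)
            evolved[label] = _evolve_on_tree(guide, seg.seq, fam_rng, protected=protected)

    # independent ancestral LHE per invasion event, evolved on the same tree
    ev_rng = streams["events"]
    lhe_leaf_seq: dict[str, str] = {}
    for event in _invasion_events(config.families):
        orf, prot = _make_orf("LHE", ev_rng, config.translation_table)
        leafmap = _evolve_on_tree(guide, orf, ev_rng, protected=prot)
        for fam in event:
            lhe_leaf_seq[fam] = leafmap[fam]

    leaf_ss = np.random.SeedSequence(config.seed + 10_001)
    leaf_rngs = leaf_ss.spawn(len(config.families))
    verify_rng = streams["verify"]

    templates: dict[str, FamilyTemplate] = {}
    for spec, lss in zip(config.families, leaf_rngs):
        rng = np.random.default_rng(lss)
        fam = spec.family_id
        slots = _family_slot_list(spec, config.scaffold_extra)
        seqs = {}
        dbs = {}
        for label in slots:
            if label == "linker":
                continue
            if label == "ORF_LHE":
                seqs[label] = _repair_stops(lhe_leaf_seq[fam], config.translation_table)
                dbs[label] = "." * len(seqs[label])
            else:
                seqs[label] = evolved[label][fam]
                if label == "ORF_RTM":
                    seqs[label] = _repair_stops(seqs[label], config.translation_table)
                dbs[label] = skeleton[label].db
        _apply_leaf_overrides(
            spec, slots, seqs, dbs, ref_genes[spec.host_gene], rng, config.translation_table
        )
        segments = [(label, seqs[label], dbs[label]) for label in slots]
        template = FamilyTemplate(spec=spec, segments=segments, reference_gene=ref_genes[spec.host_gene])
        _verify_truth(template, config.exon_len, config.translation_table, verify_rng)
        templates[fam] = template
    return templates, guide, ref_genes


def build_intron_template(spec: FamilySpec, seed: int, scaffold_extra: int = 0):
    """Build a single family template without between-family evolution.

    Returns ``(sequence, dot_bracket, truth)``. A synthetic reference host
    gene is drawn from the same seed; use :func:`build_family_templates` for
    cohort-consistent templates.
    """
    spec.validate()
    cfg = SimConfig(n_species=3, seed=seed, families=(spec,), scaffold_extra=scaffold_extra)
    templates, _, _ = build_family_templates(cfg)
    t = templates[spec.family_id]
    return t.sequence, t.dot_bracket, t.truth


# --------------------------------------------------------------------------
# cohort-level evolution and emission


@dataclass
class EmittedIntron:
    instance_id: str
    genome_id: str
    species: str
    family: str
    host_gene: str
    site: int
    sequence: str  # RNA
    dot_bracket: str
    upstream_flank: str  # RNA (<= 20 nt)
    downstream_flank: str


@dataclass
class Cohort:
    config: SimConfig
    species_tree: dendropy.Tree
    guide_tree: dendropy.Tree
    templates: dict
    reference_genes: dict
    genomes: list  # list[Genome]-like dicts: id, species, sequence, gff rows
    introns: list  # list[EmittedIntron]
    truth_rows: list  # list[dict]


def _species_leaf_map(tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def evolve_cohort(templates, species_tree, config: SimConfig) -> Cohort:
    """Evolve family templates along the species tree and assemble genomes."""
    config.validate()
    ss = np.random.SeedSequence(config.seed + 20_002)
    keys = ["presence", "rna", "genes", "spacer"]
    streams = dict(zip(keys, [np.random.default_rng(s) for s in ss.spawn(len(keys))]))

    species = _species_leaf_map(species_tree)
    n = len(species)

    # per-family per-species intron copies
    copies: dict[str, dict[str, str]] = {}
    presence: dict[str, np.ndarray] = {}
    rna_rng = streams["rna"]
    pres_rng = streams["presence"]
    for fam in sorted(templates):
        t = templates[fam]
        seq = t.sequence
        rates = np.full(len(seq), float(config.subst_rate_rna))
        # subgroup-diagnostic junctions are conserved within a family
        segs = t.segment_intervals()
        for slot in ("j23", "j45"):
            if slot in segs:
                rates[segs[slot][0] - 1 : segs[slot][1]] = 0.0
        orf_iv = t.orf_interval()
        if orf_iv is not None:
            rates[orf_iv[0] - 1 : orf_iv[1]] = float(config.subst_rate_orf)
            # purifying selection: diagnostic motif codons and the start/stop
            # stay fixed within a family
            motifs = RTM_MOTIF_POS if t.spec.iep == "RTM" else LHE_MOTIF_POS
            a0 = orf_iv[0] - 1
            rates[a0 : a0 + 3] = 0.0
            rates[orf_iv[1] - 3 : orf_iv[1]] = 0.0
            for pos, motif in motifs.items():
                rates[a0 + 3 * pos : a0 + 3 * (pos + len(motif))] = 0.0

        out: dict[str, str] = {}
        _, stop_codons = _codon_map(config.translation_table)
        fix = {"UAA": "CAA", "UAG": "CAG", "UGA": "CGA"}

        def repair(s):
            # purifying selection on the IEP: revert nonsense mutations the
            # template did not carry (a planted premature stop is preserved)
            if orf_iv is None:
                return s
            a0 = orf_iv[0] - 1
            chars = list(s)
            for k in range(a0, orf_iv[1] - 2, 3):
                codon = s[k : k + 3]
                if codon in stop_codons and seq[k : k + 3] not in stop_codons:
                    chars[k : k + 3] = fix.get(codon, "CAA")
            return "".join(chars)

        def rec(node, s):
            for child in node.child_nodes():
                d = child.edge.length or 0.0
                p = 0.75 * (1.0 - np.exp(-4.0 * d * rates / 3.0))
                s2 = repair(mutate(s, p, rna_rng))
                if child.is_leaf():
                    out[child.taxon.label] = s2
                else:
                    rec(child, s2)

        rec(species_tree.seed_node, seq)
        copies[fam] = out
        presence[fam] = pres_rng.random(n) < t.spec.presence_prob

    # species copies of reference genes
    gene_rng = streams["genes"]
    gene_copies: dict[str, dict[str, str]] = {}
    for gene in sorted({t.spec.host_gene for t in templates.values()}):
        root = None
        for t in templates.values():
            if t.spec.host_gene == gene:
                root = t.reference_gene
                break
        out = {}

        def rec_g(node, s):
            for child in node.child_nodes():
                d = (child.edge.length or 0.0) * config.subst_rate_rna
                s2 = mutate(s, jc_subst_prob(d), gene_rng, alphabet="ACGT")
                if child.is_leaf():
                    out[child.taxon.label] = s2
                else:
                    rec_g(child, s2)

        rec_g(species_tree.seed_node, root)
        gene_copies[gene] = out

    fam_by_gene: dict[str, list[str]] = {}
    for fam in sorted(templates):
        fam_by_gene.setdefault(templates[fam].spec.host_gene, []).append(fam)

    spacer_rng = streams["spacer"]
    genomes, introns, truth_rows = [], [], []
    sp_index = {sp: i for i, sp in enumerate(species)}
    for sp in species:
        gid = f"{sp}_{config.organelle}"
        parts: list[str] = []
        gff: list[dict] = []
        pos = 0
        for gene in sorted(fam_by_gene):
            spacer = random_seq(spacer_rng, 30, "ACGT")
            parts.append(spacer)
            pos += 30
            gene_seq = gene_copies[gene][sp]
            present = [
                fam
                for fam in fam_by_gene[gene]
                if presence[fam][sp_index[sp]]
            ]
            present.sort(key=lambda f: templates[f].spec.site)
            gene_start = pos + 1
            cursor = 0  # reference-gene coordinate consumed so far
            gpos = pos
            exons: list[tuple[int, int]] = []
            intron_feats: list[dict] = []
            for fam in present:
                t = templates[fam]
                site = t.spec.site
                exon_piece = gene_seq[cursor:site]
                parts.append(exon_piece)
                exons.append((gpos + 1, gpos + len(exon_piece)))
                gpos += len(exon_piece)
                intron_rna = copies[fam][sp]
                intron_dna = as_dna(intron_rna)
                parts.append(intron_dna)
                iid = f"{fam}|{gid}"
                intron_feats.append(
                    {
                        "start": gpos + 1,
                        "end": gpos + len(intron_dna),
                        "id": iid,
                        "family": fam,
                    }
                )
                up = as_rna(gene_seq[max(0, site - 20) : site])
                down = as_rna(gene_seq[site : site + 20])
                introns.append(
                    EmittedIntron(
                        instance_id=iid,
                        genome_id=gid,
                        species=sp,
                        family=fam,
                        host_gene=gene,
                        site=site,
                        sequence=intron_rna,
                        dot_bracket=t.dot_bracket,
                        upstream_flank=up,
                        downstream_flank=down,
                    )
                )
                row = dict(t.truth)
                row.update(
                    intron_id=iid, genome_id=gid, species=sp, tree_leaf=sp
                )
                truth_rows.append(row)
                gpos += len(intron_dna)
                cursor = site
            tail = gene_seq[cursor:]
            parts.append(tail)
            exons.append((gpos + 1, gpos + len(tail)))
            gpos += len(tail)
            gff.append(
                {
                    "type": "gene",
                    "start": gene_start,
                    "end": gpos,
                    "id": f"{gene}.{gid}",
                    "gene": gene,
                }
            )
            for k, (s, e) in enumerate(exons, 1):
                gff.append(
                    {
                        "type": "exon",
                        "start": s,
                        "end": e,
                        "id": f"{gene}.{gid}.exon{k}",
                        "gene": gene,
                    }
                )
            for feat in intron_feats:
                gff.append(
                    {
                        "type": "intron",
                        "start": feat["start"],
                        "end": feat["end"],
                        "id": feat["id"],
                        "gene": gene,
                        "family": feat["family"],
                    }
                )
            pos = gpos
        genomes.append(
            {
                "id": gid,
                "species": sp,
                "organelle": config.organelle,
                "sequence": "".join(parts),
                "features": gff,
            }
        )

    return Cohort(
        config=config,
        species_tree=species_tree,
        guide_tree=None,
        templates=templates,
        reference_genes={g: gene_copies[g] for g in gene_copies},
        genomes=genomes,
        introns=introns,
        truth_rows=truth_rows,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Templates + species tree + cohort evolution in one call."""
    templates, guide, ref_genes = build_family_templates(config)
    tree = simulate_species_tree(config.n_species, config.birth_rate, config.seed + 1)
    cohort = evolve_cohort(templates, tree, config)
    cohort.guide_tree = guide
    cohort.reference_genes_root = ref_genes
    return cohort


TRUTH_COLUMNS = [
    "intron_id", "genome_id", "species", "tree_leaf", "family", "host_gene",
    "site", "subgroup", "iep_type", "iep_status", "length", "linker_len",
    "branchpoint", "ebs1_status", "ebs1_seq", "ebs2_status", "ebs2_seq",
    "ebs3_status", "ebs3_seq", "has_Ia", "has_IC2", "has_ID2", "has_ID2a",
    "has_IE", "has_DIIIa", "orf_start", "orf_end", "domains",
]


def emit_cohort(cohort: Cohort, out_dir: str) -> dict[str, str]:
    """Write the cohort to ``out_dir`` as plain-text files.

    Emits genomes.fasta, genes.gff3, introns.fasta, structures.db (dot-bracket),
    truth.tsv, tree.nwk, family_tree.nwk, reference_genes.fasta, manifest.tsv.
    """
    if not cohort.introns:
        raise SimulationError("cohort is empty")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def path(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    with open(path("genomes.fasta"), "w") as fh:
        for g in cohort.genomes:
            fh.write(f">{g['id']} species={g['species']} organelle={g['organelle']}\n")
            for i in range(0, len(g["sequence"]), 80):
                fh.write(g["sequence"][i : i + 80] + "\n")

    with open(path("genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in cohort.genomes:
            for f in g["features"]:
                attrs = f"ID={f['id']};gene={f['gene']}"
                if "family" in f:
                    attrs += f";Name={f['family']}"
                fh.write(
                    "\t".join(
                        [
                            g["id"], "intronscape-sim", f["type"],
                            str(f["start"]), str(f["end"]), ".", "+", ".", attrs,
                        ]
                    )
                    + "\n"
                )

    with open(path("introns.fasta"), "w") as fh:
        for it in cohort.introns:
            fh.write(f">{it.instance_id}\n")
            seq = as_dna(it.sequence)
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(path("structures.db"), "w") as fh:
        for it in cohort.introns:
            fh.write(f">{it.instance_id}\n{it.sequence}\n{it.dot_bracket}\n")

    import pandas as pd

    truth = pd.DataFrame(cohort.truth_rows)[TRUTH_COLUMNS]
    truth.to_csv(path("truth.tsv"), sep="\t", index=False)

    cohort.species_tree.write(path=path("tree.nwk"), schema="newick")
    if cohort.guide_tree is not None:
        cohort.guide_tree.write(path=path("family_tree.nwk"), schema="newick")

    ref_root = getattr(cohort, "reference_genes_root", None)
    if ref_root is None:
        ref_root = {g: t.reference_gene for g, t in
                    ((t.spec.host_gene, t) for t in cohort.templates.values())}
    with open(path("reference_genes.fasta"), "w") as fh:
        for gene in sorted(ref_root):
            fh.write(f">{gene}\n{ref_root[gene]}\n")

    with open(path("manifest.tsv"), "w") as fh:
        fh.write("genome_id\torganelle\tspecies\tfile\n")
        for g in cohort.genomes:
            fh.write(f"{g['id']}\t{g['organelle']}\t{g['species']}\tgenomes.fasta\n")
    return paths


# --------------------------------------------------------------------------
# family-representative views (for congruence analyses)


def _common_scaffold_slots(templates, fams) -> list[str]:
    """Segment slots shared by all selected families with identical length
    (ORF/DIV-interior and family-specific slots such as the linker excluded)."""
    per_fam = {f: dict((l, s) for l, s, _ in templates[f].segments) for f in fams}
    order = [l for l, _, _ in templates[fams[0]].segments]
    skip_prefix = ("ORF_", "DIV_plain", "linker")
    common = []
    for label in order:
        if label.startswith(skip_prefix):
            continue
        if not all(label in per_fam[f] for f in fams):
            continue
        if len({len(per_fam[f][label]) for f in fams}) == 1:
            common.append(label)
    if not common:
        raise SimulationError("no shared scaffold segments among selected families")
    return common


def family_scaffold_alignment(templates, families=None) -> dict[str, str]:
    """Positionally homologous scaffold alignment of family templates."""
    fams = sorted(templates) if families is None else list(families)
    if not fams:
        raise SimulationError("no families selected")
    common = _common_scaffold_slots(templates, fams)
    per_fam = {f: dict((l, s) for l, s, _ in templates[f].segments) for f in fams}
    return {f: "".join(per_fam[f][l] for l in common) for f in fams}


#: scaffold slots treated as mutation hotspots (masked before tree building):
#: accessory DI elements, the padding helix, and the diagnostic junctions
HOTSPOT_SLOTS = ("Ia", "pad", "IC2", "ID2", "ID2a", "IE", "DIIIa", "j23", "j45")


def scaffold_hotspot_regions(templates, families=None) -> list[tuple[str, int, int]]:
    """Hotspot-region spec (label, start, end) for the scaffold alignment.

    Coordinates are 1-based inclusive columns of the alignment produced by
    :func:`family_scaffold_alignment` on the same family selection.
    """
    fams = sorted(templates) if families is None else list(families)
    common = _common_scaffold_slots(templates, fams)
    per_fam = {f: dict((l, s) for l, s, _ in templates[f].segments) for f in fams}
    regions, pos = [], 0
    for label in common:
        L = len(per_fam[fams[0]][label])
        if label in HOTSPOT_SLOTS:
            regions.append((label, pos + 1, pos + L))
        pos += L
    return regions


def family_orf_proteins(templates, iep: str, table_id: int = 1) -> dict[str, str]:
    """Translated IEP protein per family (families of the requested type only)."""
    label = "ORF_RTM" if iep == "RTM" else "ORF_LHE"
    out = {}
    for fam in sorted(templates):
        t = templates[fam]
        if t.spec.iep != iep:
            continue
        for l, s, _ in t.segments:
            if l == label:
                prot = translate_rna(s, table_id)
                out[fam] = prot.split("*")[0] if "*" in prot else prot
    return out


# --------------------------------------------------------------------------
# demo rosters (the study conditions)


def demo_families(rich: bool = False) -> tuple[FamilySpec, ...]:
    """Default family rosters.

    ``rich=False``: 12 clean families (no degenerations) spanning IIA1/IIA2/
    IIB1/IIB2 with RT/M and LHE IEPs — the zero-mutation round-trip roster.

    ``rich=True``: a mitochondrial-genome-flavoured roster including DIIIa
    insertions, 5' linker + branch-point loss, EBS2 erosion, IC2/ID2 loss,
    premature-stop and absent ORFs, an IEP-lacking IIB-like family, and two
    independent LHE invasion events; presence probabilities follow reported
    occurrence frequencies for the corresponding real families.
    """
    F = FamilySpec
    if not rich:
        return (
            F("cox1", 199, "IIA1", "RTM"),
            F("cob", 877, "IIA1", "RTM"),
            F("cox2", 424, "IIA1", "RTM"),
            F("atp1", 1316, "IIA2", "RTM"),
            F("petD", 87, "IIA2", "RTM"),
            F("rnl", 1963, "IIB1", "RTM"),
            F("petB", 277, "IIB1", "RTM"),
            F("rns", 780, "IIB1", "RTM"),
            F("nad3", 216, "IIB2", "RTM"),
            F("cox2", 751, "IIB2", "RTM"),
            F("rnl", 2698, "IIB1", "LHE"),
            F("cox1", 874, "IIB2", "LHE"),
        )
    fs = frozenset
    return (
        F("atp1", 990, "IIA1", "RTM", 0.159, fs({"add_DIIIa"})),
        F("nad5", 1057, "IIA1", "RTM", 0.045, fs({"add_DIIIa", "add_IE"})),
        F("cox1", 199, "IIA1", "RTM", 0.25),
        F("atp1", 1316, "IIA2", "RTM", 0.05, fs({"lose_IC2"})),
        F("rnl", 1963, "IIB1", "RTM", 0.3),
        F("rns", 780, "IIB1", "RTM", 0.12, fs({"lose_IC2"})),
        F("petB", 277, "IIB1", "RTM", 0.2, fs({"add_ID2a"})),
        F("nad3", 216, "IIB2", "RTM", 0.523),
        F("cox2", 751, "IIB2", "RTM", 0.3, fs({"orf_premature_stop"})),
        F("rnl", 2698, "IIB1", "LHE", 0.3, fs({"linker", "no_branchpoint_A", "lose_EBS2", "lose_ID2"})),
        F("rns", 420, "IIB1", "LHE", 0.2, fs({"linker", "no_branchpoint_A"}), invasion_donor="rnl-2698"),
        F("cox1", 874, "IIB2", "LHE", 0.477),
        F("rns", 670, "IIB2", "LHE", 0.455, fs({"lose_EBS2"}), invasion_donor="cox1-874"),
        F("cox1", 686, "IIB2", "none", 0.35, fs({"linker", "no_branchpoint_A"})),
        F("infA", 62, "IIB-like", "none", 1.0, fs({"lose_EBS2", "no_branchpoint_A", "orf_absent", "lose_ID2"})),
    )
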