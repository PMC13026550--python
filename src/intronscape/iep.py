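"""Intron-encoded protein (IEP) annotation.

ORFs are searched in the three forward frames of DIV (IEPs are sense-encoded
there), translated with a configurable genetic code, and typed by motif
evidence: LAGLIDADG homing endonucleases (LHE) carry two copies of the
LAGLIDADG motif ~80-150 aa apart; reverse transcriptase/maturases (RT/M)
carry the catalytic [YF]xDD block plus at least one supporting RT block
([LIV]PQG). An IEP is intact when a single stop-free ORF covers the
motif-anchored core region; motif evidence without such an ORF means the
IEP is degenerated; no ORF and no evidence means it is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .simulate import translate_rna

__all__ = [
    "ORF",
    "IEPAnnotation",
    "MotifHit",
    "find_div_orfs",
    "classify_iep",
    "assess_intactness",
    "annotate_iep",
]

LAGLIDADG = "LAGLIDADG"
LHE_MAX_MISMATCH = 3
LHE_SPACING = (80, 150)  # aa between LAGLIDADG copy starts
CORE_PAD = 20  # aa either side of the motif-anchored span


class ORF(NamedTuple):
    interval: tuple  # nt coordinates in the searched sequence, 1-based inclusive
    protein: str  # stop-to-stop translation
    frame: int  # 0..2
    aa_span: tuple  # aa coordinates within the full-frame translation
    protein_from_aug: str  # trimmed to the first internal AUG ('' if none)


class MotifHit(NamedTuple):
    name: str
    position: int  # 0-based aa position in the full-frame translation
    score: int


@dataclass
class IEPAnnotation:
    type: str = "none"  # RTM | LHE | none
    status: str = "absent"  # intact | degenerated | absent
    orf_interval: tuple | None = None  # intron/DIV coordinates of the best ORF
    protein: str | None = None
    evidence: list = field(default_factory=list)
    remnant_candidates: list = field(default_factory=list)
    conflict: bool = False
    warnings: list = field(default_factory=list)


def find_div_orfs(div_sequence: str, translation_table: int = 1, min_codons: int = 100) -> list[ORF]:
    """Enumerate stop-to-stop ORFs >= ``min_codons`` in the forward frames.

    Spans start at the first in-frame codon after the previous stop (or the
    DIV 5' boundary); the AUG-trimmed protein is reported alongside. Longest
    first.
    """
    orfs: list[ORF] = []
    for frame in range(3):
        prot = translate_rna(div_sequence[frame:], translation_table)
        start = 0
        for chunk in prot.split("*"):
            if len(chunk) >= min_codons:
                nt_start = frame + 3 * start + 1
                nt_end = frame + 3 * (start + len(chunk))
                aug = chunk.find("M")
                orfs.append(
                    ORF(
                        (nt_start, nt_end),
                        chunk,
                        frame,
                        (start, start + len(chunk)),
                        chunk[aug:] if aug >= 0 else "",
                    )
                )
            start += len(chunk) + 1  # skip the stop
    orfs.sort(key=lambda o: (-len(o.protein), o.frame, o.interval[0]))
    return orfs


def _lhe_hits(protein: str) -> list[MotifHit]:
    hits = []
    L = len(LAGLIDADG)
    for i in range(len(protein) - L + 1):
        w = protein[i : i + L]
        if "*" in w:
            continue
        mm = sum(a != b for a, b in zip(w, LAGLIDADG))
        if mm <= LHE_MAX_MISMATCH:
            hits.append(MotifHit("LAGLIDADG", i, L - mm))
    # keep local maxima (suppress overlapping shifted matches)
    pruned = []
    for h in sorted(hits, key=lambda h: (-h.score, h.position)):
        if all(abs(h.position - p.position) >= L for p in pruned):
            pruned.append(h)
    return sorted(pruned, key=lambda h: h.position)


def _rtm_hits(protein: str) -> list[MotifHit]:
    hits = []
    for i in range(len(protein) - 3):
        w = protein[i : i + 4]
        if "*" in w:
            continue
        if w[0] in "YF" and w[2:4] == "DD":
            hits.append(MotifHit("YxDD", i, 4))
        if w[0] in "LIV" and w[1:4] == "PQG":
            hits.append(MotifHit("RT-block", i, 4))
    return hits


def classify_iep(protein: str) -> tuple[str, list[MotifHit]]:
    """Type a candidate IEP from motif evidence.

    LHE: >=2 LAGLIDADG matches (<=3 mismatches) spaced 80-150 aa. RT/M: the
    [YF]xDD catalytic block plus >=1 supporting RT block. If both patterns
    qualify the higher-scoring type wins (flagged by :func:`annotate_iep`).
    """
    if len(protein) < 50:
        return "none", []
    lhe = _lhe_hits(protein)
    lhe_pair = None
    for i in range(len(lhe)):
        for j in range(i + 1, len(lhe)):
            gap = lhe[j].position - lhe[i].position
            if LHE_SPACING[0] <= gap <= LHE_SPACING[1]:
                lhe_pair = (lhe[i], lhe[j])
    rtm = _rtm_hits(protein)
    has_cat = any(h.name == "YxDD" for h in rtm)
    has_sup = any(h.name == "RT-block" for h in rtm)
    rtm_ok = has_cat and has_sup
    if lhe_pair and rtm_ok:
        lhe_score = lhe_pair[0].score + lhe_pair[1].score
        rtm_score = sum(h.score for h in rtm)
        return ("LHE", list(lhe_pair)) if lhe_score >= rtm_score else ("RTM", rtm)
    if lhe_pair:
        return "LHE", list(lhe_pair)
    if rtm_ok:
        return "RTM", rtm
    return "none", lhe + rtm  # remnant-level evidence, if any


def assess_intactness(orfs: list[ORF], expected_core: tuple | None) -> str:
    """intact / degenerated / absent from ORF coverage of the core region.

    ``expected_core`` is an aa interval in full-frame translation
    coordinates (half-open); intact requires a single stop-free ORF covering
    it. With no ORFs at all the IEP is absent.
    """
    if not orfs:
        return "absent"
    if expected_core is None:
        return "degenerated"
    a, b = expected_core
    for o in orfs:
        if o.aa_span[0] <= a and b <= o.aa_span[1]:
            return "intact"
    return "degenerated"


def annotate_iep(
    intron_sequence: str,
    layout=None,
    translation_table: int = 1,
    min_codons: int = 100,
    div_interval: tuple | None = None,
) -> IEPAnnotation:
    """Full IEP annotation of one intron (ORF search restricted to DIV)."""
    ann = IEPAnnotation()
    if div_interval is None and layout is not None:
        div_interval = layout.domains.get("DIV")
    if div_interval is None:
        ann.warnings.append("DIV not available; IEP not assessable")
        return ann
    a, b = div_interval
    div = intron_sequence[a - 1 : b]
    orfs = find_div_orfs(div, translation_table, min_codons)

    # per-ORF typing: an intact IEP must qualify within a single ORF
    best = None
    for o in orfs:
        t, ev = classify_iep(o.protein)
        if t != "none":
            score = sum(h.score for h in ev)
            if best is None or score > best[2]:
                best = (o, t, score, ev)
    if best is not None:
        o, t, _, ev = best
        ann.type = t
        ann.status = "intact"
        ann.orf_interval = (a + o.interval[0] - 1, a + o.interval[1] - 1)
        ann.protein = o.protein
        ann.evidence = ev
        return ann

    # no single qualifying ORF: pool motif evidence across whole frames
    for frame in range(3):
        prot = translate_rna(div[frame:], translation_table)
        lhe = _lhe_hits(prot)
        rtm = _rtm_hits(prot)
        lhe_pair = None
        for i in range(len(lhe)):
            for j in range(i + 1, len(lhe)):
                if LHE_SPACING[0] <= lhe[j].position - lhe[i].position <= LHE_SPACING[1]:
                    lhe_pair = (lhe[i], lhe[j])
        has_cat = any(h.name == "YxDD" for h in rtm)
        has_sup = any(h.name == "RT-block" for h in rtm)
        if lhe_pair or (has_cat and has_sup):
            ann.type = "LHE" if lhe_pair else "RTM"
            hits = list(lhe_pair) if lhe_pair else rtm
            ann.evidence = hits
            core = (
                max(0, min(h.position for h in hits) - CORE_PAD),
                max(h.position + len(LAGLIDADG) for h in hits) + CORE_PAD,
            )
            frame_orfs = [o for o in orfs if o.frame == frame]
            ann.status = assess_intactness(frame_orfs, core)
            if ann.status == "absent":
                ann.status = "degenerated"  # motif evidence exists
            if frame_orfs:
                o = frame_orfs[0]
                ann.orf_interval = (a + o.interval[0] - 1, a + o.interval[1] - 1)
                ann.protein = o.protein
            return ann
        if lhe or rtm:
            ann.remnant_candidates.extend(lhe + rtm)
    # nothing classifiable
    ann.type = "none"
    ann.status = "absent" if not orfs else "degenerated"
    if orfs:
        ann.warnings.append("ORF(s) present without RT/M or LHE motif evidence")
        ann.status = "absent"
    return ann
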