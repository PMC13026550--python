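"""Rule-based annotation of group II intron RNA features.

Works from a sequence plus its secondary structure in dot-bracket notation
(simulator ground truth or user-supplied); no folding is performed. The six
core domains DI-DVI are the top-level helices hanging off the exterior loop
between the terminal motifs; a seventh top-level helix between DIII and DIV
is the accessory DIIIa element.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._seq import is_complementary, matches_iupac

__all__ = [
    "DomainLayout",
    "StructureFeatures",
    "ConsensusResult",
    "EBSSite",
    "EBSReport",
    "StructureError",
    "parse_domains",
    "build_consensus",
    "detect_terminal_elements",
    "detect_branchpoint",
    "detect_ebs_ibs",
    "extract_junctions",
    "label_accessories",
    "classify_subgroup",
    "annotate_intron",
]

FIVE_PRIME_MOTIF = "GUGCGA"
CORE_DOMAINS = ("DI", "DII", "DIII", "DIV", "DV", "DVI")
ACCESSORY_KEYS = ("Ia", "IC2", "ID2", "ID2a", "IE", "DIIIa")

#: (stem, loop) fingerprints of canonical DI accessory sub-helices
_ACCESSORY_FINGERPRINT = {
    (4, 4): "Ia",
    (5, 5): "IC2",
    (6, 4): "ID2",
    (5, 6): "ID2a",
    (7, 4): "IE",
}


class StructureError(ValueError):
    pass


@dataclass
class DomainLayout:
    """Intervals (1-based inclusive) of core domains and accessory elements."""

    domains: dict  # name -> (start, end)
    accessories: dict = field(default_factory=dict)
    linker: tuple | None = None
    dot_bracket: str = ""
    helices: list = field(default_factory=list)  # top-level helix spans
    warnings: list = field(default_factory=list)

    @property
    def dv_length(self) -> int | None:
        if "DV" not in self.domains:
            return None
        a, b = self.domains["DV"]
        return b - a + 1


def _pair_map(db: str) -> dict[int, int]:
    stack, pairs = [], {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced dot-bracket (unmatched ')' at {i + 1})")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise StructureError(f"illegal structure character {c!r} at {i + 1}")
    if stack:
        raise StructureError(f"unbalanced dot-bracket (unmatched '(' at {stack[-1] + 1})")
    return pairs


def _top_level_helices(db: str) -> list[tuple[int, int]]:
    """0-based (start, end) spans of helices hanging off the exterior loop."""
    pairs = _pair_map(db)
    spans = []
    i = 0
    while i < len(db):
        if db[i] == "(":
            j = pairs[i]
            spans.append((i, j))
            i = j + 1
        else:
            i += 1
    return spans


def parse_domains(sequence: str, dot_bracket: str) -> DomainLayout:
    """Assign DI-DVI (and DIIIa) to the top-level helices of a structure."""
    if len(sequence) != len(dot_bracket):
        raise StructureError("sequence and dot-bracket differ in length")
    spans = _top_level_helices(dot_bracket)
    n = len(spans)
    if n < 5 or n > 8:
        raise StructureError(
            f"expected 5-8 top-level helices for a group II layout, found {n}"
        )
    notes = []
    domains: dict[str, tuple[int, int]] = {}
    accessories: dict[str, tuple[int, int]] = {}

    def iv(span):
        return (span[0] + 1, span[1] + 1)

    if n == 6:
        for name, span in zip(CORE_DOMAINS, spans):
            domains[name] = iv(span)
    elif n == 7:
        order = ["DI", "DII", "DIII", "DIIIa", "DIV", "DV", "DVI"]
        for name, span in zip(order, spans):
            if name == "DIIIa":
                accessories[name] = iv(span)
            else:
                domains[name] = iv(span)
    elif n == 5:
        notes.append("5 top-level helices: assuming DIV is missing")
        for name, span in zip(("DI", "DII", "DIII", "DV", "DVI"), spans):
            domains[name] = iv(span)
    else:  # n == 8
        notes.append("8 top-level helices: labelling extras after DIII as DIIIa/X")
        order = ["DI", "DII", "DIII", "DIIIa", "X", "DIV", "DV", "DVI"]
        for name, span in zip(order, spans):
            if name in ("DIIIa", "X"):
                accessories[name] = iv(span)
            else:
                domains[name] = iv(span)

    dvl = None
    if "DV" in domains:
        a, b = domains["DV"]
        dvl = b - a + 1
        if not 30 <= dvl <= 40:
            notes.append(f"atypical DV length {dvl} nt (expected ~34)")

    # unpaired prefix before DI, minus the 6-nt terminal motif, is the linker
    first = spans[0][0]
    linker = (1, first - 6) if first > 6 else None

    return DomainLayout(
        domains=domains,
        accessories=accessories,
        linker=linker,
        dot_bracket=dot_bracket,
        helices=[iv(s) for s in spans],
        warnings=notes,
    )


# --------------------------------------------------------------------------
# consensus representative


@dataclass
class ConsensusResult:
    representative: str
    tie_columns: set  # 0-based alignment columns where the max was tied
    kept_columns: list  # 0-based alignment columns retained
    column_frequencies: list  # per kept column: dict symbol -> frequency


_CONSENSUS_ORDER = "ACGU"


def build_consensus(aligned: list[str]) -> ConsensusResult:
    """Majority-rule representative of an aligned intron family.

    At each column the most frequent symbol wins; gaps count as a symbol and
    gap-majority columns are dropped; ties among nucleotides are broken
    alphabetically (A<C<G<U) and recorded.
    """
    rows = list(aligned)
    if not rows:
        raise ValueError("empty alignment")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    rep, ties, kept, freqs = [], set(), [], []
    for c in range(L):
        col = [r[c] for r in rows]
        counts = {s: 0 for s in _CONSENSUS_ORDER}
        gaps = 0
        for s in col:
            s = "U" if s == "T" else s
            if s == "-":
                gaps += 1
            else:
                counts[s] = counts.get(s, 0) + 1
        best = max(counts.values()) if counts else 0
        if gaps > best:
            continue
        winners = [s for s in _CONSENSUS_ORDER if counts.get(s, 0) == best]
        if len(winners) > 1:
            ties.add(c)
        rep.append(winners[0])
        kept.append(c)
        total = len(col)
        freqs.append({s: counts.get(s, 0) / total for s in _CONSENSUS_ORDER} | {"-": gaps / total})
    return ConsensusResult("".join(rep), ties, kept, freqs)


# --------------------------------------------------------------------------
# terminal elements, branch point, EBS/IBS


def detect_terminal_elements(sequence: str):
    """Locate the 5' GUGCGA motif (with linker offset) and the 3' AY end.

    Returns ``(five_prime_motif, linker_len, three_prime_AY)`` where the
    motif status is ``"canonical"``, ``"variant:<seq>"`` (one mismatch) or
    ``"absent"``.
    """
    if len(sequence) < 50:
        raise ValueError("sequence too short to carry terminal motifs")
    ay = len(sequence) >= 2 and sequence[-2] == "A" and sequence[-1] in "CU"
    limit = min(10, len(sequence) - 6)
    for i in range(limit):
        if sequence[i : i + 6] == FIVE_PRIME_MOTIF:
            return "canonical", i, ay
    for i in range(limit):
        w = sequence[i : i + 6]
        if sum(a != b for a, b in zip(w, FIVE_PRIME_MOTIF)) == 1:
            return f"variant:{w}", i, ay
    return "absent", 0, ay


def detect_branchpoint(layout: DomainLayout, sequence: str):
    """Branch-point adenosine: an unpaired A in DVI, 6-10 nt from the 3' end."""
    if "DVI" not in layout.domains:
        return ("not_assessable", None)
    a, b = layout.domains["DVI"]
    L = len(sequence)
    db = layout.dot_bracket
    for i in range(a - 1, b):  # 0-based scan within DVI
        if db[i] == "." and sequence[i] == "A" and 6 <= (L - i) <= 10:
            return ("present", i + 1)
    return ("absent", None)


@dataclass
class EBSSite:
    status: str  # found | lost | not_assessable
    interval: tuple | None = None  # intron coordinates, 1-based inclusive
    sequence: str | None = None
    ibs_interval: tuple | None = None  # exon coordinates relative to junction
    ibs_sequence: str | None = None
    matches: int = 0


@dataclass
class EBSReport:
    ebs1: EBSSite
    ebs2: EBSSite
    ebs3: EBSSite
    wobble_used: bool = False


def _ss_runs(db: str, start: int, end: int) -> list[tuple[int, int]]:
    """Maximal single-stranded (dot) runs within [start, end) (0-based)."""
    runs, i = [], start
    while i < end:
        if db[i] == ".":
            j = i
            while j < end and db[j] == ".":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _best_window(seq, runs, ibs, wobble, exclude=None):
    """Best reverse-complement window against ``ibs`` over single strands."""
    L = len(ibs)
    best = None
    for s, e in runs:
        for i in range(s, e - L + 1):
            if exclude and not (i + L <= exclude[0] or i >= exclude[1]):
                continue
            w = seq[i : i + L]
            score = sum(
                is_complementary(w[k], ibs[L - 1 - k], wobble) for k in range(L)
            )
            if best is None or score > best[0]:
                best = (score, i)
    return best  # (matches, 0-based start) or None


def detect_ebs_ibs(
    layout: DomainLayout,
    sequence: str,
    upstream_flank: str,
    downstream_flank: str,
    allow_wobble: bool = False,
) -> EBSReport:
    """Find EBS1/EBS2/EBS3 in DI by complementarity to the exon IBS windows.

    IBS1 = upstream exon -6..-1, IBS2 = -12..-7, IBS3 = downstream +1. EBS1
    requires >=5/6 complementary positions, EBS2 >=4/6, EBS3 an exact single
    pair; Watson-Crick only unless ``allow_wobble`` (then G.U counts). EBS3
    reports the most 3' match in DI (it sits near the DI 3' end).
    """
    if "DI" not in layout.domains:
        na = EBSSite("not_assessable")
        return EBSReport(na, na, na, allow_wobble)
    a, b = layout.domains["DI"]
    runs = _ss_runs(layout.dot_bracket, a - 1, b)

    def site(ibs, ibs_iv, threshold, exclude=None):
        if len(ibs) < (1 if threshold == 1 else 6):
            return EBSSite("not_assessable")
        best = _best_window(sequence, runs, ibs, allow_wobble, exclude=exclude)
        if best is None or best[0] < threshold:
            return EBSSite("lost", ibs_interval=ibs_iv, ibs_sequence=ibs,
                           matches=0 if best is None else best[0])
        score, i = best
        L = len(ibs)
        return EBSSite(
            "found", (i + 1, i + L), sequence[i : i + L], ibs_iv, ibs, score
        )

    up, down = upstream_flank, downstream_flank
    ibs1 = up[-6:] if len(up) >= 6 else ""
    ibs2 = up[-12:-6] if len(up) >= 12 else ""
    ibs3 = down[:1]

    e1 = site(ibs1, (-6, -1), 5)
    exclude = None
    if e1.status == "found":
        exclude = (e1.interval[0] - 1, e1.interval[1])
    e2 = site(ibs2, (-12, -7), 4, exclude=exclude)

    if not ibs3:
        e3 = EBSSite("not_assessable")
    else:
        hit = None
        for s, e in runs:
            for i in range(s, e):
                if is_complementary(sequence[i], ibs3, allow_wobble):
                    hit = i  # keep the most 3' match
        if hit is None:
            e3 = EBSSite("lost", ibs_interval=(1, 1), ibs_sequence=ibs3)
        else:
            e3 = EBSSite("found", (hit + 1, hit + 1), sequence[hit], (1, 1), ibs3, 1)
    return EBSReport(e1, e2, e3, allow_wobble)


# --------------------------------------------------------------------------
# junctions, accessory labelling, subgroup call


def extract_junctions(layout: DomainLayout, sequence: str):
    """(DII-DIII tetramer, DIV-DV dimer) from the unpaired joining strands.

    The tetramer is the 4 nt immediately 3' of the DII closing pair; the
    dimer is the 2 nt immediately 5' of the DV helix. ``None`` if the
    required nucleotides are not unpaired/available.
    """
    db = layout.dot_bracket
    tet = dim = None
    if "DII" in layout.domains:
        _, e = layout.domains["DII"]
        w = sequence[e : e + 4]
        if len(w) == 4 and all(c == "." for c in db[e : e + 4]):
            tet = w
    if "DV" in layout.domains:
        s, _ = layout.domains["DV"]
        if s >= 3 and all(c == "." for c in db[s - 3 : s - 1]):
            dim = sequence[s - 3 : s - 1]
    return tet, dim


def label_accessories(layout: DomainLayout, sequence: str, ebs: EBSReport | None = None) -> dict:
    """Heuristic labelling of DI sub-helices (approximate, size-fingerprint).

    EBS-carrying helices are anchored from the EBS report; the remaining
    children are matched against the canonical (stem, loop) sizes of Ia, IC2,
    ID2, ID2a and IE, honouring their canonical 5'->3' order. Helices that do
    not fit are labelled ``X``. DIIIa (outside DI) is taken from the layout.
    """
    out: dict[str, tuple[int, int]] = {}
    if "DIIIa" in layout.accessories:
        out["DIIIa"] = layout.accessories["DIIIa"]
    if "DI" not in layout.domains:
        return out
    a, b = layout.domains["DI"]
    db = layout.dot_bracket
    pairs = _pair_map(db)
    # skip the DI outer stem: consecutive ( at DI start pairing consecutively at the end
    i = a - 1
    while db[i] == "(" and pairs[i] == pairs[a - 1] - (i - (a - 1)):
        i += 1
    inner_end = pairs[a - 1] - (i - (a - 1))  # position of innermost closing pair
    children = []
    j = i
    while j < inner_end:
        if db[j] == "(":
            children.append((j, pairs[j]))
            j = pairs[j] + 1
        else:
            j += 1

    def contains(span, interval):
        return interval is not None and span[0] + 1 <= interval[0] and interval[1] <= span[1] + 1

    anchored = {}
    if ebs is not None:
        for name, site in (("EBS1h", ebs.ebs1), ("EBS2h", ebs.ebs2), ("EBS3h", ebs.ebs3)):
            if site.status == "found":
                for span in children:
                    if contains(span, site.interval):
                        anchored[span] = name
    order = ["Ia", "IC2", "ID2", "ID2a", "IE"]
    min_order = -1
    for span in children:
        if span in anchored:
            continue
        s, e = span
        stem = 0
        while db[s + stem] == "(":
            stem += 1
        loop = (e - s + 1) - 2 * stem
        size = e - s + 1
        label = _ACCESSORY_FINGERPRINT.get((stem, loop))
        if label is not None and order.index(label) > min_order:
            out[label] = (s + 1, e + 1)
            min_order = order.index(label)
        elif size > 24:
            out.setdefault("pad", (s + 1, e + 1))
        # else: unrecognized child, ignored
    return out


@dataclass
class StructureFeatures:
    """Per-intron feature calls feeding the bubble matrix and subgroup logic."""

    length: int
    five_prime_motif: str
    linker_len: int
    three_prime_AY: bool
    branchpoint: tuple
    junction_DII_DIII: str | None
    junction_DIV_DV: str | None
    ebs: EBSReport | None
    accessories: dict
    dv_length: int | None = None


def classify_subgroup(
    features: StructureFeatures,
    layout: DomainLayout | None = None,
    iep=None,
    iia_prior: str | None = None,
) -> str:
    """Subgroup call from diagnostic junction motifs.

    Decision order: (1) DII-DIII tetramer against BVGA (IIA1) and RRGA
    (IIA2) — matching both yields ``ambiguous-IIA`` unless a clade prior is
    supplied; (2) DIV-DV dimer: YW => IIB1, RG => IIB2; (3) an IEP-less,
    short (<800 nt) intron missing >=2 core features => IIB-like;
    (4) otherwise unclassified.
    """
    tet = features.junction_DII_DIII
    if tet is not None and len(tet) == 4:
        a1 = matches_iupac(tet, "BVGA")
        a2 = matches_iupac(tet, "RRGA")
        if a1 and a2:
            return iia_prior if iia_prior in ("IIA1", "IIA2") else "ambiguous-IIA"
        if a1:
            return "IIA1"
        if a2:
            return "IIA2"
    dim = features.junction_DIV_DV
    if dim is not None and len(dim) == 2:
        if matches_iupac(dim, "YW"):
            return "IIB1"
        if matches_iupac(dim, "RG"):
            return "IIB2"
    no_iep = iep is None or getattr(iep, "type", "none") == "none" or getattr(
        iep, "status", "absent"
    ) == "absent"
    absences = 0
    if features.five_prime_motif != "canonical":
        absences += 1
    if features.branchpoint[0] != "present":
        absences += 1
    if features.ebs is not None:
        if features.ebs.ebs1.status == "lost":
            absences += 1
        if features.ebs.ebs2.status == "lost":
            absences += 1
    if no_iep and features.length < 800 and absences >= 2:
        return "IIB-like"
    return "unclassified"


def annotate_intron(
    sequence: str,
    dot_bracket: str,
    upstream_flank: str = "",
    downstream_flank: str = "",
    allow_wobble: bool = False,
) -> tuple[DomainLayout, StructureFeatures]:
    """One-stop structural annotation of a single intron."""
    layout = parse_domains(sequence, dot_bracket)
    motif, linker_len, ay = detect_terminal_elements(sequence)
    bp = detect_branchpoint(layout, sequence)
    ebs = detect_ebs_ibs(layout, sequence, upstream_flank, downstream_flank, allow_wobble)
    tet, dim = extract_junctions(layout, sequence)
    acc = label_accessories(layout, sequence, ebs)
    feats = StructureFeatures(
        length=len(sequence),
        five_prime_motif=motif,
        linker_len=linker_len,
        three_prime_AY=ay,
        branchpoint=bp,
        junction_DII_DIII=tet,
        junction_DIV_DV=dim,
        ebs=ebs,
        accessories=acc,
        dv_length=layout.dv_length,
    )
    return layout, feats
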