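"""Intron family assignment and occurrence-frequency analysis.

A family is the set of introns sitting at the *identical* insertion site of
a host gene that are also sequence-homologous. The insertion site of each
occurrence is mapped onto a reference copy of the host gene by locally
aligning the upstream exon flank; the site is the reference coordinate of
the last aligned flank base. Co-sited but non-homologous introns are split
into suffixed families (``gene-site``, ``gene-site.2``, ...).

Family members are searched across genomes BLASTN-style (E <= 1e-5, query
coverage >= 30% by default) and presence/absence is summarized per organelle
into occurrence frequencies: families in >40% of sampled genomes are broadly
distributed, those in <15% narrowly distributed.
"""

from __future__ import annotations

import os
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import NamedTuple

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from ._seq import as_dna
from .model import IntronRecord
from .naming import name_intron

__all__ = [
    "SiteMapping",
    "UnmappableSiteError",
    "FamilyAssignment",
    "HomologyHit",
    "PresenceMatrix",
    "map_insertion_site",
    "pairwise_identity",
    "assign_families",
    "search_family_members",
    "build_presence_matrix",
    "occurrence_frequency",
]

BROAD_THRESHOLD = 0.40  # frequency above which a family is broadly distributed
NARROW_THRESHOLD = 0.15  # and below which it is narrowly distributed


class UnmappableSiteError(ValueError):
    pass


class SiteMapping(NamedTuple):
    site: int
    score: float
    identity: float


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def map_insertion_site(
    intron: IntronRecord, reference_gene: str, min_identity: float = 0.6
) -> SiteMapping:
    """Map an intron's insertion site onto the reference host gene.

    The upstream exon flank is locally aligned against the reference gene
    (match +2, mismatch -3, gap open -5, gap extend -2); the site is the
    reference coordinate (1-based) of the last aligned flank base, advanced
    by any unaligned flank suffix (a mutated terminal base must not shift
    the mapped site).
    """
    flank = as_dna(intron.upstream_flank)
    if len(flank) < 10:
        raise UnmappableSiteError(f"{intron.id}: upstream flank shorter than 10 nt")
    ref = as_dna(reference_gene)
    aligner = _local_aligner()
    alns = aligner.align(ref, flank)
    if len(alns) == 0:
        raise UnmappableSiteError(f"{intron.id}: no local alignment to reference")
    aln = alns[0]
    ref_blocks, q_blocks = aln.aligned
    matches = 0
    cols = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        cols += re_ - rs
        matches += sum(ref[rs + k] == flank[qs + k] for k in range(re_ - rs))
    identity = matches / cols if cols else 0.0
    if identity < min_identity:
        raise UnmappableSiteError(
            f"{intron.id}: best alignment identity {identity:.2f} below {min_identity:.2f}"
        )
    site = int(ref_blocks[-1][1])  # end of last aligned block, == 1-based last base
    trailing = len(flank) - int(q_blocks[-1][1])  # flank suffix the local aln dropped
    site = min(site + trailing, len(ref))
    return SiteMapping(site=site, score=float(aln.score), identity=identity)


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Global identity and coverage between two nucleotide sequences.

    Returns ``(identity over all alignment columns (gaps included), aligned
    columns / shorter length)`` from a Needleman-Wunsch alignment (edlib).
    Counting gap columns in the identity denominator keeps unrelated
    sequences well below homology thresholds.
    """
    a, b = as_dna(a), as_dna(b)
    if not a or not b:
        return 0.0, 0.0
    if a == b:
        return 1.0, 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    m_cols = ins = dels = 0
    for n, op in re.findall(r"(\d+)([=XMID])", res["cigar"]):
        n = int(n)
        if op in "=XM":
            m_cols += n
        elif op == "I":
            ins += n
        else:
            dels += n
    mismatches = res["editDistance"] - ins - dels
    matches = m_cols - mismatches
    aln_len = m_cols + ins + dels
    identity = matches / aln_len if aln_len else 0.0
    coverage = m_cols / min(len(a), len(b))
    return identity, coverage


@dataclass
class FamilyAssignment:
    family_id: str
    host_gene: str
    site: int
    members: list = field(default_factory=list)  # intron instance ids
    cluster_index: int = 1  # 1 = primary cluster at this site


def assign_families(
    introns: list[IntronRecord],
    reference_genes: dict[str, str],
    identity_threshold: float = 0.6,
    min_coverage: float = 0.5,
) -> tuple[list[FamilyAssignment], list[str]]:
    """Partition introns into families by shared mapped site + homology.

    Two introns share a family iff they map to the same (gene, site) *and*
    are globally >= ``identity_threshold`` identical over >= ``min_coverage``
    of the shorter sequence (single linkage within a site group). Co-sited
    non-homologous clusters get ``.2``, ``.3`` suffixes. Unmappable introns
    are returned separately.
    """
    groups: dict[tuple[str, int], list[IntronRecord]] = {}
    unassigned: list[str] = []
    for it in introns:
        ref = reference_genes.get(it.host_gene)
        if ref is None:
            unassigned.append(it.id)
            continue
        try:
            mapping = map_insertion_site(it, ref)
        except UnmappableSiteError:
            unassigned.append(it.id)
            continue
        groups.setdefault((it.host_gene, mapping.site), []).append(it)

    assignments: list[FamilyAssignment] = []
    for (gene, site), members in sorted(groups.items()):
        # single-linkage clustering on the homology relation
        k = len(members)
        parent = list(range(k))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(k):
            for j in range(i + 1, k):
                if find(i) == find(j):
                    continue
                ident, cov = pairwise_identity(members[i].sequence, members[j].sequence)
                if ident >= identity_threshold and cov >= min_coverage:
                    parent[find(j)] = find(i)
        clusters: dict[int, list[IntronRecord]] = {}
        for i in range(k):
            clusters.setdefault(find(i), []).append(members[i])
        ordered = sorted(
            clusters.values(), key=lambda c: (-len(c), min(m.id for m in c))
        )
        for idx, cluster in enumerate(ordered, 1):
            fid = name_intron(gene, site) + ("" if idx == 1 else f".{idx}")
            assignments.append(
                FamilyAssignment(
                    family_id=fid,
                    host_gene=gene,
                    site=site,
                    members=sorted(m.id for m in cluster),
                    cluster_index=idx,
                )
            )
    return assignments, sorted(unassigned)


class HomologyHit(NamedTuple):
    probe_id: str
    genome_id: str
    interval: tuple  # subject coordinates, 1-based inclusive (start may be > end on '-')
    percent_identity: float
    alignment_length: int
    evalue: float
    query_coverage: float  # fraction of the probe covered


def search_family_members(
    probe: str,
    genome,
    evalue_cutoff: float = 1e-5,
    min_coverage: float = 0.3,
    probe_id: str = "probe",
) -> list[HomologyHit]:
    """BLASTN search of a family probe against one genome.

    Runs the installed NCBI BLAST+ ``blastn`` (word size 11) in pairwise
    subject mode and filters hits by E-value and query coverage; hits are
    sorted by E-value then identity.
    """
    probe = as_dna(probe)
    if len(probe) < 11:
        raise ValueError("probe shorter than the BLASTN word size (11)")
    if len(probe) < 50:
        raise ValueError("probe must be >= 50 nt")
    genome_id = getattr(genome, "id", "subject")
    genome_seq = getattr(genome, "sequence", genome)
    with tempfile.TemporaryDirectory() as tmp:
        qpath = os.path.join(tmp, "q.fasta")
        spath = os.path.join(tmp, "s.fasta")
        with open(qpath, "w") as fh:
            fh.write(f">{probe_id}\n{probe}\n")
        with open(spath, "w") as fh:
            fh.write(f">{genome_id}\n{as_dna(genome_seq)}\n")
        cmd = [
            "blastn", "-task", "blastn", "-word_size", "11",
            "-query", qpath, "-subject", spath,
            "-evalue", str(evalue_cutoff),
            "-outfmt", "6 pident length evalue qcovs sstart send",
        ]
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
    hits = []
    for line in res.stdout.splitlines():
        pident, length, evalue, qcovs, sstart, send = line.split("\t")
        cov = float(qcovs) / 100.0
        if float(evalue) <= evalue_cutoff and cov >= min_coverage:
            hits.append(
                HomologyHit(
                    probe_id, genome_id, (int(sstart), int(send)),
                    float(pident), int(length), float(evalue), cov,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.percent_identity))
    return hits


@dataclass
class PresenceMatrix:
    """Family x genome presence/absence for one organelle compartment."""

    data: pd.DataFrame  # bool, rows = families, columns = genome ids

    def __post_init__(self):
        self.data = self.data.astype(bool)

    @property
    def families(self):
        return list(self.data.index)

    @property
    def genomes(self):
        return list(self.data.columns)


def build_presence_matrix(
    assignments: list[FamilyAssignment], genome_ids: list[str],
    member_genome: dict[str, str],
) -> PresenceMatrix:
    """Presence matrix from family assignments.

    ``member_genome`` maps intron instance id -> genome id.
    """
    df = pd.DataFrame(
        False, index=[a.family_id for a in assignments], columns=list(genome_ids)
    )
    for a in assignments:
        for m in a.members:
            g = member_genome.get(m)
            if g in df.columns:
                df.loc[a.family_id, g] = True
    return PresenceMatrix(df)


def occurrence_frequency(matrix: PresenceMatrix) -> pd.DataFrame:
    """Occurrence count, percent (one decimal) and distribution class.

    Class thresholds operate on the unrounded frequency: > 0.40 broad,
    < 0.15 narrow, otherwise intermediate.
    """
    df = matrix.data
    if df.shape[1] == 0:
        raise ValueError("presence matrix has no genome columns")
    denom = df.shape[1]
    counts = df.sum(axis=1)
    freq = counts / denom

    def classify(f: float) -> str:
        if f > BROAD_THRESHOLD:
            return "broad"
        if f < NARROW_THRESHOLD:
            return "narrow"
        return "intermediate"

    return pd.DataFrame(
        {
            "family": df.index,
            "count": counts.values,
            "denominator": denom,
            "percent": np.round(100.0 * freq.values, 1),
            "class": [classify(f) for f in freq.values],
        }
    ).reset_index(drop=True)
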