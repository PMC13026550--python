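"""Reading and writing cohort files: FASTA, GFF3, dot-bracket, truth TSV.

A cohort directory (as written by :func:`intronscape.simulate.emit_cohort`)
contains ``genomes.fasta``, ``genes.gff3`` (1-based inclusive, ``gene`` /
``exon`` / ``intron`` features), ``introns.fasta``, ``structures.db``
(3-line records: ``>id`` / sequence / dot-bracket), ``truth.tsv`` and
``reference_genes.fasta``. Intron sequences are converted to RNA on load;
minus-strand introns are reverse-complemented first.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from ._seq import as_rna, revcomp_dna
from .model import Genome, GeneModel, IntronRecord
from .naming import parse_intron_name, IntronNameError

__all__ = [
    "LinkageError",
    "read_structures",
    "write_structures",
    "read_truth",
    "load_cohort",
    "load_reference_genes",
]

FLANK_LEN = 20


class LinkageError(ValueError):
    """Cross-file identifier mismatches (e.g. GFF3 record without a genome)."""


def read_structures(path: str) -> dict[str, tuple[str, str]]:
    """Dot-bracket database: mapping id -> (RNA sequence, structure)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    for i in range(0, len(lines), 3):
        head = lines[i]
        if not head.startswith(">"):
            raise ValueError(f"{path}: expected '>' header at record {i // 3 + 1}")
        seq, db = lines[i + 1], lines[i + 2]
        if len(seq) != len(db):
            raise ValueError(f"{path}: sequence/structure length mismatch for {head[1:]}")
        out[head[1:].split()[0]] = (as_rna(seq), db)
    return out


def write_structures(path: str, records: dict[str, tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, (seq, db) in records.items():
            fh.write(f">{rid}\n{seq}\n{db}\n")


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_reference_genes(path: str) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def _parse_gff(path: str) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = {}
            for kv in f[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            rows.append(
                {
                    "seqid": f[0],
                    "type": f[2],
                    "start": int(f[3]),
                    "end": int(f[4]),
                    "strand": f[6],
                    "attrs": attrs,
                }
            )
    return rows


@dataclass
class CohortData:
    genomes: dict  # id -> Genome
    introns: list  # list[IntronRecord]
    structures: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def load_cohort(directory: str) -> CohortData:
    """Load a cohort directory into genome/intron records.

    Every ``intron`` feature in the GFF3 yields one :class:`IntronRecord`
    with exon flanks of up to 20 nt (a warning is issued when an adjacent
    exon is shorter). Raises :class:`LinkageError` when GFF3 records point
    at missing genomes.
    """
    genomes_path = os.path.join(directory, "genomes.fasta")
    gff_path = os.path.join(directory, "genes.gff3")

    genomes: dict[str, Genome] = {}
    for rec in SeqIO.parse(genomes_path, "fasta"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        genomes[rec.id] = Genome(
            id=rec.id,
            organelle=meta.get("organelle", "mt"),
            species=meta.get("species", rec.id),
            sequence=str(rec.seq).upper(),
        )

    rows = _parse_gff(gff_path)
    missing = sorted({r["seqid"] for r in rows if r["seqid"] not in genomes})
    if missing:
        raise LinkageError(f"GFF3 records reference missing genomes: {missing}")

    # register gene models
    exons_by_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in rows:
        if r["type"] == "exon":
            key = (r["seqid"], r["attrs"].get("gene", ""))
            exons_by_gene.setdefault(key, []).append((r["start"], r["end"]))
    for (gid, gene), exons in sorted(exons_by_gene.items()):
        strand = "+"
        for r in rows:
            if r["type"] == "gene" and r["seqid"] == gid and r["attrs"].get("gene") == gene:
                strand = r["strand"]
                break
        genomes[gid].genes.append(GeneModel(name=gene, strand=strand, exons=exons))

    structures = {}
    sdb = os.path.join(directory, "structures.db")
    if os.path.exists(sdb):
        structures = read_structures(sdb)

    introns: list[IntronRecord] = []
    for r in rows:
        if r["type"] != "intron":
            continue
        gid = r["seqid"]
        genome = genomes[gid]
        gene = r["attrs"].get("gene", "")
        iid = r["attrs"].get("ID", f"{gene}:{r['start']}-{r['end']}")
        strand = r["strand"]
        raw = genome.sequence[r["start"] - 1 : r["end"]]
        key = (gid, gene)
        exons = sorted(exons_by_gene.get(key, []))
        if strand == "-":
            raw = revcomp_dna(raw)
            up_iv = next(((s, e) for s, e in exons if s == r["end"] + 1), None)
            down_iv = next(((s, e) for s, e in reversed(exons) if e == r["start"] - 1), None)
        else:
            up_iv = next(((s, e) for s, e in reversed(exons) if e == r["start"] - 1), None)
            down_iv = next(((s, e) for s, e in exons if s == r["end"] + 1), None)

        def take(iv, which):
            if iv is None:
                warnings.warn(f"{iid}: no adjacent {which} exon; empty flank")
                return ""
            s, e = iv
            seq = genome.sequence[s - 1 : e]
            if strand == "-":
                seq = revcomp_dna(seq)
            if which == "upstream":
                flank = seq[-FLANK_LEN:]
            else:
                flank = seq[:FLANK_LEN]
            if len(seq) < FLANK_LEN:
                warnings.warn(
                    f"{iid}: {which} exon only {len(seq)} nt; short flank"
                )
            return as_rna(flank)

        fam = r["attrs"].get("Name")
        site = None
        if fam:
            try:
                _, site = parse_intron_name(fam)
            except IntronNameError:
                site = None
        introns.append(
            IntronRecord(
                id=iid,
                genome_id=gid,
                host_gene=gene,
                site=site,
                sequence=as_rna(raw),
                structure=structures.get(iid, (None, None))[1],
                upstream_flank=take(up_iv, "upstream"),
                downstream_flank=take(down_iv, "downstream"),
            )
        )

    truth = None
    tpath = os.path.join(directory, "truth.tsv")
    if os.path.exists(tpath):
        truth = read_truth(tpath)
    return CohortData(genomes=genomes, introns=introns, structures=structures, truth=truth)
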