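"""Low-level nucleotide utilities shared across the package.

Introns are handled internally as RNA (T is converted to U on load), genomes
as DNA. All motif patterns are defined over the RNA alphabet using IUPAC
degeneracy codes.
"""

from __future__ import annotations

import numpy as np

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

_RNA_COMP = str.maketrans("ACGUTNacgutn", "UGCAANugcaan")
_DNA_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: IUPAC degeneracy codes over the RNA alphabet.
IUPAC_RNA = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "W": frozenset("AU"),
    "S": frozenset("CG"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


def as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def comp_rna(base: str) -> str:
    return base.translate(_RNA_COMP)


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` (RNA) matches the IUPAC ``pattern`` position by position."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC_RNA[p] for s, p in zip(seq, pattern))


def is_complementary(a: str, b: str, wobble: bool = False) -> bool:
    """Can RNA bases ``a`` and ``b`` form a base pair (Watson-Crick, optionally G.U)?"""
    pair = a + b
    if pair in ("AU", "UA", "GC", "CG"):
        return True
    return wobble and pair in ("GU", "UG")


def random_seq(rng: np.random.Generator, n: int, alphabet: str = RNA_BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def draw_from_pattern(rng: np.random.Generator, pattern: str, forbid=None) -> str:
    """Draw a concrete RNA word from an IUPAC pattern.

    ``forbid`` maps position -> set of bases to exclude (used e.g. to keep a
    subgroup-diagnostic junction unambiguous between overlapping patterns).
    """
    out = []
    for i, p in enumerate(pattern):
        choices = sorted(IUPAC_RNA[p])
        if forbid and i in forbid:
            choices = [c for c in choices if c not in forbid[i]]
        if not choices:
            raise ValueError(f"no allowed base at position {i} of pattern {pattern}")
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def jc_subst_prob(d: float) -> float:
    """Probability a site differs after expected ``d`` substitutions/site (JC-like)."""
    if d <= 0:
        return 0.0
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def mutate(seq: str, p, rng: np.random.Generator, protected=None, alphabet: str = RNA_BASES) -> str:
    """Apply an equal-rate substitution process to ``seq``.

    ``p`` is either a scalar per-site substitution probability or an array of
    per-site probabilities. ``protected`` is an optional boolean mask of
    positions that never mutate.
    """
    n = len(seq)
    if n == 0:
        return seq
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), (n,))
    hits = rng.random(n) < p_arr
    if protected is not None:
        hits &= ~np.asarray(protected, dtype=bool)
    if not hits.any():
        return seq
    chars = np.frombuffer(seq.encode(), dtype="S1").copy()
    idx = {b.encode(): k for k, b in enumerate(alphabet)}
    others = {
        b.encode(): [c.encode() for c in alphabet if c != b] for b in alphabet
    }
    where = np.flatnonzero(hits)
    draws = rng.integers(0, len(alphabet) - 1, len(where))
    for j, pos in enumerate(where):
        cur = chars[pos].tobytes() if hasattr(chars[pos], "tobytes") else bytes(chars[pos])
        repl = others.get(cur)
        if repl is None:  # non-standard base (e.g. N): leave untouched
            continue
        chars[pos] = repl[draws[j]]
    return chars.tobytes().decode()
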