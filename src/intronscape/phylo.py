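"""Hotspot masking, distance matrices, neighbor-joining, bootstrap, and
tree comparison (Robinson-Foulds, monophyly).

Maximum-likelihood inference is out of scope here: the congruence and
clade-membership questions this package asks are topological, and
neighbor-joining on p/JC69 distances with a classical column bootstrap
answers them at desk scale with fully deterministic behaviour (fixed
tie-breaks, seeded resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "MaskedAlignment",
    "DistanceMatrix",
    "UndefinedDistanceError",
    "mask_regions",
    "compute_distances",
    "build_nj_tree",
    "bootstrap_support",
    "rf_distance",
    "test_monophyly",
    "center_star_align",
]

GAP_CHARS = frozenset("-.")


def _as_rows(alignment) -> tuple[list[str], list[str]]:
    """Accept dict name->seq or list of (name, seq); return (names, rows)."""
    if isinstance(alignment, MaskedAlignment):
        return alignment.names, alignment.rows
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = list(alignment)
    names = [k for k, _ in items]
    rows = [s.upper() for _, s in items]
    if not rows:
        raise ValueError("empty alignment")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    return names, rows


@dataclass
class MaskedAlignment:
    names: list
    rows: list  # retained columns only
    mask: list = field(default_factory=list)  # merged (label, start, end), 1-based
    kept_columns: list = field(default_factory=list)  # original column indices (0-based)

    @property
    def retained(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def mask_regions(alignment, region_spec=None) -> MaskedAlignment:
    """Remove labelled column intervals (1-based inclusive) from an alignment.

    Mirrors the exclusion of mutation-hotspot regions (5' terminal sequence,
    DI/DII/DIII/DIV loop regions, accessory elements) before phylogenetic
    inference. Overlapping regions are merged with a warning; a region
    outside the alignment raises; masking every column raises.
    """
    names, rows = _as_rows(alignment)
    L = len(rows[0])
    regions = sorted(region_spec or [], key=lambda r: (r[1], r[2]))
    for label, s, e in regions:
        if s < 1 or e > L or s > e:
            raise ValueError(f"mask region {label} [{s},{e}] outside alignment 1..{L}")
    merged: list[list] = []
    for label, s, e in regions:
        if merged and s <= merged[-1][2] + 0:
            if s <= merged[-1][2]:
                warnings.warn(f"overlapping mask regions merged at column {s}")
            merged[-1][2] = max(merged[-1][2], e)
            merged[-1][0] = f"{merged[-1][0]}+{label}"
        else:
            merged.append([label, s, e])
    drop = np.zeros(L, dtype=bool)
    for _, s, e in merged:
        drop[s - 1 : e] = True
    kept = [i for i in range(L) if not drop[i]]
    if not kept:
        raise ValueError("empty alignment after masking")
    new_rows = ["".join(r[i] for i in kept) for r in rows]
    return MaskedAlignment(
        names=names,
        rows=new_rows,
        mask=[tuple(m) for m in merged],
        kept_columns=kept,
    )


class UndefinedDistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def compute_distances(alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise p or JC69 distances with pairwise deletion of gap columns.

    JC69: d = -(3/4) ln(1 - 4p/3), undefined (inf) for p >= 0.75.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown model {model!r}")
    names, rows = _as_rows(alignment)
    n = len(rows)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    arr = np.array([list(r) for r in rows])
    isgap = np.isin(arr, list(GAP_CHARS))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(isgap[i] | isgap[j])
            compared = int(ok.sum())
            if compared == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            p = float((arr[i][ok] != arr[j][ok]).sum()) / compared
            if model == "p":
                d = p
            else:
                d = np.inf if p >= 0.75 else -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=names, matrix=D, model=model)


# --------------------------------------------------------------------------
# neighbor joining


def build_nj_tree(dm: DistanceMatrix, taxon_namespace=None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the lexicographically
    smallest (sorted) pair of cluster labels, where a cluster is labelled by
    its smallest leaf. Negative branch lengths are clamped to zero.
    """
    D = np.array(dm.matrix, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = taxon_namespace or dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        nodes.append(node)
    tags = list(labels)  # cluster tag = smallest leaf label
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def d(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 3:
        N = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(N):
            for aj in range(ai + 1, N):
                i, j = active[ai], active[aj]
                q = (N - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((tags[i], tags[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        vi = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (N - 2))
        vj = d(i, j) - vi
        u = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        ni_len = max(vi, 0.0)
        nj_len = max(vj, 0.0)
        u.add_child(ni)
        ni.edge.length = ni_len
        u.add_child(nj)
        nj.edge.length = nj_len
        nodes.append(u)
        tags.append(min(tags[i], tags[j]))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            key = (min(next_id, k), max(next_id, k))
            dist[key] = duk
        dist[(next_id, next_id)] = 0.0
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    vi = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    vj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    vk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    center = dendropy.Node()
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def bootstrap_support(
    alignment, model: str = "p", n_reps: int = 100, seed: int = 0
) -> dendropy.Tree:
    """Classical column bootstrap on the (masked) alignment.

    Supports (% of replicate NJ trees containing each bipartition of the
    point-estimate tree) are stored as internal-node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names, rows = _as_rows(alignment)
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(names)
    base = build_nj_tree(compute_distances(list(zip(names, rows)), model), tns)
    base.encode_bipartitions()
    counts = {e.bipartition.split_bitmask: 0 for e in base.preorder_edge_iter()
              if e.head_node.parent_node is not None and not e.head_node.is_leaf()}
    L = len(rows[0])
    for _ in range(n_reps):
        cols = rng.integers(0, L, L)
        rep_rows = ["".join(r[c] for c in cols) for r in rows]
        try:
            rep = build_nj_tree(compute_distances(list(zip(names, rep_rows)), model), tns)
        except UndefinedDistanceError:
            continue
        rep.encode_bipartitions()
        masks = {e.bipartition.split_bitmask for e in rep.preorder_edge_iter()}
        for m in counts:
            if m in masks:
                counts[m] += 1
    for e in base.preorder_edge_iter():
        if e.head_node.parent_node is not None and not e.head_node.is_leaf():
            pct = 100.0 * counts[e.bipartition.split_bitmask] / n_reps
            e.head_node.label = f"{pct:.0f}"
    return base


# --------------------------------------------------------------------------
# tree comparison


def _common_namespace(t1, t2):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    la = {x.taxon.label for x in a.leaf_node_iter()}
    lb = {x.taxon.label for x in b.leaf_node_iter()}
    if la != lb:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(la - lb)}, only in second {sorted(lb - la)}"
        )
    a.is_rooted = False
    b.is_rooted = False
    return a, b


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: |symmetric difference of non-trivial bipartitions|."""
    a, b = _common_namespace(t1, t2)
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def test_monophyly(tree: dendropy.Tree, leaves, outgroup_leaf: str) -> bool:
    """Is ``leaves`` a clade after rooting the tree on ``outgroup_leaf``?"""
    leaves = set(leaves)
    t = tree.clone(depth=1)
    all_leaves = {x.taxon.label for x in t.leaf_node_iter()}
    if not leaves <= all_leaves:
        raise ValueError(f"query leaves not in tree: {sorted(leaves - all_leaves)}")
    if outgroup_leaf in leaves:
        raise ValueError("outgroup leaf cannot be part of the query set")
    if outgroup_leaf not in all_leaves:
        raise ValueError(f"outgroup leaf {outgroup_leaf!r} not in tree")
    if leaves == all_leaves - {outgroup_leaf}:
        warnings.warn("query covers all non-outgroup leaves; trivially monophyletic")
        return True
    og = next(x for x in t.leaf_node_iter() if x.taxon.label == outgroup_leaf)
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    mrca = t.mrca(taxa=[x.taxon for x in t.leaf_node_iter() if x.taxon.label in leaves])
    clade = {x.taxon.label for x in mrca.leaf_iter()}
    return clade == leaves


# --------------------------------------------------------------------------
# light-weight progressive alignment for family representatives


def center_star_align(seqs: dict) -> dict:
    """Center-star progressive alignment (affine gaps) for high-identity sets.

    The center is the sequence minimizing the sum of pairwise edit distances;
    all others are aligned to it (match +1, mismatch -1, open -5, extend -1)
    and merged by propagating center gaps. Pre-aligned input (equal lengths)
    is returned unchanged.
    """
    import edlib
    from Bio import Align

    names = list(seqs)
    if len(names) < 2:
        return dict(seqs)
    if len({len(s) for s in seqs.values()}) == 1:
        return dict(seqs)
    dist_sum = {
        a: sum(
            edlib.align(seqs[a], seqs[b], mode="NW")["editDistance"]
            for b in names
            if b != a
        )
        for a in names
    }
    center = min(names, key=lambda a: (dist_sum[a], a))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1

    pair_alns = {}
    for name in names:
        if name == center:
            continue
        aln = aligner.align(seqs[center], seqs[name])[0]
        pair_alns[name] = aln

    # collect, per center position, the maximum insertion length before it
    L = len(seqs[center])
    ins_before = [0] * (L + 1)
    gapped = {}
    for name, aln in pair_alns.items():
        c_blocks, q_blocks = aln.aligned
        # reconstruct row pair
        c_row, q_row = [], []
        cpos, qpos = 0, 0
        for (cs, ce), (qs, qe) in zip(c_blocks, q_blocks):
            ins = qs - qpos
            dele = cs - cpos
            if ins:
                ins_before[cpos] = max(ins_before[cpos], ins)
            cpos, qpos = ce, qe
        ins = len(seqs[name]) - qpos
        if ins:
            ins_before[L] = max(ins_before[L], ins)

    def expand(center_seq, other=None, aln=None):
        """Render a row on the master coordinate system."""
        out = []
        if other is None:
            for p in range(L):
                out.append("-" * ins_before[p])
                out.append(center_seq[p])
            out.append("-" * ins_before[L])
            return "".join(out)
        c_blocks, q_blocks = aln.aligned
        row = []
        cpos, qpos = 0, 0
        events = []  # (center_pos, inserted_seq) plus aligned/deleted chars
        per_pos_char = ["-"] * L
        per_pos_ins = [""] * (L + 1)
        for (cs, ce), (qs, qe) in zip(c_blocks, q_blocks):
            if qs - qpos:
                per_pos_ins[cpos] = other[qpos:qs]
            cpos, qpos = cs, qs
            for k in range(ce - cs):
                per_pos_char[cs + k] = other[qs + k]
            cpos, qpos = ce, qe
        if len(other) - qpos:
            per_pos_ins[L] = other[qpos:]
        for p in range(L):
            pad = per_pos_ins[p]
            row.append(pad.rjust(ins_before[p], "-") if ins_before[p] else "")
            row.append(per_pos_char[p])
        row.append(per_pos_ins[L].ljust(ins_before[L], "-") if ins_before[L] else "")
        return "".join(row)

    aligned = {center: expand(seqs[center])}
    for name, aln in pair_alns.items():
        aligned[name] = expand(seqs[center], seqs[name], aln)
    return {n: aligned[n] for n in names}
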