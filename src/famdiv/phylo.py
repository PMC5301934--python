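"""Distance phylogenetics for subfamily classification.

The classification pipeline aligns domain sequences, strips gapped
columns, builds a neighbor-joining tree from corrected pairwise
distances, attaches nonparametric bootstrap supports, and assigns each
query to a subfamily via labeled anchor sequences: the smallest
well-supported clade containing the query and anchors of exactly one
subfamily lends its label.

Distances use a Kimura-style correction of the fractional mismatch,
d = -ln(1 - p - 0.2 p^2), a standard fast approximation to ML protein
distances; neighbor joining is consistent on additive matrices, so the
method recovers the true topology whenever distances are near-additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _dp
from .seqio import AMINO_ACIDS, GAP, MultipleAlignment, ProteinRecord
from .tree import Node, PhyloTree

SATURATION_P = 0.85  # mismatch fraction capped here before correction


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, substitutions/site
    saturated: Optional[np.ndarray] = None  # bool mask of capped pairs

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(~np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------------
# progressive alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62 = np.array(
    [[float(_BLOSUM62[a][b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - shared k-mer fraction; crude but monotone in relatedness."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_freqs(rows: list[tuple[str, str]]) -> np.ndarray:
    """(L, 20) per-column residue frequencies; gaps contribute nothing."""
    length = len(rows[0][1])
    freqs = np.zeros((length, 20))
    for _, seq in rows:
        for col, ch in enumerate(seq):
            if ch in _AA_INDEX:
                freqs[col, _AA_INDEX[ch]] += 1
    freqs /= len(rows)
    return freqs


def _merge_profiles(
    left: list[tuple[str, str]],
    right: list[tuple[str, str]],
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, str]]:
    f1 = _profile_freqs(left)
    f2 = _profile_freqs(right)
    S = (f1 @ _B62) @ f2.T
    M, X, Y, ptrM, ptrX, ptrY = _dp.fill_global(S, gap_open, gap_extend)
    path = _dp.traceback_global(M, X, Y, ptrM, ptrX, ptrY)
    new_left = {rid: [] for rid, _ in left}
    new_right = {rid: [] for rid, _ in right}
    for i, j in path:
        for rid, seq in left:
            new_left[rid].append(seq[i - 1] if i else GAP)
        for rid, seq in right:
            new_right[rid].append(seq[j - 1] if j else GAP)
    return [(rid, "".join(new_left[rid])) for rid, _ in left] + [
        (rid, "".join(new_right[rid])) for rid, _ in right
    ]


def align_progressive(
    records: Sequence[ProteinRecord],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Progressive multiple alignment: k-mer guide tree, then pairwise
    profile-profile merges with BLOSUM62 affine-gap dynamic programming.

    Degapping any output row recovers the corresponding input sequence.
    Deterministic: guide joins and merge order break ties lexicographically
    by smallest member id.
    """
    if len(records) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    ordered = sorted(records, key=lambda r: r.id)
    if len({r.id for r in ordered}) != len(ordered):
        raise ValueError("duplicate record ids")
    n = len(ordered)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(ordered[i].residues, ordered[j].residues)
    guide = nj_tree(DistanceMatrix([r.id for r in ordered], dm))

    by_id = {r.id: r for r in ordered}

    def build(node: Node) -> list[tuple[str, str]]:
        if node.is_leaf:
            return [(node.name, by_id[node.name].residues)]
        parts = [build(c) for c in node.children]
        parts.sort(key=lambda rows: rows[0][0])
        merged = parts[0]
        for nxt in parts[1:]:
            merged = _merge_profiles(merged, nxt, gap_open, gap_extend)
        return merged

    rows = build(guide.root)
    rows.sort(key=lambda r: r[0])
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# gap stripping


def strip_gap_columns(
    msa: MultipleAlignment, max_gap_fraction: float = 0.0
) -> tuple[MultipleAlignment, dict[int, int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``
    (default: any gap removes the column). Returns the reduced alignment
    and the old->new 1-based column map for the retained columns."""
    n_rows = msa.n_rows
    retained: list[int] = []
    for col in range(1, msa.n_columns + 1):
        gap_frac = msa.column(col).count(GAP) / n_rows
        if gap_frac <= max_gap_fraction:
            retained.append(col)
    if not retained:
        raise ValueError("no columns survive gap stripping")
    col_map = {old: new for new, old in enumerate(retained, start=1)}
    rows = [
        (rid, "".join(seq[c - 1] for c in retained)) for rid, seq in msa.rows
    ]
    return MultipleAlignment(rows), col_map


# ---------------------------------------------------------------------------
# distances


def compute_distances(msa: MultipleAlignment, on_empty: str = "error") -> DistanceMatrix:
    """Kimura-corrected pairwise distances over pairwise-complete columns.

    p is the mismatch fraction over columns where both rows are ungapped;
    d = -ln(1 - p - 0.2 p^2). p is capped at 0.85 (flagged saturated).
    ``on_empty`` controls pairs with no shared ungapped column: "error"
    raises, "cap" assigns the saturation distance (bootstrap resampling
    can produce such pairs).
    """
    if msa.n_rows < 2:
        raise ValueError("need >= 2 rows")
    codes = np.array(
        [[_AA_INDEX.get(ch, -1) for ch in seq] for _, seq in msa.rows], dtype=np.int64
    )
    valid = codes >= 0
    n = msa.n_rows
    d = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    d_cap = -np.log(1.0 - SATURATION_P - 0.2 * SATURATION_P**2)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_cols = int(both.sum())
            if n_cols == 0:
                if on_empty == "cap":
                    d[i, j] = d[j, i] = d_cap
                    saturated[i, j] = saturated[j, i] = True
                    continue
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no ungapped column"
                )
            p = float(np.mean(codes[i][both] != codes[j][both]))
            if p >= SATURATION_P:
                p = SATURATION_P
                saturated[i, j] = saturated[j, i] = True
            dist = -np.log(1.0 - p - 0.2 * p * p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.ids), d, saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling edge. With 3 taxa the root trifurcates; with 2 the
    distance splits evenly. Ties in the Q matrix resolve to the first
    (row-major) minimum, which is deterministic for a fixed id order.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    d = dm.d.copy()

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # identical taxa (distance 0) always form a cherry; joining them
        # first makes their split stable under any tie configuration
        off_diag = d + np.diag(np.full(r, np.inf))
        if off_diag.min() == 0.0:
            i, j = divmod(int(np.argmin(off_diag)), r)
        else:
            i, j = divmod(int(np.argmin(q)), r)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            li, lj = 0.0, d[i, j]
        if lj < 0:
            li, lj = d[i, j], 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = Node(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2

    root = Node()
    if len(nodes) == 2:
        nodes[0].length = nodes[1].length = 0.5 * d[0, 1]
        root.children = nodes
    else:
        l0 = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
        l1 = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
        l2 = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
        for node, ln in zip(nodes, (l0, l1, l2)):
            node.length = ln
        root.children = nodes
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    msa: MultipleAlignment, n_replicates: int = 100, seed: int = 0
) -> PhyloTree:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement; each replicate's NJ tree is
    reduced to its bipartitions, and every internal edge of the original
    tree receives the percentage of replicates containing its split.
    n_replicates=0 returns the plain tree without supports.
    """
    # canonical row order: NJ tie-breaks by matrix index, so sorting makes
    # the whole procedure invariant to input row order
    msa = MultipleAlignment(sorted(msa.rows))
    base = nj_tree(compute_distances(msa))
    if n_replicates == 0:
        return base
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = [(rid, "".join(seq[c] for c in cols)) for rid, seq in msa.rows]
        rep = nj_tree(compute_distances(MultipleAlignment(rows), on_empty="cap"))
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    all_leaves = frozenset(base.leaf_names())
    anchor = min(all_leaves)
    clade_map = base.clade_map()
    for node in base.iter_nodes():
        if node.is_leaf or node is base.root:
            continue
        below = clade_map[id(node)]
        if not 1 < len(below) < len(all_leaves) - 1:
            continue
        split = all_leaves - below if anchor in below else below
        node.support = 100.0 * counts.get(split, 0) / n_replicates
    return base


# ---------------------------------------------------------------------------
# subfamily assignment


@dataclass(frozen=True)
class SubfamilyAssignment:
    protein_id: str
    subfamily: str  # "" when unclassified
    support: float
    status: str  # "assigned" | "unclassified"


def assign_subfamilies(
    tree: PhyloTree,
    anchors: dict[str, str],
    min_support: float = 50.0,
) -> list[SubfamilyAssignment]:
    """Assign each non-anchor leaf to a subfamily via labeled anchors.

    Clades are read off the unrooted tree: every edge splits the leaves
    in two, and the side holding the query is a candidate clade (NJ's
    root placement is arbitrary, so rooted clades alone can hide a
    subfamily the root happens to sit inside). Among candidates with
    support >= min_support (edges without a support value count as fully
    supported) that contain at least one anchor, the smallest decides:
    if its anchors share one label the query is assigned that label with
    the edge's support; a mixed-label clade leaves the query
    unclassified. Deterministic and independent of anchor input order.
    """
    leaf_names = set(tree.leaf_names())
    missing = set(anchors) - leaf_names
    if missing:
        raise KeyError(f"anchor ids absent from tree: {sorted(missing)}")

    clade_map = tree.clade_map()
    # (leaf set below the edge, support of the edge)
    edges = [
        (clade_map[id(node)], node.support)
        for node in tree.iter_nodes()
        if node is not tree.root
    ]

    out: list[SubfamilyAssignment] = []
    for name in sorted(leaf_names - set(anchors)):
        candidates: list[tuple[int, list[str], float]] = []
        for below, support_raw in edges:
            side = below if name in below else leaf_names - below
            support = 100.0 if support_raw is None else support_raw
            if support < min_support:
                continue
            hit_anchors = [a for a in side if a in anchors]
            if hit_anchors:
                candidates.append((len(side), sorted(side), support))
        verdict = SubfamilyAssignment(name, "", 0.0, "unclassified")
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1]))
            size, side, support = candidates[0]
            labels = {anchors[a] for a in side if a in anchors}
            if len(labels) == 1:
                verdict = SubfamilyAssignment(name, labels.pop(), support, "assigned")
        out.append(verdict)
    return out


def assignments_to_tsv(assignments, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("protein_id\tsubfamily\tsupport\tstatus\n")
        for a in assignments:
            fh.write(f"{a.protein_id}\t{a.subfamily or '.'}\t{a.support:.0f}\t{a.status}\n")
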