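"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or direct
counting, sharing no code path with the implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from famdiv.seqio import GAP, MultipleAlignment
from famdiv.tree import Node, PhyloTree


# ---------------------------------------------------------------------------
# local profile alignment by exhaustive enumeration


def gap_cost(skipped: int, gap_open: float, gap_extend: float) -> float:
    if skipped == 0:
        return 0.0
    return gap_open + (skipped - 1) * gap_extend


def brute_force_best_local(scores, codes, gap_open, gap_extend) -> float:
    """Best local alignment score by enumerating every monotone sequence of
    match pairs; gaps between consecutive matches cost affine penalties in
    both the model and the sequence dimension."""
    m = scores.shape[0]
    n = len(codes)
    best = 0.0
    model_cols = range(1, m + 1)
    seq_pos = range(1, n + 1)
    for k in range(1, min(m, n) + 1):
        for cols in combinations(model_cols, k):
            for pos in combinations(seq_pos, k):
                score = scores[cols[0] - 1, codes[pos[0] - 1]]
                for t in range(1, k):
                    score += scores[cols[t] - 1, codes[pos[t] - 1]]
                    score -= gap_cost(cols[t] - cols[t - 1] - 1, gap_open, gap_extend)
                    score -= gap_cost(pos[t] - pos[t - 1] - 1, gap_open, gap_extend)
                if score > best:
                    best = score
    return best


# ---------------------------------------------------------------------------
# per-column divergence scan by direct counting


def brute_force_divergence_columns(
    msa: MultipleAlignment,
    reference_ids,
    partner_id: str,
    query_id: str,
    min_conservation: float = 0.9,
    max_gap_fraction: float = 0.2,
    require_partner_match: bool = True,
) -> list[int]:
    """Re-derive the divergence scan column-by-column with plain counting."""
    refs = [msa.row(r) for r in reference_ids]
    partner = msa.row(partner_id)
    query = msa.row(query_id)
    out = []
    for col in range(msa.n_columns):
        column = [r[col] for r in refs]
        non_gap = [ch for ch in column if ch != GAP]
        if not non_gap:
            continue
        if (len(column) - len(non_gap)) / len(column) > max_gap_fraction:
            continue
        counts = {ch: non_gap.count(ch) for ch in set(non_gap)}
        top = max(counts.values())
        consensus = min(ch for ch, n in counts.items() if n == top)
        if top / len(non_gap) < min_conservation:
            continue
        if require_partner_match and partner[col] != consensus:
            continue
        if query[col] == GAP or query[col] == consensus:
            continue
        out.append(col + 1)
    return out


# ---------------------------------------------------------------------------
# minimum-evolution tree search by topology enumeration


def all_unrooted_topologies(taxa: list[str]):
    """Yield every unrooted binary topology as a PhyloTree (rooted at an
    internal trifurcation), built by recursive edge insertion."""
    if len(taxa) < 4:
        raise ValueError("need >= 4 taxa")

    def edges_of(tree: Node):
        # every non-root node defines the edge to its parent
        stack = [tree]
        while stack:
            node = stack.pop()
            for child in node.children:
                yield node, child
                stack.append(child)

    def clone(node: Node) -> Node:
        return Node(
            name=node.name, length=node.length, children=[clone(c) for c in node.children]
        )

    def insert_on_each_edge(tree: Node, leaf_name: str):
        for parent, child in list(edges_of(tree)):
            t2 = clone(tree)
            # find the corresponding edge in the clone by path replay
            def find(node: Node, target: Node, orig: Node):
                if orig is target:
                    return node
                for c_new, c_old in zip(node.children, orig.children):
                    found = find(c_new, target, c_old)
                    if found is not None:
                        return found
                return None

            child2 = find(t2, child, tree)
            parent2 = find(t2, parent, tree)
            parent2.children.remove(child2)
            joint = Node(children=[child2, Node(name=leaf_name)])
            parent2.children.append(joint)
            yield t2

    base = Node(children=[Node(name=taxa[0]), Node(name=taxa[1]), Node(name=taxa[2])])
    trees = [base]
    for leaf in taxa[3:]:
        trees = [t2 for t in trees for t2 in insert_on_each_edge(t, leaf)]
    for t in trees:
        yield PhyloTree(t)


def ols_tree_length(tree: PhyloTree, ids: list[str], d: np.ndarray) -> float:
    """Ordinary-least-squares branch lengths for a fixed topology; returns
    the total tree length (the minimum-evolution criterion)."""
    parents = {id(tree.root): None}
    nodes = list(tree.iter_nodes())
    for node in nodes:
        for child in node.children:
            parents[id(child)] = node
    edges = [n for n in nodes if parents[id(n)] is not None]
    edge_index = {id(n): k for k, n in enumerate(edges)}
    leaves = {leaf.name: leaf for leaf in tree.leaves()}

    def path_edges(a: str, b: str):
        seen = {}
        node = leaves[a]
        while node is not None:
            seen[id(node)] = node
            node = parents[id(node)]
        node = leaves[b]
        tail = []
        while id(node) not in seen:
            tail.append(node)
            node = parents[id(node)]
        common = node
        head = []
        node = leaves[a]
        while node is not common:
            head.append(node)
            node = parents[id(node)]
        return head + tail

    pairs = list(combinations(range(len(ids)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for node in path_edges(ids[i], ids[j]):
            A[row, edge_index[id(node)]] = 1.0
        y[row] = d[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(x.sum())


def min_evolution_tree(ids: list[str], d: np.ndarray) -> PhyloTree:
    best = None
    best_len = np.inf
    for tree in all_unrooted_topologies(list(ids)):
        length = ols_tree_length(tree, list(ids), d)
        if length < best_len - 1e-12:
            best_len = length
            best = tree
    return best


# ---------------------------------------------------------------------------
# additive matrices from random trees


def tree_path_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    parents = {id(tree.root): None}
    for node in tree.iter_nodes():
        for child in node.children:
            parents[id(child)] = node
    leaves = {leaf.name: leaf for leaf in tree.leaves()}
    names = sorted(leaves)
    n = len(names)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        anc = {}
        node, dist = leaves[names[i]], 0.0
        while node is not None:
            anc[id(node)] = dist
            dist += node.length
            node = parents[id(node)]
        node, dist = leaves[names[j]], 0.0
        while id(node) not in anc:
            dist += node.length
            node = parents[id(node)]
        d[i, j] = d[j, i] = dist + anc[id(node)]
    return names, d
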