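import math

import numpy as np
import pytest

from famdiv import phylo, synthio
from famdiv.phylo import (
    DistanceMatrix,
    align_progressive,
    assign_subfamilies,
    bootstrap_support,
    compute_distances,
    nj_tree,
    strip_gap_columns,
)
from famdiv.profiles import AMINO_ACIDS, DEFAULT_BACKGROUND
from famdiv.seqio import MultipleAlignment, ProteinRecord

from oracles import min_evolution_tree, tree_path_distances


def make_subfamily_records(seed, n_groups=3, n_per=5, length=80, noise=0.08):
    """Well-separated synthetic subfamilies: noisy copies of random consensi."""
    rng = np.random.default_rng(seed)
    records, labels = [], {}
    for g in range(n_groups):
        consensus = "".join(
            AMINO_ACIDS[c] for c in rng.choice(20, size=length, p=DEFAULT_BACKGROUND)
        )
        for m in range(n_per):
            seq = "".join(
                ch if rng.random() > noise else AMINO_ACIDS[rng.integers(20)]
                for ch in consensus
            )
            rid = f"g{g}m{m}"
            records.append(ProteinRecord(id=rid, residues=seq))
            labels[rid] = f"SF{g}"
    return records, labels


class TestAlignProgressive:
    def test_identical_sequences_align_gapless(self):
        recs = [ProteinRecord(id=i, residues="MKLVNDAERT") for i in ("a", "b")]
        msa = align_progressive(recs)
        assert msa.row("a") == msa.row("b") == "MKLVNDAERT"

    def test_single_deletion_matches_needleman_wunsch_by_hand(self):
        # hand oracle: ACDEFG vs ACEFG -> one gap column opposite D,
        # five matched columns
        recs = [ProteinRecord(id="x", residues="ACDEFG"),
                ProteinRecord(id="y", residues="ACEFG")]
        msa = align_progressive(recs)
        assert msa.n_columns == 6
        row_x, row_y = msa.row("x"), msa.row("y")
        assert row_x == "ACDEFG"
        assert row_y.count("-") == 1
        matches = sum(a == b for a, b in zip(row_x, row_y))
        assert matches == 5

    def test_degapping_recovers_inputs(self):
        fam, _ = synthio.generate_ortholog_family(8, 100, indel_rate=0.03, seed=3)
        recs = fam.to_records()
        msa = align_progressive(recs)
        for r in recs:
            assert msa.ungapped(r.id) == r.residues

    def test_realignment_recovers_planted_homology(self):
        # >= 90% of residue pairs co-aligned in the generating alignment
        # must be co-aligned after realignment from scratch
        fam, _ = synthio.generate_ortholog_family(8, 150, indel_rate=0.02, seed=21)
        realigned = align_progressive(fam.to_records())

        def aligned_pairs(msa, a, b):
            pairs = set()
            pos_a = pos_b = 0
            for ca, cb in zip(msa.row(a), msa.row(b)):
                if ca != "-":
                    pos_a += 1
                if cb != "-":
                    pos_b += 1
                if ca != "-" and cb != "-":
                    pairs.add((pos_a, pos_b))
            return pairs

        ids = fam.ids
        total = recovered = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                truth = aligned_pairs(fam, ids[i], ids[j])
                est = aligned_pairs(realigned, ids[i], ids[j])
                total += len(truth)
                recovered += len(truth & est)
        assert recovered / total >= 0.90

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            align_progressive([ProteinRecord(id="a", residues="ACDEF")])


class TestStripGapColumns:
    def test_gapless_identity(self):
        msa = MultipleAlignment([("a", "ACDE"), ("b", "ACDE")])
        stripped, cmap = strip_gap_columns(msa)
        assert stripped.rows == msa.rows
        assert cmap == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_any_gap_removes_column_at_default(self):
        msa = MultipleAlignment([("a", "AXA"), ("b", "A-A"), ("c", "AAA"), ("d", "AAA")])
        stripped, cmap = strip_gap_columns(msa)
        assert stripped.n_columns == 2
        assert cmap == {1: 1, 3: 2}

    def test_map_round_trip_identity_on_retained(self):
        fam, _ = synthio.generate_ortholog_family(6, 120, indel_rate=0.05, seed=4)
        stripped, cmap = strip_gap_columns(fam, max_gap_fraction=0.2)
        inverse = {new: old for old, new in cmap.items()}
        for old, new in cmap.items():
            assert inverse[new] == old
        # retained columns carry identical residues
        for old, new in cmap.items():
            assert fam.column(old) == stripped.column(new)


class TestDistances:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment([("a", "ACDEF" * 10), ("b", "ACDEF" * 10)])
        assert compute_distances(msa).d[0, 1] == 0.0

    def test_closed_form_correction(self):
        # p = 0.1 over 100 columns -> d = -ln(1 - 0.1 - 0.002)
        base = "A" * 100
        mutated = "C" * 10 + "A" * 90
        msa = MultipleAlignment([("a", base), ("b", mutated)])
        d = compute_distances(msa).d[0, 1]
        assert d == pytest.approx(-math.log(1 - 0.1 - 0.2 * 0.01), rel=1e-9)

    def test_symmetry_random(self):
        fam, _ = synthio.generate_ortholog_family(8, 120, seed=6)
        dm = compute_distances(fam)
        assert np.allclose(dm.d, dm.d.T)

    def test_saturation_capped_and_flagged(self):
        msa = MultipleAlignment([("a", "A" * 60), ("b", "C" * 60)])
        dm = compute_distances(msa)
        assert np.isfinite(dm.d[0, 1])
        assert dm.saturated[0, 1]


class TestNeighborJoining:
    def test_four_taxon_additive_recovery_exact(self):
        # unrooted tree ((A,B),(C,D)), all five branches length 1
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 2, 3, 3],
            [2, 0, 3, 3],
            [3, 3, 0, 2],
            [3, 3, 2, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.leaves()}
        assert all(lengths[x] == pytest.approx(1.0) for x in ids)
        internal = [n.length for n in tree.iter_nodes()
                    if not n.is_leaf and n is not tree.root]
        assert internal == [pytest.approx(1.0)]

    def test_ultrametric_tie_deterministic(self):
        ids = ["A", "B", "C", "D"]
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        t1 = nj_tree(DistanceMatrix(ids, d))
        t2 = nj_tree(DistanceMatrix(ids, d))
        assert t1.to_newick() == t2.to_newick()

    def test_topology_recovery_on_random_additive_matrices(self):
        ok = 0
        for trial in range(100):
            _, truth = synthio.generate_ortholog_family(8, 60, depth=1.0, seed=500 + trial)
            names, d = tree_path_distances(truth.true_tree)
            est = nj_tree(DistanceMatrix(names, d))
            ok += est.bipartitions() == truth.true_tree.bipartitions()
        assert ok == 100

    def test_matches_brute_force_minimum_evolution(self):
        # <= 6 taxa: NJ on additive input equals exhaustive ME-OLS search
        for trial in range(10):
            _, truth = synthio.generate_ortholog_family(6, 60, depth=1.0, seed=700 + trial)
            names, d = tree_path_distances(truth.true_tree)
            nj = nj_tree(DistanceMatrix(names, d))
            me = min_evolution_tree(names, d)
            assert nj.bipartitions() == me.bipartitions()

    def test_agrees_with_scikit_bio_nj(self):
        # independent implementation cross-check on additive input
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for trial in range(10):
            _, truth = synthio.generate_ortholog_family(8, 60, depth=1.0, seed=9000 + trial)
            names, d = tree_path_distances(truth.true_tree)
            mine = nj_tree(DistanceMatrix(names, d)).bipartitions()
            sk_tree = skbio_nj(SkbioDM(d, ids=names))
            all_leaves = frozenset(names)
            anchor = min(all_leaves)
            theirs = set()
            for node in sk_tree.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < len(all_leaves) - 1:
                    theirs.add(all_leaves - below if anchor in below else below)
            assert mine == theirs

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestBootstrap:
    def make_two_clade_msa(self, seed=13):
        records, _ = make_subfamily_records(seed, n_groups=2, n_per=4, length=120)
        msa = align_progressive(records)
        stripped, _ = strip_gap_columns(msa, 0.5)
        return stripped

    def test_well_separated_clades_strongly_supported(self):
        tree = bootstrap_support(self.make_two_clade_msa(), n_replicates=100, seed=1)
        split = frozenset(n for n in tree.leaf_names() if n.startswith("g1"))
        clade_supports = {}
        clade_map = tree.clade_map()
        for node in tree.iter_nodes():
            if not node.is_leaf and node.support is not None:
                clade_supports[clade_map[id(node)]] = node.support
        all_leaves = frozenset(tree.leaf_names())
        matching = [
            s for c, s in clade_supports.items() if c == split or c == all_leaves - split
        ]
        assert matching and max(matching) >= 95

    def test_zero_replicates_leaves_supports_absent(self):
        tree = bootstrap_support(self.make_two_clade_msa(), n_replicates=0, seed=1)
        assert all(n.support is None for n in tree.iter_nodes())

    def test_same_seed_identical_supports(self):
        msa = self.make_two_clade_msa()
        t1 = bootstrap_support(msa, n_replicates=50, seed=9)
        t2 = bootstrap_support(msa, n_replicates=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_to_row_order(self):
        msa = self.make_two_clade_msa()
        reversed_msa = MultipleAlignment(list(reversed(msa.rows)))
        t1 = bootstrap_support(msa, n_replicates=50, seed=9)
        t2 = bootstrap_support(reversed_msa, n_replicates=50, seed=9)

        def support_table(tree):
            clade_map = tree.clade_map()
            all_leaves = frozenset(tree.leaf_names())
            anchor = min(all_leaves)
            table = {}
            for node in tree.iter_nodes():
                if node.is_leaf or node is tree.root or node.support is None:
                    continue
                below = clade_map[id(node)]
                side = all_leaves - below if anchor in below else below
                table[side] = node.support
            return table

        assert support_table(t1) == support_table(t2)


class TestAssignSubfamilies:
    def test_query_identical_to_anchor(self):
        records, labels = make_subfamily_records(31, n_groups=2, n_per=3)
        anchor_id = "g0m0"
        twin = ProteinRecord(id="query", residues=next(
            r.residues for r in records if r.id == anchor_id))
        msa = align_progressive(records + [twin])
        stripped, _ = strip_gap_columns(msa, 0.5)
        tree = bootstrap_support(stripped, n_replicates=100, seed=2)
        anchors = {rid: lab for rid, lab in labels.items()}
        result = {a.protein_id: a for a in assign_subfamilies(tree, anchors)}
        assert result["query"].status == "assigned"
        assert result["query"].subfamily == labels[anchor_id]
        assert result["query"].support == 100.0

    def test_three_subfamily_planted_assignment(self):
        correct = total = 0
        for seed in range(5):
            records, labels = make_subfamily_records(800 + seed)
            anchors = {r: l for r, l in labels.items() if r.endswith(("m0", "m1"))}
            msa = align_progressive(records)
            stripped, _ = strip_gap_columns(msa, 0.5)
            tree = bootstrap_support(stripped, n_replicates=100, seed=seed)
            for a in assign_subfamilies(tree, anchors):
                total += 1
                correct += a.status == "assigned" and a.subfamily == labels[a.protein_id]
        assert correct / total >= 0.95

    def test_query_sister_to_mixed_clade_unclassified(self):
        # handcrafted tree: query sister to a clade holding anchors of two
        # different subfamilies
        from famdiv.tree import Node, PhyloTree

        mixed = Node(length=1.0, support=100.0, children=[
            Node(name="anchor1", length=1.0), Node(name="anchor2", length=1.0)])
        inner = Node(length=1.0, support=100.0, children=[
            Node(name="query", length=1.0), mixed])
        tree = PhyloTree(Node(children=[
            inner, Node(name="out1", length=5.0), Node(name="out2", length=5.0)]))
        anchors = {"anchor1": "SF0", "anchor2": "SF1"}
        result = {a.protein_id: a for a in assign_subfamilies(tree, anchors)}
        assert result["query"].status == "unclassified"

    def test_missing_anchor_listed_in_error(self):
        records, labels = make_subfamily_records(31, n_groups=2, n_per=3)
        msa = align_progressive(records)
        stripped, _ = strip_gap_columns(msa, 0.5)
        tree = nj_tree(compute_distances(stripped))
        with pytest.raises(KeyError, match="ghost"):
            assign_subfamilies(tree, {"ghost": "SF9"})
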