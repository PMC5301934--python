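"""Synthetic proteomes, motif-bearing proteins and ortholog families with
planted ground truth.

The generator emulates the inputs of a duplicated-genome transcription
factor survey: a proteome in which a known subset of proteins carries a
(possibly truncated) noisy domain copy; proteins carrying short secondary
motifs outside the domain; and an ortholog-family alignment with a mix of
near-invariant and variable columns, indels that shift per-sequence
numbering, and a duplicated pair in which one paralog departs from deeply
conserved positions. Everything is reproducible bit-for-bit from a seed,
and every planted feature is recorded in a truth object with 1-based
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .profiles import DEFAULT_BACKGROUND, N_AA
from .seqio import AMINO_ACIDS, GAP, MultipleAlignment, ProteinRecord
from .tree import Node, PhyloTree


class InfeasibleError(ValueError):
    """Raised when the requested planting cannot be satisfied."""


#: an HLH-like 40-residue synthetic consensus: basic region then two helices
DEFAULT_DOMAIN_CONSENSUS = "RRERNRVKARINELRELLPSHNAKSDKASILDEAIEYIKQLQ"

#: default per-column substitution tolerance mixture: (weight, tolerance)
DEFAULT_CONSERVATION_MIXTURE = ((0.7, 0.02), (0.3, 0.5))


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset (all coordinates 1-based)."""

    rng_seed: int
    #: (protein_id, start, end, truncated)
    planted_domain_locations: list[tuple[str, int, int, bool]] = field(default_factory=list)
    #: (protein_id, motif_id, start)
    planted_motif_locations: list[tuple[str, str, int]] = field(default_factory=list)
    #: alignment columns where the planted paralog diverges
    planted_divergent_columns: list[int] = field(default_factory=list)
    true_tree: Optional[PhyloTree] = None
    #: per-column substitution tolerance of a generated family (internal QC)
    column_tolerances: Optional[np.ndarray] = None


def _draw_background(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    codes = rng.choice(N_AA, size=length, p=bg)
    return "".join(AMINO_ACIDS[c] for c in codes)


def _substitute(rng: np.random.Generator, residue: str, bg: np.ndarray) -> str:
    """Draw a residue from the background excluding the current one,
    guaranteeing the result is truly different."""
    idx = AMINO_ACIDS.index(residue)
    probs = bg.copy()
    probs[idx] = 0.0
    probs /= probs.sum()
    return AMINO_ACIDS[rng.choice(N_AA, p=probs)]


# ---------------------------------------------------------------------------
# proteome with planted domains


def generate_proteome(
    n_proteins: int,
    n_with_domain: int,
    domain_consensus: str = DEFAULT_DOMAIN_CONSENSUS,
    substitution_rate: float = 0.05,
    truncation_fraction: float = 0.0,
    background_freqs: Optional[np.ndarray] = None,
    length_range: tuple[int, int] = (120, 400),
    seed: int = 0,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate a proteome in which ``n_with_domain`` proteins carry a noisy
    copy of the domain consensus; the rest are i.i.d. background.

    Each planted copy has point substitutions at ``substitution_rate`` per
    site; ``round(truncation_fraction * n_with_domain)`` of the copies are
    truncated to under half the consensus length. The truth object records
    every insertion point and truncation flag.
    """
    if n_with_domain > n_proteins:
        raise ValueError("n_with_domain cannot exceed n_proteins")
    if not 0.0 <= truncation_fraction <= 1.0:
        raise ValueError("truncation_fraction must lie in [0, 1]")
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must lie in [0, 1]")
    if len(domain_consensus) < 10:
        raise ValueError("domain consensus must have >= 10 residues")

    bg = DEFAULT_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    rng = np.random.default_rng(seed)
    n_trunc = round(truncation_fraction * n_with_domain)

    records: list[ProteinRecord] = []
    truth = SyntheticTruth(rng_seed=seed)
    for k in range(n_proteins):
        pid = f"SYN{k + 1:04d}_T01"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if k < n_with_domain:
            domain = "".join(
                _substitute(rng, ch, bg) if rng.random() < substitution_rate else ch
                for ch in domain_consensus
            )
            truncated = k < n_trunc
            if truncated:
                keep = max(5, int(len(domain) * 0.4))  # < 50% of the model
                domain = domain[:keep]
            flank_total = max(20, length - len(domain))
            left = int(rng.integers(0, flank_total + 1))
            right = flank_total - left
            seq = _draw_background(rng, left, bg) + domain + _draw_background(rng, right, bg)
            truth.planted_domain_locations.append(
                (pid, left + 1, left + len(domain), truncated)
            )
        else:
            seq = _draw_background(rng, length, bg)
        records.append(ProteinRecord(id=pid, residues=seq, description="synthetic"))
    return records, truth


def plant_motifs(
    records: Sequence[ProteinRecord],
    motif_consensus: str,
    motif_id: str,
    carrier_ids: Sequence[str],
    substitution_rate: float = 0.05,
    background_freqs: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Insert a noisy copy of a secondary motif into the named proteins.

    The motif is appended in the C-terminal half, outside any N-terminal
    planted domain. Returns new records plus a truth object listing
    (protein_id, motif_id, start).
    """
    bg = DEFAULT_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    rng = np.random.default_rng(seed)
    carriers = set(carrier_ids)
    unknown = carriers - {r.id for r in records}
    if unknown:
        raise ValueError(f"carrier ids not in records: {sorted(unknown)}")

    truth = SyntheticTruth(rng_seed=seed)
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.id in carriers:
            motif = "".join(
                _substitute(rng, ch, bg) if rng.random() < substitution_rate else ch
                for ch in motif_consensus
            )
            anchor = max(len(rec.residues) * 3 // 4, len(rec.residues) - len(motif))
            seq = rec.residues[:anchor] + motif + rec.residues[anchor:]
            truth.planted_motif_locations.append((rec.id, motif_id, anchor + 1))
            out.append(ProteinRecord(id=rec.id, residues=seq, description=rec.description))
        else:
            out.append(rec)
    return out, truth


# ---------------------------------------------------------------------------
# ortholog families


def _random_tree(rng: np.random.Generator, n_leaves: int, depth: float) -> PhyloTree:
    """Random bifurcating topology by sequential joins; branch lengths
    exponential with mean depth / log2(n) so root-to-tip path length is
    about ``depth`` substitutions/site."""
    nodes = [Node(name=f"ref{i + 1:02d}") for i in range(n_leaves)]
    mean_bl = depth / max(1.0, math.log2(n_leaves)) if depth > 0 else 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = rng.exponential(mean_bl) if mean_bl > 0 else 0.0
        b.length = rng.exponential(mean_bl) if mean_bl > 0 else 0.0
        parent = Node(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return PhyloTree(nodes[0])


def generate_ortholog_family(
    n_refs: int,
    length: int,
    conservation_mixture: Sequence[tuple[float, float]] = DEFAULT_CONSERVATION_MIXTURE,
    depth: float = 1.0,
    indel_rate: float = 0.01,
    background_freqs: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[MultipleAlignment, SyntheticTruth]:
    """Evolve an ortholog family down a random tree.

    Each column draws a substitution tolerance from the mixture (weight,
    tolerance); a branch of length t substitutes the column with
    probability 1 - exp(-tolerance * t), to a background residue other
    than the current one. Indels (geometric length, mean 2) are applied
    per leaf at ``indel_rate`` events per site, so ungapped numbering
    differs between rows.
    """
    if n_refs < 4:
        raise ValueError("n_refs must be >= 4 (NJ and conservation need 4+ references)")
    if length < 50:
        raise ValueError("length must be >= 50")
    weights = [w for w, _ in conservation_mixture]
    if not math.isclose(sum(weights), 1.0, abs_tol=1e-6):
        raise ValueError("conservation mixture weights must sum to 1")

    bg = DEFAULT_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    rng = np.random.default_rng(seed)
    tree = _random_tree(rng, n_refs, depth)

    classes = rng.choice(len(conservation_mixture), size=length, p=weights)
    tolerances = np.array([conservation_mixture[c][1] for c in classes])

    root_seq = list(_draw_background(rng, length, bg))
    leaf_seqs: dict[str, list[str]] = {}

    def evolve(node: Node, seq: list[str]) -> None:
        if node.length > 0:
            p_sub = 1.0 - np.exp(-tolerances * node.length)
            hit = rng.random(length) < p_sub
            seq = seq.copy()
            for col in np.nonzero(hit)[0]:
                seq[col] = _substitute(rng, seq[col], bg)
        if node.is_leaf:
            leaf_seqs[node.name] = list(seq)
        else:
            for child in node.children:
                evolve(child, seq)

    evolve(tree.root, root_seq)

    names = sorted(leaf_seqs)
    rows = {name: leaf_seqs[name] for name in names}

    # deletions: per leaf, Poisson number of events, geometric length mean 2
    for name in names:
        n_events = rng.poisson(indel_rate * length / 2.0)
        for _ in range(n_events):
            start = int(rng.integers(0, length))
            span = int(rng.geometric(0.5))
            for col in range(start, min(start + span, length)):
                rows[name][col] = GAP

    # insertions: new columns private to one leaf
    events = []
    for name in names:
        n_events = rng.poisson(indel_rate * length / 2.0)
        for _ in range(n_events):
            events.append((int(rng.integers(0, length + 1)), name, int(rng.geometric(0.5))))
    for pos, name, span in sorted(events, reverse=True):
        for name2 in names:
            insert = (
                list(_draw_background(rng, span, bg)) if name2 == name else [GAP] * span
            )
            rows[name2][pos:pos] = insert

    msa = MultipleAlignment([(name, "".join(rows[name])) for name in names])
    truth = SyntheticTruth(rng_seed=seed, true_tree=tree, column_tolerances=tolerances)
    return msa, truth


def _column_stats(msa: MultipleAlignment, col: int) -> tuple[str, float, float]:
    """(modal residue, consensus fraction among non-gaps, gap fraction);
    modal ties broken alphabetically."""
    residues = msa.column(col)
    non_gap = [ch for ch in residues if ch != GAP]
    gap_fraction = 1.0 - len(non_gap) / len(residues)
    if not non_gap:
        return GAP, 0.0, 1.0
    counts: dict[str, int] = {}
    for ch in non_gap:
        counts[ch] = counts.get(ch, 0) + 1
    best_count = max(counts.values())
    consensus = min(ch for ch, n in counts.items() if n == best_count)
    return consensus, best_count / len(non_gap), gap_fraction


def plant_paralog_divergence(
    family: MultipleAlignment,
    n_sites: int,
    min_conservation: float = 0.9,
    background_freqs: Optional[np.ndarray] = None,
    seed: int = 0,
    partner_id: str = "paralogA",
    query_id: str = "paralogB",
) -> tuple[MultipleAlignment, SyntheticTruth]:
    """Append a duplicated pair to a reference family: the partner copies
    the column consensus everywhere; the query matches the partner except
    at exactly ``n_sites`` sampled gapless columns of conservation >=
    ``min_conservation``, where it carries a non-consensus residue.
    """
    if family.n_rows < 4:
        raise ValueError("family must have >= 4 rows")
    bg = DEFAULT_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    rng = np.random.default_rng(seed)

    consensus_row: list[str] = []
    eligible: list[int] = []
    for col in range(1, family.n_columns + 1):
        consensus, fraction, gap_fraction = _column_stats(family, col)
        consensus_row.append(consensus)
        if gap_fraction == 0.0 and fraction >= min_conservation:
            eligible.append(col)

    if len(eligible) < n_sites:
        raise InfeasibleError(
            f"only {len(eligible)} columns reach conservation {min_conservation}; "
            f"cannot plant {n_sites} divergent sites"
        )

    chosen = sorted(rng.choice(eligible, size=n_sites, replace=False).tolist()) if n_sites else []
    partner_row = "".join(consensus_row)
    query_row = list(consensus_row)
    for col in chosen:
        query_row[col - 1] = _substitute(rng, consensus_row[col - 1], bg)

    msa = MultipleAlignment(
        family.rows + [(partner_id, partner_row), (query_id, "".join(query_row))]
    )
    truth = SyntheticTruth(rng_seed=seed, planted_divergent_columns=chosen)
    return msa, truth


def insert_private_insertion(
    msa: MultipleAlignment,
    row_id: str,
    column: int,
    length: int,
    background_freqs: Optional[np.ndarray] = None,
    seed: int = 0,
) -> MultipleAlignment:
    """Insert ``length`` columns before 1-based ``column`` carrying residues
    only in ``row_id`` — the numbering-offset scenario where one paralog's
    residue indices run ahead of its partner's."""
    bg = DEFAULT_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    rng = np.random.default_rng(seed)
    if row_id not in msa.ids:
        raise KeyError(row_id)
    if not 1 <= column <= msa.n_columns + 1:
        raise IndexError(f"column {column} outside 1..{msa.n_columns + 1}")
    insert = _draw_background(rng, length, bg)
    rows = []
    for rid, seq in msa.rows:
        block = insert if rid == row_id else GAP * length
        rows.append((rid, seq[: column - 1] + block + seq[column - 1 :]))
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# truth serialisation


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    """Tab-separated truth file; one header line, 1-based inclusive coords."""
    with open(path, "w") as fh:
        fh.write("kind\tid\tfeature\tstart\tend\ttruncated\n")
        for pid, start, end, trunc in truth.planted_domain_locations:
            fh.write(f"domain\t{pid}\tdomain\t{start}\t{end}\t{str(trunc).lower()}\n")
        for pid, motif_id, start in truth.planted_motif_locations:
            fh.write(f"motif\t{pid}\t{motif_id}\t{start}\t.\t.\n")
        for col in truth.planted_divergent_columns:
            fh.write(f"divergent_column\t.\tcolumn\t{col}\t{col}\t.\n")
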