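"""Conservation-based detection of diverged residues in a duplicated
paralog pair.

Given a multiple alignment of an ortholog family (the references), plus a
recently duplicated pair — a partner that retained ancestral function and
a query suspected of divergence — the scan flags alignment columns where
(a) the references are deeply conserved, (b) the partner carries the
conserved residue, and (c) the query carries something else. Each flagged
column is mapped back to per-sequence residue numbering (which differs
between paralogs whenever indels shifted one of them) and annotated with
domain context. Sites are reported in substitution notation built from
the consensus residue, the query's own numbering and the query residue
(e.g. F113L: conserved phenylalanine replaced by leucine at query
position 113).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GAP, DomainInterval, MultipleAlignment, ProteinRecord


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the divergence scan.

    min_conservation is the dominant knob: the minimal frequency of the
    modal residue among non-gap references for a column to count as
    "deeply conserved" (default 0.9, i.e. at most ~1 in 10 references may
    deviate). mode="unseen-residue" replaces the frequency condition with
    a stricter presence test: the query residue must never occur among
    the references at that column.
    """

    min_conservation: float = 0.9
    max_gap_fraction: float = 0.2
    require_partner_match: bool = True
    min_refs: int = 10
    mode: str = "frequency"  # or "unseen-residue"

    def __post_init__(self) -> None:
        for name in ("min_conservation", "max_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mode not in ("frequency", "unseen-residue"):
            raise ValueError(f"unknown scan mode {self.mode!r}")


@dataclass
class ColumnConservation:
    consensus_residue: str  # modal residue among non-gap references
    consensus_fraction: float  # its frequency among non-gap references
    gap_fraction: float
    n_refs_effective: int  # non-gap references in the column
    tie: bool = False  # modal residue tied (broken alphabetically)
    residues_seen: frozenset = frozenset()

    @property
    def defined(self) -> bool:
        return self.n_refs_effective > 0


@dataclass
class DivergentSite:
    """One alignment column where the query departs from deep conservation."""

    column: int  # 1-based alignment column
    consensus_residue: str
    partner_residue: str
    query_residue: str
    consensus_fraction: float
    query_position: int  # 1-based in the query's ungapped sequence
    partner_position: Optional[int]  # None if the partner is gapped here
    domain_label: str = "inter-domain"

    @property
    def notation(self) -> str:
        """Substitution notation: consensus residue, query numbering, query residue."""
        return f"{self.consensus_residue}{self.query_position}{self.query_residue}"


# ---------------------------------------------------------------------------


def conservation_profile(
    msa: MultipleAlignment, reference_ids: Sequence[str]
) -> list[ColumnConservation]:
    """Per-column consensus statistics over the reference rows only.

    Gaps are excluded from the consensus denominator; modal ties break
    alphabetically and are flagged. Paralogs (non-reference rows) never
    influence the profile.
    """
    refs = list(dict.fromkeys(reference_ids))
    if len(refs) < 4:
        raise ValueError(f"need >= 4 reference ids, got {len(refs)}")
    missing = set(refs) - set(msa.ids)
    if missing:
        raise KeyError(f"reference ids absent from alignment: {sorted(missing)}")

    ref_rows = [msa.row(r) for r in refs]
    n_refs = len(ref_rows)
    profile: list[ColumnConservation] = []
    for col in range(msa.n_columns):
        residues = [row[col] for row in ref_rows]
        non_gap = [ch for ch in residues if ch != GAP]
        gap_fraction = 1.0 - len(non_gap) / n_refs
        if not non_gap:
            profile.append(
                ColumnConservation(GAP, 0.0, 1.0, 0, residues_seen=frozenset())
            )
            continue
        counts: dict[str, int] = {}
        for ch in non_gap:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        modal = sorted(ch for ch, n in counts.items() if n == best)
        profile.append(
            ColumnConservation(
                consensus_residue=modal[0],
                consensus_fraction=best / len(non_gap),
                gap_fraction=gap_fraction,
                n_refs_effective=len(non_gap),
                tie=len(modal) > 1,
                residues_seen=frozenset(counts),
            )
        )
    return profile


def map_column_to_position(msa: MultipleAlignment, row_id: str, column: int) -> Optional[int]:
    """1-based residue position of ``column`` in the row's ungapped sequence,
    or None when the row is gapped at that column."""
    row = msa.row(row_id)
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} outside 1..{len(row)}")
    if row[column - 1] == GAP:
        return None
    return column - row[:column].count(GAP)


def scan_paralog_divergence(
    msa: MultipleAlignment,
    reference_ids: Sequence[str],
    partner_id: str,
    query_id: str,
    config: ScanConfig = ScanConfig(),
) -> list[DivergentSite]:
    """Flag columns where the query paralog departs from deep conservation.

    A column is reported iff all of:
      (a) conservation — frequency mode: consensus_fraction >= min_conservation;
          unseen-residue mode: the query residue never occurs among references;
      (b) gap_fraction among references <= max_gap_fraction;
      (c) the partner carries the consensus residue (when required);
      (d) the query residue differs from the consensus and is not a gap.

    Sites come back ordered by query position.
    """
    refs = set(reference_ids)
    for rid in (partner_id, query_id):
        if rid not in msa.ids:
            raise KeyError(f"{rid!r} not in alignment")
        if rid in refs:
            raise ValueError(f"{rid!r} cannot be both a paralog and a reference")
    if len(refs) < config.min_refs:
        raise ValueError(
            f"scan needs >= {config.min_refs} references, got {len(refs)}"
        )

    profile = conservation_profile(msa, list(reference_ids))
    partner_row = msa.row(partner_id)
    query_row = msa.row(query_id)

    sites: list[DivergentSite] = []
    for col0, stats in enumerate(profile):
        if not stats.defined:
            continue
        if stats.gap_fraction > config.max_gap_fraction:
            continue
        q = query_row[col0]
        p = partner_row[col0]
        if q == GAP or q == stats.consensus_residue:
            continue
        if config.mode == "frequency":
            if stats.consensus_fraction < config.min_conservation:
                continue
        else:  # unseen-residue
            if q in stats.residues_seen:
                continue
        if config.require_partner_match and p != stats.consensus_residue:
            continue
        column = col0 + 1
        sites.append(
            DivergentSite(
                column=column,
                consensus_residue=stats.consensus_residue,
                partner_residue=p,
                query_residue=q,
                consensus_fraction=stats.consensus_fraction,
                query_position=map_column_to_position(msa, query_id, column),
                partner_position=map_column_to_position(msa, partner_id, column),
            )
        )
    sites.sort(key=lambda s: s.query_position)
    return sites


def annotate_domains(
    sites: Iterable[DivergentSite], domains: Sequence[DomainInterval]
) -> list[DivergentSite]:
    """Label each site with the domain interval containing its query
    position, or "inter-domain". Interval ends are inclusive; overlapping
    intervals are rejected."""
    ordered = sorted(domains, key=lambda d: d.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end >= b.start:
            raise ValueError(
                f"overlapping domain intervals: {a.label} [{a.start},{a.end}] "
                f"and {b.label} [{b.start},{b.end}]"
            )
    out = []
    for site in sites:
        label = "inter-domain"
        for dom in ordered:
            if dom.contains(site.query_position):
                label = dom.label
                break
        site.domain_label = label
        out.append(site)
    return out


# ---------------------------------------------------------------------------


def pairwise_paralog_report(
    seq_a: ProteinRecord, seq_b: ProteinRecord
) -> tuple[float, int, int]:
    """Global pairwise comparison of a duplicated pair.

    Returns (percent identity over aligned columns, substitution count,
    gap-containing column count) from a BLOSUM62 affine-gap global
    alignment. Substitutions and indel positions are reported separately
    so either reading of a combined "difference" count is recoverable.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(seq_a.residues, seq_b.residues)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = mismatches = indel_cols = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            indel_cols += 1
        elif a == b:
            matches += 1
        else:
            mismatches += 1
    n_cols = len(row_a)
    identity = 100.0 * matches / n_cols if n_cols else 0.0
    return identity, mismatches, indel_cols


def sites_to_tsv(sites: Iterable[DivergentSite], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "column\tquery_pos\tpartner_pos\tconsensus\tconsensus_fraction\t"
            "partner_res\tquery_res\tdomain\tnotation\n"
        )
        for s in sites:
            pp = "." if s.partner_position is None else s.partner_position
            fh.write(
                f"{s.column}\t{s.query_position}\t{pp}\t{s.consensus_residue}\t"
                f"{s.consensus_fraction:.3f}\t{s.partner_residue}\t{s.query_residue}\t"
                f"{s.domain_label}\t{s.notation}\n"
            )
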