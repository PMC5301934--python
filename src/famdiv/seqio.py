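"""Sequence and alignment I/O plus the shared data model.

Every coordinate in this package is 1-based and inclusive, matching the
residue numbering used in the phytochrome literature (position 113 means
the 113th residue of the ungapped protein).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a ProteinRecord: the 20 canonical letters plus X
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def default_locus_rule(record_id: str) -> str:
    """Strip a trailing isoform suffix like ``_T02`` from a protein id.

    Maize filtered-gene-set ids encode the locus in the accession
    (``GRMZM2G387528_T02`` is transcript 2 of locus GRMZM2G387528).
    """
    return re.sub(r"_T\d+$", "", record_id)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with locus and isoform identity."""

    id: str
    residues: str
    description: str = ""
    locus_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in VALID_RESIDUES:
                raise FormatError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        if not self.locus_id:
            object.__setattr__(self, "locus_id", default_locus_rule(self.id))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainInterval:
    """A named domain occupying residues ``start..end`` (1-based inclusive)."""

    protein_id: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.label}: start={self.start} end={self.end}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class MultipleAlignment:
    """An ordered list of (id, gapped sequence) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(widths)}")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate row ids: {dup}")
        # '.' gaps (Stockholm convention) normalised to '-'
        self.rows = [(rid, seq.replace(".", GAP).upper()) for rid, seq in self.rows]
        for rid, seq in self.rows:
            bad = set(seq) - VALID_RESIDUES - {GAP}
            if bad:
                raise FormatError(f"row {rid!r}: illegal characters {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(row_id)

    def column(self, col: int) -> list[str]:
        """Residues of 1-based column ``col`` in row order."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return [seq[col - 1] for _, seq in self.rows]

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"rows absent from alignment: {sorted(missing)}")
        return MultipleAlignment([(r, s) for r, s in self.rows if r in wanted])

    def to_records(self) -> list[ProteinRecord]:
        return [ProteinRecord(id=rid, residues=seq.replace(GAP, "")) for rid, seq in self.rows]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path,
    locus_rule: Callable[[str], str] = default_locus_rule,
) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Fails loudly: empty files, duplicate ids and non-amino-acid characters
    all raise :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            ProteinRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=desc,
                locus_id=locus_rule(rec.id),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(path: str | Path, dialect: str = "fasta") -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm file.

    ``dialect`` is ``"fasta"`` (aligned FASTA) or ``"stockholm"``; Stockholm
    annotation lines (``#=GC`` etc.) are tolerated and ignored.
    """
    if dialect not in ("fasta", "stockholm"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), dialect)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return MultipleAlignment([(rec.id, str(rec.seq)) for rec in aln])


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Newick (delegates to the tree module's serialiser)


def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`famdiv.tree.PhyloTree` as Newick with support labels."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path):
    from .tree import PhyloTree

    return PhyloTree.from_newick(Path(path).read_text().strip())


# ---------------------------------------------------------------------------
# Domain interval tables


def read_domain_intervals(path: str | Path, protein_id: str = "") -> list[DomainInterval]:
    """Read a TSV of (label, start, end) rows; '#' lines are comments."""
    out: list[DomainInterval] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"domain table line needs label/start/end: {line!r}")
        out.append(
            DomainInterval(
                protein_id=protein_id,
                label=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
            )
        )
    return out
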