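"""Secondary-motif screening and DNA-binding classification.

Plant bHLH subfamilies share short conserved motifs outside the bHLH
domain (the APB motif — "motif 14" of the standard plant catalog — marks
the PIF subfamily VIIa/b). Each catalog entry is a calibrated profile
model screened across full-length proteins; a motif is called present
when its best E-value meets the cutoff (the literature convention is a
permissive cutoff of 1 for these short models). The catalog is
data-driven: whatever seed alignments are supplied define the motif ids.

DNA-binding class uses the standard plant-bHLH basic-region diagnostic:
His at basic-region position 5 together with Glu-9 and Arg-13 predicts
G-box binding; Glu-9/Arg-13 without His-5 predicts E-box binding; fewer
than five basic residues in the region predicts no DNA binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    DomainHit,
    ProfileModel,
    build_profile,
    calibrate_evalue,
    scan_protein,
)
from .seqio import MultipleAlignment, ProteinRecord, read_alignment

BASIC_RESIDUES = set("KRH")
BASIC_REGION_COLUMNS = 13
#: (basic-region model column, required residue): His-5, Glu-9, Arg-13
GBOX_RULE = ((5, "H"), (9, "E"), (13, "R"))


@dataclass
class MotifCatalog:
    """Ordered collection of calibrated motif profiles keyed by motif id."""

    motifs: dict[str, ProfileModel]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif catalog is empty")
        for mid, model in self.motifs.items():
            if model.calibration is None:
                raise ValueError(f"motif {mid!r} is not calibrated")

    @property
    def ids(self) -> list[str]:
        return list(self.motifs)


def build_catalog(
    seed_alignments: dict[str, MultipleAlignment],
    pseudocount_weight: float = 1.0,
    n_shuffled: int = 200,
    target_length: int = 300,
    seed: int = 0,
) -> MotifCatalog:
    """Build and calibrate one profile per seed alignment.

    Calibration seeds derive deterministically from the catalog seed and
    the motif's position so the catalog is reproducible as a whole.
    """
    if not seed_alignments:
        raise ValueError("no seed alignments supplied")
    motifs = {}
    for k, (motif_id, aln) in enumerate(sorted(seed_alignments.items())):
        model = build_profile(aln, pseudocount_weight=pseudocount_weight, model_id=motif_id)
        motifs[motif_id] = calibrate_evalue(
            model, n_shuffled=n_shuffled, target_length=target_length,
            seed=(seed * 1009 + k) % (2**31),
        )
    return MotifCatalog(motifs)


def load_catalog_dir(
    directory: str | Path,
    n_shuffled: int = 200,
    target_length: int = 300,
    seed: int = 0,
) -> MotifCatalog:
    """Read a directory of motifNN.{fasta,afa,sto} seed alignments."""
    directory = Path(directory)
    alignments: dict[str, MultipleAlignment] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix in (".fasta", ".afa", ".fa"):
            alignments[path.stem] = read_alignment(path, "fasta")
        elif path.suffix in (".sto", ".stockholm"):
            alignments[path.stem] = read_alignment(path, "stockholm")
    return build_catalog(alignments, n_shuffled=n_shuffled, target_length=target_length, seed=seed)


@dataclass
class MotifPresenceMatrix:
    """Best E-value per (protein, motif); presence = E <= cutoff."""

    evalues: pd.DataFrame  # rows: protein ids, cols: motif ids, NaN = no hit
    cutoff: float

    def presence(self) -> pd.DataFrame:
        return self.evalues.le(self.cutoff) & self.evalues.notna()

    def to_tsv(self, path) -> None:
        out = self.evalues.where(self.evalues.le(self.cutoff))
        out = out.map(lambda v: "." if pd.isna(v) else f"{v:.3g}")
        out.to_csv(path, sep="\t", index_label="protein_id")


def screen_motifs(
    proteins: Sequence[ProteinRecord],
    catalog: MotifCatalog,
    evalue_cutoff: float = 1.0,
) -> MotifPresenceMatrix:
    """Scan every protein with every motif model.

    E-values are per search: one search = one motif screened across the
    whole protein set, so the search space is the summed protein length.
    Output is invariant to protein input order (rows sorted by id).
    """
    ids = sorted(p.id for p in proteins)
    total = sum(len(p.residues) for p in proteins)
    table = pd.DataFrame(np.nan, index=ids, columns=catalog.ids)
    for protein in proteins:
        for motif_id, model in catalog.motifs.items():
            hits = scan_protein(
                model, protein, max_evalue=max(10.0, evalue_cutoff), search_length=total
            )
            if hits:
                table.loc[protein.id, motif_id] = hits[0].evalue
    return MotifPresenceMatrix(evalues=table, cutoff=evalue_cutoff)


def summarize_by_group(
    matrix: MotifPresenceMatrix, group_assignments: dict[str, str]
) -> pd.DataFrame:
    """Fraction of each subfamily's members carrying each motif, plus a
    'total' row over all classified proteins."""
    presence = matrix.presence()
    groups = pd.Series(
        {pid: group_assignments.get(pid, "") for pid in presence.index}
    )
    classified = presence[groups != ""]
    by_group = classified.groupby(groups[groups != ""]).mean()
    by_group.loc["total"] = classified.mean()
    return by_group


# ---------------------------------------------------------------------------
# DNA-binding class


def classify_binding_class(
    protein: ProteinRecord,
    bhlh_hit: DomainHit,
    basic_region_columns: int = BASIC_REGION_COLUMNS,
    gbox_rule: tuple = GBOX_RULE,
    min_basic: int = 5,
) -> str:
    """Predict DNA-binding class from basic-region residues of a bHLH hit.

    The basic region is the first ``basic_region_columns`` model columns.
    Returns "G-box binder", "E-box binder", "non-binder" or
    "undetermined" (diagnostic columns not covered by the hit).
    """
    col_to_pos = {mc: sp for mc, sp in bhlh_hit.alignment}
    diag_cols = [c for c, _ in gbox_rule]
    if any(c not in col_to_pos for c in diag_cols):
        return "undetermined"

    region_residues = [
        protein.residues[col_to_pos[c] - 1]
        for c in range(1, basic_region_columns + 1)
        if c in col_to_pos
    ]
    n_basic = sum(1 for ch in region_residues if ch in BASIC_RESIDUES)
    if n_basic < min_basic:
        return "non-binder"

    def residue_at(model_col: int) -> str:
        return protein.residues[col_to_pos[model_col] - 1]

    checks = {c: residue_at(c) == aa for c, aa in gbox_rule}
    if all(checks.values()):
        return "G-box binder"
    ebox_cols = [(c, aa) for c, aa in gbox_rule if c != diag_cols[0]]
    if all(residue_at(c) == aa for c, aa in ebox_cols):
        return "E-box binder"
    return "non-binder"
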