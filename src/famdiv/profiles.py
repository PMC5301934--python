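"""Position-specific scoring models: construction, E-value calibration,
proteome scanning, completeness classification and per-locus dedup.

The model is a per-column log-odds table in bits with affine gap
penalties, scanned by local dynamic programming. Statistical significance
comes from an explicit null: maximal local scores over shuffled background
sequences follow an extreme-value (Gumbel) law, and the fitted location
and scale convert a bit score into the expected number of equal-or-better
hits per search (the E-value), scaled linearly with searched residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from . import _dp
from .seqio import AMINO_ACIDS, GAP, MultipleAlignment, ProteinRecord

N_AA = 20
CODE_X = 20  # unknown residue: scores 0 everywhere
CODE_MASK = 21  # masked positions: hugely negative

#: Robinson & Robinson amino-acid background frequencies, order ACDEFGHIKLMNPQRSTVWY
DEFAULT_BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
DEFAULT_BACKGROUND /= DEFAULT_BACKGROUND.sum()

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class CalibrationError(RuntimeError):
    """Raised when the null score distribution cannot support a Gumbel fit."""


def encode(seq: str) -> np.ndarray:
    """Residue string -> integer codes (X and unknowns -> neutral code)."""
    return np.array([_AA_INDEX.get(ch, CODE_X) for ch in seq], dtype=np.int64)


@dataclass(frozen=True)
class Calibration:
    mu: float  # Gumbel location of per-sequence maximal scores (bits)
    beta: float  # Gumbel scale (bits); lambda = 1/beta
    length: int  # length of the null sequences used

    @property
    def lam(self) -> float:
        return 1.0 / self.beta


@dataclass(frozen=True)
class ProfileModel:
    """Per-column log-odds model over the 20 canonical residues."""

    model_id: str
    match_scores: np.ndarray  # (n_columns, 22) bits; cols 20=X, 21=mask
    background: np.ndarray  # (20,)
    gap_open: float = 4.0
    gap_extend: float = 1.0
    calibration: Optional[Calibration] = None

    @property
    def n_columns(self) -> int:
        return self.match_scores.shape[0]

    def evalue(self, score: float, search_length: int) -> float:
        """Expected hits scoring >= score in a search over search_length residues."""
        if self.calibration is None:
            raise CalibrationError(
                f"model {self.model_id!r} is not calibrated; run calibrate_evalue first"
            )
        c = self.calibration
        return (search_length / c.length) * math.exp(-(score - c.mu) / c.beta)

    def score_threshold(self, evalue: float, search_length: int) -> float:
        """Inverse of :meth:`evalue`: minimal score with E <= evalue."""
        c = self.calibration
        if c is None:
            raise CalibrationError(f"model {self.model_id!r} is not calibrated")
        return c.mu - c.beta * math.log(evalue * c.length / search_length)


@dataclass
class DomainHit:
    """A located model occurrence on one protein."""

    protein_id: str
    locus_id: str
    start: int  # 1-based inclusive residue positions
    end: int
    score: float  # bits
    model_coverage: float  # fraction of model columns in match states
    evalue: Optional[float] = None
    complete: Optional[bool] = None
    model_id: str = ""
    #: (model_column, residue_position) match states, both 1-based
    alignment: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# model construction


def build_profile(
    seed: MultipleAlignment,
    pseudocount_weight: float = 1.0,
    background: Optional[np.ndarray] = None,
    model_id: str = "model",
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from a seed alignment.

    Columns whose gap fraction exceeds ``max_gap_fraction`` (default 0.5)
    are dropped from the model. Per retained column c and residue a:

        score(c, a) = log2( (count_ca + w * bg_a) / (n_c + w) / bg_a )

    where n_c counts non-gap residues in the column and w is the
    pseudocount weight. X scores 0 (background-neutral) in every column.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (N_AA,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 20 frequencies summing to 1")

    n_rows = seed.n_rows
    columns = []
    for col in range(1, seed.n_columns + 1):
        residues = seed.column(col)
        gap_frac = residues.count(GAP) / n_rows
        if gap_frac > max_gap_fraction:
            continue
        counts = np.zeros(N_AA)
        for ch in residues:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        n_c = counts.sum()
        probs = (counts + pseudocount_weight * bg) / (n_c + pseudocount_weight)
        columns.append(np.log2(probs / bg))
    if not columns:
        raise ValueError("no alignment columns survive the gap-fraction filter")

    scores = np.zeros((len(columns), 22))
    scores[:, :N_AA] = np.vstack(columns)
    scores[:, CODE_X] = 0.0
    scores[:, CODE_MASK] = _dp.NEG / 1e6  # very negative but add-safe
    return ProfileModel(
        model_id=model_id,
        match_scores=scores,
        background=bg,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# calibration


def sample_background_sequence(rng: np.random.Generator, length: int, bg: np.ndarray) -> np.ndarray:
    return rng.choice(N_AA, size=length, p=bg)


def calibrate_evalue(
    model: ProfileModel,
    n_shuffled: int = 200,
    target_length: int = 300,
    seed: int = 0,
) -> ProfileModel:
    """Fit a Gumbel law to maximal local scores on background sequences.

    Returns a copy of the model carrying the calibration; E-values then
    scale as (searched residues / target_length) * exp(-(S - mu)/beta).
    """
    if n_shuffled < 100:
        raise ValueError("n_shuffled must be >= 100 for a stable Gumbel fit")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_shuffled)
    for k in range(n_shuffled):
        codes = sample_background_sequence(rng, target_length, model.background)
        maxima[k] = _dp.best_local_score(
            model.match_scores, codes, model.gap_open, model.gap_extend
        )
    if np.std(maxima) < 1e-9:
        raise CalibrationError(
            f"model {model.model_id!r}: degenerate null score distribution"
        )
    mu, beta = stats.gumbel_r.fit(maxima)
    return replace(
        model, calibration=Calibration(mu=float(mu), beta=float(beta), length=target_length)
    )


# ---------------------------------------------------------------------------
# scanning


MIN_PROTEIN_LENGTH = 5


def scan_protein(
    model: ProfileModel,
    protein: ProteinRecord,
    max_evalue: float = 10.0,
    search_length: Optional[int] = None,
    max_hits: int = 10,
) -> list[DomainHit]:
    """Best non-overlapping local alignments of the model to one protein.

    Hits are found greedily: the optimal local alignment is reported, its
    residue span masked, and the scan repeated while the score still meets
    ``max_evalue`` (interpreted over ``search_length`` residues, default
    the protein's own length). Hits come back in descending score order.
    """
    if model.calibration is None:
        raise CalibrationError(f"model {model.model_id!r} must be calibrated before scanning")
    n = len(protein.residues)
    if n < MIN_PROTEIN_LENGTH:
        return []
    space = n if search_length is None else search_length
    min_score = model.score_threshold(max_evalue, space)

    codes = encode(protein.residues)
    hits: list[DomainHit] = []
    for _ in range(max_hits):
        M, D, I, ptrM, ptrD, ptrI = _dp.fill_local(
            model.match_scores, codes, model.gap_open, model.gap_extend
        )
        flat = int(np.argmax(M))
        i, j = divmod(flat, M.shape[1])
        score = float(M[i, j])
        if score < min_score or score <= 0:
            break
        _, _, pairs = _dp.traceback_local(M, ptrM, ptrD, ptrI, i, j)
        seq_start, seq_end = pairs[0][1], pairs[-1][1]
        hits.append(
            DomainHit(
                protein_id=protein.id,
                locus_id=protein.locus_id,
                start=seq_start,
                end=seq_end,
                score=score,
                model_coverage=len(pairs) / model.n_columns,
                evalue=model.evalue(score, space),
                model_id=model.model_id,
                alignment=pairs,
            )
        )
        codes = codes.copy()
        codes[seq_start - 1 : seq_end] = CODE_MASK
    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


def survey_proteome(
    model: ProfileModel,
    proteome: Sequence[ProteinRecord],
    evalue_cutoff: float = 0.01,
    min_coverage: float = 0.8,
) -> list[DomainHit]:
    """Scan every protein, score E-values over the whole-proteome search
    space, filter at the cutoff and flag completeness.

    Deterministic order: by locus id, then descending score, then protein id.
    """
    total = sum(len(p.residues) for p in proteome)
    hits: list[DomainHit] = []
    for protein in proteome:
        for hit in scan_protein(model, protein, max_evalue=evalue_cutoff, search_length=total):
            hit.complete = classify_completeness(hit, min_coverage)
            hits.append(hit)
    hits.sort(key=lambda h: (h.locus_id, -h.score, h.protein_id))
    return hits


def classify_completeness(hit: DomainHit, min_coverage: float = 0.8) -> bool:
    """A hit is a complete domain iff it covers >= min_coverage of model columns."""
    return hit.model_coverage >= min_coverage


def dedupe_loci(
    hits: Sequence[DomainHit], proteome: Sequence[ProteinRecord]
) -> list[DomainHit]:
    """Keep one representative hit per locus.

    Preference: complete domain over partial, then longer protein, then
    lexicographically smaller protein id. Idempotent; output sorted by
    locus id.
    """
    lengths = {p.id: len(p.residues) for p in proteome}
    best_per_protein: dict[str, DomainHit] = {}
    for h in hits:
        cur = best_per_protein.get(h.protein_id)
        if cur is None or h.score > cur.score:
            best_per_protein[h.protein_id] = h

    by_locus: dict[str, list[DomainHit]] = {}
    for h in best_per_protein.values():
        by_locus.setdefault(h.locus_id, []).append(h)

    kept = []
    for locus in sorted(by_locus):
        candidates = by_locus[locus]
        candidates.sort(
            key=lambda h: (
                0 if h.complete else 1,
                -lengths.get(h.protein_id, 0),
                h.protein_id,
            )
        )
        kept.append(candidates[0])
    return kept


def apply_curation(
    hits: Sequence[DomainHit],
    allow: Optional[set[str]] = None,
    deny: Optional[set[str]] = None,
) -> list[DomainHit]:
    """Inject manual accept/reject judgments by locus id.

    ``deny`` drops loci (e.g. hand-curated gene-model mispredictions);
    ``allow``, when given, restricts output to those loci.
    """
    out = []
    for h in hits:
        if deny and h.locus_id in deny:
            continue
        if allow is not None and h.locus_id not in allow:
            continue
        out.append(h)
    return out


def hits_to_tsv(hits: Iterable[DomainHit], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("protein_id\tlocus_id\tstart\tend\tscore_bits\tevalue\tcoverage\tcomplete\n")
        for h in hits:
            ev = "NA" if h.evalue is None else f"{h.evalue:.3g}"
            comp = "NA" if h.complete is None else str(h.complete).lower()
            fh.write(
                f"{h.protein_id}\t{h.locus_id}\t{h.start}\t{h.end}\t"
                f"{h.score:.3f}\t{ev}\t{h.model_coverage:.3f}\t{comp}\n"
            )
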