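# Methods

famdiv re-creates, at desk scale, the computational arc of a
duplicated-genome transcription-factor study: find every protein carrying
a target domain, filter to one gene model per locus, screen for
subfamily-diagnostic secondary motifs, place the family on a
bootstrap-supported tree anchored by labeled representatives, and — the
core analysis — scan a recently duplicated paralog pair for residues
where one copy departs from a position that is deeply conserved across
the wider ortholog family. This note records the models, defaults and
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Profile models and E-values

Domain and motif searches use per-column log-odds profiles rather than a
full profile HMM. For seed alignment column *c* and residue *a*,

    score(c, a) = log2( (n_ca + w·b_a) / (n_c + w) / b_a )   [bits]

with `n_ca` the residue count, `n_c` the non-gap count, `b` the
background distribution (Robinson–Robinson frequencies) and `w` the
pseudocount weight (default 1). Columns with more than 50% gaps are
dropped from the model. By Gibbs' inequality the expected per-column
score under the background is ≤ 0, which the test suite asserts.

Scanning is local dynamic programming with affine gaps (defaults: 4 bits
open, 1 bit extend — the standard order of magnitude for profile local
alignment) over three states (match / model-column deletion / sequence
insertion); gap-to-gap transitions are allowed at gap-open cost, and the
kernel is verified against an exhaustive enumeration of monotone
match-pair sequences on small instances. Multiple hits per protein are
taken greedily with masking of previously claimed spans. This is
deliberately *not* a HMMER re-implementation (no Plan7 states,
forward/backward or composition filters), and its bit scores are not
comparable to HMMER's.

Significance comes from an explicit null: maximal local scores over
`n_shuffled` (default 200) i.i.d. background sequences of a fixed length
(default 300) follow an extreme-value law; a Gumbel fit gives location
and scale, and

    E(S) = (searched residues / calibration length) · exp(−(S − μ)/β)

is the expected number of equal-or-better hits per search. "Per search"
means the whole scan (a proteome, or one motif across a protein set),
matching how a cutoff of E ≤ 1 is conventionally read. Self-consistency
is tested: scans of fresh shuffled sequences yield on the order of one
hit with E ≤ 1 per search (the acceptance band is 0.5–2.0, reflecting
Gumbel-fit error at n = 200).

A degenerate null (zero score variance) raises a calibration error
rather than producing meaningless E-values.

## Survey filtering

A hit is *complete* when it covers ≥ 80% of model columns (the
literature reports only complete/incomplete; 0.8 is our explicit,
configurable operationalisation). Locus dedup keeps one protein per
locus, preferring a complete domain over a partial one, then the longer
protein, then the lexicographically smaller id. Loci are parsed from
accessions by a configurable rule (default: strip a trailing `_Txx`
isoform suffix, the maize filtered-gene-set convention). Manual
curation of mispredicted gene models is out of automated scope and is
represented by allow/deny lists of locus ids.

## Motif catalog and binding classes

The catalog is data-driven: every supplied seed alignment becomes one
calibrated profile, so the id set is whatever the user provides (the
plant bHLH motif literature variously counts 26–28 motifs; we hard-code
none of them). Presence = best per-search E ≤ cutoff (default 1).
Lowering the cutoff can only remove presences (anti-monotone), and at
cutoff 1 roughly one background false call per motif per search is
expected — that is the price of the permissive threshold, not a defect.

DNA-binding class uses the standard plant-bHLH basic-region diagnostic,
which the source literature names but does not spell out, so it is
explicit and configurable here: over the first 13 model columns of the
bHLH hit, His-5 + Glu-9 + Arg-13 ⇒ G-box binder; Glu-9 + Arg-13 without
His-5 ⇒ E-box binder; fewer than 5 basic residues (K/R/H) ⇒ non-binder;
diagnostic columns not covered by the hit ⇒ undetermined.

## Phylogeny and subfamily assignment

Trees are distance/NJ-based by design, replacing the ML (JTT+Γ)
inference a full-scale study would run: neighbor joining on
Kimura-corrected distances, d = −ln(1 − p − 0.2p²), where p is the
mismatch fraction over pairwise-complete columns, capped at 0.85 and
flagged saturated. This is self-contained, fast, consistent on additive
matrices (tested: 100% topology recovery on random 8-taxon additive
matrices, equality with exhaustive minimum-evolution search on 6 taxa)
and adequate for subfamily-level grouping; every report labels its trees
"NJ-distance", never ML. Negative NJ branch estimates are clamped to
zero with the deficit moved to the sibling edge. Zero-distance taxa are
joined first (identical sequences always form a cherry), which makes
tie-handling deterministic and bootstrap supports stable; all other ties
resolve by matrix index after canonical (lexicographic) row ordering.

Progressive alignment uses a 3-mer-distance NJ guide tree and
profile–profile merging with BLOSUM62 expected scores and affine gaps
(11 open / 1 extend). Gap-column stripping defaults to removing any
column containing a gap (max_gap_fraction = 0, configurable), the
strictest reading of "regions with gaps were removed"; the old→new
column map is returned so results can be reported in either coordinate
system.

Bootstrap supports (default 100 replicates, configurable to 1000)
resample columns with replacement and count bipartitions. Subfamily
assignment reads clades off the *unrooted* tree — for each edge, the
split side holding the query is a candidate — because NJ root placement
is arbitrary and can sit inside a subfamily. The smallest candidate with
support ≥ 50 containing at least one anchor decides; mixed anchor labels
leave the query unclassified. Edges without a support value (no
bootstrap run, or trivial splits) count as fully supported.

## The divergence scan

Given reference rows R, a partner paralog and a query paralog, a column
is reported when:

1. conservation: the modal residue among non-gap references has
   frequency ≥ `min_conservation` (default 0.9);
2. gaps: reference gap fraction ≤ `max_gap_fraction` (default 0.2);
3. partner: the partner carries the consensus residue (default on —
   the contrast of interest is "query departs from what the partner and
   everyone else kept");
4. query: the query residue differs from the consensus and is not a gap.

`min_conservation` is the single most result-sensitive knob. 0.9 over a
few dozen references tolerates columns where a minority residue occurs
occasionally while still reading as "highly conserved"; it is surfaced
prominently in the CLI. An alternative `unseen-residue` mode replaces
condition 1 with "the query residue was never observed among the
references", the strictest presence-based reading; it catches divergence
at columns whose consensus frequency sits below the floor. Modal ties
break alphabetically and are flagged. At least `min_refs` (default 10)
references are required.

Each site maps back to per-sequence numbering (position = non-gap count
up to the column), which is why the same substitution can be, say,
position 111 in one paralog and 113 in the other when an upstream indel
separates them — the scan reports both coordinates. Notation is
consensus residue + query position + query residue (e.g. F113L). Domain
context comes from a user-supplied interval table (1-based inclusive;
overlap rejected); predicting domain boundaries is out of scope. The
pairwise paralog report (BLOSUM62 global alignment, 11/1 gaps) returns
identity, substitution columns and gap columns separately, so a combined
"difference" count is recoverable under either convention of counting
indels.

## Synthetic data: what it emulates, what it does not

The generator supplies every input the pipeline needs, with planted
ground truth, reproducible bit-for-bit from one seed:

* **Proteome** — i.i.d. background proteins (lengths 120–400) of which a
  chosen number carry a noisy domain copy (5% per-site substitutions by
  default; planted substitutions are always drawn excluding the current
  residue, so they are real changes); a chosen fraction is truncated to
  under half the model length, emulating incomplete gene models.
* **Ortholog family** — sequences evolved down a random tree
  (exponential branch lengths scaled so root-to-tip depth ≈ 1
  substitution/site). Each column draws a substitution tolerance from a
  mixture — 70% near-invariant (tolerance 0.02), 30% variable (0.5) —
  so a 0.9 conservation floor separates two real column classes. Indels
  (1% events/site, geometric length with mean 2 — the shortest model
  that produces numbering offsets between rows) make per-sequence
  numbering differ.
* **Paralog pair** — a partner that equals the column consensus and a
  query that differs at exactly *k* sampled gapless columns of
  conservation ≥ 0.9.

These defaults are the study conditions under which the acceptance
properties are evaluated (20 references × 300 columns × 4 sites for the
scan; 20 planted + 30 background proteins for the survey; a 36-reference
+ pair, 500-column family for the full-family analysis). Problem sizes
were chosen as the smallest at which the statistical properties of
interest are stable.

What passing these tests does **not** show: real proteomes have biased
composition, repeats and homologous non-target domains (our background
is i.i.d.); real ortholog alignments have site-rate autocorrelation,
alignment error and saturated deep branches; real gene-model errors are
richer than truncation. The synthetic results demonstrate correctness of
the machinery and its statistical calibration, not field performance on
maize-scale data — reproducing the published full-scale counts requires
the external proteome and curated alignments, which the CLI accepts as
ordinary inputs.

## Known limitations

* Profile scores are not HMMER-comparable; full-scale hit counts should
  be treated as approximate anchors.
* NJ subfamily assignment can differ from ML near short internal edges;
  assignments carry their bootstrap support so low-confidence calls are
  visible.
* The divergence scan is descriptive: it flags candidate sites; it is
  not a dN/dS or positive-selection test, and it does not interpret
  structure.
* No nucleotide/codon-level simulation; no splice-site modelling beyond
  truncation.
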