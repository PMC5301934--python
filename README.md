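# famdiv

Transcription-factor family surveying and paralog-divergence scanning
for duplicated plant genomes.

## The problem

After a whole-genome duplication, paralog pairs (homeologs) can
subfunctionalize: one copy keeps an ancestral protein–protein
interaction, the other loses it. The maize phytochrome B pair is the
canonical case — phyB1 binds PIF3-class bHLH transcription factors in
its active (Pfr) form while its close homeolog phyB2 does not — and the
computational route to candidate residues behind such a loss is: compare
the two paralogs against a deep ortholog alignment and flag positions
where one copy departs from a residue conserved across the whole family.

famdiv implements that analysis and the family survey around it, for
anyone studying domain families and post-duplication divergence:

* **profiles** — position-specific log-odds models (bits) built from
  seed alignments, Gumbel-calibrated E-values, local affine-gap
  scanning, completeness classification and one-protein-per-locus dedup;
* **motifs** — presence/absence screening of a secondary-motif catalog
  (e.g. the plant bHLH motif set whose motif 14 is the active
  phyB-binding APB motif) and basic-region DNA-binding classification
  (G-box / E-box / non-binder);
* **phylo** — progressive alignment, gap-column stripping,
  neighbor-joining trees on Kimura-corrected distances with bootstrap
  supports, and subfamily assignment via labeled anchor sequences;
* **divergence** — the conservation scan: per-column consensus over
  references, divergent-site detection with partner/query contrast,
  alignment-column ↔ residue-number mapping, domain annotation, and a
  pairwise paralog report (identity / substitutions / indels);
* **synthio** — synthetic proteomes, motif carriers and ortholog
  families with planted, seeded ground truth, so the whole pipeline is
  testable without downloads.

The core statistic: a column is a divergent site when the modal residue
among non-gap references reaches frequency ≥ *c* (default 0.9), the
reference gap fraction is ≤ 0.2, the partner paralog carries that
consensus residue, and the query paralog carries something else. Sites
are reported as consensus-residue + query-position + query-residue
(e.g. `F113L`), with both paralogs' residue numbering — which differ
when indels separate them.

## Worked example

```
$ python analysis/01_simulate.py
$ python analysis/05_scan_divergence.py
4 divergent sites (matches planted truth):
  C39I     column   39  partner pos 39  conservation 1.00  PAS1
  F220V    column  220  partner pos 220  conservation 1.00  GAF
  K300I    column  300  partner pos 300  conservation 0.90  PAS2
  G337K    column  337  partner pos 337  conservation 1.00  inter-domain
paralog pair: 98.83% identity, 4 substitutions, 0 indel columns
```

The family here is 20 synthetic reference orthologs (300 columns) plus a
planted duplicated pair; `C39I` means the references are conserved for
cysteine at alignment column 39 (conservation 1.00), the partner paralog
kept it, and the query paralog carries isoleucine at its residue 39,
inside the toy PAS1 interval. The pairwise report shows the pair is
98.8% identical and differs by exactly the four planted substitutions.

The same operations are available as subcommands for real data:

```
famdiv survey   --proteome proteins.fasta --seed-alignment hlh_seed.afa \
                --evalue-cutoff 1e-2 --out hits.tsv
famdiv motifs   --proteins family.fasta --catalog-dir motifs/ --out matrix.tsv
famdiv classify --domains domains.fasta --anchor-labels anchors.tsv \
                --out-tree tree.nwk --out-assignments subfamilies.tsv
famdiv diverge  --alignment phyb_family.afa --references refs.txt \
                --partner ZmPHYB1 --query ZmPHYB2 --domain-map domains.tsv \
                --out sites.tsv
famdiv run      --config pipeline.cfg
```

`analysis/` contains the numbered study scripts (simulate → survey →
motifs → classify → diverge), each writing its tables under `results/`.
Three small pre-generated fixture bundles live in `examples/fixtures/`.

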