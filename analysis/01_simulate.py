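#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, under results/data/: a 50-protein proteome with 20 planted domain
copies (2 truncated), the same proteins with a secondary motif planted in
six of them, a 20-reference ortholog family with a duplicated pair
carrying 4 divergent sites, and the truth tables for all of it.
"""

from pathlib import Path

from famdiv import seqio, synthio

SEED = 20160604  # study seed; all downstream scripts reuse it
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
APB_LIKE = "NPLHELLDESWPPQ"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    proteome, dom_truth = synthio.generate_proteome(
        n_proteins=50, n_with_domain=20, truncation_fraction=0.1, seed=SEED
    )
    carriers = [p.id for p in proteome[:6]]
    proteome, motif_truth = synthio.plant_motifs(
        proteome, APB_LIKE, "motif14", carriers, seed=SEED + 1
    )
    seqio.write_fasta(proteome, OUT / "proteome.fasta")
    synthio.write_truth_tsv(dom_truth, OUT / "domain_truth.tsv")
    synthio.write_truth_tsv(motif_truth, OUT / "motif_truth.tsv")

    family, _ = synthio.generate_ortholog_family(n_refs=20, length=300, seed=SEED + 2)
    planted, div_truth = synthio.plant_paralog_divergence(
        family, n_sites=4, min_conservation=0.9, seed=SEED + 3
    )
    seqio.write_alignment(planted, OUT / "family.afa")
    synthio.write_truth_tsv(div_truth, OUT / "family_truth.tsv")
    (OUT / "family_refs.txt").write_text("\n".join(family.ids) + "\n")

    print(f"proteome: {len(proteome)} proteins, 20 planted domains (2 truncated), "
          f"motif14 planted in {len(carriers)}")
    print(f"family: {planted.n_rows} rows x {planted.n_columns} columns, "
          f"divergent columns {div_truth.planted_divergent_columns}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
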