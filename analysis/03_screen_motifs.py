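#!/usr/bin/env python
"""Screen the proteome against a two-motif catalog at the permissive
E <= 1 cutoff and summarise presence by group.

motif14 (the APB-like motif) was planted into six proteins; motif15 was
planted nowhere and should come back (near-)absent — the presence/absence
asymmetry that marks a subfamily-specific motif. Writes
results/motif_matrix.tsv and results/motif_by_group.tsv.
"""

import csv
from pathlib import Path

from famdiv import motifs, seqio
from famdiv.seqio import MultipleAlignment

SEED = 20160604
ROOT = Path(__file__).resolve().parent.parent / "results"
APB_LIKE = "NPLHELLDESWPPQ"
UNPLANTED = "WWCCHHKKYYPPAG"


def main() -> None:
    proteome = seqio.read_fasta(ROOT / "data" / "proteome.fasta")
    carriers = set()
    with open(ROOT / "data" / "motif_truth.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["kind"] == "motif":
                carriers.add(row["id"])

    catalog = motifs.build_catalog(
        {
            "motif14": MultipleAlignment([(f"a{i}", APB_LIKE) for i in range(3)]),
            "motif15": MultipleAlignment([(f"b{i}", UNPLANTED) for i in range(3)]),
        },
        seed=SEED,
    )
    matrix = motifs.screen_motifs(proteome, catalog, evalue_cutoff=1.0)
    matrix.to_tsv(ROOT / "motif_matrix.tsv")

    groups = {p.id: ("carrier" if p.id in carriers else "other") for p in proteome}
    summary = motifs.summarize_by_group(matrix, groups)
    summary.to_csv(ROOT / "motif_by_group.tsv", sep="\t")

    presence = matrix.presence()
    hit_carriers = int(presence.loc[sorted(carriers), "motif14"].sum())
    print(f"motif14 found in {hit_carriers}/{len(carriers)} planted carriers")
    print(f"motif14 calls outside carriers: "
          f"{int(presence['motif14'].sum()) - hit_carriers} "
          f"(~1 false call per search is expected at E<=1)")
    print(f"motif15 (planted nowhere) calls: {int(presence['motif15'].sum())}")
    print(f"matrix -> {ROOT / 'motif_matrix.tsv'}")


if __name__ == "__main__":
    main()
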