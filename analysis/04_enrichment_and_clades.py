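#!/usr/bin/env python
"""Interpret the enrichment matrix and the clade-specific motif report.

Reads the score matrix and clade report from 02 and summarizes them: how
many classes reach each score band per organism, which classes are
universally enriched, and which classes are confined to a single clade
(the planted exclusive hexanucleotides should be the only hits).

Run from the repository root after 02:  python analysis/04_enrichment_and_clades.py
"""

from pathlib import Path

import pandas as pd

PIPELINE = Path("results/analysis/pipeline")
RESULTS = Path("results/analysis")


def main() -> None:
    matrix = pd.read_csv(PIPELINE / "score_matrix.tsv", sep="\t", index_col=0)
    bands = pd.DataFrame(
        {score: (matrix == score).sum(axis=1) for score in (3, 2, 1, 0, -1, -2)}
    )
    bands.index.name = "organism_id"
    out = RESULTS / "score_bands.tsv"
    bands.to_csv(out, sep="\t")
    print("score-band occupancy per organism (columns are scores):")
    print(bands.to_string())

    top = matrix.columns[(matrix == 3).all(axis=0)].tolist()
    print(f"\nclasses scoring 3 in every organism: {top or 'none'}")

    clades = pd.read_csv(PIPELINE / "clade_specific.tsv", sep="\t")
    print(f"\nclade-specific classes ({len(clades)}):")
    if len(clades):
        print(clades.to_string(index=False))
    clades.to_csv(RESULTS / "clade_specific.tsv", sep="\t", index=False)
    print(f"\nband table -> {out}")


if __name__ == "__main__":
    main()
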