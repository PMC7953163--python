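#!/usr/bin/env python
"""Summarize the panel's repeat landscape: dominant categories, top motifs,
GC content and copy-number variability.

Reads the pipeline outputs of 02 and prints the comparative story: which
motif-length category dominates each clade, the top-5 canonical classes
per organism, per-category GC, and the CV of repeat copy numbers.

Run from the repository root after 02:  python analysis/03_landscape_statistics.py
"""

from pathlib import Path

import pandas as pd

from ssrscape import scan, stats

FIXTURES = Path("scratch/analysis/fixtures")
PIPELINE = Path("results/analysis/pipeline")
RESULTS = Path("results/analysis")


def main() -> None:
    meta = pd.read_csv(FIXTURES / "metadata.tsv", sep="\t")
    panel = pd.read_csv(PIPELINE / "panel.tsv", sep="\t")
    print("dominant motif-length category per organism:")
    for _, row in panel.iterrows():
        print(f"  {row['organism_id']:<12} ({row['clade']}): "
              f"unit length {int(row['dominant_unit'])}, "
              f"abundance {row['abundance_loci_per_mb']:.1f} loci/Mb, "
              f"density {row['density_bp_per_mb']:.1f} bp/Mb")

    rows = []
    for _, mrow in meta.iterrows():
        records = list(scan.read_fasta(FIXTURES / mrow["fasta"]))
        perfect, compounds, imperfect = scan.scan_all(records, scan.ScanParams())
        top, per_unit = stats.top_motifs(perfect, 5)
        gc = stats.gc_content(perfect)
        cv = stats.rcn_cv_by_group(perfect)
        rows.append(
            {
                "organism_id": mrow["organism_id"],
                "clade": mrow["clade"],
                "top5_classes": ",".join(top),
                "dominant_mono": per_unit.get(1, ""),
                "dominant_di": per_unit.get(2, ""),
                "gc_mono_pct": round(gc.get(1, float("nan")), 2),
                "gc_di_pct": round(gc.get(2, float("nan")), 2),
                "cv_mono_pct": round(
                    cv.set_index("unit_length")["cv_percent"].get(1, float("nan")), 2
                ),
            }
        )
    df = pd.DataFrame(rows)
    out = RESULTS / "landscape.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(f"\ntop motifs and GC/CV per organism -> {out}")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
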