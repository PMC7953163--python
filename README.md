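# ssrscape

Comparative microsatellite landscape analysis for multi-genome panels.

Microsatellites (simple sequence repeats, SSRs) are tandem repetitions of
short DNA motifs (1–6 bp). Comparative surveys characterize a set of
genomes by scanning for three locus categories — perfect arrays (P-SSRs),
compound arrays of neighbouring perfect loci (C-SSRs), and imperfect
arrays interrupted by substitutions or indels (I-SSRs) — then summarizing
how repeat content is distributed across motif classes, genic
compartments, and clades. `ssrscape` implements that workflow end to end
for anyone studying repeat landscapes across related genomes, together
with a synthetic-genome generator that plants ground-truth loci so every
stage can be validated exactly.

## The model in brief

* **Canonical motif classes.** A repeat unit is *primitive* when it is not
  an exact repetition of a shorter unit. Units related by circular
  rotation and/or reverse complementation describe the same locus, so the
  5356 primitive 1–6 bp units collapse into 501 canonical classes, each
  named by its lexicographically smallest member — (A)n, (AC)n, (AAT)n in
  the field's usual notation.
* **Detection.** P-SSRs are maximal complete-copy tandem runs meeting
  per-unit-length minimum copies (defaults 12/7/5/4/4/4 for mono→hexa);
  P-SSRs separated by ≤ d<sub>MAX</sub> bp (default 10) merge transitively
  into C-SSRs and leave the perfect tally; I-SSRs are found by seeding on
  short perfect runs and extending unit-wise under a +1 match / −1
  mismatch / −2 gap score, reported above a score and length floor with
  ≥ 1 edit. Ambiguous bases (N) are masked; densities use the non-N
  genome length.
* **Landscape statistics.** Abundance (loci/Mb), density (bp/Mb),
  motif-length category proportions and the dominant category, top
  motifs, GC content per category, the coefficient of variability
  CV = 100·SD/mean of repeat copy numbers, and Pearson correlations
  (two-sided t test, n−2 df) against genome size.
* **Enrichment scores.** Per organism, the 501 class densities are banded
  into integer scores: frequency < 10 ⇒ −2 (excluded from ranking); ranks
  1–5 / 6–20 / 21–35 by density ⇒ 3 / 2 / 1; the bottom 20 surviving
  ranks ⇒ −1; otherwise 0. Rows stack into an organisms × 501 score
  matrix. A class is *clade-specific* when it reaches the presence
  threshold in at least one species of exactly one clade.

## Worked example

```python
from ssrscape import ScanParams, SequenceRecord, find_perfect, find_imperfect

params = ScanParams()
rec = SequenceRecord("chr1", "G" + "A" * 12 + "G" + "AC" * 5 + "G" + "AC" * 5)
for p in find_perfect(rec, params):
    print(p.start, p.end, p.motif, p.canonical, p.repeats)
for i in find_imperfect(rec, params):
    print(i.start, i.end, i.motif, i.insertions, i.score)
```

prints

```
2 13 A A 12
15 35 AC 1 18.0
```

— a perfect (A)12 locus at 2–13, and an imperfect (AC)n locus spanning
15–35 whose single inserted `G` costs the −2 gap penalty (10 + 10 matches
− 2 = 18).

From the shell, the same pipeline runs over whole panels:

```
ssrscape simulate --seed 1 --outdir fixtures/          # synthetic panel
ssrscape run --config run.toml                         # scan→annotate→stats→enrich
ssrscape scan --fasta genome.fa.gz --out loci.tsv      # single stages
```

The `analysis/` directory holds the numbered study scripts
(01_simulate_panel.py … 05_genome_size_correlation.py); each writes its
tables under `results/analysis/` and prints what it found.

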