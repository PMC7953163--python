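"""Per-organism microsatellite landscape statistics.

Abundance is loci per megabase and density is repeat bp per megabase, both
over the effective (non-ambiguous) genome length.  Category proportions,
dominant motifs, GC content of perfect loci, and the coefficient of
variability (CV) of repeat copy numbers follow the conventions common in
comparative SSR surveys; Pearson correlations with two-sided t-based
significance connect landscape measures to genome size across organisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motifspace import class_order
from .scan import CompoundSSR, ImperfectSSR, PerfectSSR


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class GenomeSummary:
    """All per-organism tallies consumed by the cross-organism analyses."""

    organism_id: str
    clade: str
    effective_genome_bp: int
    category_counts: dict[str, int]          # {"P": ..., "C": ..., "I": ...}
    category_bp: dict[str, int]
    class_frequency: pd.Series               # P-SSR locus count per canonical class
    class_density: pd.Series                 # P-SSR bp per Mb per canonical class
    unit_counts: dict[int, int]              # P-SSR count per unit length
    unit_proportions: dict[int, float]
    unit_gc_percent: dict[int, float]        # missing lengths absent
    unit_rcns: dict[int, list[int]]          # repeat copy numbers per unit length
    dominant_unit: int | None = None
    dominant_unit_tied: bool = False

    @property
    def total_ssr_count(self) -> int:
        return sum(self.category_counts.values())

    @property
    def total_ssr_bp(self) -> int:
        return sum(self.category_bp.values())


def abundance_density(
    locus_count: int, total_bp: int, effective_genome_bp: int
) -> tuple[float, float]:
    """(loci/Mb, bp/Mb) over the effective genome length.

    >>> abundance_density(100, 3000, 2_000_000)
    (50.0, 1500.0)
    """
    if effective_genome_bp <= 0:
        raise ValueError("effective genome size must be positive")
    mb = effective_genome_bp / 1e6
    return locus_count / mb, total_bp / mb


def category_proportions(
    perfect: Sequence[PerfectSSR],
) -> tuple[dict[int, float], int | None, bool]:
    """Proportion of perfect loci per motif-length category (1-6).

    Each category's share is its locus count over the total number of
    perfect loci in the organism.  Returns (proportions, dominant category,
    tie flag); the dominant category is the argmax, ties broken toward the
    shorter unit.
    """
    if not perfect:
        return {}, None, False
    counts: dict[int, int] = {}
    for p in perfect:
        counts[p.unit_length] = counts.get(p.unit_length, 0) + 1
    total = len(perfect)
    props = {k: counts[k] / total for k in sorted(counts)}
    best = max(counts.values())
    winners = sorted(k for k, v in counts.items() if v == best)
    return props, winners[0], len(winners) > 1


def top_motifs(
    perfect: Sequence[PerfectSSR], k: int
) -> tuple[list[str], dict[int, str]]:
    """Top-k canonical classes by perfect-locus frequency, plus the dominant
    class per unit length.  Ties break lexicographically by representative."""
    if k < 1:
        raise ValueError("k must be >= 1")
    freq: dict[str, int] = {}
    for p in perfect:
        freq[p.canonical] = freq.get(p.canonical, 0) + 1
    ranked = sorted(freq, key=lambda rep: (-freq[rep], rep))
    per_unit: dict[int, str] = {}
    for length in range(1, 7):
        cands = [rep for rep in freq if len(rep) == length]
        if cands:
            per_unit[length] = min(cands, key=lambda rep: (-freq[rep], rep))
    return ranked[:k], per_unit


def gc_content(
    perfect: Sequence[PerfectSSR],
) -> dict[int, float]:
    """GC percent of perfect loci grouped by unit length.

    Per group: 100 x (G+C bases over all loci) / (total bases over all
    loci); empty groups are absent from the result (missing, not zero).
    """
    gc_bp: dict[int, float] = {}
    total_bp: dict[int, int] = {}
    for p in perfect:
        k = p.unit_length
        gc_bp[k] = gc_bp.get(k, 0.0) + p.gc_fraction * p.length
        total_bp[k] = total_bp.get(k, 0) + p.length
    return {k: 100.0 * gc_bp[k] / total_bp[k] for k in sorted(total_bp)}


def rcn_cv(rcns: Sequence[int]) -> float | None:
    """Coefficient of variability of repeat copy numbers, percent.

    CV = 100 x sample standard deviation (n-1 denominator) / mean;
    undefined (None) for fewer than two values or zero mean.

    >>> round(rcn_cv([4, 6]), 2)
    28.28
    """
    if len(rcns) < 2:
        return None
    arr = np.asarray(rcns, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return 100.0 * arr.std(ddof=1) / mean


def rcn_cv_by_group(
    perfect: Sequence[PerfectSSR],
    compartments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """CV of repeat copy numbers grouped by unit length and, when
    compartment labels are given, by (unit length, compartment)."""
    rows = []
    groups: dict[tuple, list[int]] = {}
    for idx, p in enumerate(perfect):
        comp = compartments[idx] if compartments is not None else "all"
        groups.setdefault((p.unit_length, comp), []).append(p.repeats)
    for (k, comp), rcns in sorted(groups.items()):
        rows.append(
            {
                "unit_length": k,
                "compartment": comp,
                "n": len(rcns),
                "mean_rcn": float(np.mean(rcns)),
                "cv_percent": rcn_cv(rcns),
            }
        )
    return pd.DataFrame(rows)


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t test on n-2 degrees of freedom
    (t = r sqrt((n-2)/(1-r^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def summarize_genome(
    organism_id: str,
    clade: str,
    effective_genome_bp: int,
    perfect: Sequence[PerfectSSR],
    compounds: Sequence[CompoundSSR],
    imperfect: Sequence[ImperfectSSR],
) -> GenomeSummary:
    """Assemble the full per-organism summary from scanned loci."""
    if effective_genome_bp <= 0:
        raise ValueError("effective genome size must be positive")
    order = class_order()
    freq = pd.Series(0, index=order, dtype=int)
    bp = pd.Series(0, index=order, dtype=int)
    unit_rcns: dict[int, list[int]] = {}
    for p in perfect:
        freq[p.canonical] += 1
        bp[p.canonical] += p.length
        unit_rcns.setdefault(p.unit_length, []).append(p.repeats)
    mb = effective_genome_bp / 1e6

    compound_bp = sum(c.length for c in compounds)
    props, dominant, tied = category_proportions(perfect)
    counts = {k: len(v) for k, v in unit_rcns.items()}
    return GenomeSummary(
        organism_id=organism_id,
        clade=clade,
        effective_genome_bp=effective_genome_bp,
        category_counts={
            "P": len(perfect),
            "C": len(compounds),
            "I": len(imperfect),
        },
        category_bp={
            "P": int(bp.sum()),
            "C": compound_bp,
            "I": sum(i.length for i in imperfect),
        },
        class_frequency=freq,
        class_density=bp / mb,
        unit_counts=counts,
        unit_proportions=props,
        unit_gc_percent=gc_content(perfect),
        unit_rcns=unit_rcns,
        dominant_unit=dominant,
        dominant_unit_tied=tied,
    )


# ---------------------------------------------------------------------------
# panel-level tables


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def panel_table(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    """One row per organism with the headline landscape statistics."""
    rows = []
    for s in summaries:
        total_count = s.total_ssr_count
        total_bp = s.total_ssr_bp
        abundance, density = abundance_density(
            total_count, total_bp, s.effective_genome_bp
        )
        row = {
            "organism_id": s.organism_id,
            "clade": s.clade,
            "effective_genome_bp": s.effective_genome_bp,
            "p_count": s.category_counts["P"],
            "c_count": s.category_counts["C"],
            "i_count": s.category_counts["I"],
            "p_bp": s.category_bp["P"],
            "c_bp": s.category_bp["C"],
            "i_bp": s.category_bp["I"],
            "total_count": total_count,
            "total_bp": total_bp,
            "abundance_loci_per_mb": abundance,
            "density_bp_per_mb": density,
            "dominant_unit": s.dominant_unit,
            "dominant_unit_tied": s.dominant_unit_tied,
        }
        for k in range(1, 7):
            row[f"prop_unit{k}"] = s.unit_proportions.get(k, float("nan"))
            row[f"gc_unit{k}"] = s.unit_gc_percent.get(k, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_tsv(path, summary: GenomeSummary) -> None:
    """Per-organism summary TSV: headline block then per-class table."""
    with open(path, "w") as fh:
        fh.write(f"##organism={summary.organism_id}\tclade={summary.clade}\n")
        fh.write(f"##effective_genome_bp={summary.effective_genome_bp}\n")
        for cat in ("P", "C", "I"):
            fh.write(
                f"##category_{cat}\tcount={summary.category_counts[cat]}\t"
                f"bp={summary.category_bp[cat]}\n"
            )
        fh.write("canonical\tfrequency\tdensity_bp_per_mb\n")
        for rep in summary.class_frequency.index:
            f = int(summary.class_frequency[rep])
            d = float(summary.class_density[rep])
            fh.write(f"{rep}\t{f}\t{_fmt(d)}\n")


def write_panel_tsv(path, summaries: Sequence[GenomeSummary]) -> None:
    df = panel_table(summaries)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_correlations_tsv(path, rows: Mapping[str, CorrelationResult]) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tr\tp\tn\n")
        for name in sorted(rows):
            res = rows[name]
            fh.write(f"{name}\t{_fmt(res.r)}\t{_fmt(res.p)}\t{res.n}\n")
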