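"""Rank-based enrichment scores and clade-specific motif detection.

Each organism's 501 canonical classes are banded into integer scores
{-2,-1,0,1,2,3} from their perfect-SSR densities:

1. classes with locus frequency below 10 score -2 and leave the ranking
   universe (a sampling-bias floor);
2. the remaining classes are ranked by density, descending (ties broken by
   the lexicographic representative); ranks 1-5 score 3, 6-20 score 2 and
   21-35 score 1 (nested prefix bands);
3. the 20 lowest-ranked remaining classes score -1 (never overriding a
   positive band, which can only collide when 55 or fewer classes remain);
4. everything else scores 0.

Stacking rows over organisms gives the score matrix behind comparative
repeat-landscape heatmaps.  A canonical class is *clade-specific* when its
frequency reaches a presence threshold in at least one species of exactly
one clade and stays below it in every species of every other clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifspace import class_order
from .stats import GenomeSummary

N_CLASSES = 501
FREQ_FLOOR = 10
TOP_BANDS = ((5, 3), (20, 2), (35, 1))  # nested rank prefixes -> score
BOTTOM_BAND = 20


def rank_scores(
    density: Sequence[float],
    frequency: Sequence[int],
    class_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Integer enrichment scores for one organism's 501-class vectors.

    *density* and *frequency* must be aligned to the fixed class order
    (unit length, then representative); pass *class_names* to use another
    ordering for the lexicographic tie-break.
    """
    density = np.asarray(density, dtype=float)
    frequency = np.asarray(frequency)
    if class_names is None:
        class_names = class_order()
    if density.size != len(class_names) or frequency.size != len(class_names):
        raise ValueError(
            f"expected vectors of length {len(class_names)}, "
            f"got {density.size}/{frequency.size}"
        )

    scores = np.zeros(density.size, dtype=int)
    eligible = np.asarray(frequency) >= FREQ_FLOOR
    scores[~eligible] = -2

    idx = np.flatnonzero(eligible)
    # rank by density descending, ties by representative (stable, portable)
    ranked = sorted(idx, key=lambda i: (-density[i], class_names[i]))
    for rank0, i in enumerate(ranked):
        rank = rank0 + 1
        for cutoff, score in TOP_BANDS:
            if rank <= cutoff:
                scores[i] = score
                break
    for i in ranked[-BOTTOM_BAND:] if len(ranked) else []:
        if scores[i] == 0:  # guard: never demote a positive band
            scores[i] = -1
    return scores


def build_matrix(
    summaries: Sequence[GenomeSummary],
    *,
    order_columns: bool = False,
) -> pd.DataFrame:
    """Organisms x 501-classes score matrix (rows in input order).

    With ``order_columns=True`` columns are reordered by mean score,
    descending (ties by class order) — the "enrichment-first" view that
    places universally abundant classes on the left.
    """
    if not summaries:
        raise ValueError("at least one organism summary is required")
    names = class_order()
    rows = {
        s.organism_id: rank_scores(
            s.class_density.to_numpy(), s.class_frequency.to_numpy(), names
        )
        for s in summaries
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    if order_columns:
        mean = matrix.mean(axis=0)
        cols = sorted(names, key=lambda c: (-mean[c], names.index(c)))
        matrix = matrix[cols]
    return matrix


@dataclass(frozen=True)
class CladeSpecificClass:
    clade: str
    canonical: str
    carriers: tuple[str, ...]
    max_frequency: int


def clade_specific(
    frequencies: Mapping[str, Mapping[str, int] | pd.Series],
    clade_map: Mapping[str, str],
    presence_threshold: int = FREQ_FLOOR,
) -> list[CladeSpecificClass]:
    """Canonical classes confined to a single clade.

    A class is specific to clade X when its frequency reaches
    *presence_threshold* in at least one species of X and stays below the
    threshold in every species of every other clade.  Carrier species are
    reported per class.  Every organism in *frequencies* must appear in
    *clade_map*.
    """
    missing = [org for org in frequencies if org not in clade_map]
    if missing:
        raise KeyError(f"organisms missing from clade map: {missing}")

    present: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for org, freq in frequencies.items():
        clade = clade_map[org]
        items = freq.items() if hasattr(freq, "items") else freq
        for rep, count in items:
            if count >= presence_threshold:
                present.setdefault(rep, {}).setdefault(clade, []).append(
                    (org, int(count))
                )

    report: list[CladeSpecificClass] = []
    for rep in sorted(present, key=lambda r: (len(r), r)):
        clades = present[rep]
        if len(clades) != 1:
            continue
        clade, carriers = next(iter(clades.items()))
        report.append(
            CladeSpecificClass(
                clade=clade,
                canonical=rep,
                carriers=tuple(org for org, _ in sorted(carriers)),
                max_frequency=max(c for _, c in carriers),
            )
        )
    return report


def write_matrix_tsv(path, matrix: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("organism_id\t" + "\t".join(matrix.columns) + "\n")
        for org, row in matrix.iterrows():
            fh.write(org + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_clade_report_tsv(path, report: Sequence[CladeSpecificClass]) -> None:
    with open(path, "w") as fh:
        fh.write("clade\tcanonical\tcarriers\tmax_frequency\n")
        for item in report:
            fh.write(
                f"{item.clade}\t{item.canonical}\t{','.join(item.carriers)}\t"
                f"{item.max_frequency}\n"
            )
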