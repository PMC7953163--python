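"""Reference brute-force perfect-SSR scanner.

A deliberately simple, quadratic-time re-derivation of the perfect-repeat
semantics: walk the sequence position by position; at each position try
unit lengths 1-6 from shortest to longest, count complete copies of the
unit by direct string comparison, and emit a locus when the unit is
primitive and the copy count meets the threshold, resuming after its span.

It shares no code with the production scanner in :mod:`ssrscape.scan` (no
numpy, no run-length machinery) and exists as the independent arbiter of
scanner correctness and of synthetic-spacer validity.
"""

from __future__ import annotations

from .motifspace import canonical_class, is_primitive
from .scan import PerfectSSR, ScanParams


def brute_force_perfect(
    seq: str, seq_id: str = "seq", min_repeats: dict[int, int] | None = None
) -> list[PerfectSSR]:
    """All perfect SSR loci of *seq* under greedy left-to-right semantics.

    ``N`` (or any non-ACGT character) breaks runs: loci never span it.
    """
    if min_repeats is None:
        min_repeats = ScanParams().min_repeats
    seq = seq.upper()
    n = len(seq)
    loci: list[PerfectSSR] = []
    i = 0
    while i < n:
        if seq[i] not in "ACGT":
            i += 1
            continue
        emitted = False
        for k in range(1, 7):
            unit = seq[i : i + k]
            if len(unit) < k or any(c not in "ACGT" for c in unit):
                continue
            if not is_primitive(unit):
                continue
            copies = 1
            j = i + k
            while seq[j : j + k] == unit:
                copies += 1
                j += k
            if copies >= min_repeats[k]:
                loci.append(
                    PerfectSSR(
                        seq_id=seq_id,
                        start=i + 1,
                        end=i + copies * k,
                        motif=unit,
                        canonical=canonical_class(unit),
                        repeats=copies,
                    )
                )
                i += copies * k
                emitted = True
                break
        if not emitted:
            i += 1
    return loci


def has_seed_run(seq: str, min_copies: int, min_length: int) -> bool:
    """True if *seq* contains any perfect run of a primitive 1-6 bp unit
    with at least *min_copies* complete copies spanning *min_length* bp.

    Conservative screen used to certify synthetic spacers free of material
    that could seed an imperfect-repeat extension.
    """
    seq = seq.upper()
    n = len(seq)
    for i in range(n):
        for k in range(1, 7):
            unit = seq[i : i + k]
            if len(unit) < k or any(c not in "ACGT" for c in unit):
                continue
            if not is_primitive(unit):
                continue
            copies = 1
            j = i + k
            while seq[j : j + k] == unit:
                copies += 1
                j += k
            if copies >= min_copies and copies * k >= min_length:
                return True
    return False
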