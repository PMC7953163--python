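"""Microsatellite detection: perfect, compound, and imperfect loci.

Three locus categories are produced, mirroring the usual comparative-SSR
taxonomy:

* **P-SSR** (perfect): uninterrupted tandem copies of one primitive 1-6 bp
  unit, with per-unit-length minimum copy thresholds.
* **C-SSR** (compound): two or more perfect loci separated by at most
  ``dmax`` intervening bases, merged transitively; members leave the
  perfect tally so the categories stay disjoint.
* **I-SSR** (imperfect): a tandem array interrupted by substitutions,
  insertions or deletions, found by seeding on short perfect runs and
  extending unit-wise under a match/mismatch/gap score.

Ambiguous bases (``N``) are masked, not excised: detection runs inside
maximal N-free windows so reported coordinates stay on the input assembly,
and the non-N length serves as the effective genome size for densities.

Coordinates are 1-based inclusive throughout, as in GFF3.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .motifspace import canonical_class, is_primitive

#: Krait/MISA-lineage minimum complete-copy thresholds per unit length.
DEFAULT_MIN_REPEATS = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class ScanParams:
    """Tunable thresholds for all three scanners.

    ``min_repeats`` maps unit length (1-6) to the minimum number of complete
    copies a perfect locus needs.  ``dmax`` is the largest gap (bp) across
    which neighbouring perfect loci are merged into a compound locus.  The
    ``issr_*`` group parameterizes the imperfect search: a seed must be a
    perfect run of at least ``issr_seed_min_repeats`` copies and
    ``issr_seed_min_length`` bp; extension scores ``+issr_match_score`` per
    matching base, ``-issr_substitution_penalty`` per mismatch and
    ``-issr_gap_penalty`` per inserted/deleted base, giving up in a
    direction after ``issr_max_consecutive_edits`` consecutive edited
    positions; a locus is reported when its best score reaches
    ``issr_min_score``, spans ``issr_min_length`` bp and carries at least
    one edit.
    """

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    dmax: int = 10
    issr_seed_min_repeats: int = 3
    issr_seed_min_length: int = 8
    issr_max_consecutive_edits: int = 2
    issr_match_score: float = 1.0
    issr_substitution_penalty: float = 1.0
    issr_gap_penalty: float = 2.0
    issr_min_score: float = 10.0
    issr_min_length: int = 12

    def __post_init__(self) -> None:
        for k in range(1, 7):
            if self.min_repeats.get(k, 0) < 1:
                raise ValueError(f"min_repeats must be positive for unit length {k}")
        if self.dmax < 0:
            raise ValueError("dmax must be >= 0")
        for name in (
            "issr_seed_min_repeats",
            "issr_seed_min_length",
            "issr_min_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "issr_match_score",
            "issr_substitution_penalty",
            "issr_gap_penalty",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def echo(self) -> str:
        """One-line parameter echo for TSV provenance headers."""
        mr = ",".join(f"{k}:{self.min_repeats[k]}" for k in sorted(self.min_repeats))
        return (
            f"min_repeats={mr};dmax={self.dmax};"
            f"issr_seed_min_repeats={self.issr_seed_min_repeats};"
            f"issr_seed_min_length={self.issr_seed_min_length};"
            f"issr_max_consecutive_edits={self.issr_max_consecutive_edits};"
            f"issr_match_score={self.issr_match_score:g};"
            f"issr_substitution_penalty={self.issr_substitution_penalty:g};"
            f"issr_gap_penalty={self.issr_gap_penalty:g};"
            f"issr_min_score={self.issr_min_score:g};"
            f"issr_min_length={self.issr_min_length:g}"
        )

    def with_overrides(self, **kwargs) -> "ScanParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence to scan; residues uppercase over {A,C,G,T,N}."""

    seq_id: str
    residues: str

    @property
    def effective_length(self) -> int:
        return len(self.residues) - self.residues.count("N")

    def __post_init__(self) -> None:
        clean = self.residues.upper()
        if any(c not in "ACGTN" for c in set(clean)):
            # IUPAC ambiguity codes and anything else collapse to N
            clean = "".join(c if c in "ACGT" else "N" for c in clean)
        object.__setattr__(self, "residues", clean)


@dataclass(frozen=True)
class PerfectSSR:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str  # unit as first read at start
    canonical: str
    repeats: int

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def gc_fraction(self) -> float:
        return (self.motif.count("G") + self.motif.count("C")) / len(self.motif)


@dataclass(frozen=True)
class ImperfectSSR:
    seq_id: str
    start: int
    end: int
    motif: str
    canonical: str
    substitutions: int
    insertions: int
    deletions: int
    score: float

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def edits(self) -> int:
        return self.substitutions + self.insertions + self.deletions


@dataclass(frozen=True)
class CompoundSSR:
    seq_id: str
    members: tuple[PerfectSSR, ...]

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def gaps(self) -> tuple[int, ...]:
        return tuple(
            b.start - a.end - 1 for a, b in zip(self.members, self.members[1:])
        )


# ---------------------------------------------------------------------------
# masking


def mask_windows(record: SequenceRecord) -> list[tuple[int, int]]:
    """Maximal N-free windows of *record*, 1-based inclusive.

    Concatenated window lengths equal the record's effective (non-N) length.
    """
    seq = record.residues
    windows: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(seq):
        if c == "N":
            if start is not None:
                windows.append((start + 1, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        windows.append((start + 1, len(seq)))
    return windows


# ---------------------------------------------------------------------------
# perfect scan


def _run_starts(eq: np.ndarray) -> np.ndarray:
    """For a boolean array, length of the True run starting at each index."""
    n = eq.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    boundaries = np.append(np.flatnonzero(~eq), n)
    nxt = boundaries[np.searchsorted(boundaries, np.arange(n), side="left")]
    return nxt - np.arange(n)


def _copies_arrays(arr: np.ndarray, max_unit: int = 6) -> dict[int, np.ndarray]:
    """copies[k][i] = number of complete copies of arr[i:i+k] starting at i."""
    n = arr.size
    out: dict[int, np.ndarray] = {}
    for k in range(1, max_unit + 1):
        copies = np.zeros(n, dtype=np.int64)
        if n >= k:
            eq = arr[:-k] == arr[k:] if n > k else np.zeros(0, dtype=bool)
            runs = _run_starts(eq)
            copies[: n - k] = runs // k + 1
            copies[n - k] = 1
        out[k] = copies
    return out


def _scan_window_perfect(
    window: str, offset: int, seq_id: str, min_repeats: dict[int, int]
) -> list[PerfectSSR]:
    """Greedy left-to-right perfect scan of one N-free window.

    At each position the shortest qualifying primitive unit wins; a locus
    consumes its span (scan resumes at end+1); trailing partial units are
    excluded, so length = unit_length x complete copies.
    """
    arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    n = arr.size
    copies = _copies_arrays(arr)
    thresholds = [None] + [min_repeats[k] for k in range(1, 7)]
    candidate = np.zeros(n, dtype=bool)
    for k in range(1, 7):
        candidate |= copies[k] >= thresholds[k]
    positions = np.flatnonzero(candidate)

    loci: list[PerfectSSR] = []
    resume = 0
    for i in map(int, positions):
        if i < resume:
            continue
        for k in range(1, 7):
            c = int(copies[k][i])
            if c < thresholds[k]:
                continue
            unit = window[i : i + k]
            if not is_primitive(unit):
                continue
            loci.append(
                PerfectSSR(
                    seq_id=seq_id,
                    start=offset + i + 1,
                    end=offset + i + c * k,
                    motif=unit,
                    canonical=canonical_class(unit),
                    repeats=c,
                )
            )
            resume = i + c * k
            break
    return loci


def find_perfect(record: SequenceRecord, params: ScanParams) -> list[PerfectSSR]:
    """Detect perfect SSRs in *record* within N-free windows.

    Loci are maximal complete-copy tandem runs of a primitive 1-6 bp unit
    meeting ``params.min_repeats``; reported sorted, non-overlapping.
    """
    loci: list[PerfectSSR] = []
    for wstart, wend in mask_windows(record):
        window = record.residues[wstart - 1 : wend]
        loci.extend(
            _scan_window_perfect(window, wstart - 1, record.seq_id, params.min_repeats)
        )
    return loci


# ---------------------------------------------------------------------------
# compound merge


def find_compound(
    perfect: Sequence[PerfectSSR], dmax: int
) -> tuple[list[CompoundSSR], list[PerfectSSR]]:
    """Merge perfect loci separated by <= dmax bp into compound loci.

    Merging is transitive and class-agnostic.  Members are removed from the
    returned perfect remainder, keeping the P and C categories disjoint.
    Input must be sorted by (seq_id, start) and non-overlapping per seq_id.
    """
    for a, b in zip(perfect, perfect[1:]):
        if (a.seq_id, a.start) > (b.seq_id, b.start):
            raise ValueError("perfect loci must be sorted by (seq_id, start)")
        if a.seq_id == b.seq_id and b.start <= a.end:
            raise ValueError(
                f"overlapping perfect loci at {a.seq_id}:{a.start}-{a.end} / "
                f"{b.start}-{b.end}"
            )

    compounds: list[CompoundSSR] = []
    remainder: list[PerfectSSR] = []
    chain: list[PerfectSSR] = []

    def flush() -> None:
        if len(chain) >= 2:
            compounds.append(CompoundSSR(chain[0].seq_id, tuple(chain)))
        else:
            remainder.extend(chain)
        chain.clear()

    for locus in perfect:
        if chain and (
            locus.seq_id != chain[-1].seq_id
            or locus.start - chain[-1].end - 1 > dmax
        ):
            flush()
        chain.append(locus)
    flush()
    return compounds, remainder


# ---------------------------------------------------------------------------
# imperfect scan


def _find_seeds(
    window: str, params: ScanParams
) -> list[tuple[int, int, str]]:
    """Perfect runs usable as imperfect-search seeds: (start0, copies, unit)."""
    arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    n = arr.size
    copies = _copies_arrays(arr)
    seeds: list[tuple[int, int, str]] = []
    min_rep = params.issr_seed_min_repeats
    min_len = params.issr_seed_min_length
    candidate = np.zeros(n, dtype=bool)
    for k in range(1, 7):
        candidate |= (copies[k] >= min_rep) & (copies[k] * k >= min_len)
    positions = np.flatnonzero(candidate)
    resume = 0
    for i in map(int, positions):
        if i < resume:
            continue
        for k in range(1, 7):
            c = int(copies[k][i])
            if c < min_rep or c * k < min_len:
                continue
            unit = window[i : i + k]
            if not is_primitive(unit):
                continue
            seeds.append((i, c, unit))
            resume = i + c * k
            break
    return seeds


def _extend_dir(
    window: str,
    unit: str,
    seed_start: int,
    seed_end: int,
    direction: int,
    params: ScanParams,
) -> tuple[int, float, int, int, int]:
    """Extend right (direction=+1) from seed_end or left (-1) from seed_start-1.

    Returns (last matched position in that direction, score delta, subs, ins,
    dels) for the maximal-scoring checkpoint; positions are 0-based and the
    returned position equals the seed boundary when nothing is gained.
    """
    k = len(unit)
    match = params.issr_match_score
    sub_pen = params.issr_substitution_penalty
    gap_pen = params.issr_gap_penalty
    max_cons = params.issr_max_consecutive_edits
    n = len(window)

    if direction == 1:
        pos = seed_end
        phase = (seed_end - seed_start) % k
        boundary = seed_end - 1
    else:
        pos = seed_start - 1
        phase = (seed_start - 1 - seed_start) % k
        boundary = seed_start

    score = 0.0
    subs = ins = dels = 0
    cons = 0
    best = (boundary, 0.0, 0, 0, 0)
    best_score = 0.0

    while 0 <= pos < n:
        exp = unit[phase]
        c = window[pos]
        if c == exp:
            score += match
            cons = 0
            if score > best_score:
                best_score = score
                best = (pos, score, subs, ins, dels)
            pos += direction
            phase = (phase + direction) % k
            continue
        if cons + 1 > max_cons:
            break
        nxt = pos + direction
        if 0 <= nxt < n and window[nxt] == exp:
            # insertion relative to the repeat template: consume the extra base
            score -= gap_pen
            ins += 1
            pos += direction
        elif k > 1 and c == unit[(phase + direction) % k]:
            # deletion: skip the template base, re-examine the same sequence base
            score -= gap_pen
            dels += 1
            phase = (phase + direction) % k
        else:
            score -= sub_pen
            subs += 1
            pos += direction
            phase = (phase + direction) % k
        cons += 1
    return best


def _scan_window_imperfect(
    window: str, offset: int, seq_id: str, params: ScanParams
) -> list[ImperfectSSR]:
    loci: list[ImperfectSSR] = []
    last_end0 = -1  # 0-based inclusive end of the last reported locus
    for seed_start, seed_copies, unit in _find_seeds(window, params):
        k = len(unit)
        seed_end = seed_start + seed_copies * k  # exclusive
        if seed_start <= last_end0:
            continue
        right = _extend_dir(window, unit, seed_start, seed_end, +1, params)
        left = _extend_dir(window, unit, seed_start, seed_end, -1, params)
        start0 = left[0]
        end0 = right[0]
        if start0 <= last_end0:
            continue
        edits = sum(left[2:]) + sum(right[2:])
        if edits < 1:
            continue  # pure perfect arrays belong to find_perfect
        score = (
            seed_copies * k * params.issr_match_score + left[1] + right[1]
        )
        length = end0 - start0 + 1
        if score < params.issr_min_score or length < params.issr_min_length:
            continue
        loci.append(
            ImperfectSSR(
                seq_id=seq_id,
                start=offset + start0 + 1,
                end=offset + end0 + 1,
                motif=unit,
                canonical=canonical_class(unit),
                substitutions=left[2] + right[2],
                insertions=left[3] + right[3],
                deletions=left[4] + right[4],
                score=score,
            )
        )
        last_end0 = end0
    return loci


def find_imperfect(record: SequenceRecord, params: ScanParams) -> list[ImperfectSSR]:
    """Detect imperfect SSRs by seed-and-extend within N-free windows.

    Seeds are short perfect runs; extension proceeds unit-wise in both
    directions under the scoring scheme in :class:`ScanParams`, keeping the
    maximal-scoring checkpoint per direction.  Loci need at least one edit;
    reported loci never overlap each other.
    """
    loci: list[ImperfectSSR] = []
    for wstart, wend in mask_windows(record):
        window = record.residues[wstart - 1 : wend]
        loci.extend(_scan_window_imperfect(window, wstart - 1, record.seq_id, params))
    return loci


# ---------------------------------------------------------------------------
# FASTA / TSV I/O

LOCI_COLUMNS = [
    "seq_id",
    "category",
    "start",
    "end",
    "motif",
    "canonical",
    "unit_length",
    "repeats",
    "length",
    "subs",
    "ins",
    "dels",
    "score",
    "member_count",
    "gaps",
]


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Iterate records from a FASTA file (plain or gzip); header parsed to
    the first whitespace."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        seq_id: str | None = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if seq_id is not None:
                    yield SequenceRecord(seq_id, "".join(chunks))
                seq_id = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if seq_id is not None:
            yield SequenceRecord(seq_id, "".join(chunks))


def scan_all(
    records: Iterable[SequenceRecord], params: ScanParams
) -> tuple[list[PerfectSSR], list[CompoundSSR], list[ImperfectSSR]]:
    """Run the full three-category scan over *records*."""
    perfect_all: list[PerfectSSR] = []
    imperfect_all: list[ImperfectSSR] = []
    for rec in records:
        perfect_all.extend(find_perfect(rec, params))
        imperfect_all.extend(find_imperfect(rec, params))
    compounds, perfect_rest = find_compound(perfect_all, params.dmax)
    return perfect_rest, compounds, imperfect_all


def write_loci_tsv(
    path: str | Path,
    perfect: Sequence[PerfectSSR],
    compounds: Sequence[CompoundSSR],
    imperfect: Sequence[ImperfectSSR],
    params: ScanParams,
) -> None:
    """Write all loci to one TSV with a ``##params=`` provenance header."""
    rows: list[tuple] = []
    for p in perfect:
        rows.append(
            (p.seq_id, "P", p.start, p.end, p.motif, p.canonical, p.unit_length,
             p.repeats, p.length, "", "", "", "", "", "")
        )
    for c in compounds:
        rows.append(
            (c.seq_id, "C", c.start, c.end, "", "", "", "", c.length,
             "", "", "", "", len(c.members), ",".join(map(str, c.gaps)))
        )
        for m in c.members:
            rows.append(
                (m.seq_id, "Cm", m.start, m.end, m.motif, m.canonical,
                 m.unit_length, m.repeats, m.length, "", "", "", "", "", "")
            )
    for i in imperfect:
        rows.append(
            (i.seq_id, "I", i.start, i.end, i.motif, i.canonical, i.unit_length,
             "", i.length, i.substitutions, i.insertions, i.deletions,
             f"{i.score:g}", "", "")
        )
    rows.sort(key=lambda r: (r[0], r[2], 0 if r[1] != "Cm" else 1))
    with open(path, "w") as fh:
        fh.write(f"##params={params.echo()}\n")
        fh.write("\t".join(LOCI_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_loci_tsv(
    path: str | Path,
) -> tuple[list[PerfectSSR], list[CompoundSSR], list[ImperfectSSR]]:
    """Read a loci TSV written by :func:`write_loci_tsv`."""
    perfect: list[PerfectSSR] = []
    imperfect: list[ImperfectSSR] = []
    compounds: list[CompoundSSR] = []
    pending: dict[tuple, list[PerfectSSR]] = {}
    compound_rows: list[tuple] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            cat = rec["category"]
            if cat == "P" or cat == "Cm":
                p = PerfectSSR(
                    rec["seq_id"], int(rec["start"]), int(rec["end"]),
                    rec["motif"], rec["canonical"], int(rec["repeats"]),
                )
                if cat == "P":
                    perfect.append(p)
                else:
                    pending.setdefault(rec["seq_id"], []).append(p)
            elif cat == "I":
                imperfect.append(
                    ImperfectSSR(
                        rec["seq_id"], int(rec["start"]), int(rec["end"]),
                        rec["motif"], rec["canonical"], int(rec["subs"]),
                        int(rec["ins"]), int(rec["dels"]), float(rec["score"]),
                    )
                )
            elif cat == "C":
                compound_rows.append(
                    (rec["seq_id"], int(rec["start"]), int(rec["end"]))
                )
    for seq_id, start, end in compound_rows:
        members = sorted(
            (m for m in pending.get(seq_id, []) if start <= m.start and m.end <= end),
            key=lambda m: m.start,
        )
        compounds.append(CompoundSSR(seq_id, tuple(members)))
    return perfect, compounds, imperfect
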