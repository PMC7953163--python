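"""Synthetic genomes with planted microsatellite ground truth.

The generator emulates the statistical structure the comparative analysis
assumes: multi-sequence genomes with an i.i.d. background of chosen GC
content, assembly-gap-like ``N`` blocks, and planted perfect, compound and
imperfect loci of known motif class, copy number and edit structure,
together with a nested gene/mRNA/exon/CDS annotation that realizes an
intended genic compartment for each locus.

Fixture validity is independent of the production scanner wherever the
scanner itself is under test: spacers between planted loci are
rejection-checked to contain no perfect run that could qualify as a locus
or seed an imperfect extension, and the bases flanking each planted locus
are resampled until the brute-force reference scanner recovers exactly the
planted loci in a local window.  Repeat copy numbers follow a truncated
geometric tail, mimicking the empirical decay of repeat lengths.

Multi-organism panels arrange organisms into clades with clade-level motif
profiles (e.g. a mononucleotide-dominant versus a dinucleotide-dominant
clade, or a clade carrying exclusive motif classes), standing in for a
real multi-species genome collection.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .motifspace import canonical_class, class_members, is_primitive
from .oracle import brute_force_perfect
from .scan import ScanParams, SequenceRecord, find_imperfect

#: Realistic default class mix (mammalian-flavoured: heavy A / AC / AG).
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "A": 0.30, "C": 0.03,
    "AC": 0.17, "AG": 0.12, "AT": 0.07,
    "AAT": 0.05, "AAC": 0.04, "AGC": 0.02,
    "AAAT": 0.07, "AAAG": 0.04, "AAAC": 0.02,
    "AAAAC": 0.03, "AAAAT": 0.02,
    "AAAAAC": 0.01, "AACCCT": 0.01,
}

#: Mono-dominant profile (primate-like genomes in comparative surveys).
MONO_DOMINANT_WEIGHTS: dict[str, float] = {
    "A": 0.52, "C": 0.04,
    "AC": 0.10, "AT": 0.06, "AG": 0.05,
    "AAT": 0.05, "AAC": 0.03,
    "AAAT": 0.08, "AAAG": 0.03,
    "AAAAC": 0.02, "AAAAT": 0.01, "AACCCT": 0.01,
}

#: Di-dominant profile (rodent-like genomes).
DI_DOMINANT_WEIGHTS: dict[str, float] = {
    "A": 0.16, "C": 0.02,
    "AC": 0.28, "AG": 0.20, "AT": 0.06,
    "AAT": 0.05, "AAC": 0.03,
    "AAAT": 0.08, "AAAG": 0.05,
    "AAAAC": 0.03, "AAAAT": 0.02, "AACCCT": 0.02,
}

MIN_SPACER_FACTOR = 2  # spacers >= 2*dmax + 1, keeping planted loci independent
JUNCTION_CONTEXT = 12  # bp of spacer context checked around each planted locus


class SizingError(ValueError):
    """Requested plants cannot fit in the requested sequence length."""


@dataclass(frozen=True)
class PlantedLocus:
    """Ground-truth record for one planted locus."""

    seq_id: str
    start: int  # 1-based inclusive
    end: int
    category: str  # P / C / I
    motif: str
    canonical: str
    repeats: int  # complete copies (P); 0 for C
    edits: int  # total planted edits (I); 0 otherwise
    compartment: str  # intended genic compartment
    members: tuple[tuple[int, int, str, int], ...] = ()  # C: (start, end, motif, copies)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def unit_length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic genome."""

    seed: int
    n_sequences: int = 2
    sequence_length: int = 100_000
    gc: float = 0.42
    n_block_rate: float = 1.0  # expected N blocks per 100 kb
    n_block_length: int = 60
    n_perfect: int = 40
    n_compound: int = 6
    n_imperfect: int = 14
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    rcn_geom_p: float | None = 0.35  # None -> fixed minimum+2 copies
    rcn_max_extra: int = 12
    issr_edit_choices: tuple[int, ...] = (1, 2)
    compound_member_choices: tuple[int, ...] = (2, 3)
    compartment_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "CDS": 0.10, "exon": 0.10, "intron": 0.30, "intergenic": 0.50,
        }
    )
    params: ScanParams = field(default_factory=ScanParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if abs(sum(self.compartment_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("compartment fractions must sum to 1")
        if abs(sum(self.class_weights.values()) - 1.0) > 1e-6:
            raise ValueError("class weights must sum to 1")
        for rep in self.class_weights:
            if canonical_class(rep) != rep:
                raise ValueError(f"class weight key {rep!r} is not canonical")


def derive_seed(master_seed: int, label: str) -> int:
    """Stable sub-seed from a master seed and a label (below 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# background sampling and spacer certification

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _seed_spans(
    arr: np.ndarray, min_copies: int = 3, min_length: int = 8
) -> list[tuple[int, int]]:
    """Spans [start, end) of tandem runs able to seed a repeat detection.

    A span qualifies when some primitive 1-6 bp unit repeats for at least
    *min_copies* complete copies covering *min_length* bp.  Vectorized over
    per-lag equality runs; used only for fixture construction.
    """
    n = arr.size
    spans: list[tuple[int, int]] = []
    for k in range(1, 7):
        if n <= k:
            continue
        eq = arr[:-k] == arr[k:]
        padded = np.concatenate(([False], eq, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive, in eq coordinates
        for s, e in zip(starts, ends):
            m = e - s
            copies = m // k + 1
            if copies < min_copies or copies * k < min_length:
                continue
            unit = arr[s : s + k].tobytes().decode()
            if not is_primitive(unit):
                continue
            spans.append((int(s), int(s + m + k)))
    spans.sort()
    return spans


def _certified_spacer(
    rng: np.random.Generator, length: int, gc: float, max_rounds: int = 500
) -> np.ndarray:
    """Random background of *length* bp certified free of seed-capable runs.

    Offending spans are locally resampled rather than rejecting the whole
    spacer, so arbitrarily long spacers converge quickly.
    """
    arr = _random_bases(rng, length, gc)
    for _ in range(max_rounds):
        spans = _seed_spans(arr)
        if not spans:
            return arr
        for s, e in spans:
            lo, hi = max(0, s - 2), min(length, e + 2)
            arr[lo:hi] = _random_bases(rng, hi - lo, gc)
    raise RuntimeError("spacer certification did not converge")


# ---------------------------------------------------------------------------
# locus block construction


def _sample_class(rng: np.random.Generator, weights: dict[str, float]) -> str:
    reps = sorted(weights)
    p = np.array([weights[r] for r in reps])
    return reps[rng.choice(len(reps), p=p / p.sum())]


def _sample_motif(rng: np.random.Generator, rep: str) -> str:
    members = sorted(class_members(rep))
    return members[rng.integers(len(members))]


def _sample_copies(rng: np.random.Generator, spec: PlantSpec, k: int) -> int:
    base = spec.params.min_repeats[k]
    if spec.rcn_geom_p is None:
        return base + 2
    extra = int(rng.geometric(spec.rcn_geom_p)) - 1
    return base + min(extra, spec.rcn_max_extra)


@dataclass
class _Block:
    category: str
    text: str
    motif: str = ""
    repeats: int = 0
    edits: int = 0
    members: tuple[tuple[int, int, str, int], ...] = ()  # offsets within block


def _build_perfect_block(rng: np.random.Generator, spec: PlantSpec) -> _Block:
    rep = _sample_class(rng, spec.class_weights)
    motif = _sample_motif(rng, rep)
    copies = _sample_copies(rng, spec, len(motif))
    return _Block("P", motif * copies, motif=motif, repeats=copies)


def _build_compound_block(rng: np.random.Generator, spec: PlantSpec) -> _Block:
    n_members = int(
        rng.choice(np.asarray(spec.compound_member_choices, dtype=int))
    )
    for _ in range(200):
        parts: list[str] = []
        members: list[tuple[int, int, str, int]] = []
        offset = 0
        for i in range(n_members):
            rep = _sample_class(rng, spec.class_weights)
            motif = _sample_motif(rng, rep)
            copies = _sample_copies(rng, spec, len(motif))
            text = motif * copies
            members.append((offset, offset + len(text) - 1, motif, copies))
            parts.append(text)
            offset += len(text)
            if i < n_members - 1:
                gap = int(rng.integers(1, spec.params.dmax + 1))
                parts.append(_random_bases(rng, gap, spec.gc).tobytes().decode())
                offset += gap
        block_text = "".join(parts)
        # gap bases must neither extend a member nor shift its frame
        found = [
            (p.start - 1, p.end - 1, p.motif)
            for p in brute_force_perfect(block_text, min_repeats=spec.params.min_repeats)
        ]
        if found == [(ms, me, motif) for ms, me, motif, _ in members]:
            return _Block("C", block_text, members=tuple(members))
    raise RuntimeError("compound block construction did not converge")


def _segment_copies(spec: PlantSpec, k: int) -> int:
    """Perfect copies per imperfect-locus segment: enough to seed the
    imperfect search, strictly below the perfect-locus threshold."""
    p = spec.params
    need = max(p.issr_seed_min_repeats, math.ceil(p.issr_seed_min_length / k))
    cap = p.min_repeats[k] - 1
    if need > cap:
        raise SizingError(
            f"imperfect segments infeasible for unit length {k}: "
            f"seed needs {need} copies but perfect threshold allows {cap}"
        )
    return need


def _build_imperfect_block(rng: np.random.Generator, spec: PlantSpec) -> _Block:
    for _ in range(200):
        rep = _sample_class(rng, spec.class_weights)
        motif = _sample_motif(rng, rep)
        k = len(motif)
        if k > 1:
            # rotate so the first two template bases differ (keeps greedy
            # edit classification unambiguous at planted edit sites)
            for r in range(k):
                rot = motif[r:] + motif[:r]
                if rot[0] != rot[1]:
                    motif = rot
                    break
        n_edits = int(rng.choice(np.asarray(spec.issr_edit_choices, dtype=int)))
        seg = _segment_copies(spec, k)
        edit_kinds = ["ins", "sub", "del"] if k > 1 else ["ins", "sub"]
        parts = [motif * seg]
        total_edits = 0
        for _ in range(n_edits):
            kind = edit_kinds[rng.integers(len(edit_kinds))]
            if kind == "ins":
                base = rng.choice([b for b in "ACGT" if b != motif[0]])
                parts.append(str(base))
            elif kind == "sub":
                banned = {motif[0], motif[1 % k]}
                base = rng.choice([b for b in "ACGT" if b not in banned])
                parts.append(str(base) + motif[1:])
            else:  # deletion of the first base of a copy
                parts.append(motif[1:])
            total_edits += 1
            parts.append(motif * seg)
        text = "".join(parts)
        # in isolation the block must contain no perfect-qualifying run and
        # be recovered by the imperfect search with the planted span/edits
        if brute_force_perfect(text, min_repeats=spec.params.min_repeats):
            continue
        issr = find_imperfect(SequenceRecord("b", text), spec.params)
        if (
            len(issr) == 1
            and issr[0].start == 1
            and issr[0].end == len(text)
            and issr[0].edits == total_edits
        ):
            return _Block("I", text, motif=motif, repeats=0, edits=total_edits)
    raise RuntimeError("imperfect block construction did not converge")


# ---------------------------------------------------------------------------
# assembly


def _check_junction_window(
    seq: np.ndarray,
    block: _Block,
    start0: int,
    params: ScanParams,
) -> bool:
    """True when the reference scanner sees exactly the planted loci in a
    window of the block plus JUNCTION_CONTEXT bp of flanking spacer."""
    lo = max(0, start0 - JUNCTION_CONTEXT)
    hi = min(seq.size, start0 + len(block.text) + JUNCTION_CONTEXT)
    window = seq[lo:hi].tobytes().decode()
    found = brute_force_perfect(window, min_repeats=params.min_repeats)
    if block.category == "P":
        expect = [(start0 - lo + 1, start0 - lo + len(block.text), block.motif)]
    elif block.category == "C":
        expect = [
            (start0 - lo + ms + 1, start0 - lo + me + 1, motif)
            for ms, me, motif, _ in block.members
        ]
    else:  # imperfect: no perfect-qualifying run may appear anywhere
        expect = []
    got = [(p.start, p.end, p.motif) for p in found]
    if got != expect:
        return False
    if block.category == "I":
        rec = SequenceRecord("w", window)
        issr = find_imperfect(rec, params)
        want_start = start0 - lo + 1
        want_end = start0 - lo + len(block.text)
        if len(issr) != 1:
            return False
        i = issr[0]
        if abs(i.start - want_start) > 0 or abs(i.end - want_end) > 0:
            return False
        if i.edits != block.edits:
            return False
    return True


def _repair_junction(
    seq: np.ndarray,
    block: _Block,
    start0: int,
    spacer_bounds: tuple[int, int, int, int],
    rng: np.random.Generator,
    spec: PlantSpec,
    max_tries: int = 200,
) -> None:
    """Resample flanking spacer bases until the junction window checks out."""
    llo, lhi, rlo, rhi = spacer_bounds  # editable ranges in seq coordinates
    if _check_junction_window(seq, block, start0, spec.params):
        return
    for _ in range(max_tries):
        if lhi > llo:
            seq[llo:lhi] = _random_bases(rng, lhi - llo, spec.gc)
        if rhi > rlo:
            seq[rlo:rhi] = _random_bases(rng, rhi - rlo, spec.gc)
        if not _check_junction_window(seq, block, start0, spec.params):
            continue
        # the patch must not have introduced seed material reaching into
        # the neighbouring spacer interior
        glo = max(0, llo - 20)
        ghi = min(seq.size, rhi + 20)
        window = seq[glo:ghi]
        bad = False
        for s, e in _seed_spans(window):
            abs_s, abs_e = glo + s, glo + e
            if abs_e <= start0 or abs_s >= start0 + len(block.text):
                bad = True
                break
        if not bad:
            return
    raise RuntimeError("junction repair did not converge")


def generate_genome(
    spec: PlantSpec, organism_id: str = "org"
) -> tuple[list[SequenceRecord], list[PlantedLocus]]:
    """Generate FASTA-ready records and the planted-locus truth table.

    Deterministic for a fixed spec (including seed).  Raises
    :class:`SizingError` before emitting anything if the requested plants
    cannot fit with minimum spacers.
    """
    rng = np.random.default_rng(spec.seed)
    dmax = spec.params.dmax
    min_spacer = MIN_SPACER_FACTOR * dmax + 1

    counts = {"P": spec.n_perfect, "C": spec.n_compound, "I": spec.n_imperfect}
    order: list[str] = (
        ["P"] * counts["P"] + ["C"] * counts["C"] + ["I"] * counts["I"]
    )
    rng.shuffle(order)

    per_seq: list[list[str]] = [[] for _ in range(spec.n_sequences)]
    for i, cat in enumerate(order):
        per_seq[i % spec.n_sequences].append(cat)

    comp_names = sorted(spec.compartment_fractions)
    comp_p = np.array([spec.compartment_fractions[c] for c in comp_names])

    records: list[SequenceRecord] = []
    truth: list[PlantedLocus] = []

    for si, cats in enumerate(per_seq):
        seq_id = f"{organism_id}_seq{si + 1}"
        length = spec.sequence_length
        blocks: list[_Block] = []
        for cat in cats:
            if cat == "P":
                blocks.append(_build_perfect_block(rng, spec))
            elif cat == "C":
                blocks.append(_build_compound_block(rng, spec))
            else:
                blocks.append(_build_imperfect_block(rng, spec))
        block_bp = sum(len(b.text) for b in blocks)
        n_spacers = len(blocks) + 1
        slack = length - block_bp - n_spacers * min_spacer
        if slack < 0:
            raise SizingError(
                f"{seq_id}: {block_bp} bp of plants + {n_spacers} minimum "
                f"spacers exceed sequence length {length}"
            )
        extra = rng.multinomial(slack, np.full(n_spacers, 1.0 / n_spacers))
        spacer_lengths = [min_spacer + int(e) for e in extra]

        seq = np.empty(length, dtype=np.uint8)
        pos = 0
        spacer_spans: list[tuple[int, int]] = []
        block_starts: list[int] = []
        for bi in range(n_spacers):
            slen = spacer_lengths[bi]
            seq[pos : pos + slen] = _certified_spacer(rng, slen, spec.gc)
            spacer_spans.append((pos, pos + slen))
            pos += slen
            if bi < len(blocks):
                text = blocks[bi].text
                seq[pos : pos + len(text)] = np.frombuffer(
                    text.encode(), dtype=np.uint8
                )
                block_starts.append(pos)
                pos += len(text)
        assert pos == length

        margin = 6
        for bi, block in enumerate(blocks):
            start0 = block_starts[bi]
            lspan = spacer_spans[bi]
            rspan = spacer_spans[bi + 1]
            bounds = (
                max(lspan[0], lspan[1] - margin), lspan[1],
                rspan[0], min(rspan[1], rspan[0] + margin),
            )
            _repair_junction(seq, block, start0, bounds, rng, spec)

        # assembly-gap-like N blocks in spacer interiors
        n_blocks = rng.poisson(spec.n_block_rate * length / 1e5)
        eligible = [
            (s, e) for s, e in spacer_spans
            if e - s >= spec.n_block_length + 2 * (margin + 8)
        ]
        for _ in range(int(n_blocks)):
            if not eligible:
                break
            s, e = eligible[rng.integers(len(eligible))]
            lo = s + margin + 8
            hi = e - margin - 8 - spec.n_block_length
            if hi <= lo:
                continue
            nstart = int(rng.integers(lo, hi))
            seq[nstart : nstart + spec.n_block_length] = ord("N")

        residues = seq.tobytes().decode()
        records.append(SequenceRecord(seq_id, residues))

        for bi, block in enumerate(blocks):
            start0 = block_starts[bi]
            compartment = comp_names[rng.choice(len(comp_names), p=comp_p)]
            if block.category == "C":
                members = tuple(
                    (start0 + ms + 1, start0 + me + 1, motif, copies)
                    for ms, me, motif, copies in block.members
                )
                truth.append(
                    PlantedLocus(
                        seq_id, start0 + 1, start0 + len(block.text), "C",
                        "", "", 0, 0, compartment, members,
                    )
                )
            elif block.category == "P":
                truth.append(
                    PlantedLocus(
                        seq_id, start0 + 1, start0 + len(block.text), "P",
                        block.motif, canonical_class(block.motif),
                        block.repeats, 0, compartment,
                    )
                )
            else:
                truth.append(
                    PlantedLocus(
                        seq_id, start0 + 1, start0 + len(block.text), "I",
                        block.motif, canonical_class(block.motif),
                        0, block.edits, compartment,
                    )
                )

    truth.sort(key=lambda t: (t.seq_id, t.start))
    return records, truth


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    records: Sequence[SequenceRecord], truth: Sequence[PlantedLocus]
) -> str:
    """GFF3 text realizing each planted locus's intended compartment.

    Genes are laid out in the spacer territory around each non-intergenic
    locus (pads never reach half the flanking spacer, so genes of
    neighbouring loci cannot collide or swallow other loci).
    """
    lengths = {r.seq_id: len(r.residues) for r in records}
    by_seq: dict[str, list[PlantedLocus]] = {}
    for t in truth:
        by_seq.setdefault(t.seq_id, []).append(t)

    lines = ["##gff-version 3"]
    for seq_id in sorted(lengths):
        lines.append(f"##sequence-region {seq_id} 1 {lengths[seq_id]}")

    counter = 0
    for seq_id in sorted(by_seq):
        loci = sorted(by_seq[seq_id], key=lambda t: t.start)
        for i, locus in enumerate(loci):
            if locus.compartment == "intergenic":
                continue
            prev_end = loci[i - 1].end if i > 0 else 0
            next_start = (
                loci[i + 1].start if i + 1 < len(loci) else lengths[seq_id] + 1
            )
            pad_l = min(10, max(1, (locus.start - prev_end - 1) // 2))
            pad_r = min(10, max(1, (next_start - locus.end - 1) // 2))
            gstart = max(1, locus.start - pad_l)
            gend = min(lengths[seq_id], locus.end + pad_r)
            counter += 1
            gid = f"gene{counter:05d}"
            tid = f"mrna{counter:05d}"
            attrs_g = f"ID={gid}"
            attrs_t = f"ID={tid};Parent={gid}"

            def row(ftype: str, start: int, end: int, attrs: str, phase: str = ".") -> str:
                return (
                    f"{seq_id}\tssrscape_synth\t{ftype}\t{start}\t{end}\t.\t+\t"
                    f"{phase}\t{attrs}"
                )

            lines.append(row("gene", gstart, gend, attrs_g))
            lines.append(row("mRNA", gstart, gend, attrs_t))
            if locus.compartment == "CDS":
                lines.append(row("exon", gstart, gend, f"Parent={tid}"))
                lines.append(row("CDS", gstart, gend, f"ID=cds{counter:05d};Parent={tid}", "0"))
            elif locus.compartment == "exon":
                if pad_r < 5:
                    # not enough room for a trailing coding exon; put the
                    # CDS ahead of the locus instead
                    lines.append(row("exon", gstart, locus.start - 2, f"Parent={tid}"))
                    lines.append(row("CDS", gstart, locus.start - 2, f"ID=cds{counter:05d};Parent={tid}", "0"))
                    lines.append(row("exon", locus.start, gend, f"Parent={tid}"))
                else:
                    lines.append(row("exon", gstart, locus.end + 1, f"Parent={tid}"))
                    lines.append(row("exon", locus.end + 4, gend, f"Parent={tid}"))
                    lines.append(row("CDS", locus.end + 4, gend, f"ID=cds{counter:05d};Parent={tid}", "0"))
            elif locus.compartment == "intron":
                lines.append(row("exon", gstart, locus.start - 1, f"Parent={tid}"))
                lines.append(row("exon", locus.end + 1, gend, f"Parent={tid}"))
                lines.append(row("CDS", gstart, locus.start - 1, f"ID=cds{counter:05d};Parent={tid}", "0"))
            else:
                raise ValueError(f"unknown compartment {locus.compartment!r}")
    return "\n".join(lines) + "\n"


def validate_fixture(
    records: Sequence[SequenceRecord],
    truth: Sequence[PlantedLocus],
    params: ScanParams,
) -> list[str]:
    """Independent consistency check of a generated fixture.

    Verifies with the brute-force reference scanner that each planted
    perfect locus (and compound member) is recovered verbatim in its local
    window and that imperfect-locus windows contain no perfect-qualifying
    run.  Returns a list of problems (empty when consistent).
    """
    seqs = {r.seq_id: r.residues for r in records}
    problems: list[str] = []
    for t in truth:
        seq = seqs.get(t.seq_id)
        if seq is None:
            problems.append(f"truth references unknown sequence {t.seq_id}")
            continue
        lo = max(0, t.start - 1 - JUNCTION_CONTEXT)
        hi = min(len(seq), t.end + JUNCTION_CONTEXT)
        window = seq[lo : hi]
        found = [
            (p.start + lo, p.end + lo, p.motif)
            for p in brute_force_perfect(window, min_repeats=params.min_repeats)
        ]
        if t.category == "P":
            expect = [(t.start, t.end, t.motif)]
            if seq[t.start - 1 : t.end] != t.motif * t.repeats:
                problems.append(f"{t.seq_id}:{t.start}: planted text mismatch")
        elif t.category == "C":
            expect = [(ms, me, motif) for ms, me, motif, _ in t.members]
        else:
            expect = []
        if found != expect:
            problems.append(
                f"{t.seq_id}:{t.start}: reference scan found {found}, "
                f"expected {expect}"
            )
    return problems


# ---------------------------------------------------------------------------
# panels


@dataclass(frozen=True)
class CladeSpec:
    """Per-clade plan inside a panel."""

    name: str
    n_organisms: int
    genome_size: int = 200_000
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    exclusive_classes: tuple[str, ...] = ()
    exclusive_count: int = 12
    perfect_per_mb: float = 400.0
    compound_per_mb: float = 60.0
    imperfect_per_mb: float = 140.0


@dataclass(frozen=True)
class PanelSpec:
    """Multi-organism, multi-clade panel plan."""

    seed: int
    clades: tuple[CladeSpec, ...]
    n_sequences: int = 2
    gc: float = 0.42
    rcn_geom_p: float | None = 0.35
    with_annotation: bool = True
    params: ScanParams = field(default_factory=ScanParams)

    def __post_init__(self) -> None:
        if len(self.clades) < 2:
            raise ValueError("a panel needs at least two clades")
        for clade in self.clades:
            if clade.n_organisms < 1:
                raise ValueError(f"clade {clade.name} needs at least one organism")


@dataclass
class OrganismFixture:
    organism_id: str
    clade: str
    spec: PlantSpec
    records: list[SequenceRecord]
    truth: list[PlantedLocus]
    gff3: str | None
    exclusive_classes: tuple[str, ...]

    @property
    def genome_bp(self) -> int:
        return sum(len(r.residues) for r in self.records)

    @property
    def effective_genome_bp(self) -> int:
        return sum(r.effective_length for r in self.records)


def _plant_exclusive(
    fixture_truth: list[PlantedLocus],
    records: list[SequenceRecord],
    clade: CladeSpec,
    spec: PlantSpec,
    rng: np.random.Generator,
) -> None:
    """Overwrite spacer interiors with loci of the clade-exclusive classes."""
    if not clade.exclusive_classes:
        return
    seq_arrays = {r.seq_id: bytearray(r.residues.encode()) for r in records}
    by_seq: dict[str, list[PlantedLocus]] = {}
    for t in fixture_truth:
        by_seq.setdefault(t.seq_id, []).append(t)
    new_loci: list[PlantedLocus] = []
    seq_ids = sorted(seq_arrays)
    for rep in clade.exclusive_classes:
        copies = spec.params.min_repeats[len(rep)] + 1
        text = rep * copies
        need = clade.exclusive_count
        planted = 0
        attempt = 0
        while planted < need and attempt < need * 200:
            attempt += 1
            seq_id = seq_ids[int(rng.integers(len(seq_ids)))]
            arr = seq_arrays[seq_id]
            pos0 = int(rng.integers(30, len(arr) - len(text) - 30))
            interval = (pos0 + 1, pos0 + len(text))
            occupied = by_seq.get(seq_id, []) + [
                t for t in new_loci if t.seq_id == seq_id
            ]
            margin = 2 * spec.params.dmax + 1
            if any(
                not (interval[1] + margin < t.start or interval[0] - margin > t.end)
                for t in occupied
            ):
                continue
            context = bytes(arr[max(0, pos0 - 30) : pos0 + len(text) + 30]).decode()
            if "N" in context:
                continue
            original = bytes(arr[pos0 : pos0 + len(text)])
            arr[pos0 : pos0 + len(text)] = text.encode()
            lo = max(0, pos0 - JUNCTION_CONTEXT)
            hi = min(len(arr), pos0 + len(text) + JUNCTION_CONTEXT)
            check = bytes(arr[lo:hi]).decode()
            found = [
                (p.start + lo, p.end + lo, p.motif)
                for p in brute_force_perfect(check, min_repeats=spec.params.min_repeats)
            ]
            if found != [(pos0 + 1, pos0 + len(text), rep)]:
                arr[pos0 : pos0 + len(text)] = original
                continue
            new_loci.append(
                PlantedLocus(
                    seq_id, pos0 + 1, pos0 + len(text), "P", rep, rep,
                    copies, 0, "intergenic",
                )
            )
            planted += 1
        if planted < need:
            raise RuntimeError(
                f"could not place {need} exclusive loci of class {rep}"
            )
    for i, r in enumerate(records):
        records[i] = SequenceRecord(r.seq_id, bytes(seq_arrays[r.seq_id]).decode())
    fixture_truth.extend(new_loci)
    fixture_truth.sort(key=lambda t: (t.seq_id, t.start))


def generate_panel(panel: PanelSpec) -> list[OrganismFixture]:
    """Generate every organism of a panel, deterministically per seed."""
    fixtures: list[OrganismFixture] = []
    for clade in panel.clades:
        for i in range(clade.n_organisms):
            organism_id = f"{clade.name}_{i + 1}"
            seq_len = clade.genome_size // panel.n_sequences
            mb = clade.genome_size / 1e6
            spec = PlantSpec(
                seed=derive_seed(panel.seed, organism_id),
                n_sequences=panel.n_sequences,
                sequence_length=seq_len,
                gc=panel.gc,
                class_weights=dict(clade.class_weights),
                rcn_geom_p=panel.rcn_geom_p,
                n_perfect=max(1, round(clade.perfect_per_mb * mb)),
                n_compound=max(1, round(clade.compound_per_mb * mb)),
                n_imperfect=max(1, round(clade.imperfect_per_mb * mb)),
                params=panel.params,
            )
            records, truth = generate_genome(spec, organism_id)
            rng = np.random.default_rng(derive_seed(panel.seed, organism_id + ":x"))
            _plant_exclusive(truth, records, clade, spec, rng)
            gff3 = (
                generate_annotation(records, truth) if panel.with_annotation else None
            )
            fixtures.append(
                OrganismFixture(
                    organism_id, clade.name, spec, records, truth, gff3,
                    clade.exclusive_classes,
                )
            )
    return fixtures


# ---------------------------------------------------------------------------
# serialization


def truth_table(truth: Sequence[PlantedLocus]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "seq_id": t.seq_id,
                "start": t.start,
                "end": t.end,
                "category": t.category,
                "motif": t.motif,
                "canonical": t.canonical,
                "repeats": t.repeats,
                "edits": t.edits,
                "compartment": t.compartment,
                "members": ";".join(
                    f"{ms}-{me}:{motif}x{copies}" for ms, me, motif, copies in t.members
                ),
            }
        )
    return pd.DataFrame(rows)


def write_fasta(path: str | Path, records: Sequence[SequenceRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.seq_id}\n")
            for i in range(0, len(r.residues), 80):
                fh.write(r.residues[i : i + 80] + "\n")


def write_fixture(
    outdir: str | Path, fixture: OrganismFixture
) -> dict[str, Path]:
    """Write FASTA, GFF3 and truth TSV for one organism; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fasta = outdir / f"{fixture.organism_id}.fa"
    write_fasta(fasta, fixture.records)
    paths["fasta"] = fasta
    if fixture.gff3 is not None:
        gff = outdir / f"{fixture.organism_id}.gff3"
        gff.write_text(fixture.gff3)
        paths["gff3"] = gff
    truth_path = outdir / f"{fixture.organism_id}.truth.tsv"
    truth_table(fixture.truth).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def write_panel(outdir: str | Path, fixtures: Sequence[OrganismFixture]) -> Path:
    """Write all organisms plus the panel metadata TSV; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fixture in fixtures:
        paths = write_fixture(outdir, fixture)
        rows.append(
            {
                "organism_id": fixture.organism_id,
                "clade": fixture.clade,
                "genome_bp": fixture.genome_bp,
                "fasta": paths["fasta"].name,
                "gff3": paths.get("gff3", Path("")).name,
                "truth": paths["truth"].name,
            }
        )
    meta = outdir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    return meta
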