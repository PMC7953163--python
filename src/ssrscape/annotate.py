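"""Genic-compartment annotation of SSR loci from GFF3.

Gene, mRNA, exon and CDS features are read from GFF3 into per-sequence
interval trees; introns are derived per transcript as the gaps between its
sorted exons and then unioned per sequence.  A locus is assigned to
compartments by its **start position**: it is CDS if the start lies in a
CDS interval (which implies exon), exonic if in any exon, intronic if
inside a gene but in no exon, and intergenic outside all gene spans.
Positions exonic in one isoform and intronic in another are labelled
exonic (exon priority).  All coordinates are GFF3-style 1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

COMPARTMENTS = ("CDS", "exon", "intron", "intergenic")


class GFF3Error(ValueError):
    """Raised for malformed GFF3 input, with the offending line number."""


@dataclass
class FeatureIndex:
    """Per-sequence interval trees for gene/exon/CDS/intron compartments."""

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    exons: dict[str, IntervalTree] = field(default_factory=dict)
    cds: dict[str, IntervalTree] = field(default_factory=dict)
    introns: dict[str, IntervalTree] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def seq_ids(self) -> set[str]:
        return set(self.genes)

    def has_seq(self, seq_id: str) -> bool:
        return seq_id in self.genes


@dataclass(frozen=True)
class RegionCall:
    """Compartment labels for one locus, assigned by start position."""

    seq_id: str
    start: int
    end: int
    labels: frozenset[str]

    @property
    def genic(self) -> bool:
        return "intergenic" not in self.labels

    @property
    def primary(self) -> str:
        """Mutually exclusive label: CDS > exon > intron > intergenic."""
        for label in COMPARTMENTS:
            if label in self.labels:
                return label
        return "intron"  # genic but feature-sparse annotation


def _validate_gff3_lines(path: Path) -> None:
    """Cheap structural pass so malformed rows fail with a line number."""
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3Error(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GFF3Error(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end or start < 1:
                raise GFF3Error(f"{path}:{lineno}: invalid interval {start}-{end}")


def build_feature_index(gff3: str | Path) -> FeatureIndex:
    """Parse GFF3 (plain or gzip) into a :class:`FeatureIndex`.

    Handles gene/mRNA (or transcript)/exon/CDS rows linked by ID/Parent
    (parsed with :mod:`gffutils` into an in-memory database).  Exons
    extending beyond their gene span are clamped with a warning; introns
    are the gaps between consecutive exons of each transcript.
    """
    import gffutils

    path = Path(gff3)
    _validate_gff3_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # sqlite/attribute errors from gffutils
        raise GFF3Error(f"{path}: {exc}") from exc

    index = FeatureIndex()
    warnings = index.warnings

    def tree(store: dict[str, IntervalTree], seq_id: str) -> IntervalTree:
        return store.setdefault(seq_id, IntervalTree())

    gene_span: dict[str, tuple[str, int, int]] = {}
    for gene in db.features_of_type("gene"):
        gene_span[gene.id] = (gene.seqid, gene.start, gene.end)
        tree(index.genes, gene.seqid).addi(gene.start, gene.end + 1, gene.id)

    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            parents = [p.id for p in db.parents(tx, featuretype="gene")]
            if not parents:
                warnings.append(f"transcript {tx.id} without a gene parent")
            exons = sorted(
                (e.start, e.end) for e in db.children(tx, featuretype="exon")
            )
            clamped = []
            for start, end in exons:
                for gid in parents:
                    gseq, gstart, gend = gene_span[gid]
                    if start < gstart or end > gend:
                        warnings.append(
                            f"exon {tx.seqid}:{start}-{end} clamped to gene {gid}"
                        )
                        start, end = max(start, gstart), min(end, gend)
                clamped.append((start, end))
                tree(index.exons, tx.seqid).addi(start, end + 1)
            for (_, prev_end), (next_start, _) in zip(clamped, clamped[1:]):
                if next_start > prev_end + 1:
                    tree(index.introns, tx.seqid).addi(prev_end + 1, next_start)

    for cds in db.features_of_type("CDS"):
        tree(index.cds, cds.seqid).addi(cds.start, cds.end + 1)
        # CDS positions are exonic by definition
        tree(index.exons, cds.seqid).addi(cds.start, cds.end + 1)

    # orphan exons (no transcript parent) still define exonic positions
    for exon in db.features_of_type("exon"):
        if not any(True for _ in db.parents(exon, featuretype=("mRNA", "transcript"))):
            tree(index.exons, exon.seqid).addi(exon.start, exon.end + 1)

    for store in (index.genes, index.exons, index.cds, index.introns):
        for t in store.values():
            t.merge_overlaps(strict=False)
    return index


def locate(
    seq_id: str,
    start: int,
    end: int,
    index: FeatureIndex,
    *,
    missing: str = "error",
) -> RegionCall:
    """Compartment call for one locus interval by its start position.

    ``missing`` controls behaviour for sequences absent from the index:
    ``"error"`` raises; ``"intergenic"`` records a warning and calls the
    locus intergenic (useful for unannotated scaffolds).
    """
    if not index.has_seq(seq_id) and seq_id not in index.exons:
        if missing == "error":
            raise KeyError(f"sequence {seq_id!r} is not present in the feature index")
        index.warnings.append(f"unindexed sequence {seq_id!r} treated as intergenic")
        return RegionCall(seq_id, start, end, frozenset({"intergenic"}))

    labels: set[str] = set()
    point = start
    if seq_id in index.cds and index.cds[seq_id].overlaps(point, point + 1):
        labels.update({"CDS", "exon"})
    elif seq_id in index.exons and index.exons[seq_id].overlaps(point, point + 1):
        labels.add("exon")
    elif seq_id in index.introns and index.introns[seq_id].overlaps(point, point + 1):
        labels.add("intron")

    in_gene = seq_id in index.genes and index.genes[seq_id].overlaps(point, point + 1)
    if not in_gene and not labels:
        labels.add("intergenic")
    return RegionCall(seq_id, start, end, frozenset(labels))


def locate_all(
    loci: Iterable, index: FeatureIndex, *, missing: str = "error"
) -> list[RegionCall]:
    """Vector form of :func:`locate` over locus objects with
    seq_id/start/end attributes."""
    return [
        locate(l.seq_id, l.start, l.end, index, missing=missing) for l in loci
    ]


def region_tally(
    loci: Sequence, calls: Sequence[RegionCall]
) -> pd.DataFrame:
    """Per-compartment counts, proportions and total bp by unit length.

    Compartment membership follows the call labels, so CDS loci contribute
    to both the CDS and exon rows (exon is a superset of CDS positions);
    intergenic is exclusive.  Proportions are within-compartment and sum to
    1 where the compartment is non-empty; empty compartments report missing
    (NaN) proportions rather than zero.
    """
    if len(loci) != len(calls):
        raise ValueError("loci and calls must align one-to-one")
    rows = []
    for compartment in COMPARTMENTS:
        counts = {k: 0 for k in range(1, 7)}
        total_bp = 0
        n = 0
        for locus, call in zip(loci, calls):
            if compartment not in call.labels:
                continue
            k = getattr(locus, "unit_length", None)
            if k in counts:
                counts[k] += 1
            n += 1
            total_bp += locus.length
        for k in range(1, 7):
            rows.append(
                {
                    "compartment": compartment,
                    "unit_length": k,
                    "count": counts[k],
                    "proportion": counts[k] / n if n else float("nan"),
                    "compartment_loci": n,
                    "compartment_bp": total_bp,
                }
            )
    return pd.DataFrame(rows)


def write_calls_tsv(path: str | Path, loci: Sequence, calls: Sequence[RegionCall]) -> None:
    """Write one row per locus: coordinates, labels, and primary compartment."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tlabels\tprimary\n")
        for locus, call in zip(loci, calls):
            labels = ",".join(sorted(call.labels))
            fh.write(
                f"{locus.seq_id}\t{locus.start}\t{locus.end}\t{labels}\t{call.primary}\n"
            )


def read_calls_tsv(path: str | Path) -> list[RegionCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            calls.append(
                RegionCall(
                    rec["seq_id"], int(rec["start"]), int(rec["end"]),
                    frozenset(rec["labels"].split(",")) if rec["labels"] else frozenset(),
                )
            )
    return calls
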