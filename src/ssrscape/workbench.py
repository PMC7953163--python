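"""End-to-end pipeline orchestration: scan -> annotate -> stats -> enrich.

A run is described by a :class:`RunConfig` (loadable from TOML) pointing at
an organism metadata TSV with columns ``organism_id``, ``clade``, ``fasta``
and optionally ``gff3`` (paths relative to the metadata file).  The
pipeline scans every genome, classifies loci into genic compartments where
annotation exists, writes per-organism summaries, the cross-organism panel
table, the enrichment score matrix, the clade-specificity report and
genome-size correlations, and finishes with a manifest of input paths,
parameters and content digests so identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, enrich, scan, stats
from .scan import ScanParams

logger = logging.getLogger("ssrscape")


@dataclass
class RunConfig:
    metadata: Path
    outdir: Path
    params: ScanParams = field(default_factory=ScanParams)
    presence_threshold: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        base = path.parent
        params_data = data.get("params", {})
        if "min_repeats" in params_data:
            params_data["min_repeats"] = {
                int(k): int(v) for k, v in params_data["min_repeats"].items()
            }
        return cls(
            metadata=base / data["metadata"],
            outdir=base / data.get("outdir", "results"),
            params=ScanParams(**params_data),
            presence_threshold=int(data.get("presence_threshold", 10)),
            seed=int(data.get("seed", 0)),
            log_level=data.get("log_level", "INFO"),
        )

    def to_toml(self, path: str | Path) -> None:
        """Round-trippable TOML dump (paths relative to the file)."""
        path = Path(path)
        p = self.params
        mr = ", ".join(f'"{k}" = {v}' for k, v in sorted(p.min_repeats.items()))
        text = (
            f'metadata = "{self.metadata}"\n'
            f'outdir = "{self.outdir}"\n'
            f"presence_threshold = {self.presence_threshold}\n"
            f"seed = {self.seed}\n"
            f'log_level = "{self.log_level}"\n\n'
            "[params]\n"
            f"dmax = {p.dmax}\n"
            f"issr_seed_min_repeats = {p.issr_seed_min_repeats}\n"
            f"issr_seed_min_length = {p.issr_seed_min_length}\n"
            f"issr_max_consecutive_edits = {p.issr_max_consecutive_edits}\n"
            f"issr_match_score = {p.issr_match_score}\n"
            f"issr_substitution_penalty = {p.issr_substitution_penalty}\n"
            f"issr_gap_penalty = {p.issr_gap_penalty}\n"
            f"issr_min_score = {p.issr_min_score}\n"
            f"issr_min_length = {p.issr_min_length}\n\n"
            "[params.min_repeats]\n"
            + "\n".join(f'"{k}" = {v}' for k, v in sorted(p.min_repeats.items()))
            + "\n"
        )
        path.write_text(text)


class StageError(RuntimeError):
    """A pipeline stage failed for a specific organism."""

    def __init__(self, stage: str, organism: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for organism {organism!r}: {cause}")
        self.stage = stage
        self.organism = organism
        self.cause = cause


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"organism_id", "clade", "fasta"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta


def validate_inputs(config: RunConfig) -> list[str]:
    """Pre-flight report: unreadable files, FASTA/GFF3 seq_id mismatches,
    incomplete metadata rows.  Returns a list of problems (empty = clean)."""
    problems: list[str] = []
    try:
        meta = read_metadata(config.metadata)
    except Exception as exc:
        return [f"metadata: {exc}"]
    base = config.metadata.parent
    for _, row in meta.iterrows():
        org = row.get("organism_id") or "<missing id>"
        if not row.get("organism_id"):
            problems.append("metadata row without organism_id")
        fasta = base / str(row["fasta"])
        if not fasta.exists():
            problems.append(f"{org}: FASTA not found: {fasta}")
            continue
        try:
            seq_ids = {rec.seq_id for rec in scan.read_fasta(fasta)}
        except Exception as exc:
            problems.append(f"{org}: unreadable FASTA: {exc}")
            continue
        if not seq_ids:
            problems.append(f"{org}: FASTA contains no sequences")
        gff = row.get("gff3")
        if gff and str(gff) not in ("", "nan"):
            gff_path = base / str(gff)
            if not gff_path.exists():
                problems.append(f"{org}: GFF3 not found: {gff_path}")
                continue
            try:
                index = annotate.build_feature_index(gff_path)
            except Exception as exc:
                problems.append(f"{org}: unreadable GFF3: {exc}")
                continue
            orphan = index.seq_ids() - seq_ids
            if orphan:
                problems.append(
                    f"{org}: GFF3 references sequences absent from FASTA: "
                    f"{sorted(orphan)}"
                )
    return problems


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for every organism; returns the manifest dict."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s [%(message)s]",
    )
    meta = read_metadata(config.metadata)
    base = config.metadata.parent
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summaries: list[stats.GenomeSummary] = []
    frequencies: dict[str, pd.Series] = {}
    clade_map: dict[str, str] = {}
    genome_sizes: dict[str, int] = {}
    outputs: list[Path] = []

    for _, row in meta.iterrows():
        org = str(row["organism_id"])
        clade = str(row["clade"])
        clade_map[org] = clade
        fasta = base / str(row["fasta"])
        logger.info("scan: %s", org)
        try:
            records = list(scan.read_fasta(fasta))
            perfect, compounds, imperfect = scan.scan_all(records, config.params)
        except Exception as exc:
            raise StageError("scan", org, exc) from exc
        loci_path = outdir / f"{org}.loci.tsv"
        scan.write_loci_tsv(loci_path, perfect, compounds, imperfect, config.params)
        outputs.append(loci_path)

        gff = row.get("gff3")
        if gff and str(gff) not in ("", "nan"):
            logger.info("annotate: %s", org)
            try:
                index = annotate.build_feature_index(base / str(gff))
                all_loci = sorted(
                    [*perfect, *compounds, *imperfect],
                    key=lambda l: (l.seq_id, l.start),
                )
                calls = annotate.locate_all(all_loci, index, missing="intergenic")
            except Exception as exc:
                raise StageError("annotate", org, exc) from exc
            calls_path = outdir / f"{org}.calls.tsv"
            annotate.write_calls_tsv(calls_path, all_loci, calls)
            outputs.append(calls_path)
            tally_path = outdir / f"{org}.region_tally.tsv"
            annotate.region_tally(all_loci, calls).to_csv(
                tally_path, sep="\t", index=False, float_format="%.6g"
            )
            outputs.append(tally_path)

        logger.info("stats: %s", org)
        try:
            effective = sum(r.effective_length for r in records)
            summary = stats.summarize_genome(
                org, clade, effective, perfect, compounds, imperfect
            )
        except Exception as exc:
            raise StageError("stats", org, exc) from exc
        summaries.append(summary)
        frequencies[org] = summary.class_frequency
        genome_sizes[org] = effective
        summary_path = outdir / f"{org}.summary.tsv"
        stats.write_summary_tsv(summary_path, summary)
        outputs.append(summary_path)

    logger.info("panel: %d organisms", len(summaries))
    panel_path = outdir / "panel.tsv"
    stats.write_panel_tsv(panel_path, summaries)
    outputs.append(panel_path)

    matrix = enrich.build_matrix(summaries)
    matrix_path = outdir / "score_matrix.tsv"
    enrich.write_matrix_tsv(matrix_path, matrix)
    outputs.append(matrix_path)

    report = enrich.clade_specific(
        frequencies, clade_map, config.presence_threshold
    )
    clade_path = outdir / "clade_specific.tsv"
    enrich.write_clade_report_tsv(clade_path, report)
    outputs.append(clade_path)

    correlations: dict[str, stats.CorrelationResult] = {}
    if len(summaries) >= 3:
        sizes = [genome_sizes[s.organism_id] for s in summaries]
        for name, values in (
            ("genome_size_vs_ssr_count", [s.total_ssr_count for s in summaries]),
            ("genome_size_vs_ssr_bp", [s.total_ssr_bp for s in summaries]),
        ):
            try:
                correlations[name] = stats.correlate(sizes, values)
            except ValueError:
                logger.info("correlation %s undefined for this panel", name)
    corr_path = outdir / "correlations.tsv"
    stats.write_correlations_tsv(corr_path, correlations)
    outputs.append(corr_path)

    manifest = {
        "metadata": str(config.metadata),
        "params": config.params.echo(),
        "presence_threshold": config.presence_threshold,
        "seed": config.seed,
        "organisms": [str(o) for o in meta["organism_id"]],
        "outputs": {p.name: _digest(p) for p in sorted(outputs)},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
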