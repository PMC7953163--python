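"""Synthetic-genome generator: determinism, truth consistency, panels."""

import numpy as np
import pytest

from ssrscape import annotate, scan, synth
from ssrscape.scan import ScanParams
from ssrscape.synth import (
    CladeSpec,
    PanelSpec,
    PlantSpec,
    SizingError,
    derive_seed,
    generate_annotation,
    generate_genome,
    generate_panel,
    validate_fixture,
)


def test_determinism_same_seed_same_fasta(small_genome):
    spec, records, truth = small_genome
    records2, truth2 = generate_genome(spec, "small")
    assert [r.residues for r in records2] == [r.residues for r in records]
    assert truth2 == truth


def test_different_seeds_differ():
    a = PlantSpec(seed=1, sequence_length=20_000, n_perfect=5, n_compound=1, n_imperfect=2)
    b = PlantSpec(seed=2, sequence_length=20_000, n_perfect=5, n_compound=1, n_imperfect=2)
    ra, _ = generate_genome(a)
    rb, _ = generate_genome(b)
    assert ra[0].residues != rb[0].residues


def test_planted_text_realized_verbatim(small_genome):
    spec, records, truth = small_genome
    seqs = {r.seq_id: r.residues for r in records}
    for t in truth:
        if t.category == "P":
            assert seqs[t.seq_id][t.start - 1 : t.end] == t.motif * t.repeats
        elif t.category == "C":
            for ms, me, motif, copies in t.members:
                assert seqs[t.seq_id][ms - 1 : me] == motif * copies


def test_truth_sorted_non_overlapping(small_genome):
    _, _, truth = small_genome
    for a, b in zip(truth, truth[1:]):
        if a.seq_id == b.seq_id:
            assert b.start > a.end


def test_validator_passes_clean_fixture(small_genome):
    spec, records, truth = small_genome
    assert validate_fixture(records, truth, spec.params) == []


def test_validator_flags_corruption(small_genome):
    spec, records, truth = small_genome
    first_p = next(t for t in truth if t.category == "P")
    seq = records[0].residues if records[0].seq_id == first_p.seq_id else records[1].residues
    broken = seq[: first_p.start] + "G" * 3 + seq[first_p.start + 3 :]
    corrupted = [
        scan.SequenceRecord(r.seq_id, broken if r.seq_id == first_p.seq_id else r.residues)
        for r in records
    ]
    assert validate_fixture(corrupted, truth, spec.params) != []


def test_background_gc_envelope():
    spec = PlantSpec(
        seed=99, n_sequences=1, sequence_length=300_000, gc=0.40,
        n_perfect=0, n_compound=0, n_imperfect=0, n_block_rate=0.0,
    )
    records, truth = generate_genome(spec)
    assert truth == []
    seq = records[0].residues
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    # binomial SE at n=3e5 is ~0.0009; allow a generous envelope
    assert abs(gc - 0.40) < 0.008


def test_sizing_error():
    spec = PlantSpec(seed=1, n_sequences=1, sequence_length=500, n_perfect=50)
    with pytest.raises(SizingError):
        generate_genome(spec)


def test_n_blocks_reduce_effective_length():
    spec = PlantSpec(
        seed=13, n_sequences=1, sequence_length=100_000, n_block_rate=10.0,
        n_perfect=10, n_compound=2, n_imperfect=2,
    )
    records, _ = generate_genome(spec)
    r = records[0]
    assert r.effective_length < len(r.residues)
    assert "N" in r.residues


def test_annotation_round_trip(small_genome):
    spec, records, truth = small_genome
    gff3 = generate_annotation(records, truth)
    path_free_cases = {"CDS": 0, "exon": 0, "intron": 0, "intergenic": 0}
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "t.gff3"
        path.write_text(gff3)
        index = annotate.build_feature_index(path)
        for t in truth:
            call = annotate.locate(t.seq_id, t.start, t.end, index)
            if t.compartment == "CDS":
                assert "CDS" in call.labels, t
            elif t.compartment == "exon":
                assert "exon" in call.labels and "CDS" not in call.labels, t
            elif t.compartment == "intron":
                assert call.labels == {"intron"}, t
            else:
                assert call.labels == {"intergenic"}, t
            path_free_cases[t.compartment] += 1
    # the compartment plan actually exercised more than one compartment
    assert sum(1 for v in path_free_cases.values() if v > 0) >= 3


def test_derive_seed_stable_and_bounded():
    assert derive_seed(42, "org1") == derive_seed(42, "org1")
    assert derive_seed(42, "org1") != derive_seed(42, "org2")
    assert 0 <= derive_seed(42, "x") < 2**31


def test_spacers_free_of_qualifying_loci(small_genome, params):
    """Regions outside planted loci contain no perfect loci at all."""
    spec, records, truth = small_genome
    planted = {}
    for t in truth:
        planted.setdefault(t.seq_id, []).append((t.start, t.end))
    for r in records:
        for p in scan.find_perfect(r, params):
            spans = planted[r.seq_id]
            assert any(s <= p.start and p.end <= e for s, e in spans), p


def test_panel_structure(small_panel):
    panel, fixtures = small_panel
    assert len(fixtures) == 4
    assert {f.clade for f in fixtures} == {"monodom", "didom"}
    ids = [f.organism_id for f in fixtures]
    assert len(set(ids)) == 4
    seqs = {f.organism_id: f.records[0].residues for f in fixtures}
    assert seqs["monodom_1"] != seqs["monodom_2"]


def test_panel_exclusive_classes_planted(small_panel):
    panel, fixtures = small_panel
    for f in fixtures:
        planted = {t.canonical for t in f.truth if t.category == "P"}
        if f.clade == "didom":
            assert "AACGTC" in planted
            n = sum(t.canonical == "AACGTC" for t in f.truth)
            assert n >= 12
        else:
            assert "AACGTC" not in planted


def test_panel_determinism(small_panel):
    panel, fixtures = small_panel
    again = generate_panel(panel)
    for a, b in zip(fixtures, again):
        assert a.organism_id == b.organism_id
        assert [r.residues for r in a.records] == [r.residues for r in b.records]


def test_write_panel_outputs(tmp_path, small_panel):
    _, fixtures = small_panel
    meta_path = synth.write_panel(tmp_path, fixtures[:2])
    import pandas as pd

    meta = pd.read_csv(meta_path, sep="\t")
    assert list(meta.columns[:3]) == ["organism_id", "clade", "genome_bp"]
    for _, row in meta.iterrows():
        assert (tmp_path / row["fasta"]).exists()
        assert (tmp_path / row["gff3"]).exists()
        assert (tmp_path / row["truth"]).exists()
    # FASTA round-trips through the scanner reader
    records = list(scan.read_fasta(tmp_path / meta.iloc[0]["fasta"]))
    assert records[0].seq_id.startswith(meta.iloc[0]["organism_id"])
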