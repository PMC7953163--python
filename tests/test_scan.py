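"""Scanner semantics: masking, perfect/compound/imperfect detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrscape import scan
from ssrscape.motifspace import revcomp
from ssrscape.oracle import brute_force_perfect
from ssrscape.scan import (
    CompoundSSR,
    PerfectSSR,
    ScanParams,
    SequenceRecord,
    find_compound,
    find_imperfect,
    find_perfect,
    mask_windows,
)
from ssrscape.synth import _certified_spacer


def rec(seq: str, seq_id: str = "s") -> SequenceRecord:
    return SequenceRecord(seq_id, seq)


def keyed(loci):
    return [(p.start, p.end, p.motif, p.repeats) for p in loci]


# ---------------------------------------------------------------------------
# masking


@pytest.mark.parametrize(
    "seq,windows",
    [
        ("ACGT", [(1, 4)]),
        ("ACNNGT", [(1, 2), (5, 6)]),
        ("NNNN", []),
        ("NACGTN", [(2, 5)]),
    ],
)
def test_mask_windows(seq, windows):
    r = rec(seq)
    assert mask_windows(r) == windows
    assert sum(e - s + 1 for s, e in windows) == r.effective_length


def test_iupac_codes_collapse_to_n():
    r = rec("ACRYGT")
    assert r.residues == "ACNNGT"


# ---------------------------------------------------------------------------
# perfect


def test_find_perfect_examples(params):
    assert keyed(find_perfect(rec("G" + "A" * 12 + "G"), params)) == [
        (2, 13, "A", 12)
    ]
    assert find_perfect(rec("AC" * 6), params) == []
    # trailing partial unit excluded
    assert keyed(find_perfect(rec("AC" * 7 + "A"), params)) == [(1, 14, "AC", 7)]


def test_find_perfect_respects_n_mask(params):
    seq = "A" * 6 + "N" + "A" * 6
    assert find_perfect(rec(seq), params) == []
    seq = "A" * 12 + "N" + "A" * 12
    assert keyed(find_perfect(rec(seq), params)) == [
        (1, 12, "A", 12),
        (14, 25, "A", 12),
    ]


def test_find_perfect_substring_identity(params):
    seq = "GG" + "AGC" * 6 + "TT" + "ATTT" * 5 + "C"
    r = rec(seq)
    loci = find_perfect(r, params)
    assert len(loci) == 2
    for p in loci:
        assert seq[p.start - 1 : p.end] == p.motif * p.repeats
        assert p.length == p.unit_length * p.repeats


def test_find_perfect_shortest_unit_wins_at_equal_start(params):
    # A*24 is also (AA)x12 etc.; the primitive mono unit must win
    loci = find_perfect(rec("A" * 24), params)
    assert keyed(loci) == [(1, 24, "A", 24)]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_oracle_equivalence_random(seed):
    """Production scanner is locus-identical to the brute-force reference
    on random sequences with occasional planted repeats."""
    params = ScanParams()
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), size=800, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    if seed % 2:
        pos = int(rng.integers(0, 700))
        seq = seq[:pos] + "TA" * 8 + seq[pos:]
    r = rec(seq)
    got = keyed(find_perfect(r, params))
    want = keyed(brute_force_perfect(seq, min_repeats=params.min_repeats))
    assert got == want


def test_reverse_complement_covariance(params):
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    seq = seq[:1000] + "GT" * 9 + seq[1000:2000] + "TTTAA" * 5 + seq[2000:]
    fwd = find_perfect(rec(seq), params)
    bwd = find_perfect(rec(revcomp(seq)), params)
    n = len(seq)
    mirrored = sorted(
        (n - p.end + 1, n - p.start + 1, p.canonical, p.repeats) for p in bwd
    )
    forward = sorted((p.start, p.end, p.canonical, p.repeats) for p in fwd)
    assert len(mirrored) == len(forward)
    for (ms, me, mc, mr), (fs, fe, fc, fr) in zip(mirrored, forward):
        # greedy leftmost starts may differ by a sub-unit phase shift
        # when a flanking base continues the pattern on one strand only
        assert (mc, mr) == (fc, fr)
        assert abs(ms - fs) < len(mc) and abs(me - fe) < len(mc)


def test_loci_sorted_non_overlapping(params):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    seq = seq[:500] + "A" * 13 + seq[500:1500] + "ACG" * 7 + seq[1500:]
    loci = find_perfect(rec(seq), params)
    assert loci == sorted(loci, key=lambda p: p.start)
    for a, b in zip(loci, loci[1:]):
        assert b.start > a.end


# ---------------------------------------------------------------------------
# compound


def _p(start, motif, repeats, seq_id="s"):
    k = len(motif)
    return PerfectSSR(seq_id, start, start + k * repeats - 1, motif, motif, repeats)


def test_find_compound_merges_within_dmax():
    loci = [_p(1, "A", 12), _p(15, "AC", 7)]
    compounds, rest = find_compound(loci, dmax=10)
    assert rest == []
    assert len(compounds) == 1
    assert compounds[0].gaps == (2,)
    assert compounds[0].start == 1 and compounds[0].end == 28


def test_find_compound_respects_dmax():
    loci = [_p(1, "A", 12), _p(15, "AC", 7)]
    compounds, rest = find_compound(loci, dmax=1)
    assert compounds == [] and len(rest) == 2


def test_find_compound_transitive_merge():
    loci = [_p(1, "A", 12), _p(16, "AC", 7), _p(34, "AAG", 5)]
    # gaps: 16-12-1=3 and 34-29-1=4
    compounds, rest = find_compound(loci, dmax=5)
    assert rest == []
    assert len(compounds) == 1 and len(compounds[0].members) == 3
    assert compounds[0].gaps == (3, 4)


def test_find_compound_rejects_bad_input():
    with pytest.raises(ValueError, match="sorted"):
        find_compound([_p(100, "A", 12), _p(1, "AC", 7)], dmax=10)
    with pytest.raises(ValueError, match="overlap"):
        find_compound([_p(1, "A", 12), _p(5, "AC", 7)], dmax=10)


def test_categories_disjoint_after_compounding(params):
    seq = "G" * 30 + "A" * 12 + "CG" + "AC" * 7 + "G" * 30 + "TTA" * 6 + "G" * 30
    perfect = find_perfect(rec(seq), params)
    compounds, rest = find_compound(perfect, params.dmax)
    member_keys = {(m.start, m.end) for c in compounds for m in c.members}
    rest_keys = {(p.start, p.end) for p in rest}
    assert member_keys.isdisjoint(rest_keys)
    assert len(member_keys) + len(rest_keys) == len(perfect)


# ---------------------------------------------------------------------------
# imperfect


def test_find_imperfect_insertion(params):
    seq = "AC" * 5 + "G" + "AC" * 5
    loci = find_imperfect(rec(seq), params)
    assert len(loci) == 1
    i = loci[0]
    assert (i.start, i.end) == (1, 21)
    assert (i.substitutions, i.insertions, i.deletions) == (0, 1, 0)
    assert i.score == 10 * params.issr_match_score * 2 - params.issr_gap_penalty


def test_find_imperfect_needs_an_edit(params):
    assert find_imperfect(rec("AC" * 10), params) == []


def test_find_imperfect_substitution(params):
    seq = "ACT" * 4 + "G" + "CT" + "ACT" * 4  # one substituted base mid-array
    loci = find_imperfect(rec(seq), params)
    assert len(loci) == 1
    assert loci[0].edits == 1
    assert (loci[0].start, loci[0].end) == (1, len(seq))


def test_find_imperfect_empty_on_certified_background(params):
    """A rejection-checked spacer of 1 kb yields no imperfect loci."""
    rng = np.random.default_rng(4242)
    spacer = _certified_spacer(rng, 1000, 0.42).tobytes().decode()
    assert find_imperfect(rec(spacer), params) == []
    assert find_perfect(rec(spacer), params) == []


def test_imperfect_loci_do_not_overlap(params):
    seq = ("AC" * 5 + "G" + "AC" * 5 + "TGTGATTGCGTAGCAATGCCA") * 3
    loci = find_imperfect(rec(seq), params)
    for a, b in zip(loci, loci[1:]):
        assert b.start > a.end
    for locus in loci:
        assert locus.edits >= 1


# ---------------------------------------------------------------------------
# I/O round trip


def test_loci_tsv_round_trip(tmp_path, params):
    seq = (
        "G" * 30 + "A" * 12 + "CG" + "AC" * 7 + "G" * 30
        + "AC" * 5 + "T" + "AC" * 5 + "GATGCCAGTAAGGCAT" * 3
    )
    r = rec(seq, "chr1")
    perfect, compounds, imperfect = scan.scan_all([r], params)
    out = tmp_path / "loci.tsv"
    scan.write_loci_tsv(out, perfect, compounds, imperfect, params)
    text = out.read_text()
    assert text.startswith("##params=")
    p2, c2, i2 = scan.read_loci_tsv(out)
    assert keyed(p2) == keyed(perfect)
    assert [(c.start, c.end, len(c.members)) for c in c2] == [
        (c.start, c.end, len(c.members)) for c in compounds
    ]
    assert [(i.start, i.end, i.edits) for i in i2] == [
        (i.start, i.end, i.edits) for i in imperfect
    ]


def test_scan_params_validation():
    with pytest.raises(ValueError):
        ScanParams(min_repeats={1: 0, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4})
    with pytest.raises(ValueError):
        ScanParams(issr_gap_penalty=-1)
    p = ScanParams().with_overrides(dmax=3)
    assert p.dmax == 3
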