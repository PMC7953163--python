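"""Rank-score banding and clade-specific motif detection."""

import numpy as np
import pandas as pd
import pytest

from ssrscape import enrich, stats
from ssrscape.motifspace import class_order
from ssrscape.enrich import build_matrix, clade_specific, rank_scores

NAMES = class_order()


def oracle_scores(density, frequency, names):
    """Straightforward independent re-implementation of the banding rule."""
    scores = {}
    eligible = []
    for i, name in enumerate(names):
        if frequency[i] < 10:
            scores[name] = -2
        else:
            eligible.append(((-density[i], name), name))
    eligible.sort()
    ordered = [name for _, name in eligible]
    for rank, name in enumerate(ordered, start=1):
        if rank <= 5:
            scores[name] = 3
        elif rank <= 20:
            scores[name] = 2
        elif rank <= 35:
            scores[name] = 1
        else:
            scores[name] = 0
    for name in ordered[-20:]:
        if scores[name] == 0:
            scores[name] = -1
    return np.array([scores[n] for n in names])


def test_frequency_floor_overrides_density():
    density = np.zeros(501)
    frequency = np.full(501, 50)
    density[0] = 1e9  # highest density of all ...
    frequency[0] = 9  # ... but frequency below 10
    scores = rank_scores(density, frequency)
    assert scores[0] == -2


def test_rank_bands():
    density = np.arange(501, 0, -1, dtype=float)  # strictly decreasing
    frequency = np.full(501, 100)
    scores = rank_scores(density, frequency)
    assert list(scores[:5]) == [3] * 5
    assert list(scores[5:20]) == [2] * 15
    assert list(scores[20:35]) == [1] * 15
    assert scores[24] == 1  # rank 25
    assert list(scores[35:481]) == [0] * 446
    assert list(scores[481:]) == [-1] * 20


def test_sixty_eligible_classes():
    """With 60 surviving classes: ranks 36-40 score 0, ranks 41-60 score -1."""
    density = np.zeros(501)
    frequency = np.zeros(501, dtype=int)
    density[:60] = np.arange(60, 0, -1, dtype=float)
    frequency[:60] = 10
    scores = rank_scores(density, frequency)
    assert list(scores[35:40]) == [0] * 5
    assert list(scores[40:60]) == [-1] * 20
    assert list(scores[60:]) == [-2] * 441


@pytest.mark.parametrize("seed", range(25))
def test_matches_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    density = rng.gamma(0.5, 200, size=501).round(3)
    frequency = rng.poisson(12, size=501)
    got = rank_scores(density, frequency, NAMES)
    want = oracle_scores(density, frequency, NAMES)
    assert (got == want).all()


def test_band_cardinality_invariants_on_random_panels():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        density = rng.gamma(0.4, 300, size=501)
        frequency = rng.poisson(rng.uniform(2, 40), size=501)
        scores = rank_scores(density, frequency, NAMES)
        counts = {v: int((scores == v).sum()) for v in (3, 2, 1, 0, -1, -2)}
        assert counts[3] <= 5
        assert counts[2] <= 15
        assert counts[1] <= 15
        assert counts[-1] <= 20
        assert (scores[np.asarray(frequency) < 10] == -2).all()
        assert sum(counts.values()) == 501


def test_scale_invariance():
    rng = np.random.default_rng(7)
    density = rng.gamma(1.0, 10, size=501)
    frequency = rng.poisson(15, size=501)
    base = rank_scores(density, frequency, NAMES)
    assert (rank_scores(density * 37.5, frequency, NAMES) == base).all()


def test_order_equivariance():
    rng = np.random.default_rng(8)
    density = rng.gamma(1.0, 10, size=501)
    frequency = rng.poisson(15, size=501)
    base = rank_scores(density, frequency, NAMES)
    perm = rng.permutation(501)
    permuted_names = [NAMES[i] for i in perm]
    permuted = rank_scores(density[perm], frequency[perm], permuted_names)
    inverse = np.empty(501, dtype=int)
    inverse[perm] = np.arange(501)
    assert (permuted[inverse] == base).all()


def test_vector_length_checked():
    with pytest.raises(ValueError):
        rank_scores(np.zeros(500), np.zeros(500))


def _summary(org, clade, freq_map, genome_bp=1_000_000):
    freq = pd.Series(0, index=NAMES, dtype=int)
    bp = pd.Series(0.0, index=NAMES)
    for rep, count in freq_map.items():
        freq[rep] = count
        bp[rep] = count * 3 * len(rep)
    return stats.GenomeSummary(
        organism_id=org, clade=clade, effective_genome_bp=genome_bp,
        category_counts={"P": int(freq.sum()), "C": 0, "I": 0},
        category_bp={"P": int(bp.sum()), "C": 0, "I": 0},
        class_frequency=freq, class_density=bp / (genome_bp / 1e6),
        unit_counts={}, unit_proportions={}, unit_gc_percent={}, unit_rcns={},
    )


def test_build_matrix_single_organism():
    s = _summary("o1", "x", {"A": 50, "AC": 30, "AG": 9})
    m = build_matrix([s])
    expected = rank_scores(s.class_density.to_numpy(), s.class_frequency.to_numpy())
    assert list(m.loc["o1"]) == list(expected)
    assert list(m.columns) == NAMES


def test_build_matrix_identical_summaries_identical_rows():
    s1 = _summary("o1", "x", {"A": 50, "AC": 30})
    s2 = _summary("o2", "x", {"A": 50, "AC": 30})
    m = build_matrix([s1, s2])
    assert (m.loc["o1"] == m.loc["o2"]).all()
    assert list(m.index) == ["o1", "o2"]


def test_build_matrix_column_ordering():
    s = _summary("o1", "x", {"AC": 100, "A": 12})
    m = build_matrix([s], order_columns=True)
    assert m.columns[0] in {"A", "AC"}
    assert set(m.columns) == set(NAMES)


def test_clade_specific_basic():
    freqs = {
        "a1": {"AACGTC": 12, "A": 50},
        "a2": {"A": 40},
        "b1": {"A": 60},
        "b2": {"A": 55},
    }
    clades = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    report = clade_specific(freqs, clades, presence_threshold=10)
    specific = {(r.clade, r.canonical): r for r in report}
    assert ("A", "AACGTC") in specific
    assert specific[("A", "AACGTC")].carriers == ("a1",)
    # A is present everywhere -> not specific
    assert not any(r.canonical == "A" for r in report)


def test_clade_specific_two_clades_excluded():
    freqs = {"a1": {"AAT": 15}, "b1": {"AAT": 20}}
    clades = {"a1": "A", "b1": "B"}
    assert clade_specific(freqs, clades, 10) == []


def test_clade_specific_boundary_threshold():
    """Frequency 9 elsewhere is below a threshold of 10: still specific."""
    freqs = {"a1": {"AAAC": 15}, "b1": {"AAAC": 9}, "b2": {}}
    clades = {"a1": "A", "b1": "B", "b2": "B"}
    report = clade_specific(freqs, clades, 10)
    assert [(r.clade, r.canonical) for r in report] == [("A", "AAAC")]
    assert report[0].max_frequency == 15


def test_clade_specific_reports_are_disjoint():
    rng = np.random.default_rng(3)
    orgs = {f"o{i}": f"C{i % 3}" for i in range(9)}
    freqs = {
        org: {NAMES[j]: int(rng.poisson(8)) for j in rng.integers(0, 501, size=40)}
        for org in orgs
    }
    report = clade_specific(freqs, orgs, 10)
    seen = {}
    for r in report:
        assert r.canonical not in seen
        seen[r.canonical] = r.clade


def test_clade_specific_requires_complete_clade_map():
    with pytest.raises(KeyError):
        clade_specific({"a1": {"A": 12}}, {}, 10)
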