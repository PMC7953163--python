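"""Shared fixtures: default parameters and reusable synthetic fixtures."""

from __future__ import annotations

import pytest

from ssrscape import synth
from ssrscape.scan import ScanParams


@pytest.fixture(scope="session")
def params() -> ScanParams:
    return ScanParams()


@pytest.fixture(scope="session")
def small_genome():
    """One 60 kb organism with all three locus categories planted."""
    spec = synth.PlantSpec(
        seed=20240901,
        n_sequences=2,
        sequence_length=30_000,
        n_perfect=16,
        n_compound=4,
        n_imperfect=6,
        n_block_rate=4.0,
    )
    records, truth = synth.generate_genome(spec, "small")
    return spec, records, truth


@pytest.fixture(scope="session")
def small_panel():
    """Two-clade, four-organism panel with annotation, 100 kb genomes."""
    panel = synth.PanelSpec(
        seed=77,
        clades=(
            synth.CladeSpec(
                "monodom", 2, 100_000,
                class_weights=dict(synth.MONO_DOMINANT_WEIGHTS),
            ),
            synth.CladeSpec(
                "didom", 2, 100_000,
                class_weights=dict(synth.DI_DOMINANT_WEIGHTS),
                exclusive_classes=("AACGTC",),
            ),
        ),
    )
    return panel, synth.generate_panel(panel)
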