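"""Shared fixtures: a fixed reference gene and a small simulated run.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import pytest

from umilink.simulate import (
    ErrorModel,
    LibraryConfig,
    generate_library,
    make_reference,
    simulate_reads,
)

# Codons pinned so that the canonical mutation names used across the tests
# (A64E, R102S, E323V, D308V) are realisable on this reference:
# GCA->GaA gives A->E, CGT->aGT gives R->S, GAA->GtA gives E->V, GAT->GtT D->V.
FORCED_CODONS = {64: "GCA", 102: "CGT", 323: "GAA", 308: "GAT"}


@pytest.fixture(scope="session")
def ref():
    """A 1248-bp reference gene (416 sense codons, no internal stops)."""
    return make_reference(n_codons=416, seed=5, forced_codons=FORCED_CODONS)


@pytest.fixture(scope="session")
def small_run(ref):
    """20 templates at 25x coverage, 10% read error; returns
    (templates, reads, config)."""
    cfg = LibraryConfig(n_templates=20, barcode="AAGGTTCCAAGGTTCCAAGGTTCC")
    templates = generate_library(ref, cfg, seed=11)
    reads = simulate_reads(templates, 25, ErrorModel(0.06, 0.02, 0.02, seed=12))
    return templates, reads, cfg
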