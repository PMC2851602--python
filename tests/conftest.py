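"""Shared fixtures: small seeded genomes and catalogs built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from chondriome import simulate as sim

# a spacer with stop codons in all six frames and no ATG; revcomp("CTAG"
# * k) is again a CTAG repeat, so planted-ORF fixtures stay clean on both
# strands
STOP_SPACER = "CTAG" * 30


@pytest.fixture(scope="session")
def small_reference():
    """40 kb repeat-free reference with 6 planted genes."""
    cfg = sim.SimConfig(seed=21, genome_length=40_000, n_repeat_pairs=0, n_genes=6)
    g, catalog, repeats = sim.simulate_reference(cfg)
    return g, catalog, repeats


@pytest.fixture(scope="session")
def midsize_reference():
    """100 kb repeat-free reference used by event-recovery tests."""
    cfg = sim.SimConfig(seed=5, genome_length=100_000, n_repeat_pairs=0, n_genes=8)
    g, catalog, repeats = sim.simulate_reference(cfg)
    return g, catalog, repeats


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
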