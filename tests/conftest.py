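"""Shared fixtures: simulated libraries and the synthetic genome.

Heavy simulations are session-scoped so the enrichment/discovery tests and
the acceptance tests share one library.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import bnsmotif as b
from bnsmotif.synthetic import (
    BnSCondition,
    SimulationConfig,
    default_selection_model,
    generate_bns_library,
    generate_synthetic_genome_and_peaks,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# probe sequences used in the published EMSA experiments (barcode + 21 nt region)
PROBE_P1 = "GAATTATCGGTAATCCATCGAGGT"
PROBE_P2 = "AGGGTTGGTATCGATTATCGAGTT"
PROBE_CP = "CAAAAGTGCGGCTGCGTGGTGCAC"

MIZM1 = "ATCGGTAATC"
MIZM2 = "ATCGAT"


@pytest.fixture(scope="session")
def library_100k():
    """100,000 retained reads under the default selection model at the
    moderate condition (50 nM protein, 50 mM salt), planted Mizm1."""
    cfg = SimulationConfig(
        seed=1234,
        conditions=[BnSCondition("ACC", 50.0, 50.0)],
        selection=default_selection_model(),
        n_background=1000,
        n_selected=100_000,
    )
    lib = generate_bns_library(cfg)
    return [r.region for r in lib.selected["ACC"]]


@pytest.fixture(scope="session")
def enrichment_100k(library_100k):
    table = b.count_kmers(library_100k, 10)
    return b.fold_enrichment(table)


@pytest.fixture(scope="session")
def library_20k():
    cfg = SimulationConfig(
        seed=77,
        conditions=[BnSCondition("ACC", 50.0, 50.0)],
        selection=default_selection_model(),
        n_background=1000,
        n_selected=20_000,
    )
    lib = generate_bns_library(cfg)
    return [r.region for r in lib.selected["ACC"]]


@pytest.fixture(scope="session")
def planted_reads():
    """500 reads, each carrying one exact Mizm1 instance in uniform flanks."""
    rng = np.random.default_rng(4)
    reads = []
    for _ in range(500):
        s = list("".join(rng.choice(list("ACGT"), 21)))
        off = int(rng.integers(0, 12))
        s[off : off + 10] = MIZM1
        reads.append("".join(s))
    return reads


@pytest.fixture(scope="session")
def synthetic_peak_data():
    return generate_synthetic_genome_and_peaks(
        seed=5, n_genes=30, n_peaks=400, motif=MIZM1, frac_motif_peaks=0.5, proximal_bias=0.9
    )
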