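"""Selection simulator and synthetic genome: determinism, retention-model
behavior, the non-monotone enrichment regime, and truth-table guarantees."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import bnsmotif as b
from bnsmotif.errors import UsageError
from bnsmotif.peaks import extract_peak_sequences
from bnsmotif.synthetic import (
    BnSCondition,
    SelectionModel,
    SimulationConfig,
    default_selection_model,
    generate_background_library,
    generate_bns_library,
    generate_synthetic_genome_and_peaks,
    table1_conditions,
)

from conftest import MIZM1


class TestBackgroundLibrary:
    def test_uniform_kmer_frequencies(self):
        n = 4096 * 100
        lib = generate_background_library(n, 6, seed=0)
        table = b.count_kmers(lib, 6, "forward_only")
        expected = n / 4096
        sd = math.sqrt(n * (1 / 4096) * (1 - 1 / 4096))
        worst = max(abs(c - expected) for c in table.counts.values())
        assert worst < 5 * sd
        assert len(table.counts) == 4096

    def test_deterministic_and_single(self):
        assert generate_background_library(50, 21, seed=3) == generate_background_library(
            50, 21, seed=3
        )
        (one,) = generate_background_library(1, 12, seed=9)
        assert len(one) == 12


class TestSelectionModel:
    def test_zero_protein_gives_no_specific_retention(self):
        m = default_selection_model()
        assert m.specific_retention(0.0, 0.0, 50.0) == 0.0
        assert m.nonspecific_retention(0.0, 50.0) == m.carryover

    @given(
        st.floats(0, 40),
        st.floats(0, 1000),
        st.floats(0, 500),
    )
    def test_retention_probabilities_bounded(self, deficit, protein, salt):
        m = default_selection_model()
        p = m.specific_retention(deficit, protein, salt) + m.nonspecific_retention(protein, salt)
        assert 0.0 <= min(p, 1.0) <= 1.0
        assert m.specific_retention(deficit, protein, salt) <= 1.0

    def test_wash_ordering_enforced(self):
        with pytest.raises(UsageError):
            SelectionModel(wash_decay_specific=0.05, wash_decay_nonspecific=0.01)

    def test_table1_conditions_have_unique_barcodes(self):
        conds = table1_conditions("FL") + table1_conditions("ZF")
        assert len({c.barcode for c in conds}) == 10


def _max_planted_fold(regions, k=10):
    table = b.count_kmers(regions, k)
    return b.neighborhood_max_enrichment(b.fold_enrichment(table), MIZM1)


class TestBnsLibrary:
    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(UsageError, match="unique"):
            SimulationConfig(
                seed=0,
                conditions=[BnSCondition("ACC", 50, 50), BnSCondition("ACC", 5, 50)],
                selection=default_selection_model(),
            )

    def test_carryover_only_pool_is_background_like(self):
        """With zero protein the retained pool reduces to pure carryover."""
        cfg = SimulationConfig(
            seed=8,
            conditions=[BnSCondition("ACC", 0.0, 50.0)],
            selection=default_selection_model(),
            n_background=1000,
            n_selected=20_000,
        )
        lib = generate_bns_library(cfg)
        regions = [r.region for r in lib.selected["ACC"]]
        recs = b.fold_enrichment(b.count_kmers(regions, 6), min_count=20)
        folds = np.array([r.fold_enrichment for r in recs])
        # all 6-mer enrichments within sampling noise of 1
        mean_count = 20_000 * 16 * 2 / 4096
        tol = 5 / math.sqrt(mean_count)
        assert abs(np.mean(folds) - 1) < 0.05
        assert np.percentile(folds, 99) < 1 + 4 * tol

    def test_specific_retention_monotone_in_protein(self):
        """alpha = eps = 0: every read's retention probability, and in
        particular that of consensus-bearing reads, is non-decreasing in
        protein concentration (occupancy rises toward saturation)."""
        m = default_selection_model(nonspecific_floor=0.0, carryover=0.0)
        for deficit in (0.0, 5.0, 15.0, 30.0):
            vals = [m.specific_retention(deficit, p, 20.0) for p in (0, 1, 5, 20, 80, 350, 2000)]
            assert vals == sorted(vals)
        # absolute yield from a fixed candidate pool rises with protein
        from bnsmotif.synthetic import _MotifScorer, _retention_probability

        rng = np.random.default_rng(15)
        mat = rng.integers(0, 4, size=(5000, 21), dtype=np.int8)
        scorers = [(_MotifScorer(mot), aff) for mot, aff in m.planted_motifs]
        yields = [
            _retention_probability(mat, scorers, m, p, 20.0).sum() for p in (5.0, 50.0, 350.0)
        ]
        assert yields == sorted(yields)

    def test_titration_closed_form_predicts_middle_peak(self):
        """Independent closed-form oracle for the 5/50/350 nM titration at
        100 mM salt: enrichment ~ retention(consensus read) / retention(bulk),
        evaluated from the model formulas directly."""
        m = default_selection_model()
        motif = m.planted_motifs[0][0]
        # background best-match distribution: P(best window has h matches)
        # for 48 window-strand trials of a width-10 consensus
        p_h = [
            math.comb(10, h) * 0.25**h * 0.75 ** (10 - h) for h in range(11)
        ]
        n_trials = 2 * 12
        cdf = np.cumsum(p_h)
        best_pmf = []
        for h in range(11):
            best_pmf.append(cdf[h] ** n_trials - (cdf[h - 1] ** n_trials if h else 0.0))
        S = motif.log_odds(pseudocount=0.1)
        delta_per_mismatch = float(S.max(axis=1)[0] - sorted(S[0])[1])
        preds = {}
        for protein in (5.0, 50.0, 350.0):
            spec_bulk = sum(
                w * m.specific_retention(delta_per_mismatch * (10 - h), protein, 100.0)
                for h, w in enumerate(best_pmf)
            )
            bulk = m.nonspecific_retention(protein, 100.0) + spec_bulk
            consensus_read = m.specific_retention(0.0, protein, 100.0) + m.nonspecific_retention(
                protein, 100.0
            )
            preds[protein] = consensus_read / bulk
        assert preds[50.0] > preds[5.0] and preds[50.0] > preds[350.0]

    def test_same_seed_identical_library(self):
        cfg = SimulationConfig(
            seed=5,
            conditions=[BnSCondition("ACC", 50, 50)],
            selection=default_selection_model(),
            n_background=200,
            n_selected=500,
        )
        a = generate_bns_library(cfg)
        c = generate_bns_library(cfg)
        assert a.background == c.background
        assert [r.region for r in a.selected["ACC"]] == [r.region for r in c.selected["ACC"]]


class TestSyntheticGenome:
    def test_truth_table_recovered_by_string_search(self, synthetic_peak_data):
        data = synthetic_peak_data
        seqs = extract_peak_sequences(data.peaks, data.genome)
        rc = b.reverse_complement(MIZM1)
        found = {pid: (MIZM1 in s or rc in s) for pid, s in seqs}
        truth = dict(zip(data.truth.peak_id, (bool(x) for x in data.truth.has_motif)))
        assert found == truth
        # planted peaks carry exactly one instance at the recorded offset
        by_id = dict(seqs)
        for row in data.truth.itertuples():
            if row.has_motif:
                s = by_id[row.peak_id]
                starts = [
                    i
                    for i in range(len(s) - 10 + 1)
                    if s[i : i + 10] in (MIZM1, rc)
                ]
                assert starts == [row.planted_offset]

    def test_boundary_bias_is_deterministic_split(self):
        data = generate_synthetic_genome_and_peaks(
            seed=2, n_genes=10, n_peaks=60, frac_motif_peaks=0.5, proximal_bias=1.0
        )
        for row in data.truth.itertuples():
            if row.has_motif:
                assert abs(row.true_tss_distance) > 1500
            else:
                assert abs(row.true_tss_distance) <= 1500

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        from bnsmotif.synthetic import write_synthetic_genome

        for d in ("a", "b"):
            data = generate_synthetic_genome_and_peaks(seed=11, n_genes=8, n_peaks=40)
            write_synthetic_genome(data, tmp_path / d)
        for name in ("genome.fa", "genes.tsv", "peaks.bed", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_impossible_layout_raises(self):
        from bnsmotif.errors import GenerationError

        with pytest.raises(GenerationError):
            generate_synthetic_genome_and_peaks(seed=0, n_genes=50, genome_length=100_000)
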