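"""Motif discovery: seeding arithmetic, ZOOPS EM behavior on planted and
null data, match-back thresholds, and the full pipeline's invariants."""

import numpy as np
import pytest

import bnsmotif as b
from bnsmotif.discovery import (
    DiscoveryConfig,
    best_window_scores,
    discover_motifs,
    em_zoops,
    match_back,
    seed_from_kmers,
)
from bnsmotif.enrichment import EnrichmentRecord
from bnsmotif.errors import UsageError
from bnsmotif.motifs import Motif
from bnsmotif.scanning import build_log_odds, null_score_distribution
from bnsmotif.synthetic import (
    BnSCondition,
    SelectionModel,
    SimulationConfig,
    generate_background_library,
    generate_bns_library,
)

from conftest import MIZM1, MIZM2


def _rec(kmer, fold=10.0):
    return EnrichmentRecord(kmer, 50, 1e-4, 1e-5, fold)


def _info_per_column(motif):
    p = motif.probs
    return float((2.0 + (p * np.log2(np.maximum(p, 1e-12))).sum(axis=1)).mean())


class TestSeeding:
    def test_seed_probabilities(self):
        (seed,) = seed_from_kmers([_rec("ATCGAT")], n_seeds=1, p0=0.7)
        np.testing.assert_allclose(seed.probs[0], [0.7, 0.1, 0.1, 0.1])
        np.testing.assert_allclose(seed.probs[1], [0.1, 0.1, 0.1, 0.7])
        assert seed.consensus == "ATCGAT"

    def test_more_seeds_than_records_uses_all(self):
        seeds = seed_from_kmers([_rec("ACGTAC"), _rec("TTTTTT", 5)], n_seeds=10)
        assert len(seeds) == 2

    def test_sharp_seed_keeps_consensus(self):
        (seed,) = seed_from_kmers([_rec("ATCGGTAATC")], n_seeds=1, p0=0.97)
        assert seed.consensus == "ATCGGTAATC"

    def test_empty_records_rejected(self):
        with pytest.raises(UsageError):
            seed_from_kmers([], 5)


class TestEmZoops:
    def test_recovers_planted_motif_with_high_site_prior(self, planted_reads):
        fit = em_zoops(planted_reads, Motif.from_consensus(MIZM1, p0=0.7))
        assert fit.motif.consensus == MIZM1
        assert fit.gamma >= 0.95
        assert fit.converged

    def test_log_likelihood_monotone(self, planted_reads):
        fit = em_zoops(planted_reads[:200], Motif.from_consensus(MIZM2, p0=0.7))
        diffs = np.diff(fit.log_likelihood_path)
        assert (diffs >= -1e-7).all()

    def test_null_data_collapses_motif_information(self):
        """No signal: the fitted motif degenerates toward the background
        while planted data keeps ~2 bits per column."""
        null = generate_background_library(500, 21, seed=9)
        fit = em_zoops(null, Motif.from_consensus(MIZM1, p0=0.7), max_iter=200)
        assert _info_per_column(fit.motif) < 0.5

    def test_uniform_init_gives_symmetric_first_posteriors(self):
        uniform = Motif("flat", np.full((6, 4), 0.25))
        seqs = ["ACGTACGTACGT"] * 3
        fit = em_zoops(seqs, uniform, max_iter=1)
        # with motif == background every offset is equally likely, so the
        # first M-step average equals the column composition of all windows
        assert fit.n_iterations == 1
        assert np.isfinite(fit.log_likelihood)

    def test_width_longer_than_sequences_rejected(self):
        with pytest.raises(UsageError):
            em_zoops(["ACGT"], Motif.from_consensus(MIZM1, p0=0.7))


class TestMatchBack:
    def test_exact_consensus_retained_at_full_threshold(self):
        motif = Motif.from_consensus(MIZM2, p0=0.97)
        reads = ["AAAAAAATCGATAAAAAAAAA", "CCCCCCCCCCCCCCCCCCCCC"]
        kept = match_back(reads, motif, score_fraction=1.0)
        assert kept == [reads[0]]

    def test_tiny_threshold_retains_everything(self):
        motif = Motif.from_consensus(MIZM2, p0=0.9)
        reads = generate_background_library(200, 21, seed=2)
        assert match_back(reads, motif, score_fraction=1e-9) == reads

    def test_null_retention_matches_score_distribution_tail(self):
        """Retained fraction of random reads ~ both-strand tail mass of the
        null window-score distribution (independent DP oracle)."""
        motif = Motif.from_consensus(MIZM1, p0=0.9)
        # 0.85 puts the threshold between the 1- and 2-mismatch score atoms
        frac = 0.85
        reads = generate_background_library(30_000, 21, seed=12)
        kept = match_back(reads, motif, score_fraction=frac)
        S = build_log_odds(motif, pseudocount=0.1)
        thr = S.min(axis=1).sum() + frac * (S.max(axis=1).sum() - S.min(axis=1).sum())
        dist = null_score_distribution(S, granularity=4000)
        p_win = dist.pvalue(thr)
        n_positions = 2 * 12  # windows x strands per read
        expect = 1 - (1 - p_win) ** n_positions
        sd = np.sqrt(expect * (1 - expect) / len(reads))
        assert abs(len(kept) / len(reads) - expect) < 4 * sd + 0.1 * expect

    def test_scores_agree_with_direct_scan(self):
        motif = Motif.from_consensus("ATCGGTAATCAGG", p0=0.8)  # width 13 packs
        reads = generate_background_library(50, 21, seed=7)
        S = motif.log_odds()
        from bnsmotif._encode import encode, window_scores

        best = best_window_scores(reads, motif)
        for r, expected in zip(reads, best):
            enc = encode(r)
            manual = max(
                window_scores(enc, S).max(), window_scores(enc, S[::-1, ::-1]).max()
            )
            assert expected == pytest.approx(manual, abs=1e-6)


class TestDiscover:
    def test_two_planted_motifs_both_reported(self):
        """A library with two planted motifs yields both consensi (up to
        reverse complement) in the top five.  The long motif gets the higher
        per-site affinity (as observed for the full-length protein) and a
        soft energy scale so its partial matches stay in the pool; exact
        sites of the short palindrome are ~250x more frequent in a random
        pool, so it is recovered regardless."""
        m1 = Motif.from_consensus(MIZM1, p0=0.9, motif_id="m1")
        m2 = Motif.from_consensus(MIZM2, p0=0.9, motif_id="m2")
        model = SelectionModel(
            planted_motifs=[(m1, 2.0), (m2, 0.15)],
            nonspecific_floor=0.1,
            carryover=0.005,
            energy_scale=0.35,
        )
        cfg = SimulationConfig(
            seed=41,
            conditions=[BnSCondition("ACC", 80.0, 50.0)],
            selection=model,
            n_background=1000,
            n_selected=30_000,
        )
        lib = generate_bns_library(cfg)
        motifs = discover_motifs(
            [r.region for r in lib.selected["ACC"]],
            DiscoveryConfig(widths=(6, 10), n_seeds=5, n_rounds=1),
            seed=41,
        )
        consensi = {m.consensus for m in motifs}
        assert MIZM1 in consensi or b.reverse_complement(MIZM1) in consensi
        assert MIZM2 in consensi  # palindromic

    def test_null_library_scores_below_two(self):
        null = generate_background_library(20_000, 21, seed=13)
        motifs = discover_motifs(
            null, DiscoveryConfig(widths=(6, 10), n_seeds=3, n_rounds=1), seed=13
        )
        assert all((m.enrichment_score or 0) < 2 for m in motifs)

    def test_strand_symmetry_and_determinism(self, planted_reads):
        cfg = DiscoveryConfig(widths=(10,), n_seeds=2, n_rounds=1)
        fwd = discover_motifs(planted_reads, cfg, seed=3)
        rev = discover_motifs([b.reverse_complement(s) for s in planted_reads], cfg, seed=3)
        again = discover_motifs(planted_reads, cfg, seed=3)
        canon = lambda ms: [m.consensus for m in ms]
        assert canon(fwd) == canon(rev) == canon(again)
        assert np.array_equal(fwd[0].probs, again[0].probs)

    def test_em_fit_recovers_planted_pwm_under_strong_selection(self):
        """Mean per-column total-variation distance between the EM fit and
        the planted PWM stays below 0.1 when selection is strong."""
        planted = Motif.from_consensus(MIZM1, p0=0.7, motif_id="planted")
        model = SelectionModel(
            planted_motifs=[(planted, 1.0)], nonspecific_floor=0.0, carryover=0.0
        )
        cfg = SimulationConfig(
            seed=21,
            conditions=[BnSCondition("ACC", 500.0, 0.0)],
            selection=model,
            n_background=1000,
            n_selected=100_000,
        )
        lib = generate_bns_library(cfg)
        regions = [r.region for r in lib.selected["ACC"]]
        rng = np.random.default_rng(0)
        cluster = [regions[i] for i in rng.choice(len(regions), 10_000, replace=False)]
        fit = em_zoops(cluster, Motif.from_consensus(MIZM1, p0=0.7))
        ref = planted.probs if fit.motif.consensus == MIZM1 else planted.probs[::-1, ::-1]
        tv = 0.5 * np.abs(fit.motif.probs - ref).sum(axis=1)
        assert tv.mean() < 0.1

    def test_empty_read_set_rejected(self):
        with pytest.raises(UsageError):
            discover_motifs([], DiscoveryConfig())
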