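"""PWM scoring: log-odds arithmetic, exact null distributions, probe
scans, occurrence fractions, strand symmetry, and motif comparison."""

from itertools import product

import numpy as np
import pytest

import bnsmotif as b
from bnsmotif.errors import UsageError
from bnsmotif.motifs import Motif
from bnsmotif.scanning import (
    build_log_odds,
    compare_motifs,
    fraction_of_sequences_with_match,
    null_score_distribution,
    scan_sequences,
)
from bnsmotif.synthetic import generate_background_library

from conftest import MIZM1, MIZM2, PROBE_CP, PROBE_P1, PROBE_P2


class TestLogOdds:
    def test_uniform_motif_scores_zero(self):
        S = build_log_odds(Motif("flat", np.full((4, 4), 0.25)))
        assert np.allclose(S, 0.0)

    def test_deterministic_column_with_pseudocount(self):
        m = Motif("d", np.array([[1.0, 0, 0, 0]]))
        S = build_log_odds(m, pseudocount=0.01)
        assert S[0, 0] == pytest.approx(np.log2(0.99257 / 0.25), abs=1e-3)

    def test_doubling_background_lowers_entry_one_bit(self):
        m = Motif("d", np.array([[0.4, 0.2, 0.2, 0.2]]))
        s1 = build_log_odds(m, background=np.array([0.25, 0.25, 0.25, 0.25]))
        s2 = build_log_odds(m, background=np.array([0.5, 1 / 6, 1 / 6, 1 / 6]))
        # the pseudocount is background-weighted, so compare without it
        s1 = build_log_odds(m, background=np.array([0.25] * 4), pseudocount=0.0)
        s2 = build_log_odds(
            m, background=np.array([0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]), pseudocount=0.0
        )
        assert s2[0, 0] == pytest.approx(s1[0, 0] - 1.0)

    def test_zero_background_rejected(self):
        with pytest.raises(UsageError):
            build_log_odds(Motif("d", np.full((2, 4), 0.25)), background=np.array([0.5, 0.5, 0, 0]))


class TestNullDistribution:
    def test_consensus_word_tail_probability(self):
        S = build_log_odds(Motif.from_consensus(MIZM2, p0=0.95))
        dist = null_score_distribution(S)
        assert dist.pvalue_of_int(len(dist.sf) - 1) == pytest.approx(4.0**-6)
        assert dist.pvalue_of_int(0) == 1.0
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_dp_equals_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        S = build_log_odds(Motif("r", rng.dirichlet(np.ones(4), size=width)))
        dist = null_score_distribution(S, granularity=1000)
        ints = np.array(
            [
                sum(dist.int_matrix[i, bx] for i, bx in enumerate(word))
                for word in product(range(4), repeat=width)
            ]
        )
        for t in sorted(set(ints)):
            assert dist.pvalue_of_int(t) == pytest.approx((ints >= t).mean(), abs=1e-12)

    def test_nonuniform_background_enumeration(self):
        rng = np.random.default_rng(0)
        q = np.array([0.4, 0.1, 0.2, 0.3])
        S = build_log_odds(Motif("r", rng.dirichlet(np.ones(4), size=4)), background=q)
        dist = null_score_distribution(S, background=q)
        ints, weights = [], []
        for word in product(range(4), repeat=4):
            ints.append(sum(dist.int_matrix[i, bx] for i, bx in enumerate(word)))
            weights.append(np.prod([q[bx] for bx in word]))
        ints, weights = np.array(ints), np.array(weights)
        for t in sorted(set(ints)):
            assert dist.pvalue_of_int(t) == pytest.approx(weights[ints >= t].sum(), abs=1e-12)


class TestProbeScans:
    """The printed EMSA probe sequences as scan fixtures."""

    def test_p1_single_mizm1_site_at_offset_five(self):
        hits = scan_sequences([("P1", PROBE_P1)], Motif.from_consensus(MIZM1, p0=0.95))
        assert [(h.start, h.strand) for h in hits] == [(5, "+")]
        assert hits[0].matched_sequence == MIZM1
        assert 0 < hits[0].p_value < 1e-4

    def test_p2_palindromic_mizm2_site_at_offset_nine(self):
        # the smallest width-6 p-value is 4^-6 ~ 2.4e-4, so the cutoff must
        # sit above it; 3e-4 admits only exact-consensus windows
        hits = scan_sequences(
            [("P2", PROBE_P2)], Motif.from_consensus(MIZM2, p0=0.95), p_threshold=3e-4
        )
        assert [(h.start, h.strand) for h in hits] == [(9, "+"), (9, "-")]

    @pytest.mark.parametrize("consensus,p0", [(MIZM1, 0.95), (MIZM2, 0.95)])
    def test_control_probe_never_matches(self, consensus, p0):
        hits = scan_sequences([("CP", PROBE_CP)], Motif.from_consensus(consensus, p0))
        assert hits == []

    def test_short_sequences_yield_no_matches(self):
        assert scan_sequences([("s", "ACGT")], Motif.from_consensus(MIZM1, p0=0.9)) == []

    def test_strand_symmetry_mirrored_coordinates(self):
        motif = Motif.from_consensus(MIZM1, p0=0.9)
        seqs = generate_background_library(300, 40, seed=8)
        fwd = scan_sequences(list(enumerate(seqs)), motif, p_threshold=1e-3)
        rev = scan_sequences(
            [(i, b.reverse_complement(s)) for i, s in enumerate(seqs)], motif, p_threshold=1e-3
        )
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (h.seq_id, 40 - h.start - motif.width, flip[h.strand]) for h in rev
        )
        assert sorted((h.seq_id, h.start, h.strand) for h in fwd) == mirrored


class TestOccurrenceFraction:
    def test_all_and_none(self):
        motif = Motif.from_consensus(MIZM2, p0=0.95)
        seqs = [f"AAAA{MIZM2}AAAA"] * 5
        assert fraction_of_sequences_with_match(seqs, motif, p_threshold=3e-4) == 1.0
        assert fraction_of_sequences_with_match(["CCCCCCCCCCCC"] * 5, motif, 3e-4) == 0.0

    def test_planted_fraction_recovered(self, synthetic_peak_data):
        from bnsmotif.peaks import extract_peak_sequences

        data = synthetic_peak_data
        seqs = extract_peak_sequences(data.peaks, data.genome)
        frac = fraction_of_sequences_with_match(seqs, Motif.from_consensus(MIZM1, p0=0.9))
        truth = data.truth.has_motif.mean()
        assert frac == pytest.approx(truth, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            fraction_of_sequences_with_match([], Motif.from_consensus(MIZM2, p0=0.9))


class TestCompareMotifs:
    def test_self_comparison_is_perfect(self):
        rng = np.random.default_rng(1)
        q = Motif("q", rng.dirichlet(np.ones(4), size=8))
        res = compare_motifs(q, [q], n_permutations=200, seed=0)[0]
        assert res.offset == 0 and res.orientation == "forward"
        assert res.score == pytest.approx(1.0)
        assert res.e_value >= res.p_value

    def test_mizm2_aligns_to_first_six_mizm1_columns(self):
        """Mizm2 sits on Mizm1 columns 1-6 with 5/6 consensus identity."""
        q = Motif.from_consensus(MIZM2, p0=0.7, motif_id="Mizm2")
        t = Motif.from_consensus(MIZM1, p0=0.7, motif_id="Mizm1")
        res = compare_motifs(q, [t], n_permutations=500, seed=0)[0]
        assert res.offset == 0 and res.overlap == 6
        aligned = MIZM1[res.offset : res.offset + 6]
        matches = sum(a == c for a, c in zip(MIZM2, aligned))
        assert matches == 5

    def test_reverse_complement_recognized(self):
        rng = np.random.default_rng(2)
        q = Motif("q", rng.dirichlet(np.ones(4), size=8))
        t = q.reverse_complement("t")
        res = compare_motifs(q, [t], n_permutations=200, seed=0)[0]
        assert res.orientation == "reverse_complement"
        assert res.score == pytest.approx(1.0)

    def test_null_pvalues_super_uniform(self):
        """Against column-shuffled targets the permutation p-values are
        (super-)uniform: P(p <= a) <= ~a."""
        rng = np.random.default_rng(3)
        q = Motif("q", rng.dirichlet(np.ones(4), size=8))
        pvals = []
        for i in range(40):
            probs = rng.dirichlet(np.ones(4), size=8)
            t = Motif(f"t{i}", probs[rng.permutation(8)])
            pvals.append(compare_motifs(q, [t], n_permutations=99, seed=i)[0].p_value)
        pvals = np.array(pvals)
        for a in (0.1, 0.25, 0.5):
            assert (pvals <= a).mean() <= a + 3 * np.sqrt(a * (1 - a) / len(pvals))

    def test_narrow_query_rejected(self):
        with pytest.raises(UsageError):
            compare_motifs(Motif("q", np.full((3, 4), 0.25)), [])
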