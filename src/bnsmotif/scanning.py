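"""PWM scoring: log-odds matrices, exact null score distributions and
p-values, both-strand scanning, occurrence fractions, and motif-motif
comparison.

P-values are exact under the background model: the score matrix is
discretized onto an integer grid (scores rounded down, FIMO-style) and the
null distribution of the total score is computed by position-wise
convolution of the per-column score distributions.  Scanning sums the same
integerized column scores, so scanned scores and the null distribution live
on one shared grid and the reported p-value of a window is exactly the
probability that a background-drawn window scores at least as high.

P-values are per window and per strand; no multiple-testing correction is
applied across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encode import encode, window_scores
from .errors import UsageError
from .motifs import Motif

DEFAULT_P_THRESHOLD = 1e-4  # FIMO's default per-match cutoff


def build_log_odds(
    motif: Motif,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> np.ndarray:
    """Log2 odds matrix in bits: ``log2(smoothed_prob / background_prob)``.

    Probabilities are smoothed with a background-weighted pseudocount,
    ``p' = (p + c*q) / (1 + c)``, which keeps every entry finite.
    """
    q = motif.background if background is None else np.asarray(background, dtype=float)
    if q.shape != (4,):
        raise UsageError("background must be a 4-vector")
    if (q <= 0).any():
        raise UsageError("background entries must be strictly positive")
    q = q / q.sum()
    smoothed = (motif.probs + pseudocount * q[None, :]) / (1.0 + pseudocount)
    return np.log2(smoothed / q[None, :])


@dataclass
class ScoreDistribution:
    """Discretized null distribution of a PWM's window score.

    ``int_matrix[i, b]`` is the integerized score contribution of base ``b``
    at column ``i``; ``pmf[t]``/``sf[t]`` are the probability mass and
    survival function of the integer total under the background.
    """

    int_matrix: np.ndarray  # (w, 4) int64, per-column offset removed
    scale: float  # integer units per bit
    offset: float  # sum of per-column minima (bits)
    pmf: np.ndarray
    sf: np.ndarray
    background: np.ndarray

    @property
    def width(self) -> int:
        return self.int_matrix.shape[0]

    def int_score(self, float_score: float) -> int:
        """Map a float score (bits) onto the integer grid (rounded down)."""
        t = int(np.floor((float_score - self.offset) * self.scale + 1e-9))
        return min(max(t, 0), len(self.sf) - 1)

    def pvalue_of_int(self, t: int) -> float:
        t = min(max(int(t), 0), len(self.sf) - 1)
        return float(self.sf[t])

    def pvalue(self, float_score: float) -> float:
        """P(background window score >= given score), on the shared grid."""
        return self.pvalue_of_int(self.int_score(float_score))

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is strictly below threshold.

        Returns one past the maximum score if no score qualifies.
        """
        qualifying = np.nonzero(self.sf < p_threshold)[0]
        return int(qualifying[0]) if qualifying.size else len(self.sf)


def null_score_distribution(
    score_matrix: np.ndarray,
    background: np.ndarray | None = None,
    granularity: int = 1000,
) -> ScoreDistribution:
    """Exact PMF of the window score under the background, by convolution.

    ``granularity`` is the number of integer bins spanning the full score
    range (must be >= 1000, following the FIMO-style discretization).
    """
    S = np.asarray(score_matrix, dtype=np.float64)
    if not np.isfinite(S).all():
        raise UsageError("score matrix must be finite; apply a pseudocount upstream")
    if granularity < 1000:
        raise UsageError("granularity must be at least 1000")
    q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=np.float64)
    q = q / q.sum()
    w = S.shape[0]
    col_min = S.min(axis=1)
    span = float((S.max(axis=1) - col_min).sum())
    scale = (granularity - 1) / span if span > 0 else 1.0
    # integerize with the per-column minimum removed; floor with a small
    # epsilon so exact grid points do not round down spuriously
    E = np.floor((S - col_min[:, None]) * scale + 1e-9).astype(np.int64)
    pmf = np.zeros(1, dtype=np.float64)
    pmf[0] = 1.0
    for i in range(w):
        nxt = np.zeros(len(pmf) + int(E[i].max()), dtype=np.float64)
        for b in range(4):
            nxt[E[i, b] : E[i, b] + len(pmf)] += q[b] * pmf
        pmf = nxt
    sf = np.cumsum(pmf[::-1])[::-1]
    np.minimum(sf, 1.0, out=sf)
    return ScoreDistribution(
        int_matrix=E,
        scale=scale,
        offset=float(col_min.sum()),
        pmf=pmf,
        sf=sf,
        background=q,
    )


@dataclass
class MotifMatch:
    """A scored, stranded occurrence of a motif in a sequence."""

    seq_id: str
    start: int  # 0-based, forward-strand coordinates of the window start
    strand: str
    score: float  # bits
    p_value: float
    matched_sequence: str = ""

    @property
    def stop(self) -> int:
        return self.start + len(self.matched_sequence)


def _as_records(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, dict):
        return list(sequences.items())
    records = []
    for i, item in enumerate(sequences):
        if isinstance(item, tuple):
            records.append(item)
        else:
            records.append((f"seq_{i + 1}", item))
    return records


def scan_sequences(
    sequences,
    motif: Motif,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    strand_policy: str = "both",
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    granularity: int = 1000,
) -> list[MotifMatch]:
    """Report every window x strand whose score p-value is below threshold.

    ``sequences`` may be a dict, a list of (id, sequence) pairs, or a list
    of plain strings.  Reverse-strand matches are reported at the window's
    forward-strand start.  Sequences shorter than the motif yield no
    matches.  Matches are sorted by (seq_id, start, strand).
    """
    if not 0.0 < p_threshold < 1.0:
        raise UsageError("p_threshold must lie in (0, 1)")
    if strand_policy not in ("both", "forward_only"):
        raise UsageError(f"unknown strand_policy {strand_policy!r}")
    records = _as_records(sequences)
    S = build_log_odds(motif, background=background, pseudocount=pseudocount)
    dist = null_score_distribution(S, background=background, granularity=granularity)
    thr = dist.score_threshold(p_threshold)
    strands = [("+", dist.int_matrix, S)]
    if strand_policy == "both":
        S_rc = S[::-1, ::-1]
        strands.append(("-", dist.int_matrix[::-1, ::-1], S_rc))
    matches = []
    w = motif.width
    for seq_id, seq in records:
        enc = encode(seq.upper())
        m = len(seq) - w + 1
        if m <= 0:
            continue
        for strand, E, Sf in strands:
            ints = _int_window_scores(enc, E)
            hits = np.nonzero(ints >= thr)[0]
            for j in hits:
                fscore = float(window_scores(enc[j : j + w], Sf)[0])
                matches.append(
                    MotifMatch(
                        seq_id=seq_id,
                        start=int(j),
                        strand=strand,
                        score=fscore,
                        p_value=dist.pvalue_of_int(int(ints[j])),
                        matched_sequence=seq[j : j + w].upper(),
                    )
                )
    matches.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return matches


def _int_window_scores(enc: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Integer window scores; windows containing N score -1 (never match)."""
    w = E.shape[0]
    m = enc.shape[0] - w + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    total = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for i in range(w):
        col = enc[i : i + m]
        ok = col >= 0
        valid &= ok
        total += E[i, np.where(ok, col, 0)]
    total[~valid] = -1
    return total


def fraction_of_sequences_with_match(
    sequences,
    motif: Motif,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    **kwargs,
) -> float:
    """Fraction of sequences with at least one reported match.

    A sequence counts once even when a palindromic motif matches the same
    window on both strands.
    """
    records = _as_records(sequences)
    if not records:
        raise UsageError("empty sequence set")
    hits = {m.seq_id for m in scan_sequences(records, motif, p_threshold, **kwargs)}
    return len(hits) / len(records)


# ---------------------------------------------------------------------------
# motif-motif comparison


@dataclass
class ComparisonResult:
    """Best ungapped alignment of a query motif against one target."""

    query_id: str
    target_id: str
    offset: int  # query start relative to target start
    orientation: str  # "forward" | "reverse_complement"
    score: float  # mean per-column Pearson correlation over the overlap
    p_value: float
    e_value: float
    overlap: int


def _column_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between paired probability 4-vectors.

    A constant column (zero variance) has correlation 0 with anything.
    """
    a = A - A.mean(axis=1, keepdims=True)
    b = B - B.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    out = np.zeros(len(num))
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def _best_alignment(
    query: np.ndarray, target: np.ndarray, min_overlap: int = 4
) -> tuple[float, int, int]:
    """Best (mean-correlation, offset, overlap) over all ungapped offsets."""
    wq, wt = query.shape[0], target.shape[0]
    best = (-np.inf, 0, 0)
    for offset in range(-wq + min_overlap, wt - min_overlap + 1):
        lo_q = max(0, -offset)
        lo_t = max(0, offset)
        n = min(wq - lo_q, wt - lo_t)
        if n < min_overlap:
            continue
        r = _column_correlations(query[lo_q : lo_q + n], target[lo_t : lo_t + n])
        score = float(r.mean())
        if score > best[0]:
            best = (score, offset, n)
    return best


def compare_motifs(
    query: Motif,
    targets: list[Motif],
    orientation_policy: str = "both",
    n_permutations: int = 1000,
    seed: int = 0,
    min_overlap: int = 4,
) -> list[ComparisonResult]:
    """Align a query PWM to each target over all offsets and orientations.

    Column similarity is the Pearson correlation of probability 4-vectors;
    an alignment's score is the mean over the overlap (>= ``min_overlap``
    columns).  The p-value is a permutation rank: the target's columns are
    independently shuffled ``n_permutations`` times and the best alignment
    score recomputed each time.  ``e_value = p_value * len(targets)``.
    """
    if query.width < min_overlap:
        raise UsageError(f"query width must be at least {min_overlap}")
    if orientation_policy not in ("both", "forward_only"):
        raise UsageError(f"unknown orientation_policy {orientation_policy!r}")
    rng = np.random.default_rng(seed)
    results = []
    for target in targets:
        orientations = [("forward", query.probs)]
        if orientation_policy == "both":
            orientations.append(("reverse_complement", query.probs[::-1, ::-1]))
        best_score, best_offset, best_orient, best_overlap = -np.inf, 0, "forward", 0
        for orient, Q in orientations:
            score, offset, overlap = _best_alignment(Q, target.probs, min_overlap)
            # strict improvement beyond float noise, so forward wins exact ties
            # (a reverse-complement palindrome scores identically both ways)
            if score > best_score + 1e-9:
                best_score, best_offset, best_orient, best_overlap = (
                    score,
                    offset,
                    orient,
                    overlap,
                )
        exceed = 0
        for _ in range(n_permutations):
            perm = target.probs[rng.permutation(target.width)]
            perm_best = -np.inf
            for orient, Q in orientations:
                s, _, _ = _best_alignment(Q, perm, min_overlap)
                perm_best = max(perm_best, s)
            if perm_best >= best_score:
                exceed += 1
        p = (1 + exceed) / (n_permutations + 1)
        results.append(
            ComparisonResult(
                query_id=query.motif_id,
                target_id=target.motif_id,
                offset=best_offset,
                orientation=best_orient,
                score=best_score,
                p_value=p,
                e_value=p * len(targets),
                overlap=best_overlap,
            )
        )
    results.sort(key=lambda r: r.p_value)
    return results
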