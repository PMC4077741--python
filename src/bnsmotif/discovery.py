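"""De-novo motif discovery on selected read pools.

The discovery loop mirrors iterative-refinement motif elicitation on
sampled read clusters: PWMs are seeded from the most enriched k-mers, fit
with a zero-or-one-occurrence-per-sequence (ZOOPS) EM on a randomly
sampled cluster, matched back against the full read set, refit on the
matching subset for a configurable number of rounds, deduplicated up to
reverse complement, and ranked by the fold enrichment of the k-mer
neighborhood of their consensus.

The ZOOPS model: each sequence independently contains one motif site with
prior probability gamma (uniform over offsets and strands) or none.  The
E-step computes the exact posterior over {no site} and every offset x
strand; the M-step re-estimates the PWM from posterior-weighted site
counts (with a pseudocount) and gamma as the mean posterior site mass.
The observed-data log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encode import encode_matrix, pack_windows, score_table
from .enrichment import (
    EnrichmentRecord,
    count_kmers,
    fold_enrichment,
    neighborhood_max_enrichment,
)
from .errors import UsageError
from .motifs import Motif, hamming
from .seqio import BnSRead, reverse_complement


def _regions(reads) -> list[str]:
    return [r.region if isinstance(r, BnSRead) else str(r) for r in reads]


def seed_from_kmers(
    records: list[EnrichmentRecord], n_seeds: int = 5, p0: float = 0.7
) -> list[Motif]:
    """One PWM per top-enriched k-mer: probability ``p0`` on the k-mer's
    base per column, the rest split evenly."""
    if not records:
        raise UsageError("cannot seed motifs from an empty enrichment list")
    if n_seeds < 1:
        raise UsageError("n_seeds must be at least 1")
    seeds = []
    for rec in records[:n_seeds]:
        m = Motif.from_consensus(rec.kmer, p0=p0, motif_id=f"seed_{rec.kmer}")
        m.enrichment_score = rec.fold_enrichment
        seeds.append(m)
    return seeds


@dataclass
class EMFit:
    """Result of one ZOOPS EM run."""

    motif: Motif
    gamma: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihood_path: list[float] = field(default_factory=list)


def em_zoops(
    sample,
    init: Motif,
    gamma0: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 100,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> EMFit:
    """Fit a ZOOPS motif model by EM, searching both strands.

    ``sample`` is a list of sequences (or reads), each at least as long as
    the initial motif.  Stops when the largest absolute change in the
    probability matrix falls below ``tol`` or after ``max_iter`` iterations.
    """
    seqs = _regions(sample)
    if not seqs:
        raise UsageError("empty sequence sample")
    w = init.width
    if min(len(s) for s in seqs) < w:
        raise UsageError("motif width exceeds the shortest sequence")
    if not 0.0 < gamma0 < 1.0:
        raise UsageError("gamma0 must lie in (0, 1)")
    q = np.asarray(init.background if background is None else background, dtype=np.float64)
    q = q / q.sum()
    X = encode_matrix(seqs)
    n, L = X.shape
    lengths = np.array([len(s) for s in seqs])
    m_max = L - w + 1
    # valid forward windows per row (no padding, no N)
    valid = np.ones((n, m_max), dtype=bool)
    for c in range(w):
        valid &= X[:, c : c + m_max] >= 0
    valid &= np.arange(m_max)[None, :] < (lengths - w + 1)[:, None]
    n_offsets = valid.sum(axis=1)  # per-strand; total positions = 2 * n_offsets
    if (n_offsets == 0).any():
        raise UsageError("a sequence has no N-free window at this width")

    Xc = np.clip(X, 0, 3)
    logq = np.log(q)
    const = np.array(
        [np.where(X[i, : lengths[i]] >= 0, logq[Xc[i, : lengths[i]]], 0.0).sum() for i in range(n)]
    )

    probs = init.probs.copy()
    gamma = float(gamma0)
    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            lratio = np.log(np.maximum(probs, 1e-300)) - logq[None, :]
        lr_fwd = lratio
        lr_rev = lratio[::-1, ::-1]
        odds = np.zeros((n, m_max, 2))
        for s_idx, lr in enumerate((lr_fwd, lr_rev)):
            llr = np.zeros((n, m_max))
            for c in range(w):
                llr += lr[c, Xc[:, c : c + m_max]]
            ex = np.exp(np.minimum(llr, 700.0))
            ex[~valid] = 0.0
            odds[:, :, s_idx] = ex
        prior_site = gamma / (2.0 * n_offsets)
        Z = (1.0 - gamma) + prior_site * odds.sum(axis=(1, 2))
        post = prior_site[:, None, None] * odds / Z[:, None, None]
        ll = float(np.sum(np.log(Z) + const))
        ll_path.append(ll)

        counts = np.zeros((w, 4))
        counts_rc = np.zeros((w, 4))
        for c in range(w):
            base = Xc[:, c : c + m_max].ravel()
            counts[c] = np.bincount(base, weights=post[:, :, 0].ravel(), minlength=4)
            counts_rc[c] = np.bincount(base, weights=post[:, :, 1].ravel(), minlength=4)
        counts += counts_rc[::-1, ::-1]
        new_probs = counts + pseudocount
        new_probs /= new_probs.sum(axis=1, keepdims=True)
        gamma = float(np.mean(1.0 - (1.0 - gamma) / Z))
        gamma = min(max(gamma, 1e-6), 1.0 - 1e-6)
        delta = np.abs(new_probs - probs).max()
        probs = new_probs
        if delta < tol:
            converged = True
            break

    motif = Motif(
        motif_id=f"{init.motif_id}_fit",
        probs=probs,
        background=q,
        nsites=max(gamma * n, 1.0),
    )
    return EMFit(
        motif=motif,
        gamma=gamma,
        log_likelihood=ll_path[-1],
        n_iterations=it,
        converged=converged,
        log_likelihood_path=ll_path,
    )


def best_window_scores(reads, motif: Motif, pseudocount: float = 0.1) -> np.ndarray:
    """Best both-strand log-odds window score (bits) of each read."""
    seqs = _regions(reads)
    S = motif.log_odds(pseudocount=pseudocount)
    w = motif.width
    out = np.full(len(seqs), -np.inf)
    order: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) >= w:
            order.setdefault(len(s), []).append(i)
    if w <= 13:
        t_fwd = score_table(S)
        t_rev = score_table(S[::-1, ::-1])
        for _, idx in sorted(order.items()):
            mat = encode_matrix([seqs[i] for i in idx])
            packed, valid = pack_windows(mat, w)
            sc = np.maximum(t_fwd[packed], t_rev[packed])
            sc[~valid] = -np.inf
            out[idx] = sc.max(axis=1)
    else:
        from ._encode import encode, window_scores

        S_rev = S[::-1, ::-1]
        for i, s in enumerate(seqs):
            if len(s) < w:
                continue
            enc = encode(s)
            best = max(window_scores(enc, S).max(), window_scores(enc, S_rev).max())
            out[i] = best
    return out


def match_back(full_reads, motif: Motif, score_fraction: float = 0.8):
    """Reads whose best both-strand window reaches a scaled score threshold.

    The threshold interpolates between the minimum and maximum attainable
    window score: ``min + score_fraction * (max - min)``, so
    ``score_fraction -> 0`` retains everything and ``score_fraction = 1``
    requires a maximal-score window.
    """
    if not 0.0 < score_fraction <= 1.0:
        raise UsageError("score_fraction must lie in (0, 1]")
    S = motif.log_odds(pseudocount=0.1)
    smin = float(S.min(axis=1).sum())
    smax = float(S.max(axis=1).sum())
    thr = smin + score_fraction * (smax - smin)
    best = best_window_scores(full_reads, motif)
    keep = best >= thr - 1e-9
    return [r for r, k in zip(full_reads, keep) if k]


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the discovery pipeline."""

    widths: tuple[int, ...] = (6, 8, 10)
    cluster_size: int = 10_000
    n_rounds: int = 3
    n_seeds: int = 5
    seed_p0: float = 0.7
    score_fraction: float = 0.8
    min_count: int = 5
    top_n: int = 5
    em_tol: float = 1e-4
    em_max_iter: int = 100
    pseudocount: float = 0.1
    min_matched: int = 50


def _canonicalize(motif: Motif) -> Motif:
    """Orient a motif so its consensus is the lexicographically smaller of
    itself and its reverse complement."""
    cons = motif.consensus
    if reverse_complement(cons) < cons:
        return motif.reverse_complement(motif_id=motif.motif_id)
    return motif


def discover_motifs(
    reads,
    config: DiscoveryConfig | None = None,
    seed: int = 0,
) -> list[Motif]:
    """Full discovery pipeline; returns the top motifs ranked by enrichment.

    Per width: k-mer enrichment on all reads -> seed PWMs -> ZOOPS EM on a
    sampled cluster -> match back -> refit, repeated ``n_rounds`` times.
    Final motifs get the maximum fold enrichment among k-mers within
    Hamming distance 1 of their consensus (or its reverse complement),
    are deduplicated up to Hamming distance 1 / reverse complement, and the
    top ``top_n`` are returned, canonically oriented.
    """
    cfg = config or DiscoveryConfig()
    regions = _regions(reads)
    if not regions:
        raise UsageError("empty read set")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xD15C]))
    candidates: list[Motif] = []
    for width in cfg.widths:
        if width > min(len(s) for s in regions):
            continue
        table = count_kmers(regions, width)
        records = fold_enrichment(table, None, min_count=cfg.min_count)
        if not records:
            continue
        folds = {r.kmer: r.fold_enrichment for r in records}
        seeds = seed_from_kmers(records, cfg.n_seeds, cfg.seed_p0)
        csize = min(cfg.cluster_size, len(regions))
        cluster_idx = rng.choice(len(regions), size=csize, replace=False)
        cluster = [regions[i] for i in cluster_idx]
        for seed_motif in seeds:
            fit = em_zoops(
                cluster,
                seed_motif,
                tol=cfg.em_tol,
                max_iter=cfg.em_max_iter,
                pseudocount=cfg.pseudocount,
            )
            motif = fit.motif
            for _ in range(cfg.n_rounds):
                matched = match_back(regions, motif, cfg.score_fraction)
                if len(matched) < cfg.min_matched:
                    break
                if len(matched) > cfg.cluster_size:
                    pick = rng.choice(len(matched), size=cfg.cluster_size, replace=False)
                    matched = [matched[i] for i in pick]
                fit = em_zoops(
                    matched,
                    motif,
                    tol=cfg.em_tol,
                    max_iter=cfg.em_max_iter,
                    pseudocount=cfg.pseudocount,
                )
                motif = fit.motif
            motif.enrichment_score = neighborhood_max_enrichment(folds, motif.consensus)
            candidates.append(_canonicalize(motif))

    candidates.sort(key=lambda m: (-(m.enrichment_score or 0.0), m.consensus))
    kept: list[Motif] = []
    for cand in candidates:
        cons = cand.consensus
        dup = False
        for other in kept:
            oc = other.consensus
            if len(oc) != len(cons):
                continue
            if hamming(cons, oc) <= 1 or hamming(cons, reverse_complement(oc)) <= 1:
                dup = True
                break
        if not dup:
            kept.append(cand)
        if len(kept) == cfg.top_n:
            break
    for i, m in enumerate(kept, start=1):
        m.motif_id = f"motif_{i}_{m.consensus}"
    return kept
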