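"""Demultiplexing and k-mer fold enrichment of selected pools over background.

Counting is both-strand by default (the selection acts on double-stranded
probes): every length-k window contributes one count to its forward k-mer
and one to its reverse complement, so a reverse-complement palindrome
legitimately counts twice per window.  Fold enrichment is the ratio of a
k-mer's window frequency in the selected pool to its frequency in (or
expected under) the background; absent background k-mers are floored at
half a count so enrichment stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._encode import (
    _MAX_PACK_K,
    encode_matrix,
    pack_windows,
    revcomp_codes,
    unpack_kmers,
)
from .errors import UsageError
from .motifs import hamming
from .seqio import BnSRead

FORWARD_ONLY = "forward_only"
BOTH_STRANDS = "both_strands"


def demultiplex(
    reads: Iterable[BnSRead],
    conditions,
    min_mean_q: float = 0.0,
) -> tuple[dict[str, list[BnSRead]], list[BnSRead]]:
    """Partition reads by exact 3-nt barcode match.

    Reads with an unknown barcode or mean Phred quality below
    ``min_mean_q`` go to the unassigned list.  Per-condition bins plus
    unassigned always partition the input.
    """
    barcodes = [c.barcode if hasattr(c, "barcode") else str(c) for c in conditions]
    if len(set(barcodes)) != len(barcodes):
        raise UsageError("duplicate barcodes in condition set")
    bins: dict[str, list[BnSRead]] = {b: [] for b in barcodes}
    unassigned: list[BnSRead] = []
    for read in reads:
        if read.mean_quality() < min_mean_q or read.barcode not in bins:
            unassigned.append(read)
        else:
            bins[read.barcode].append(read)
    return bins, unassigned


@dataclass
class KmerCountTable:
    """Window counts of every k-mer observed in a sequence set."""

    k: int
    counts: dict[str, int]
    total_windows: int
    strand_policy: str

    @property
    def strands_counted(self) -> int:
        return 2 if self.strand_policy == BOTH_STRANDS else 1

    def frequency(self, kmer: str) -> float:
        if self.total_windows == 0:
            return 0.0
        return self.counts.get(kmer, 0) / self.total_windows


def count_kmers(
    sequences: Sequence[str],
    k: int,
    strand_policy: str = BOTH_STRANDS,
) -> KmerCountTable:
    """Count every length-k window; under both_strands each window also
    counts as one occurrence of its reverse-complement k-mer.

    Windows containing N are skipped.  ``total_windows`` is the number of
    forward windows, summed over sequences.
    """
    if strand_policy not in (FORWARD_ONLY, BOTH_STRANDS):
        raise UsageError(f"unknown strand_policy {strand_policy!r}")
    if k < 1:
        raise UsageError("k must be at least 1")
    seqs = [s.region if isinstance(s, BnSRead) else str(s) for s in sequences]
    total_windows = sum(max(len(s) - k + 1, 0) for s in seqs)
    if total_windows == 0:
        warnings.warn(f"k={k} larger than every sequence; empty count table")
        return KmerCountTable(k=k, counts={}, total_windows=0, strand_policy=strand_policy)
    if k <= _MAX_PACK_K:
        counts = _count_packed(seqs, k, strand_policy)
    else:
        counts = _count_naive(seqs, k, strand_policy)
    return KmerCountTable(
        k=k, counts=counts, total_windows=total_windows, strand_policy=strand_policy
    )


def _count_packed(seqs: list[str], k: int, strand_policy: str) -> dict[str, int]:
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(s)
    chunks = []
    for _, group in sorted(by_len.items()):
        mat = encode_matrix(group)
        packed, valid = pack_windows(mat, k)
        chunks.append(packed[valid])
    codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    uniq, cnt = np.unique(codes, return_counts=True)
    if strand_policy == BOTH_STRANDS:
        # each forward window w also counts once toward revcomp(w), so the
        # final count of x is fwd(x) + fwd(revcomp(x))
        rc = revcomp_codes(uniq, k)
        all_codes = np.concatenate([uniq, rc])
        all_cnt = np.concatenate([cnt, cnt])
        uniq, inverse = np.unique(all_codes, return_inverse=True)
        cnt = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(cnt, inverse, all_cnt)
    return dict(zip(unpack_kmers(uniq, k), cnt.tolist()))


def _count_naive(seqs: list[str], k: int, strand_policy: str) -> dict[str, int]:
    from .seqio import reverse_complement

    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            window = s[i : i + k]
            if "N" in window:
                continue
            counts[window] = counts.get(window, 0) + 1
            if strand_policy == BOTH_STRANDS:
                rc = reverse_complement(window)
                counts[rc] = counts.get(rc, 0) + 1
    return counts


@dataclass
class EnrichmentRecord:
    """A k-mer's observed vs expected window frequency and their ratio."""

    kmer: str
    observed_count: int
    observed_freq: float
    expected_freq: float
    fold_enrichment: float


def fold_enrichment(
    selected: KmerCountTable,
    background: KmerCountTable | None = None,
    min_count: int = 5,
) -> list[EnrichmentRecord]:
    """Fold enrichment of every selected k-mer over the background.

    ``background=None`` uses the uniform model: expected frequency
    ``4**-k`` per window per counted strand.  With an empirical background
    table, k-mers absent from it are floored at half a count.  Records are
    sorted by fold enrichment descending, ties broken lexicographically;
    k-mers with selected count below ``min_count`` are omitted.
    """
    if selected.total_windows == 0:
        return []
    if background is not None:
        if background.k != selected.k:
            raise UsageError("selected and background tables use different k")
        if background.strand_policy != selected.strand_policy:
            raise UsageError("selected and background tables use different strand policies")
        if background.total_windows == 0:
            raise UsageError("background table is empty")
    uniform_expected = selected.strands_counted * 4.0 ** (-selected.k)
    records = []
    for kmer, count in selected.counts.items():
        if count < min_count:
            continue
        observed = count / selected.total_windows
        if background is None:
            expected = uniform_expected
        else:
            bg = background.counts.get(kmer, 0)
            expected = max(bg, 0.5) / background.total_windows
        records.append(
            EnrichmentRecord(
                kmer=kmer,
                observed_count=count,
                observed_freq=observed,
                expected_freq=expected,
                fold_enrichment=observed / expected,
            )
        )
    records.sort(key=lambda r: (-r.fold_enrichment, r.kmer))
    return records


def neighborhood_max_enrichment(
    records: Sequence[EnrichmentRecord] | dict[str, float],
    consensus: str,
    max_hamming: int = 1,
    include_revcomp: bool = True,
) -> float:
    """Maximum fold enrichment among k-mers within Hamming distance
    ``max_hamming`` of a consensus (or, optionally, of its reverse
    complement).  Returns 0.0 when no neighborhood k-mer was recorded.
    """
    from .seqio import reverse_complement

    if isinstance(records, dict):
        folds = records
    else:
        folds = {r.kmer: r.fold_enrichment for r in records}
    targets = [consensus]
    if include_revcomp:
        rc = reverse_complement(consensus)
        if rc != consensus:
            targets.append(rc)
    best = 0.0
    for kmer, fe in folds.items():
        if len(kmer) != len(consensus):
            continue
        for t in targets:
            if hamming(kmer, t) <= max_hamming:
                best = max(best, fe)
                break
    return best


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("kmer\tobserved_count\tobserved_freq\texpected_freq\tfold_enrichment\n")
        for r in records:
            fh.write(
                f"{r.kmer}\t{r.observed_count}\t{r.observed_freq:.8g}"
                f"\t{r.expected_freq:.8g}\t{r.fold_enrichment:.6g}\n"
            )
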