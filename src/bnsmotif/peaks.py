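"""Peak annotation relative to genes: TSS distances, region classes,
proximal fractions, distance histograms, and 2x2 chi-squared tests of
motif presence vs TSS proximity.

Conventions: the peak is represented by its midpoint (floor of
(start+end)/2); the nearest TSS is chosen by absolute distance (ties
broken by lower TSS coordinate, then gene id); distances are
strand-adjusted so that negative always means upstream of the gene.
Region classes partition peaks with priority
promoter > tts > exon > intron > intergenic, where the promoter is
-1000..+100 bp around the TSS and the TTS region -100..+1000 bp around the
termination site, both in strand-adjusted coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import StageError, UsageError
from .seqio import GeneRecord, Peak

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000
PROXIMAL_WINDOW_BP = 1500
REGION_CLASSES = ("promoter", "tts", "exon", "intron", "intergenic")


def extract_peak_sequences(
    peaks: Sequence[Peak], genome: dict[str, str]
) -> list[tuple[str, str]]:
    """Forward-strand sequence of each half-open peak interval."""
    out = []
    for p in peaks:
        if p.chrom not in genome:
            raise StageError(f"peak {p.peak_id}: chromosome {p.chrom!r} absent from genome")
        contig = genome[p.chrom]
        if p.end > len(contig):
            raise StageError(
                f"peak {p.peak_id}: interval [{p.start}, {p.end}) extends past "
                f"{p.chrom} length {len(contig)}"
            )
        out.append((p.peak_id, contig[p.start : p.end].upper()))
    return out


@dataclass
class PeakAnnotation:
    """A peak's relation to the nearest gene."""

    peak_id: str
    tss_distance: int  # signed, strand-adjusted; negative = upstream
    nearest_gene: str
    region_class: str
    has_motif: bool


def _strand_adjusted(mid: int, ref: int, strand: str) -> int:
    return mid - ref if strand == "+" else ref - mid


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneRecord],
    motif_flags: dict[str, bool] | Sequence[bool] | None = None,
) -> list[PeakAnnotation]:
    """Annotate each peak with signed TSS distance and a region class.

    ``motif_flags`` maps peak ids to motif presence (or lists flags in peak
    order); omitted peaks default to False.
    """
    if not genes:
        raise UsageError("gene list is empty")
    if motif_flags is None:
        flags = {p.peak_id: False for p in peaks}
    elif isinstance(motif_flags, dict):
        flags = {p.peak_id: bool(motif_flags.get(p.peak_id, False)) for p in peaks}
    else:
        if len(motif_flags) != len(peaks):
            raise UsageError("motif_flags length must match the peak list")
        flags = {p.peak_id: bool(f) for p, f in zip(peaks, motif_flags)}

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gl]), gl)

    annotations = []
    for p in peaks:
        if p.chrom not in index:
            raise StageError(f"peak {p.peak_id}: no genes on chromosome {p.chrom!r}")
        tss_arr, gl = index[p.chrom]
        mid = p.midpoint
        j = int(np.searchsorted(tss_arr, mid))
        # candidates around the insertion point; ties resolved by the sort
        # order of the gene list (lower TSS coordinate, then gene id)
        best = None
        for cand in range(max(0, j - 1), min(len(gl), j + 1)):
            g = gl[cand]
            d_abs = abs(mid - g.tss)
            if best is None or d_abs < best[0]:
                best = (d_abs, g)
        g = best[1]
        dist = _strand_adjusted(mid, g.tss, g.strand)
        annotations.append(
            PeakAnnotation(
                peak_id=p.peak_id,
                tss_distance=int(dist),
                nearest_gene=g.gene_id,
                region_class=_classify(mid, g),
                has_motif=flags[p.peak_id],
            )
        )
    return annotations


def _classify(mid: int, g: GeneRecord) -> str:
    d_tss = _strand_adjusted(mid, g.tss, g.strand)
    if -PROMOTER_UPSTREAM <= d_tss <= PROMOTER_DOWNSTREAM:
        return "promoter"
    d_tts = _strand_adjusted(mid, g.tts, g.strand)
    if -TTS_UPSTREAM <= d_tts <= TTS_DOWNSTREAM:
        return "tts"
    if g.tx_start <= mid < g.tx_end:
        for s, e in zip(g.exon_starts, g.exon_ends):
            if s <= mid < e:
                return "exon"
        return "intron"
    return "intergenic"


def proximal_fraction(
    annotations: Sequence[PeakAnnotation], window_bp: int = PROXIMAL_WINDOW_BP
) -> float:
    """Fraction of peaks with |TSS distance| <= window_bp."""
    if not annotations:
        raise UsageError("empty annotation list")
    if window_bp <= 0:
        raise UsageError("window_bp must be positive")
    return sum(abs(a.tss_distance) <= window_bp for a in annotations) / len(annotations)


def density_summary(
    annotations: Sequence[PeakAnnotation],
    clamp_bp: int = 50_000,
    bin_width: int = 2_000,
) -> "np.recarray":
    """Histogram of signed TSS distances, clamped to +/- clamp_bp.

    Distances beyond the clamp are tallied in the boundary bins.  Returns a
    record array with fields (bin_left, bin_right, count); counts sum to
    the number of annotations.
    """
    if not annotations:
        raise UsageError("empty annotation list")
    if bin_width <= 0:
        raise UsageError("bin_width must be positive")
    if clamp_bp <= 0:
        raise UsageError("clamp_bp must be positive")
    d = np.clip([a.tss_distance for a in annotations], -clamp_bp, clamp_bp)
    edges = np.arange(-clamp_bp, clamp_bp + bin_width, bin_width, dtype=float)
    if edges[-1] < clamp_bp:
        edges = np.append(edges, clamp_bp)
    counts, _ = np.histogram(d, bins=edges)
    out = np.recarray(len(counts), dtype=[("bin_left", float), ("bin_right", float), ("count", int)])
    out.bin_left = edges[:-1]
    out.bin_right = edges[1:]
    out.count = counts
    return out


@dataclass
class ContingencyResult:
    """Pearson chi-squared test on the 2x2 motif x proximity table."""

    table: np.ndarray  # rows: motif -/+, cols: distal/proximal
    chi2: float
    df: int
    p_value: float
    degenerate: bool


def contingency_chi2(
    annotations: Sequence[PeakAnnotation], window_bp: int = PROXIMAL_WINDOW_BP
) -> ContingencyResult:
    """Chi-squared (no continuity correction, df=1) of motif vs proximity."""
    if not annotations:
        raise UsageError("empty annotation list")
    table = np.zeros((2, 2), dtype=np.int64)
    for a in annotations:
        table[int(a.has_motif), int(abs(a.tss_distance) <= window_bp)] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ContingencyResult(table=table, chi2=0.0, df=1, p_value=float("nan"), degenerate=True)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyResult(table=table, chi2=float(chi2), df=int(df), p_value=float(p), degenerate=False)


def class_counts(annotations: Iterable[PeakAnnotation]) -> dict[str, dict[str, int]]:
    """Region-class counts split by motif flag."""
    out = {"with_motif": dict.fromkeys(REGION_CLASSES, 0), "without_motif": dict.fromkeys(REGION_CLASSES, 0)}
    for a in annotations:
        key = "with_motif" if a.has_motif else "without_motif"
        out[key][a.region_class] += 1
    return out
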