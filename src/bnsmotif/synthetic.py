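"""Synthetic Bind-n-Seq libraries and a synthetic genome/peak set.

The selection simulator is an explicit stand-in for the wet selection: a
random 21-mer pool is filtered by a one-site occupancy model.  For a read
``s`` with best both-strand log-odds score ``b(s)`` against a planted motif
(maximum attainable score ``b_max``), specific retention is

    p_spec = P / (P + K_half * exp(lambda * (b_max - b(s)))) * exp(-w_spec * salt)

i.e. Hill-coefficient-1 occupancy whose effective dissociation constant
grows exponentially with the score deficit, times an exponential wash
survival.  Nonspecific carryover is

    p_ns = alpha * P / (P + K_half) * exp(-w_nonspec * salt) + epsilon

with ``w_nonspec > w_spec`` (nonspecific complexes wash off faster) and a
salt-independent carryover floor ``epsilon``.  A read is retained with
probability ``min(1, p_spec + p_ns)``.  Everything is a pure function of
the seed and the parameters.

The genome generator plants one motif instance in a configurable fraction
of peaks and biases motif-free peaks toward TSS-proximal positions, with a
truth table recording planted status and true TSS distance.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._encode import encode, decode, revcomp_enc, pack_windows, score_table
from .errors import GenerationError, UsageError
from .motifs import Motif, MIZM1_CONSENSUS
from .seqio import (
    BnSRead,
    GeneRecord,
    Peak,
    write_bed,
    write_fasta,
    write_fastq,
    write_gene_table,
)

LN2 = math.log(2.0)

#: The ten Bind-n-Seq conditions (barcode, protein nM, salt mM): five for the
#: full-length construct, five for the zinc-finger construct.
TABLE1_CONDITIONS_FL = [("ACA", 50.0, 1.0), ("ACC", 50.0, 50.0), ("ACG", 50.0, 100.0),
                        ("ACT", 5.0, 100.0), ("AGA", 350.0, 100.0)]
TABLE1_CONDITIONS_ZF = [("AGC", 50.0, 1.0), ("AGG", 50.0, 50.0), ("AGT", 50.0, 100.0),
                        ("ATA", 5.0, 100.0), ("ATC", 120.0, 100.0)]
DEFAULT_BARCODES = [b for b, _, _ in TABLE1_CONDITIONS_FL + TABLE1_CONDITIONS_ZF]


@dataclass(frozen=True)
class BnSCondition:
    """One experimental condition: barcode, protein concentration, wash salt."""

    barcode: str
    protein_nM: float
    salt_mM: float

    def __post_init__(self) -> None:
        if len(self.barcode) != 3:
            raise UsageError(f"barcode must be 3 nt, got {self.barcode!r}")
        if self.protein_nM < 0 or self.salt_mM < 0:
            raise UsageError("protein and salt concentrations must be non-negative")


def table1_conditions(construct: str = "FL") -> list[BnSCondition]:
    rows = TABLE1_CONDITIONS_FL if construct == "FL" else TABLE1_CONDITIONS_ZF
    return [BnSCondition(*r) for r in rows]


@dataclass
class SelectionModel:
    """Parametric retention model linking PWM score to read survival.

    Parameters
    ----------
    planted_motifs : list of (Motif, float)
        Motifs driving specific retention; the float is a relative affinity
        (>= 0) dividing the half-saturation constant for that motif.
    energy_scale : float
        lambda, in 1/bits: one bit of score deficit multiplies the effective
        dissociation constant by exp(lambda).  The default ln 2 makes one
        bit of log-odds exactly one factor of two in affinity.
    half_saturation_nM : float
        Protein concentration at half occupancy for a perfect site.
    nonspecific_floor : float
        alpha in [0, 1]: amplitude of protein-dependent nonspecific binding.
    wash_decay_specific, wash_decay_nonspecific : float
        Exponential wash survival rates, 1/mM; nonspecific must exceed
        specific.
    carryover : float
        epsilon: salt- and protein-independent retention floor.
    """

    planted_motifs: list[tuple[Motif, float]] = field(default_factory=list)
    energy_scale: float = LN2
    half_saturation_nM: float = 50.0
    nonspecific_floor: float = 0.2
    wash_decay_specific: float = 0.01
    wash_decay_nonspecific: float = 0.03
    carryover: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonspecific_floor <= 1.0:
            raise UsageError("nonspecific_floor must lie in [0, 1]")
        if self.wash_decay_nonspecific <= self.wash_decay_specific:
            raise UsageError("wash_decay_nonspecific must exceed wash_decay_specific")
        if not 0.0 <= self.carryover <= 1.0:
            raise UsageError("carryover must be a probability")
        if self.half_saturation_nM <= 0:
            raise UsageError("half_saturation_nM must be positive")
        for _, aff in self.planted_motifs:
            if aff < 0:
                raise UsageError("relative affinities must be non-negative")

    # closed-form pieces, also useful as test oracles ------------------------

    def specific_retention(
        self, score_deficit_bits: float, protein_nM: float, salt_mM: float,
        relative_affinity: float = 1.0,
    ) -> float:
        """Retention probability of a read via specific binding alone."""
        if protein_nM <= 0 or relative_affinity <= 0:
            return 0.0
        k_eff = (self.half_saturation_nM / relative_affinity) * math.exp(
            self.energy_scale * score_deficit_bits
        )
        occ = protein_nM / (protein_nM + k_eff)
        return occ * math.exp(-self.wash_decay_specific * salt_mM)

    def nonspecific_retention(self, protein_nM: float, salt_mM: float) -> float:
        """Protein-dependent nonspecific retention plus the carryover floor."""
        occ = protein_nM / (protein_nM + self.half_saturation_nM) if protein_nM > 0 else 0.0
        return (
            self.nonspecific_floor * occ * math.exp(-self.wash_decay_nonspecific * salt_mM)
            + self.carryover
        )


def default_selection_model(
    consensus: str = MIZM1_CONSENSUS,
    consensus_weight: float = 0.6,
    relative_affinity: float = 1.0,
    **overrides,
) -> SelectionModel:
    """The documented default model with one planted motif.

    ``consensus_weight`` is the planted PWM's per-column probability of the
    consensus base (0.6 by default: a specific but not razor-sharp site).
    """
    motif = Motif.from_consensus(consensus, p0=consensus_weight, motif_id="planted")
    return SelectionModel(planted_motifs=[(motif, relative_affinity)], **overrides)


@dataclass
class SimulationConfig:
    """Full specification of one simulated Bind-n-Seq experiment."""

    seed: int
    conditions: list[BnSCondition]
    selection: SelectionModel
    n_background: int = 100_000
    n_selected: int = 100_000
    region_length: int = 21
    max_candidate_factor: int = 4000  # cap on candidates per retained read

    def __post_init__(self) -> None:
        if self.n_background <= 0 or self.n_selected <= 0:
            raise UsageError("n_background and n_selected must be positive")
        barcodes = [c.barcode for c in self.conditions]
        if len(set(barcodes)) != len(barcodes):
            raise UsageError("condition barcodes must be unique")
        for m, _ in self.selection.planted_motifs:
            if m.width > self.region_length:
                raise UsageError("planted motif wider than the binding region")


def default_config(
    seed: int = 0,
    conditions: list[BnSCondition] | None = None,
    n_background: int = 100_000,
    n_selected: int = 100_000,
    **model_overrides,
) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        conditions=conditions if conditions is not None else [BnSCondition("ACC", 50.0, 50.0)],
        selection=default_selection_model(**model_overrides),
        n_background=n_background,
        n_selected=n_selected,
    )


# ---------------------------------------------------------------------------
# read-pool generation


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def generate_background_library(n: int, length: int = 21, seed: int = 0) -> list[str]:
    """i.i.d. uniform random sequences over {A,C,G,T}; pure function of seed."""
    if n <= 0:
        raise UsageError("n must be positive")
    mat = _rng_for(seed, 0xBAC).integers(0, 4, size=(n, length), dtype=np.int8)
    return [decode(row) for row in mat]


class _MotifScorer:
    """Best both-strand window score of fixed-length reads against one motif."""

    def __init__(self, motif: Motif, pseudocount: float = 0.1):
        self.width = motif.width
        S = motif.log_odds(pseudocount=pseudocount)
        self.table_fwd = score_table(S)
        self.table_rev = score_table(S[::-1, ::-1])
        self.b_max = float(self.table_fwd.max())

    def best_scores(self, mat: np.ndarray) -> np.ndarray:
        packed, valid = pack_windows(mat, self.width)
        s = np.maximum(self.table_fwd[packed], self.table_rev[packed])
        s[~valid] = -np.inf
        return s.max(axis=1)


def _retention_probability(
    mat: np.ndarray, scorers: list[tuple[_MotifScorer, float]],
    model: SelectionModel, protein: float, salt: float,
) -> np.ndarray:
    n = mat.shape[0]
    p_spec = np.zeros(n)
    if protein > 0:
        wash = math.exp(-model.wash_decay_specific * salt)
        for scorer, affinity in scorers:
            if affinity <= 0:
                continue
            deficit = scorer.b_max - scorer.best_scores(mat)
            k_eff = (model.half_saturation_nM / affinity) * np.exp(
                np.minimum(model.energy_scale * deficit, 700.0)
            )
            p_spec = np.maximum(p_spec, wash * protein / (protein + k_eff))
    p_ns = model.nonspecific_retention(protein, salt)
    return np.minimum(p_spec + p_ns, 1.0)


@dataclass
class BnsLibrary:
    """Output bundle of one simulated experiment."""

    config: SimulationConfig
    background: list[str]
    selected: dict[str, list[BnSRead]]  # keyed by condition barcode


def generate_bns_library(config: SimulationConfig) -> BnsLibrary:
    """Simulate retained read pools for every condition, plus background.

    Candidate reads are drawn uniformly and pass the retention filter
    independently; sampling continues (in chunks) until ``n_selected`` reads
    are retained per condition.  Retained reads get the condition barcode
    prepended and constant Q40 qualities.
    """
    scorers = [(_MotifScorer(m), aff) for m, aff in config.selection.planted_motifs]
    background = generate_background_library(
        config.n_background, config.region_length, seed=config.seed
    )
    selected: dict[str, list[BnSRead]] = {}
    chunk = 1_000_000
    for ci, cond in enumerate(config.conditions):
        rng = _rng_for(config.seed, 1, ci)
        kept: list[str] = []
        candidates_used = 0
        budget = config.max_candidate_factor * config.n_selected
        while len(kept) < config.n_selected:
            if candidates_used >= budget:
                raise GenerationError(
                    f"condition {cond.barcode}: retention too low to collect "
                    f"{config.n_selected} reads within {budget} candidates"
                )
            size = min(chunk, budget - candidates_used)
            mat = rng.integers(0, 4, size=(size, config.region_length), dtype=np.int8)
            p = _retention_probability(
                mat, scorers, config.selection, cond.protein_nM, cond.salt_mM
            )
            keep = rng.random(size) < p
            candidates_used += size
            for row in mat[keep]:
                kept.append(decode(row))
                if len(kept) == config.n_selected:
                    break
        selected[cond.barcode] = [
            BnSRead(
                read_id=f"{cond.barcode}_{i + 1}",
                barcode=cond.barcode,
                region=region,
                qualities=[40] * (len(cond.barcode) + len(region)),
            )
            for i, region in enumerate(kept)
        ]
    return BnsLibrary(config=config, background=background, selected=selected)


def write_bns_library(library: BnsLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Write background.fastq, one FASTQ per condition, and a pooled FASTQ."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    bg_reads = [
        BnSRead(read_id=f"bg_{i + 1}", barcode="NNN", region=seq, qualities=None)
        for i, seq in enumerate(library.background)
    ]
    # background reads carry no condition barcode: write region only
    paths["background"] = out_dir / "background.fastq"
    with paths["background"].open("w") as fh:
        for r in bg_reads:
            fh.write(f"@{r.read_id}\n{r.region}\n+\n{'I' * len(r.region)}\n")
    pooled = out_dir / "selected_pool.fastq"
    with pooled.open("w") as pooled_fh:
        for barcode, reads in library.selected.items():
            p = out_dir / f"{barcode}.fastq"
            write_fastq(reads, p)
            pooled_fh.write(p.read_text())
            paths[barcode] = p
    paths["pooled"] = pooled
    return paths


# ---------------------------------------------------------------------------
# synthetic genome + gene table + peaks


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    genes: list[GeneRecord]
    peaks: list[Peak]
    truth: pd.DataFrame  # peak_id, has_motif, planted_offset, strand, true_tss_distance


def _signed_tss_distance(mid: int, genes: list[GeneRecord]) -> tuple[float, str]:
    """Strand-adjusted signed distance to the nearest TSS (ties: lower coord)."""
    best = None
    for g in sorted(genes, key=lambda g: (g.tss, g.gene_id)):
        d_abs = abs(mid - g.tss)
        if best is None or d_abs < best[0]:
            signed = mid - g.tss if g.strand == "+" else g.tss - mid
            best = (d_abs, signed, g.gene_id)
    return float(best[1]), best[2]


def _occurrence_starts(seq: str, consensus: str) -> list[int]:
    rc = _revcomp_str(consensus)
    w = len(consensus)
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if window == consensus or window == rc:
            hits.append(i)
    return hits


def _revcomp_str(s: str) -> str:
    return decode(revcomp_enc(encode(s)))


def generate_synthetic_genome_and_peaks(
    seed: int = 0,
    n_genes: int = 30,
    n_peaks: int = 400,
    motif: Motif | str = MIZM1_CONSENSUS,
    frac_motif_peaks: float = 0.5,
    proximal_bias: float = 0.9,
    genome_length: int | None = None,
    peak_width: int = 200,
    proximal_bp: int = 1500,
    max_distal_bp: int = 30_000,
) -> SyntheticGenome:
    """Random genome in which a planted motif prefers TSS-distal peaks.

    Motif-free peaks are placed TSS-proximal (|distance| <= ``proximal_bp``)
    with probability ``proximal_bias``; motif-containing peaks with
    probability ``1 - proximal_bias``.  Each motif-containing peak carries
    exactly one planted consensus instance at a random offset and strand,
    and motif-free peaks are guaranteed clean of the consensus on both
    strands.
    """
    if not (0.0 <= frac_motif_peaks <= 1.0 and 0.0 <= proximal_bias <= 1.0):
        raise UsageError("frac_motif_peaks and proximal_bias must lie in [0, 1]")
    consensus = motif if isinstance(motif, str) else motif.consensus
    w = len(consensus)
    if w >= peak_width:
        raise UsageError("peak_width must exceed the motif width")
    rng = _rng_for(seed, 0x6E0)
    glen = genome_length or max(200_000, n_genes * 40_000)
    slot = glen // n_genes
    margin = 2_000
    if slot - 2 * margin < 5_000:
        raise GenerationError(
            f"genome of {glen} bp too small for {n_genes} non-overlapping genes"
        )
    chrom = "chr1"
    genome_arr = rng.integers(0, 4, size=glen, dtype=np.int8)

    genes: list[GeneRecord] = []
    for gi in range(n_genes):
        gene_len = int(rng.integers(4_000, min(12_000, slot - 2 * margin) + 1))
        lo = gi * slot + margin
        hi = (gi + 1) * slot - margin - gene_len
        tx_start = int(rng.integers(lo, max(lo + 1, hi)))
        tx_end = tx_start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 7))
        inner = np.sort(
            rng.choice(np.arange(tx_start + 100, tx_end - 100), size=2 * (n_ex - 1), replace=False)
        )
        exon_starts = [tx_start] + [int(x) for x in inner[1::2]]
        exon_ends = [int(x) for x in inner[0::2]] + [tx_end]
        genes.append(
            GeneRecord(
                gene_id=f"g{gi + 1}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
        )

    n_motif = int(round(frac_motif_peaks * n_peaks))
    has_motif = np.zeros(n_peaks, dtype=bool)
    has_motif[:n_motif] = True
    rng.shuffle(has_motif)

    tss_arr = np.array([g.tss for g in genes])
    occupied: list[tuple[int, int]] = []  # sorted peak intervals

    def overlaps(start: int, end: int) -> bool:
        i = bisect_left(occupied, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(occupied):
                s, e = occupied[j]
                if s < end and start < e:
                    return True
        return False

    peaks: list[Peak] = []
    rows = []
    for pi in range(n_peaks):
        motif_here = bool(has_motif[pi])
        want_proximal = rng.random() < (1.0 - proximal_bias if motif_here else proximal_bias)
        placed = False
        for _ in range(2_000):
            g = genes[int(rng.integers(0, n_genes))]
            if want_proximal:
                mid = g.tss + int(rng.integers(-proximal_bp, proximal_bp + 1))
            else:
                sign = -1 if rng.random() < 0.5 else 1
                mid = g.tss + sign * int(
                    rng.integers(proximal_bp + peak_width, max_distal_bp + 1)
                )
            start = mid - peak_width // 2
            end = start + peak_width
            if start < 0 or end > glen or overlaps(start, end):
                continue
            nearest = np.abs(tss_arr - mid).min()
            if want_proximal != (nearest <= proximal_bp):
                continue
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place peak {pi + 1} (genome too crowded for {n_peaks} peaks)"
            )
        insort(occupied, (start, end))
        peak = Peak(chrom=chrom, start=start, end=end, peak_id=f"peak_{pi + 1}")
        peaks.append(peak)

        planted_offset, planted_strand = -1, "."
        if motif_here:
            planted_offset = int(rng.integers(0, peak_width - w + 1))
            planted_strand = "+" if rng.random() < 0.5 else "-"
            site = encode(consensus if planted_strand == "+" else _revcomp_str(consensus))
            genome_arr[start + planted_offset : start + planted_offset + w] = site

        # guarantee the truth table is exactly recoverable by string search
        for _ in range(100):
            seq = decode(genome_arr[start:end])
            occ = _occurrence_starts(seq, consensus)
            if motif_here and occ == [planted_offset]:
                break
            if not motif_here and not occ:
                break
            redraw = np.ones(peak_width, dtype=bool)
            if motif_here:
                redraw[planted_offset : planted_offset + w] = False
            idx = np.nonzero(redraw)[0]
            genome_arr[start + idx] = rng.integers(0, 4, size=idx.size, dtype=np.int8)
        else:  # pragma: no cover - overwhelmingly unlikely
            raise GenerationError(f"could not sanitize peak {peak.peak_id}")

        true_dist, _ = _signed_tss_distance((start + end) // 2, genes)
        rows.append(
            {
                "peak_id": peak.peak_id,
                "has_motif": motif_here,
                "planted_offset": planted_offset,
                "strand": planted_strand,
                "true_tss_distance": true_dist,
            }
        )

    truth = pd.DataFrame(rows)
    return SyntheticGenome(
        genome={chrom: decode(genome_arr)}, genes=genes, peaks=peaks, truth=truth
    )


def write_synthetic_genome(data: SyntheticGenome, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "genes": out_dir / "genes.tsv",
        "peaks": out_dir / "peaks.bed",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(sorted(data.genome.items()), paths["genome"])
    write_gene_table(data.genes, paths["genes"])
    write_bed(data.peaks, paths["peaks"])
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
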