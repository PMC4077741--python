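"""Readers and writers for the external formats, plus sequence utilities.

Formats handled: 4-line FASTQ (Bind-n-Seq dialect: first 3 bases are the
condition barcode, the remainder the randomized binding region), FASTA,
BED3/BED4, MEME minimal motif format, and a refFlat-like tab-separated
gene table.  Coordinates are 0-based half-open throughout; a minus-strand
gene's TSS is ``tx_end - 1`` (its last transcribed 0-based coordinate) so
that distances on both strands live in one coordinate frame.

All writers emit byte-stable output given identical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._encode import ALPHABET
from .errors import FormatError
from .motifs import Motif

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BARCODE_LENGTH = 3
REGION_LENGTH = 21


def clean_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase and validate a nucleotide string over {A,C,G,T,N}.

    Characters outside the alphabet are rejected, not silently masked.
    """
    s = seq.strip().upper()
    bad = set(s) - _VALID
    if bad:
        raise FormatError(f"{context} contains invalid characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N.  An involution."""
    return clean_sequence(seq).translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain records


@dataclass
class BnSRead:
    """One barcoded selection read: 3-nt barcode + randomized binding region."""

    read_id: str
    barcode: str
    region: str
    qualities: list[int] | None = None

    @property
    def sequence(self) -> str:
        return self.barcode + self.region

    def mean_quality(self) -> float:
        if not self.qualities:
            return float("inf")
        return float(np.mean(self.qualities))


@dataclass
class Peak:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    peak_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"peak {self.peak_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneRecord:
    """A gene model in refFlat-like coordinates (0-based txStart, 1-past-end txEnd)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: list[int] = field(default_factory=list)
    exon_ends: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise FormatError(f"gene {self.gene_id}: txEnd must exceed txStart")
        if len(self.exon_starts) != len(self.exon_ends):
            raise FormatError(f"gene {self.gene_id}: exon start/end lists differ in length")

    @property
    def tss(self) -> int:
        """Transcription start site: txStart on +, txEnd-1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (opposite end of the gene)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[BnSRead]:
    """Stream 4-line FASTQ records, splitting each read into barcode + region.

    The first ``BARCODE_LENGTH`` bases are the condition barcode; the rest is
    the randomized binding region.  Malformed records raise
    :class:`FormatError` naming the line number.
    """
    path = Path(path)
    with path.open() as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.strip():
                continue
            if not header.startswith("@"):
                raise FormatError(f"{path.name}:{lineno}: expected '@' header, got {header.strip()!r}")
            seq_line = fh.readline()
            plus_line = fh.readline()
            qual_line = fh.readline()
            if not qual_line:
                raise FormatError(f"{path.name}:{lineno}: truncated FASTQ record")
            seq = clean_sequence(seq_line, context=f"{path.name}:{lineno + 1}")
            if not plus_line.startswith("+"):
                raise FormatError(f"{path.name}:{lineno + 2}: missing '+' separator")
            qual = qual_line.strip()
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path.name}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            if len(seq) <= BARCODE_LENGTH:
                raise FormatError(f"{path.name}:{lineno + 1}: read shorter than barcode")
            read_id = header[1:].strip().split()[0]
            yield BnSRead(
                read_id=read_id,
                barcode=seq[:BARCODE_LENGTH],
                region=seq[BARCODE_LENGTH:],
                qualities=[ord(c) - 33 for c in qual],
            )
            lineno += 3


def write_fastq(reads: Iterable[BnSRead], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in reads:
            seq = r.sequence
            qual = (
                "".join(chr(q + 33) for q in r.qualities)
                if r.qualities is not None
                else "I" * len(seq)
            )
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs; lowercase input is uppercased."""
    path = Path(path)
    with path.open() as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path.name}: sequence data before any FASTA header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, clean_sequence(str(rec.seq), context=f"record {rec.id}")))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in records:
            SeqIO.write([SeqRecord(Seq(seq), id=rid, description="")], fh, "fasta")
    # Biopython wraps at 60 columns; width kept as documentation of that fact.


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_motifs(path: str | Path) -> list[Motif]:
    """Parse MEME minimal motif format (version 4)."""
    path = Path(path)
    background = None
    motifs: list[Motif] = []
    lines = path.read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in ALPHABET])
            i += 1
            continue
        if line.startswith("MOTIF"):
            toks = line.split()
            motif_id = toks[1] if len(toks) > 1 else f"motif_{len(motifs) + 1}"
            i += 1
            # find the letter-probability header
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path.name}:{i + 1}: MOTIF {motif_id} has no matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path.name}: MOTIF {motif_id} has no letter-probability matrix")
            header = lines[i].strip()
            attrs = dict(
                zip(
                    header.replace("letter-probability matrix:", "").split()[::2],
                    header.replace("letter-probability matrix:", "").split()[1::2],
                )
            )
            w = int(attrs.get("w=", attrs.get("w", 0)) or 0)
            nsites = float(attrs.get("nsites=", attrs.get("nsites", 20)) or 20)
            i += 1
            rows = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in s.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path.name}:{i + 1}: expected 4 probabilities, got {len(vals)}")
                if not (1 - 1e-3) <= sum(vals) <= (1 + 1e-3):
                    raise FormatError(
                        f"{path.name}:{i + 1}: probability row sums to {sum(vals):.6f}, outside [0.999, 1.001]"
                    )
                rows.append(vals)
                i += 1
            if w and len(rows) != w:
                raise FormatError(f"{path.name}: MOTIF {motif_id}: {len(rows)} rows but w={w}")
            motifs.append(
                Motif(
                    motif_id=motif_id,
                    probs=np.array(rows),
                    background=background if background is not None else np.full(4, 0.25),
                    nsites=nsites,
                )
            )
            continue
        i += 1
    return motifs


def write_meme_motifs(motifs: Iterable[Motif], path: str | Path) -> None:
    motifs = list(motifs)
    with Path(path).open("w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.nsites:g} E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Peak]:
    """BED3+ intervals in file order; 3-column lines get ids ``peak_1``..."""
    path = Path(path)
    peaks = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise FormatError(f"{path.name}:{lineno}: BED needs at least 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
        if end <= start or start < 0:
            raise FormatError(f"{path.name}:{lineno}: need 0 <= start < end, got {start}, {end}")
        name = cols[3] if len(cols) > 3 and cols[3] else f"peak_{len(peaks) + 1}"
        peaks.append(Peak(chrom=cols[0], start=start, end=end, peak_id=name))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


# ---------------------------------------------------------------------------
# gene table (refFlat-like)

_GENE_COLUMNS = [
    "geneName",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
]


def _parse_int_list(s: str) -> list[int]:
    return [int(x) for x in str(s).rstrip(",").split(",") if x != ""]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Tab-separated gene models with refFlat-style exon lists.

    Expected columns: geneName chrom strand txStart txEnd exonCount
    exonStarts exonEnds (header line optional).
    """
    path = Path(path)
    genes = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if cols[0] == "geneName":
            continue
        if len(cols) < 8:
            raise FormatError(f"{path.name}:{lineno}: expected 8 columns, got {len(cols)}")
        try:
            exon_starts = _parse_int_list(cols[6])
            exon_ends = _parse_int_list(cols[7])
            rec = GeneRecord(
                gene_id=cols[0],
                chrom=cols[1],
                strand=cols[2],
                tx_start=int(cols[3]),
                tx_end=int(cols[4]),
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
        except FormatError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
        if int(cols[5]) != len(exon_starts):
            raise FormatError(f"{path.name}:{lineno}: exonCount disagrees with exonStarts")
        genes.append(rec)
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(len(g.exon_starts)),
                        ",".join(map(str, g.exon_starts)) + ",",
                        ",".join(map(str, g.exon_ends)) + ",",
                    ]
                )
                + "\n"
            )
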