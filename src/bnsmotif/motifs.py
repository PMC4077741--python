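"""Position weight matrices.

A :class:`Motif` is a per-position base-probability matrix over {A,C,G,T}
together with a background distribution, an effective site count, and
(optionally) a fold-enrichment score attached by the discovery pipeline.
Row order of matrices follows the encoding A, C, G, T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encode import ALPHABET, encode
from .errors import UsageError

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Paper-reported consensus sequences for the two Miz-1 binding motifs.
MIZM1_CONSENSUS = "ATCGGTAATC"
MIZM2_CONSENSUS = "ATCGAT"


@dataclass
class Motif:
    """A DNA binding motif as a probability matrix.

    Parameters
    ----------
    motif_id : str
        Identifier used in MEME files and reports.
    probs : ndarray of shape (width, 4)
        Per-position base probabilities; rows are normalised on construction.
    background : ndarray of shape (4,)
        Background base distribution (default uniform).
    nsites : float
        Effective number of sites the matrix was estimated from.
    counts : ndarray of shape (width, 4), optional
        Raw base counts, when the motif came from counted sites.
    enrichment_score : float, optional
        Fold enrichment attached by the discovery pipeline.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    nsites: float = 20.0
    counts: np.ndarray | None = None
    enrichment_score: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise UsageError("probability matrix must have shape (width, 4)")
        if (self.probs < 0).any():
            raise UsageError("probabilities must be non-negative")
        rowsum = self.probs.sum(axis=1)
        if (rowsum <= 0).any():
            raise UsageError("each probability row must have positive mass")
        self.probs = self.probs / rowsum[:, None]
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.background.shape != (4,) or (self.background <= 0).any():
            raise UsageError("background must be a strictly positive 4-vector")
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Per-column most probable base."""
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self, motif_id: str | None = None) -> "Motif":
        return Motif(
            motif_id=motif_id or f"{self.motif_id}_rc",
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background.copy(),
            nsites=self.nsites,
            counts=None if self.counts is None else self.counts[::-1, ::-1].copy(),
            enrichment_score=self.enrichment_score,
        )

    def log_odds(
        self,
        background: np.ndarray | None = None,
        pseudocount: float = 0.1,
    ) -> np.ndarray:
        """Log2 odds score matrix (bits); see :func:`build_log_odds`."""
        from .scanning import build_log_odds

        return build_log_odds(self, background=background, pseudocount=pseudocount)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        p0: float = 0.7,
        motif_id: str | None = None,
        background: np.ndarray | None = None,
        nsites: float = 20.0,
    ) -> "Motif":
        """Build a PWM giving probability ``p0`` to each consensus base.

        The remaining mass (1 - p0) is split evenly over the other three
        bases.  Requires 0.25 < p0 < 1 so the consensus is the argmax.
        """
        if not 0.25 < p0 < 1.0:
            raise UsageError("p0 must lie in (0.25, 1)")
        enc = encode(consensus)
        if (enc < 0).any():
            raise UsageError("consensus may not contain N")
        probs = np.full((len(consensus), 4), (1.0 - p0) / 3.0)
        probs[np.arange(len(consensus)), enc] = p0
        return cls(
            motif_id=motif_id or consensus,
            probs=probs,
            background=UNIFORM_BACKGROUND.copy() if background is None else background,
            nsites=nsites,
        )

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.1,
        motif_id: str = "motif",
        background: np.ndarray | None = None,
    ) -> "Motif":
        counts = np.asarray(counts, dtype=np.float64)
        if (counts < 0).any():
            raise UsageError("counts must be non-negative")
        sm = counts + pseudocount
        m = cls(
            motif_id=motif_id,
            probs=sm / sm.sum(axis=1, keepdims=True),
            background=UNIFORM_BACKGROUND.copy() if background is None else background,
            nsites=float(counts.sum(axis=1).mean()),
        )
        m.counts = counts
        return m


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise UsageError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))
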