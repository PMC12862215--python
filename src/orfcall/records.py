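"""Core record types shared across the package.

A transcript is a spliced mRNA/ncRNA sequence in transcript coordinates
(no genome coordinates anywhere in this package).  Coding transcripts
carry the span of their annotated coding sequence (CDS) as a 0-based
half-open interval ``[cds_start, cds_end)`` covering start codon through
stop codon inclusive; ``cds_end - cds_start`` is therefore a multiple
of 3 and the stop codon occupies ``[cds_end - 3, cds_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")

# Per-position label classes.  The network's output channels follow the
# same order: channel 0 = TIS, 1 = TTS, 2 = everything else.
TIS = 0
TTS = 1
NONE = 2

CLASS_NAMES = ("TIS", "TTS", "NONE")


@dataclass
class TranscriptRecord:
    """One transcript with its sequence and (optional) CDS annotation."""

    transcript_id: str
    gene_symbol: str
    sequence: str
    biotype: str  # "coding" or "noncoding"
    cds_start: Optional[int] = None  # 0-based inclusive start of the start codon
    cds_end: Optional[int] = None  # 0-based exclusive end of the stop codon

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(
                f"{self.transcript_id}: biotype must be 'coding' or 'noncoding', "
                f"got {self.biotype!r}"
            )
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters {sorted(bad)} in sequence"
            )
        if self.biotype == "coding":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.transcript_id}: coding record lacks CDS span")
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: CDS length "
                    f"{self.cds_end - self.cds_start} is not a multiple of 3"
                )
        else:
            if self.cds_start is not None or self.cds_end is not None:
                raise ValueError(
                    f"{self.transcript_id}: noncoding record carries CDS coordinates"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def tts_start(self) -> Optional[int]:
        """0-based start of the stop codon, or None for noncoding records."""
        if self.cds_end is None:
            return None
        return self.cds_end - 3


@dataclass
class EncodedSample:
    """A transcript encoded for the network: integer tokens + class labels.

    ``tokens`` and ``labels`` have fixed length ``L_max``; positions at or
    beyond ``valid_length`` are padding (token 0, label NONE) and are
    masked out of the loss and all metrics.
    """

    transcript_id: str
    tokens: np.ndarray  # int8/int64, shape (L_max,), values in 0..4
    labels: np.ndarray  # shape (L_max,), values in {TIS, TTS, NONE}
    valid_length: int
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.tokens.shape != self.labels.shape:
            raise ValueError("tokens/labels shape mismatch")
        if self.valid_length > self.tokens.shape[0]:
            raise ValueError("valid_length exceeds encoded length")


@dataclass
class DatasetSplit:
    """Gene-level train/heldout partition: all isoforms travel together."""

    assignment: Dict[str, str]  # gene_symbol -> "train" | "heldout"
    ratio: float = 0.80
    seed: int = 0

    def partition_of(self, gene_symbol: str) -> str:
        return self.assignment[gene_symbol]

    def genes(self, partition: str) -> list:
        return sorted(g for g, p in self.assignment.items() if p == partition)


def orf_scan(sequence: str):
    """Brute-force ORF enumeration: every (ATG, first in-frame stop) pair.

    Returns a list of ``(atg_start, stop_start)`` tuples sorted by ATG
    position.  The stop codon is the first in-frame stop strictly
    downstream of the ATG, so the enumerated ORFs contain no internal
    in-frame stop by construction.  Quadratic and dependency-free on
    purpose: this is the reference oracle the fast enumerator is checked
    against.
    """
    pairs = []
    n = len(sequence)
    for i in range(n - 2):
        if sequence[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, n - 2, 3):
            if sequence[j : j + 3] in STOP_CODONS:
                pairs.append((i, j))
                break
    return pairs
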