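"""Transcriptome input/output, encoding, and gene-level splitting.

Sequences come in as FASTA, annotations as a tab-separated table with
columns ``transcript_id, gene_symbol, biotype, cds_start, cds_end``
(coordinates 0-based half-open; the last two empty for noncoding rows).
A minimal GenBank flat-file reader is provided for convenience: it uses
only the CDS feature of each record and converts coordinates on read.

Encoding follows the integer scheme A, C, G, T/U -> 1..4 with both
ambiguous bases (N) and padding mapped to 0.  Labels are per-position
classes: the three nucleotides of the start codon are TIS, the three of
the stop codon are TTS, everything else NONE.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .records import NONE, TIS, TTS, DatasetSplit, EncodedSample, TranscriptRecord

logger = logging.getLogger(__name__)

# A,C,G,T -> 1..4; N and padding -> 0.
_BASE_TO_TOKEN = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 0}
_TOKEN_TO_BASE = {1: "A", 2: "C", 3: "G", 4: "T", 0: "N"}

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _t in _BASE_TO_TOKEN.items():
    _ENCODE_LUT[ord(_b)] = _t


def strip_version(transcript_id: str) -> str:
    """Drop the version suffix: text after (and including) the first '.'."""
    return transcript_id.split(".", 1)[0]


def normalize_sequence(raw: str, name: str = "<sequence>") -> str:
    """Uppercase, unify U->T, and reject characters outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"record {name}: invalid characters {sorted(bad)}")
    return seq


def read_transcript_fasta(path) -> List[Tuple[str, str]]:
    """Read a transcript FASTA into ``(id, sequence)`` pairs.

    Identifiers have their version suffix stripped; sequences are
    normalised (uppercase, U unified to T) and validated against the
    {A,C,G,T,N} alphabet.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((strip_version(rec.id), normalize_sequence(str(rec.seq), rec.id)))
    return out


def read_annotation_table(path, sequences: Dict[str, str]) -> List[TranscriptRecord]:
    """Join an annotation TSV with sequences into TranscriptRecords.

    Coding rows whose CDS length is not a multiple of 3 are excluded with
    a logged warning rather than raised, mirroring how curation glitches
    are handled in practice.  A transcript present in the table but
    missing from the FASTA, or listed twice, is an error.
    """
    records: List[TranscriptRecord] = []
    seen = set()
    n_excluded = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "transcript_id":  # optional header
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            tid = strip_version(parts[0])
            gene, biotype = parts[1], parts[2]
            if tid in seen:
                raise ValueError(f"duplicate transcript_id {tid!r}")
            seen.add(tid)
            if tid not in sequences:
                raise ValueError(f"transcript {tid!r} in annotation but not in FASTA")
            cds_start = cds_end = None
            if biotype == "coding":
                if len(parts) < 5 or parts[3] == "" or parts[4] == "":
                    raise ValueError(f"{path}:{lineno}: coding row lacks CDS span")
                cds_start, cds_end = int(parts[3]), int(parts[4])
                if (cds_end - cds_start) % 3 != 0:
                    logger.warning(
                        "excluding %s: CDS length %d not a multiple of 3",
                        tid,
                        cds_end - cds_start,
                    )
                    n_excluded += 1
                    continue
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_symbol=gene,
                    sequence=sequences[tid],
                    biotype=biotype,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    if n_excluded:
        logger.warning("excluded %d coding records with invalid CDS length", n_excluded)
    return records


def read_genbank_cds(path) -> List[TranscriptRecord]:
    """Minimal GenBank flat-file reader: sequence + first CDS feature only.

    Records without a CDS feature become noncoding.  Coordinates arrive
    via Biopython already converted to 0-based half-open.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = normalize_sequence(str(rec.seq), rec.id)
        gene = rec.annotations.get("gene", "")
        cds = next((f for f in rec.features if f.type == "CDS"), None)
        if cds is not None and not gene:
            gene = "".join(cds.qualifiers.get("gene", [""]))
        if cds is None:
            records.append(
                TranscriptRecord(strip_version(rec.id), gene or rec.id, seq, "noncoding")
            )
        else:
            records.append(
                TranscriptRecord(
                    strip_version(rec.id),
                    gene or rec.id,
                    seq,
                    "coding",
                    cds_start=int(cds.location.start),
                    cds_end=int(cds.location.end),
                )
            )
    return records


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a nucleotide string elementwise to integer tokens (A..T -> 1..4, N -> 0)."""
    if not sequence:
        return np.zeros(0, dtype=np.int8)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    tokens = _ENCODE_LUT[arr]
    if (tokens < 0).any():
        bad = sorted({chr(c) for c in arr[tokens < 0]})
        raise ValueError(f"invalid characters {bad} in sequence")
    return tokens


def decode_tokens(tokens: Sequence[int]) -> str:
    """Inverse of :func:`encode_sequence`; token 0 decodes to 'N' (N and padding collide)."""
    return "".join(_TOKEN_TO_BASE[int(t)] for t in tokens)


def encode_labels(record: TranscriptRecord) -> np.ndarray:
    """Per-position classes: 3 TIS positions, 3 TTS positions, rest NONE."""
    labels = np.full(record.length, NONE, dtype=np.int8)
    if record.biotype == "coding":
        labels[record.cds_start : record.cds_start + 3] = TIS
        labels[record.cds_end - 3 : record.cds_end] = TTS
    return labels


def pad_or_truncate(
    tokens: np.ndarray,
    labels: np.ndarray,
    l_max: int,
    transcript_id: str = "",
    biotype: str = "coding",
) -> EncodedSample:
    """Fix the encoded length to ``l_max``: 0/NONE padding, 3'-end truncation."""
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    n = len(tokens)
    out_tokens = np.zeros(l_max, dtype=tokens.dtype if n else np.int8)
    out_labels = np.full(l_max, NONE, dtype=labels.dtype if n else np.int8)
    keep = min(n, l_max)
    out_tokens[:keep] = tokens[:keep]
    out_labels[:keep] = labels[:keep]
    return EncodedSample(
        transcript_id=transcript_id,
        tokens=out_tokens,
        labels=out_labels,
        valid_length=keep,
        biotype=biotype,
    )


def length_percentile(lengths: Iterable[int], q: float = 99.9) -> int:
    """The q-th percentile of transcript lengths, rounded up to an integer.

    Used to choose the padded model length so that only the longest
    q-th-percentile tail of transcripts gets truncated.
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("empty length list")
    return int(np.ceil(np.percentile(arr, q)))


def build_dataset(
    records: Sequence[TranscriptRecord], l_max: int
) -> List[EncodedSample]:
    """Encode records for training, dropping coding ones whose stop codon
    would fall at or beyond ``l_max`` after truncation (their labels would
    be unlearnable).  The dropped count is logged.
    """
    samples = []
    n_dropped = 0
    for rec in records:
        if rec.biotype == "coding" and rec.cds_end > l_max:
            n_dropped += 1
            continue
        samples.append(
            pad_or_truncate(
                encode_sequence(rec.sequence),
                encode_labels(rec),
                l_max,
                transcript_id=rec.transcript_id,
                biotype=rec.biotype,
            )
        )
    if n_dropped:
        logger.warning(
            "dropped %d coding transcripts with CDS beyond l_max=%d", n_dropped, l_max
        )
    return samples


def split_by_gene(
    records: Sequence[TranscriptRecord], ratio: float = 0.80, seed: int = 0
) -> DatasetSplit:
    """Partition genes (not transcripts) into train/heldout.

    Every isoform of a gene lands in the same partition, preventing
    leakage of gene-specific sequence between splits.  Deterministic
    given the seed; the train set gets ``round(ratio * n_genes)`` genes
    (at least one when any exist).
    """
    if not records:
        raise ValueError("no records to split")
    genes = sorted({r.gene_symbol for r in records})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    n_train = int(round(ratio * len(genes)))
    n_train = min(max(n_train, 1), len(genes))
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[genes[idx]] = "train" if rank < n_train else "heldout"
    return DatasetSplit(assignment=assignment, ratio=ratio, seed=seed)


def subset_by_split(
    records: Sequence[TranscriptRecord], split: DatasetSplit, partition: str
) -> List[TranscriptRecord]:
    return [r for r in records if split.assignment[r.gene_symbol] == partition]


def write_split_manifest(split: DatasetSplit, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_symbol\tpartition\n")
        for gene in sorted(split.assignment):
            fh.write(f"{gene}\t{split.assignment[gene]}\n")


def read_split_manifest(path) -> DatasetSplit:
    assignment = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("", "gene_symbol"):
                continue
            assignment[parts[0]] = parts[1]
    return DatasetSplit(assignment=assignment)


def write_fasta(records: Sequence[TranscriptRecord], path, version_suffix: str = ".1") -> None:
    """Write records as FASTA.  A version suffix is appended to ids so the
    reader's version-stripping path is exercised on round trips."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}{version_suffix}\n")
            for i in range(0, rec.length, 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def write_annotation_table(records: Sequence[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_symbol\tbiotype\tcds_start\tcds_end\n")
        for rec in records:
            if rec.biotype == "coding":
                fh.write(
                    f"{rec.transcript_id}\t{rec.gene_symbol}\tcoding\t"
                    f"{rec.cds_start}\t{rec.cds_end}\n"
                )
            else:
                fh.write(f"{rec.transcript_id}\t{rec.gene_symbol}\tnoncoding\t\t\n")
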