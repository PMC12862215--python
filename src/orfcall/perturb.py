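"""Region-aware sequence perturbations with truth-coordinate bookkeeping.

Three operations probe what the trained network has learned:

* small insertions/deletions (1-3 nt) at a random position inside a
  chosen region — inside the CDS a 1- or 2-nt indel is a frameshift;
* a GC-preserving shuffle of a region (uniform permutation of its
  bases, so the base multiset is preserved bit-exactly);
* the identity condition, the unperturbed baseline.

For coding transcripts the regions are the annotated 5'UTR / CDS /
3'UTR.  Noncoding transcripts get positional stand-ins: first 5% of the
sequence as 5'UTR-like, middle 90% as CDS-like, last 5% as 3'UTR-like
(floor rounding; the remainder accrues to the middle region).

After an indel, every truth boundary strictly downstream of the edit
shifts by the net length change.  A frameshifting CDS indel therefore
leaves a "truth" stop span that is no longer a stop codon in frame —
deliberately so: scoring the prediction against this shifted truth is
what exposes the model's frame sensitivity.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluate import classify_orf_outcome, prediction_from_runs, summarize
from .records import TranscriptRecord

logger = logging.getLogger(__name__)

REGIONS = ("UTR5", "CDS", "UTR3")
BASES = "ACGT"


@dataclass(frozen=True)
class RegionSpec:
    region: str
    start: int  # 0-based half-open interval within the transcript
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PerturbationSpec:
    region: str  # UTR5 | CDS | UTR3
    operation: str  # insert | delete | shuffle | identity
    size: Optional[int] = None  # 1-3 nt, indels only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.operation in ("insert", "delete"):
            if self.size not in (1, 2, 3):
                raise ValueError("indel size must be 1, 2, or 3")
        elif self.size is not None:
            raise ValueError(f"size is not applicable to {self.operation!r}")

    @property
    def label(self) -> str:
        if self.operation in ("insert", "delete"):
            return f"{self.region}_{self.operation}{self.size}"
        if self.operation == "identity":
            return "identity"
        return f"{self.region}_{self.operation}"


def define_regions(record: TranscriptRecord) -> List[RegionSpec]:
    """UTR5/CDS/UTR3 intervals tiling the transcript without overlap."""
    n = record.length
    if record.biotype == "coding":
        if record.cds_end - record.cds_start <= 0:
            raise ValueError(f"{record.transcript_id}: empty CDS")
        bounds = (0, record.cds_start, record.cds_end, n)
    else:
        flank = int(0.05 * n)  # floor; remainder goes to the middle region
        bounds = (0, flank, n - flank, n)
    return [
        RegionSpec(region, bounds[i], bounds[i + 1])
        for i, region in enumerate(REGIONS)
    ]


def _rng_for(record_id: str, spec: PerturbationSpec) -> np.random.Generator:
    """Per-transcript RNG: reproducible from (record id, spec, seed),
    independent across transcripts."""
    return np.random.default_rng(
        [spec.seed & 0x7FFFFFFF, zlib.crc32(record_id.encode())]
    )


def _region_interval(record: TranscriptRecord, region: str) -> RegionSpec:
    for spec in define_regions(record):
        if spec.region == region:
            return spec
    raise ValueError(f"unknown region {region!r}")


def _shift_boundary(b: Optional[int], edit_pos: int, net: int,
                    deletion_end: Optional[int] = None) -> Optional[int]:
    """Shift one truth boundary by the net length change when it lies
    strictly downstream of the edit."""
    if b is None:
        return None
    if net > 0:  # insertion at edit_pos pushes positions > edit_pos
        return b + net if b > edit_pos else b
    # deletion of [edit_pos, deletion_end)
    if b >= deletion_end:
        return b + net
    return b


def apply_indel(
    record: TranscriptRecord, spec: PerturbationSpec
) -> TranscriptRecord:
    """Insert or delete ``spec.size`` bases at a random position in the region.

    Returns a new record whose CDS coordinates are shifted for every
    boundary strictly downstream of the edit.  The shifted record is
    built without re-validation (a frameshifted "stop" span is valid
    measurement truth even though it is no longer a stop codon).
    """
    rng = _rng_for(record.transcript_id, spec)
    interval = _region_interval(record, spec.region)
    size = spec.size
    seq = record.sequence
    if spec.operation == "insert":
        if interval.length < 1:
            raise ValueError(
                f"{record.transcript_id}: region {spec.region} empty, cannot insert"
            )
        pos = int(rng.integers(interval.start, interval.end))
        insert = "".join(BASES[i] for i in rng.integers(0, 4, size=size))
        new_seq = seq[:pos] + insert + seq[pos:]
        net = size
        new_start = _shift_boundary(record.cds_start, pos, net)
        new_end = _shift_boundary(record.cds_end, pos, net)
    elif spec.operation == "delete":
        if interval.length < size:
            raise ValueError(
                f"{record.transcript_id}: region {spec.region} shorter than "
                f"deletion size {size}"
            )
        pos = int(rng.integers(interval.start, interval.end - size + 1))
        new_seq = seq[:pos] + seq[pos + size :]
        net = -size
        new_start = _shift_boundary(record.cds_start, pos, net, pos + size)
        new_end = _shift_boundary(record.cds_end, pos, net, pos + size)
    else:
        raise ValueError(f"apply_indel cannot perform {spec.operation!r}")
    out = TranscriptRecord.__new__(TranscriptRecord)
    out.transcript_id = record.transcript_id
    out.gene_symbol = record.gene_symbol
    out.sequence = new_seq
    out.biotype = record.biotype
    out.cds_start = new_start
    out.cds_end = new_end
    return out


def shuffle_region(
    record: TranscriptRecord, region: str, seed: int = 0
) -> TranscriptRecord:
    """Uniform random permutation of a region's bases (GC preserved exactly).

    Truth coordinates are unchanged.  A region shorter than 2 nt is a
    no-op with a warning.
    """
    interval = _region_interval(record, region)
    if interval.length < 2:
        logger.warning(
            "%s: region %s too short to shuffle, leaving unchanged",
            record.transcript_id, region,
        )
        return record
    rng = _rng_for(record.transcript_id,
                   PerturbationSpec(region, "shuffle", seed=seed))
    chars = list(record.sequence[interval.start : interval.end])
    rng.shuffle(chars)
    new_seq = (
        record.sequence[: interval.start]
        + "".join(chars)
        + record.sequence[interval.end :]
    )
    out = TranscriptRecord.__new__(TranscriptRecord)
    out.transcript_id = record.transcript_id
    out.gene_symbol = record.gene_symbol
    out.sequence = new_seq
    out.biotype = record.biotype
    out.cds_start = record.cds_start
    out.cds_end = record.cds_end
    return out


def apply_perturbation(
    record: TranscriptRecord, spec: PerturbationSpec
) -> TranscriptRecord:
    if spec.operation == "identity":
        return record
    if spec.operation == "shuffle":
        return shuffle_region(record, spec.region, seed=spec.seed)
    return apply_indel(record, spec)


def run_experiment(
    records: Sequence[TranscriptRecord],
    model,
    conditions: Sequence[PerturbationSpec],
    l_max: Optional[int] = None,
    batch_size: int = 16,
) -> pd.DataFrame:
    """Perturb, predict with raw argmax decoding, classify, summarise.

    Evaluation deliberately uses the raw model output (no integrated
    scoring) so that the measured sensitivity reflects what the network
    itself learned.  The identity condition reproduces the unperturbed
    baseline exactly.  Returns one row per condition with the outcome
    fractions in percent.
    """
    from .pipeline import predict_tracks  # local import to avoid a cycle

    rows = []
    for spec in conditions:
        perturbed = [apply_perturbation(rec, spec) for rec in records]
        tracks = predict_tracks(model, perturbed, l_max=l_max,
                                batch_size=batch_size)
        outcomes = []
        for rec in perturbed:
            decoding = tracks[rec.transcript_id].decoding
            pred = prediction_from_runs(decoding.tis_runs, decoding.tts_runs)
            outcomes.append((rec.biotype, classify_orf_outcome(pred, rec)))
        summary = summarize(outcomes)
        row = {
            "condition": spec.label,
            "n": len(perturbed),
            "overall_accuracy": summary.overall_accuracy,
        }
        truth_class = "coding" if all(r.biotype == "coding" for r in perturbed) \
            else "noncoding" if all(r.biotype == "noncoding" for r in perturbed) \
            else "mixed"
        for biotype in ("coding", "noncoding"):
            for cat, pct in summary.per_category[biotype].items():
                row[f"{biotype}_{cat}"] = pct
        row["truth_class"] = truth_class
        rows.append(row)
    return pd.DataFrame(rows)


def standard_conditions(region: str = "CDS", seed: int = 0
                        ) -> List[PerturbationSpec]:
    """Identity + 1/2/3-nt insertions and deletions in one region."""
    conditions = [PerturbationSpec(region, "identity", seed=seed)]
    for size in (1, 2, 3):
        conditions.append(PerturbationSpec(region, "insert", size, seed))
        conditions.append(PerturbationSpec(region, "delete", size, seed))
    return conditions
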