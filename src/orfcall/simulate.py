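"""Synthetic transcriptome generator.

Emulates the statistical structure the labelling task assumes, at desk
scale: protein-coding transcripts are 5'UTR + ATG (in a Kozak-like
context) + a codon-biased CDS with no internal in-frame stop + stop
codon + 3'UTR; noncoding transcripts are background sequence rejected
until they contain no ATG-initiated, stop-terminated ORF of at least
``min_spurious_orf`` codons.  Transcripts are grouped into genes with
1-3 isoforms; isoforms of a coding gene share their CDS and differ in
their UTRs, which is what makes the gene-level split meaningful.

Signal strength is tunable: ``kozak_strength`` is the per-position
probability that a context base is drawn from the Kozak PWM rather
than uniformly, and the CDS codon distribution follows the bundled
human codon-usage frequencies.  Defaults are chosen so the full
network architecture learns the task to high accuracy within a few
epochs at these transcript sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .records import STOP_CODONS, TranscriptRecord, orf_scan
from .scoring import DEFAULT_KOZAK_PWM, HUMAN_CODON_FREQ_PER_1000

Range = Union[int, Tuple[int, int]]

# Human stop-codon usage, approximately: TGA is the most common.
STOP_WEIGHTS = {"TAA": 0.28, "TAG": 0.24, "TGA": 0.48}

BASES = "ACGT"


@dataclass
class SynthConfig:
    n_coding: int = 100
    n_noncoding: int = 100
    isoforms_per_gene: Range = (1, 3)
    utr5_len: Range = (5, 15)
    cds_codons: Range = (10, 25)  # total codons including ATG and stop
    utr3_len: Range = (5, 15)
    kozak_strength: float = 0.95
    background_gc: float = 0.40
    min_spurious_orf: int = 9  # codons; noncoding resampled above this
    decoy_atgs: int = 0  # optional hard-mode ATGs planted in noncoding
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("counts must be >= 0")
        if self.min_spurious_orf < 1:
            raise ValueError("min_spurious_orf must be >= 1")
        if not 0.0 <= self.kozak_strength <= 1.0:
            raise ValueError("kozak_strength must lie in [0, 1]")
        for name in ("isoforms_per_gene", "utr5_len", "cds_codons", "utr3_len"):
            rng = getattr(self, name)
            if isinstance(rng, tuple) and rng[0] > rng[1]:
                raise ValueError(f"invalid range for {name}")
        lo = self.cds_codons if isinstance(self.cds_codons, int) \
            else self.cds_codons[0]
        if lo < 2:
            raise ValueError("cds_codons must be >= 2 (ATG + stop)")


def _draw(rng: np.random.Generator, r: Range) -> int:
    if isinstance(r, int):
        return r
    return int(rng.integers(r[0], r[1] + 1))


def _sense_codon_sampler():
    codons = [c for c in HUMAN_CODON_FREQ_PER_1000 if c not in STOP_CODONS]
    freqs = np.array([HUMAN_CODON_FREQ_PER_1000[c] for c in codons])
    return codons, freqs / freqs.sum()


_SENSE_CODONS, _SENSE_PROBS = _sense_codon_sampler()
_STOP_LIST = list(STOP_WEIGHTS)
_STOP_PROBS = np.array([STOP_WEIGHTS[s] for s in _STOP_LIST])
_STOP_PROBS = _STOP_PROBS / _STOP_PROBS.sum()


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _kozak_base(rng: np.random.Generator, position: int, strength: float,
                gc: float) -> str:
    """Context base at a PWM position: PWM-distributed with probability
    ``strength``, otherwise background."""
    if rng.random() < strength:
        row = DEFAULT_KOZAK_PWM[position]
        probs = np.array([row[b] for b in BASES])
        return BASES[rng.choice(4, p=probs)]
    return _background(rng, 1, gc)


def _sample_cds_interior(rng: np.random.Generator, n_codons: int,
                         first_base: Optional[str] = None) -> str:
    """Sense codons drawn from the usage bias; the first codon can be
    constrained to start with a given base (the +3 Kozak position)."""
    if n_codons == 0:
        return ""
    codons = [str(_SENSE_CODONS[i])
              for i in rng.choice(len(_SENSE_CODONS), size=n_codons,
                                  p=_SENSE_PROBS)]
    if first_base is not None:
        idx = [i for i, c in enumerate(_SENSE_CODONS)
               if c.startswith(first_base)]
        probs = _SENSE_PROBS[idx] / _SENSE_PROBS[idx].sum()
        codons[0] = str(_SENSE_CODONS[int(rng.choice(idx, p=probs))])
    return "".join(codons)


def sample_coding_transcript(
    config: SynthConfig,
    rng: np.random.Generator,
    transcript_id: str = "SYNC000001",
    gene_symbol: str = "GC0001",
    cds_core: Optional[Tuple[str, str, str]] = None,
) -> TranscriptRecord:
    """One coding transcript; ``cds_core`` (interior, stop, +3 base) can
    be supplied so isoforms of a gene share their CDS."""
    if cds_core is None:
        cds_core = sample_cds_core(config, rng)
    interior, stop, _plus3 = cds_core
    utr5_n = _draw(rng, config.utr5_len)
    utr3_n = _draw(rng, config.utr3_len)
    utr5 = list(_background(rng, utr5_n, config.background_gc))
    # overwrite the last 6 UTR bases with Kozak-context draws
    for pos in range(-min(6, utr5_n), 0):
        utr5[utr5_n + pos] = _kozak_base(rng, pos, config.kozak_strength,
                                         config.background_gc)
    utr3 = _background(rng, utr3_n, config.background_gc)
    sequence = "".join(utr5) + "ATG" + interior + stop + utr3
    cds_start = utr5_n
    cds_end = utr5_n + 3 + len(interior) + 3
    return TranscriptRecord(
        transcript_id=transcript_id,
        gene_symbol=gene_symbol,
        sequence=sequence,
        biotype="coding",
        cds_start=cds_start,
        cds_end=cds_end,
    )


def sample_cds_core(config: SynthConfig, rng: np.random.Generator
                    ) -> Tuple[str, str, str]:
    """(interior codons, stop codon, +3 context base) for one gene."""
    n_codons = _draw(rng, config.cds_codons)
    plus3 = _kozak_base(rng, 3, config.kozak_strength, config.background_gc)
    interior = _sample_cds_interior(rng, n_codons - 2, first_base=plus3)
    stop = str(_STOP_LIST[int(rng.choice(len(_STOP_LIST), p=_STOP_PROBS))])
    return interior, stop, plus3


def _max_orf_codons(sequence: str) -> int:
    pairs = orf_scan(sequence)
    if not pairs:
        return 0
    return max((stop - atg) // 3 for atg, stop in pairs)


def sample_noncoding_transcript(
    config: SynthConfig,
    rng: np.random.Generator,
    transcript_id: str = "SYNN000001",
    gene_symbol: str = "GN0001",
    max_tries: int = 1000,
) -> TranscriptRecord:
    """Background sequence with no ORF of >= ``min_spurious_orf`` codons.

    Length is drawn from the same composite distribution as coding
    transcripts so the two classes are not separable by length alone.
    """
    n = (
        _draw(rng, config.utr5_len)
        + 3 * _draw(rng, config.cds_codons)
        + _draw(rng, config.utr3_len)
    )
    for _ in range(max_tries):
        seq = _background(rng, n, config.background_gc)
        if config.decoy_atgs:
            seq = _plant_decoys(seq, rng, config.decoy_atgs)
        if _max_orf_codons(seq) < config.min_spurious_orf:
            return TranscriptRecord(
                transcript_id=transcript_id,
                gene_symbol=gene_symbol,
                sequence=seq,
                biotype="noncoding",
            )
    raise RuntimeError(
        f"could not sample a noncoding transcript of length {n} without an "
        f"ORF of >= {config.min_spurious_orf} codons after {max_tries} tries; "
        "lower min_spurious_orf or transcript lengths"
    )


def _plant_decoys(seq: str, rng: np.random.Generator, n_decoys: int) -> str:
    chars = list(seq)
    for _ in range(n_decoys):
        pos = int(rng.integers(0, len(chars) - 2))
        chars[pos : pos + 3] = "ATG"
    return "".join(chars)


def generate_transcriptome(config: SynthConfig) -> List[TranscriptRecord]:
    """The full synthetic set: coding + noncoding records grouped into
    genes.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records: List[TranscriptRecord] = []
    t_idx = 0
    g_idx = 0
    while t_idx < config.n_coding:
        g_idx += 1
        gene = f"GC{g_idx:05d}"
        core = sample_cds_core(config, rng)
        n_iso = min(_draw(rng, config.isoforms_per_gene),
                    config.n_coding - t_idx)
        for _ in range(n_iso):
            t_idx += 1
            records.append(
                sample_coding_transcript(
                    config, rng,
                    transcript_id=f"SYNC{t_idx:06d}",
                    gene_symbol=gene,
                    cds_core=core,
                )
            )
    t_idx = 0
    g_idx = 0
    while t_idx < config.n_noncoding:
        g_idx += 1
        gene = f"GN{g_idx:05d}"
        n_iso = min(_draw(rng, config.isoforms_per_gene),
                    config.n_noncoding - t_idx)
        for _ in range(n_iso):
            t_idx += 1
            records.append(
                sample_noncoding_transcript(
                    config, rng,
                    transcript_id=f"SYNN{t_idx:06d}",
                    gene_symbol=gene,
                )
            )
    return records
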