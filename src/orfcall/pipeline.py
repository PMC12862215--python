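"""End-to-end prediction: probability tracks, ORF calls, evaluation.

Ties the pieces together: encode transcripts, run the network in
evaluation mode (batched by length for throughput), decode raw argmax
runs, enumerate and score candidate ORFs, and select a final call per
transcript.  Both the raw-argmax and the integrated-scoring views of
each transcript are produced so they can be compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .evaluate import (OrfOutcome, classify_orf_outcome,
                       prediction_from_decision, prediction_from_runs,
                       summarize)
from .model import RawDecoding, SiteLabeler, raw_argmax_decode, to_probabilities
from .records import TranscriptRecord
from .scoring import (CandidateORF, Decision, KozakPWM, ScoringParams,
                      default_codon_weights, score_candidates, select_orf,
                      translate_orf)

logger = logging.getLogger(__name__)


@dataclass
class TrackResult:
    """Per-position probabilities and their raw argmax decoding."""

    probs: np.ndarray  # (length, 3)
    decoding: RawDecoding


def predict_tracks(
    model: SiteLabeler,
    records: Sequence[TranscriptRecord],
    l_max: Optional[int] = None,
    batch_size: int = 16,
) -> Dict[str, TrackResult]:
    """Run the network over transcripts; returns one track per transcript.

    Transcripts longer than ``l_max`` are truncated at the 3' end with
    a warning.  Batches are grouped by length so padding stays small;
    padded positions are masked inside the network, so batching does
    not change any transcript's logits.
    """
    entries = []
    for rec in records:
        tokens = tio.encode_sequence(rec.sequence)
        if l_max is not None and tokens.shape[0] > l_max:
            logger.warning(
                "%s: length %d exceeds l_max=%d, truncating",
                rec.transcript_id, tokens.shape[0], l_max,
            )
            tokens = tokens[:l_max]
        entries.append((rec.transcript_id, tokens))
    order = sorted(range(len(entries)), key=lambda i: entries[i][1].shape[0])
    out: Dict[str, TrackResult] = {}
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        lengths = [entries[i][1].shape[0] for i in idx]
        l_batch = max(lengths)
        tokens = np.zeros((len(idx), l_batch), dtype=np.int64)
        for row, i in enumerate(idx):
            tokens[row, : lengths[row]] = entries[i][1]
        logits = model.forward(tokens, lengths=lengths, train=False)
        probs = to_probabilities(logits)
        for row, i in enumerate(idx):
            p = probs[row, : lengths[row]]
            out[entries[i][0]] = TrackResult(
                probs=p, decoding=raw_argmax_decode(p)
            )
    return out


@dataclass
class TranscriptCall:
    """Everything predicted for one transcript."""

    record: TranscriptRecord
    track: TrackResult
    candidates: List[CandidateORF]
    decision: Decision


def call_transcripts(
    model: SiteLabeler,
    records: Sequence[TranscriptRecord],
    params: Optional[ScoringParams] = None,
    pwm: Optional[KozakPWM] = None,
    codon_weights: Optional[Dict[str, float]] = None,
    l_max: Optional[int] = None,
    batch_size: int = 16,
) -> List[TranscriptCall]:
    """Probability tracks -> candidate ORFs -> integrated decision."""
    params = params or ScoringParams()
    pwm = pwm or KozakPWM()
    codon_weights = codon_weights or default_codon_weights()
    tracks = predict_tracks(model, records, l_max=l_max, batch_size=batch_size)
    calls = []
    for rec in records:
        track = tracks[rec.transcript_id]
        seq = rec.sequence[: track.probs.shape[0]]
        candidates = score_candidates(seq, track.probs, params, pwm,
                                      codon_weights)
        decision = select_orf(candidates, params)
        if decision.is_coding and decision.orf.protein is None:
            orf = decision.orf
            decision.orf.protein = translate_orf(
                seq[orf.tis_start : orf.tts_start + 3]
            )
        calls.append(TranscriptCall(rec, track, candidates, decision))
    return calls


def calls_to_frame(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    """Predictions table, one row per transcript."""
    rows = []
    for call in calls:
        d = call.decision
        row = {
            "transcript_id": call.record.transcript_id,
            "decision": "coding" if d.is_coding else "noncoding",
            "tis_start": d.orf.tis_start if d.is_coding else "",
            "tts_start": d.orf.tts_start if d.is_coding else "",
            "tis_codon": (
                call.record.sequence[d.orf.tis_start : d.orf.tis_start + 3]
                if d.is_coding else ""
            ),
            "tts_codon": (
                call.record.sequence[d.orf.tts_start : d.orf.tts_start + 3]
                if d.is_coding else ""
            ),
            "tis_prob": d.orf.tis_prob if d.is_coding else "",
            "tts_prob": d.orf.tts_prob if d.is_coding else "",
            "kozak_raw": d.orf.kozak_raw if d.is_coding else "",
            "kozak_norm": d.orf.kozak_norm if d.is_coding else "",
            "cai": d.orf.cai_score if d.is_coding else "",
            "gc": d.orf.gc_score if d.is_coding else "",
            "integrated_score": d.orf.integrated_score if d.is_coding else "",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_protein_fasta(calls: Sequence[TranscriptCall], path) -> None:
    with open(path, "w") as fh:
        for call in calls:
            if call.decision.is_coding and call.decision.orf.protein:
                fh.write(f">{call.record.transcript_id}\n")
                fh.write(call.decision.orf.protein + "\n")


def outcomes_integrated(
    calls: Sequence[TranscriptCall],
) -> List[Tuple[str, OrfOutcome]]:
    """ORF-level outcomes with the integrated-scoring prediction."""
    return [
        (
            c.record.biotype,
            classify_orf_outcome(prediction_from_decision(c.decision), c.record),
        )
        for c in calls
    ]


def outcomes_raw(
    calls: Sequence[TranscriptCall],
) -> List[Tuple[str, OrfOutcome]]:
    """ORF-level outcomes with the raw argmax prediction."""
    return [
        (
            c.record.biotype,
            classify_orf_outcome(
                prediction_from_runs(
                    c.track.decoding.tis_runs, c.track.decoding.tts_runs
                ),
                c.record,
            ),
        )
        for c in calls
    ]


def selftest(seed: int = 0, epochs: int = 2, model_config=None) -> Dict[str, Dict]:
    """Small end-to-end pipeline check: simulate -> train (reduced
    epochs) -> predict -> evaluate -> perturb.

    Returns a per-stage report; each stage carries ``ok`` plus a few
    metrics.  The model is the full architecture, the data are small
    and short, so this checks the plumbing (shapes, determinism,
    bookkeeping), not final accuracy.
    """
    from .model import ModelConfig, build_model
    from .perturb import PerturbationSpec, run_experiment
    from .simulate import SynthConfig, generate_transcriptome
    from .train import TrainConfig, train

    report: Dict[str, Dict] = {}
    config = SynthConfig(
        n_coding=40, n_noncoding=40,
        utr5_len=(5, 15), cds_codons=(10, 25), utr3_len=(5, 15),
        min_spurious_orf=9, seed=seed,
    )
    records = generate_transcriptome(config)
    report["simulate"] = {
        "ok": len(records) == 80,
        "n_records": len(records),
    }

    split = tio.split_by_gene(records, ratio=0.8, seed=seed)
    train_recs = tio.subset_by_split(records, split, "train")
    val_recs = tio.subset_by_split(records, split, "heldout")
    l_max = max(r.length for r in records)
    train_set = tio.build_dataset(train_recs, l_max)
    val_set = tio.build_dataset(val_recs, l_max)
    model = build_model(model_config or ModelConfig(), seed=seed)
    result = train(model, train_set, val_set,
                   TrainConfig(max_epochs=epochs, batch_size=8, seed=seed))
    losses = [h["train_loss"] for h in result.history]
    report["train"] = {
        "ok": bool(np.isfinite(losses).all()),
        "epochs_run": len(result.history),
        "final_train_loss": losses[-1],
        "best_val_loss": result.best_val_loss,
    }

    calls = call_transcripts(model, val_recs)
    report["predict"] = {
        "ok": len(calls) == len(val_recs),
        "n_calls": len(calls),
    }

    summary = summarize(outcomes_integrated(calls))
    fractions_ok = all(
        abs(sum(cats.values()) - 100.0) < 1e-9
        for cats in summary.per_category.values()
        if sum(cats.values()) > 0
    )
    report["evaluate"] = {
        "ok": fractions_ok,
        "overall_accuracy": summary.overall_accuracy,
        "balanced_accuracy": summary.balanced_accuracy,
    }

    coding_val = [r for r in val_recs if r.biotype == "coding"][:10]
    table = run_experiment(
        coding_val, model,
        [PerturbationSpec("CDS", "identity", seed=seed),
         PerturbationSpec("CDS", "insert", 1, seed=seed)],
    )
    baseline = run_experiment(
        coding_val, model, [PerturbationSpec("CDS", "identity", seed=seed)]
    )
    identity_matches = np.isclose(
        table.iloc[0]["overall_accuracy"], baseline.iloc[0]["overall_accuracy"]
    )
    report["perturb"] = {
        "ok": bool(identity_matches),
        "n_conditions": len(table),
    }
    report["pass"] = {"ok": all(stage["ok"] for stage in report.values())}
    return report
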