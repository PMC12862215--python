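"""The end-to-end synthetic benchmark: simulate, train, score, perturb.

One seeded function runs the package's whole study at desk scale:
generate a synthetic transcriptome, train the full-width architecture
on an 80% gene-level split, apply integrated scoring to the held-out
20%, compare integrated against raw argmax decoding, measure the
discriminative power of the integrated score (ROC/Youden), and run the
CDS indel perturbation experiment on freshly simulated coding
transcripts.  Both the test suite and ``scripts/acceptance.py`` drive
this function; everything derives from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .evaluate import Summary, nucleotide_metrics, summarize
from .model import ModelConfig, SiteLabeler, build_model
from .perturb import PerturbationSpec, run_experiment
from .pipeline import (TranscriptCall, call_transcripts, outcomes_integrated,
                       outcomes_raw)
from .records import TranscriptRecord
from .scoring import roc_youden
from .simulate import SynthConfig, generate_transcriptome
from .train import TrainConfig, TrainResult, train

# Desk-scale study conditions: 1,000 + 1,000 transcripts at the
# generator defaults, padded to 400 nt, full architecture, a fixed
# small number of epochs at the default batch size.
N_CODING = 1000
N_NONCODING = 1000
L_MAX = 400
MAX_EPOCHS = 6
BATCH_SIZE = 4
SPLIT_RATIO = 0.8
N_PERTURB = 400


@dataclass
class BenchmarkResult:
    model: SiteLabeler
    train_result: TrainResult
    heldout: List[TranscriptRecord]
    calls: List[TranscriptCall]
    summary_integrated: Summary
    summary_raw: Summary
    nucleotide: Dict
    auc: float
    youden_threshold: float
    perturbation: Optional[pd.DataFrame] = None


def train_benchmark_model(
    seed: int = 1,
    max_epochs: int = MAX_EPOCHS,
    n_coding: int = N_CODING,
    n_noncoding: int = N_NONCODING,
    l_max: int = L_MAX,
    batch_size: int = BATCH_SIZE,
) -> Tuple[SiteLabeler, TrainResult, List[TranscriptRecord]]:
    """Simulate, split at the gene level, train; returns the best model
    and the held-out records."""
    records = generate_transcriptome(
        SynthConfig(n_coding=n_coding, n_noncoding=n_noncoding, seed=seed)
    )
    split = tio.split_by_gene(records, ratio=SPLIT_RATIO, seed=seed)
    train_set = tio.build_dataset(
        tio.subset_by_split(records, split, "train"), l_max
    )
    val_set = tio.build_dataset(
        tio.subset_by_split(records, split, "heldout"), l_max
    )
    model = build_model(ModelConfig(), seed=seed)
    result = train(
        model, train_set, val_set,
        TrainConfig(max_epochs=max_epochs, batch_size=batch_size, seed=seed),
    )
    heldout = tio.subset_by_split(records, split, "heldout")
    return model, result, heldout


def evaluate_benchmark_model(
    model: SiteLabeler,
    heldout: List[TranscriptRecord],
    l_max: int = L_MAX,
) -> Dict:
    """Integrated + raw ORF-level summaries, nucleotide metrics, and the
    ROC of the best integrated score per transcript."""
    calls = call_transcripts(model, heldout, l_max=l_max)
    summary_int = summarize(outcomes_integrated(calls))
    summary_raw = summarize(outcomes_raw(calls))

    # nucleotide-level confusion on the held-out set
    pred_classes, true_classes = [], []
    for call in calls:
        rec = call.record
        pred_classes.append(call.track.decoding.classes)
        true_classes.append(tio.encode_labels(rec)[: call.track.probs.shape[0]])
    nucleotide = nucleotide_metrics(
        np.concatenate(pred_classes), np.concatenate(true_classes)
    )

    # transcript-level discrimination by the integrated score
    scores = [
        max((c.integrated_score for c in call.candidates), default=0.0)
        for call in calls
    ]
    labels = [1 if call.record.biotype == "coding" else 0 for call in calls]
    auc, youden = roc_youden(scores, labels)
    return {
        "calls": calls,
        "summary_integrated": summary_int,
        "summary_raw": summary_raw,
        "nucleotide": nucleotide,
        "auc": auc,
        "youden_threshold": youden,
    }


def cds_indel_conditions(seed: int) -> List[PerturbationSpec]:
    conditions = [PerturbationSpec("CDS", "identity", seed=seed)]
    for size in (1, 2, 3):
        conditions.append(PerturbationSpec("CDS", "insert", size, seed=seed))
        conditions.append(PerturbationSpec("CDS", "delete", size, seed=seed))
    return conditions


def run_perturbation_study(
    model: SiteLabeler,
    seed: int = 1,
    n_transcripts: int = N_PERTURB,
    l_max: int = L_MAX,
) -> pd.DataFrame:
    """CDS indel experiment on freshly simulated coding transcripts
    (held out by construction: a different stream of the generator)."""
    records = generate_transcriptome(
        SynthConfig(n_coding=n_transcripts, n_noncoding=0, seed=seed + 10_000)
    )
    return run_experiment(records, model, cds_indel_conditions(seed),
                          l_max=l_max)


def run_benchmark(
    seed: int = 1,
    max_epochs: int = MAX_EPOCHS,
    with_perturbation: bool = True,
) -> BenchmarkResult:
    model, train_result, heldout = train_benchmark_model(
        seed=seed, max_epochs=max_epochs
    )
    ev = evaluate_benchmark_model(model, heldout)
    perturbation = (
        run_perturbation_study(model, seed=seed) if with_perturbation else None
    )
    return BenchmarkResult(
        model=model,
        train_result=train_result,
        heldout=heldout,
        calls=ev["calls"],
        summary_integrated=ev["summary_integrated"],
        summary_raw=ev["summary_raw"],
        nucleotide=ev["nucleotide"],
        auc=ev["auc"],
        youden_threshold=ev["youden_threshold"],
        perturbation=perturbation,
    )
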