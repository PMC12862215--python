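"""Nucleotide-level metrics and the ORF-level outcome taxonomy.

A transcript's prediction is judged at two levels.  Per-nucleotide:
a 3x3 confusion matrix over TIS/TTS/non-site with per-class precision,
recall, and F1.  Per-ORF: one of seven categories —

* PERFECT            both 3-nt codon spans exactly match the annotation
* NEAR_PERFECT       each boundary within +-1 nt, but not both exact
* TIS_ONLY           start codon exact, stop wrong
* TTS_ONLY           stop codon exact, start wrong
* OTHER_ERROR        anything else on a coding transcript (including a
                     noncoding call), or an invalid site combination on
                     a noncoding one
* CORRECT_NONCODING  noncoding transcript with no predicted sites
* FALSE_ORF          noncoding transcript with a complete predicted ORF

Overall accuracy counts PERFECT and CORRECT_NONCODING as correct
(near-perfect calls are not credited); balanced accuracy is the
macro-average of the coding and noncoding accuracies, with an explicit
seeded downsampling construction available as a cross-check.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .records import CLASS_NAMES, NONE, TIS, TTS, TranscriptRecord


class OrfOutcome(Enum):
    PERFECT = "PERFECT"
    NEAR_PERFECT = "NEAR_PERFECT"
    TIS_ONLY = "TIS_ONLY"
    TTS_ONLY = "TTS_ONLY"
    OTHER_ERROR = "OTHER_ERROR"
    FALSE_ORF = "FALSE_ORF"
    CORRECT_NONCODING = "CORRECT_NONCODING"


@dataclass
class OrfPrediction:
    """Predicted codon spans for one transcript.

    ``tis_start``/``tts_start`` are the starts of the predicted start
    and stop codons (None when the corresponding site was not called);
    ``is_orf`` marks a complete, frame-consistent ATG..stop pair.  In
    integrated-scoring mode these come from the selected candidate; in
    raw mode from the argmax runs.
    """

    tis_start: Optional[int] = None
    tts_start: Optional[int] = None
    is_orf: bool = False


def nucleotide_metrics(
    predicted: np.ndarray, true: np.ndarray, mask: Optional[np.ndarray] = None
) -> Dict:
    """3x3 confusion matrix and per-class precision/recall/F1.

    ``mask`` selects the positions to score (padding excluded).
    """
    predicted = np.asarray(predicted).ravel()
    true = np.asarray(true).ravel()
    if predicted.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    if mask is not None:
        mask = np.asarray(mask).ravel().astype(bool)
        if mask.shape != true.shape:
            raise ValueError("mask length mismatch")
        predicted, true = predicted[mask], true[mask]
    labels = [TIS, TTS, NONE]
    cm = _sk_confusion(true, predicted, labels=labels)
    precision, recall, f1, support = _sk_prfs(
        true, predicted, labels=labels, zero_division=0.0
    )
    per_class = {
        CLASS_NAMES[cls]: {
            "precision": float(precision[k]),
            "recall": float(recall[k]),
            "f1": float(f1[k]),
            "support": int(support[k]),
        }
        for k, cls in enumerate(labels)
    }
    return {"confusion": cm, "per_class": per_class}


def classify_orf_outcome(
    prediction: OrfPrediction, truth: TranscriptRecord
) -> OrfOutcome:
    """Assign one transcript's prediction to the outcome taxonomy."""
    if truth.biotype == "coding":
        t_tis, t_tts = truth.cds_start, truth.tts_start
        p_tis, p_tts = prediction.tis_start, prediction.tts_start
        if p_tis is None and p_tts is None:
            return OrfOutcome.OTHER_ERROR  # called noncoding
        if p_tis == t_tis and p_tts == t_tts:
            return OrfOutcome.PERFECT
        if (
            p_tis is not None
            and p_tts is not None
            and abs(p_tis - t_tis) <= 1
            and abs(p_tts - t_tts) <= 1
        ):
            return OrfOutcome.NEAR_PERFECT
        if p_tis == t_tis:
            return OrfOutcome.TIS_ONLY
        if p_tts == t_tts:
            return OrfOutcome.TTS_ONLY
        return OrfOutcome.OTHER_ERROR
    # noncoding truth
    if prediction.tis_start is None and prediction.tts_start is None:
        return OrfOutcome.CORRECT_NONCODING
    if prediction.is_orf:
        return OrfOutcome.FALSE_ORF
    if prediction.tis_start is not None and prediction.tts_start is None:
        return OrfOutcome.TIS_ONLY
    if prediction.tts_start is not None and prediction.tis_start is None:
        return OrfOutcome.TTS_ONLY
    return OrfOutcome.OTHER_ERROR


def prediction_from_decision(decision) -> OrfPrediction:
    """Integrated-scoring mode: the selected candidate's codon spans."""
    if not decision.is_coding:
        return OrfPrediction()
    return OrfPrediction(
        tis_start=decision.orf.tis_start,
        tts_start=decision.orf.tts_start,
        is_orf=True,
    )


def prediction_from_runs(
    tis_runs: Sequence[Tuple[int, int]],
    tts_runs: Sequence[Tuple[int, int]],
) -> OrfPrediction:
    """Raw argmax mode: the earliest TIS run and earliest TTS run.

    ``is_orf`` requires a downstream, in-frame stop relative to the
    start — the same triplet consistency the candidate enumerator
    enforces (internal stops cannot be checked without the sequence and
    are not part of this raw-mode judgement).
    """
    tis_start = tis_runs[0][0] if tis_runs else None
    tts_start = tts_runs[0][0] if tts_runs else None
    is_orf = (
        tis_start is not None
        and tts_start is not None
        and tts_start > tis_start
        and (tts_start - tis_start) % 3 == 0
    )
    return OrfPrediction(tis_start=tis_start, tts_start=tts_start, is_orf=is_orf)


def error_pattern(
    tis_runs: Sequence[Tuple[int, int]],
    tts_runs: Sequence[Tuple[int, int]],
    sequence: str,
) -> str:
    """Compact signature of a raw prediction: the 3-nt sequence at each
    predicted site start, in positional order, each followed by '-';
    an empty prediction yields '-'.
    """
    sites = sorted(
        [(start, "TIS") for start, _ in tis_runs]
        + [(start, "TTS") for start, _ in tts_runs]
    )
    if not sites:
        return "-"
    return "".join(f"{sequence[s : s + 3]}-" for s, _ in sites)


def pattern_frequency_table(patterns: Sequence[str]) -> pd.DataFrame:
    """Frequency table of error-pattern strings (pattern, count, percentage)."""
    counts = Counter(patterns)
    total = sum(counts.values())
    rows = [
        {"pattern": p, "count": c, "percentage": 100.0 * c / total}
        for p, c in counts.most_common()
    ]
    return pd.DataFrame(rows)


@dataclass
class Summary:
    per_category: Dict[str, Dict[str, float]]  # truth class -> category -> %
    overall_accuracy: float
    balanced_accuracy: Optional[float]
    coding_accuracy: Optional[float]
    noncoding_accuracy: Optional[float]
    n_coding: int
    n_noncoding: int

    @property
    def balanced_defined(self) -> bool:
        return self.balanced_accuracy is not None


def summarize(outcomes: Sequence[Tuple[str, OrfOutcome]]) -> Summary:
    """Aggregate per-transcript outcomes into the metrics table.

    ``outcomes`` pairs each transcript's truth biotype with its outcome.
    Overall accuracy = (PERFECT + CORRECT_NONCODING) / N; balanced
    accuracy = mean of coding and noncoding accuracies, None (flagged)
    when a truth class is absent.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarise")
    by_class: Dict[str, Counter] = {"coding": Counter(), "noncoding": Counter()}
    for biotype, outcome in outcomes:
        by_class[biotype][outcome] += 1
    n_coding = sum(by_class["coding"].values())
    n_noncoding = sum(by_class["noncoding"].values())
    per_category = {}
    for biotype, counter in by_class.items():
        n = sum(counter.values())
        per_category[biotype] = {
            cat.value: (100.0 * counter[cat] / n if n else 0.0)
            for cat in OrfOutcome
        }
    n_correct = (
        by_class["coding"][OrfOutcome.PERFECT]
        + by_class["noncoding"][OrfOutcome.CORRECT_NONCODING]
    )
    coding_acc = (
        by_class["coding"][OrfOutcome.PERFECT] / n_coding if n_coding else None
    )
    noncoding_acc = (
        by_class["noncoding"][OrfOutcome.CORRECT_NONCODING] / n_noncoding
        if n_noncoding
        else None
    )
    balanced = (
        (coding_acc + noncoding_acc) / 2.0
        if coding_acc is not None and noncoding_acc is not None
        else None
    )
    return Summary(
        per_category=per_category,
        overall_accuracy=n_correct / (n_coding + n_noncoding),
        balanced_accuracy=balanced,
        coding_accuracy=coding_acc,
        noncoding_accuracy=noncoding_acc,
        n_coding=n_coding,
        n_noncoding=n_noncoding,
    )


def downsampled_balanced_accuracy(
    outcomes: Sequence[Tuple[str, OrfOutcome]], seed: int = 0
) -> float:
    """Accuracy on an explicitly balanced set: the larger truth class is
    downsampled (without replacement) to the size of the smaller one.
    In expectation this equals the macro-averaged balanced accuracy.
    """
    rng = np.random.default_rng(seed)
    coding = [o for b, o in outcomes if b == "coding"]
    noncoding = [o for b, o in outcomes if b == "noncoding"]
    if not coding or not noncoding:
        raise ValueError("both truth classes required for a balanced set")
    n = min(len(coding), len(noncoding))
    coding_sub = [coding[i] for i in rng.choice(len(coding), n, replace=False)]
    nc_sub = [noncoding[i] for i in rng.choice(len(noncoding), n, replace=False)]
    correct = sum(o == OrfOutcome.PERFECT for o in coding_sub) + sum(
        o == OrfOutcome.CORRECT_NONCODING for o in nc_sub
    )
    return correct / (2 * n)


def summary_to_frame(summary: Summary) -> pd.DataFrame:
    rows = []
    for biotype, cats in summary.per_category.items():
        for cat, pct in cats.items():
            rows.append({"truth": biotype, "category": cat, "percentage": pct})
    return pd.DataFrame(rows)
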