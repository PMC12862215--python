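"""The ORF-level outcome taxonomy and summary metrics.

Builds a handful of (prediction, truth) pairs covering every category,
then summarises them the way a real evaluation run would.
"""

from orfcall import OrfPrediction, TranscriptRecord, classify_orf_outcome, summarize

coding = TranscriptRecord("NM_X", "GENE1", "AA" + "ATG" + "GCC" * 5 + "TAA" + "AAAA",
                          "coding", 2, 23)
noncoding = TranscriptRecord("NR_X", "GENE2", "ACGT" * 10, "noncoding")

cases = [
    ("exact call",            OrfPrediction(2, 20, is_orf=True), coding),
    ("stop off by one",       OrfPrediction(2, 21, is_orf=True), coding),
    ("stop in wrong place",   OrfPrediction(2, 35, is_orf=True), coding),
    ("start wrong",           OrfPrediction(8, 20, is_orf=True), coding),
    ("called noncoding",      OrfPrediction(),                   coding),
    ("correct rejection",     OrfPrediction(),                   noncoding),
    ("spurious full ORF",     OrfPrediction(0, 12, is_orf=True), noncoding),
]

outcomes = []
for label, pred, truth in cases:
    outcome = classify_orf_outcome(pred, truth)
    outcomes.append((truth.biotype, outcome))
    print(f"{label:<22} -> {outcome.value}")

summary = summarize(outcomes)
print(f"\noverall accuracy  {summary.overall_accuracy:.3f}  "
      "(PERFECT + CORRECT_NONCODING over all transcripts)")
print(f"balanced accuracy {summary.balanced_accuracy:.3f}  "
      "(mean of per-class accuracies; robust to class imbalance)")
print("\nTruth-class breakdown (percent):")
for biotype, cats in summary.per_category.items():
    shown = {k: round(v, 1) for k, v in cats.items() if v > 0}
    print(f"  {biotype}: {shown}")
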