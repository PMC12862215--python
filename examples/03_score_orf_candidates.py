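"""Score candidate ORFs on a hand-built probability track.

No trained model needed: this example builds the per-position
(p_TIS, p_TTS, p_none) track by hand to show exactly how the
integrated scoring system turns probabilities plus biological features
(Kozak context, codon adaptation, GC content) into a final ORF call.
"""

import numpy as np

from orfcall import ScoringParams, score_candidates, select_orf, translate_orf

# a transcript with two ATGs: a weak upstream one and a strong one in a
# good Kozak context (GCCGCC_ATG_G)
sequence = "ATGCTTTAAGCCGCCACCATGGCTGAGAAGCTGTTCTAA"
n = len(sequence)

probs = np.zeros((n, 3))
probs[:, 2] = 1.0
for start, p in [(0, 0.10), (18, 0.85)]:   # TIS signal at the two ATGs
    probs[start : start + 3, 0] = p
    probs[start : start + 3, 2] = 1 - p
for start, p in [(6, 0.10), (36, 0.90)]:   # TTS signal at the two stops
    probs[start : start + 3, 1] = p
    probs[start : start + 3, 2] = 1 - p

params = ScoringParams()  # weights 0.30/0.50/0.04/0.04/0.00, threshold 0.635
candidates = score_candidates(sequence, probs, params)

print(f"{'tis':>4} {'tts':>4} {'p_tis':>6} {'p_tts':>6} {'kozak':>6} "
      f"{'cai':>5} {'gc':>6} {'score':>6}")
for c in candidates:
    print(f"{c.tis_start:>4} {c.tts_start:>4} {c.tis_prob:>6.2f} "
          f"{c.tts_prob:>6.2f} {c.kozak_norm:>6.3f} {c.cai_score:>5.2f} "
          f"{c.gc_score:>6.2f} {c.integrated_score:>6.3f}")

decision = select_orf(candidates, params)
orf = decision.orf
print(f"\nDecision: {'coding' if decision.is_coding else 'noncoding'} — "
      f"ORF [{orf.tis_start}, {orf.tts_start + 3}), integrated score "
      f"{orf.integrated_score:.3f} >= threshold {params.threshold}")
print("Protein:", translate_orf(sequence[orf.tis_start : orf.tts_start + 3]))
print("\nThe upstream ATG scores below threshold (weak probabilities and "
      "poor context),\nso the downstream, well-supported ORF is selected.")
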