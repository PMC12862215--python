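"""Kozak/CAI/GC component scores, candidate enumeration, integration,
selection, grid search, and ROC threshold selection."""

import itertools
import math

import numpy as np
import pytest

from orfcall.records import orf_scan
from orfcall.scoring import (CandidateORF, KozakPWM, ScoringCase,
                             ScoringParams, cai_score,
                             codon_signal_probability, default_codon_weights,
                             enumerate_candidates, gc_score, grid_accuracy,
                             integrated_score, optimize_weights,
                             read_probability_tracks, roc_youden,
                             score_candidates, select_orf, translate_orf,
                             write_probability_tracks)


def _uniform_probs(n):
    return np.full((n, 3), 1 / 3)


class TestKozak:
    def test_row_sums_exactly_one(self):
        pwm = KozakPWM()
        for pos, row in pwm.table.items():
            assert math.fsum(row[b] for b in "ACGT") == 1.0

    def test_argmax_context_scores(self):
        # context G,C,C,G,C,C | ATG | G: hand multiplication of the
        # per-position maxima, x 10000
        pwm = KozakPWM()
        raw, norm = pwm.score("GCCGCCATGG", 6)
        oracle = 0.32 * 0.30 * 0.32 * 0.45 * 0.35 * 0.35 * 1 * 1 * 1 * 0.40 * 10000
        assert raw == pytest.approx(oracle, rel=1e-12)
        assert raw == pytest.approx(6.77376, rel=1e-9)
        assert norm == pytest.approx(1.0, abs=1e-12)

    def test_all_t_context(self):
        pwm = KozakPWM()
        raw, _ = pwm.score("TTTTTTATGT", 6)
        assert raw == pytest.approx(0.0864, rel=1e-9)

    def test_boundary_flanks_contribute_quarter(self):
        pwm = KozakPWM()
        raw, _ = pwm.score("ATGG", 0)
        oracle = 0.25**6 * 1 * 1 * 1 * 0.40 * 10000
        assert raw == pytest.approx(oracle, rel=1e-12)

    def test_requires_atg(self):
        with pytest.raises(ValueError):
            KozakPWM().score("GCCGCCTTGG", 6)

    def test_bad_row_rejected(self):
        table = {p: dict(v) for p, v in KozakPWM().table.items()}
        table[-6]["A"] = 0.5
        with pytest.raises(ValueError):
            KozakPWM(table)

    def test_normalised_range_random_contexts(self, rng):
        pwm = KozakPWM()
        for _ in range(50):
            ctx = "".join("ACGT"[i] for i in rng.integers(0, 4, 6))
            tail = "ACGT"[rng.integers(0, 4)]
            _, norm = pwm.score(ctx + "ATG" + tail, 6)
            assert 0.0 <= norm <= 1.0


class TestCai:
    def test_all_optimal_codons(self):
        weights = {"GCC": 1.0, "AAG": 1.0}
        assert cai_score("GCCAAG", weights) == pytest.approx(1.0)

    def test_geometric_mean(self):
        weights = {"AAA": 0.25, "GGG": 1.0}
        assert cai_score("AAAGGG", weights) == pytest.approx(0.5)

    def test_single_codon(self):
        assert cai_score("TTT", {"TTT": 0.7}) == pytest.approx(0.7)

    def test_unknown_codon_raises(self):
        with pytest.raises(ValueError):
            cai_score("TAA", default_codon_weights())

    def test_default_table_family_maxima(self):
        weights = default_codon_weights()
        assert len(weights) == 61
        assert all(0 < w <= 1 for w in weights.values())
        # every synonymous family contains a codon with w == 1
        from Bio.Data import CodonTable

        fams = {}
        for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
            fams.setdefault(aa, []).append(weights[codon])
        assert all(max(ws) == 1.0 for ws in fams.values())


class TestGc:
    def test_maximum_at_mu(self):
        # 42% GC: exponent zero, score exactly 1
        assert gc_score("GCGCA" + "AT" * 10 + "GCGCA") != 1.0  # sanity: not mu
        seq = "G" * 42 + "A" * 58
        assert gc_score(seq) == pytest.approx(1.0)

    def test_closed_form_at_one_sigma(self):
        seq = "G" * 64 + "A" * 36
        assert gc_score(seq) == pytest.approx(2 * math.exp(-0.5) - 1, rel=1e-12)
        assert gc_score(seq) == pytest.approx(0.21306, abs=1e-5)

    def test_symmetry_about_mu(self):
        low = "G" * 20 + "A" * 80
        high = "G" * 64 + "A" * 36
        assert gc_score(low) == pytest.approx(gc_score(high), rel=1e-12)


class TestCodonSignal:
    def test_mean_of_three(self):
        probs = np.zeros((3, 3))
        probs[:, 0] = [0.9, 0.6, 0.3]
        assert codon_signal_probability(probs, 0, 0) == pytest.approx(0.6)

    def test_constant_track(self):
        probs = np.full((9, 3), 0.2)
        assert codon_signal_probability(probs, 3, 1) == pytest.approx(0.2)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            codon_signal_probability(np.zeros((4, 3)), 2, 0)


class TestEnumerate:
    def _params(self):
        return ScoringParams(tis_floor=0.0, tts_floor=0.0, max_candidates=None)

    def test_single_orf(self):
        seq = "AAATGGCCTAAGG"
        cands = enumerate_candidates(seq, _uniform_probs(len(seq)), self._params())
        assert [(c.tis_start, c.tts_start) for c in cands] == [(2, 8)]

    def test_nested_atgs_share_stop(self):
        seq = "ATGATGTAA"
        cands = enumerate_candidates(seq, _uniform_probs(len(seq)), self._params())
        assert [(c.tis_start, c.tts_start) for c in cands] == [(0, 6), (3, 6)]

    def test_no_atg_empty(self):
        seq = "CCCCCCCC"
        assert enumerate_candidates(seq, _uniform_probs(len(seq)), self._params()) == []

    def test_matches_brute_force_on_random_sequences(self, rng):
        params = self._params()
        for _ in range(100):
            n = int(rng.integers(10, 200))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            fast = [
                (c.tis_start, c.tts_start)
                for c in enumerate_candidates(seq, _uniform_probs(n), params)
            ]
            assert fast == orf_scan(seq)

    def test_floors_filter_candidates(self):
        seq = "ATGATGTAA"
        probs = np.zeros((9, 3))
        probs[:, 2] = 1.0
        probs[0:3, 0] = 0.5  # only the first ATG has TIS signal
        probs[6:9, 1] = 0.5
        params = ScoringParams(tis_floor=0.1, tts_floor=0.1, max_candidates=None)
        cands = enumerate_candidates(seq, probs, params)
        assert [(c.tis_start, c.tts_start) for c in cands] == [(0, 6)]

    def test_candidate_cap_keeps_strongest(self, rng):
        seq = "ATG" * 30 + "TAA"
        n = len(seq)
        probs = _uniform_probs(n)
        params = ScoringParams(tis_floor=0.0, tts_floor=0.0, max_candidates=5)
        cands = enumerate_candidates(seq, probs, params)
        assert len(cands) == 5
        starts = [c.tis_start for c in cands]
        assert starts == sorted(starts)


class TestIntegration:
    def test_all_ones_gives_sum_of_weights(self):
        cand = CandidateORF(0, 9, tis_prob=1, tts_prob=1, kozak_norm=1,
                            cai_score=1, gc_score=1)
        assert integrated_score(cand, ScoringParams()) == pytest.approx(0.88)

    def test_all_zero(self):
        cand = CandidateORF(0, 9)
        assert integrated_score(cand, ScoringParams()) == 0.0

    def test_mixed_components(self):
        cand = CandidateORF(0, 9, tis_prob=0.9, tts_prob=0.8, kozak_norm=0.5,
                            cai_score=0.5, gc_score=-0.4)
        assert integrated_score(cand, ScoringParams()) == pytest.approx(0.71)

    def test_monotone_in_each_weighted_component(self):
        params = ScoringParams(w_gc=0.1)
        base = CandidateORF(0, 9, tis_prob=0.5, tts_prob=0.5, kozak_norm=0.5,
                            cai_score=0.5, gc_score=0.0)
        s0 = integrated_score(base, params)
        for attr in ("tis_prob", "tts_prob", "kozak_norm", "cai_score",
                     "gc_score"):
            bumped = CandidateORF(0, 9, **{
                "tis_prob": base.tis_prob, "tts_prob": base.tts_prob,
                "kozak_norm": base.kozak_norm, "cai_score": base.cai_score,
                "gc_score": base.gc_score, attr: getattr(base, attr) + 0.2,
            })
            assert integrated_score(bumped, params) > s0


class TestSelect:
    def test_above_threshold_coding(self):
        cand = CandidateORF(2, 11, integrated_score=0.70)
        decision = select_orf([cand], ScoringParams())
        assert decision.is_coding and decision.orf is cand

    def test_below_threshold_noncoding(self):
        cand = CandidateORF(2, 11, integrated_score=0.60)
        assert not select_orf([cand], ScoringParams()).is_coding

    def test_empty_noncoding(self):
        assert not select_orf([], ScoringParams()).is_coding

    def test_order_invariance_and_tie_break(self, rng):
        cands = [
            CandidateORF(10, 40, integrated_score=0.9),
            CandidateORF(4, 40, integrated_score=0.9),
            CandidateORF(4, 22, integrated_score=0.9),
            CandidateORF(7, 40, integrated_score=0.8),
        ]
        picks = set()
        for perm in itertools.permutations(cands):
            decision = select_orf(list(perm), ScoringParams(threshold=0.5))
            picks.add((decision.orf.tis_start, decision.orf.tts_start))
        assert picks == {(4, 22)}


class TestTranslate:
    def test_simple_peptide(self):
        assert translate_orf("ATGGCCTAA") == "MA"

    def test_start_stop_only(self):
        assert translate_orf("ATGTAA") == "M"

    @pytest.mark.parametrize("bad", ["ATGGC", "ATGTAATAA", "TTGGCCTAA", "ATGGCCGCC"])
    def test_invalid_orfs_rejected(self, bad):
        with pytest.raises(ValueError):
            translate_orf(bad)


class TestRocYouden:
    def test_perfect_separation(self):
        auc, thr = roc_youden([0.9, 0.8, 0.4, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)
        assert 0.4 < thr <= 0.8

    def test_independent_scores_auc_half(self, rng):
        n = 4000
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        auc, _ = roc_youden(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_youden([0.5, 0.6], [1, 1])

    def test_matches_enumeration_oracle(self, rng):
        """AUC and Youden threshold agree with direct enumeration over
        all distinct score cutoffs on a small random problem."""
        scores = rng.random(40)
        labels = (scores + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, thr = roc_youden(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        # rank construction of AUC
        oracle_auc = np.mean([
            (1.0 if p > q else 0.5 if p == q else 0.0)
            for p in pos for q in neg
        ])
        assert auc == pytest.approx(oracle_auc, abs=1e-12)
        best_j = max(
            np.mean(pos >= t) - np.mean(neg >= t) for t in np.unique(scores)
        )
        j_at_thr = np.mean(pos >= thr) - np.mean(neg >= thr)
        assert j_at_thr == pytest.approx(best_j, abs=1e-12)


class TestOptimizeWeights:
    def _toy_cases(self, rng, n=40):
        cases = []
        for i in range(n):
            coding = i % 2 == 0
            cand = CandidateORF(
                3, 30,
                tis_prob=0.9 if coding else 0.3,
                tts_prob=0.9 if coding else 0.3,
                kozak_norm=0.5, cai_score=0.5, gc_score=0.0,
            )
            cases.append(ScoringCase([cand], (3, 30) if coding else None))
        return cases

    def test_single_point_grid(self, rng):
        cases = self._toy_cases(rng)
        best, surface = optimize_weights(cases, {"threshold": [0.5]})
        assert best.threshold == 0.5
        assert len(surface) == 1

    def test_perfectly_separating_point_found(self, rng):
        cases = self._toy_cases(rng)
        grid = {"w_tis": [0.3], "w_tts": [0.5], "threshold": [0.2, 0.6, 0.95]}
        best, surface = optimize_weights(cases, grid)
        # scores: coding ~0.87; noncoding ~0.30: only 0.6 separates
        assert best.threshold == 0.6
        assert surface["accuracy"].max() == pytest.approx(1.0)

    def test_grid_size_is_product_of_axes(self, rng):
        cases = self._toy_cases(rng, n=10)
        grid = {"w_tis": [0.2, 0.3], "w_tts": [0.4, 0.5, 0.6],
                "threshold": [0.3, 0.6]}
        _, surface = optimize_weights(cases, grid)
        assert len(surface) == 12

    def test_empty_grid_axis_raises(self, rng):
        with pytest.raises(ValueError):
            optimize_weights(self._toy_cases(rng), {"threshold": []})


class TestTrackRoundTrip:
    def test_write_read_round_trip(self, tmp_path, rng):
        tracks = {
            "t1": rng.random((5, 3)),
            "t2": rng.random((3, 3)),
        }
        path = tmp_path / "tracks.tsv"
        write_probability_tracks(tracks, path)
        loaded = read_probability_tracks(path)
        assert set(loaded) == {"t1", "t2"}
        np.testing.assert_allclose(loaded["t1"], tracks["t1"], atol=1e-6)
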