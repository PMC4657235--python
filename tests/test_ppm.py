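import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flankalign.ppm import (
    ExtractionParams,
    IndelPredictor,
    PPMModel,
    ScanResult,
    extract_indelfrs,
    scan_sequence,
    train_ppm,
    train_predictor,
    window_logloss,
)
from flankalign.seqio import AMINO_ACIDS, ProteinSequence

AA = list(AMINO_ACIDS)


class TestTraining:
    def test_direct_counting(self):
        m = train_ppm(["AAAA"], 1)
        assert m.counts[""] == {"A": 4}
        assert m.counts["A"] == {"A": 3}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_ppm([], 2)

    def test_accepts_protein_sequences(self):
        m = train_ppm([ProteinSequence("a", "ARAR")], 1)
        assert m.counts["A"] == {"R": 2}

    @given(st.lists(st.text(alphabet="ARND", min_size=1, max_size=12),
                    min_size=1, max_size=5),
           st.integers(min_value=0, max_value=3))
    def test_probabilities_normalize_for_every_context(self, corpus, order):
        m = train_ppm(corpus, order)
        for ctx in list(m.counts)[:20]:
            total = sum(m.symbol_prob(sym, ctx) for sym in AA)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestSymbolProb:
    def test_uniform_fallback_for_untrained_model(self):
        # no context observed at any order: the uniform order-(-1) floor
        assert PPMModel(2).symbol_prob("W", "YY") == pytest.approx(1 / 20)

    def test_escape_to_uniform_through_order_zero(self):
        # ARND trained: order-0 holds 4 distinct symbols (total 4, escape 4/8),
        # so an unseen symbol gets 0.5 * 1/20
        m = train_ppm(["ARND"], 2)
        assert m.symbol_prob("W", "YY") == pytest.approx(0.5 / 20, abs=1e-12)

    def test_escape_recursion_matches_hand_arithmetic(self):
        # corpus ARAR, D=2; context 'A' holds {R: 2} so
        # P(R|A) = 2/3 + (1/3) * P0(R), with P0(R) = 2/6 + (2/6)*(1/20)
        m = train_ppm(["ARAR"], 2)
        p0 = 2 / 6 + (2 / 6) * (1 / 20)
        assert m.symbol_prob("R", "A") == pytest.approx(2 / 3 + p0 / 3, abs=1e-12)
        assert m.symbol_prob("R", "A") > 2 * m.symbol_prob("A", "A")

    def test_only_last_d_context_symbols_used(self):
        m = train_ppm(["ARAR"], 1)
        assert m.symbol_prob("R", "WWWA") == m.symbol_prob("R", "A")

    def test_symbol_outside_alphabet(self):
        m = train_ppm(["ARND"], 1)
        with pytest.raises(ValueError):
            m.symbol_prob("B", "A")

    def test_repeat_pattern_prefers_continuation(self):
        m = train_ppm(["ARARARAR"], 2)
        assert m.symbol_prob("R", "A") > 10 * m.symbol_prob("A", "A")


class TestWindowLogloss:
    def test_uniform_model_gives_log2_20(self):
        m = PPMModel(0)  # untrained: every probability is 1/20
        assert window_logloss(m, "ARNDCQEGHI") == pytest.approx(
            math.log2(20), abs=1e-12
        )

    def test_hand_expanded_sum(self):
        # model from AAAA, D=1: P0(A) = 4/5 + (1/5)(1/20) = 0.81,
        # P(A|A) = 3/4 + (1/4)(0.81) = 0.9525; ten-term window of A's
        m = train_ppm(["AAAA"], 1)
        p0 = 4 / 5 + (1 / 5) * (1 / 20)
        p1 = 3 / 4 + (1 / 4) * p0
        expected = -(math.log2(p0) + 9 * math.log2(p1)) / 10
        assert window_logloss(m, "A" * 10) == pytest.approx(expected, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            window_logloss(PPMModel(1), "AAA", L=10)

    def test_nonnegative_on_random_windows(self, rng):
        m = train_ppm(["".join(rng.choice(AA, 50)) for _ in range(3)], 4)
        for _ in range(20):
            w = "".join(rng.choice(AA, 10))
            assert window_logloss(m, w) >= 0

    def test_familiar_windows_score_below_random(self, rng):
        # windows drawn from the training corpus vs uniform random windows
        corpus = ["".join(rng.choice(AA[:6], 40)) for _ in range(10)]
        m = train_ppm(corpus, 4)
        familiar = []
        for seq in corpus:
            for i in range(0, 30, 6):
                familiar.append(window_logloss(m, seq[i : i + 10]))
        random_w = [
            window_logloss(m, "".join(rng.choice(AA, 10))) for _ in range(60)
        ]
        assert np.mean(familiar) < np.mean(random_w)


class TestScan:
    def _predictor(self, rng, L=10, D=4):
        corpus = ["".join(rng.choice(AA, 30)) for _ in range(5)]
        return train_predictor(corpus, corpus, order=D, L=L)

    def test_window_count(self, rng):
        pred = self._predictor(rng)
        seq = ProteinSequence("a", "".join(rng.choice(AA, 25)))
        scan = scan_sequence(pred, seq)
        assert scan.lppm.shape == scan.rppm.shape == (16,)

    def test_length_equal_window_gives_one(self, rng):
        pred = self._predictor(rng)
        scan = scan_sequence(pred, "".join(rng.choice(AA, 10)))
        assert scan.lppm.size == 1

    def test_too_short_rejected(self, rng):
        pred = self._predictor(rng)
        with pytest.raises(ValueError, match="shorter than the scan window"):
            scan_sequence(pred, "".join(rng.choice(AA, 9)))

    def test_scan_is_pure(self, rng):
        pred = self._predictor(rng)
        seq = "".join(rng.choice(AA, 40))
        a, b = scan_sequence(pred, seq), scan_sequence(pred, seq)
        assert np.array_equal(a.lppm, b.lppm) and np.array_equal(a.rppm, b.rppm)


class TestExtraction:
    def test_constant_curves_give_no_intervals(self):
        scan = ScanResult(np.full(30, 2.0), np.full(30, 2.0), 10)
        assert extract_indelfrs(scan) == ()

    def test_paired_dip_spans_flanks(self):
        lppm = np.full(40, 4.0)
        rppm = np.full(40, 4.0)
        lppm[12] = 1.0
        rppm[17] = 1.0
        scan = ScanResult(lppm, rppm, 10)
        assert extract_indelfrs(scan) == ((12, 27),)

    def test_unpaired_anchor_yields_window_length(self):
        lppm = np.full(40, 4.0)
        lppm[12] = 1.0
        scan = ScanResult(lppm, np.full(40, 4.0), 10)
        assert extract_indelfrs(scan) == ((12, 22),)

    def test_output_sorted_disjoint(self, rng):
        for _ in range(20):
            scan = ScanResult(rng.uniform(1, 4, 60), rng.uniform(1, 4, 60), 10)
            ivs = extract_indelfrs(scan)
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                assert a1 < b1 <= a2 < b2
            n = 60 + 10 - 1
            assert all(0 <= a < b <= n for a, b in ivs)

    def test_deterministic(self, rng):
        scan = ScanResult(rng.uniform(1, 4, 50), rng.uniform(1, 4, 50), 10)
        assert extract_indelfrs(scan) == extract_indelfrs(scan)


class TestAnnotate:
    def test_gpo_covers_whole_sequence(self, rng):
        corpus = ["".join(rng.choice(AA, 30)) for _ in range(5)]
        pred = train_predictor(corpus, corpus)
        seq = ProteinSequence("a", "".join(rng.choice(AA, 37)))
        ann = pred.annotate(seq)
        assert ann.gpo.size == 37
        assert ann.seq is seq

    def test_annotate_deterministic(self, rng):
        corpus = ["".join(rng.choice(AA, 30)) for _ in range(5)]
        pred = train_predictor(corpus, corpus)
        seq = ProteinSequence("a", "".join(rng.choice(AA, 40)))
        a, b = pred.annotate(seq), pred.annotate(seq)
        assert np.array_equal(a.gpo, b.gpo) and a.ifrs == b.ifrs


class TestPersistence:
    def test_save_load_bit_exact(self, rng, tmp_path):
        left = ["".join(rng.choice(AA, 25)) for _ in range(4)]
        right = ["".join(rng.choice(AA, 25)) for _ in range(4)]
        pred = train_predictor(left, right, params=ExtractionParams(1.5, 20))
        p = tmp_path / "pred.json"
        pred.save(p)
        back = IndelPredictor.load(p)
        assert back.L == pred.L and back.order == pred.order
        assert back.params == pred.params
        for sym in AA[:5]:
            for ctx in ("", "A", "AR", left[0][:4]):
                assert back.left.symbol_prob(sym, ctx) == pred.left.symbol_prob(sym, ctx)
                assert back.right.symbol_prob(sym, ctx) == pred.right.symbol_prob(sym, ctx)
        json.loads(p.read_text())  # file is plain JSON

    def test_mismatched_orders_rejected(self):
        with pytest.raises(ValueError):
            IndelPredictor(PPMModel(2), PPMModel(3))

    def test_window_must_exceed_order(self):
        with pytest.raises(ValueError):
            IndelPredictor(PPMModel(4), PPMModel(4), L=4)
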