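import itertools

import numpy as np
import pytest

from relrna.metrics import (
    DesignOutput,
    NussinovPredictor,
    accuracy,
    dotbracket_to_pairs,
    mcc_pairs,
    perplexity,
    recovery,
    sc_score,
    sc_score_detailed,
)
from relrna.structures import BasePairSet


def one_hot(seq):
    m = np.zeros((len(seq), 4))
    for i, c in enumerate(seq):
        m[i, "ACGU".index(c)] = 1.0
    return m


class TestPerplexity:
    def test_uniform_is_four(self):
        probs = np.full((12, 4), 0.25)
        assert perplexity(probs, "ACGU" * 3) == pytest.approx(4.0)

    def test_one_hot_is_one(self):
        assert perplexity(one_hot("GGCAU"), "GGCAU") == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # reference-letter probabilities 0.5 and 0.125:
        # exp(-(ln 0.5 + ln 0.125)/2) = exp(ln 16 / 2) = 4
        probs = np.array([[0.5, 0.5, 0, 0], [0.125, 0.875, 0, 0]])
        assert perplexity(probs, "AA") == pytest.approx(4.0)

    def test_zero_probability_warns_inf(self):
        probs = np.array([[0.0, 1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning):
            assert perplexity(probs, "A") == float("inf")

    def test_n_positions_masked(self):
        probs = np.array([[1, 0, 0, 0], [0.25, 0.25, 0.25, 0.25]])
        assert perplexity(probs, "AN") == pytest.approx(1.0)

    def test_always_at_least_one(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=30)
        assert perplexity(p, "ACGU" * 7 + "AC") >= 1.0


class TestAccuracy:
    def test_one_hot_correct(self):
        assert accuracy(one_hot("ACGU"), "ACGU") == 1.0

    def test_complement_is_zero(self):
        assert accuracy(one_hot("UGCA"), "ACGU") == 0.0

    def test_three_of_four(self):
        probs = one_hot("ACGA")
        assert accuracy(probs, "ACGU") == pytest.approx(0.75)

    def test_tie_broken_by_letter_order(self):
        probs = np.array([[0.5, 0.5, 0.0, 0.0]])
        assert accuracy(probs, "A") == 1.0  # A wins the A/C tie
        assert accuracy(probs, "C") == 0.0


class TestRecovery:
    def test_identical_samples(self):
        assert recovery(["ACGU", "ACGU"], "ACGU") == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            recovery(["ACG"], "ACGU")

    def test_single_sample_equals_one_hot_accuracy(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGU")) for _ in range(40))
        s = "".join(rng.choice(list("ACGU")) for _ in range(40))
        assert recovery([s], ref) == pytest.approx(accuracy(one_hot(s), ref))

    def test_sample_order_invariance(self):
        samples = ["ACGU", "AAAA", "UUUU"]
        ref = "ACGA"
        assert recovery(samples, ref) == recovery(samples[::-1], ref)

    def test_uniform_random_near_quarter(self):
        rng = np.random.default_rng(12345)
        L, n = 1000, 16
        ref = "".join(rng.choice(list("ACGU")) for _ in range(L))
        samples = ["".join(rng.choice(list("ACGU")) for _ in range(L))
                   for _ in range(n)]
        se = np.sqrt(0.25 * 0.75 / (L * n))
        assert recovery(samples, ref) == pytest.approx(0.25, abs=3 * se)


class TestMCC:
    def brute_force_mcc(self, pred, ref, L):
        tp = fp = fn = tn = 0
        for i, j in itertools.combinations(range(L), 2):
            p = (i, j) in pred
            r = (i, j) in ref
            tp += p and r
            fp += p and not r
            fn += r and not p
            tn += not p and not r
        num = tp * tn - fp * fn
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        return num / np.sqrt(den) if den else 0.0

    def test_matches_brute_force_on_toy(self):
        pred = {(0, 9), (1, 8)}
        ref = {(0, 9), (2, 7)}
        assert mcc_pairs(pred, ref, 10) == pytest.approx(
            self.brute_force_mcc(pred, ref, 10)
        )

    def test_exact_prediction(self):
        ref = BasePairSet(pairs={(0, 9), (1, 8), (2, 7)})
        assert mcc_pairs(ref, ref, 10) == pytest.approx(1.0)

    def test_empty_prediction_nonempty_reference(self):
        assert mcc_pairs(set(), {(0, 9)}, 10) == 0.0

    def test_both_empty_is_one(self):
        assert mcc_pairs(set(), set(), 10) == 1.0

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        L = 12
        allp = list(itertools.combinations(range(L), 2))
        for _ in range(10):
            pred = {allp[k] for k in rng.choice(len(allp), 6, replace=False)}
            ref = {allp[k] for k in rng.choice(len(allp), 6, replace=False)}
            assert mcc_pairs(pred, ref, L) == pytest.approx(
                self.brute_force_mcc(pred, ref, L)
            )


class _EchoPredictor:
    """Test double returning a fixed pair set."""

    def __init__(self, pairs):
        self.pairs = pairs

    def fold(self, sequence):
        return BasePairSet(pairs=set(self.pairs))


class _FailingPredictor:
    def fold(self, sequence):
        raise RuntimeError("boom")


class TestScScore:
    def test_perfect_predictor(self):
        ref = BasePairSet(pairs={(0, 9), (1, 8)})
        score = sc_score(["ACGUACGUAC"] * 3, ref, _EchoPredictor(ref.pairs))
        assert score == 1.0

    def test_empty_prediction_scores_zero(self):
        ref = BasePairSet(pairs={(0, 9)})
        assert sc_score(["ACGUACGUAC"], ref, _EchoPredictor(set())) == 0.0

    def test_failures_recorded_and_skipped(self):
        ref = BasePairSet(pairs={(0, 9)})
        out = sc_score_detailed(["ACGUACGUAC"], ref, _FailingPredictor())
        assert out["n_failed"] == 1 and out["n_evaluated"] == 0
        assert np.isnan(out["sc_score"])


class TestDotBracket:
    def test_nested(self):
        bp = dotbracket_to_pairs("((..))")
        assert bp.pairs == {(0, 5), (1, 4)}

    def test_pseudoknot_brackets(self):
        bp = dotbracket_to_pairs("((..[[..))..]]")
        assert (0, 9) in bp.pairs and (4, 13) in bp.pairs

    def test_unbalanced(self):
        with pytest.raises(ValueError):
            dotbracket_to_pairs("((.)")


class TestNussinov:
    def test_folds_designed_hairpin(self):
        # GGGG....CCCC can stack 4 WC pairs around the loop
        bp = NussinovPredictor().fold("GGGGAAAACCCC")
        assert len(bp) >= 3
        for i, j in bp.pairs:
            assert j - i > 3

    def test_no_pairs_possible(self):
        assert len(NussinovPredictor().fold("AAAAAAA")) == 0


def test_design_output_metrics_bundle():
    ref = "ACGUACGUAC"
    out = DesignOutput(probabilities=one_hot(ref), samples=[ref, ref],
                       reference=ref)
    pairs = BasePairSet(pairs={(0, 9)})
    m = out.compute_metrics(reference_pairs=pairs,
                            predictor=_EchoPredictor({(0, 9)}))
    assert m["recovery"] == 1.0 and m["accuracy"] == 1.0
    assert m["perplexity"] == pytest.approx(1.0)
    assert m["sc_score"] == 1.0
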