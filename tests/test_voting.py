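"""Majority voting, window-fraction accuracy, voted evaluation."""

import itertools

import numpy as np
import pytest

from hdsemg3d.cubes import CubeDataset, ImageSequence
from hdsemg3d.voting import (
    ConfusionMatrix, VotingWindow, accuracy_vs_window_sweep, eq3_fraction,
    evaluate_voted, majority_vote, vote_entire_trial,
)


class TestEq3Fraction:
    @pytest.mark.parametrize("preds,target,expect", [
        ([1, 1, 2], 1, 200 / 3),
        ([0, 1, 1, 1], 1, 75.0),
        ([5, 5, 5], 5, 100.0),
        ([2, 2], 9, 0.0),
    ])
    def test_fraction(self, preds, target, expect):
        assert eq3_fraction(preds, target) == pytest.approx(expect)

    def test_permutation_invariant(self, rng):
        preds = rng.integers(0, 3, 20).tolist()
        shuffled = rng.permutation(preds).tolist()
        assert eq3_fraction(preds, 1) == eq3_fraction(shuffled, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            eq3_fraction([], 0)


class TestMajorityVote:
    def test_clear_majority(self):
        assert majority_vote([2, 2, 3]) == 2

    def test_single_prediction_identity(self):
        assert majority_vote([1]) == 1

    def test_tie_goes_to_most_recent(self):
        assert majority_vote([1, 2, 1, 2]) == 2

    def test_tie_rule_exhaustive_binary_length4(self):
        """Check the tie rule against a brute-force oracle on every binary
        sequence of length 4."""
        for seq in itertools.product([0, 1], repeat=4):
            counts = {lab: seq.count(lab) for lab in set(seq)}
            top = max(counts.values())
            tied = [lab for lab, c in counts.items() if c == top]
            if len(tied) == 1:
                expect = tied[0]
            else:  # most recent occurrence among tied labels
                expect = max(tied, key=lambda lab: max(
                    i for i, s in enumerate(seq) if s == lab))
            assert majority_vote(list(seq)) == expect

    def test_smallest_tie_break_option(self):
        assert majority_vote([1, 2, 1, 2], tie_break="smallest") == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestVotingWindow:
    def test_realtime_bound_warns_not_errors(self):
        with pytest.warns(UserWarning, match="real-time"):
            w = VotingWindow(nc=40, t_cube_ms=10.0)
        assert w.length_ms == 400.0

    def test_within_bound_silent(self):
        VotingWindow(nc=15, t_cube_ms=10.0)


class TestConfusionMatrix:
    def test_row_percentages_sum_to_100(self, rng):
        cm = ConfusionMatrix.empty(4)
        for _ in range(50):
            cm.add(int(rng.integers(0, 4)), int(rng.integers(0, 4)))
        pct = cm.percentages()
        filled = cm.counts.sum(axis=1) > 0
        np.testing.assert_allclose(pct[filled].sum(axis=1), 100.0)

    def test_counts_total_equals_decisions(self):
        cm = ConfusionMatrix.empty(3)
        for t, p in [(0, 0), (1, 2), (2, 2), (1, 1)]:
            cm.add(t, p)
        assert cm.counts.sum() == 4
        assert cm.accuracy() == pytest.approx(75.0)


class _StubModel:
    """Deterministic per-cube classifier for evaluator tests.

    Predicts the sequence label with probability 1 - flip per cube; flips
    are precomputed from a seed, keyed by a running cube counter.
    """

    def __init__(self, G, flips):
        from hdsemg3d.network import build_2d_cnn

        self.spec = build_2d_cnn((4, 6, 1), G=G,
                                 conv_channels=(1, 1, 1), dense_units=(2, 2))
        self._flips = flips
        self._i = 0
        self._labels = None

    def predict(self, ds):
        n = len(ds)
        true = ds.labels
        out = []
        for k in range(n):
            flip = self._flips[self._i % len(self._flips)]
            self._i += 1
            out.append((true[k] + flip) % self.spec.n_classes)
        probs = np.zeros((n, self.spec.n_classes))
        probs[np.arange(n), out] = 1.0
        return np.asarray(out), probs


def _sequences(G=2, n_trials=4, length=60, fs=1000.0):
    rng = np.random.default_rng(0)
    return [ImageSequence(frames=rng.random((length, 4, 6)), fs=fs,
                          label=g, meta={"trial": t})
            for g in range(G) for t in range(n_trials)]


class TestEvaluateVoted:
    def test_perfect_classifier_all_windows(self):
        model = _StubModel(2, flips=[0])
        for ms in (10, 30, 60):
            acc, cm, eq3 = evaluate_voted(model, _sequences(), l_cube=5,
                                          voting_ms=ms)
            assert acc == 100.0
            assert eq3 == 100.0

    def test_always_wrong_classifier(self):
        model = _StubModel(2, flips=[1])
        acc, _, eq3 = evaluate_voted(model, _sequences(), l_cube=5,
                                     voting_ms=25)
        assert acc == 0.0 and eq3 == 0.0

    def test_nc1_equals_per_cube_accuracy(self):
        """With one cube per window, voting is the identity."""
        flips = ([0] * 7 + [1] * 3) * 5
        model_voted = _StubModel(2, flips=flips)
        acc, _, _ = evaluate_voted(model_voted, _sequences(), l_cube=5,
                                   voting_ms=5)
        model_raw = _StubModel(2, flips=flips)
        raw = np.concatenate([
            model_raw.predict(_ds(seq)) [0] == seq.label
            for seq in _sequences()])
        assert acc == pytest.approx(100.0 * raw.mean())

    def test_window_shorter_than_cube_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            evaluate_voted(_StubModel(2, [0]), _sequences(), l_cube=5,
                           voting_ms=2)

    def test_confusion_counts_equal_windows(self):
        model = _StubModel(2, flips=[0, 1])
        acc, cm, _ = evaluate_voted(model, _sequences(), l_cube=5,
                                    voting_ms=15)
        n_windows_per_seq = (60 // 5) // 3
        assert cm.counts.sum() == n_windows_per_seq * 8

    def test_binomial_tail_oracle(self):
        """i.i.d. per-cube error 0.3, nc = 5, binary task: the voted error
        must match the closed-form binomial tail P(X >= 3), X ~ B(5, 0.3)."""
        from scipy.stats import binom

        rng = np.random.default_rng(42)
        n_windows = 10_000
        flips = (rng.random(n_windows * 5) < 0.3).astype(int)
        model = _StubModel(2, flips=flips.tolist())
        seqs = [ImageSequence(frames=np.zeros((2500, 4, 6)), fs=1000.0,
                              label=0, meta={"trial": t})
                for t in range(100)]
        acc, _, _ = evaluate_voted(model, seqs, l_cube=5, voting_ms=25)
        expected_err = 1.0 - binom.cdf(2, 5, 0.3)
        observed_err = 1.0 - acc / 100.0
        se = np.sqrt(expected_err * (1 - expected_err) / n_windows)
        assert abs(observed_err - expected_err) < 4 * se


def _ds(seq):
    from hdsemg3d.cubes import extract_cubes

    return extract_cubes(seq, l=5, stride=5)


class TestTrialVoteAndSweep:
    def test_trial_majority_correct_at_60pct(self):
        flips = [0, 0, 0, 1, 1] * 100  # 60% correct per cube
        model = _StubModel(2, flips=flips)
        seq = _sequences(G=1, n_trials=1, length=100)[0]
        assert vote_entire_trial(model, seq, l_cube=5) == seq.label

    def test_single_cube_trial(self):
        model = _StubModel(2, flips=[1])
        seq = _sequences(G=1, n_trials=1, length=5)[0]
        assert vote_entire_trial(model, seq, l_cube=5) == \
            (seq.label + 1) % 2

    def test_sweep_flat_for_perfect_classifier(self):
        model = _StubModel(2, flips=[0])
        curve = accuracy_vs_window_sweep(model, _sequences(), l_cube=5,
                                         window_grid_ms=[5, 15, 30])
        assert [a for _, a in curve] == [100.0, 100.0, 100.0]

    def test_sweep_first_point_is_per_cube_accuracy(self):
        flips = ([0] * 4 + [1]) * 40
        m1 = _StubModel(2, flips=flips)
        curve = accuracy_vs_window_sweep(m1, _sequences(), l_cube=5,
                                         window_grid_ms=[5])
        m2 = _StubModel(2, flips=flips)
        raw = np.concatenate([m2.predict(_ds(s))[0] == s.label
                              for s in _sequences()])
        assert curve[0][1] == pytest.approx(100.0 * raw.mean())

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            accuracy_vs_window_sweep(_StubModel(2, [0]), _sequences(),
                                     l_cube=5, window_grid_ms=[30, 10])
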