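"""Cross-validated identification, accuracy curves, utility and ITR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soabci import (
    PsoConfig,
    accuracy_curve,
    bci_utility,
    crossvalidate,
    identify_target,
    utility_table,
    wolpaw_itr,
)
from soabci.errors import FoldError, GroupingError
from tests.conftest import make_epochset

FAST_PSO = PsoConfig(n_particles=4, n_iterations=4, seed=0)


class TestCrossvalidate:
    def test_partition_covers_all_trials_once(self, noise_epochs):
        scores = crossvalidate(noise_epochs, FAST_PSO, seed=0)
        assert len(scores) == noise_epochs.n_epochs
        per_trial = scores.groupby(["block", "trial"])
        assert (per_trial.size() == 6).all()
        assert (per_trial.fold.nunique() == 1).all()
        # Folds are balanced over trials.
        trial_folds = per_trial.fold.first()
        assert trial_folds.value_counts().max() - \
            trial_folds.value_counts().min() <= 1

    def test_separable_scores_order_correctly(self, separable_epochs):
        scores = crossvalidate(separable_epochs, FAST_PSO, seed=0)
        for _, trial in scores.groupby(["block", "trial"]):
            tgt = trial[trial.is_target].score.iloc[0]
            assert (trial[~trial.is_target].score < tgt).all()

    def test_determinism(self, noise_epochs):
        a = crossvalidate(noise_epochs, FAST_PSO, seed=3)
        b = crossvalidate(noise_epochs, FAST_PSO, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_held_out_fold_never_trains_its_own_model(self, noise_epochs):
        # Reconstruct fold 0's model from the other folds only; it must
        # reproduce crossvalidate's fold-0 scores, and must keep doing so
        # when fold-0 epochs are corrupted (their data never enters
        # training).
        from soabci.preprocess import to_features
        from soabci.rfda import FdaSolver
        from soabci.evaluate import assign_folds

        scores = crossvalidate(noise_epochs, FAST_PSO, seed=1)
        trials = assign_folds(noise_epochs, 5, seed=1)
        fold_of = {(b, t): f for b, t, f in
                   zip(trials.block, trials.trial, trials.fold)}
        epoch_fold = np.array([
            fold_of[(b, t)] for b, t in
            zip(noise_epochs.meta.block, noise_epochs.meta.trial)])
        X = to_features(noise_epochs)
        y = noise_epochs.is_target
        lam0 = scores[scores.fold == 0]["lambda"].iloc[0]
        model = FdaSolver(X[epoch_fold != 0], y[epoch_fold != 0]).model(lam0)
        manual = X[epoch_fold == 0] @ model.w + model.bias
        assert np.allclose(scores[scores.fold == 0].score.to_numpy(), manual)

        mutated = make_epochset(target_offset=0.0, noise_sd=1.0, seed=2)
        mutated.data[epoch_fold == 0] += 1e3  # corrupt held-out epochs
        scores2 = crossvalidate(mutated, FAST_PSO, seed=1)
        manual2 = (to_features(mutated)[epoch_fold == 0] @ model.w
                   + model.bias)
        assert np.allclose(scores2[scores2.fold == 0].score.to_numpy(),
                           manual2)

    def test_too_few_trials_per_direction(self):
        eps = make_epochset(n_blocks=2, trials_per_block=2)
        with pytest.raises(FoldError):
            crossvalidate(eps, FAST_PSO)


class TestIdentifyTarget:
    @staticmethod
    def _table(trial_scores):
        """Build a one-fold ScoreTable from per-trial direction scores."""
        rows = []
        for t, per_dir in enumerate(trial_scores):
            for d, s in per_dir.items():
                rows.append((0, 0, t, d, s, d == 30, 30))
        return pd.DataFrame(rows, columns=[
            "fold", "block", "trial", "direction_deg", "score", "is_target",
            "target_direction_deg"])

    def test_hand_computed_averaging_example(self):
        # Target scores {0.4, 0.6}; best non-target {0.7, 0.1}.
        scores = self._table([
            {30: 0.4, -30: 0.7, 90: 0.0, -90: 0.0, 150: 0.0, -150: 0.0},
            {30: 0.6, -30: 0.1, 90: 0.0, -90: 0.0, 150: 0.0, -150: 0.0},
        ])
        n1 = identify_target(scores, n=1)
        assert n1.correct.tolist() == [False, True]
        n2 = identify_target(scores, n=2)
        assert n2.correct.tolist() == [True]  # mean 0.5 > 0.4

    def test_always_max_target_gives_perfect_accuracy(self):
        scores = self._table([
            {30: 1.0, -30: 0.2, 90: 0.1, -90: 0.0, 150: -0.3, -150: -1.0}
            for _ in range(6)
        ])
        for n in (1, 2, 3):
            assert identify_target(scores, n=n).correct.all()

    def test_n_larger_than_trials_raises(self):
        scores = self._table([{d: 0.0 for d in (30, -30, 90, -90, 150, -150)}])
        with pytest.raises(GroupingError):
            identify_target(scores, n=5)

    def test_random_scores_hit_chance_level(self):
        rng = np.random.default_rng(0)
        rows = []
        n_trials = 900
        for t in range(n_trials):
            for d in (30, -30, 90, -90, 150, -150):
                rows.append((t % 5, 0, t, d, rng.normal(), d == 30, 30))
        scores = pd.DataFrame(rows, columns=[
            "fold", "block", "trial", "direction_deg", "score", "is_target",
            "target_direction_deg"])
        out = identify_target(scores, n=1)
        acc = out.correct.mean()
        se = np.sqrt((1 / 6) * (5 / 6) / n_trials)
        assert abs(acc - 1 / 6) < 4 * se


class TestAccuracyCurve:
    def test_separable_curve_is_flat_100(self, separable_epochs):
        scores = crossvalidate(separable_epochs, FAST_PSO, seed=0)
        curve = accuracy_curve(scores, n_max=3)
        assert (curve.accuracy_pct.dropna() == 100.0).all()

    def test_set_counts_shrink_with_n(self, noise_epochs):
        scores = crossvalidate(noise_epochs, FAST_PSO, seed=0)
        curve = accuracy_curve(scores, n_max=3)
        assert curve.n.tolist() == [1, 2, 3]
        assert curve.n_sets.iloc[0] >= curve.n_sets.iloc[1] * 2

    def test_unavailable_points_flagged_not_raised(self):
        eps = make_epochset(n_blocks=5, trials_per_block=6)
        scores = crossvalidate(eps, FAST_PSO, seed=0)
        curve = accuracy_curve(scores, n_max=10)
        assert len(curve) == 10
        assert curve.accuracy_pct.isna().any()


class TestBciUtility:
    def test_spot_values_match_direct_evaluation(self):
        # U = (2P/100 - 1) log2(N-1) / c, c = nNt seconds -> per minute.
        assert bci_utility(100, 6, 1, 1.1) == pytest.approx(
            np.log2(5) / 6.6 * 60, abs=1e-9)
        assert bci_utility(75, 6, 2, 0.5) == pytest.approx(
            0.5 * np.log2(5) / 6 * 60, abs=1e-9)
        assert bci_utility(100, 6, 1, 1.1) == pytest.approx(21.11, abs=0.01)
        assert bci_utility(75, 6, 2, 0.5) == pytest.approx(11.61, abs=0.01)

    def test_below_half_accuracy_is_worthless(self):
        assert bci_utility(49.9, 6, 2, 0.5) == 0.0
        assert bci_utility(0, 6, 1, 0.2) == 0.0

    def test_scaling_and_continuity(self):
        for k in (2, 3, 5):
            assert bci_utility(80, 6, 4 * k, 0.5) == pytest.approx(
                bci_utility(80, 6, 4, 0.5) / k, rel=1e-12)
        assert bci_utility(50, 6, 1, 0.5) == 0.0
        assert bci_utility(50 + 1e-9, 6, 1, 0.5) < 1e-7

    def test_strictly_increasing_above_half(self):
        ps = np.linspace(50, 100, 51)
        us = [bci_utility(p, 6, 2, 0.5) for p in ps]
        assert np.all(np.diff(us) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bci_utility(120, 6, 1, 0.5)
        with pytest.raises(ValueError):
            bci_utility(80, 1, 1, 0.5)
        with pytest.raises(ValueError):
            bci_utility(80, 6, 1, 0.0)


class TestWolpawItr:
    def test_perfect_accuracy_closed_form(self):
        assert wolpaw_itr(100, 6, 1, 1.0) == pytest.approx(
            np.log2(6) / 6 * 60, abs=1e-9)
        assert wolpaw_itr(100, 6, 1, 1.0) == pytest.approx(25.85, abs=0.01)

    def test_chance_accuracy_carries_no_information(self):
        assert wolpaw_itr(100 / 6, 6, 1, 1.0) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(P=st.floats(0, 100), N=st.integers(2, 10),
           n=st.integers(1, 10),
           t=st.floats(0.1, 2.0, allow_nan=False))
    def test_non_negative_everywhere(self, P, N, n, t):
        assert wolpaw_itr(P, N, n, t) >= 0.0
        assert bci_utility(P, N, n, t) >= 0.0

    def test_utility_table_combines_curve(self):
        curve = pd.DataFrame({
            "n": [1, 2], "n_sets": [10, 5], "n_correct": [8, 5],
            "accuracy_pct": [80.0, 100.0], "fold_mean_pct": [80.0, 100.0]})
        table = utility_table(curve, soa_s=0.5)
        assert table.utility_bits_per_min.iloc[0] == pytest.approx(
            bci_utility(80, 6, 1, 0.5))
        assert table.itr_bits_per_min.iloc[1] == pytest.approx(
            wolpaw_itr(100, 6, 2, 0.5))
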