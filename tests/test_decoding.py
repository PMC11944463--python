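"""Shrinkage LDA, leave-one-trial-out decoding, schemes, and smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import emodecode as ed
from emodecode.decoding import _loto_accuracy, scheme_trials
from emodecode.simulate import class_topographies


def oracle_predict(X_train, y_train, X_test, lam):
    """Independent brute-force LDA oracle: argmax over classes of
    log prior - 1/2 Mahalanobis^2 under the shrunk pooled covariance."""
    labels = list(dict.fromkeys(y_train.tolist()))
    n, d = X_train.shape
    means, ns = {}, {}
    scatter = np.zeros((d, d))
    for lab in labels:
        rows = X_train[y_train == lab]
        means[lab] = rows.mean(axis=0)
        ns[lab] = len(rows)
        c = rows - means[lab]
        scatter += c.T @ c
    cov = scatter / (n - len(labels))
    cov = cov + lam * (np.trace(cov) / d) * np.eye(d)
    inv = np.linalg.inv(cov)
    preds = []
    for x in X_test:
        best, best_score = None, -np.inf
        for lab in labels:
            diff = x - means[lab]
            score = np.log(ns[lab] / n) - 0.5 * diff @ inv @ diff
            if score > best_score:  # strict: ties keep the earlier label
                best, best_score = lab, score
        preds.append(best)
    return np.array(preds, dtype=object)


class TestLDA:
    def test_two_class_boundary(self):
        """Equal-covariance 1-D LDA on N(0,1) vs N(4,1): boundary at 2."""
        rng = np.random.default_rng(0)
        n = 4000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)])[:, None]
        y = np.array(["a"] * n + ["b"] * n)
        model = ed.train_lda(X, y)
        grid = np.linspace(0, 4, 4001)[:, None]
        pred = ed.predict_lda(model, grid)
        boundary = grid[np.argmax(pred == "b"), 0]
        assert abs(boundary - 2.0) < 0.1

    def test_degenerate_covariance_handled(self):
        """Duplicated rows per class (zero within-class variance): shrinkage
        keeps the covariance invertible and training accuracy is 1."""
        X = np.repeat(np.array([[0.0, 0.0], [1.0, 3.0], [4.0, 1.0]]), 3,
                      axis=0)
        y = np.repeat(np.array(["a", "b", "c"], dtype=object), 3)
        model = ed.train_lda(X, y)
        assert np.isfinite(np.linalg.cond(model.pooled_covariance))
        assert (ed.predict_lda(model, X) == y).all()

    def test_matches_oracle_on_random_instances(self):
        """Predictions equal the brute-force Mahalanobis oracle on 50 random
        4-class problems."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = rng.integers(2, 10)
            centers = rng.normal(0, 2, (4, d))
            X, y = [], []
            for k, lab in enumerate(ed.EMOTIONS):
                m = rng.integers(3, 12)
                X.append(centers[k] + rng.normal(size=(m, d)))
                y += [lab] * m
            X = np.vstack(X)
            y = np.array(y, dtype=object)
            X_test = rng.normal(0, 2, (20, d))
            model = ed.train_lda(X, y)
            assert (ed.predict_lda(model, X_test)
                    == oracle_predict(X, y, X_test, model.shrinkage)).all()

    def test_class_mean_predicts_itself(self):
        rng = np.random.default_rng(2)
        X = np.vstack([k + rng.normal(0, 0.1, (5, 3)) for k in range(3)])
        y = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5, dtype=object)
        model = ed.train_lda(X, y)
        pred = ed.predict_lda(model, model.class_means)
        assert (pred == np.array(model.class_labels, dtype=object)).all()

    def test_tie_breaks_to_first_label(self):
        """A point equidistant between two class means under a spherical
        covariance goes to the first class in label order."""
        X = np.array([[0.0, 1.0], [0.0, -1.0], [2.0, 1.0], [2.0, -1.0]])
        y = np.array(["happiness", "pleasure"] * 2, dtype=object)
        model = ed.train_lda(X, y)
        assert ed.predict_lda(model, np.array([[1.0, 0.0]]))[0] == "happiness"

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "a", "b"], dtype=object)
        with pytest.raises(ValueError, match="'b'"):
            ed.train_lda(X, y)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        model = ed.train_lda(rng.normal(size=(10, 4)),
                             np.array(["a", "b"] * 5, dtype=object))
        with pytest.raises(ValueError, match="dimension"):
            ed.predict_lda(model, np.zeros((2, 5)))

    def test_priors_sum_and_covariance_spd(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        y = np.array((["a"] * 25) + (["b"] * 15), dtype=object)
        model = ed.train_lda(X, y)
        assert np.isclose(model.priors.sum(), 1.0)
        assert np.allclose(model.pooled_covariance,
                           model.pooled_covariance.T)
        assert np.linalg.eigvalsh(model.pooled_covariance).min() > 0


class TestLOTO:
    def test_downdate_equals_naive_refit(self):
        """The O(d^2) downdated leave-one-out equals refitting from scratch."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 5))
        y = np.array(list(ed.EMOTIONS) * 6, dtype=object)
        fast = _loto_accuracy(X, y, 0.01)
        correct = 0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            model = ed.train_lda(X[keep], y[keep], 0.01)
            correct += ed.predict_lda(model, X[i:i + 1])[0] == y[i]
        assert fast == correct / len(y)

    def test_accuracy_is_exact_fraction(self):
        """LOTO accuracy equals (correct trials)/n: n folds, each trial
        tested once, so n * accuracy is an integer count."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 4))
        y = np.array(list(ed.EMOTIONS) * 10, dtype=object)
        acc = _loto_accuracy(X, y, 0.01)
        assert np.isclose(acc * 40, round(acc * 40))


def _noiseless_eeg(small_design):
    """Effect-dominated data: exact class patterns on every morph inside
    500-900 ms, plus a small jitter floor so covariances are invertible and
    resampling edge leakage stays below the noise."""
    effects = tuple(
        ed.EffectSpec("musician", morph, window_ms=(500.0, 900.0),
                      amplitude=1.0)
        for morph in ("full", "f0", "timbre"))
    cfg = ed.SimulationConfig(
        white_noise_sd=0.0, pink_noise_sd=0.0, channel_mixing=0.0,
        include_eog=False, effects=effects)
    trials = ed.build_trial_table(small_design, n_reps=2, n_blocks=4, seed=8)
    eeg = ed.simulate_subject_eeg(trials, small_design,
                                  ed.Subject("s", "musician", 9), cfg)
    rng = np.random.default_rng(10)
    eeg.data += 0.05 * rng.standard_normal(eeg.data.shape)
    return eeg


class TestSchemes:
    def test_cross_scheme_train_test_disjoint(self, small_preprocessed):
        for name in ("full_to_f0", "full_to_timbre"):
            train, test = scheme_trials(small_preprocessed.trial_meta,
                                        ed.SCHEMES[name])
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) > 0 and len(test) > 0

    def test_average_trials_excluded(self, small_preprocessed):
        meta = small_preprocessed.trial_meta
        for scheme in ed.SCHEMES.values():
            train, test = scheme_trials(meta, scheme)
            rows = np.union1d(train, test)
            assert (meta.emotion.iloc[rows] != "average").all()

    def test_null_accuracy_at_chance(self):
        """Labels independent of the data: accuracy inside the central 99%
        binomial band around 0.25."""
        rng = np.random.default_rng(7)
        n = 400
        meta = pd.DataFrame({
            "emotion": np.array(list(ed.EMOTIONS) * (n // 4), dtype=object),
            "morph": "full",
        })
        data = rng.normal(size=(n, 16, 3))
        eeg = ed.EpochedEEG(data, 100.0, np.array([0.0, 10.0, 20.0]),
                            [f"C{i}" for i in range(16)], meta)
        acc = ed.decode_timepoint(eeg, 1, "all_all")
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.25) / n
        assert lo <= acc <= hi

    def test_perfect_separation_in_effect_window(self, small_design):
        """Noiseless injected effect with distinct topographies: accuracy 1
        inside the window, and elevated nowhere else."""
        eeg = _noiseless_eeg(small_design)
        pre = ed.preprocess(ed.rereference_average(eeg, eog_labels=()))
        i_in = int(np.flatnonzero(pre.times == 700.0)[0])
        assert ed.decode_timepoint(pre, i_in, "all_all") == 1.0
        assert ed.decode_timepoint(pre, i_in, "full_to_f0") == 1.0

    def test_timecourse_elevated_only_in_window(self, small_design):
        """Raw curve ~1.0 inside 500-900 ms, ~chance outside; a +-40 ms guard
        band absorbs anti-alias edge leakage from resampling."""
        eeg = _noiseless_eeg(small_design)
        tc = ed.time_resolved_decode(ed.preprocess(eeg), "all_all")
        inside = (tc.times >= 500) & (tc.times < 900)
        outside = (tc.times < 460) | (tc.times >= 940)
        assert tc.accuracy[inside].min() > 0.9
        assert tc.accuracy[outside].mean() < 0.45

    def test_no_test_trials_errors(self, small_design):
        trials = ed.build_trial_table(small_design, n_reps=1, n_blocks=2,
                                      seed=0)
        cfg = ed.SimulationConfig(include_eog=False, effects=())
        eeg = ed.simulate_subject_eeg(trials, small_design,
                                      ed.Subject("s", "musician", 3), cfg)
        keep = eeg.trial_meta.morph != "f0"
        sub = ed.EpochedEEG(eeg.data[keep.to_numpy()], eeg.sampling_rate,
                            eeg.times, eeg.channel_labels,
                            eeg.trial_meta[keep].reset_index(drop=True))
        with pytest.raises(ValueError, match="full_to_f0"):
            ed.decode_timepoint(sub, 0, "full_to_f0")

    def test_channel_permutation_invariance(self, small_preprocessed):
        """Decoding is invariant to a channel permutation applied
        consistently to train and test data."""
        eeg = small_preprocessed
        i = int(np.flatnonzero(eeg.times == 700.0)[0])
        rng = np.random.default_rng(11)
        perm = rng.permutation(eeg.n_channels)
        shuffled = ed.EpochedEEG(eeg.data[:, perm, :], eeg.sampling_rate,
                                 eeg.times,
                                 [eeg.channel_labels[p] for p in perm],
                                 eeg.trial_meta)
        for name in ("all_all", "full_to_f0"):
            assert np.isclose(ed.decode_timepoint(eeg, i, name),
                              ed.decode_timepoint(shuffled, i, name))

    def test_common_mode_killed_by_average_reference(self, small_design):
        """Adding a constant to all channels at a timepoint changes nothing
        after average referencing."""
        eeg = _noiseless_eeg(small_design)
        bumped = ed.EpochedEEG(eeg.data + 50.0, eeg.sampling_rate, eeg.times,
                               eeg.channel_labels, eeg.trial_meta)
        a = ed.preprocess(eeg)
        b = ed.preprocess(bumped)
        i = int(np.flatnonzero(a.times == 700.0)[0])
        assert np.isclose(ed.decode_timepoint(a, i, "all_all"),
                          ed.decode_timepoint(b, i, "all_all"))

    def test_monotone_snr(self, small_design):
        """Mean accuracy over the effect window is non-decreasing in effect
        amplitude (small sampling tolerance)."""
        trials = ed.build_trial_table(small_design, n_reps=2, n_blocks=4,
                                      seed=12)
        accs = []
        for amp in (0.0, 1.0, 4.0):
            cfg = ed.SimulationConfig(
                white_noise_sd=1.0, pink_noise_sd=2.0, channel_mixing=0.0,
                include_eog=False,
                effects=tuple(
                    ed.EffectSpec("musician", morph,
                                  window_ms=(500.0, 900.0), amplitude=amp)
                    for morph in ("full", "f0")))
            eeg = ed.simulate_subject_eeg(trials, small_design,
                                          ed.Subject("s", "musician", 13),
                                          cfg)
            pre = ed.preprocess(eeg)
            idx = np.flatnonzero((pre.times >= 500) & (pre.times < 900))[::4]
            accs.append(np.mean([ed.decode_timepoint(pre, i, "full_to_f0")
                                 for i in idx]))
        assert accs[1] >= accs[0] - 0.05
        assert accs[2] >= accs[1] - 0.05
        assert accs[2] > accs[0] + 0.2


class TestSmoothing:
    def _tc(self, values):
        v = np.asarray(values, dtype=float)
        return ed.AccuracyTimecourse("s", "musician", "all_all",
                                     10.0 * np.arange(len(v)), v,
                                     np.full(len(v), 10))

    def test_hand_example(self):
        """[1,2,3,4,5], window 5: center 3, first value mean(1,2,3) = 2."""
        out = ed.smooth_timecourse(self._tc([1, 2, 3, 4, 5]), 5)
        assert out.accuracy[2] == 3.0
        assert out.accuracy[0] == 2.0
        assert out.accuracy[-1] == 4.0
        assert out.smoothed

    def test_constant_unchanged(self):
        out = ed.smooth_timecourse(self._tc([0.3] * 7), 5)
        assert np.allclose(out.accuracy, 0.3)

    def test_window_one_is_identity(self):
        vals = [0.1, 0.9, 0.4]
        out = ed.smooth_timecourse(self._tc(vals), 1)
        assert np.allclose(out.accuracy, vals)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ed.smooth_timecourse(self._tc([1, 2, 3]), 4)
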