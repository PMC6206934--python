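"""Direction decoders, lagged ensembles and the self-paced switch."""
import numpy as np
import pytest

from plvdecode import decoding as dec


def _separable(rng, n=10, d=4, gap=4.0):
    left = rng.standard_normal((n, d)) - gap / 2
    right = rng.standard_normal((n, d)) + gap / 2
    return left, right


class TestConfidenceClassifier:
    def test_separable_training_accuracy(self, rng):
        left, right = _separable(rng)
        X = np.vstack([left, right])
        y = [-1] * len(left) + [1] * len(right)
        clf = dec.fit_confidence_classifier(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_confidence_in_range_and_sign_consistent(self, rng):
        left, right = _separable(rng)
        X = np.vstack([left, right])
        y = [-1] * len(left) + [1] * len(right)
        clf = dec.fit_confidence_classifier(X, y)
        conf = clf.confidence(X)
        assert np.all(np.abs(conf) <= 1.0)
        assert np.array_equal(np.sign(conf), clf.predict(X))

    def test_boundary_pattern_near_zero_confidence(self, rng):
        left, right = _separable(rng, n=20)
        X = np.vstack([left, right])
        y = [-1] * len(left) + [1] * len(right)
        clf = dec.fit_confidence_classifier(X, y)
        midpoint = X.mean(axis=0, keepdims=True)
        assert abs(clf.confidence(midpoint)[0]) < 0.25

    def test_label_flip_flips_confidence(self, rng):
        left, right = _separable(rng)
        X = np.vstack([left, right])
        y = np.array([-1] * len(left) + [1] * len(right))
        c1 = dec.fit_confidence_classifier(X, y).confidence(X)
        c2 = dec.fit_confidence_classifier(X, -y).confidence(X)
        assert np.allclose(c1, -c2, atol=1e-4)

    def test_string_labels_accepted(self, rng):
        left, right = _separable(rng)
        X = np.vstack([left, right])
        y = ["left"] * len(left) + ["right"] * len(right)
        clf = dec.fit_confidence_classifier(X, y)
        assert set(clf.predict(X)) <= {-1, 1}

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.raises(ValueError):
            dec.fit_confidence_classifier(X, [1] * 6)


class TestStaticLoocv:
    def test_fold_structure_on_40_trials(self, rng):
        left = rng.standard_normal((20, 30))
        right = rng.standard_normal((20, 30)) + 2.0
        res = dec.loocv_static_accuracy(left, right, k=10)
        assert res.n_folds == 40
        assert res.predictions.shape == (40,)
        assert all(size == 39 for size in res.train_sizes)
        assert all(len(f) == 10 for f in res.fold_features)

    def test_feature_selection_never_sees_held_out_trial(self, rng):
        # one trial carries a huge artifact in feature 5; folds holding it
        # out must not select feature 5 because without that trial the
        # feature is pure noise
        left = rng.standard_normal((8, 40))
        right = rng.standard_normal((8, 40))
        right[:, 11] += 6.0  # genuine effect elsewhere
        left[0, 5] = 1e6     # single-trial artifact
        res = dec.loocv_static_accuracy(left, right, k=1)
        assert 5 not in res.fold_features[0]   # fold holding out trial 0
        assert all(11 in f for f in res.fold_features[1:])

    def test_chance_level_on_shuffled_labels(self, rng):
        # features carry class structure, labels are scrambled: accuracy
        # must fall inside the binomial 95% band around 0.5
        X = rng.standard_normal((40, 25))
        perm = rng.permutation(40)
        left, right = X[perm[:20]], X[perm[20:]]
        res = dec.loocv_static_accuracy(left, right, k=10)
        half_width = 1.96 * np.sqrt(0.25 / 40)
        assert abs(res.accuracy - 0.5) <= half_width + 1e-9

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            dec.loocv_static_accuracy(rng.standard_normal((1, 5)),
                                      rng.standard_normal((1, 5)))


class TestTimeResolved:
    def test_curve_length_and_bank(self, rng):
        n_tau = 6
        L = rng.standard_normal((8, 12, n_tau))
        R = rng.standard_normal((8, 12, n_tau))
        R[:, 3, 2:5] += 5.0
        res = dec.time_resolved_svms(L, R, selected=np.array([3, 7]))
        assert res.accuracy.shape == (n_tau,)
        assert len(res.bank) == n_tau
        assert res.accuracy[2:5].min() > 0.9

    def test_empty_feature_set_rejected(self, rng):
        L = rng.standard_normal((6, 4, 3))
        with pytest.raises(ValueError):
            dec.time_resolved_svms(L, L, selected=np.array([], dtype=int))


def _bank_with_curve(rng, accuracy, n_feat=3):
    """A classifier bank whose members carry controlled hyperplanes."""
    bank = []
    for i in range(len(accuracy)):
        X = rng.standard_normal((10, n_feat))
        y = np.sign(X[:, i % n_feat] + 1e-9)
        y[y == 0] = 1
        if np.unique(y).size < 2:
            y[0] = -y[0]
        bank.append(dec.ConfidenceClassifier().fit(X, y))
    return bank


class TestBuildEnsemble:
    def test_two_separated_peaks(self, rng):
        acc = np.array([0.5, 0.95, 0.5, 0.5, 0.93, 0.5])
        bank = _bank_with_curve(rng, acc)
        ens = dec.build_ensemble(acc, bank, selected=np.arange(3), step=0.35,
                                 min_separation=2)
        assert ens.n_members == 2
        assert ens.lags.tolist() == [1, 4]

    def test_colliding_peak_dropped(self, rng):
        acc = np.array([0.5, 0.95, 0.93, 0.5, 0.5])
        bank = _bank_with_curve(rng, acc)
        ens = dec.build_ensemble(acc, bank, selected=np.arange(3), step=0.35,
                                 min_separation=2)
        assert ens.lags.tolist() == [1]

    def test_duplicate_hyperplane_dropped(self, rng):
        acc = np.array([0.5, 0.95, 0.5, 0.5, 0.95, 0.5])
        bank = _bank_with_curve(rng, acc)
        bank[4] = bank[1]  # identical separating hyperplane
        ens = dec.build_ensemble(acc, bank, selected=np.arange(3), step=0.35,
                                 min_separation=2)
        assert ens.n_members == 1

    def test_lags_strictly_increasing(self, rng):
        acc = np.array([0.91, 0.5, 0.95, 0.5, 0.92, 0.5, 0.90])
        bank = _bank_with_curve(rng, acc)
        ens = dec.build_ensemble(acc, bank, selected=np.arange(3), step=0.35,
                                 min_separation=2)
        assert np.all(np.diff(ens.lags) > 0)


class TestEnsembleReadout:
    def _ensemble(self, rng, lags, n_feat=2):
        acc = np.full(max(lags) + 1, 0.5)
        bank = _bank_with_curve(rng, acc, n_feat=n_feat)
        members = [bank[i] for i in lags]
        return dec.EnsembleModel(members=members, lags=np.array(lags),
                                 selected=np.arange(n_feat), step=0.35)

    def test_mean_of_member_readings(self, rng):
        ens = self._ensemble(rng, [0, 2])
        vecs = rng.standard_normal((2, 10))
        Z, z_ens = dec.ensemble_readout(vecs, ens)
        assert Z.shape == (2, 10)
        assert z_ens.shape == (8,)   # n_tau - max lag
        expected = 0.5 * (Z[0, :8] + Z[1, 2:10])
        assert np.allclose(z_ens, expected)
        assert np.all(np.abs(z_ens) <= 1.0)

    def test_short_stream_warns_and_empty(self, rng):
        ens = self._ensemble(rng, [0, 6])
        vecs = rng.standard_normal((2, 4))
        with pytest.warns(RuntimeWarning, match="shorter"):
            _, z_ens = dec.ensemble_readout(vecs, ens)
        assert z_ens.size == 0


def _traces(rng, n_mi=20, n_rest=10, length=150):
    """Toy classification-index traces: MI peaked early, rest flat noise."""
    t = np.arange(length)
    mi = [np.tanh(2 * np.exp(-0.5 * ((t - 30) / 25.0) ** 2)
                  + 0.05 * rng.standard_normal(length)) for _ in range(n_mi)]
    rest = [0.05 * rng.standard_normal(length) for _ in range(n_rest)]
    return mi, rest


class TestSwitch:
    def test_segment_counts_match_study_design(self, rng):
        mi, rest = _traces(rng)
        switch = dec.train_switch(mi, rest, step=0.02, rng=rng)
        # 20 trials x 5 segments = 100 MI-event + 100 baseline segments
        assert switch.segment_len == 25
        assert switch.classifier._svc.n_features_in_ == 25
        assert switch.classifier._svc.class_weight_ .size == 2

    def test_separable_traces_high_training_accuracy(self, rng):
        mi, rest = _traces(rng)
        switch = dec.train_switch(mi, rest, step=0.02, rng=rng)
        mi_seg = np.stack([m[20:45] for m in mi])
        rest_seg = np.stack([r[60:85] for r in rest])
        assert switch.classifier.proba(mi_seg).mean() > 0.9
        assert switch.classifier.proba(rest_seg).mean() < 0.3

    def test_interval_shorter_than_segment_rejected(self, rng):
        mi, rest = _traces(rng, length=30)
        with pytest.raises(ValueError):
            dec.train_switch(mi, rest, step=0.02, mi_interval=(0.2, 0.3),
                             rng=rng)

    def test_stream_decode_counts_and_threshold(self, rng):
        mi, rest = _traces(rng)
        switch = dec.train_switch(mi, rest, step=0.02, rng=rng)
        mi_det = dec.stream_decode(np.asarray(mi[0]), switch)
        assert len(mi_det) >= 1
        assert mi_det[0].direction == 1  # positive-going toy peak
        rest_det = dec.stream_decode(np.asarray(rest[0]), switch)
        assert len(rest_det) == 0
        # unreachable confidence -> no detections anywhere
        assert dec.stream_decode(np.asarray(mi[0]), switch, threshold=1.0) == []

    def test_consecutive_exceedances_merge(self, rng):
        mi, rest = _traces(rng)
        switch = dec.train_switch(mi, rest, step=0.02, rng=rng)
        # the toy MI bump stays above threshold for many consecutive
        # segments yet must collapse into few detections
        dets = dec.stream_decode(np.asarray(mi[1]), switch)
        assert 1 <= len(dets) <= 3
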