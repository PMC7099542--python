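"""Network construction, ROI-level splitting and training mechanics."""

import numpy as np
import pytest

import sinocad as sc
from sinocad import nn
from sinocad.core import ROIPatch


class TestBuildNet:
    def test_single_input_shapes_and_parameters(self):
        net = sc.build_net(sc.single_input_spec((40, 40, 1)), seed=0)
        shapes = net.output_shapes((40, 40, 1))
        assert shapes[0] == (40, 40, 32)        # conv 7x7x32, same padding
        assert shapes[2] == (20, 20, 32)        # pool
        assert shapes[3] == (20, 20, 64)        # conv 5x5x64
        assert shapes[5] == (10, 10, 64)        # pool
        assert shapes[-2] == (1000,)
        assert shapes[-1] == (2,)
        expected = ((7 * 7 * 1 * 32 + 32) + (5 * 5 * 32 * 64 + 64)
                    + (6400 * 1000 + 1000) + (1000 * 2 + 2))
        assert net.n_parameters() == expected

    def test_multichannel_input_keeps_topology(self):
        net = sc.build_net(sc.single_input_spec((40, 40, 16)), seed=0)
        shapes = net.output_shapes((40, 40, 16))
        assert shapes[0] == (40, 40, 32)
        assert net.layers[0].W.shape == (7, 7, 16, 32)

    def test_dual_input_parameters(self):
        net = sc.build_net(sc.dual_input_spec((40, 40, 16), (40, 40, 1)), seed=0)
        expected = ((7 * 7 * 16 * 32 + 32) + (5 * 5 * 32 * 64 + 64)      # sinogram branch
                    + (7 * 7 * 1 * 64 + 64) + (5 * 5 * 64 * 64 + 64)    # image branch
                    + ((6400 + 6400) * 1000 + 1000) + (1000 * 2 + 2))   # fused head
        assert net.n_parameters() == expected

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            sc.build_net(sc.single_input_spec((3, 3, 1)))

    def test_softmax_rows_sum_to_one(self, rng):
        net = sc.build_net(sc.single_input_spec((16, 16, 1)), seed=1)
        p = nn.predict_proba(net, rng.random((9, 16, 16, 1)).astype(np.float32))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()


def _records(n_per_class):
    rng = np.random.default_rng(0)
    out = []
    for label in (0, 1):
        for i in range(n_per_class):
            out.append(ROIPatch(rng.random((16, 16)), roi_id=f"c{label}_{i}", label=label))
    return out


class TestSplitDataset:
    def test_partition_sizes_and_no_overlap(self):
        train, test = sc.split_dataset(_records(50), fraction=0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert not ({r.roi_id for r in train} & {r.roi_id for r in test})

    def test_deterministic_and_seed_sensitive(self):
        r = _records(50)
        t1, _ = sc.split_dataset(r, seed=5)
        t2, _ = sc.split_dataset(r, seed=5)
        t3, _ = sc.split_dataset(r, seed=6)
        assert [x.roi_id for x in t1] == [x.roi_id for x in t2]
        assert {x.roi_id for x in t1} != {x.roi_id for x in t3}

    def test_representations_stay_together(self):
        # two records per ROI (image + sinogram variant) must co-locate
        base = _records(20)
        doubled = base + [ROIPatch(p.pixels * 0.5, roi_id=p.roi_id, label=p.label)
                          for p in base]
        train, test = sc.split_dataset(doubled, seed=3)
        assert not ({r.roi_id for r in train} & {r.roi_id for r in test})
        # every roi_id appears exactly twice on its side
        for side in (train, test):
            ids, counts = np.unique([r.roi_id for r in side], return_counts=True)
            assert (counts == 2).all()

    def test_small_class_rejected(self):
        records = _records(5)[:6]     # class 1 ends up with a single ROI
        records = [r for r in records if not (r.label == 1 and r.roi_id != "c1_0")]
        with pytest.raises(ValueError, match="fewer than 2"):
            sc.split_dataset(records)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        X = rng.random((40, 16, 16, 1)).astype(np.float32)
        y = (rng.random(40) < 0.5).astype(int)
        clf = sc.CNNClassifier(learning_rate=0.0, epochs=3, val_fraction=0.0,
                               random_state=0)
        ref = sc.build_net(sc.single_input_spec((16, 16, 1)), seed=0)
        clf.fit(X, y)
        for p, q in zip(clf.model_.params, ref.params):
            assert np.array_equal(p, q)
        assert np.allclose(np.diff(clf.training_log_.train_loss), 0.0, atol=1e-5)

    def test_plateaued_validation_stops_early(self, rng):
        # constant inputs with random labels: validation loss cannot improve
        X = np.ones((60, 16, 16, 1), dtype=np.float32)
        y = (rng.random(60) < 0.5).astype(int)
        clf = sc.CNNClassifier(epochs=25, patience=3, learning_rate=0.0,
                               val_fraction=0.2, random_state=0).fit(X, y)
        assert clf.training_log_.stopped_epoch < 25

    def test_shape_mismatch_rejected(self, rng):
        X = rng.random((30, 16, 16, 1)).astype(np.float32)
        y = (np.arange(30) % 2)
        clf = sc.CNNClassifier(epochs=1, val_fraction=0.0, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="shape"):
            clf.predict_proba(rng.random((4, 20, 20, 1)))

    def test_separable_data_learned(self, rng):
        # bright-top vs bright-bottom squares: trivially separable
        n = 60
        X = np.zeros((2 * n, 16, 16, 1), dtype=np.float32)
        X[:n, 2:7, 2:14, 0] = 1.0
        X[n:, 9:14, 2:14, 0] = 1.0
        X += rng.normal(0, 0.05, X.shape).astype(np.float32)
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        clf = sc.CNNClassifier(epochs=15, learning_rate=1e-3, val_fraction=0.0,
                               random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        X = rng.random((36, 16, 16, 1)).astype(np.float32)
        y = np.arange(36) % 2
        return sc.CNNClassifier(epochs=1, val_fraction=0.0, random_state=0).fit(X, y), X

    def test_probabilities_normalised(self, fitted):
        clf, X = fitted
        p = clf.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicates_score_identically(self, fitted):
        clf, X = fitted
        batch = np.concatenate([X[:1], X[:1], X[1:4]])
        p = clf.predict_proba(batch)
        assert np.array_equal(p[0], p[1])

    def test_batched_equals_per_sample(self, fitted):
        clf, X = fitted
        full = clf.predict_proba(X[:8])
        singles = np.concatenate([clf.predict_proba(X[i:i + 1]) for i in range(8)])
        assert np.allclose(full, singles, atol=1e-6)


def test_dual_input_classifier_end_to_end(rng):
    xs = rng.random((24, 16, 16, 2)).astype(np.float32)
    xi = rng.random((24, 16, 16, 1)).astype(np.float32)
    y = np.arange(24) % 2
    clf = sc.DualInputCNNClassifier(epochs=2, val_fraction=0.0, random_state=0)
    clf.fit((xs, xi), y)
    p = clf.predict_proba((xs, xi))
    assert p.shape == (24, 2)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
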