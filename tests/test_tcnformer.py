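import numpy as np
import pytest

from myograde import io as mio
from myograde import nn
from myograde import tcnformer as tf


@pytest.fixture(scope="module")
def default_model():
    return tf.build_model(tf.TcnformerConfig(seed=7))


class TestArchitecture:
    def test_default_parameter_count(self, default_model):
        """The calibrated 5-class model matches the published trainable count."""
        assert tf.count_parameters(default_model) == 167781

    def test_feature_dimension_is_560(self, default_model, rng):
        feat = default_model.feature(rng.random((2, 4, 200)))
        assert feat.shape == (2, 560)

    def test_probability_rows_sum_to_one(self, default_model, rng):
        p = default_model.forward(rng.random((5, 4, 200)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_batch_permutation_equivariance(self, default_model, rng):
        x = rng.random((6, 4, 200))
        perm = rng.permutation(6)
        np.testing.assert_allclose(default_model.forward(x)[perm],
                                   default_model.forward(x[perm]), atol=1e-10)

    def test_constant_input_gives_identical_rows(self, default_model):
        p = default_model.forward(np.zeros((4, 4, 200)))
        assert np.ptp(p, axis=0).max() < 1e-12

    def test_same_seed_same_parameters(self):
        a = tf.build_model(tf.TcnformerConfig(seed=3))
        b = tf.build_model(tf.TcnformerConfig(seed=3))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_wrong_input_shape_names_expectation(self, default_model, rng):
        with pytest.raises(ValueError, match=r"4, *200"):
            default_model.forward(rng.random((2, 3, 200)))

    def test_incompatible_feature_dim_reports_both(self):
        cfg = tf.TcnformerConfig(d_head_out=10)  # 40*10 != 560
        with pytest.raises(ValueError, match="400"):
            tf.build_model(cfg)

    def test_parameter_count_invariant_to_seed(self):
        assert (tf.count_parameters(tf.build_model(tf.TcnformerConfig(seed=1)))
                == tf.count_parameters(tf.build_model(tf.TcnformerConfig(seed=2))))

    def test_frozen_model_counts_zero(self):
        m = tf.build_model(tf.TcnformerConfig(seed=0))
        for p in m.params():
            p.trainable = False
        assert tf.count_parameters(m) == 0

    def test_extra_linear_map_adds_exact_count(self, rng):
        m = tf.build_model(tf.TcnformerConfig(seed=0))
        base = tf.count_parameters(m)
        extra = nn.Dense(10, 10, rng, bias=False)
        assert base + nn.count_parameters(extra) == base + 100

    @pytest.mark.parametrize("layout,expected", [("parallel", 13), ("serial", 25)])
    def test_receptive_field_formula(self, layout, expected):
        cfg = tf.TcnformerConfig(tcn_layout=layout)
        assert tf.receptive_field(cfg) == expected

    def test_serial_layout_builds_and_runs(self, rng):
        cfg = tf.TcnformerConfig(tcn_layout="serial", seed=1)
        m = tf.TcnformerModel(cfg)
        p = m.forward(rng.random((2, 4, 200)))
        assert p.shape == (2, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


class _StubModel:
    """Fixed per-segment predictions for vote-aggregation tests."""

    def __init__(self, grades, n_classes=5):
        self.cfg = tf.TcnformerConfig(n_classes=n_classes)
        self._grades = np.asarray(grades)
        self._i = 0

    def forward(self, x, train=False):
        out = np.zeros((len(x), self.cfg.n_classes))
        g = self._grades[self._i:self._i + len(x)]
        self._i += len(x)
        out[np.arange(len(x)), g - 1] = 1.0
        return out


def _segs_for(grades, subject="r1"):
    n = len(grades)
    return mio.SegmentSet(data=np.zeros((n, 4, 200)),
                          labels=np.asarray(grades),
                          subject_ids=np.array([subject] * n, dtype=object),
                          starts=np.arange(n) * 100)


class TestGradeAggregation:
    def test_unanimous_vote(self):
        segs = _segs_for([3] * 9)
        _, per_rec = tf.predict_grade(_StubModel([3] * 9), segs)
        assert per_rec == {"r1": 3}

    def test_majority_vote(self):
        votes = [4] * 5 + [3] * 4
        _, per_rec = tf.predict_grade(_StubModel(votes), _segs_for(votes))
        assert per_rec == {"r1": 4}

    def test_tie_breaks_to_higher_grade(self):
        votes = [2] * 4 + [3] * 4
        _, per_rec = tf.predict_grade(_StubModel(votes), _segs_for(votes))
        assert per_rec == {"r1": 3}


class TestKfold:
    def _benchmark_like(self, rng, n_subjects=4, per_subject=10):
        datas, labels, subs = [], [], []
        for g in range(1, 6):
            for s in range(n_subjects):
                datas.append(rng.random((per_subject, 4, 200)))
                labels.append(np.full(per_subject, g))
                subs.append(np.array([f"g{g}s{s}"] * per_subject, dtype=object))
        return mio.SegmentSet(data=np.concatenate(datas),
                              labels=np.concatenate(labels),
                              subject_ids=np.concatenate(subs),
                              starts=np.zeros(5 * n_subjects * per_subject,
                                              dtype=np.int64))

    def test_splits_are_subject_disjoint_partitions(self, rng):
        segs = self._benchmark_like(rng)
        for tr, va in tf.kfold_indices(segs, folds=10, seed=0):
            tr_subj = set(segs.subject_ids[tr])
            va_subj = set(segs.subject_ids[va])
            assert not tr_subj & va_subj
            assert len(tr) + len(va) == len(segs)
            assert sorted(np.concatenate([tr, va])) == list(range(len(segs)))

    def test_split_ratio_and_stratification(self, rng):
        segs = self._benchmark_like(rng, n_subjects=5)
        tr, va = tf.kfold_indices(segs, folds=1, val_fraction=0.2, seed=1)[0]
        assert len(va) == 50  # one subject (10 segments) per grade
        for g in range(1, 6):
            assert (segs.labels[va] == g).sum() == 10

    def test_same_seed_identical_splits(self, rng):
        segs = self._benchmark_like(rng)
        a = tf.kfold_indices(segs, folds=3, seed=5)
        b = tf.kfold_indices(segs, folds=3, seed=5)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_single_subject_grade_falls_back_with_warning(self, rng):
        segs = self._benchmark_like(rng, n_subjects=1)
        with pytest.warns(UserWarning, match="fewer than 2 subjects"):
            splits = tf.kfold_indices(segs, folds=1, seed=0)
        tr, va = splits[0]
        assert len(tr) and len(va)


class TestTraining:
    def _separable_set(self, rng, n_per_class=12):
        """Linearly separable toy data: each grade is a distinct DC level."""
        datas, labels = [], []
        for g in range(1, 6):
            level = g / 6.0
            datas.append(np.clip(
                level + 0.01 * rng.standard_normal((n_per_class, 4, 200)),
                0, 1))
            labels.append(np.full(n_per_class, g))
        subs = np.array([f"s{i}" for i in range(5 * n_per_class)], dtype=object)
        return mio.SegmentSet(data=np.concatenate(datas),
                              labels=np.concatenate(labels),
                              subject_ids=subs,
                              starts=np.zeros(5 * n_per_class, dtype=np.int64))

    def test_separable_data_reaches_full_train_accuracy(self, rng):
        segs = self._separable_set(rng)
        model = tf.build_model(tf.TcnformerConfig(seed=2, dropout=0.1))
        hist = tf.train(model, segs, segs, epochs=50, lr=1e-3, seed=0)
        assert hist["train_acc"][0] < 0.6  # starts near chance
        assert max(hist["train_acc"]) == 1.0

    def test_initial_loss_near_log_k(self, rng):
        """Before any learning, balanced 5-class cross-entropy is ~ln 5."""
        segs = self._separable_set(rng)
        model = tf.build_model(tf.TcnformerConfig(seed=4))
        probs = model.forward(segs.data[:20], train=True)
        loss, _ = nn.cross_entropy(probs, segs.labels[:20] - 1)
        assert abs(loss - np.log(5)) < 0.25

    def test_label_out_of_range_rejected(self, rng):
        segs = self._separable_set(rng)
        segs.labels[0] = 9
        model = tf.build_model(tf.TcnformerConfig(seed=0))
        with pytest.raises(mio.ValidationError, match="1..5"):
            tf.train(model, segs, segs, epochs=1)

    def test_empty_split_rejected(self, rng):
        segs = self._separable_set(rng)
        model = tf.build_model(tf.TcnformerConfig(seed=0))
        with pytest.raises(mio.ValidationError, match="non-empty"):
            tf.train(model, segs.subset([]), segs, epochs=1)


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, tmp_path, rng, default_model):
        x = rng.random((3, 4, 200))
        bounds = {"s1": rng.random((4, 2))}
        tf.save_model(default_model, tmp_path / "m.npz", bounds=bounds)
        back, b2 = tf.load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(back.forward(x), default_model.forward(x),
                                   atol=1e-12)
        np.testing.assert_array_equal(b2["s1"], bounds["s1"])
        assert back.cfg == default_model.cfg
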