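import numpy as np
import pytest

from myograde import io as mio
from myograde import tcnformer as tf
from myograde import tdc


def brute_force_soft_assign(z, mu, alpha):
    """Explicit double-loop student-t soft assignment."""
    N, K = len(z), len(mu)
    Q = np.zeros((N, K))
    for i in range(N):
        f = np.zeros(K)
        for j in range(K):
            d2 = float(((z[i] - mu[j]) ** 2).sum())
            f[j] = (1 + d2 / alpha) ** (-(alpha + 1) / 2)
        Q[i] = f / f.sum()
    return Q


def brute_force_target(Q):
    N, K = Q.shape
    mass = [sum(Q[i][j] for i in range(N)) for j in range(K)]
    P = np.zeros_like(Q)
    for i in range(N):
        w = [Q[i][j] ** 2 / mass[j] for j in range(K)]
        s = sum(w)
        P[i] = [v / s for v in w]
    return P


class TestSoftAssign:
    def test_single_cluster_assigns_everything(self, rng):
        z = rng.normal(size=(7, 3))
        Q = tdc.soft_assign(z, z[:1] * 0.0)
        np.testing.assert_allclose(Q, 1.0)

    def test_equidistant_point_splits_evenly(self):
        z = np.array([[0.0, 0.0]])
        mu = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(tdc.soft_assign(z, mu)[0], [0.5, 0.5])

    def test_hand_case_two_thirds_one_third(self):
        """alpha=1, squared distances 0 and 1 -> weights (1, 1/2)."""
        z = np.array([[0.0]])
        mu = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(tdc.soft_assign(z, mu)[0],
                                   [2 / 3, 1 / 3], atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(6, 3))
        mu = rng.normal(size=(4, 3))
        alpha = float(rng.uniform(0.5, 3.0))
        np.testing.assert_allclose(tdc.soft_assign(z, mu, alpha),
                                   brute_force_soft_assign(z, mu, alpha),
                                   atol=1e-10)

    def test_rows_stochastic(self, rng):
        Q = tdc.soft_assign(rng.normal(size=(30, 5)), rng.normal(size=(6, 5)))
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(Q >= 0)

    def test_nonfinite_latent_rejected(self):
        z = np.array([[np.nan, 0.0]])
        with pytest.raises(mio.ValidationError):
            tdc.soft_assign(z, np.zeros((2, 2)))


class TestTargetDistribution:
    def test_one_hot_is_fixed_point(self):
        Q = np.eye(3)[[0, 1, 2, 0]]
        np.testing.assert_allclose(tdc.target_distribution(Q), Q)

    def test_uniform_stays_uniform(self):
        Q = np.full((6, 4), 0.25)
        np.testing.assert_allclose(tdc.target_distribution(Q), Q)

    def test_hand_case(self):
        Q = np.array([[0.9, 0.1], [0.6, 0.4]])
        np.testing.assert_allclose(tdc.target_distribution(Q),
                                   brute_force_target(Q), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        Q = rng.random((6, 3))
        Q /= Q.sum(axis=1, keepdims=True)
        P = tdc.target_distribution(Q)
        np.testing.assert_allclose(P, brute_force_target(Q), atol=1e-10)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_mass_cluster_rejected(self):
        Q = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(mio.ValidationError, match="zero soft mass"):
            tdc.target_distribution(Q)


class TestClusteringLoss:
    def test_zero_iff_equal(self, rng):
        Q = rng.random((5, 4))
        Q /= Q.sum(axis=1, keepdims=True)
        assert tdc.clustering_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case_log_two(self):
        P = np.array([[1.0, 0.0]])
        Q = np.array([[0.5, 0.5]])
        assert tdc.clustering_loss(P, Q) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((8, 3))
        P /= P.sum(axis=1, keepdims=True)
        Q = rng.random((8, 3))
        Q /= Q.sum(axis=1, keepdims=True)
        assert tdc.clustering_loss(P, Q) >= 0.0

    def test_kl_gradients_match_finite_differences(self, rng):
        z = rng.normal(size=(5, 3))
        mu = rng.normal(size=(4, 3))
        P = rng.random((5, 4))
        P /= P.sum(axis=1, keepdims=True)
        for alpha in (1.0, 2.5):
            dz, dmu = tdc.kl_gradients(z, mu, P, alpha)

            def loss():
                return tdc.clustering_loss(P, tdc.soft_assign(z, mu, alpha))

            eps = 1e-6
            for arr, grad in ((z, dz), (mu, dmu)):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    old = arr[i]
                    arr[i] = old + eps
                    fp = loss()
                    arr[i] = old - eps
                    fm = loss()
                    arr[i] = old
                    assert abs(grad[i] - (fp - fm) / (2 * eps)) < 1e-6


class TestReconstruction:
    def test_perfect_reconstruction_zero_loss(self, rng):
        x = rng.random((3, 4, 200))
        loss, _ = tdc.reconstruction_loss(x, x.reshape(3, -1))
        assert loss == 0.0

    def test_constant_offset_gives_800_c_squared(self, rng):
        """x̂ = x + c elementwise on the flattened 800-vector."""
        x = rng.random((5, 4, 200))
        c = 0.3
        loss, _ = tdc.reconstruction_loss(x, x.reshape(5, -1) + c)
        assert loss == pytest.approx(800 * c ** 2)

    def test_gradient_direction(self, rng):
        x = rng.random((2, 4, 200))
        xhat = x.reshape(2, -1) + 1.0
        _, g = tdc.reconstruction_loss(x, xhat)
        np.testing.assert_allclose(g, 2.0 / 2.0 * np.ones_like(g))


class TestFineGrades:
    def test_fractional_values_enumerate_25_levels(self):
        vals = sorted(tdc.FineGrade(g, j).fractional
                      for g in range(1, 6) for j in range(5))
        assert len(set(np.round(vals, 1))) == 25
        assert vals[0] == pytest.approx(1.0)
        assert vals[-1] == pytest.approx(5.8)

    def test_invalid_fine_grade_rejected(self):
        with pytest.raises(mio.ValidationError):
            tdc.FineGrade(6, 0)
        with pytest.raises(mio.ValidationError):
            tdc.FineGrade(3, 5)

    def test_index_round_trip(self):
        for idx in range(25):
            assert tdc.fine_class_index(tdc.fine_from_index(idx)) == idx

    def test_rms_ordering_rule(self):
        """Sub-clusters are ranked by member RMS: the weakest cluster gets
        sub-index 0 (grade g.0), the strongest gets 4 (grade g.8)."""
        n = 10
        state = tdc.ClusterState()
        Q = np.zeros((n, 5))
        hard = np.array([4, 4, 3, 3, 2, 2, 1, 1, 0, 0])
        Q[np.arange(n), hard] = 1.0
        state.grades[3] = tdc.GradeClusterState(
            grade=3, model=None, indices=np.arange(n), Q=Q, P=Q, hard=hard)
        # rms increases with position, so cluster 4 (first segments) is weakest
        rms = np.linspace(0.1, 1.0, n)
        fine = tdc.assign_fine_labels(state, np.full(n, 3), rms)
        assert fine[0].fractional == pytest.approx(3.0)   # cluster 4, weakest
        assert fine[-1].fractional == pytest.approx(3.8)  # cluster 0, strongest
        assert [f.coarse for f in fine] == [3] * n

    def test_empty_subcluster_warns_and_relabels(self):
        n = 8
        state = tdc.ClusterState()
        hard = np.array([0, 0, 1, 1, 2, 2, 3, 3])  # cluster 4 empty
        Q = np.zeros((n, 5))
        Q[np.arange(n), hard] = 1.0
        state.grades[2] = tdc.GradeClusterState(
            grade=2, model=None, indices=np.arange(n), Q=Q, P=Q, hard=hard)
        with pytest.warns(UserWarning, match="empty sub-cluster"):
            fine = tdc.assign_fine_labels(state, np.full(n, 2),
                                          np.linspace(0.1, 1, n))
        assert all(f.coarse == 2 for f in fine)
        assert {f.sub for f in fine} == {0, 1, 2, 3}


class TestAutoencoder:
    def test_full_tdc_parameter_count(self):
        """Autoencoder (encoder front end + latent map + decoder) plus the 5
        cluster centres matches the published trainable count."""
        cfg = tdc.TdcConfig(seed=0)
        ae = tdc.Autoencoder(cfg)
        model = tdc.TdcModel(ae, np.zeros((cfg.k_sub, cfg.d_z)))
        assert tdc.nn.count_parameters(model) == 299601

    def test_reconstruction_shape_matches_input(self, rng):
        ae = tdc.Autoencoder(tdc.TdcConfig(seed=1))
        x = rng.random((3, 4, 200))
        assert ae.reconstruct(x).shape == (3, 800)

    def test_encoder_transfer_does_not_mutate_source(self, rng):
        src = tf.build_model(tf.TcnformerConfig(seed=2))
        before = {p.name: p.value.copy() for p in src.params()}
        ae = tdc.Autoencoder(tdc.TdcConfig(seed=0), encoder=src)
        for p in ae.params():
            p.value += 1.0
        for p in src.params():
            np.testing.assert_array_equal(p.value, before[p.name])

    def test_pretraining_reduces_reconstruction_loss(self, rng):
        data = rng.random((40, 4, 200))
        segs = mio.SegmentSet(
            data=data, labels=np.ones(40, dtype=int),
            subject_ids=np.array(["s"] * 40, dtype=object),
            starts=np.zeros(40, dtype=np.int64))
        cfg = tdc.TdcConfig(seed=0, pretrain_epochs=12)
        _, hist = tdc.pretrain_autoencoder(segs, cfg)
        first = np.mean(hist["rec_loss"][:3])
        last = np.mean(hist["rec_loss"][-3:])
        assert last < first

    def test_empty_set_rejected(self):
        segs = mio.SegmentSet(data=np.zeros((0, 4, 200)))
        with pytest.raises(mio.ValidationError, match="empty"):
            tdc.pretrain_autoencoder(segs, tdc.TdcConfig())


class TestLambdaZeroLimit:
    def test_objective_reduces_to_reconstruction(self, rng):
        """With lambda = 0 the joint objective equals the reconstruction loss
        and the cluster centres receive zero gradient."""
        z = rng.normal(size=(10, 4))
        mu = rng.normal(size=(3, 4))
        Q = tdc.soft_assign(z, mu)
        P = tdc.target_distribution(Q)
        lam = 0.0
        x = rng.random((10, 4, 200))
        xhat = x.reshape(10, -1) + 0.1
        rec, _ = tdc.reconstruction_loss(x, xhat)
        total = rec + lam * tdc.clustering_loss(P, Q)
        assert total == rec
        _, dmu = tdc.kl_gradients(z, mu, P)
        assert np.any(dmu != 0)  # the KL gradient itself is nonzero
        assert np.all(lam * dmu == 0)  # but contributes nothing at lambda=0

    def test_grade_with_too_few_segments_rejected(self, rng):
        data = rng.random((3, 4, 200))
        segs = mio.SegmentSet(data=data, labels=np.full(3, 2),
                              subject_ids=np.array(["s"] * 3, dtype=object),
                              starts=np.zeros(3, dtype=np.int64))
        cfg = tdc.TdcConfig(seed=0, pretrain_epochs=1, epochs=1)
        ae, _ = tdc.pretrain_autoencoder(segs, cfg)
        with pytest.raises(mio.ValidationError, match="sub-cluster"):
            tdc.tdc_train(segs, segs.labels, cfg, autoencoder=ae)
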