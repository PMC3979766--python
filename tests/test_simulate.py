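import numpy as np
import pytest

from smartclust.simulate import (
    GmmSpec,
    QpskSpec,
    S1Spec,
    S2Spec,
    gen_gmm,
    gen_qpsk,
    gen_s1,
    gen_s2,
)


class TestQpsk:
    def test_noiseless_limit_on_constellation(self):
        data, labels = gen_qpsk(QpskSpec(n=64, snr_db=300.0),
                                np.random.default_rng(0))
        mags = np.abs(data.values)
        np.testing.assert_allclose(mags, 1 / np.sqrt(2), atol=1e-9)
        # unit symbol energy
        np.testing.assert_allclose((data.values**2).sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_noise_variance_matches_snr(self):
        spec = QpskSpec(n=20000, snr_db=15.0)
        data, labels = gen_qpsk(spec, np.random.default_rng(1))
        sigma2 = 10 ** (-1.5) / 2
        corners = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]]) / np.sqrt(2)
        resid = data.values - corners[labels - 1]
        assert np.var(resid) == pytest.approx(sigma2, rel=0.05)

    def test_per_label_means_near_corners(self):
        spec = QpskSpec(n=4000, snr_db=15.0)
        data, labels = gen_qpsk(spec, np.random.default_rng(2))
        sigma = np.sqrt(10 ** (-1.5) / 2)
        corners = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]]) / np.sqrt(2)
        for lab in range(1, 5):
            pts = data.values[labels == lab]
            tol = 3 * sigma / np.sqrt(len(pts))
            assert np.all(np.abs(pts.mean(axis=0) - corners[lab - 1]) < tol)

    def test_symbols_roughly_uniform(self):
        _, labels = gen_qpsk(QpskSpec(n=8000), np.random.default_rng(3))
        counts = np.bincount(labels)[1:]
        assert counts.min() > 0.8 * 2000


class TestGmm:
    def test_degenerate_weights(self):
        spec = GmmSpec(weights=[1.0, 0.0, 0.0], n=50)
        _, labels = gen_gmm(spec, np.random.default_rng(0))
        assert np.all(labels == 1)

    def test_zero_covariance_hits_means(self):
        spec = GmmSpec(
            weights=[0.5, 0.5],
            means=[[0.0, 0.0], [3.0, 3.0]],
            covariances=[np.zeros((2, 2))] * 2,
            n=40,
        )
        data, labels = gen_gmm(spec, np.random.default_rng(1))
        means = np.array(spec.means)
        np.testing.assert_allclose(data.values, means[labels - 1], atol=1e-12)

    def test_proportions_converge_to_weights(self):
        spec = GmmSpec(n=30000)
        _, labels = gen_gmm(spec, np.random.default_rng(2))
        props = np.bincount(labels)[1:] / 30000
        np.testing.assert_allclose(props, 1 / 3, atol=0.01)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            GmmSpec(
                weights=[1.0],
                means=[[0.0, 0.0]],
                covariances=[np.array([[1.0, 2.0], [2.0, 1.0]])],
                n=10,
            )

    def test_default_regime_shape(self):
        spec = GmmSpec()
        assert spec.n == 900
        means = np.array(spec.means)
        # collinear, two units apart on one axis
        assert np.ptp(means[:, 0]) == 0.0
        np.testing.assert_allclose(np.diff(np.sort(means[:, 1])), 2.0)
        np.testing.assert_allclose(spec.covariances[0], np.diag([4.0, 0.4]))


class TestS1:
    def test_degenerate_hierarchy_is_piecewise_constant(self):
        spec = S1Spec(k=3, m_samples=20, sample_sd=0.0, gene_sd=0.0,
                      noise_sd=0.0)
        data, labels = gen_s1(spec, np.random.default_rng(0))
        for c in range(1, 4):
            rows = data.values[labels == c]
            # all genes in the cluster identical
            assert np.max(np.abs(rows - rows[0][None, :])) < 1e-12
            # profile has at most 4 distinct levels
            assert np.unique(np.round(rows[0], 9)).size <= 4

    def test_sizes_poisson_with_floor(self):
        spec = S1Spec(k=8, size_mean=12.0, size_floor=10)
        data, labels = gen_s1(spec, np.random.default_rng(1))
        sizes = np.bincount(labels)[1:]
        assert sizes.size == 8
        assert sizes.min() >= 10
        assert data.n == sizes.sum()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            S1Spec(m_samples=3)

    def test_between_cluster_correlation_low(self):
        # cluster templates are independent draws, so profiles of different
        # clusters are uncorrelated on average
        cors = []
        for seed in range(30):
            data, labels = gen_s1(S1Spec(k=2, size_mean=10),
                                  np.random.default_rng(seed))
            a = data.values[labels == 1].mean(axis=0)
            b = data.values[labels == 2].mean(axis=0)
            cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors)) < 0.2


class TestS2:
    def test_noiseless_model_exact(self):
        spec = S2Spec(g=10, m=24, k=5, theta_mag=0.0, theta_phase=0.0)
        data, labels = gen_s2(spec, np.random.default_rng(0))
        j = np.arange(24)
        for g in range(10):
            omega = 2 * np.pi * (labels[g] - 1) / 5
            expected = 3.0 * np.sin(2 * np.pi * j / 8 + omega)
            np.testing.assert_allclose(data.values[g], expected, atol=1e-12)
        # period 8: three identical cycles over 24 samples
        np.testing.assert_allclose(data.values[:, :8], data.values[:, 8:16],
                                   atol=1e-12)

    def test_amplitude_bound_when_noiseless(self):
        data, _ = gen_s2(S2Spec(theta_mag=0.0, theta_phase=0.0),
                         np.random.default_rng(1))
        assert np.max(np.abs(data.values)) <= 3.0 + 1e-12

    def test_phase_noise_degrades_within_cluster_correlation(self):
        def mean_within_corr(theta, seeds=15):
            vals = []
            for seed in range(seeds):
                data, labels = gen_s2(
                    S2Spec(g=50, k=5, theta_phase=theta, theta_mag=0.1),
                    np.random.default_rng(seed),
                )
                for c in range(1, 6):
                    rows = data.values[labels == c]
                    cmat = np.corrcoef(rows)
                    iu = np.triu_indices_from(cmat, k=1)
                    vals.append(cmat[iu].mean())
            return np.mean(vals)

        assert mean_within_corr(1.0) < mean_within_corr(0.1)

    def test_cluster_sizes_equal(self):
        _, labels = gen_s2(S2Spec(), np.random.default_rng(2))
        np.testing.assert_array_equal(np.bincount(labels)[1:], [100] * 5)


class TestReproducibility:
    @pytest.mark.parametrize(
        "gen,spec",
        [
            (gen_qpsk, QpskSpec(n=64)),
            (gen_gmm, GmmSpec(n=64)),
            (gen_s1, S1Spec(k=3, size_mean=12)),
            (gen_s2, S2Spec(g=20, k=5)),
        ],
    )
    def test_same_seed_bitwise_identical(self, gen, spec):
        a, la = gen(spec, np.random.default_rng(99))
        b, lb = gen(spec, np.random.default_rng(99))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(la, lb)
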