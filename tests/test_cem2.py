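import numpy as np
import pytest

from smartclust.cem2 import (
    AllComponentsAnnihilated,
    annihilating_weight_update,
    cem2_run,
    estep,
    hard_labels,
    injection_site,
    mstep_component,
    split_inject,
)
from smartclust.core import (
    CovStructure,
    DataMatrix,
    GaussianComponent,
    MixtureModel,
    estimate_covariance,
)
from smartclust.mml import message_length, partition_to_mixture
from tests.conftest import make_blobs


def mixture_1d(means, variances, weights, cov=CovStructure.FULL):
    comps = [
        GaussianComponent(w, [mu], [[v]])
        for mu, v, w in zip(means, variances, weights)
    ]
    return MixtureModel(comps, cov)


class TestEstep:
    def test_equidistant_point_splits_evenly(self):
        mix = mixture_1d([-1.0, 1.0], [1.0, 1.0], [0.5, 0.5])
        m = DataMatrix.from_array([[0.0], [0.0]])
        w = estep(m, mix)
        np.testing.assert_allclose(w, 0.5)

    def test_prior_only_case(self):
        mix = mixture_1d([0.0, 0.0], [1.0, 1.0], [0.8, 0.2])
        m = DataMatrix.from_array([[0.3], [-2.0]])
        w = estep(m, mix)
        np.testing.assert_allclose(w[:, 0], 0.8)
        np.testing.assert_allclose(w[:, 1], 0.2)

    def test_zero_weight_component_gets_zero_column(self):
        mix = mixture_1d([0.0, 5.0], [1.0, 1.0], [1.0, 0.0])
        m = DataMatrix.from_array([[5.0], [0.0]])
        w = estep(m, mix)
        np.testing.assert_array_equal(w[:, 1], 0.0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0)

    def test_rows_sum_to_one(self, rng):
        mix = mixture_1d([-3.0, 0.0, 3.0], [1.0, 0.5, 2.0],
                         [0.2, 0.5, 0.3])
        m = DataMatrix.from_array(rng.standard_normal((50, 1)) * 4)
        w = estep(m, mix)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)


class TestAnnihilatingWeightUpdate:
    def test_below_threshold_component_dies(self):
        w = np.zeros((53, 2))
        w[:50, 0] = 1.0
        w[50:, 1] = 1.0  # column sums (50, 3), N=10 -> numerators (45, 0)
        out = annihilating_weight_update(w, 10)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_symmetric_columns(self):
        w = np.zeros((60, 2))
        w[:30, 0] = 1.0
        w[30:, 1] = 1.0
        out = annihilating_weight_update(w, 10)
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_all_annihilated_raises(self):
        w = np.zeros((8, 2))
        w[:4, 0] = 1.0
        w[4:, 1] = 1.0  # column sums (4, 4), N=10
        with pytest.raises(AllComponentsAnnihilated):
            annihilating_weight_update(w, 10)

    def test_result_sums_to_one(self, rng):
        w = rng.random((100, 4))
        w /= w.sum(axis=1, keepdims=True)
        out = annihilating_weight_update(w, 4)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestMstepComponent:
    def test_indicator_weights_reduce_to_sample_mean(self):
        m = DataMatrix.from_array([[0.0, 0.0], [2.0, 0.0], [9.0, 9.0]])
        w = np.array([[1.0, 0], [1.0, 0], [0.0, 1]])
        c = mstep_component(m, w, 0, CovStructure.FULL)
        np.testing.assert_allclose(c.mean, [1.0, 0.0])

    def test_uniform_weights_give_global_centroid(self, rng):
        x = rng.standard_normal((40, 3))
        m = DataMatrix.from_array(x)
        w = np.full((40, 1), 1.0)
        c = mstep_component(m, w, 0, CovStructure.DIAGONAL)
        np.testing.assert_allclose(c.mean, x.mean(axis=0), atol=1e-12)

    def test_spherical_tag_isotropic(self, rng):
        x = rng.standard_normal((100, 2)) * np.array([3.0, 0.5])
        m = DataMatrix.from_array(x)
        w = np.full((100, 1), 1.0)
        c = mstep_component(m, w, 0, CovStructure.SPHERICAL)
        assert c.covariance[0, 0] == pytest.approx(c.covariance[1, 1])

    def test_insufficient_support_rejected(self):
        m = DataMatrix.from_array([[0.0], [1.0], [2.0]])
        w = np.array([[0.5], [0.5], [0.5]])
        with pytest.raises(ValueError, match="support"):
            mstep_component(m, w, 0, CovStructure.FULL)


class TestCem2Run:
    def test_single_gaussian_prefers_k1_by_mml(self, rng):
        x = rng.standard_normal((200, 2))
        m = DataMatrix.from_array(x)
        mix0 = MixtureModel(
            [
                GaussianComponent(0.5, x[0], np.eye(2)),
                GaussianComponent(0.5, x[1], np.eye(2)),
            ],
            CovStructure.FULL,
        )
        mix, trace, merges = cem2_run(m, mix0)
        assert mix.k_nz <= 2
        k1 = partition_to_mixture(m, np.ones(200, dtype=int),
                                  CovStructure.FULL)
        if mix.k_nz == 2:
            assert message_length(m, k1) < message_length(m, mix)

    def test_recovers_separated_components(self, rng):
        m, truth = make_blobs(
            rng, [(0, 0), (10, 0), (0, 10), (10, 10)], n_per=125, sd=1.0
        )
        centers = np.array([(0, 0), (10, 0), (0, 10), (10, 10)], dtype=float)
        comps = [
            GaussianComponent(0.25, c + 0.5, 4 * np.eye(2)) for c in centers
        ]
        mix, trace, merges = cem2_run(
            m, MixtureModel(comps, CovStructure.FULL)
        )
        assert merges == 0
        assert mix.k_nz == 4
        got = np.sort(mix.means, axis=0)
        np.testing.assert_allclose(got, np.sort(centers, axis=0), atol=0.5)

    def test_single_sweep_contract(self, rng):
        m, _ = make_blobs(rng, [(0, 0), (5, 5)], n_per=40)
        comps = [
            GaussianComponent(0.5, m.values[0], np.eye(2)),
            GaussianComponent(0.5, m.values[-1], np.eye(2)),
        ]
        _, trace, _ = cem2_run(
            m, MixtureModel(comps, CovStructure.FULL), tol=0.0, max_sweeps=1
        )
        assert len(trace.records) == 1

    def test_message_length_monotone_within_run(self):
        # ridge regularization makes each M-step slightly inexact, so the
        # per-sweep decrease holds to 1e-5 relative rather than machine
        # precision
        for seed in range(5):
            gen = np.random.default_rng(seed)
            m, _ = make_blobs(gen, [(0, 0), (6, 0), (0, 6)], n_per=60,
                              sd=0.8)
            comps = [
                GaussianComponent(0.5, m.values[0], 5 * np.eye(2)),
                GaussianComponent(0.5, m.values[-1], 5 * np.eye(2)),
            ]
            _, trace, _ = cem2_run(m, MixtureModel(comps, CovStructure.FULL))
            lengths = trace.lengths
            for a, b in zip(lengths, lengths[1:]):
                assert b <= a + 1e-5 * abs(a)

    def test_weights_sum_to_one_in_result(self, rng):
        m, _ = make_blobs(rng, [(0, 0), (8, 8)], n_per=50)
        comps = [
            GaussianComponent(0.5, m.values[0], np.eye(2)),
            GaussianComponent(0.5, m.values[-1], np.eye(2)),
        ]
        mix, _, _ = cem2_run(m, MixtureModel(comps, CovStructure.FULL))
        assert mix.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestSplitInject:
    def test_farthest_object_becomes_new_mean(self):
        m = DataMatrix.from_array([[0.0], [1.0], [9.0], [10.0], [25.0]])
        mix = mixture_1d([0.0, 10.0], [1.0, 1.0], [0.5, 0.5])
        out = split_inject(m, mix)
        assert float(out.components[-1].mean[0]) == 25.0

    def test_new_covariance_is_average(self):
        m = DataMatrix.from_array([[0.0], [1.0], [9.0], [10.0], [25.0]])
        mix = mixture_1d([0.0, 10.0], [1.0, 3.0], [0.5, 0.5])
        out = split_inject(m, mix)
        assert out.components[-1].covariance[0, 0] == pytest.approx(2.0)

    def test_k1_newcomer_gets_half_weight(self):
        m = DataMatrix.from_array([[0.0], [1.0], [5.0]])
        mix = mixture_1d([0.0], [1.0], [1.0])
        out = split_inject(m, mix)
        np.testing.assert_allclose(out.weights, [0.5, 0.5])

    def test_weights_renormalized(self):
        m = DataMatrix.from_array([[0.0], [1.0], [9.0], [10.0], [25.0]])
        mix = mixture_1d([0.0, 10.0], [1.0, 1.0], [0.7, 0.3])
        out = split_inject(m, mix)
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.weights[-1] == pytest.approx(1.0 / 3.0)

    def test_exclusion_moves_site(self):
        m = DataMatrix.from_array([[0.0], [1.0], [9.0], [10.0], [25.0]])
        mix = mixture_1d([0.0, 10.0], [1.0, 1.0], [0.5, 0.5])
        assert injection_site(m, mix) == 4
        assert injection_site(m, mix, exclude=[4]) in (1, 2)


class TestHardLabels:
    def test_labels_follow_posterior(self):
        mix = mixture_1d([0.0, 10.0], [1.0, 1.0], [0.5, 0.5])
        m = DataMatrix.from_array([[0.2], [9.8], [0.1]])
        np.testing.assert_array_equal(hard_labels(m, mix), [1, 2, 1])
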