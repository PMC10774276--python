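"""KuLSIF density-ratio estimation: solver optimality, calibration, recovery."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import selectivefd as sfd
from selectivefd.density_ratio import KulsifConfig, kulsif_objective


def quadratic_min_value(f, m):
    """Exact minimum of a black-box quadratic on R^m.

    Reconstructs the quadratic from function evaluations alone (first and
    second differences are exact for a quadratic), then solves the normal
    equations — independent of the package's closed-form solver.
    """
    J0 = f(np.zeros(m))
    E = np.eye(m)
    Jp = np.array([f(E[i]) for i in range(m)])
    Jm = np.array([f(-E[i]) for i in range(m)])
    g = (Jp - Jm) / 2
    H = np.empty((m, m))
    for i in range(m):
        H[i, i] = Jp[i] + Jm[i] - 2 * J0
        for j in range(i + 1, m):
            H[i, j] = H[j, i] = f(E[i] + E[j]) - Jp[i] - Jp[j] + J0
    alpha = np.linalg.lstsq(H, -g, rcond=None)[0]
    return 0.5 * alpha @ H @ alpha + g @ alpha + J0


class TestUniformReference:
    def test_box_containment_zero_margin(self, rng):
        X = rng.uniform(0, 1, size=(50, 2))
        sample, box = sfd.sample_uniform_reference(X, n_u=200, margin=0.0, seed=1)
        assert sample.shape == (200, 2)
        assert (sample >= box[:, 0]).all() and (sample <= box[:, 1]).all()
        assert (box[:, 0] >= X.min(axis=0)).all() and (box[:, 1] <= X.max(axis=0)).all()

    def test_zero_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sfd.sample_uniform_reference(rng.normal(size=(5, 2)), n_u=0)

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        a, _ = sfd.sample_uniform_reference(X, n_u=10, seed=42)
        b, _ = sfd.sample_uniform_reference(X, n_u=10, seed=42)
        assert np.array_equal(a, b)

    def test_degenerate_dimension_widened_with_warning(self):
        X = np.column_stack([np.zeros(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            sample, box = sfd.sample_uniform_reference(X, n_u=5, margin=0.0, seed=0)
        assert box[0, 1] > box[0, 0]


class TestMedianBandwidth:
    def test_single_pair(self):
        assert sfd.median_bandwidth(np.array([[0.0], [3.0]])) == pytest.approx(3.0)

    def test_three_point_enumeration(self):
        # pairwise distances {1, 1, 2} -> median 1
        assert sfd.median_bandwidth(np.array([[0.0], [1.0], [2.0]])) == pytest.approx(1.0)

    def test_matches_analytic_median_for_gaussian(self, rng):
        # for 2D standard normals, ||X-Y||^2 ~ 2*chi2(2); median = sqrt(2*2*ln2)
        pts = rng.normal(size=(1000, 2))
        analytic = np.sqrt(4 * np.log(2))
        assert sfd.median_bandwidth(pts, seed=0) == pytest.approx(analytic, rel=0.15)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            sfd.median_bandwidth(np.zeros((5, 2)))


class TestKulsifSolver:
    def test_matches_direct_minimization_on_small_instances(self):
        """Closed-form solve equals brute-force quadratic minimization."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_k = int(rng.integers(3, 30))
            n_u = int(rng.integers(3, 60 - n_k))
            d = int(rng.integers(1, 4))
            S_k = rng.normal(size=(n_k, d))
            S_u = rng.uniform(-2, 2, size=(n_u, d))
            beta = 10.0 ** rng.uniform(-3, -1)
            model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=beta, bandwidth=1.0))
            f_ours = kulsif_objective(model.coefficients, S_k, S_u, 1.0, beta)
            f_oracle = quadratic_min_value(
                lambda a: kulsif_objective(a, S_k, S_u, 1.0, beta), n_k + n_u
            )
            assert abs(f_ours - f_oracle) <= 1e-6 * max(abs(f_oracle), 1e-12)

    def test_identity_limit_mean_ratio_near_one(self, rng):
        S_k = rng.uniform(0, 1, size=(1000, 2))
        S_u = rng.uniform(0, 1, size=(1000, 2))
        model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-3))
        fresh = rng.uniform(0, 1, size=(2000, 2))
        assert sfd.evaluate_ratio(model, fresh).mean() == pytest.approx(1.0, abs=0.2)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            KulsifConfig(beta=0.0)

    def test_deterministic_model(self, rng):
        S_k, S_u = rng.normal(size=(30, 2)), rng.uniform(-2, 2, size=(30, 2))
        m1 = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-2))
        m2 = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-2))
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert m1.bandwidth == m2.bandwidth


class TestRatioRecovery:
    def test_gaussian_vs_uniform_pointwise(self):
        """w(0) approximates the closed-form density ratio ~3.99."""
        r = np.random.default_rng(123)
        S_k = truncnorm.rvs(-5, 5, scale=0.2, size=(5000, 1), random_state=r)
        S_u = r.uniform(-1, 1, size=(5000, 1))
        model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-3))
        truth = truncnorm.pdf(0, -5, 5, scale=0.2) / 0.5
        w0 = float(sfd.evaluate_ratio(model, [[0.0]])[0])
        assert w0 == pytest.approx(truth, rel=0.2)

    def test_far_ood_point_scores_near_zero(self, rng):
        S_k = rng.normal(size=(300, 2))
        S_u, box = sfd.sample_uniform_reference(S_k, n_u=300, seed=1)
        model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-3), box=box)
        near = sfd.evaluate_ratio(model, S_k[:1])
        far = sfd.evaluate_ratio(model, np.array([[50.0, 50.0]]))
        assert abs(far[0]) < 0.05
        assert near[0] > far[0]


class TestEvaluateRatio:
    def test_empty_input(self, rng):
        S = rng.normal(size=(10, 2))
        model = sfd.fit_kulsif(S, S + 1, KulsifConfig(beta=1e-2))
        assert sfd.evaluate_ratio(model, np.empty((0, 2))).shape == (0,)

    def test_pointwise_function_on_repeated_rows(self, rng):
        S = rng.normal(size=(10, 2))
        model = sfd.fit_kulsif(S, S + 1, KulsifConfig(beta=1e-2))
        X = np.repeat(rng.normal(size=(1, 2)), 4, axis=0)
        out = sfd.evaluate_ratio(model, X)
        assert (out == out[0]).all()

    def test_dimension_mismatch(self, rng):
        S = rng.normal(size=(10, 2))
        model = sfd.fit_kulsif(S, S + 1, KulsifConfig(beta=1e-2))
        with pytest.raises(ValueError):
            sfd.evaluate_ratio(model, rng.normal(size=(3, 5)))


class TestThresholdCalibration:
    @pytest.fixture()
    def fitted(self, rng):
        S_k = rng.normal(size=(200, 2))
        S_u, _ = sfd.sample_uniform_reference(S_k, n_u=200, seed=2)
        model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-3))
        val = rng.normal(size=(100, 2))
        return model, val

    def test_quantile_endpoints(self, fitted):
        model, val = fitted
        ratios = sfd.evaluate_ratio(model, val)
        lo = sfd.calibrate_threshold(model, val, tau_client=0.0)
        hi = sfd.calibrate_threshold(model, val, tau_client=1.0)
        assert lo.threshold_value == pytest.approx(ratios.min())
        assert hi.threshold_value == pytest.approx(ratios.max())

    def test_at_most_tau_fraction_strictly_below(self, fitted):
        model, val = fitted
        for tau in (0.1, 0.25, 0.5, 0.9):
            th = sfd.calibrate_threshold(model, val, tau_client=tau)
            ratios = sfd.evaluate_ratio(model, val)
            assert np.mean(ratios < th.threshold_value) <= tau
            # the threshold is an attained validation ratio
            assert np.isclose(ratios, th.threshold_value).any()

    def test_tau_out_of_range(self, fitted):
        model, val = fitted
        with pytest.raises(ValueError):
            sfd.calibrate_threshold(model, val, tau_client=1.5)


def test_ratio_model_serialization_roundtrip(tmp_path, rng):
    S_k = rng.normal(size=(20, 2))
    S_u, box = sfd.sample_uniform_reference(S_k, n_u=20, seed=3)
    model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-2), box=box)
    path = tmp_path / "ratio.json"
    model.to_json(str(path))
    back = sfd.RatioModel.from_json(str(path))
    X = rng.normal(size=(15, 2))
    assert np.allclose(sfd.evaluate_ratio(back, X), sfd.evaluate_ratio(model, X))
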