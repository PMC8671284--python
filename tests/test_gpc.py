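import numpy as np
import pytest

import aortuq as aq
from aortuq.gpc import basis_matrix, n_terms

PARAM = aq.UncertainParam(low=-0.15, high=-0.08, order=3)


def surrogate_of(f, param=PARAM, n_nodes=None):
    n = n_nodes or param.order + 1
    nodes, _ = aq.quadrature_nodes(param, n)
    return aq.project(f(nodes), param)


class TestQuadratureNodes:
    def test_single_node_is_midpoint(self):
        nodes, weights = aq.quadrature_nodes(PARAM, 1)
        assert nodes[0] == pytest.approx(-0.115)
        assert weights[0] == pytest.approx(1.0)

    def test_four_node_positions(self):
        nodes, _ = aq.quadrature_nodes(PARAM, 4)
        # affine image of the standard abscissae ±0.3399810, ±0.8611363
        std = np.array([-0.8611363116, -0.3399810436, 0.3399810436, 0.8611363116])
        expected = -0.115 + 0.035 * std
        np.testing.assert_allclose(sorted(nodes), sorted(expected), atol=1e-9)
        np.testing.assert_allclose(sorted(nodes),
                                   [-0.14514, -0.12690, -0.10310, -0.08486],
                                   atol=1e-5)

    @pytest.mark.parametrize("n", [1, 2, 5, 12])
    def test_weights_sum_to_one(self, n):
        _, weights = aq.quadrature_nodes(PARAM, n)
        assert weights.sum() == pytest.approx(1.0, rel=1e-13)


class TestBasis:
    def test_orthonormal_under_gauss_rule(self):
        nodes, weights = aq.quadrature_nodes(PARAM, PARAM.order + 1)
        phi = basis_matrix(PARAM, nodes)
        gram = (phi * weights[:, None]).T @ phi
        np.testing.assert_allclose(gram, np.eye(PARAM.order + 1), atol=1e-12)

    def test_term_count_tensor_formula(self):
        assert n_terms(np.array([3])) == 4
        assert n_terms(np.array([2, 3])) == 12  # mechanical multi-param form


class TestProject:
    def test_constant_goes_to_mean_coefficient(self):
        exp = surrogate_of(lambda a: np.full_like(a, 7.5))
        np.testing.assert_allclose(exp.coeffs, [7.5, 0, 0, 0], atol=1e-13)

    def test_basis_function_maps_to_unit_vector(self):
        nodes, _ = aq.quadrature_nodes(PARAM, 4)
        phi2 = basis_matrix(PARAM, nodes)[:, 2]
        exp = aq.project(phi2, PARAM)
        np.testing.assert_allclose(exp.coeffs, [0, 0, 1, 0], atol=1e-12)

    def test_cubic_reproduced_exactly(self):
        exp = surrogate_of(lambda a: a ** 3)
        rng = np.random.default_rng(1)
        pts = rng.uniform(PARAM.low, PARAM.high, 100)
        np.testing.assert_allclose(aq.evaluate(exp, pts), pts ** 3, atol=1e-15)

    def test_insufficient_nodes_rejected(self):
        nodes, _ = aq.quadrature_nodes(PARAM, 2)
        with pytest.raises(ValueError, match="nodes"):
            aq.project(nodes ** 2, PARAM)

    def test_waveform_outputs_projected_per_sample(self):
        nodes, _ = aq.quadrature_nodes(PARAM, 4)
        evals = np.stack([np.array([a, a ** 2, 1.0]) for a in nodes])
        exp = aq.project(evals, PARAM)
        assert exp.coeffs.shape == (4, 3)
        mean, std = aq.moments(exp)
        assert mean[2] == pytest.approx(1.0) and std[2] == pytest.approx(0.0, abs=1e-13)


class TestLeastSquaresProjection:
    def test_hand_picked_nodes_interpolate_polynomials(self):
        nodes = np.array([-0.15, -0.13, -0.10, -0.08])  # rounded study values
        exp = aq.project_lstsq(nodes ** 2, PARAM, nodes)
        pts = np.linspace(PARAM.low, PARAM.high, 50)
        np.testing.assert_allclose(aq.evaluate(exp, pts), pts ** 2, atol=1e-10)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            aq.project_lstsq(np.zeros(3), PARAM, np.array([-0.14, -0.11, -0.09]))


class TestEvaluate:
    def test_outside_support_warns(self):
        exp = surrogate_of(lambda a: a)
        with pytest.warns(UserWarning, match="outside"):
            aq.evaluate(exp, 0.0)

    def test_interpolates_at_nodes(self):
        nodes, _ = aq.quadrature_nodes(PARAM, 4)
        f = nodes ** 3 - 2 * nodes
        exp = aq.project(f, PARAM)
        np.testing.assert_allclose(aq.evaluate(exp, nodes), f, atol=1e-14)


class TestMoments:
    def test_constant_has_zero_std(self):
        _, std = aq.moments(surrogate_of(lambda a: np.full_like(a, 3.0)))
        assert std == pytest.approx(0.0, abs=1e-13)

    def test_identity_closed_form(self):
        a, b = PARAM.low, PARAM.high
        mean, std = aq.moments(surrogate_of(lambda x: x))
        assert mean == pytest.approx((a + b) / 2, rel=1e-12)
        assert std == pytest.approx((b - a) / np.sqrt(12), rel=1e-12)

    def test_square_closed_form(self):
        a, b = PARAM.low, PARAM.high
        mean, std = aq.moments(surrogate_of(lambda x: x ** 2))
        m_exact = (b ** 3 - a ** 3) / (3 * (b - a))
        v_exact = (b ** 5 - a ** 5) / (5 * (b - a)) - m_exact ** 2
        assert mean == pytest.approx(m_exact, rel=1e-12)
        assert std == pytest.approx(np.sqrt(v_exact), rel=1e-12)

    @pytest.mark.parametrize("f", [lambda x: x, lambda x: x ** 2, np.exp],
                             ids=["identity", "square", "exp"])
    def test_monte_carlo_oracle_agreement(self, f):
        """Surrogate moments match 10⁶-draw Monte Carlo within 3 SE."""
        mean, std = aq.moments(surrogate_of(f))
        rng = np.random.default_rng(12345)
        n = 10 ** 6
        samples = f(rng.uniform(PARAM.low, PARAM.high, n))
        se_mean = samples.std(ddof=1) / np.sqrt(n)
        assert abs(mean - samples.mean()) < 3 * se_mean
        # SE of the sample SD via the estimated kurtosis
        m2 = samples.var(ddof=1)
        m4 = np.mean((samples - samples.mean()) ** 4)
        se_sd = np.sqrt(max(m4 - m2 ** 2, 0) / n) / (2 * np.sqrt(m2))
        assert abs(std - samples.std(ddof=1)) < 3 * se_sd


class TestPdf:
    def test_identity_map_density_is_uniform(self):
        exp = surrogate_of(lambda a: a)
        edges, dens = aq.pdf(exp, n_samples=200_000, seed=1, bins=20)
        width = PARAM.high - PARAM.low
        inner = dens[2:-2]
        np.testing.assert_allclose(inner, 1.0 / width, rtol=0.05)

    def test_density_integrates_to_one(self):
        exp = surrogate_of(np.exp)
        edges, dens = aq.pdf(exp, n_samples=50_000, seed=2, bins=40)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, rel=1e-9)

    def test_constant_surrogate_single_bin(self):
        exp = aq.GPCExpansion(coeffs=np.array([5.0, 0.0, 0.0, 0.0]), param=PARAM)
        edges, dens = aq.pdf(exp, n_samples=2000, seed=3, bins=10)
        occupied = dens > 0
        assert occupied.sum() == 1
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        exp = surrogate_of(np.exp)
        e1, d1 = aq.pdf(exp, n_samples=5000, seed=7)
        e2, d2 = aq.pdf(exp, n_samples=5000, seed=7)
        np.testing.assert_array_equal(d1, d2)

    def test_minimum_sample_count(self):
        with pytest.raises(ValueError):
            aq.pdf(surrogate_of(np.exp), n_samples=10)


class TestConvergenceCheck:
    def test_constant_is_converged(self):
        assert aq.convergence_check(surrogate_of(
            lambda a: np.full_like(a, 2.0))) < 1e-14

    def test_pure_top_mode_is_one(self):
        nodes, _ = aq.quadrature_nodes(PARAM, 4)
        top = basis_matrix(PARAM, nodes)[:, -1]
        assert aq.convergence_check(aq.project(top, PARAM)) == pytest.approx(1.0)

    def test_smooth_function_decays_fast(self):
        # on a narrow interval the Legendre coefficients of exp collapse
        assert aq.convergence_check(surrogate_of(np.exp)) < 1e-4
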