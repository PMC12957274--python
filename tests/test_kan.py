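"""KAN core: B-spline bases, edge activations, layers, stacks, fitting."""

import numpy as np
import pytest

from kansleep.kan import (
    EdgeFunction,
    KANLayer,
    KANStack,
    SplineGrid,
    bspline_basis,
    edge_eval,
    fit_kan,
    kan_forward,
    kan_layer_forward,
    load_kan,
    save_kan,
    silu,
    spline_eval,
)


class TestSilu:
    @pytest.mark.parametrize("x, expected", [
        (0.0, 0.0),
        (1.0, 0.731059),
        (30.0, 30.0),
    ])
    def test_values(self, x, expected):
        assert silu(x) == pytest.approx(expected, abs=1e-6)

    def test_saturation(self):
        assert abs(silu(30.0) - 30.0) < 1e-9


class TestBasis:
    def test_order0_is_indicator(self):
        g = SplineGrid(0.0, 1.0, 4, 0)
        b = bspline_basis(0.3, g)
        assert b.shape == (4,)
        assert b.sum() == 1.0
        assert b[1] == 1.0  # 0.3 lies in [0.25, 0.5)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_partition_of_unity(self, k, rng):
        g = SplineGrid(-1.0, 1.0, 5, k)
        x = rng.uniform(-0.999, 0.999, 1000)
        np.testing.assert_allclose(bspline_basis(x, g).sum(axis=-1), 1.0, atol=1e-9)

    def test_hat_functions_hand_values(self):
        # G=2, k=1 on [0,1]: hats centered at 0, 0.5, 1 on extended knots
        g = SplineGrid(0.0, 1.0, 2, 1)
        np.testing.assert_allclose(bspline_basis(0.25, g), [0.5, 0.5, 0.0],
                                   atol=1e-12)

    def test_nonnegative_inside_domain(self, rng):
        g = SplineGrid()
        assert (bspline_basis(rng.uniform(-1, 1, 500), g) >= 0).all()

    def test_derivative_matches_finite_difference(self, rng):
        g = SplineGrid()
        x = rng.uniform(-0.9, 0.9, 50)
        _, d = bspline_basis(x, g, deriv=True)
        eps = 1e-6
        fd = (bspline_basis(x + eps, g) - bspline_basis(x - eps, g)) / (2 * eps)
        np.testing.assert_allclose(d, fd, atol=1e-5)


class TestSplineAndEdge:
    def test_unit_coefficients_partition(self, rng):
        g = SplineGrid()
        edge = EdgeFunction(c=np.ones(g.n_basis), grid=g)
        for x in rng.uniform(-0.99, 0.99, 20):
            assert spline_eval(x, edge) == pytest.approx(1.0, abs=1e-9)

    def test_zero_coefficients(self):
        edge = EdgeFunction(c=np.zeros(SplineGrid().n_basis))
        assert spline_eval(0.37, edge) == 0.0

    def test_linear_reproduction_at_greville(self):
        g = SplineGrid(-1.0, 1.0, 5, 3)
        edge = EdgeFunction(c=g.greville, grid=g)
        x = np.linspace(-0.99, 0.99, 101)
        np.testing.assert_allclose(spline_eval(x, edge), x, atol=1e-6)

    def test_edge_reduces_to_silu(self, rng):
        g = SplineGrid()
        edge = EdgeFunction(w_b=1.0, w_s=0.0, c=rng.standard_normal(g.n_basis),
                            grid=g)
        x = rng.uniform(-2, 2, 20)
        np.testing.assert_allclose(edge_eval(x, edge), silu(x), atol=1e-12)

    def test_edge_constant_spline_part(self):
        g = SplineGrid()
        edge = EdgeFunction(w_b=0.0, w_s=3.5, c=np.ones(g.n_basis), grid=g)
        assert edge_eval(0.1, edge) == pytest.approx(3.5, abs=1e-9)

    def test_edge_composition_value(self):
        g = SplineGrid()
        edge = EdgeFunction(w_b=2.0, w_s=3.0, c=np.ones(g.n_basis), grid=g)
        assert edge_eval(1.0, edge) == pytest.approx(2 * 0.731059 + 3, abs=1e-5)

    def test_wrong_coefficient_count_rejected(self):
        with pytest.raises(ValueError):
            EdgeFunction(c=np.ones(3), grid=SplineGrid())


class TestLayerAndStack:
    def test_two_to_one_silu_reduction(self):
        layer = KANLayer(2, 1)
        layer.wb[...] = 1.0
        layer.ws[...] = 0.0
        x = np.array([0.3, -0.7])
        out = kan_layer_forward(x, layer)
        assert out[0] == pytest.approx(silu(0.3) + silu(-0.7), abs=1e-12)

    def test_single_edge_layer(self, rng):
        layer = KANLayer(1, 1, rng=rng)
        x = 0.42
        expected = edge_eval(x, layer.edge(0, 0))
        assert kan_layer_forward(np.array([x]), layer)[0] == pytest.approx(
            expected, abs=1e-9)

    def test_layer_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n_in = int(rng.integers(1, 7))
            n_out = int(rng.integers(1, 7))
            layer = KANLayer(n_in, n_out, rng=rng)
            layer.wb[...] = rng.standard_normal((n_out, n_in))
            layer.ws[...] = rng.standard_normal((n_out, n_in))
            x = rng.uniform(-1.5, 1.5, n_in)
            out = kan_layer_forward(x, layer)
            expected = np.array([
                sum(edge_eval(x[i], layer.edge(j, i)) for i in range(n_in))
                for j in range(n_out)
            ])
            np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_single_layer_stack_equals_layer(self, rng):
        stack = KANStack([3, 2], seed=4)
        x = rng.uniform(-1, 1, 3)
        np.testing.assert_allclose(kan_forward(x, stack),
                                   kan_layer_forward(x, stack.layers[0]),
                                   atol=1e-12)

    def test_default_width_plan_ten_channels(self):
        stack = KANStack([10 * 256, 128, 64], seed=0)
        out = kan_forward(np.zeros(2560), stack)
        assert out.shape == (64,)

    def test_width_chain_violation_rejected(self):
        stack = KANStack([3, 4], seed=0)
        with pytest.raises(ValueError):
            stack.forward(np.zeros((1, 5)))

    def test_gradients_match_finite_differences(self, rng):
        stack = KANStack([3, 4, 2], seed=1)
        x = rng.uniform(-0.9, 0.9, (5, 3))
        y = rng.standard_normal((5, 2))

        def loss():
            return float(np.mean((stack.forward(x) - y) ** 2))

        resid = stack.forward(x) - y
        stack.zero_grad()
        stack.backward(2 * resid / resid.size)
        for _, p, g in stack.params():
            flat, gflat = p.reshape(-1), g.reshape(-1)
            for k in rng.choice(p.size, size=min(p.size, 6), replace=False):
                eps, old = 1e-6, flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - gflat[k]) < 1e-4 * max(1.0, abs(fd))


class TestFitting:
    def test_zero_budget_is_noop(self, rng):
        stack = KANStack([2, 3, 1], seed=2)
        before = [p.copy() for _, p, _ in stack.params()]
        fit_kan(stack, rng.uniform(-1, 1, (10, 2)), rng.standard_normal(10),
                budget=0)
        for (_, p, _), b in zip(stack.params(), before):
            np.testing.assert_array_equal(p, b)

    def test_constant_target(self, rng):
        stack = KANStack([1, 4, 1], seed=3)
        x = rng.uniform(-1, 1, (50, 1))
        trace = fit_kan(stack, x, np.full(50, 2.5), budget=400, lr=2e-2)
        assert trace[-1] < 1e-3

    def test_loss_trace_decreases_smoothed(self, rng):
        stack = KANStack([1, 6, 1], seed=5)
        x = rng.uniform(-1, 1, (100, 1))
        trace = fit_kan(stack, x, np.sin(2 * x[:, 0]), budget=600, lr=2e-2)
        assert np.mean(trace[-50:]) < np.mean(trace[:50])

    def test_fit_determinism(self, rng):
        x = rng.uniform(-1, 1, (30, 1))
        y = x[:, 0] ** 2
        traces = []
        for _ in range(2):
            stack = KANStack([1, 4, 1], seed=6)
            traces.append(fit_kan(stack, x, y, budget=50, seed=11))
        assert traces[0] == traces[1]


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        stack = KANStack([2, 3, 1], seed=8)
        fit_kan(stack, rng.uniform(-1, 1, (20, 2)), rng.standard_normal(20),
                budget=20)
        path = tmp_path / "kan.npz"
        save_kan(stack, path)
        back = load_kan(path)
        x = rng.uniform(-1, 1, (5, 2))
        np.testing.assert_array_equal(stack.forward(x), back.forward(x))
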