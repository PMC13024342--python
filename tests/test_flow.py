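"""Rectified-flow primitives, Euler integration, and training recovery."""

import numpy as np
import pytest

from neuroflow import nn
from neuroflow.flow import (
    FlowTrainConfig,
    VelocityNet,
    VelocityNetConfig,
    euler_sample,
    flow_matching_loss,
    generate_for_table,
    interpolate_state,
    train_flow,
)


class _ConstantField:
    """Stub velocity model returning a fixed vector."""

    def __init__(self, v):
        self.v = np.asarray(v, dtype=np.float64)

    def eval(self):
        return self

    def velocity(self, x, t, c):
        return np.tile(self.v, (np.atleast_2d(x).shape[0], 1))


class _LinearField:
    """v(x, t) = x, whose exact flow is x0 * e at t = 1."""

    def eval(self):
        return self

    def velocity(self, x, t, c):
        return np.atleast_2d(x)


class TestInterpolation:
    def test_endpoints(self):
        x0, x1 = np.array([1.0, 2.0]), np.array([5.0, -2.0])
        np.testing.assert_array_equal(interpolate_state(x0, x1, 0.0), x0)
        np.testing.assert_array_equal(interpolate_state(x0, x1, 1.0), x1)

    def test_midpoint(self):
        np.testing.assert_array_equal(
            interpolate_state(np.zeros(2), np.array([2.0, 4.0]), 0.5), [1.0, 2.0]
        )

    def test_linearity_identity(self):
        rng = np.random.default_rng(0)
        x0, x1 = rng.normal(size=4), rng.normal(size=4)
        for t in (0.2, 0.5, 0.9):
            np.testing.assert_allclose(
                interpolate_state(x0, x1, t) - x0, t * (x1 - x0), atol=1e-15
            )

    @pytest.mark.parametrize("t", [-0.1, 1.1])
    def test_time_outside_unit_interval_rejected(self, t):
        with pytest.raises(ValueError):
            interpolate_state(np.zeros(2), np.ones(2), t)


class TestFlowMatchingLoss:
    def test_zero_at_optimum(self):
        rng = np.random.default_rng(1)
        x0, x1 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert flow_matching_loss(x1 - x0, x0, x1) == 0.0

    def test_dimension_normalized_offset(self):
        x0 = np.zeros((1, 2))
        x1 = np.zeros((1, 2))
        v = np.array([[2.0, 0.0]])
        assert flow_matching_loss(v, x0, x1) == pytest.approx(2.0)  # 4 / 2

    def test_tensor_input_matches_array_input(self):
        rng = np.random.default_rng(2)
        v, x0, x1 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert flow_matching_loss(nn.Tensor(v), x0, x1).item() == pytest.approx(
            flow_matching_loss(v, x0, x1)
        )


class TestEulerSampler:
    @pytest.mark.parametrize("n_steps", [1, 3, 10, 57])
    def test_constant_field_is_exact_for_any_step_count(self, n_steps):
        x0 = np.array([1.0, -1.0])
        x1 = np.array([4.0, 7.0])
        model = _ConstantField(x1 - x0)
        out = euler_sample(model, c=np.zeros(2), x0=x0, n_steps=n_steps)
        np.testing.assert_allclose(out, x1, atol=1e-12)

    def test_zero_field_returns_start(self):
        out = euler_sample(_ConstantField([0.0, 0.0]), np.zeros(2), np.array([3.0, 5.0]), 10)
        np.testing.assert_array_equal(out, [3.0, 5.0])

    def test_linear_ode_matches_euler_error_bound(self):
        # dx/dt = x  =>  Euler gives x0 (1 + 1/N)^N, exact flow gives x0 e
        x0 = np.array([1.0])
        out10 = euler_sample(_LinearField(), np.zeros(1), x0, 10)
        out1000 = euler_sample(_LinearField(), np.zeros(1), x0, 1000)
        exact = np.e
        assert abs(out10[0] - (1 + 1 / 10) ** 10) < 1e-12
        assert abs(out1000[0] - exact) < abs(out10[0] - exact)
        assert abs(out10[0] - exact) == pytest.approx(exact - (1.1) ** 10, abs=1e-12)

    def test_invalid_step_count_rejected(self):
        with pytest.raises(ValueError):
            euler_sample(_ConstantField([0.0]), np.zeros(1), np.zeros(1), 0)


class TestTraining:
    def test_single_triple_overfits_below_tolerance(self):
        rng = np.random.default_rng(3)
        cfg = VelocityNetConfig(state_dim=4, cond_dim=4, hidden=32, n_res_blocks=1)
        net = VelocityNet(cfg, seed=0)
        opt = nn.Adam(net.parameters(), lr=1e-3)
        x0 = rng.normal(size=(1, 4))
        x1 = rng.normal(size=(1, 4))
        c = rng.normal(size=(1, 4))
        loss_val = np.inf
        for step in range(2000):
            t = rng.uniform(0, 1, 1)
            xt = t[:, None] * x1 + (1 - t[:, None]) * x0
            net.train()
            v = net(nn.Tensor(xt), t, nn.Tensor(c))
            loss = flow_matching_loss(v, x0, x1)
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_val = loss.item()
            if loss_val < 1e-3:
                break
        assert loss_val < 1e-3

    def test_point_mass_target_recovery(self):
        # fixed condition, single target point: samples land on the point
        target = np.array([[1.5, -0.5]])
        cond = np.array([[0.3, 0.7]])
        model = train_flow(
            np.tile(cond, (20, 1)), np.array(["AD"] * 20),
            np.tile(target, (20, 1)), np.array(["AD"] * 20),
            cfg=FlowTrainConfig(epochs=400, batch_size=16, seed=0),
        )
        gen = generate_for_table(model, np.tile(cond, (50, 1)), seed=1)
        dists = np.linalg.norm(gen - target, axis=1)
        assert dists.mean() < 0.05

    def test_loss_trend_decreases(self, small_cohort):
        from neuroflow.alignment import AlignmentConfig, encode, train_alignment

        sp, ee = small_cohort.speech_features, small_cohort.eeg_features
        model, _ = train_alignment(sp, ee, AlignmentConfig(epochs=20, seed=1))
        zs = encode(model, sp, "speech")
        ze = encode(model, ee, "eeg")
        fm = train_flow(
            zs, sp["label"].to_numpy(), ze, ee["label"].to_numpy(),
            cfg=FlowTrainConfig(epochs=50, seed=1),
        )
        h = np.array(fm.history)
        decile = max(len(h) // 10, 1)
        assert h[:decile].mean() > h[-decile:].mean()

    def test_no_common_classes_rejected(self):
        with pytest.raises(ValueError):
            train_flow(
                np.zeros((3, 2)), np.array(["MCI"] * 3),
                np.zeros((3, 2)), np.array(["AD", "HC", "AD"]),
            )


class TestGeneration:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        rng = np.random.default_rng(0)
        return train_flow(
            rng.normal(size=(12, 3)), np.array(["AD", "HC"] * 6),
            rng.normal(size=(12, 3)), np.array(["AD", "HC"] * 6),
            cfg=FlowTrainConfig(epochs=3, seed=0),
        )

    def test_one_row_per_condition_with_state_width(self, tiny_model):
        rng = np.random.default_rng(1)
        out = generate_for_table(tiny_model, rng.normal(size=(7, 3)), seed=2)
        assert out.shape == (7, 3)

    def test_same_seed_reproduces_output(self, tiny_model):
        rng = np.random.default_rng(2)
        cond = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(
            generate_for_table(tiny_model, cond, seed=3),
            generate_for_table(tiny_model, cond, seed=3),
        )

    def test_default_step_count_is_ten(self, tiny_model):
        assert tiny_model.cfg.n_steps == 10

    def test_condition_width_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            generate_for_table(tiny_model, np.zeros((2, 5)), seed=0)
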