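"""Alignment losses, gradient reversal, batch loading, and training."""

import numpy as np
import pytest

from neuroflow import nn
from neuroflow.alignment import (
    AlignmentConfig,
    center_loss,
    consistency_loss,
    encode,
    grl_schedule,
    paired_batches,
    pseudo_mci,
    total_loss,
    train_alignment,
    weighted_cross_entropy,
)


class TestGRL:
    def test_forward_is_identity(self):
        x = nn.Tensor(np.array([[1.0, -2.0, 3.0]]), requires_grad=True)
        np.testing.assert_array_equal(nn.grad_reverse(x, 0.3).data, x.data)

    def test_backward_negates_and_scales_gradient(self):
        x = nn.Tensor(np.array([2.0]), requires_grad=True)
        # f(y) = y^2 so f'(x) = 2x = 4; through GRL: -lambda * 4
        (nn.grad_reverse(x, 0.25) ** 2).sum().backward()
        assert x.grad[0] == pytest.approx(-0.25 * 4.0)

    def test_schedule_ramps_from_zero_to_ceiling(self):
        cfg = AlignmentConfig()
        assert grl_schedule(0, 200, cfg) == 0.0
        assert grl_schedule(199, 200, cfg) == pytest.approx(0.1)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            nn.grad_reverse(nn.Tensor(np.zeros(2)), -1.0)


class TestWeightedCrossEntropy:
    def test_balanced_classes_equal_unweighted(self):
        rng = np.random.default_rng(0)
        logits = nn.Tensor(rng.normal(size=(6, 3)))
        labels = np.array(["AD", "HC", "MCI"] * 2)
        props = {"AD": 1 / 3, "HC": 1 / 3, "MCI": 1 / 3}
        weighted = weighted_cross_entropy(logits, labels, props).item()
        unweighted = nn.softmax_cross_entropy(
            logits, np.array([0, 1, 2, 0, 1, 2])
        ).item()
        assert weighted == pytest.approx(unweighted, rel=1e-12)

    def test_confident_correct_predictions_give_near_zero(self):
        logits = nn.Tensor(np.eye(3) * 100.0)
        labels = np.array(["AD", "HC", "MCI"])
        props = {"AD": 0.5, "HC": 0.25, "MCI": 0.25}
        assert weighted_cross_entropy(logits, labels, props).item() < 1e-10

    def test_two_class_hand_computation(self):
        # proportions AD 0.25 / HC 0.75 -> weights 4 and 4/3
        logits_arr = np.array([[2.0, -1.0, -50.0], [0.5, 1.5, -50.0]])
        labels = np.array(["AD", "HC"])
        props = {"AD": 0.25, "HC": 0.75, "MCI": 0.0}
        p = np.exp(logits_arr - logits_arr.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        nll = -np.log([p[0, 0], p[1, 1]])
        expected = (4 * nll[0] + (4 / 3) * nll[1]) / (4 + 4 / 3)
        got = weighted_cross_entropy(nn.Tensor(logits_arr), labels, props).item()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_proportion_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(
                nn.Tensor(np.zeros((1, 3))), np.array(["MCI"]),
                {"AD": 0.5, "HC": 0.5, "MCI": 0.0},
            )


class TestCenterLoss:
    def test_zero_when_features_at_centers(self):
        centers = nn.Tensor(np.array([[1.0, 0], [0, 1.0], [2.0, 2.0]]))
        z = nn.Tensor(np.array([[1.0, 0], [2.0, 2.0]]))
        labels = np.array(["AD", "MCI"])
        assert center_loss(z, labels, centers).item() < 1e-5

    def test_single_sample_returns_its_distance(self):
        centers = nn.Tensor(np.zeros((3, 2)))
        z = nn.Tensor(np.array([[3.0, 4.0]]))  # distance 5
        assert center_loss(z, np.array(["AD"]), centers).item() == pytest.approx(5.0)

    def test_mean_of_distances(self):
        centers = nn.Tensor(np.zeros((3, 1)))
        z = nn.Tensor(np.array([[1.0], [2.0], [3.0]]))
        labels = np.array(["AD", "HC", "MCI"])
        assert center_loss(z, labels, centers).item() == pytest.approx(2.0, abs=1e-6)

    def test_moving_toward_center_decreases_loss(self):
        centers = nn.Tensor(np.zeros((3, 2)))
        far = center_loss(nn.Tensor(np.array([[4.0, 0]])), np.array(["AD"]), centers)
        near = center_loss(nn.Tensor(np.array([[1.0, 0]])), np.array(["AD"]), centers)
        assert near.item() < far.item()


class TestConsistencyLoss:
    def test_identical_class_means_give_zero(self):
        z = nn.Tensor(np.array([[1.0, 2.0], [3.0, 0.0]]))
        y = np.array(["AD", "HC"])
        loss, skipped = consistency_loss(z, y, z, y)
        assert loss.item() == 0.0 and not skipped

    def test_hand_computed_single_class(self):
        zs = nn.Tensor(np.array([[1.0, 0.0]]))
        ze = nn.Tensor(np.array([[0.0, 0.0]]))
        loss, _ = consistency_loss(zs, np.array(["AD"]), ze, np.array(["AD"]))
        assert loss.item() == pytest.approx(0.5)  # mean of (1, 0) squared

    def test_empty_eeg_batch_skips(self):
        zs = nn.Tensor(np.ones((2, 3)))
        ze = nn.Tensor(np.ones((0, 3)))
        loss, skipped = consistency_loss(
            zs, np.array(["AD", "HC"]), ze, np.array([])
        )
        assert loss.item() == 0.0 and skipped

    def test_mci_never_contributes(self):
        zs = nn.Tensor(np.array([[5.0, 5.0]]))
        ze = nn.Tensor(np.array([[0.0, 0.0]]))
        loss, skipped = consistency_loss(
            zs, np.array(["MCI"]), ze, np.array(["MCI"])
        )
        assert loss.item() == 0.0 and skipped


class TestPseudoMCI:
    def test_midpoint(self):
        z = pseudo_mci(np.array([2.0, 0.0]), np.array([0.0, 2.0]), 0.5)
        np.testing.assert_array_equal(z, [1.0, 1.0])

    def test_near_endpoint_approaches_ad(self):
        z_ad, z_hc = np.array([1.0, 1.0]), np.array([-1.0, -1.0])
        z = pseudo_mci(z_ad, z_hc, 1 - 1e-9)
        np.testing.assert_allclose(z, z_ad, atol=1e-8)

    def test_samples_stay_in_convex_hull(self):
        rng = np.random.default_rng(0)
        z_ad, z_hc = rng.normal(size=5), rng.normal(size=5)
        lo, hi = np.minimum(z_ad, z_hc), np.maximum(z_ad, z_hc)
        for alpha in rng.beta(2, 2, 1000):
            z = pseudo_mci(z_ad, z_hc, float(np.clip(alpha, 1e-9, 1 - 1e-9)))
            assert np.all(z >= lo - 1e-12) and np.all(z <= hi + 1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.5, 2.0])
    def test_alpha_outside_open_interval_rejected(self, alpha):
        with pytest.raises(ValueError):
            pseudo_mci(np.zeros(2), np.ones(2), alpha)


class TestTotalLoss:
    def test_unit_components_with_default_weights(self):
        cfg = AlignmentConfig()
        parts = [nn.Tensor(1.0)] * 4
        assert total_loss(*parts, cfg).item() == pytest.approx(6.15)

    def test_zero_components(self):
        cfg = AlignmentConfig()
        assert total_loss(*([nn.Tensor(0.0)] * 4), cfg).item() == 0.0

    def test_mixed_components(self):
        cfg = AlignmentConfig()
        parts = [nn.Tensor(v) for v in (2.0, 0.0, 0.0, 1.0)]
        assert total_loss(*parts, cfg).item() == pytest.approx(7.0)


class TestPairedBatches:
    def test_speech_partition_covers_every_row_once(self):
        rng = np.random.default_rng(0)
        seen = []
        batches = list(paired_batches(280, 52, 64, rng))
        assert len(batches) == 5  # ceil(280/64), last one short
        for sb, _ in batches:
            seen.extend(sb)
        assert sorted(seen) == list(range(280))

    def test_eeg_iterator_resets_and_starves_no_row(self):
        rng = np.random.default_rng(1)
        eeg_seen = []
        for _, eb in paired_batches(280, 52, 64, rng):
            eeg_seen.extend(eb)
        counts = np.bincount(eeg_seen, minlength=52)
        assert counts.min() >= 1  # every EEG row used at least once
        assert len(eeg_seen) > 52 * 4  # reset at least 4 times mid-epoch

    def test_same_seed_gives_identical_sequence(self):
        a = [(s.tolist(), e.tolist()) for s, e in
             paired_batches(100, 20, 16, np.random.default_rng(5))]
        b = [(s.tolist(), e.tolist()) for s, e in
             paired_batches(100, 20, 16, np.random.default_rng(5))]
        assert a == b


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self, small_cohort):
        cfg = AlignmentConfig(epochs=40, seed=0)
        model, history = train_alignment(
            small_cohort.speech_features, small_cohort.eeg_features, cfg
        )
        return model, history, cfg

    def test_loss_identity_holds_every_epoch(self, trained):
        _, history, cfg = trained
        for rep in history:
            expected = (
                rep.cls
                + cfg.lambda_center * rep.center
                + cfg.lambda_domain * rep.domain
                + cfg.lambda_consist * rep.consist
            )
            assert rep.total == pytest.approx(expected, abs=1e-6)

    def test_encode_outputs_subspace_width(self, trained, small_cohort):
        model, _, _ = trained
        z = encode(model, small_cohort.speech_features, "speech")
        assert z.shape == (len(small_cohort.speech_features), 128)
        np.testing.assert_array_equal(
            z, encode(model, small_cohort.speech_features, "speech")
        )

    def test_encoders_are_independent(self, trained, small_cohort):
        model, _, _ = trained
        before = encode(model, small_cohort.eeg_features, "eeg")
        model.speech_encoder.fc1.weight.data += 10.0
        after = encode(model, small_cohort.eeg_features, "eeg")
        model.speech_encoder.fc1.weight.data -= 10.0
        np.testing.assert_array_equal(before, after)

    def test_training_brings_cross_modal_class_centers_together(self, small_cohort):
        from neuroflow.alignment import AlignmentModel

        cfg = AlignmentConfig(epochs=40, seed=3)
        sp, ee = small_cohort.speech_features, small_cohort.eeg_features

        def center_gap(model):
            zs = encode(model, sp, "speech")
            ze = encode(model, ee, "eeg")
            gaps = []
            for c in ("AD", "HC"):
                ms = zs[sp["label"].to_numpy() == c].mean(axis=0)
                me = ze[ee["label"].to_numpy() == c].mean(axis=0)
                gaps.append(np.linalg.norm(ms - me))
            return np.mean(gaps)

        init = AlignmentModel(
            sp.shape[1] - 1, ee.shape[1] - 1, cfg
        )
        gap_before = center_gap(init)
        trained_model, _ = train_alignment(sp, ee, cfg)
        assert center_gap(trained_model) < gap_before

    def test_missing_speech_class_rejected(self, small_cohort):
        sp = small_cohort.speech_features.query("label != 'MCI'")
        with pytest.raises(ValueError):
            train_alignment(sp, small_cohort.eeg_features, AlignmentConfig(epochs=1))

    def test_mci_in_eeg_rejected(self, small_cohort):
        ee = small_cohort.eeg_features.copy()
        ee.loc[ee.index[0], "label"] = "MCI"
        with pytest.raises(ValueError):
            train_alignment(small_cohort.speech_features, ee, AlignmentConfig(epochs=1))
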