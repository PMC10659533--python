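import numpy as np
import pytest

from neuroprog.errors import ConfigurationError, DataError, NeuroprogError
from neuroprog.multitask_cnn import (
    ArchConfig, DeepDataset, LossWeights, TrainingSchedule, build_network,
    combine_losses, grid_search_weights, multitask_loss, train_deep,
)
from neuroprog.nn import Conv3d, Dense


def _toy_dataset(n=12, grid=8, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(float)
    jd = np.ones((n, 1, grid, grid, grid))
    if signal:
        for i in range(n):
            if y[i] == 1:
                jd[i, 0, 2:5, 2:5, 2:5] = 0.4
    return DeepDataset(
        clinical=rng.random((n, 4)),
        y_progression=y,
        y_slope=rng.random(n),
        y_hippocampus=rng.random(n),
        mri=rng.normal(0, 0.1, (n, 1, grid, grid, grid)),
        jd=jd,
        subject_ids=[f"s{i}" for i in range(n)],
    )


def _arch(grid=8, **kw):
    return ArchConfig(grid_shape=(grid, grid, grid), n_clinical=4,
                      channels=(4, 8, 8), hidden=8, **kw)


class TestGradients:
    def test_conv_backward_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 4, 6, 6, 6))
        for kwargs in (dict(kernel=3, stride=2, padding=1),
                       dict(kernel=3, stride=2, padding=1, groups=4),
                       dict(kernel=1,)):
            cout = 4 if kwargs.get("groups") else 6
            make = lambda: Conv3d(4, cout, rng=np.random.default_rng(5), **kwargs)
            layer = make()
            out = layer.forward(x, train=True)
            R = np.random.default_rng(2).normal(size=out.shape)
            dx = layer.backward(R)
            eps = 1e-5
            for trial in range(4):
                ii = tuple(np.random.default_rng(trial).integers(0, s) for s in x.shape)
                xp, xm = x.copy(), x.copy()
                xp[ii] += eps
                xm[ii] -= eps
                num = (np.sum(make().forward(xp, train=False) * R)
                       - np.sum(make().forward(xm, train=False) * R)) / (2 * eps)
                assert dx[ii] == pytest.approx(num, abs=1e-6)


class TestLoss:
    def test_weighted_sum_arithmetic(self):
        # 1*0.7 + 0.025*2.0 + 0.025*1.2 = 0.78
        assert combine_losses(0.7, 2.0, 1.2, LossWeights(1, 0.025, 0.025)) \
            == pytest.approx(0.78)

    def test_single_task_reduction(self):
        assert combine_losses(0.7, 2.0, 1.2, LossWeights(1, 0, 0)) == 0.7

    def test_linearity_in_each_weight(self):
        l = (0.9, 1.7, 0.3)
        for i in range(3):
            w = [0.5, 0.5, 0.5]
            base = combine_losses(*l, LossWeights(*w))
            w[i] += 0.25
            bumped = combine_losses(*l, LossWeights(*w))
            assert bumped - base == pytest.approx(0.25 * l[i])

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_losses(1.0, 1.0, 1.0, LossWeights(-0.1, 1, 1))

    def test_perfect_regression_predictions_zero_out_l2_l3(self):
        data = _toy_dataset()
        net = build_network(_arch())
        out = net.predict(data)
        out.mmse_slope_hat = data.y_slope.copy()
        out.hippocampal_volume_hat = data.y_hippocampus.copy()
        w = LossWeights(1, 0.025, 0.025)
        full = multitask_loss(out, data, w)
        l1_only = multitask_loss(out, data, LossWeights(1, 0, 0))
        assert full == pytest.approx(l1_only)


class TestNetwork:
    def test_outputs_in_open_interval(self):
        data = _toy_dataset()
        out = build_network(_arch()).predict(data)
        assert np.all((out.p_progression > 0) & (out.p_progression < 1))
        assert np.all(np.isfinite(out.mmse_slope_hat))
        assert np.all(np.isfinite(out.hippocampal_volume_hat))

    def test_jd_only_configuration(self):
        data = _toy_dataset()
        data.mri = None
        out = build_network(_arch(use_mri=False)).predict(data)
        assert out.p_progression.shape == (12,)

    def test_missing_required_channel_error(self):
        data = _toy_dataset()
        data.jd = None
        with pytest.raises(DataError, match="jd"):
            build_network(_arch()).predict(data)

    def test_identical_seed_identical_parameters(self):
        a, b = build_network(_arch(seed=4)), build_network(_arch(seed=4))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        c = build_network(_arch(seed=5))
        assert any(not np.array_equal(pa, pc)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_too_small_grid_names_minimum(self):
        with pytest.raises(ConfigurationError, match=r"\(8, 8, 8\)"):
            build_network(ArchConfig(grid_shape=(4, 8, 8)))

    def test_parameter_count_reported(self):
        net = build_network(_arch())
        assert net.n_parameters == sum(p.size for p in net.parameters()) > 0


class TestTraining:
    def test_zero_epochs_leaves_network_unchanged(self):
        data = _toy_dataset()
        net = build_network(_arch())
        before = [p.copy() for p in net.parameters()]
        train_deep(net, data, schedule=TrainingSchedule(epochs=0))
        for p, q in zip(net.parameters(), before):
            np.testing.assert_array_equal(p, q)

    def test_training_is_deterministic(self):
        data = _toy_dataset()
        nets = []
        for _ in range(2):
            net = build_network(_arch(seed=1))
            train_deep(net, data, schedule=TrainingSchedule(epochs=2, batch_size=6),
                       seed=9)
            nets.append(net)
        for pa, pb in zip(nets[0].parameters(), nets[1].parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_auxiliary_heads_untouched_when_weights_zero(self):
        """w2=w3=0 reduces to single-task training: the auxiliary heads keep
        their initial parameters and the shared trunk follows the L1-only
        trajectory."""
        data = _toy_dataset()
        net = build_network(_arch(seed=2))
        slope_w0 = net.head_slope.W.copy()
        hip_w0 = net.head_hippocampus.W.copy()
        hist = train_deep(net, data, schedule=TrainingSchedule(epochs=3, batch_size=6),
                          weights=LossWeights(1, 0, 0), seed=0)
        np.testing.assert_array_equal(net.head_slope.W, slope_w0)
        np.testing.assert_array_equal(net.head_hippocampus.W, hip_w0)
        np.testing.assert_allclose(hist["train_total"], hist["train_l1"])

    def test_overfit_small_batch(self):
        """Capacity sanity check: 8 subjects, no augmentation, 200 epochs of
        the progression loss drive the training cross-entropy below 0.1."""
        data = _toy_dataset(n=8, seed=3)
        net = build_network(_arch(seed=0))
        hist = train_deep(net, data,
                          schedule=TrainingSchedule(epochs=200, batch_size=8,
                                                    lr0=2e-2, lr_decay=1.0),
                          weights=LossWeights(1, 0.025, 0.025), seed=0)
        assert hist["train_l1"].iloc[-1] < 0.1

    def test_nan_input_aborts_with_diagnostic(self):
        data = _toy_dataset()
        data.clinical[0, 0] = np.nan
        net = build_network(_arch())
        with pytest.raises(NeuroprogError, match="epoch 0"):
            train_deep(net, data, schedule=TrainingSchedule(epochs=1, batch_size=12))

    def test_history_records_validation(self):
        data = _toy_dataset()
        net = build_network(_arch())
        hist = train_deep(net, data, val_data=data,
                          schedule=TrainingSchedule(epochs=2, batch_size=6))
        assert {"train_l1", "train_l2", "train_l3", "val_l1", "val_total"} <= set(hist)
        assert len(hist) == 2


class TestGridSearch:
    def test_single_candidate_returned(self):
        data = _toy_dataset()
        folds = [(data.take(np.arange(8)), data.take(np.arange(8, 12)))]
        w, table = grid_search_weights([0.025], "progression", folds, _arch(),
                                       TrainingSchedule(epochs=1, batch_size=8))
        assert w == LossWeights(1.0, 0.025, 0.025)
        assert len(table) == 1

    def test_weight_structure_per_main_task(self):
        data = _toy_dataset()
        folds = [(data.take(np.arange(8)), data.take(np.arange(8, 12)))]
        w, _ = grid_search_weights([0.0, 0.05], "slope", folds, _arch(),
                                   TrainingSchedule(epochs=1, batch_size=8))
        assert w.w2 == 1.0 and w.w1 == w.w3 and w.w1 in (0.0, 0.05)

    def test_empty_candidates_error(self):
        with pytest.raises(ConfigurationError):
            grid_search_weights([], "progression", [], _arch())
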