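"""Flat-net: topology audit, parameter counting, gradients, training contracts."""

import numpy as np
import pytest

from vtloc.flatnet import (FlatNetConfig, TrainConfig, build_flatnet,
                           count_parameters, partition_landmarks,
                           predict_landmarks, train_localizer)
from vtloc.flatnet.layers import Adam, Conv2D, mae_loss
from vtloc.schema import load_schema

TINY = FlatNetConfig(filters_l1=2, filters_l2=2, filters_l4=4, filters_l5=4,
                     filters_l6=4, outputs_per_network=1)


def closed_form_count(c: FlatNetConfig) -> int:
    """Independent per-layer weight+bias sum for the Flat-net topology."""
    k2, k4 = c.kernel_l1_l2 ** 2, c.kernel_l4 ** 2
    n_br = len(c.branch_dilation_rates)
    branches = n_br * (k2 * c.input_channels * c.filters_l1 + c.filters_l1
                       + k2 * c.filters_l1 * c.filters_l2 + c.filters_l2)
    l4 = k4 * n_br * c.filters_l2 * c.filters_l4 + c.filters_l4
    l5 = c.filters_l4 * c.filters_l5 + c.filters_l5
    l6 = c.filters_l5 * c.filters_l6 + c.filters_l6
    l7 = c.filters_l6 * c.outputs_per_network + c.outputs_per_network
    return branches + l4 + l5 + l6 + l7


class TestPartition:
    @pytest.mark.parametrize("max_per,n_groups,sizes", [
        (5, 5, [5, 5, 5, 5, 1]),
        (3, 7, [3, 3, 3, 3, 3, 3, 3]),
        (21, 1, [21]),
    ])
    def test_group_counts(self, schema, max_per, n_groups, sizes):
        part = partition_landmarks(schema, max_per)
        assert len(part) == n_groups
        assert [len(g) for g in part.groups] == sizes
        assert part.flat == schema.abbreviations    # greedy in schema order

    def test_invalid_max_rejected(self, schema):
        with pytest.raises(ValueError):
            partition_landmarks(schema, 0)


class TestArchitecture:
    def test_no_pooling_striding_upsampling_or_dense(self):
        net = build_flatnet(TINY)
        infos = net.layers()
        assert all(i.kind in ("conv", "concat") for i in infos)
        assert all(i.stride == 1 for i in infos if i.kind == "conv")

    def test_layer_shapes_and_activations(self):
        net = build_flatnet(FlatNetConfig(filters_l1=2, filters_l2=3,
                                          filters_l4=4, filters_l5=5,
                                          filters_l6=6, outputs_per_network=2))
        infos = {i.name: i for i in net.layers()}
        for b in range(5):
            assert infos[f"L1.branch{b}"].kernel == 9
            assert infos[f"L1.branch{b}"].activation == "relu"
            assert infos[f"L2.branch{b}"].dilation == \
                infos[f"L1.branch{b}"].dilation
        assert infos["L3"].kind == "concat" and infos["L3"].c_out == 5 * 3
        assert infos["L4"].kernel == 5
        assert infos["L5"].kernel == infos["L6"].kernel == infos["L7"].kernel == 1
        assert infos["L7"].activation == "tanh"
        assert all(infos[f"L{k}"].activation == "relu" for k in (4, 5, 6))

    def test_resolution_preserved_and_tanh_range(self):
        net = build_flatnet(FlatNetConfig(filters_l1=2, filters_l2=2,
                                          filters_l4=4, filters_l5=4,
                                          filters_l6=4, outputs_per_network=5))
        x = np.random.default_rng(0).random((2, 64, 64, 3), dtype=np.float32)
        y = net.forward(x)
        assert y.shape == (2, 64, 64, 5)
        assert np.all(y > -1) and np.all(y < 1)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FlatNetConfig(branch_dilation_rates=(1, 2, 4))
        with pytest.raises(ValueError):
            FlatNetConfig(branch_dilation_rates=(1, 2, 4, 8, 0))
        with pytest.raises(ValueError):
            FlatNetConfig(filters_l1=0)

    def test_translation_equivariance_in_interior(self):
        # a fully-convolutional stack with zero padding commutes with
        # translation wherever receptive fields avoid the boundary
        cfg = FlatNetConfig(branch_dilation_rates=(1, 1, 2, 2, 1),
                            filters_l1=2, filters_l2=2, filters_l4=2,
                            filters_l5=2, filters_l6=2, outputs_per_network=1)
        net = build_flatnet(cfg, rng_seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((1, 64, 64, 3), dtype=np.float32)
        sx, sy = 5, 3
        xs = np.zeros_like(x)
        xs[0, sy:, sx:, :] = x[0, :-sy, :-sx, :]
        y = net.forward(x)[0, :, :, 0]
        ys = net.forward(xs)[0, :, :, 0]
        # receptive-field half-width: 2 dilated 9x9 at rate 2 plus a 5x5
        band = 2 * 8 * 2 // 2 + 2 + max(sx, sy)
        inner = np.s_[band:-band, band:-band]
        np.testing.assert_allclose(ys[inner],
                                   y[band - sy:-band - sy, band - sx:-band - sx],
                                   atol=1e-5)


class TestParameterCount:
    @pytest.mark.parametrize("cfg", [
        TINY,
        FlatNetConfig(),
        FlatNetConfig(filters_l1=8, filters_l2=16, filters_l4=32,
                      filters_l5=32, filters_l6=16, outputs_per_network=21),
        FlatNetConfig(branch_dilation_rates=(1, 3, 5, 7, 9), filters_l1=3,
                      filters_l2=5, filters_l4=7, filters_l5=9, filters_l6=11,
                      outputs_per_network=2),
    ])
    def test_matches_closed_form(self, cfg):
        assert count_parameters(build_flatnet(cfg)) == closed_form_count(cfg)

    def test_finite_difference_in_l4_filters(self):
        base = TINY
        doubled = FlatNetConfig(**{**base.__dict__, "filters_l4": 2 * base.filters_l4})
        delta = count_parameters(build_flatnet(doubled)) - \
            count_parameters(build_flatnet(base))
        c = base
        expected = (c.kernel_l4 ** 2 * 5 * c.filters_l2 * c.filters_l4
                    + c.filters_l4 + c.filters_l4 * c.filters_l5)
        assert delta == expected


class TestGradients:
    @pytest.mark.parametrize("dilation,activation", [(1, "relu"), (3, "tanh"),
                                                     (2, None)])
    def test_conv_gradients_match_finite_differences(self, dilation, activation):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 7, 7, 2)).astype(np.float32)
        t = rng.standard_normal((1, 7, 7, 3)).astype(np.float32)
        lay = Conv2D(3, 2, 3, dilation=dilation, activation=activation, rng=rng)
        y = lay.forward(x, train=True)
        _, g = mae_loss(y, t)
        dx = lay.backward(g)
        eps = 1e-3
        for idx in [(0, 1, 1, 2), (2, 2, 0, 1)]:
            w0 = lay.W[idx]
            lay.W[idx] = w0 + eps
            lp, _ = mae_loss(lay.forward(x), t)
            lay.W[idx] = w0 - eps
            lm, _ = mae_loss(lay.forward(x), t)
            lay.W[idx] = w0
            assert lay.dW[idx] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)
        xi = (0, 3, 4, 1)
        xp = x.copy()
        xp[xi] += eps
        lp, _ = mae_loss(lay.forward(xp), t)
        xp[xi] -= 2 * eps
        lm, _ = mae_loss(lay.forward(xp), t)
        assert dx[xi] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)

    def test_adam_descends_on_quadratic_fit(self):
        # one 1x1 conv fitting a linear map: loss must shrink
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 8, 8, 2)).astype(np.float32)
        t = (2 * x[..., :1] - 0.5 * x[..., 1:]).astype(np.float32)
        lay = Conv2D(1, 2, 1, activation=None, rng=rng)
        opt = Adam([lay], learning_rate=1e-2)
        first = None
        for _ in range(200):
            y = lay.forward(x, train=True)
            loss, g = mae_loss(y, t)
            first = first if first is not None else loss
            lay.backward(g)
            opt.step()
        assert loss < 0.2 * first


class TestTraining:
    def test_history_bookkeeping_and_validation_split(self, small_corpus):
        part = partition_landmarks(load_schema(), 21)
        loc = train_localizer(small_corpus, part, TINY,
                              TrainConfig(max_epochs=2, batch_size=2,
                                          plateau_patience=10, rng_seed=0))
        assert len(loc.history) == 1
        assert len(loc.history[0]["train_loss"]) == 2
        assert all(np.isfinite(loc.history[0]["train_loss"]))
        assert all(np.isfinite(loc.history[0]["val_loss"]))

    def test_validation_split_is_five_percent(self):
        # 100 training items -> 5 validation items
        assert max(1, int(round(0.05 * 100))) == 5  # documented rounding rule
        assert max(1, int(round(0.05 * 30))) == 2

    def test_predict_contract(self, small_corpus):
        part = partition_landmarks(load_schema(), 21)
        loc = train_localizer(small_corpus[:2], part, TINY,
                              TrainConfig(max_epochs=1, rng_seed=0))
        coords = predict_landmarks(loc, small_corpus[0].image)
        assert coords.shape == (21, 2)
        rows, cols = small_corpus[0].shape
        assert np.all(coords[:, 0] >= 0) and np.all(coords[:, 0] < cols)
        assert np.all(coords[:, 1] >= 0) and np.all(coords[:, 1] < rows)

    def test_predict_rejects_wrong_size(self, small_corpus):
        part = partition_landmarks(load_schema(), 21)
        loc = train_localizer(small_corpus[:2], part, TINY,
                              TrainConfig(max_epochs=1, rng_seed=0))
        with pytest.raises(ValueError, match="does not match"):
            predict_landmarks(loc, np.zeros((32, 32)))

    def test_empty_corpus_rejected(self):
        part = partition_landmarks(load_schema(), 21)
        with pytest.raises(ValueError):
            train_localizer([], part, TINY, TrainConfig())

    def test_save_load_round_trip(self, small_corpus, tmp_path):
        from vtloc.flatnet import TrainedLocalizer
        part = partition_landmarks(load_schema(), 11)
        loc = train_localizer(small_corpus[:2], part, TINY,
                              TrainConfig(max_epochs=1, rng_seed=0))
        loc.save(tmp_path / "model")
        back = TrainedLocalizer.load(tmp_path / "model")
        assert back.partition.groups == part.groups
        a = predict_landmarks(loc, small_corpus[0].image)
        b = predict_landmarks(back, small_corpus[0].image)
        np.testing.assert_array_equal(a, b)
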