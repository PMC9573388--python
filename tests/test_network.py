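import numpy as np
import pytest

from ecgfusion.network import (
    ModelConfig,
    ParallelCrossNetwork,
    build_model,
    conv_block_shape,
    count_parameters,
    count_parameters_closed_form,
    cross_fuse,
    grid_to_seq,
    reshape_seq_to_grid,
    trace_shapes,
)

REDUCED = ModelConfig(seq_len=20, image_shape=(12, 12), lstm_units=(2, 3, 3),
                      conv_filters=(2, 3, 3), dense_units=8, n_classes=4)


class TestShapeArithmetic:
    @pytest.mark.parametrize(
        "inp,filters,expected",
        [
            ((100, 100, 1), 16, (50, 50, 16)),
            ((54, 50, 16), 32, (27, 25, 32)),
            ((135, 25, 32), 64, (68, 13, 64)),
        ],
    )
    def test_conv_block_ceiling_pooling(self, inp, filters, expected):
        assert conv_block_shape(inp, filters) == expected

    def test_conv_block_rejects_nonpositive_filters(self):
        with pytest.raises(ValueError):
            conv_block_shape((10, 10, 1), 0)

    @pytest.mark.parametrize(
        "seq,rows,cols,expected",
        [((200, 16), 4, 50, (4, 50, 16)), ((2700, 32), 108, 25, (108, 25, 32))],
    )
    def test_seq_to_grid(self, seq, rows, cols, expected):
        assert reshape_seq_to_grid(seq, rows, cols) == expected

    def test_seq_to_grid_rejects_bad_factorization(self):
        with pytest.raises(ValueError, match="150"):
            reshape_seq_to_grid((200, 16), 3, 50)

    def test_grid_seq_roundtrip(self):
        for shape in [(4, 50, 16), (108, 25, 32), (7, 3, 5)]:
            seq = grid_to_seq(shape)
            assert reshape_seq_to_grid(seq, shape[0], shape[1]) == shape

    @pytest.mark.parametrize(
        "top,bottom,expected",
        [
            ((4, 50, 16), (50, 50, 16), (54, 50, 16)),
            ((108, 25, 32), (27, 25, 32), (135, 25, 32)),
        ],
    )
    def test_cross_fuse_concatenates_first_axis(self, top, bottom, expected):
        assert cross_fuse(top, bottom) == expected

    def test_cross_fuse_rejects_width_mismatch(self):
        with pytest.raises(ValueError):
            cross_fuse((4, 50, 16), (50, 49, 16))


class TestModelConfig:
    def test_mismatched_units_and_filters_rejected(self):
        with pytest.raises(ValueError, match="lstm_units"):
            ModelConfig(lstm_units=(16, 32, 64), conv_filters=(8, 32, 64))


class TestTrace:
    def test_default_trace_flatten_and_head(self):
        tr = trace_shapes()
        assert tr.shape("Flatten_1") == (216000,)
        assert tr.shape("Flatten_2") == (56576,)
        names = [n for n, _ in tr]
        assert names[-3:] == ["Dropout", "Dense_1", "Dense_2"]
        assert tr.shape("Concatenate_3") == (272576,)
        assert tr.shape("Dense_1") == (128,)
        assert tr.shape("Dense_2") == (4,)

    def test_tsv_export_contains_all_rows(self):
        tsv = trace_shapes().to_tsv()
        assert "Lstm_unit_2\t(2700, 32)" in tsv
        assert tsv.splitlines()[0] == "Layer\tOutput Volume"

    def test_nondivisible_seq_is_padded_not_rejected(self):
        # 50 timesteps against 14-wide conv maps -> padded to 56 = 4 x 14
        cfg = ModelConfig(seq_len=50, image_shape=(28, 28),
                          lstm_units=(4, 8, 8), conv_filters=(4, 8, 8))
        tr = trace_shapes(cfg)
        assert tr.shape("Reshape_1") == (4, 14, 4)
        assert tr.shape("Concatenate_1") == (18, 14, 4)


class TestParameterCount:
    def test_dense_head_alone_is_34_889_856(self):
        flat = trace_shapes().shape("Concatenate_3")[0]
        assert flat * 128 + 128 == 34_889_856

    def test_single_unit_lstm_has_12_parameters(self):
        assert 4 * ((1 + 1) * 1 + 1) == 12
        from ecgfusion.layers import LSTM

        layer = LSTM(1, 1, np.random.default_rng(0))
        assert sum(p.size for p in layer.params()) == 12

    def test_first_conv_has_160_parameters(self):
        from ecgfusion.layers import Conv2D

        conv = Conv2D(1, 16, np.random.default_rng(0))
        assert sum(p.size for p in conv.params()) == 9 * 16 + 16 == 160

    def test_framework_count_equals_closed_form_on_reduced_model(self):
        model, _ = build_model(REDUCED, seed=0)
        assert count_parameters(model) == count_parameters_closed_form(REDUCED)

    def test_default_model_exceeds_34_million(self):
        # closed form only: instantiating the 35M-param head is not needed
        assert count_parameters_closed_form() >= 34_000_000


class TestForwardBackward:
    def test_forward_output_is_a_distribution(self, rng):
        model, _ = build_model(REDUCED, seed=0)
        probs = model.forward(rng.standard_normal((3, 20, 1)),
                              rng.standard_normal((3, 12, 12, 1)))
        assert probs.shape == (3, 4)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_forward_rejects_mismatched_inputs(self, rng):
        model, _ = build_model(REDUCED, seed=0)
        with pytest.raises(ValueError, match="do not match"):
            model.forward(rng.standard_normal((3, 21, 1)),
                          rng.standard_normal((3, 12, 12, 1)))

    def test_whole_network_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        cfg = ModelConfig(seq_len=10, image_shape=(6, 6), lstm_units=(2, 3, 3),
                          conv_filters=(2, 3, 3), dense_units=5, n_classes=3,
                          dropout_rate=0.0)
        net = ParallelCrossNetwork(cfg, seed=0)
        seq = rng.standard_normal((3, 10, 1))
        img = rng.standard_normal((3, 6, 6, 1))
        y = np.eye(3)[rng.integers(0, 3, 3)]

        def loss():
            p = np.clip(net.forward(seq, img, training=True), 1e-12, None)
            return float(-(y * np.log(p)).sum() / 3)

        probs = net.forward(seq, img, training=True)
        for p in net.params():
            p.grad = None
        net.backward((probs - y) / 3)
        eps = 1e-6
        for p in net.params():
            v = np.random.default_rng(abs(hash(p.name)) % 2**31).standard_normal(
                p.value.shape)
            p.value += eps * v
            lp = loss()
            p.value -= 2 * eps * v
            lm = loss()
            p.value += eps * v
            fd = (lp - lm) / (2 * eps)
            an = float((p.grad * v).sum())
            assert fd == pytest.approx(an, rel=1e-4, abs=1e-7), p.name

    def test_save_load_roundtrip_preserves_predictions(self, rng, tmp_path):
        model, _ = build_model(REDUCED, seed=3)
        seq = rng.standard_normal((4, 20, 1))
        img = rng.standard_normal((4, 12, 12, 1))
        before = model.forward(seq, img)
        path = tmp_path / "model.npz"
        model.save(path)
        after = ParallelCrossNetwork.load(path).forward(seq, img)
        np.testing.assert_allclose(before, after)

    def test_trace_matches_actual_forward_shapes(self, rng):
        """Dry forward pass agrees with the symbolic shape trace."""
        model, tr = build_model(REDUCED, seed=0)
        model.forward(rng.standard_normal((2, 20, 1)),
                      rng.standard_normal((2, 12, 12, 1)), training=True)
        h1s, g1s, cat1s, _, h2s, g2s, cat2s, _, h3s, f3s = model._shapes
        assert h1s[1:] == tr.shape("Lstm_unit_1")
        assert cat1s[1:] == tr.shape("Concatenate_1")
        assert cat2s[1:] == tr.shape("Concatenate_2")
        assert h3s[1:] == tr.shape("Lstm_unit_3")
        assert f3s[1:] == tr.shape("Conv_block_3")
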