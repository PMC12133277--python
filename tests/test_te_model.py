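"""TE(k) model: positional encoding, size transfer, determinism."""

import numpy as np
import pytest

from trendy.te_model import (
    TEConfig,
    build_te,
    load_checkpoint,
    positional_encoding_2d,
    save_checkpoint,
    te_forward,
)


def pe_transcription(n, d):
    """Independent direct transcription of the encoding definition:
    1-based x (row), y (column), j = 1..d/4, omega_j = 10^(-32(j-1)/d);
    first half of d interleaves sin/cos of (y-1)*omega_j, second half of
    (x-1)*omega_j."""
    pe = np.zeros((n, n, d))
    for x in range(1, n + 1):
        for y in range(1, n + 1):
            for j in range(1, d // 4 + 1):
                w = 10.0 ** (-32.0 * (j - 1) / d)
                pe[x - 1, y - 1, 2 * j - 1 - 1] = np.sin((y - 1) * w)
                pe[x - 1, y - 1, 2 * j - 1] = np.cos((y - 1) * w)
                pe[x - 1, y - 1, 2 * j - 1 - 1 + d // 2] = np.sin((x - 1) * w)
                pe[x - 1, y - 1, 2 * j - 1 + d // 2] = np.cos((x - 1) * w)
    return pe


class TestPositionalEncoding:
    @pytest.mark.parametrize("n,d", [(3, 8), (10, 64)])
    def test_matches_independent_transcription(self, n, d):
        assert np.abs(positional_encoding_2d(n, d) - pe_transcription(n, d)).max() < 1e-12

    def test_entries_bounded_by_one(self):
        pe = positional_encoding_2d(6, 16)
        assert pe.min() >= -1.0 and pe.max() <= 1.0

    def test_origin_cell_is_sin_zero_cos_one(self):
        pe = positional_encoding_2d(4, 8)
        # at x=y=1 every sine slot is sin(0)=0 and every cosine slot cos(0)=1
        assert set(np.round(pe[0, 0], 12)) <= {0.0, 1.0}
        assert np.isclose(np.abs(pe[0, 0]).sum(), pe.shape[2] / 2)

    def test_half_axis_coordinate_dependence(self):
        d = 16
        pe = positional_encoding_2d(5, d)
        # first half varies only with the column, second half only with the row
        assert np.allclose(pe[:, :, : d // 2], pe[:1, :, : d // 2])
        assert np.allclose(pe[:, :, d // 2 :], pe[:, :1, d // 2 :])
        assert not np.allclose(pe[:, 0, : d // 2], pe[:, 1, : d // 2])

    def test_d_not_divisible_by_four_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding_2d(4, 10)


class TestBuildTe:
    def test_k1_has_no_segment_embedding(self):
        model = build_te(TEConfig(k=1, d=8, l=1, h=2))
        assert model.segment_embed is None

    def test_k3_token_width_is_d_times_k(self):
        model = build_te(TEConfig(k=3, d=64, l=1, h=8))
        assert model.encoder_layers[0].ff1.weight.shape == (192, 4 * 192)
        assert model.output_proj.weight.shape == (192, 1)

    def test_same_seed_identical_parameters(self):
        m1 = build_te(TEConfig(k=2, d=8, l=2, h=2), rng_seed=7)
        m2 = build_te(TEConfig(k=2, d=8, l=2, h=2), rng_seed=7)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.data, p2.data)

    @pytest.mark.parametrize(
        "bad", [{"d": 10}, {"k": 0}, {"l": 0}, {"d": 8, "h": 3}, {"dropout": 1.0}]
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            TEConfig(**bad)


class TestForward:
    def test_size_transfer_same_weights(self):
        # one model, never told n, processes 10- and 18-gene inputs
        model = build_te(TEConfig(k=3, d=8, l=1, h=2), rng_seed=0)
        rng = np.random.default_rng(0)
        out10 = te_forward(model, rng.normal(size=(3, 10, 10)))
        out18 = te_forward(model, rng.normal(size=(3, 18, 18)))
        assert out10.shape == (10, 10) and out18.shape == (18, 18)

    def test_parameter_count_independent_of_n(self):
        model = build_te(TEConfig(k=1, d=8, l=1, h=2), rng_seed=0)
        before = model.n_parameters()
        te_forward(model, np.zeros((1, 5, 5)))
        te_forward(model, np.zeros((1, 9, 9)))
        assert model.n_parameters() == before

    def test_evaluation_mode_deterministic(self):
        model = build_te(TEConfig(k=2, d=8, l=2, h=2, dropout=0.5), rng_seed=1)
        x = np.random.default_rng(2).normal(size=(2, 6, 6))
        assert np.array_equal(te_forward(model, x), te_forward(model, x))

    def test_wrong_k_rejected(self):
        model = build_te(TEConfig(k=2, d=8, l=1, h=2))
        with pytest.raises(ValueError):
            te_forward(model, np.zeros((3, 4, 4)))

    def test_permutation_equivariance_without_pe(self):
        # without positional encoding the token set is only permuted, so the
        # output matrix is permuted identically; adding PE breaks this
        model = build_te(TEConfig(k=1, d=8, l=2, h=2), rng_seed=3)
        model.eval()
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 1, 5, 5))
        perm = np.array([2, 0, 4, 1, 3])
        xp = x[:, :, perm][:, :, :, perm]

        from trendy.nn.autograd import no_grad

        with no_grad():
            out = model.forward(x, add_positional=False).data[0]
            out_p = model.forward(xp, add_positional=False).data[0]
            out_pe = model.forward(x, add_positional=True).data[0]
            out_pe_p = model.forward(xp, add_positional=True).data[0]
        assert np.allclose(out_p, out[perm][:, perm], atol=1e-5)
        assert not np.allclose(out_pe_p, out_pe[perm][:, perm], atol=1e-5)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        model = build_te(TEConfig(k=2, d=8, l=1, h=2), rng_seed=5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == model.config
        x = np.random.default_rng(6).normal(size=(2, 4, 4))
        assert np.array_equal(te_forward(model, x), te_forward(loaded, x))
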