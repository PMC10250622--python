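"""Region stacking, conv+GLU blocks, positional encoding and self-attention."""

import numpy as np
import pytest

from helixcpi import nn
from helixcpi.encoder import (EncoderConfig, HelixEncoderParams,
                              PaddedRegionStack, conv_glu_block, encode_batch,
                              encode_protein, pad_and_stack,
                              self_attention_block, sinusoidal_encoding)
from helixcpi.protein_features import EmbeddedRegion, train_word2vec, split_regions, embed_segments

from conftest import make_receptor


def regions_of_lengths(lengths, dim=100, rng=None, names=None):
    rng = rng or np.random.default_rng(0)
    names = names or [f"TM{i + 1}" for i in range(len(lengths))]
    return [EmbeddedRegion(n, rng.standard_normal((p, dim)).astype(np.float32))
            for n, p in zip(names, lengths)]


class TestPadAndStack:
    def test_pmax_and_shape(self):
        stack = pad_and_stack(regions_of_lengths([20, 25, 22, 24, 21, 23, 25]))
        assert stack.stack.shape == (7, 25, 100)
        assert stack.p_max == 25

    def test_mask_leading_trues_and_zero_padding(self):
        stack = pad_and_stack(regions_of_lengths([3, 5]))
        assert stack.mask[0].tolist() == [True] * 3 + [False] * 2
        assert not stack.stack[0, 3:].any()

    def test_equal_lengths_no_padding(self):
        stack = pad_and_stack(regions_of_lengths([4] * 7))
        assert stack.mask.all()

    def test_eight_regions(self):
        lengths = [20, 21, 22, 23, 30, 24, 25, 26]
        names = ["TM1", "TM2", "TM3", "TM4", "ECL2", "TM5", "TM6", "TM7"]
        stack = pad_and_stack(regions_of_lengths(lengths, names=names))
        assert stack.stack.shape == (8, 30, 100)
        assert stack.region_order == tuple(names)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            pad_and_stack([])


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = sinusoidal_encoding(4, 8)
        np.testing.assert_allclose(pe[0], [0, 1, 0, 1, 0, 1, 0, 1], atol=1e-7)

    def test_values_bounded(self):
        pe = sinusoidal_encoding(100, 64)
        assert np.abs(pe).max() <= 1.0 + 1e-6


class TestConvGLU:
    def test_zero_input_zero_params_give_zero(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv1dSame(rng, 10, 16, 3, "c")
        conv.w.data[:] = 0
        conv.b.data[:] = 0
        out = conv_glu_block(nn.constant(np.zeros((1, 6, 10), np.float32)), conv, 8)
        assert not out.data.any()

    def test_kernel_one_is_positionwise(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv1dSame(rng, 10, 16, 1, "c")
        x = np.random.default_rng(1).standard_normal((1, 6, 10)).astype(np.float32)
        base = conv_glu_block(nn.constant(x), conv, 8).data
        x2 = x.copy()
        x2[0, 3] += 1.0
        out = conv_glu_block(nn.constant(x2), conv, 8).data
        changed = np.abs(out - base).sum(axis=2)[0]
        assert changed[3] > 0 and not changed[[0, 1, 2, 4, 5]].any()

    def test_length_preserved(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv1dSame(rng, 10, 16, 3, "c")
        out = conv_glu_block(nn.constant(np.ones((2, 9, 10), np.float32)), conv, 8)
        assert out.shape == (2, 9, 8)


@pytest.fixture(scope="module")
def default_params():
    return HelixEncoderParams(np.random.default_rng(0), EncoderConfig(), 7)


class TestSelfAttention:
    def test_attention_rows_sum_to_one_over_valid_keys(self, default_params):
        rng = np.random.default_rng(0)
        x = nn.constant(rng.standard_normal((2, 10, 64)).astype(np.float32))
        mask = np.ones((2, 10), dtype=bool)
        mask[0, 7:] = False
        out, weights = self_attention_block(x, mask, default_params)
        sums = weights.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-5)
        assert weights[0][:, :, 7:].max() < 1e-7  # masked keys get no mass

    def test_single_unmasked_key_takes_weight_one(self, default_params):
        rng = np.random.default_rng(0)
        x = nn.constant(rng.standard_normal((1, 6, 64)).astype(np.float32))
        mask = np.zeros((1, 6), dtype=bool)
        mask[0, 2] = True
        _, weights = self_attention_block(x, mask, default_params)
        np.testing.assert_allclose(weights[0, :, :, 2], 1.0, atol=1e-6)

    def test_output_shape_preserved(self, default_params):
        x = nn.constant(np.zeros((1, 14, 64), np.float32))
        out, _ = self_attention_block(x, np.ones((1, 14), bool), default_params)
        assert out.shape == (1, 14, 64)


class TestEncodeProtein:
    @pytest.fixture(scope="class")
    def vocab(self):
        return train_word2vec(["ACDEFGHIKLMNPQRSTVWY" * 3], seed=0, epochs=1)

    def _stack(self, receptor, vocab, ecls=()):
        return pad_and_stack(embed_segments(split_regions(receptor, ecls), vocab))

    def test_shape_law_seven_and_eight_regions(self, vocab):
        rng = np.random.default_rng(5)
        r = make_receptor(rng=rng)
        st7 = self._stack(r, vocab)
        enc7 = encode_protein(st7, HelixEncoderParams(np.random.default_rng(0),
                                                      EncoderConfig(), 7))
        assert enc7.matrix.shape == (st7.p_max * 7, 64)
        st8 = self._stack(r, vocab, ("ECL2",))
        enc8 = encode_protein(st8, HelixEncoderParams(
            np.random.default_rng(0), EncoderConfig(include_ecls=("ECL2",)), 8))
        assert enc8.matrix.shape == (st8.p_max * 8, 64)

    def test_provenance_follows_anatomical_order(self, vocab):
        r = make_receptor()
        st = self._stack(r, vocab, ("ECL2",))
        enc = encode_protein(st, HelixEncoderParams(
            np.random.default_rng(0), EncoderConfig(include_ecls=("ECL2",)), 8))
        region_seq = [rid for rid, _ in enc.provenance]
        expected = []
        for rid in ("TM1", "TM2", "TM3", "TM4", "ECL2", "TM5", "TM6", "TM7"):
            expected.extend([rid] * st.p_max)
        assert region_seq == expected

    def test_deterministic_for_fixed_seed(self, vocab):
        r = make_receptor()
        st = self._stack(r, vocab)
        a = encode_protein(st, HelixEncoderParams(np.random.default_rng(3),
                                                  EncoderConfig(), 7))
        b = encode_protein(st, HelixEncoderParams(np.random.default_rng(3),
                                                  EncoderConfig(), 7))
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_batch_padding_leaves_valid_rows_unchanged(self, vocab):
        # encoding alone vs alongside a longer receptor must agree at
        # every real row: batch-level padding is inert
        rng = np.random.default_rng(6)
        short = make_receptor("S", tm_len=8, rng=rng)
        long = make_receptor("L", tm_len=14, rng=rng)
        params = HelixEncoderParams(np.random.default_rng(0), EncoderConfig(), 7)
        st_s, st_l = self._stack(short, vocab), self._stack(long, vocab)
        alone = encode_protein(st_s, params)
        batched, mask = encode_batch([st_s, st_l], params)
        P = st_l.p_max
        cols = np.concatenate([np.arange(r * P, r * P + st_s.p_max)
                               for r in range(7)])
        np.testing.assert_allclose(batched.data[0][cols][alone.mask],
                                   alone.matrix[alone.mask], atol=1e-5)
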