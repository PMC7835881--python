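"""The Siamese network: DuSE recalibration oracles, weight sharing,
probability-map bounds, embeddings, matching head and checkpointing."""

import numpy as np
import pytest

from tomoshot.autodiff import Tensor
from tomoshot.model import (ModelConfig, OneShotNet, load_checkpoint,
                            save_checkpoint)
from tomoshot.nn import ChannelSqueezeExcite, DuSE, SpatialSqueezeExcite


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def duse_oracle(f, w1, w2, w3):
    """Scalar triple-loop evaluation of the dual squeeze-and-excitation:
    channel gate sigmoid(w2 relu(w1 v)) with v the per-channel spatial mean,
    plus spatial gate sigmoid(sum_c w3_c f_c) per voxel, summed."""
    c, h, w, d = f.shape
    v = np.array([f[z].mean() for z in range(c)])
    vhat = sigmoid(w2 @ np.maximum(w1 @ v, 0.0))
    f_sc = np.empty_like(f)
    for z in range(c):
        f_sc[z] = f[z] * vhat[z]
    f_cs = np.empty_like(f)
    for i in range(h):
        for j in range(w):
            for k in range(d):
                m = sum(w3[z] * f[z, i, j, k] for z in range(c))
                for z in range(c):
                    f_cs[z, i, j, k] = f[z, i, j, k] * sigmoid(m)
    return f_sc, f_cs, f_sc + f_cs


@pytest.fixture
def small_net():
    return OneShotNet(ModelConfig(channels=(2, 4, 8), embedding_dim=512,
                                  input_size=16, seed=3))


class TestDuSE:
    def _blocks(self, channels, rng):
        cse = ChannelSqueezeExcite(channels, 2, rng)
        sse = SpatialSqueezeExcite(channels, rng)
        return cse, sse

    def test_constant_channel_mean_is_exact(self, rng):
        cse, _ = self._blocks(4, rng)
        f = np.zeros((1, 4, 3, 3, 3), np.float32)
        for z, val in enumerate((0.5, -1.0, 2.0, 0.0)):
            f[0, z] = val
        from tomoshot.nn import global_avg_pool
        v = global_avg_pool(Tensor(f)).data
        assert np.allclose(v[0], [0.5, -1.0, 2.0, 0.0])

    def test_zero_weights_halve_input(self, rng):
        cse, sse = self._blocks(4, rng)
        for layer in (cse.fc1, cse.fc2):
            layer.weight.data[:] = 0.0
        sse.conv.weight.data[:] = 0.0
        f = Tensor(rng.normal(size=(2, 4, 3, 3, 3)).astype(np.float32))
        assert np.allclose(cse(f).data, 0.5 * f.data, atol=1e-6)
        assert np.allclose(sse(f).data, 0.5 * f.data, atol=1e-6)

    def test_spatial_gate_saturates_to_identity(self, rng):
        sse = SpatialSqueezeExcite(1, rng)
        sse.conv.weight.data[:] = 50.0
        f = Tensor(np.full((1, 1, 3, 3, 3), 3.0, np.float32))
        assert np.allclose(sse(f).data, f.data, atol=1e-4)

    @pytest.mark.parametrize("channels,size", [(2, 4), (4, 5), (6, 6)])
    def test_branches_match_scalar_oracle(self, channels, size, rng):
        cse = ChannelSqueezeExcite(channels, 2, rng)
        sse = SpatialSqueezeExcite(channels, rng)
        f = rng.normal(size=(channels, size, size, size)).astype(np.float32)
        w1 = cse.fc1.weight.data.T  # oracle uses (hidden, C) orientation
        w2 = cse.fc2.weight.data.T
        w3 = sse.conv.weight.data[0, :, 0, 0, 0]
        o_sc, o_cs, o_sum = duse_oracle(f.astype(np.float64), w1, w2, w3)
        t = Tensor(f[None])
        assert np.abs(cse(t).data[0] - o_sc).max() < 1e-5
        assert np.abs(sse(t).data[0] - o_cs).max() < 1e-5

    def test_duse_is_sum_of_branches_and_matches_oracle(self, rng):
        duse = DuSE(4, 2, rng)
        f = rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32)
        t = Tensor(f)
        expected = duse.cse(t).data + duse.sse(t).data
        assert np.array_equal(duse(t).data, expected)
        o = duse_oracle(f[0].astype(np.float64),
                        duse.cse.fc1.weight.data.T,
                        duse.cse.fc2.weight.data.T,
                        duse.sse.conv.weight.data[0, :, 0, 0, 0])[2]
        assert np.abs(duse(t).data[0] - o).max() < 1e-5

    def test_all_zero_se_weights_make_duse_identity(self, rng):
        duse = DuSE(4, 2, rng)
        duse.cse.fc1.weight.data[:] = 0.0
        duse.cse.fc2.weight.data[:] = 0.0
        duse.sse.conv.weight.data[:] = 0.0
        f = Tensor(rng.normal(size=(1, 4, 3, 3, 3)).astype(np.float32))
        assert np.allclose(duse(f).data, f.data, atol=1e-6)


class TestStreams:
    def test_weight_sharing_across_streams(self, small_net, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        lat_support = small_net.volume_encode(x)
        lat_target = small_net.volume_encode(x)
        assert np.array_equal(lat_support.data, lat_target.data)
        assert np.array_equal(
            small_net.volume_decode(lat_support).data,
            small_net.volume_decode(lat_target).data)
        assert np.array_equal(
            small_net.feature_encode(lat_support).data,
            small_net.feature_encode(lat_target).data)

    def test_batch_order_preserved(self, small_net, rng):
        batch = rng.normal(size=(3, 16, 16, 16)).astype(np.float32)
        lat = small_net.volume_encode(batch)
        for i in range(3):
            single = small_net.volume_encode(batch[i])
            assert np.allclose(lat.data[i], single.data[0], atol=1e-5)

    def test_wrong_input_size_rejected(self, small_net, rng):
        with pytest.raises(ValueError, match="cubes"):
            small_net.volume_encode(rng.normal(size=(8, 8, 8)))

    def test_probability_map_bounded(self, small_net, rng):
        x = rng.normal(size=(2, 16, 16, 16)).astype(np.float32) * 10
        probs = small_net.volume_decode(small_net.volume_encode(x))
        assert probs.shape == (2, 16, 16, 16)
        assert probs.data.min() >= 0.0 and probs.data.max() <= 1.0

    def test_embedding_has_512_dimensions(self, small_net, rng):
        x = rng.normal(size=(2, 16, 16, 16)).astype(np.float32)
        emb = small_net.embed(x)
        assert emb.shape == (2, 512)

    def test_fresh_constructions_are_identical(self, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        cfg = ModelConfig(channels=(2, 4, 8), input_size=16, seed=9)
        a = OneShotNet(cfg).embed(x).data
        b = OneShotNet(cfg).embed(x).data
        assert np.array_equal(a, b)


class TestMatching:
    def test_pairwise_distance_definition(self):
        a = Tensor(np.array([[1.0, 3.0]], np.float32))
        b = Tensor(np.array([[2.0, 1.0]], np.float32))
        d = OneShotNet.pairwise_distance(a, b)
        assert np.array_equal(d.data, [[1.0, 2.0]])

    def test_pairwise_distance_symmetric_and_zero_on_equal(self, rng):
        a = Tensor(rng.normal(size=(1, 512)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 512)).astype(np.float32))
        ab = OneShotNet.pairwise_distance(a, b).data
        ba = OneShotNet.pairwise_distance(b, a).data
        assert np.array_equal(ab, ba)
        assert not OneShotNet.pairwise_distance(a, a).data.any()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            OneShotNet.pairwise_distance(
                Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 5))))

    def test_softmax_uniform_for_equal_logits(self, small_net):
        d = [Tensor(np.zeros(512, np.float32)) for _ in range(4)]
        scores = small_net.match_scores(d, mode="softmax-over-support")
        assert np.allclose(scores, 0.25, atol=1e-6)

    def test_softmax_normalizes(self, small_net, rng):
        d = [Tensor(rng.random(512).astype(np.float32)) for _ in range(5)]
        scores = small_net.match_scores(d, mode="softmax-over-support")
        assert abs(scores.sum() - 1.0) < 1e-6

    def test_zero_distance_zero_bias_head_scores_half(self, small_net):
        small_net.head.bias.data[:] = 0.0
        score = small_net.match_scores(
            [Tensor(np.zeros(512, np.float32))], mode="pairwise-sigmoid")
        assert abs(score[0] - 0.5) < 1e-6

    def test_empty_distances_rejected(self, small_net):
        with pytest.raises(ValueError, match="at least one"):
            small_net.match_scores([])

    def test_argmax_tie_break_prefers_lowest_index(self):
        assert OneShotNet.predict_class(np.array([0.4, 0.4, 0.2])) == 0


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, small_net, rng, tmp_path):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        before = small_net.embed(x).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(small_net, path)
        restored = load_checkpoint(path)
        assert np.array_equal(restored.embed(x).data, before)
        assert restored.config == small_net.config
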