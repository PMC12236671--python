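"""Decoder architecture and training mechanics: partitioning, embedding
shapes, attention semantics, parameter accounting, stratification,
determinism, and the logistic baseline."""

import numpy as np
import pytest

from memdecode.model.autodiff import Tensor
from memdecode.model.network import (CRABlock, LogisticBaseline, ModelConfig,
                                     MultiRegionTransformer, TrainingConfig,
                                     bce_with_logits)
from memdecode.model.training import (exclude_rare_combinations,
                                      partition_channels,
                                      stratified_epoch_order, train)
from memdecode.pipeline import roc_auc

SMALL = dict(hidden_size=24, intermediate_size=48, depth=2, heads=4,
             n_concepts=4)


def small_model(shapes, seed=0, **over):
    return MultiRegionTransformer(shapes, ModelConfig(**{**SMALL, **over,
                                                         "seed": seed}))


class TestPartition:
    def test_24_channels_in_3_bundles(self):
        t = np.zeros((5, 2, 24, 50), dtype=np.float32)
        cmap = {b: list(range(8 * b, 8 * b + 8)) for b in range(3)}
        streams = partition_channels(t, cmap)
        assert len(streams) == 3
        assert all(s.shape == (5, 2, 8, 50) for s in streams)

    def test_channel_in_two_bundles_rejected(self):
        t = np.zeros((5, 2, 16, 50), dtype=np.float32)
        cmap = {0: list(range(8)), 1: [7] + list(range(8, 15))}
        with pytest.raises(ValueError, match="more than one"):
            partition_channels(t, cmap)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            partition_channels(np.zeros((5, 2, 8, 50)), {})

    def test_non_eight_bundle_rejected(self):
        with pytest.raises(ValueError, match="exactly 8"):
            partition_channels(np.zeros((5, 2, 7, 50)), {0: list(range(7))})


class TestEmbedding:
    def test_token_count_80_patches_plus_class(self):
        m = small_model([(2, 8, 50)], patch_width=5)
        emb = m.embeds[0]
        assert emb.n_patches == 80
        x = np.zeros((3, 2, 8, 50), dtype=np.float32)
        assert emb(x).shape == (3, 81, SMALL["hidden_size"])

    def test_indivisible_patching_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            small_model([(2, 8, 49)], patch_width=5)

    def test_embedding_deterministic_per_seed(self):
        x = np.random.default_rng(0).normal(size=(2, 2, 8, 50)).astype(np.float32)
        e1 = small_model([(2, 8, 50)], seed=5).embeds[0](x).data
        e2 = small_model([(2, 8, 50)], seed=5).embeds[0](x).data
        np.testing.assert_array_equal(e1, e2)


class TestParameterCount:
    def test_matches_closed_form(self):
        h, i, d, r, nc = 24, 48, 2, 3, 4
        m = small_model([(2, 8, 50)] * r, hidden_size=h, intermediate_size=i,
                        depth=d, n_concepts=nc)
        per_linear = lambda a, b: a * b + b
        attn = 4 * per_linear(h, h)
        ln = 2 * h
        rsa = attn + ln + per_linear(h, i) + per_linear(i, h) + ln
        cra = attn + ln
        embed = per_linear(2 * 5, h) + h + (80 + 1) * h   # proj + cls + pos
        expected = r * embed + d * (rsa + cra) + per_linear(h, nc)
        assert m.parameter_count() == expected

    def test_rsa_cra_shared_across_regions(self):
        one = small_model([(2, 8, 50)]).parameter_count()
        three = small_model([(2, 8, 50)] * 3).parameter_count()
        embed = small_model([(2, 8, 50)]).embeds[0]
        embed_params = sum(p.data.size for p in embed.parameters())
        assert three - one == 2 * embed_params


class TestForward:
    def test_outputs_in_unit_interval_not_summing_to_one(self):
        m = small_model([(2, 8, 50)] * 2)
        x = [np.random.default_rng(s).normal(size=(6, 2, 8, 50)).astype(np.float32)
             for s in (0, 1)]
        out = m.forward(x)
        assert ((out > 0) & (out < 1)).all()
        assert not np.allclose(out.sum(axis=1), 1.0)

    def test_identical_input_identical_output(self):
        m = small_model([(2, 8, 50)])
        x = [np.random.default_rng(2).normal(size=(4, 2, 8, 50)).astype(np.float32)]
        np.testing.assert_array_equal(m.forward(x), m.forward(x))

    def test_shape_mismatch_rejected(self):
        m = small_model([(2, 8, 50)])
        with pytest.raises(ValueError, match="region"):
            m.forward([np.zeros((2, 2, 8, 50), dtype=np.float32)] * 2)
        with pytest.raises(ValueError, match="shape"):
            m.forward([np.zeros((2, 2, 16, 50), dtype=np.float32)])


class TestCRA:
    def test_single_region_identity(self):
        rng = np.random.default_rng(0)
        blk = CRABlock(rng, 24, 4)
        c = [Tensor(rng.normal(size=(3, 1, 24)).astype(np.float32))]
        out = blk(c)
        np.testing.assert_array_equal(out[0].data, c[0].data)

    def test_two_regions_attend_to_each_other_only(self):
        rng = np.random.default_rng(1)
        blk = CRABlock(rng, 24, 4)
        a = Tensor(rng.normal(size=(2, 1, 24)).astype(np.float32))
        b = Tensor(rng.normal(size=(2, 1, 24)).astype(np.float32))
        out_ab = blk([a, b])
        # region order permutation permutes outputs identically
        out_ba = blk([b, a])
        np.testing.assert_allclose(out_ab[0].data, out_ba[1].data, atol=1e-6)
        np.testing.assert_allclose(out_ab[1].data, out_ba[0].data, atol=1e-6)


class TestTrainingMechanics:
    def labels(self):
        rng = np.random.default_rng(3)
        return rng.integers(0, 2, size=(240, 4)).astype(np.float32)

    def test_combination_screen_time_exclusion_boundary(self):
        # 199 windows = 49.75 s -> excluded; 200 windows = 50 s -> kept
        labels = np.concatenate([np.tile([1, 0, 0, 0], (199, 1)),
                                 np.tile([0, 1, 0, 0], (200, 1))])
        keep = exclude_rare_combinations(labels, 50.0)
        assert not keep[:199].any() and keep[199:].all()

    def test_stratified_batches_preserve_proportions(self):
        labels = np.concatenate([np.tile([1, 0, 0, 0], (150, 1)),
                                 np.tile([0, 1, 0, 0], (50, 1))])
        order = stratified_epoch_order(labels, np.random.default_rng(0))
        first_half = labels[order[:100]]
        assert abs(first_half[:, 0].mean() - 0.75) < 0.1

    def test_all_excluded_is_an_error(self):
        x = [np.zeros((8, 2, 8, 50), dtype=np.float32)]
        m = small_model([(2, 8, 50)])
        cfg = TrainingConfig(epochs=1, min_combination_screentime_s=1e6)
        with pytest.raises(ValueError, match="excluded"):
            train(m, x, np.zeros((8, 4)), cfg)

    def test_loss_trace_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        x = [rng.normal(size=(60, 2, 8, 10)).astype(np.float32)]
        y = rng.integers(0, 2, (60, 4)).astype(np.float32)
        hists = []
        for _ in range(2):
            m = small_model([(2, 8, 10)], seed=7)
            cfg = TrainingConfig(lr=1e-3, epochs=2, batch_size=16,
                                 min_combination_screentime_s=0.0, seed=7)
            hists.append(train(m, x, y, cfg)["loss"])
        assert hists[0] == hists[1]

    def test_step_decay_schedule(self):
        rng = np.random.default_rng(5)
        x = [rng.normal(size=(20, 2, 8, 10)).astype(np.float32)]
        y = rng.integers(0, 2, (20, 4)).astype(np.float32)
        m = small_model([(2, 8, 10)])
        cfg = TrainingConfig(lr=1e-3, epochs=4, batch_size=20,
                             lr_step_epochs=2, lr_decay=0.5,
                             min_combination_screentime_s=0.0, seed=0)
        hist = train(m, x, y, cfg)
        assert hist["lr"] == [1e-3, 1e-3, 5e-4, 5e-4]

    def test_loss_decreases_on_learnable_signal(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, (200, 4)).astype(np.float32)
        x = np.zeros((200, 2, 8, 10), dtype=np.float32)
        for c in range(4):  # concept c elevates channels 2c, 2c+1
            x[:, :, 2 * c:2 * c + 2, :] += y[:, c, None, None, None] * 1.5
        x += rng.normal(0, 0.3, x.shape).astype(np.float32)
        m = small_model([(2, 8, 10)])
        cfg = TrainingConfig(lr=2e-3, epochs=5, batch_size=32,
                             min_combination_screentime_s=0.0, seed=0)
        hist = train(m, [x], y, cfg)
        assert hist["loss"][-1] < hist["loss"][0]
        assert np.all(np.diff(hist["loss"]) < 0.05)  # monotone up to noise


class TestBCE:
    def test_matches_reference_value(self):
        z = Tensor(np.array([[0.0, 2.0], [-1.0, 1.0]]), requires_grad=True)
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = bce_with_logits(z, y)
        p = 1 / (1 + np.exp(-z.data))
        ref = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert float(loss.data) == pytest.approx(ref, rel=1e-5)

    def test_gradient_is_sigmoid_minus_target_over_n(self):
        z = Tensor(np.array([[0.5, -0.5]]), requires_grad=True)
        y = np.array([[1.0, 0.0]])
        bce_with_logits(z, y).backward()
        p = 1 / (1 + np.exp(-z.data))
        np.testing.assert_allclose(z.grad, (p - y) / 2, rtol=1e-5)


class TestLogisticBaseline:
    def test_zero_input_gives_bias_only(self):
        m = LogisticBaseline([(2, 8, 50)], ModelConfig(**SMALL, seed=0))
        x = [np.zeros((3, 2, 8, 50), dtype=np.float32)]
        z = m.logits(x).data
        np.testing.assert_allclose(z, np.tile(m.lin.b.data, (3, 1)), atol=1e-7)

    def test_learns_linearly_separable_pattern(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, (300, 4)).astype(np.float32)
        x = rng.normal(0, 0.5, (300, 2, 8, 10)).astype(np.float32)
        for c in range(4):
            x[:, :, 2 * c, :] += y[:, c, None, None] * 1.0
        m = LogisticBaseline([(2, 8, 10)], ModelConfig(**SMALL, seed=0))
        cfg = TrainingConfig(lr=5e-3, epochs=10, batch_size=64,
                             min_combination_screentime_s=0.0, seed=1)
        train(m, [x], y, cfg)
        act = m.predict([x])
        aucs = [roc_auc(act[:, c], y[:, c]) for c in range(4)]
        assert min(aucs) > 0.9

    def test_xor_pattern_linear_fails_transformer_succeeds(self):
        """Concept = exactly one of two channels active: linearly
        inseparable, so the linear model stays near chance while the
        attention model separates it at a matched training budget."""
        rng = np.random.default_rng(9)

        def draw(n):
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            y = (a ^ b).astype(np.float32)[:, None] * np.ones((1, 4), np.float32)
            x = rng.normal(0, 0.25, (n, 2, 8, 10)).astype(np.float32)
            x[:, :, 0, :] += a[:, None, None] * 1.5
            x[:, :, 1, :] += b[:, None, None] * 1.5
            return x, y

        x, y = draw(480)
        x_test, y_test = draw(480)
        cfg = TrainingConfig(lr=2e-3, epochs=12, batch_size=64,
                             min_combination_screentime_s=0.0, seed=2)
        lin = LogisticBaseline([(2, 8, 10)], ModelConfig(**SMALL, seed=3))
        train(lin, [x], y, cfg)
        auc_lin = roc_auc(lin.predict([x_test])[:, 0], y_test[:, 0])
        tr = small_model([(2, 8, 10)], seed=3)
        train(tr, [x], y, cfg)
        auc_tr = roc_auc(tr.predict([x_test])[:, 0], y_test[:, 0])
        assert abs(auc_lin - 0.5) < 0.1
        assert auc_tr > 0.7
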