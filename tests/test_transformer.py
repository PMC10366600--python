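"""Masked-span Transformer: masking, loss locality, training contracts."""

import numpy as np
import pytest
from scipy import stats

from ethosim import transformer as tr
from ethosim.nn import Tensor
from ethosim.simulator import GeneratedSeries
from ethosim.transformer import (SpanTransformer, TransformerConfig,
                                 mask_span, slice_positions)


CLASSES = ["b00", "b01", "b02"]


def make_series(n=600, label="b01", value=0.0, periodic=None, seed=0):
    rng = np.random.default_rng(seed)
    x = np.full((n, 1), float(value))
    if periodic:
        x[:, 0] += np.sin(2 * np.pi * np.arange(n) / periodic)
    x += 0.05 * rng.standard_normal(x.shape)
    labs = np.array([label] * n)
    return GeneratedSeries(x, labs, labs.copy(), [], seed, "synthetic-constant")


@pytest.fixture(scope="module")
def tiny_model():
    cfg = TransformerConfig(epochs=1, n_layers=2, width=16, ff_hidden=32)
    return SpanTransformer(cfg, CLASSES, np.random.default_rng(0))


class TestMaskSpan:
    def test_span_length_default_config(self, rng):
        """20-sample sequences at ratio 0.45 mask exactly 9 samples."""
        seq = rng.standard_normal((20, 1))
        masked, start, length = mask_span(seq, 0.45, rng)
        assert length == 9
        assert TransformerConfig().span_length == 9

    def test_masked_run_contiguous(self, rng):
        seq = rng.standard_normal((20, 1)) + 5.0
        token = np.array([-99.0])
        masked, start, length = mask_span(seq, 0.45, rng, mask_token=token)
        hit = np.where(masked[:, 0] == -99.0)[0]
        assert len(hit) == length
        assert np.array_equal(hit, np.arange(start, start + length))
        # everything outside the span untouched
        out = np.r_[0:start, start + length:20]
        assert np.array_equal(masked[out], seq[out])

    def test_start_uniform(self, rng):
        """Chi-square goodness of fit for span starts over {0..11}."""
        counts = np.zeros(12)
        seq = np.zeros((20, 1))
        for _ in range(10_000):
            _, start, _ = mask_span(seq, 0.45, rng)
            counts[start] += 1
        _, p = stats.chisquare(counts)
        assert p > 1e-4

    def test_invalid_ratio(self, rng):
        for ratio in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                mask_span(np.zeros((20, 1)), ratio, rng)


class TestSlicePositions:
    def test_central_slice_20_5(self):
        assert slice_positions(20, 5).tolist() == [7, 8, 9, 10, 11]

    def test_slice_longer_than_seq_rejected(self):
        with pytest.raises(ValueError):
            TransformerConfig(seq_len=4, slice_len=5).validate()


class TestMaskedLossLocality:
    def test_unmasked_targets_do_not_affect_loss(self, tiny_model, rng):
        """Perturbing targets outside the span leaves the loss unchanged."""
        cfg = tiny_model.config
        X = rng.standard_normal((4, cfg.seq_len, 1))
        srng1 = np.random.default_rng(11)
        loss1 = float(tiny_model.reconstruction_loss(X, srng1).data)
        # recompute the same spans, then perturb unmasked positions
        srng2 = np.random.default_rng(11)
        L = cfg.span_length
        starts = np.random.default_rng(11).integers(0, cfg.seq_len - L + 1, 4)
        X2 = X.copy()
        for b, s in enumerate(starts):
            outside = np.r_[0:s, s + L:cfg.seq_len]
            X2[b, outside, 0] += 123.0
        # masked input differs outside the span, so encode the originals but
        # swap targets only: emulate by masking manually
        masked1, m = tiny_model._mask_batch(X, np.random.default_rng(11))
        recon = tiny_model.decoder(tiny_model._encode(masked1))
        diff1 = ((recon - Tensor(X)) * Tensor(m)).data
        diff2 = ((recon - Tensor(X2 * (1 - m) + X * m)) * Tensor(m)).data
        assert np.allclose((diff1 ** 2).sum(), (diff2 ** 2).sum())

    def test_gradient_zero_wrt_unmasked_targets(self, tiny_model, rng):
        cfg = tiny_model.config
        X = rng.standard_normal((2, cfg.seq_len, 1))
        masked, m = tiny_model._mask_batch(X, np.random.default_rng(5))
        target = Tensor(X, requires_grad=True)
        recon = tiny_model.decoder(tiny_model._encode(masked))
        diff = (recon - target) * Tensor(m)
        loss = (diff * diff).sum()
        loss.backward()
        assert np.all(target.grad[m[:, :, 0] == 0] == 0)
        assert np.any(target.grad[m[:, :, 0] == 1] != 0)


class TestClassifySlice:
    def test_distribution_sums_to_one(self, tiny_model, rng):
        dist = tiny_model.classify_slice(rng.standard_normal((20, 1)))
        assert dist.shape == (3,)
        assert dist.sum() == pytest.approx(1.0)

    def test_wrong_shape_errors(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.classify_slice(np.zeros((10, 1)))

    def test_agrees_with_predict_series(self, tiny_model):
        series = make_series(n=80)
        pred = tr.predict_series(tiny_model, series)
        # interior sample: its sequence is [i-9, i+11)
        i = 40
        dist = tiny_model.classify_slice(series.features[i - 9:i + 11])
        assert pred[i] == tiny_model.classes[int(np.argmax(dist))]


class TestFit:
    def test_constant_series_reconstruction(self):
        series = make_series(n=500, value=2.0)
        cfg = TransformerConfig(epochs=8, batches_per_epoch=12, batch_size=32,
                                n_layers=2, width=16, ff_hidden=32,
                                w_cls=0.0, seed=1)
        model, curves = tr.fit(series, cfg, classes=["b01"])
        assert curves["recon"].iloc[-1] < curves["recon"].iloc[0]
        assert curves["recon"].iloc[-1] < 0.3
        # span prediction close to the constant value
        rng = np.random.default_rng(2)
        seq = series.features[100:120]
        pred = model.reconstruct(seq, 7, 9)
        assert np.allclose(pred, 2.0, atol=0.5)

    def test_pure_pretraining_leaves_classifier_untrained(self):
        series = make_series(n=300)
        cfg = TransformerConfig(epochs=2, batches_per_epoch=4, batch_size=16,
                                n_layers=1, width=16, ff_hidden=16,
                                pretrain_epochs=2, seed=0)
        model, curves = tr.fit(series, cfg, classes=["b01"])
        fresh = SpanTransformer(cfg, ["b01"], np.random.default_rng(cfg.seed))
        assert np.array_equal(model.cls_out.W.data, fresh.cls_out.W.data)
        assert (curves["cls"] == 0).all()

    def test_deterministic(self):
        series = make_series(n=300)
        cfg = TransformerConfig(epochs=2, batches_per_epoch=4, batch_size=16,
                                n_layers=1, width=16, ff_hidden=16, seed=9)
        m1, _ = tr.fit(series, cfg, classes=["b01"])
        m2, _ = tr.fit(series, cfg, classes=["b01"])
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.data, p2.data)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            tr.fit(make_series(n=10), TransformerConfig(epochs=1))


class TestPositionalEncoding:
    def test_ablation_degrades_periodic_reconstruction(self):
        """Without positions the model cannot locate the span's phase, so
        masked reconstruction of a periodic signal degrades."""
        series = make_series(n=600, periodic=6, seed=4)
        common = dict(epochs=10, batches_per_epoch=10, batch_size=32,
                      n_layers=2, width=16, ff_hidden=32, w_cls=0.0, seed=3)
        _, with_pos = tr.fit(series, TransformerConfig(**common), classes=["b01"])
        _, without = tr.fit(series, TransformerConfig(use_positional=False,
                                                      **common), classes=["b01"])
        assert with_pos["recon"].iloc[-1] < without["recon"].iloc[-1]


class TestPredictSeries:
    def test_length_and_determinism(self, tiny_model):
        series = make_series(n=100)
        a = tr.predict_series(tiny_model, series)
        b = tr.predict_series(tiny_model, series)
        assert len(a) == len(series)
        assert np.array_equal(a, b)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, tiny_model):
        tr.save_model(tiny_model, tmp_path / "m")
        loaded = tr.load_model(tmp_path / "m")
        seq = np.random.default_rng(8).standard_normal((20, 1))
        assert np.allclose(loaded.classify_slice(seq),
                           tiny_model.classify_slice(seq))
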