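"""Surrogate architectures: layer arithmetic, SN module, MC dropout, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porediff import nn
from porediff.models import (
    Model,
    ModelKind,
    SNHead,
    SurrogateSpec,
    build_cnet,
    build_model,
    build_unet,
    build_unet_half,
    describe,
    mc_dropout_predict,
    sn_transform,
)

RNG = np.random.default_rng(20240917)


def small_unet_spec(**kw):
    defaults = dict(kind="UNET", input_side=16, dropout_p=0.1,
                    n_containers=2, blocks_per_container=1, channels=4)
    defaults.update(kw)
    return SurrogateSpec(**defaults)


class TestArchitectureArithmetic:
    def test_cnet_flatten_length_400(self):
        model = build_cnet(SurrogateSpec(kind="CNET", input_side=128))
        assert model.flatten_length == 400  # 100 channels x 2 x 2

    def test_cnet_forward_finite_two_vector(self):
        model = build_cnet(SurrogateSpec(kind="CNET", input_side=128))
        out = model.predict(RNG.random((2, 1, 128, 128)).astype(np.float32))
        assert out.shape == (2, 2)
        assert np.isfinite(out).all()

    def test_cnet_rejects_incompatible_input(self):
        with pytest.raises(ValueError):
            build_cnet(SurrogateSpec(kind="CNET", input_side=16))

    def test_unet_output_matches_input_shape(self):
        model = build_unet(small_unet_spec())
        x = RNG.random((2, 1, 16, 16)).astype(np.float32)
        assert model.predict(x).shape == x.shape

    def test_unet_half_bottleneck_arithmetic(self):
        # canonical encoder: 128 / 2^6 = 2, so 64*2*2 features at the flatten
        model = build_unet_half(
            SurrogateSpec(kind="UNET_HALF", input_side=128, n_containers=6,
                          blocks_per_container=1, channels=64)
        )
        assert model.flatten_length == 64 * 2 * 2

    def test_input_side_divisibility_enforced(self):
        with pytest.raises(ValueError):
            SurrogateSpec(kind="UNET", input_side=100, n_containers=3)

    def test_describe_reports_parameters(self):
        model = build_model(small_unet_spec())
        text = describe(model)
        assert "total parameters" in text
        assert str(model.n_parameters()) in text


class TestSNModule:
    @pytest.mark.parametrize(
        "y_top, pre, expect_out, expect_pen",
        [
            ((0.5, 0.8), (0.0, 0.0), (0.5, 0.8), 0.0),  # sigma(0)=1/2 identity
            ((1.0, 1.0), (np.log(3.0), 0.0), (1.5, 1.0), 0.25),
            ((1.0, 2.0), (50.0, 50.0), (2.0, 4.0), 2.0),  # sigma->1 limit
        ],
    )
    def test_transform_examples(self, y_top, pre, expect_out, expect_pen):
        out, pen = sn_transform(np.array(y_top), np.array(pre))
        assert out == pytest.approx(np.array(expect_out), abs=1e-9)
        assert pen == pytest.approx(expect_pen, abs=1e-9)

    @given(
        st.floats(-30, 30).map(lambda v: 0.0 if abs(v) < 1e-3 else v),
        st.floats(-30, 30).map(lambda v: 0.0 if abs(v) < 1e-3 else v),
    )
    @settings(max_examples=50, deadline=None)
    def test_factors_strictly_inside_0_2(self, p1, p2):
        _, pen = sn_transform(np.ones(2), np.array([p1, p2]))
        yb = 2.0 / (1.0 + np.exp(-np.array([p1, p2])))
        assert np.all(yb > 0.0) and np.all(yb < 2.0)
        assert pen >= 0.0
        assert (pen == 0.0) == (p1 == 0.0 and p2 == 0.0)

    def test_head_layer_matches_pure_transform(self):
        head = SNHead(4, rng=np.random.default_rng(0), dtype=np.float64)
        x = np.random.default_rng(1).random((3, 4))
        out = head.forward(x)
        yt = head.top.forward(x)
        pre = head.bottom.forward(x)
        expect, _ = sn_transform(yt, pre)
        assert out == pytest.approx(expect)


class TestMCDropout:
    def _scalar_model(self, p=0.1):
        spec = SurrogateSpec(kind="UNET_HALF", input_side=16, dropout_p=p,
                             n_containers=2, blocks_per_container=1, channels=4)
        return build_unet_half(spec, rng=np.random.default_rng(3))

    def test_zero_dropout_gives_zero_spread(self):
        model = self._scalar_model(p=0.0)
        x = RNG.random((2, 1, 16, 16)).astype(np.float32)
        res = mc_dropout_predict(model, x, M=5, seed=0)
        assert np.all(res.sigma == 0.0)
        assert res.mean == pytest.approx(model.predict(x))

    def test_fixed_seed_is_bit_reproducible(self):
        model = self._scalar_model()
        x = RNG.random((2, 1, 16, 16)).astype(np.float32)
        r1 = mc_dropout_predict(model, x, M=8, seed=7)
        r2 = mc_dropout_predict(model, x, M=8, seed=7)
        assert np.array_equal(r1.mean, r2.mean)
        assert np.array_equal(r1.sigma, r2.sigma)
        r3 = mc_dropout_predict(model, x, M=8, seed=8)
        assert not np.array_equal(r1.mean, r3.mean)

    def test_spread_stabilizes_with_many_passes(self):
        # toy 2-layer model: std estimate converges as M grows
        net = nn.Sequential(
            nn.Dense(4, 16, rng=np.random.default_rng(0)),
            nn.ReLU(),
            nn.Dropout(0.1),
            nn.Dense(16, 2, rng=np.random.default_rng(1)),
        )
        model = Model(SurrogateSpec(kind="CNET"), net)
        x = np.random.default_rng(2).random((1, 4))
        s500 = mc_dropout_predict(model, x, M=500, seed=0).sigma.mean()
        s1000 = mc_dropout_predict(model, x, M=1000, seed=1).sigma.mean()
        assert abs(s1000 - s500) / s1000 < 0.1

    def test_requires_dropout_layer(self):
        net = nn.Sequential(nn.Dense(4, 2))
        model = Model(SurrogateSpec(kind="CNET"), net)
        with pytest.raises(ValueError, match="dropout"):
            mc_dropout_predict(model, np.zeros((1, 4)), M=4)

    def test_m_floor(self):
        with pytest.raises(ValueError):
            mc_dropout_predict(self._scalar_model(), np.zeros((1, 1, 16, 16)), M=1)

    def test_deterministic_without_dropout(self):
        model = self._scalar_model()
        x = RNG.random((1, 1, 16, 16)).astype(np.float32)
        assert np.array_equal(model.predict(x), model.predict(x))


def numeric_grad_check(model, x, y, n_probe=4, eps=1e-6):
    """Finite-difference check of d(MSE+penalty)/dparam."""
    sn = model.sn_head

    def loss():
        pred = model.forward(x, training=True)
        val = float(((pred - y) ** 2).mean())
        if sn is not None:
            val += sn.mean_penalty()
        return val

    pred = model.forward(x, training=True)
    for p in model.params():
        p.grad[...] = 0.0
    model.backward((2.0 / pred.size) * (pred - y))
    worst = 0.0
    rng = np.random.default_rng(0)
    for p in model.params():
        flat = p.value.ravel()
        for idx in rng.choice(flat.size, size=min(n_probe, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[idx]
            worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
    return worst


class TestGradients:
    """Finite-difference validation of the hand-written backprop."""

    def test_unet_gradients(self):
        spec = small_unet_spec(input_side=8, dropout_p=0.0)
        model = build_unet(spec, rng=np.random.default_rng(1), dtype=np.float64)
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 1, 8, 8)), rng.normal(size=(2, 1, 8, 8))
        assert numeric_grad_check(model, x, y) < 1e-4

    def test_unet_half_with_sn_gradients(self):
        spec = SurrogateSpec(kind="UNET_HALF", input_side=8, dropout_p=0.0,
                             sn_enabled=True, n_containers=2,
                             blocks_per_container=1, channels=4)
        model = build_unet_half(spec, rng=np.random.default_rng(1), dtype=np.float64)
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(3, 1, 8, 8)), rng.normal(size=(3, 2))
        assert numeric_grad_check(model, x, y) < 1e-5

    def test_cnet_head_gradients(self):
        # the dense/tanh/linear head on a tiny standalone stack
        rng = np.random.default_rng(3)
        net = nn.Sequential(
            nn.Dense(6, 5, rng=rng, dtype=np.float64),
            nn.Tanh(),
            nn.Dense(5, 2, rng=rng, dtype=np.float64),
        )
        model = Model(SurrogateSpec(kind="CNET"), net)
        x, y = rng.normal(size=(4, 6)), rng.normal(size=(4, 2))
        assert numeric_grad_check(model, x, y) < 1e-7

    def test_batchnorm_train_mode_gradients(self):
        rng = np.random.default_rng(4)
        net = nn.Sequential(
            nn.Conv2d(1, 3, 3, pad=1, rng=rng, dtype=np.float64),
            nn.BatchNorm(3, dtype=np.float64),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense(3 * 36, 2, rng=rng, dtype=np.float64),
        )
        model = Model(SurrogateSpec(kind="CNET"), net)
        x, y = rng.normal(size=(4, 1, 6, 6)), rng.normal(size=(4, 2))
        assert numeric_grad_check(model, x, y) < 1e-5
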