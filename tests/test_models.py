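"""Model zoo: positional encoding, forward-pass oracle, masking, multitask
head routing, parameter accounting, and gradient correctness."""

import math

import numpy as np
import pytest
from scipy.special import erf

from methylsite import nn
from methylsite.embeddings import EmbeddedWindow
from methylsite.models import (
    MLPModel,
    MLPSpec,
    MultitaskHeadSpec,
    TransformerModel,
    TransformerSpec,
    load_checkpoint,
    methylsight2_default_spec,
    predict_multitask,
    predict_single,
    save_checkpoint,
    sinusoidal_positional_encoding,
)
from methylsite.records import PTM_TASKS, ValidationError

TINY = TransformerSpec(token_dim=6, embed_width=8, n_blocks=1, n_heads=2,
                       head_hidden_widths=(5,), dropout=0.0, context=5)


def _tiny_batch(rng, n=3, spec=TINY, masked=True):
    tokens = rng.normal(size=(n, spec.context, spec.token_dim))
    mask = np.ones((n, spec.context))
    if masked:
        mask[0, :2] = 0
        tokens[0, :2] = 0
    return tokens, mask


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = sinusoidal_positional_encoding(7, 10)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)

    def test_position_one_first_column(self):
        for width in (4, 10, 64):
            pe = sinusoidal_positional_encoding(3, width)
            assert pe[1, 0] == pytest.approx(math.sin(1.0))

    def test_closed_form_everywhere(self):
        context, width = 9, 12
        pe = sinusoidal_positional_encoding(context, width)
        for pos in range(context):
            for i in range(width // 2):
                angle = pos / 10000 ** (2 * i / width)
                assert pe[pos, 2 * i] == pytest.approx(math.sin(angle))
                assert pe[pos, 2 * i + 1] == pytest.approx(math.cos(angle))
        assert np.all(np.abs(pe) <= 1.0)

    def test_odd_width_rejected(self):
        with pytest.raises(ValidationError):
            sinusoidal_positional_encoding(5, 7)


def naive_forward(model, tokens, mask, task=None):
    """Independent scalar-loop re-implementation of the transformer path."""
    spec = model.spec
    scores = []
    for b in range(tokens.shape[0]):
        x = tokens[b].copy()
        m = mask[b]
        for t in range(spec.context):
            if m[t] == 0:
                x[t] = 0.0
        # pre-attention dense + positional encoding
        W, bb = model.dense_in.W.value, model.dense_in.b.value
        h = np.array([x[t] @ W + bb for t in range(spec.context)])
        h = h + model.pe
        for blk in model.blocks:
            h = naive_block(blk, h, m, spec)
        h = naive_layernorm(model.ln_out, h)
        for t in range(spec.context):
            if m[t] == 0:
                h[t] = 0.0
        flat = h.reshape(-1)
        head = model.heads[model._resolve_task(task)]
        z = flat
        for layer in head.layers:
            z = np.maximum(z @ layer.W.value + layer.b.value, 0.0)
        z = z @ head.out.W.value + head.out.b.value
        scores.append(1.0 / (1.0 + math.exp(-float(z[0]))))
    return np.array(scores)


def naive_layernorm(ln, h):
    out = np.empty_like(h)
    for t in range(h.shape[0]):
        mu = h[t].mean()
        var = ((h[t] - mu) ** 2).mean()
        out[t] = ln.gain.value * (h[t] - mu) / math.sqrt(var + ln.eps) \
            + ln.bias.value
    return out


def naive_block(blk, h, m, spec):
    hn = naive_layernorm(blk.ln1, h)
    T, E = hn.shape
    nh, dk = blk.attn.n_heads, blk.attn.dk
    Q = hn @ blk.attn.wq.W.value + blk.attn.wq.b.value
    K = hn @ blk.attn.wk.W.value + blk.attn.wk.b.value
    V = hn @ blk.attn.wv.W.value + blk.attn.wv.b.value
    ctx = np.zeros((T, E))
    for head in range(nh):
        sl = slice(head * dk, (head + 1) * dk)
        for t in range(T):
            logits = np.array([
                Q[t, sl] @ K[s, sl] / math.sqrt(dk) if m[s] == 1 else -1e9
                for s in range(T)
            ])
            w = np.exp(logits - logits.max())
            w = w / w.sum()
            ctx[t, sl] = sum(w[s] * V[s, sl] for s in range(T))
    a = h + ctx @ blk.attn.wo.W.value + blk.attn.wo.b.value
    an = naive_layernorm(blk.ln2, a)
    f1 = an @ blk.ff1.W.value + blk.ff1.b.value
    g1 = 0.5 * f1 * (1.0 + erf(f1 / math.sqrt(2.0)))
    return a + g1 @ blk.ff2.W.value + blk.ff2.b.value


class TestTransformerForward:
    def test_matches_independent_implementation(self, rng):
        model = TransformerModel(TINY, seed=9)
        tokens, mask = _tiny_batch(rng)
        expected = naive_forward(model, tokens, mask)
        got = model.score(tokens, mask)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_multitask_matches_independent_implementation(self, rng):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=2)
        tokens, mask = _tiny_batch(rng)
        for task in PTM_TASKS:
            np.testing.assert_allclose(
                model.score(tokens, mask, task=task),
                naive_forward(model, tokens, mask, task=task), atol=1e-6)

    def test_zero_final_layer_scores_half(self, rng):
        model = TransformerModel(TINY, seed=0)
        head = model.heads["single"]
        head.out.W.value[:] = 0.0
        head.out.b.value[:] = 0.0
        tokens, mask = _tiny_batch(rng)
        np.testing.assert_array_equal(model.score(tokens, mask), 0.5)

    def test_eval_mode_deterministic(self, rng):
        spec = TransformerSpec(token_dim=6, embed_width=8, n_blocks=1,
                               n_heads=2, head_hidden_widths=(5,),
                               dropout=0.4, context=5)
        model = TransformerModel(spec, seed=1)
        tokens, mask = _tiny_batch(rng, spec=spec)
        a = model.score(tokens, mask)
        b = model.score(tokens, mask)
        np.testing.assert_array_equal(a, b)

    def test_pad_content_invariance(self, rng):
        model = TransformerModel(TINY, seed=5)
        tokens, mask = _tiny_batch(rng)
        base = model.score(tokens, mask)
        corrupted = tokens.copy()
        corrupted[0, :2] = rng.normal(size=(2, TINY.token_dim)) * 50
        np.testing.assert_allclose(model.score(corrupted, mask), base,
                                   atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        model = TransformerModel(TINY, seed=0)
        with pytest.raises(ValidationError, match="5x7"):
            model.forward(rng.normal(size=(1, 5, 7)), np.ones((1, 5)))


class TestMultitaskHeads:
    def test_four_scores_in_range_and_task_dependent(self, rng):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=3)
        tokens, mask = _tiny_batch(rng, n=1)
        w = EmbeddedWindow(tokens=tokens[0], mask=mask[0])
        scores = {t: predict_multitask(model, w, t).score for t in PTM_TASKS}
        assert all(0.0 <= s <= 1.0 for s in scores.values())
        assert len(set(scores.values())) > 1

    def test_identical_head_parameters_give_identical_scores(self, rng):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=3)
        src = model.heads["methylation"]
        for t in PTM_TASKS[1:]:
            for p_dst, p_src in zip(model.heads[t].params(), src.params()):
                p_dst.value = p_src.value.copy()
        tokens, mask = _tiny_batch(rng, n=2)
        ref = model.score(tokens, mask, task="methylation")
        for t in PTM_TASKS[1:]:
            np.testing.assert_array_equal(model.score(tokens, mask, task=t),
                                          ref)

    def test_trunk_output_independent_of_requested_head(self, rng):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=3)
        tokens, mask = _tiny_batch(rng)
        flats = [model.trunk_forward(tokens, mask) for _ in PTM_TASKS]
        for f in flats[1:]:
            np.testing.assert_allclose(f, flats[0], atol=1e-6)

    def test_unknown_task_rejected(self, rng):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=0)
        tokens, mask = _tiny_batch(rng, n=1)
        with pytest.raises(ValidationError):
            model.score(tokens, mask, task="phosphorylation")


class TestParameterAccounting:
    @pytest.mark.parametrize("spec", [
        TINY,
        TransformerSpec(token_dim=12, embed_width=16, n_blocks=2, n_heads=4,
                        head_hidden_widths=(7, 3), dropout=0.1, context=7),
    ])
    def test_single_task_count_matches_closed_form(self, spec):
        model = TransformerModel(spec, seed=0)
        assert model.parameter_count() == spec.parameter_count()

    def test_multitask_count(self):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=0)
        expected = TINY.trunk_parameter_count() + sum(
            TINY.head_parameter_count((4,)) for _ in PTM_TASKS)
        assert model.parameter_count() == expected

    def test_full_scale_spec_is_buildable_arithmetic(self):
        spec, heads = methylsight2_default_spec()
        total = spec.trunk_parameter_count() + sum(
            spec.head_parameter_count(w) for w in heads.heads.values())
        assert total > 50_000_000  # full-scale model is GPU-sized

    def test_mlp_count(self):
        spec = MLPSpec(input_dim=10, hidden_widths=(8, 4), dropout=0.1)
        assert MLPModel(spec).parameter_count() == spec.parameter_count() \
            == 10 * 8 + 8 + 8 * 4 + 4 + 4 + 1


class TestGradients:
    def test_finite_difference_check(self, rng):
        model = TransformerModel(TINY, seed=3)
        tokens, mask = _tiny_batch(rng, n=2)
        y = np.array([1.0, 0.0])

        def loss():
            p = nn.sigmoid(model.forward(tokens, mask))
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        p = nn.sigmoid(model.forward(tokens, mask))
        model.backward((p - y) / len(y))
        params = model.trunk_params() + model.head_params()
        for param in params[::5]:
            flat = param.value.ravel()
            grad = param.grad.ravel()
            for idx in (0, flat.size // 2):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grad[idx], rel=1e-4, abs=1e-8)

    def test_inactive_head_gradients_absent(self, rng):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=1)
        tokens, mask = _tiny_batch(rng, n=2)
        all_params = model.params()
        for p in all_params:
            p.grad = None
        p = nn.sigmoid(model.forward(tokens, mask, task="acetylation"))
        model.backward(p - np.array([1.0, 0.0]))
        for t in PTM_TASKS:
            grads = [q.grad for q in model.heads[t].params()]
            if t == "acetylation":
                assert all(g is not None for g in grads)
            else:
                assert all(g is None for g in grads)
        assert all(q.grad is not None for q in model.trunk_params())


class TestMLPAndCheckpoint:
    def test_mlp_predict_single(self, rng):
        spec = MLPSpec(input_dim=6, hidden_widths=(4,))
        model = MLPModel(spec, seed=0)
        pred = predict_single(model, rng.normal(size=6))
        assert 0.0 <= pred.score <= 1.0

    def test_checkpoint_roundtrip_transformer(self, rng, tmp_path):
        heads = MultitaskHeadSpec({t: (4,) for t in PTM_TASKS})
        model = TransformerModel(TINY, heads, seed=8)
        tokens, mask = _tiny_batch(rng)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        for t in PTM_TASKS:
            np.testing.assert_array_equal(model.score(tokens, mask, task=t),
                                          back.score(tokens, mask, task=t))

    def test_checkpoint_roundtrip_mlp(self, rng, tmp_path):
        model = MLPModel(MLPSpec(input_dim=5, hidden_widths=(3,)), seed=4)
        x = rng.normal(size=(7, 5))
        path = tmp_path / "mlp.npz"
        save_checkpoint(model, path)
        np.testing.assert_array_equal(load_checkpoint(path).score(x),
                                      model.score(x))
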