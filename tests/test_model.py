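"""Transformer core: tokenization, attention, gradients, parameter count."""

import numpy as np
import pytest

from vfssvit import (
    FrameStack,
    ModelConfig,
    bce_from_logit,
    bce_loss,
    count_parameters,
    extract_patches,
    forward,
    forward_backward,
    init_params,
    load_checkpoint,
    resize_isotropic,
    save_checkpoint,
    unpatchify,
)
from vfssvit.model import CapacityError, _mhsa_fwd, embed_and_assemble

TINY = ModelConfig(tp=2, p=2, d=8, n_heads=2, n_layers=2, ffn_dim=16,
                   head_dims=(6, 4), input_hw=4)
SMALL = ModelConfig(tp=10, p=8, d=32, n_heads=4, n_layers=2, head_dims=(32, 16),
                    input_hw=64)


def tiny_tokens(rng, t=5):
    return extract_patches(rng.random((t, 4, 4)), TINY).tokens


class TestTokenization:
    def test_token_count_law_at_paper_scale(self):
        cfg = ModelConfig()  # Tp=25, P=16, input 256
        grid = extract_patches(np.zeros((100, 256, 256), dtype=np.float32), cfg)
        assert grid.grid_shape == (4, 16, 16)
        assert grid.tokens.shape == (1024, 6400)
        assert grid.pad_frames == 0

    def test_end_padding_to_next_multiple(self):
        cfg = ModelConfig(input_hw=256)
        grid = extract_patches(np.ones((30, 256, 256), dtype=np.float32), cfg)
        assert grid.pad_frames == 20
        assert grid.grid_shape[0] == 2
        video = unpatchify(grid, cfg)
        assert video.shape[0] == 50
        assert video[30:].max() == 0.0  # padding is zero and at the end
        assert video[:30].min() == 1.0

    def test_round_trip_identity_on_random_clips(self, rng):
        cfg = SMALL
        for _ in range(50):
            t = int(rng.integers(1, 35))
            video = rng.random((t, 64, 64))
            grid = extract_patches(video, cfg)
            back = unpatchify(grid, cfg)
            np.testing.assert_array_equal(back[:t], video)

    def test_non_divisible_spatial_size_rejected(self, rng):
        with pytest.raises(ValueError, match="not divisible"):
            extract_patches(rng.random((10, 60, 60)), SMALL)


class TestResize:
    def test_identity_at_target_size(self, rng):
        st = FrameStack(frames=rng.random((3, 64, 64)).astype(np.float32))
        assert resize_isotropic(st, 64) is st

    def test_constant_preserved(self):
        st = FrameStack(frames=np.full((2, 32, 32), 0.37, dtype=np.float32))
        out = resize_isotropic(st, 16)
        np.testing.assert_allclose(out.frames, 0.37, atol=1e-6)

    def test_checkerboard_downscale_preserves_mean(self):
        board = np.indices((512, 512)).sum(axis=0) % 2
        st = FrameStack(frames=board[None].astype(np.float32))
        out = resize_isotropic(st, 256)
        assert out.frames.shape == (1, 256, 256)
        assert abs(out.frames.mean() - board.mean()) < 0.01 * board.mean()


class TestEmbedding:
    def test_zero_patches_give_positional_embeddings(self, rng):
        params = init_params(TINY, 6, rng)
        z = embed_and_assemble(np.zeros((6, TINY.token_dim)), params)
        assert z.shape == (7, TINY.d)
        np.testing.assert_allclose(z[1:], params["pos"][1:7])

    def test_identity_projection_recovers_patches(self, rng):
        cfg = ModelConfig(tp=1, p=2, d=4, n_heads=2, n_layers=1, input_hw=4)
        params = init_params(cfg, 4, rng)
        params["embed.E"] = np.eye(4)
        x = rng.random((4, 4))
        z = embed_and_assemble(x, params)
        np.testing.assert_allclose(z[1:] - params["pos"][1:5], x)

    def test_capacity_error_names_token_count(self, rng):
        params = init_params(TINY, 4, rng)
        with pytest.raises(CapacityError, match="N=8"):
            embed_and_assemble(np.zeros((8, TINY.token_dim)), params)


class TestAttention:
    def test_rows_stochastic_across_layers_and_heads(self, rng):
        toks = tiny_tokens(rng, 9)
        params = init_params(TINY, toks.shape[0], rng)
        _, attns, _ = forward(params, toks, TINY, collect_attention=True)
        assert len(attns) == TINY.n_layers
        for a in attns:
            assert a.shape[0] == TINY.n_heads
            assert np.all(a >= 0)
            np.testing.assert_allclose(a.sum(-1), 1.0, atol=1e-5)

    def test_single_token_attention_is_identity(self, rng):
        d, h = 8, 2
        zn = rng.normal(size=(1, d))
        wq, wk, wv = (rng.normal(size=(d, d)) for _ in range(3))
        out, attn, cache = _mhsa_fwd(zn, wq, wk, wv, np.eye(d), h)
        np.testing.assert_allclose(attn, 1.0)
        np.testing.assert_allclose(out, zn @ wv)

    def test_matches_per_head_brute_force(self, rng):
        """Batched multi-head attention equals an explicit per-head loop."""
        d, h = 12, 3
        dh = d // h
        for _ in range(20):
            s = int(rng.integers(2, 9))
            zn = rng.normal(size=(s, d))
            wq, wk, wv, wo = (rng.normal(size=(d, d)) for _ in range(4))
            out, _, _ = _mhsa_fwd(zn, wq, wk, wv, wo, h)

            heads = []
            for i in range(h):
                sl = slice(i * dh, (i + 1) * dh)
                q, k, v = zn @ wq[:, sl], zn @ wk[:, sl], zn @ wv[:, sl]
                scores = q @ k.T / np.sqrt(dh)
                e = np.exp(scores - scores.max(axis=1, keepdims=True))
                a = e / e.sum(axis=1, keepdims=True)
                heads.append(a @ v)
            expected = np.concatenate(heads, axis=1) @ wo
            np.testing.assert_allclose(out, expected, atol=1e-5)


class TestEncoderLayer:
    def test_zeroed_output_projections_make_identity_layer(self, rng):
        params = init_params(TINY, 12, rng)
        for i in range(TINY.n_layers):
            params[f"enc.{i}.attn.Wo"] = np.zeros_like(params[f"enc.{i}.attn.Wo"])
            params[f"enc.{i}.ffn.W2"] = np.zeros_like(params[f"enc.{i}.ffn.W2"])
            params[f"enc.{i}.ffn.b2"] = np.zeros_like(params[f"enc.{i}.ffn.b2"])
        toks = tiny_tokens(rng)
        z0 = embed_and_assemble(toks, params)
        # with both residual branches zeroed the encoder is the identity, so
        # the final-LN input equals Z0; verify via a forward with L=0-like
        # behaviour: logits computed from LN(Z0) must match the model.
        from vfssvit.model import _ln_fwd

        pred, _, _ = forward(params, toks, TINY)
        zf, _ = _ln_fwd(z0, params["final_ln.g"], params["final_ln.b"])
        x = zf[0]
        for j in range(len(TINY.head_dims)):
            x = np.maximum(x @ params[f"head.{j}.W"] + params[f"head.{j}.b"], 0.0)
        logit = float(x @ params["head.out.w"] + params["head.out.b"])
        assert pred.logit == pytest.approx(logit, abs=1e-12)

    def test_hand_worked_three_token_layer(self, rng):
        """One encoder layer on a 3-token sequence vs an explicit scalar-loop
        recomputation of layer norm, attention, and the feed-forward block."""
        d, h, f = 4, 2, 6
        cfg = ModelConfig(tp=1, p=2, d=d, n_heads=h, n_layers=1, ffn_dim=f,
                          input_hw=2, head_type="linear")
        params = init_params(cfg, 3, rng)
        toks = rng.normal(size=(3, 4)) * 0.5
        z0 = embed_and_assemble(toks, params)

        def naive_ln(x, g, b, eps=1e-5):
            out = np.empty_like(x)
            for i in range(x.shape[0]):
                mu = sum(x[i]) / len(x[i])
                var = sum((v - mu) ** 2 for v in x[i]) / len(x[i])
                xhat = np.array([(v - mu) / np.sqrt(var + eps) for v in x[i]])
                out[i] = xhat * g + b
            return out

        def naive_softmax_row(row):
            e = [np.exp(v - max(row)) for v in row]
            return np.array(e) / sum(e)

        zn1 = naive_ln(z0, params["enc.0.ln1.g"], params["enc.0.ln1.b"])
        dh = d // h
        s = z0.shape[0]  # 3 patch tokens + 1 class token
        head_outs = []
        for i in range(h):
            sl = slice(i * dh, (i + 1) * dh)
            q = zn1 @ params["enc.0.attn.Wq"][:, sl]
            k = zn1 @ params["enc.0.attn.Wk"][:, sl]
            v = zn1 @ params["enc.0.attn.Wv"][:, sl]
            o = np.zeros_like(q)
            for a_row in range(s):
                w = naive_softmax_row([q[a_row] @ k[b_row] / np.sqrt(dh) for b_row in range(s)])
                for b_row in range(s):
                    o[a_row] += w[b_row] * v[b_row]
            head_outs.append(o)
        z1 = z0 + np.concatenate(head_outs, axis=1) @ params["enc.0.attn.Wo"]
        zn2 = naive_ln(z1, params["enc.0.ln2.g"], params["enc.0.ln2.b"])
        ffn = np.maximum(zn2 @ params["enc.0.ffn.W1"] + params["enc.0.ffn.b1"], 0.0)
        z2 = z1 + ffn @ params["enc.0.ffn.W2"] + params["enc.0.ffn.b2"]

        zf = naive_ln(z2, params["final_ln.g"], params["final_ln.b"])
        logit = zf[0] @ params["head.out.w"] + params["head.out.b"]

        pred, _, _ = forward(params, toks, cfg)
        assert pred.logit == pytest.approx(float(logit), abs=1e-8)


class TestHeadAndLoss:
    def test_zero_logit_gives_half(self, rng):
        params = init_params(TINY, 12, rng)
        params["head.out.w"] = np.zeros_like(params["head.out.w"])
        params["head.out.b"] = np.asarray(0.0)
        pred, _, _ = forward(params, tiny_tokens(rng), TINY)
        assert pred.y_hat == pytest.approx(0.5)

    def test_zero_weights_with_bias_give_sigmoid_of_bias(self, rng):
        from scipy.special import expit

        params = init_params(TINY, 12, rng)
        params["head.out.w"] = np.zeros_like(params["head.out.w"])
        params["head.out.b"] = np.asarray(1.7)
        pred, _, _ = forward(params, tiny_tokens(rng), TINY)
        assert pred.y_hat == pytest.approx(float(expit(1.7)))

    def test_bce_closed_forms(self):
        assert bce_loss(0.5, 1.0) == pytest.approx(np.log(2), abs=1e-12)
        assert bce_loss(1.0 - 1e-9, 1.0) < 1e-6
        assert bce_from_logit(0.0, 1.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_logit_gradient_matches_finite_differences(self, rng):
        from scipy.special import expit

        for _ in range(10):
            z = float(rng.normal(scale=3))
            y = float(rng.integers(0, 2))
            eps = 1e-6
            fd = (bce_from_logit(z + eps, y) - bce_from_logit(z - eps, y)) / (2 * eps)
            assert fd == pytest.approx(expit(z) - y, abs=1e-5)


class TestGradients:
    def test_full_model_gradient_matches_finite_differences(self, rng):
        toks = tiny_tokens(rng, 5)
        params = init_params(TINY, toks.shape[0], rng)
        _, _, grads = forward_backward(params, toks, 1.0, TINY)
        keys = sorted(params)
        for _ in range(3):
            direction = {k: rng.normal(size=params[k].shape) for k in keys}
            eps = 1e-6
            lp, _, _ = forward_backward(
                {k: params[k] + eps * direction[k] for k in keys}, toks, 1.0, TINY)
            lm, _, _ = forward_backward(
                {k: params[k] - eps * direction[k] for k in keys}, toks, 1.0, TINY)
            fd = (lp - lm) / (2 * eps)
            analytic = sum(float((grads[k] * direction[k]).sum()) for k in keys)
            assert analytic == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestPermutationInvariance:
    def test_output_invariant_when_positional_embeddings_are_zero(self, rng):
        toks = tiny_tokens(rng, 11)
        params = init_params(TINY, toks.shape[0], rng)
        params["pos"] = np.zeros_like(params["pos"])
        base, _, _ = forward(params, toks, TINY)
        for _ in range(20):
            perm = rng.permutation(toks.shape[0])
            pred, _, _ = forward(params, toks[perm], TINY)
            assert pred.y_hat == pytest.approx(base.y_hat, abs=1e-5)

    def test_forward_is_deterministic(self, rng):
        toks = tiny_tokens(rng, 7)
        params = init_params(TINY, toks.shape[0], rng)
        a, _, _ = forward(params, toks, TINY)
        b, _, _ = forward(params, toks, TINY)
        assert a.logit == b.logit


class TestParameterCount:
    def test_closed_form_matches_instantiation_default_config(self, rng):
        cfg = ModelConfig()
        params = init_params(cfg, 40, rng)
        assert count_parameters(cfg, 40) == sum(v.size for v in params.values())

    def test_additivity_in_layers(self):
        cfg8 = ModelConfig(n_layers=8)
        cfg9 = ModelConfig(n_layers=9)
        d, f = cfg8.d, cfg8.ffn_width
        per_layer = 2 * d + 4 * d * d + 2 * d + d * f + f + f * d + d
        assert count_parameters(cfg9, 10) - count_parameters(cfg8, 10) == per_layer

    def test_doubling_width_matches_instantiation(self, rng):
        for d in (32, 64):
            cfg = ModelConfig(d=d, n_heads=8)
            params = init_params(cfg, 12, rng)
            assert count_parameters(cfg, 12) == sum(v.size for v in params.values())


class TestCheckpoint:
    def test_roundtrip_preserves_params_and_config(self, tmp_path, rng):
        params = init_params(SMALL, 20, rng)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, params, SMALL, extra={"best_epoch": 3})
        p2, cfg2, extra = load_checkpoint(path)
        assert cfg2 == SMALL
        assert extra["best_epoch"] == 3
        assert set(p2) == set(params)
        for k in params:
            np.testing.assert_array_equal(p2[k], params[k])


def test_overfits_small_batch():
    """Gradient sanity: training loss on 8 clips collapses below 0.05."""
    import pandas as pd

    from vfssvit import SplitPlan, SyntheticConfig, TrainConfig, generate_study
    from vfssvit.train import AugmentConfig, train_model

    cfg = SyntheticConfig(n_subjects=4, clips_per_subject=2, frame_hw=(32, 32),
                          length_range=(10, 14), noise_sigma=0.02, seed=5)
    study = generate_study(cfg)
    clips = {f"c{i}": np.asarray(c.frames, float) for i, c in enumerate(study.clips)}
    labels = {f"c{i}": int(l) for i, l in enumerate(study.labels)}
    plan = SplitPlan(
        assignment={c: "train" for c in clips},
        folds={},
        subject_map={f"c{i}": s for i, s in enumerate(study.subject_ids)},
    )
    mcfg = ModelConfig(tp=5, p=8, d=16, n_heads=2, n_layers=1, head_dims=(8, 4),
                       input_hw=32)
    tcfg = TrainConfig(epochs=80, patience=80, lr=1e-3, grad_accum=4, seed=0,
                       aug=AugmentConfig(rot_deg=0, zoom_max=0, noise_sigma=0))
    res = train_model(clips, labels, plan, mcfg, tcfg)
    assert res.history["train_loss"].iloc[-1] < 0.05
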