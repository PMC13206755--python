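"""Architecture contracts: geometry, freezing, parameter accounting,
residual identities, checkpoint interchange."""

import numpy as np
import pytest

import fundusseg as fs
from fundusseg.model import PreAdapter, BottleneckAdapter, CBAM
from fundusseg.nn import Tensor, no_grad, resize_bicubic


RNG = np.random.default_rng(0)


def tiny_batch(n=2, size=64):
    return RNG.normal(size=(n, 3, size, size)).astype(np.float32)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_forward_shapes_through_the_pipeline(tiny_model, tiny_cfg):
    x = Tensor(tiny_batch())
    with no_grad():
        canvas = tiny_model.pre_adapter_forward(x)
        assert canvas.shape == (2, 3, 64, 64)
        tokens, taps = tiny_model.encoder_forward(canvas)
        g2 = tiny_cfg.grid_size ** 2
        assert tokens.shape == (2, g2, tiny_cfg.embed_dim)
        assert len(taps) == 4 and all(t.shape == tokens.shape for t in taps)
        maps = tiny_model.decoder_forward(tokens)
        assert maps.shape == (2, 3, tiny_cfg.grid_size, tiny_cfg.grid_size)
        skips = tiny_model.skip_branch_forward(taps)
        assert [s.shape[-1] for s in skips] == [64, 32, 16, 8]
        assert all(s.shape[1] == tiny_cfg.skip_channels for s in skips)
        logits = tiny_model.post_adapter_forward(maps, skips, (64, 64))
        assert logits.shape == (2, 3, 64, 64)


def test_output_side_follows_input_side(tiny_model):
    """Geometry invariance: logits come back at the input resolution."""
    with no_grad():
        out = tiny_model(tiny_batch(1, 96))
    assert out.shape == (1, 3, 96, 96)


def test_two_class_model_emits_two_planes():
    model = fs.build_model(fs.ModelConfig.tiny(num_classes=2), seed=0)
    with no_grad():
        out = model(tiny_batch(1))
    assert out.shape == (1, 2, 64, 64)


def test_pre_adapter_accommodates_other_input_sizes():
    cfg = fs.ModelConfig.canonical()
    pre = PreAdapter(cfg, np.random.default_rng(0))
    pre.eval()
    with no_grad():
        out = pre(Tensor(RNG.normal(size=(1, 3, 592, 592)).astype(np.float32)))
        assert out.shape == (1, 3, 224, 224)
        out = pre(Tensor(RNG.normal(size=(1, 3, 256, 256)).astype(np.float32)))
        assert out.shape == (1, 3, 224, 224)
    with pytest.raises(ValueError):
        pre(Tensor(np.zeros((1, 4, 256, 256), np.float32)))
    with pytest.raises(ValueError):
        pre(Tensor(np.zeros((1, 3, 16, 16), np.float32)))


@pytest.mark.parametrize("bad", [
    dict(canvas_size=225),                       # not divisible by patch
    dict(patch_size=12, canvas_size=60),         # stage count not integral
    dict(skip_taps=(2, 1, 3, 4)),                # not increasing
    dict(skip_taps=(1, 2, 3, 9)),                # tap beyond depth
    dict(num_classes=4),
    dict(norm_kind="instance"),
])
def test_invalid_configurations_are_rejected(bad):
    with pytest.raises(ValueError):
        fs.ModelConfig.tiny(**bad)


# ---------------------------------------------------------------------------
# freezing and parameter accounting
# ---------------------------------------------------------------------------

def test_backbone_frozen_adapters_trainable(tiny_model):
    frozen = {n for n, p in tiny_model.named_parameters() if p.frozen}
    trainable = {n for n, p in tiny_model.named_parameters() if not p.frozen}
    assert any(n.startswith("encoder.patch_embed") for n in frozen)
    assert "encoder.pos_embed" in frozen
    assert all(".adapter." in n or not n.startswith("encoder.") for n in trainable)


def test_unfreeze_last_n_marks_only_the_tail_trainable():
    model = fs.build_model(fs.ModelConfig.tiny(unfreeze_last_n=2), seed=0)
    for name, p in model.encoder.named_parameters():
        if ".adapter." in name or not name.startswith("blocks."):
            continue
        idx = int(name.split(".")[1][len("layer"):])
        assert p.frozen == (idx < 2), name


def adapter_count(d, mid):
    return (d * mid + mid) + (mid * d + d)


def cnn_block_count(cin, cout):
    return (cin * cout * 9 + cout) + 2 * cout


def expected_tunable(cfg: fs.ModelConfig) -> int:
    """Closed-form per-module parameter counts, derived independently."""
    d, dd, k, c = cfg.embed_dim, cfg.decoder_dim, cfg.num_classes, cfg.skip_channels
    total = 0
    if cfg.use_block_adapters:
        total += cfg.depth * adapter_count(d, cfg.adapter_mid)
    vit_block = (4 * d) + (d * 3 * d + 3 * d) + (d * d + d) + (d * 4 * d + 4 * d) + (4 * d * d + d)
    total += cfg.unfreeze_last_n * vit_block
    dec_block = (4 * dd) + (dd * 3 * dd + 3 * dd) + (dd * dd + dd) \
        + (dd * 4 * dd + 4 * dd) + (4 * dd * dd + dd)
    total += (d * dd + dd) + k * dd + cfg.decoder_depth * dec_block \
        + 2 * dd + 2 * dd * dd + 2 * k
    if cfg.use_pre_adapter:
        total += cnn_block_count(3, 64) + cnn_block_count(64, 64) + (64 * 3 * 9 + 3) + 3
    if cfg.use_skips:
        mid_c = min(c, max(c // 16, 4))
        cbam = (c * mid_c + mid_c) + (mid_c * c + c) + (2 * 49 + 1)
        total += 4 * ((d * c + c) + cnn_block_count(c, c) + cbam)
    if cfg.use_post_adapter:
        total += cnn_block_count(k, c) + 3 * cnn_block_count(c, c)
        if cfg.use_skips:
            total += 4 * cnn_block_count(2 * c, c)
        total += cnn_block_count(c, c) + (c * k + k)
    return total


@pytest.mark.parametrize("overrides", [
    {},
    dict(num_classes=2),
    dict(embed_dim=48, num_heads=4, decoder_dim=32, decoder_heads=2),
    dict(depth=5, skip_taps=(1, 3, 4, 5), unfreeze_last_n=1),
    dict(use_skips=False),
    dict(use_pre_adapter=False, use_block_adapters=False),
    dict(use_post_adapter=False, use_skips=False),
    dict(skip_channels=8, adapter_mid=8, decoder_depth=1),
    dict(unfreeze_last_n=2),
])
def test_tunable_count_matches_closed_form(overrides):
    cfg = fs.ModelConfig.tiny(**overrides)
    model = fs.build_model(cfg, seed=0)
    assert fs.count_tunable_parameters(model) == expected_tunable(cfg)


def test_single_bottleneck_adapter_count_closed_form():
    adapter = BottleneckAdapter(1024, 128, np.random.default_rng(0))
    n = sum(p.data.size for p in adapter.parameters())
    assert n == adapter_count(1024, 128) == 263_296


def test_frozen_encoder_size_is_vit_large_scale(tiny_model, tiny_cfg):
    d = tiny_cfg.embed_dim
    per_block = (4 * d) + (d * 3 * d + 3 * d) + (d * d + d) + (d * 4 * d + 4 * d) + (4 * d * d + d)
    expected = (3 * 16 * 16 * d + d) + tiny_cfg.grid_size ** 2 * d \
        + tiny_cfg.depth * per_block + 2 * d
    assert fs.count_frozen_parameters(tiny_model) == expected


# ---------------------------------------------------------------------------
# residual identities
# ---------------------------------------------------------------------------

def test_zero_adapter_up_projection_reproduces_adapter_free_encoder(tiny_cfg):
    model = fs.build_model(tiny_cfg, seed=3)
    x = Tensor(tiny_batch(1))
    with no_grad():
        canvas = model.pre_adapter_forward(x)
    for block in model.encoder.blocks._layers:
        block.adapter.up.weight.data[:] = 0.0
        block.adapter.up.bias.data[:] = 0.0
    with no_grad():
        with_adapters, _ = model.encoder_forward(canvas)
    saved = []
    for block in model.encoder.blocks._layers:
        saved.append(block.adapter)
        object.__setattr__(block, "adapter", None)
    try:
        with no_grad():
            without, _ = model.encoder_forward(canvas)
    finally:
        for block, ad in zip(model.encoder.blocks._layers, saved):
            object.__setattr__(block, "adapter", ad)
    assert np.array_equal(with_adapters.data, without.data)


def test_zero_cnn_path_reduces_pre_adapter_to_plain_bicubic(tiny_cfg):
    model = fs.build_model(tiny_cfg, seed=4)
    model.eval()
    model.pre_adapter.conv_out.weight.data[:] = 0.0
    model.pre_adapter.conv_out.bias.data[:] = 0.0
    x = Tensor(tiny_batch(2, 96))
    with no_grad():
        out = model.pre_adapter_forward(x)
        ref = resize_bicubic(x, 64, 64)
    assert np.array_equal(out.data, ref.data)


def test_cbam_with_unit_gates_is_identity():
    cbam = CBAM(16, np.random.default_rng(0))
    cbam.fc1.weight.data[:] = 0.0
    cbam.fc2.weight.data[:] = 0.0
    cbam.fc2.bias.data[:] = 100.0       # sigmoid(100) == 1.0 in float32
    cbam.spatial_conv.weight.data[:] = 0.0
    cbam.spatial_conv.bias.data[:] = 100.0
    x = Tensor(RNG.normal(size=(2, 16, 8, 8)).astype(np.float32))
    with no_grad():
        out = cbam(x)
    assert np.array_equal(out.data, x.data)


def test_mask_product_zero_patches_give_zero_scores(tiny_model):
    dec = tiny_model.decoder
    patches = Tensor(np.zeros((1, 16, 64), np.float32))
    cls = Tensor(RNG.normal(size=(1, 3, 64)).astype(np.float32))
    with no_grad():
        scores = dec.mask_product(patches, cls)
    assert np.allclose(scores.data, 0.0)


def test_mask_product_orthogonal_features_give_zero_score(tiny_model):
    dec = tiny_model.decoder
    d = 64
    # choose patch/class inputs whose projections are orthogonal by construction
    dec.proj_patch.data = np.eye(d, dtype=np.float32)
    dec.proj_classes.data = np.eye(d, dtype=np.float32)
    patches = np.zeros((1, 2, d), np.float32)
    patches[0, :, 0] = 1.0
    cls = np.zeros((1, 3, d), np.float32)
    cls[0, :, 1] = 1.0  # orthogonal to every patch feature
    with no_grad():
        scores = dec.mask_product(Tensor(patches), Tensor(cls))
    assert np.allclose(scores.data, 0.0, atol=1e-6)


# ---------------------------------------------------------------------------
# prediction contract
# ---------------------------------------------------------------------------

def test_predict_probabilities_form_a_simplex(tiny_model):
    probs, labels = tiny_model.predict(tiny_batch(2))
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    assert set(np.unique(labels)) <= {0, 1, 2}


def test_constant_logits_break_ties_toward_class_zero(tiny_cfg):
    model = fs.build_model(tiny_cfg, seed=5)
    model.post_adapter.out_conv.weight.data[:] = 0.0
    model.post_adapter.out_conv.bias.data[:] = 0.0     # all logits tie
    _, labels = model.predict(tiny_batch(1))
    assert np.all(labels == 0)
    model.post_adapter.out_conv.bias.data[:] = np.array([5.0, 0.0, 0.0])
    _, labels = model.predict(tiny_batch(1))
    assert np.all(labels == 0)                          # background strictly maximal


# ---------------------------------------------------------------------------
# persistence and checkpoint interchange
# ---------------------------------------------------------------------------

def test_save_load_roundtrip_preserves_predictions(tiny_model, tmp_path):
    x = tiny_batch(1)
    probs0, labels0 = tiny_model.predict(x)
    fs.save_model(tiny_model, tmp_path, name="model")
    reloaded = fs.load_model(tmp_path, name="model")
    probs1, labels1 = reloaded.predict(x)
    assert np.array_equal(labels0, labels1)
    np.testing.assert_allclose(probs0, probs1, atol=1e-6)
    import json

    sidecar = json.loads((tmp_path / "model.json").read_text())
    assert sidecar["tunable_parameters"] == fs.count_tunable_parameters(tiny_model)


def _mae_named_encoder_state(model):
    cfg = model.cfg
    enc = model.encoder
    p = cfg.patch_size
    state = {
        "patch_embed.proj.weight": enc.patch_embed.weight.data.reshape(
            cfg.embed_dim, 3, p, p),
        "patch_embed.proj.bias": enc.patch_embed.bias.data,
        "pos_embed": np.concatenate(
            [np.zeros((1, 1, cfg.embed_dim), np.float32), enc.pos_embed.data], axis=1
        ),  # with a class-token row, as MAE checkpoints carry
        "norm.weight": enc.norm.weight.data,
        "norm.bias": enc.norm.bias.data,
        "cls_token": np.zeros((1, 1, cfg.embed_dim), np.float32),  # ignored
    }
    for i, blk in enumerate(enc.blocks._layers):
        for sub, param in [
            ("norm1.weight", blk.norm1.weight), ("norm1.bias", blk.norm1.bias),
            ("attn.qkv.weight", blk.attn.qkv.weight), ("attn.qkv.bias", blk.attn.qkv.bias),
            ("attn.proj.weight", blk.attn.proj.weight), ("attn.proj.bias", blk.attn.proj.bias),
            ("norm2.weight", blk.norm2.weight), ("norm2.bias", blk.norm2.bias),
            ("mlp.fc1.weight", blk.mlp.fc1.weight), ("mlp.fc1.bias", blk.mlp.fc1.bias),
            ("mlp.fc2.weight", blk.mlp.fc2.weight), ("mlp.fc2.bias", blk.mlp.fc2.bias),
        ]:
            state[f"blocks.{i}.{sub}"] = param.data
    return state


def test_mae_checkpoint_import_transfers_encoder(tiny_cfg, tmp_path):
    donor = fs.build_model(tiny_cfg, seed=7)
    np.savez(tmp_path / "enc.npz", **_mae_named_encoder_state(donor))
    recipient = fs.build_model(tiny_cfg, pretrained=tmp_path / "enc.npz", seed=8)
    report = recipient._import_report
    assert "pos_embed" in report["matched"]
    assert "cls_token" in report["unmatched"]
    for model in (donor, recipient):  # silence the (non-checkpoint) adapters
        for blk in model.encoder.blocks._layers:
            blk.adapter.up.weight.data[:] = 0.0
            blk.adapter.up.bias.data[:] = 0.0
    x = Tensor(tiny_batch(1))
    with no_grad():
        a, _ = donor.encoder_forward(donor.pre_adapter_forward(x) * 0 + 1.0)
        b, _ = recipient.encoder_forward(recipient.pre_adapter_forward(x) * 0 + 1.0)
    np.testing.assert_allclose(a.data, b.data, atol=1e-6)


def test_checkpoint_geometry_mismatch_names_the_offender(tiny_cfg, tmp_path):
    state = {"patch_embed.proj.weight": np.zeros((10, 3, 16, 16), np.float32)}
    np.savez(tmp_path / "bad.npz", **state)
    with pytest.raises(ValueError, match="patch_embed.proj.weight"):
        fs.build_model(tiny_cfg, pretrained=tmp_path / "bad.npz", seed=0)
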