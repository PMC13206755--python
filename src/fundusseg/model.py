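"""Adapter-based segmentation network around a frozen ViT encoder.

The architecture adapts a masked-autoencoder-pretrained ViT-large retinal
encoder to joint optic-disc / optic-cup segmentation while keeping the
backbone frozen.  Five trainable components surround it:

* **Pre-adapter** — a light convolutional path (3→64→64→3) whose output is
  bicubically downsampled to the 224-pixel encoder canvas and added, scaled
  by three per-channel scalars (init 0.1), to a plain bicubic downsample of
  the input.  This accommodates arbitrary input sizes without touching the
  encoder's positional embeddings.
* **ViT block adapters** — bottlenecks (width→mid→width, GELU, residual)
  inserted between the first layer norm and the multi-head attention of every
  encoder block.
* **Mask-transformer decoder** — 2 transformer blocks over the patch tokens
  plus K learned class embeddings; mask maps are inner products between
  L2-normalised projected class embeddings and patch features.
* **Skip branches with CBAM** — token maps tapped after encoder blocks
  (6, 12, 18, 24 canonically) are projected to 64 channels, upsampled to
  224/112/56/28, passed through a CNN block and channel-then-spatial
  attention gates.
* **Post-adapter** — four [CNN block → ×2 bicubic] stages carry the K×14×14
  mask maps to canvas size, fusing the same-side skip map after each stage,
  followed by a CNN block, a 1×1 output convolution and a final bicubic
  resize to the input resolution.

A softmax over the K output planes yields per-pixel class probabilities;
argmax (ties to the lowest class index) yields the label mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
    concat,
    gelu,
    make_norm2d,
    matmul,
    no_grad,
    relu,
    reshape,
    resize_bicubic,
    sigmoid,
    softmax,
    tmax,
    tmean,
    transpose,
    trunc_normal,
    tsum,
)
from .nn.tensor import swap_last2


def _l2norm(x: Tensor) -> Tensor:
    return x * (tsum(x * x, axis=-1, keepdims=True) + 1e-12) ** -0.5


class BasicCNNBlock(Module):
    """3×3 convolution → normalization → ReLU (the model's basic CNN block)."""

    def __init__(self, in_ch: int, out_ch: int, norm_kind: str, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.norm = make_norm2d(norm_kind, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.norm(self.conv(x)))


class PreAdapter(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.block1 = BasicCNNBlock(3, 64, cfg.norm_kind, rng)
        self.block2 = BasicCNNBlock(64, 64, cfg.norm_kind, rng)
        self.conv_out = Conv2d(64, 3, 3, rng, padding=1)
        self.channel_scale = Parameter(np.full(3, 0.1, dtype=np.float32))
        self.canvas = cfg.canvas_size

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError(f"Pre-adapter expects 3-channel input, got {x.shape[1]}")
        if min(x.shape[2], x.shape[3]) < 32:
            raise ValueError("Pre-adapter input must be at least 32 pixels per side")
        main = relu(self.conv_out(self.block2(self.block1(x))))
        main = resize_bicubic(main, self.canvas, self.canvas)
        residual = resize_bicubic(x, self.canvas, self.canvas)
        return residual + reshape(self.channel_scale, (1, 3, 1, 1)) * main


class BottleneckAdapter(Module):
    """width → mid → width bottleneck with GELU and a residual skip."""

    def __init__(self, dim: int, mid: int, rng):
        super().__init__()
        self.down = Linear(dim, mid, rng)
        self.up = Linear(mid, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.up(gelu(self.down(x)))


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = reshape(self.qkv(x), (b, n, 3, self.heads, self.head_dim))
        qkv = transpose(qkv, (2, 0, 3, 1, 4))  # 3,B,H,N,hd
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = softmax(matmul(q, swap_last2(k)) * self.scale, axis=-1)
        out = transpose(matmul(attn, v), (0, 2, 1, 3))  # B,N,H,hd
        return self.proj(reshape(out, (b, n, d)))


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-norm ViT block; optional bottleneck adapter between LN and MHA."""

    def __init__(self, dim: int, heads: int, rng, adapter_mid: int | None = None):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        if adapter_mid is not None:
            self.adapter = BottleneckAdapter(dim, adapter_mid, rng)
        else:
            self.adapter = None
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, 4 * dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        if self.adapter is not None:
            h = self.adapter(h)
        x = x + self.attn(h)
        return x + self.mlp(self.norm2(x))


class ViTEncoder(Module):
    """Patch embedding + positional embeddings + ``depth`` transformer blocks.

    Runs with no class token: the fine-tuned forward path carries exactly
    grid² patch tokens.  Outputs the final-norm tokens plus the raw token
    sequences tapped after the blocks listed in ``skip_taps`` (1-indexed).
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        p, d = cfg.patch_size, cfg.embed_dim
        self.patch_embed = Linear(3 * p * p, d, rng)
        n = cfg.grid_size ** 2
        self.pos_embed = Parameter(trunc_normal(rng, (1, n, d)))
        mid = cfg.adapter_mid if cfg.use_block_adapters else None
        self.blocks = nn.Sequential(
            *[TransformerBlock(d, cfg.num_heads, rng, adapter_mid=mid)
              for _ in range(cfg.depth)]
        )
        self.norm = LayerNorm(d)
        self.cfg = cfg

    def patchify(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        p, g = self.cfg.patch_size, self.cfg.grid_size
        x = reshape(x, (b, 3, g, p, g, p))
        x = transpose(x, (0, 2, 4, 1, 3, 5))  # B,gh,gw,C,ph,pw
        return reshape(x, (b, g * g, 3 * p * p))

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        if x.shape[-1] != self.cfg.canvas_size or x.shape[-2] != self.cfg.canvas_size:
            raise ValueError(
                f"encoder expects {self.cfg.canvas_size}² input, got "
                f"{x.shape[-2]}×{x.shape[-1]}"
            )
        tokens = self.patch_embed(self.patchify(x)) + self.pos_embed
        taps = []
        tap_set = set(self.cfg.skip_taps)
        for i, block in enumerate(self.blocks._layers, start=1):
            tokens = block(tokens)
            if i in tap_set:
                taps.append(tokens)
        return self.norm(tokens), taps


class MaskTransformerDecoder(Module):
    """Mask-transformer decoder: class embeddings attend with patch tokens.

    K class embeddings are appended to the projected token sequence; after the
    decoder blocks, patch and class features are projected (scaled random
    square matrices), L2-normalised, and their inner products — normalised per
    pixel across classes — form the K×grid×grid mask maps.
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        d = cfg.decoder_dim
        self.proj_in = Linear(cfg.embed_dim, d, rng)
        self.cls_emb = Parameter(trunc_normal(rng, (1, cfg.num_classes, d)))
        self.blocks = nn.Sequential(
            *[TransformerBlock(d, cfg.decoder_heads, rng) for _ in range(cfg.decoder_depth)]
        )
        self.norm = LayerNorm(d)
        scale = d ** -0.5
        self.proj_patch = Parameter(scale * rng.standard_normal((d, d)).astype(np.float32))
        self.proj_classes = Parameter(scale * rng.standard_normal((d, d)).astype(np.float32))
        self.mask_norm = LayerNorm(cfg.num_classes)
        self.cfg = cfg

    def mask_product(self, patches: Tensor, cls: Tensor) -> Tensor:
        """Inner products between projected, L2-normalised class embeddings
        and patch features → (B, N, K) mask scores."""
        patches = _l2norm(matmul(patches, self.proj_patch))
        cls = _l2norm(matmul(cls, self.proj_classes))
        return matmul(patches, swap_last2(cls))

    def forward(self, tokens: Tensor) -> Tensor:
        b, n, _ = tokens.shape
        k, g = self.cfg.num_classes, self.cfg.grid_size
        x = self.proj_in(tokens)
        cls = self.cls_emb + np.zeros((b, 1, 1), dtype=np.float32)  # broadcast over batch
        x = concat([x, cls], axis=1)
        x = self.norm(self.blocks(x))
        masks = self.mask_norm(self.mask_product(x[:, :n], x[:, n:]))
        return transpose(reshape(masks, (b, g, g, k)), (0, 3, 1, 2))


class CBAM(Module):
    """Channel-then-spatial multiplicative attention gates."""

    def __init__(self, channels: int, rng, reduction: int = 16, spatial_kernel: int = 7):
        super().__init__()
        mid = min(channels, max(channels // reduction, 4))
        self.fc1 = Linear(channels, mid, rng)
        self.fc2 = Linear(mid, channels, rng)
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, rng, padding=spatial_kernel // 2)

    def _gate_mlp(self, pooled: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(pooled)))

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        avg = tmean(x, axis=(2, 3))
        mx = tmax(x, axis=(2, 3))
        ch_gate = sigmoid(self._gate_mlp(avg) + self._gate_mlp(mx))
        x = x * reshape(ch_gate, (b, c, 1, 1))
        sp = concat([tmean(x, axis=1, keepdims=True), tmax(x, axis=1, keepdims=True)], axis=1)
        sp_gate = sigmoid(self.spatial_conv(sp))
        return x * sp_gate


class SkipBranch(Module):
    """1×1 projection → bicubic upsample → CNN block → CBAM for one tap."""

    def __init__(self, cfg: ModelConfig, target_side: int, rng):
        super().__init__()
        self.proj = Conv2d(cfg.embed_dim, cfg.skip_channels, 1, rng)
        self.block = BasicCNNBlock(cfg.skip_channels, cfg.skip_channels, cfg.norm_kind, rng)
        self.cbam = CBAM(cfg.skip_channels, rng)
        self.target_side = target_side
        self.grid = cfg.grid_size

    def forward(self, tap: Tensor) -> Tensor:
        b, n, d = tap.shape
        g = self.grid
        if n != g * g:
            raise ValueError(f"skip tap has {n} tokens, expected {g * g}")
        fmap = transpose(reshape(tap, (b, g, g, d)), (0, 3, 1, 2))
        fmap = self.proj(fmap)
        fmap = resize_bicubic(fmap, self.target_side, self.target_side)
        return self.cbam(self.block(fmap))


class PostAdapter(Module):
    """Progressive ×2 upsampling of the mask maps with skip fusion."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        c, k = cfg.skip_channels, cfg.num_classes
        kind = cfg.norm_kind
        stages = []
        for i in range(cfg.num_stages):
            stages.append(BasicCNNBlock(k if i == 0 else c, c, kind, rng))
        self.stages = nn.Sequential(*stages)
        if cfg.use_skips:
            self.fusions = nn.Sequential(
                *[BasicCNNBlock(2 * c, c, kind, rng) for _ in range(cfg.num_stages)]
            )
        else:
            self.fusions = None
        self.final_block = BasicCNNBlock(c, c, kind, rng)
        self.out_conv = Conv2d(c, k, 1, rng)
        self.cfg = cfg

    def forward(self, mask_maps: Tensor, skips: list[Tensor] | None,
                out_hw: tuple[int, int]) -> Tensor:
        cfg = self.cfg
        x = mask_maps
        side = cfg.grid_size
        if x.shape[-1] != side:
            raise ValueError(f"mask maps side {x.shape[-1]} != grid size {side}")
        use_skips = self.fusions is not None and skips is not None
        if use_skips and len(skips) != 4:
            raise ValueError(f"expected 4 skip maps, got {len(skips)}")
        for i, stage in enumerate(self.stages._layers):
            x = stage(x)
            side *= 2
            x = resize_bicubic(x, side, side)
            if use_skips:
                skip = skips[len(skips) - 1 - i]  # deepest tap pairs with smallest side
                if skip.shape[-1] != side:
                    raise ValueError(
                        f"stage {i + 1}: skip map side {skip.shape[-1]} "
                        f"does not match stage side {side}"
                    )
                x = self.fusions._layers[i](concat([x, skip], axis=1))
        x = self.out_conv(self.final_block(x))
        return resize_bicubic(x, out_hw[0], out_hw[1])


class SegmentationModel(Module):
    """Full pipeline: Pre-adapter → encoder → decoder → skips → Post-adapter."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        if cfg.use_pre_adapter:
            self.pre_adapter = PreAdapter(cfg, rng)
        else:
            self.pre_adapter = None
        self.encoder = ViTEncoder(cfg, rng)
        self.decoder = MaskTransformerDecoder(cfg, rng)
        if cfg.use_skips:
            sides = [cfg.canvas_size >> i for i in range(4)]  # canvas, /2, /4, /8
            self.skip_branches = nn.Sequential(
                *[SkipBranch(cfg, side, rng) for side in sides]
            )
        else:
            self.skip_branches = None
        if cfg.use_post_adapter:
            self.post_adapter = PostAdapter(cfg, rng)
        else:
            self.post_adapter = None
        self._freeze_backbone()

    # -- freezing -------------------------------------------------------------
    def _freeze_backbone(self):
        """Freeze the encoder backbone (not the block adapters)."""
        cfg = self.cfg
        thaw_from = cfg.depth - cfg.unfreeze_last_n
        for name, p in self.encoder.named_parameters():
            if name.startswith("blocks.layer"):
                idx = int(name.split(".")[1][len("layer"):])
                if ".adapter." in name:
                    p.frozen = False
                else:
                    p.frozen = idx < thaw_from
            else:  # patch_embed, pos_embed, final norm
                p.frozen = True
            # frozen weights need no gradient of their own (activations still
            # propagate through them to reach the adapters below)
            p.requires_grad = not p.frozen

    # -- forward passes (spec operations) -------------------------------------
    def pre_adapter_forward(self, x: Tensor) -> Tensor:
        if self.pre_adapter is not None:
            return self.pre_adapter(x)
        return resize_bicubic(nn.as_tensor(x), self.cfg.canvas_size, self.cfg.canvas_size)

    def encoder_forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        return self.encoder(nn.as_tensor(x))

    def decoder_forward(self, tokens: Tensor) -> Tensor:
        return self.decoder(nn.as_tensor(tokens))

    def skip_branch_forward(self, taps: list[Tensor]) -> list[Tensor]:
        if self.skip_branches is None:
            raise RuntimeError("model was built with use_skips=False")
        if len(taps) != 4:
            raise ValueError(f"expected 4 taps, got {len(taps)}")
        return [br(tap) for br, tap in zip(self.skip_branches._layers, taps)]

    def post_adapter_forward(self, mask_maps: Tensor, skips, out_hw) -> Tensor:
        if self.post_adapter is None:
            return resize_bicubic(nn.as_tensor(mask_maps), out_hw[0], out_hw[1])
        return self.post_adapter(nn.as_tensor(mask_maps), skips, out_hw)

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        out_hw = (x.shape[-2], x.shape[-1])
        canvas = self.pre_adapter_forward(x)
        tokens, taps = self.encoder_forward(canvas)
        mask_maps = self.decoder_forward(tokens)
        skips = self.skip_branch_forward(taps) if self.skip_branches is not None else None
        return self.post_adapter_forward(mask_maps, skips, out_hw)

    def predict(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Probability maps (B,K,H,W) and label masks (B,H,W).

        Softmax over classes at every pixel; argmax with ties broken toward
        the lowest class index.
        """
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(np.asarray(x, dtype=np.float32)).data
        finally:
            if was_training:
                self.train()
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        labels = np.argmax(logits, axis=1)  # np.argmax returns the first (lowest) max
        return probs, labels.astype(np.int64)


# ---------------------------------------------------------------------------
# construction / parameter accounting / persistence
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, pretrained: str | Path | None = None,
                seed: int = 0) -> SegmentationModel:
    """Build the network; optionally import pretrained encoder weights.

    The encoder backbone is frozen (minus the last ``unfreeze_last_n``
    blocks); adapters, decoder, skip branches and Post-adapter are trainable.
    """
    rng = np.random.default_rng(seed)
    model = SegmentationModel(config, rng)
    if pretrained is not None:
        report = import_encoder_checkpoint(model, pretrained)
        model._import_report = report
    return model


def count_tunable_parameters(model: SegmentationModel) -> int:
    """Element count over parameters excluded from the frozen set."""
    return int(sum(p.data.size for p in model.parameters() if not p.frozen))


def count_frozen_parameters(model: SegmentationModel) -> int:
    return int(sum(p.data.size for p in model.parameters() if p.frozen))


def save_model(model: SegmentationModel, directory: str | Path, name: str = "model"):
    """Weights (.npz) plus a JSON sidecar with the config and tunable count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights_path = directory / f"{name}.npz"
    np.savez(weights_path, **model.state_dict())
    sidecar = {
        "config": model.cfg.to_dict(),
        "tunable_parameters": count_tunable_parameters(model),
    }
    with open(directory / f"{name}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return weights_path


def load_model(directory: str | Path, name: str = "model") -> SegmentationModel:
    directory = Path(directory)
    with open(directory / f"{name}.json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig.from_dict(sidecar["config"])
    model = build_model(cfg)
    with np.load(directory / f"{name}.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# -- MAE/ViT-large checkpoint import ----------------------------------------

def _interp_pos_embed(pos: np.ndarray, src_grid: int, dst_grid: int) -> np.ndarray:
    from .nn.resize import resize_bicubic_np

    d = pos.shape[-1]
    planes = pos.reshape(src_grid, src_grid, d).transpose(2, 0, 1)
    planes = resize_bicubic_np(planes, dst_grid, dst_grid)
    return planes.transpose(1, 2, 0).reshape(1, dst_grid * dst_grid, d)


def import_encoder_checkpoint(model: SegmentationModel, path: str | Path) -> dict:
    """Import MAE/ViT-large-named encoder weights from an .npz archive.

    Accepts the standard naming (``patch_embed.proj.*``, ``pos_embed``,
    ``blocks.N.{norm1,attn.qkv,attn.proj,norm2,mlp.fc1,mlp.fc2}.*``,
    ``norm.*``); a leading class-token row in ``pos_embed`` is dropped.
    Names that do not correspond to encoder weights (adapter/decoder weights)
    are left at initialization and reported as unmatched.
    """
    cfg = model.cfg
    with np.load(str(path)) as data:
        ckpt = {k: data[k] for k in data.files}
    matched, unmatched = [], []

    def assign(param: Parameter, arr: np.ndarray, key: str):
        if arr.shape != param.data.shape:
            raise ValueError(
                f"checkpoint geometry mismatch for '{key}': checkpoint shape "
                f"{arr.shape}, model expects {param.data.shape}"
            )
        param.data = arr.astype(np.float32).copy()
        matched.append(key)

    enc = model.encoder
    for key, arr in ckpt.items():
        if key == "patch_embed.proj.weight":
            assign(enc.patch_embed.weight, arr.reshape(arr.shape[0], -1), key)
        elif key == "patch_embed.proj.bias":
            assign(enc.patch_embed.bias, arr, key)
        elif key == "pos_embed":
            arr = np.asarray(arr)
            n = cfg.grid_size ** 2
            if arr.ndim == 3 and arr.shape[1] == n + 1:
                arr = arr[:, 1:]  # drop the class-token embedding
            src_n = arr.shape[1]
            if src_n != n:
                src_grid = int(round(np.sqrt(src_n)))
                if src_grid * src_grid != src_n:
                    raise ValueError(
                        f"checkpoint geometry mismatch for 'pos_embed': "
                        f"{arr.shape} is not a square token grid"
                    )
                arr = _interp_pos_embed(arr, src_grid, cfg.grid_size)
            assign(enc.pos_embed, arr.reshape(1, n, cfg.embed_dim), key)
        elif key.startswith("blocks."):
            parts = key.split(".")
            idx = int(parts[1])
            if idx >= cfg.depth:
                unmatched.append(key)
                continue
            sub = ".".join(parts[2:])
            block = enc.blocks._layers[idx]
            table = {
                "norm1.weight": block.norm1.weight, "norm1.bias": block.norm1.bias,
                "attn.qkv.weight": block.attn.qkv.weight, "attn.qkv.bias": block.attn.qkv.bias,
                "attn.proj.weight": block.attn.proj.weight, "attn.proj.bias": block.attn.proj.bias,
                "norm2.weight": block.norm2.weight, "norm2.bias": block.norm2.bias,
                "mlp.fc1.weight": block.mlp.fc1.weight, "mlp.fc1.bias": block.mlp.fc1.bias,
                "mlp.fc2.weight": block.mlp.fc2.weight, "mlp.fc2.bias": block.mlp.fc2.bias,
            }
            if sub in table:
                assign(table[sub], arr, key)
            else:
                unmatched.append(key)
        elif key == "norm.weight":
            assign(enc.norm.weight, arr, key)
        elif key == "norm.bias":
            assign(enc.norm.bias, arr, key)
        else:
            unmatched.append(key)
    return {"matched": matched, "unmatched": unmatched}
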