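"""The dual-branch attention network.

Two weight-independent bi-Inception branches embed the full-face flow feature
and its puzzled counterpart (3×28×28 each) into 48×7×7 maps.  The full-face
branch is refined by CBAM attention (AARS); the puzzled branch relies on the
hand-crafted ROI selection already baked into its input (HARS).  The two maps
are concatenated to 96×7×7 and classified by a two-layer head with dropout.

Default shape chain per branch: 3×28×28 → 24×14×14 → 48×7×7.

The public contract is channels-first (N, C, H, W); internally feature maps
are channels-last because that keeps the convolution reshapes copy-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class BranchConfig:
    """Architecture hyperparameters shared by both branches."""

    inception_filters: list[int] = field(default_factory=lambda: [6, 12])
    input_channels: int = 3
    input_size: int = 28
    attention_enabled: bool = True       # CBAM on the full-face branch
    puzzled_attention: bool = False      # ablation: CBAM on the puzzled branch too
    cbam_reduction: int = 16
    sam_kernel: int = 7
    hidden_units: int = 512
    n_classes: int = 3
    dropout: float = 0.5

    def __post_init__(self):
        if any(f <= 0 for f in self.inception_filters):
            raise ValueError("inception filter counts must be positive")


class InceptionBlock(nn.Module):
    """Four parallel convolution paths concatenated, then 2×2/2 max-pooling.

    Paths: 1×1; 1×1→3×3; 1×1→5×5; 3×3/1 max-pool→1×1.  Every path emits
    ``filters`` channels (so the block outputs 4·filters), every convolution
    is followed by ReLU, and the trailing stride-2 pool halves the spatial
    size.  Feature maps are NHWC.
    """

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, filters, 1, rng=rng, dtype=dtype)
        self.reduce3 = nn.Conv2d(in_channels, filters, 1, rng=rng, dtype=dtype)
        self.conv3 = nn.Conv2d(filters, filters, 3, padding=1, rng=rng, dtype=dtype)
        self.reduce5 = nn.Conv2d(in_channels, filters, 1, rng=rng, dtype=dtype)
        self.conv5 = nn.Conv2d(filters, filters, 5, padding=2, rng=rng, dtype=dtype)
        self.pool_proj = nn.Conv2d(in_channels, filters, 1, rng=rng, dtype=dtype)
        self.out_channels = 4 * filters

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] < 2 or x.shape[2] < 2:
            raise ValueError(f"spatial size {x.shape[1:3]} too small for pooling")
        b1 = self.conv1(x).relu()
        b2 = self.conv3(self.reduce3(x).relu()).relu()
        b3 = self.conv5(self.reduce5(x).relu()).relu()
        b4 = self.pool_proj(nn.max_pool2d(x, 3, 1, padding=1)).relu()
        out = nn.concat([b1, b2, b3, b4], axis=3)
        return nn.max_pool2d(out, 2, 2)


class ChannelAttention(nn.Module):
    """Sigmoid channel gate from max- and average-pooled descriptors.

    Both global descriptors pass through one weight-shared two-layer MLP and
    are summed before the sigmoid, giving per-channel weights in (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = nn.Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, channels, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        mx = x.max(axis=(1, 2))
        av = x.mean(axis=(1, 2))
        return (self._mlp(mx) + self._mlp(av)).sigmoid()

    def _mlp(self, d: Tensor) -> Tensor:
        return self.fc2(self.fc1(d).relu())


class SpatialAttention(nn.Module):
    """Sigmoid spatial gate from channel-pooled maps through one convolution."""

    def __init__(self, kernel: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = nn.concat([x.max(axis=3, keepdims=True), x.mean(axis=3, keepdims=True)],
                           axis=3)
        return self.conv(pooled).sigmoid()


class CBAM(nn.Module):
    """Channel attention then spatial attention, applied multiplicatively."""

    def __init__(self, channels: int, reduction: int, sam_kernel: int,
                 rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng, dtype)
        self.spatial = SpatialAttention(sam_kernel, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        mc = self.channel(x)
        n, c = mc.shape
        gated = x * mc.reshape(n, 1, 1, c)
        return gated * self.spatial(gated)


class BiInception(nn.Module):
    """Two stacked Inception blocks (one branch of the dual network)."""

    def __init__(self, config: BranchConfig, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        self.blocks = []
        in_ch = config.input_channels
        for f in config.inception_filters:
            block = InceptionBlock(in_ch, f, rng, dtype)
            self.blocks.append(block)
            in_ch = block.out_channels
        self.out_channels = in_ch

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


@dataclass
class DualFeatures:
    """Evaluation-mode forward-pass record for a batch (channels-first)."""

    Ve: np.ndarray          # (N, 48, 7, 7) full-face branch
    Vp: np.ndarray          # (N, 48, 7, 7) puzzled branch
    fused: np.ndarray       # (N, 96, 7, 7)
    probs: np.ndarray       # (N, n_classes)

    def __post_init__(self):
        s = self.probs.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=1e-6) or (self.probs < 0).any():
            raise ValueError("probs must be a probability vector")


class DualATME(nn.Module):
    """Dual-branch micro-expression classifier.

    Parameters are initialised fan-in uniform from ``seed``; dropout draws
    from a generator derived from the same seed, so training is reproducible.
    ``dtype`` defaults to float32 — the network is small and single precision
    roughly halves training time.
    """

    def __init__(self, config: BranchConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.config = config or BranchConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.entire_branch = BiInception(self.config, rng, dtype)
        self.puzzled_branch = BiInception(self.config, rng, dtype)
        c_out = self.entire_branch.out_channels
        self.attention = (CBAM(c_out, self.config.cbam_reduction, self.config.sam_kernel,
                               rng, dtype)
                          if self.config.attention_enabled else None)
        self.puzzled_attn = (CBAM(c_out, self.config.cbam_reduction, self.config.sam_kernel,
                                  rng, dtype)
                             if self.config.puzzled_attention else None)
        side = self.config.input_size // (2 ** len(self.config.inception_filters))
        self.flat_dim = 2 * c_out * side * side
        self.fc1 = nn.Linear(self.flat_dim, self.config.hidden_units, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(self.config.hidden_units, self.config.n_classes, rng=rng, dtype=dtype)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward ------------------------------------------------------------

    def _to_internal(self, x: np.ndarray | Tensor, name: str) -> Tensor:
        arr = x.data if isinstance(x, Tensor) else np.asarray(x)
        expect = (self.config.input_channels, self.config.input_size, self.config.input_size)
        if arr.ndim != 4 or arr.shape[1:] != expect:
            raise ValueError(f"{name} must be (N, {expect[0]}, {expect[1]}, {expect[2]}), "
                             f"got {arr.shape}")
        return Tensor(np.ascontiguousarray(arr.transpose(0, 2, 3, 1), dtype=self.dtype))

    def forward(self, x_entire, x_puzzled) -> dict:
        """Graph-building forward pass on channels-first input batches.

        Returns internal channels-last branch maps (``Ve``, ``Vp``, ``fused``)
        plus ``logits`` and ``probs``; layout does not matter for the losses,
        which only flatten the maps.
        """
        xe = self._to_internal(x_entire, "x_entire")
        xp = self._to_internal(x_puzzled, "x_puzzled")
        ve = self.entire_branch(xe)
        if self.attention is not None:
            ve = self.attention(ve)
        vp = self.puzzled_branch(xp)
        if self.puzzled_attn is not None:
            vp = self.puzzled_attn(vp)
        fused = nn.concat([ve, vp], axis=3)
        flat = fused.reshape(fused.shape[0], self.flat_dim)
        hidden = self.fc1(flat).relu()
        hidden = nn.dropout(hidden, self.config.dropout, self._dropout_rng, self.training)
        logits = self.fc2(hidden)
        return {"Ve": ve, "Vp": vp, "fused": fused, "logits": logits,
                "probs": nn.softmax(logits)}

    def __call__(self, x_entire, x_puzzled) -> dict:
        return self.forward(x_entire, x_puzzled)

    def branch_feature_maps(self, x: np.ndarray, branch: str = "entire") -> list[np.ndarray]:
        """Channels-first output of each Inception block for one input batch."""
        t = self._to_internal(np.asarray(x), "x")
        maps = []
        with nn.no_grad():
            for block in getattr(self, f"{branch}_branch").blocks:
                t = block(t)
                maps.append(t.data.transpose(0, 3, 1, 2))
        return maps

    def predict_proba(self, x_entire: np.ndarray, x_puzzled: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode class probabilities for a batch."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(np.asarray(x_entire), np.asarray(x_puzzled))
        finally:
            if was_training:
                self.train()
        return out["probs"].data

    def architecture_summary(self) -> dict:
        side = self.config.input_size // (2 ** len(self.config.inception_filters))
        c = self.entire_branch.out_channels
        return {
            "config": asdict(self.config),
            "branch_output": [c, side, side],
            "fused": [2 * c, side, side],
            "flattened": self.flat_dim,
            "parameters": int(sum(p.data.size for p in self.parameters())),
        }

    def save_architecture_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.architecture_summary(), fh, indent=2)


def forward_dual(model: DualATME, x_entire: np.ndarray, x_puzzled: np.ndarray) -> DualFeatures:
    """Evaluation-mode forward pass returning channels-first feature maps.

    Accepts a single (3, H, W) pair or a batch (N, 3, H, W).
    """
    xe = np.asarray(x_entire, dtype=float)
    xp = np.asarray(x_puzzled, dtype=float)
    if xe.ndim == 3:
        xe, xp = xe[None], xp[None]
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            out = model.forward(xe, xp)
    finally:
        if was_training:
            model.train()
    return DualFeatures(Ve=out["Ve"].data.transpose(0, 3, 1, 2),
                        Vp=out["Vp"].data.transpose(0, 3, 1, 2),
                        fused=out["fused"].data.transpose(0, 3, 1, 2),
                        probs=out["probs"].data)
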