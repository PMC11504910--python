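"""The multi-attention classifier: head, three-branch body, FC tail.

Head: two conv-BN-ReLU stages (7x7 then 3x3, each stride 2), a 3x3/2
max-pool, then two Enhanced Inception Modules built from depthwise-separable
convolutions — taking a 224 x 224 single-channel input down to a 28 x 28
body feature map.

Body: three parallel attention branches (CBAM, multi-head self-attention,
slot attention). The CBAM and MHSA branches are reduced by global average
pooling to C-vectors; the slot branch already yields a dim-vector. Enabled
branch summaries are concatenated.

Tail: FC -> LayerNorm -> ReLU -> Dropout -> FC -> ReLU -> Dropout ->
FC(num_classes) with a 2-way softmax read-out.

Stage depths and widths are not fixed by the architecture description and
are exposed in :class:`NetworkConfig`; ``NetworkConfig.desk_scale()`` gives a
narrow variant sized for CPU experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat, global_avg_pool, max_pool2d, no_grad, softmax
from .attention import CBAM, ConfigurationError, MultiHeadSelfAttention, SlotAttention
from .nn import BatchNorm2d, Conv2d, Dropout, LayerNorm, Linear, Module

__all__ = [
    "NetworkConfig", "Prediction", "DepthwiseSeparableConv", "EnhancedInception",
    "StenosisNet", "build_ablation_variant", "save_checkpoint", "load_checkpoint",
    "BRANCHES",
]

BRANCHES = ("cbam", "mhsam", "sam")


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    head_widths: tuple[int, int] = (32, 64)
    head_conv_kernel: int = 7
    head_strides: tuple[int, int] = (2, 2)
    eim_branch_width: int = 32
    eim_out: int = 128
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    mhsa_heads: int = 4
    mhsa_dim: int | None = None  # None -> body channel count
    sam_num_slots: int = 4
    sam_dim: int = 64
    sam_iters: int = 3
    sam_token_grid: int = 7
    sam_mode: str = "grid"
    tail_widths: tuple[int, int] = (256, 64)
    dropout_p: float = 0.5
    num_classes: int = 2
    enabled_branches: tuple[str, ...] = BRANCHES
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if not self.enabled_branches:
            raise ConfigurationError("at least one attention branch must be enabled")
        for b in self.enabled_branches:
            if b not in BRANCHES:
                raise ConfigurationError(f"unknown branch {b!r}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")

    @classmethod
    def desk_scale(cls, **overrides) -> "NetworkConfig":
        """Narrow widths and a coarser stem (14x14 body map) for CPU-scale
        training; the stage structure and branch wiring are unchanged."""
        base = dict(head_widths=(8, 16), head_strides=(4, 2),
                    eim_branch_width=8, eim_out=32,
                    cbam_reduction=8, sam_dim=32, tail_widths=(64, 32))
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Prediction:
    probabilities: np.ndarray  # (num_classes,) nonnegative, sums to 1
    predicted_class: int


class DepthwiseSeparableConv(Module):
    """Depthwise k x k conv followed by a pointwise 1x1 conv (same padding).

    Parameter count k^2*in_c + in_c*out_c (+ biases), below a standard conv's
    k^2*in_c*out_c for k >= 3 and out_c >= 2.
    """

    def __init__(self, in_c: int, out_c: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ConfigurationError("DSC kernel must be odd for same padding")
        self.depthwise = Conv2d(in_c, in_c, kernel, rng, padding=kernel // 2,
                                depthwise=True)
        self.pointwise = Conv2d(in_c, out_c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class EnhancedInception(Module):
    """Parallel DSC 1x1 / 3x3 / 5x5 branches plus a 3x3 stride-1 max-pool,
    concatenated and fused by 1x1 conv + BN + ReLU."""

    def __init__(self, in_c: int, branch_width: int, out_c: int,
                 rng: np.random.Generator):
        super().__init__()
        self.b1 = DepthwiseSeparableConv(in_c, branch_width, 1, rng)
        self.b3 = DepthwiseSeparableConv(in_c, branch_width, 3, rng)
        self.b5 = DepthwiseSeparableConv(in_c, branch_width, 5, rng)
        self.fuse = Conv2d(3 * branch_width + in_c, out_c, 1, rng)
        self.bn = BatchNorm2d(out_c)

    def forward(self, x: Tensor) -> Tensor:
        pooled = max_pool2d(x, 3, 1, padding=1)
        cat = concat([self.b1(x), self.b3(x), self.b5(x), pooled], axis=1)
        return self.bn(self.fuse(cat)).relu()


class _ConvBNReLU(Module):
    def __init__(self, in_c, out_c, kernel, stride, rng):
        super().__init__()
        self.conv = Conv2d(in_c, out_c, kernel, rng, stride=stride,
                           padding=kernel // 2)
        self.bn = BatchNorm2d(out_c)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class StenosisNet(Module):
    """Full classifier; see module docstring for the stage layout."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w1, w2 = cfg.head_widths
        self.stage1 = _ConvBNReLU(cfg.in_channels, w1, cfg.head_conv_kernel,
                                  cfg.head_strides[0], rng)
        self.stage2 = _ConvBNReLU(w1, w2, 3, cfg.head_strides[1], rng)
        self.eim1 = EnhancedInception(w2, cfg.eim_branch_width, cfg.eim_out, rng)
        self.eim2 = EnhancedInception(cfg.eim_out, cfg.eim_branch_width,
                                      cfg.eim_out, rng)
        c = cfg.eim_out
        if "cbam" in cfg.enabled_branches:
            self.cbam = CBAM(c, rng, cfg.cbam_reduction, cfg.cbam_spatial_kernel)
        if "mhsam" in cfg.enabled_branches:
            self.mhsam = MultiHeadSelfAttention(c, rng, cfg.mhsa_heads,
                                                cfg.mhsa_dim)
        if "sam" in cfg.enabled_branches:
            self.sam = SlotAttention(c, rng, cfg.sam_num_slots, cfg.sam_dim,
                                     cfg.sam_iters, cfg.sam_token_grid,
                                     cfg.sam_mode)
        fusion = self.fusion_width()
        t1, t2 = cfg.tail_widths
        self.fc1 = Linear(fusion, t1, rng)
        self.ln = LayerNorm(t1)
        self.drop1 = Dropout(cfg.dropout_p, np.random.default_rng(rng.integers(2**31)))
        self.fc2 = Linear(t1, t2, rng)
        self.drop2 = Dropout(cfg.dropout_p, np.random.default_rng(rng.integers(2**31)))
        self.fc3 = Linear(t2, cfg.num_classes, rng)

    def fusion_width(self) -> int:
        """Width of the concatenated branch summary entering the tail."""
        w = 0
        if "cbam" in self.cfg.enabled_branches:
            w += self.cfg.eim_out
        if "mhsam" in self.cfg.enabled_branches:
            w += self.cfg.eim_out
        if "sam" in self.cfg.enabled_branches:
            w += self.cfg.sam_dim
        return w

    # -- forward --------------------------------------------------------------
    def _head(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(
                f"head stage1: expected {self.cfg.in_channels} channel(s), got {c}")
        if h < 16 or w < 16:
            raise ValueError(
                f"head striding: input {h}x{w} too small (needs >= 16x16)")
        x = self.stage1(x)
        x = self.stage2(x)
        x = max_pool2d(x, 3, 2, padding=1)
        x = self.eim1(x)
        return self.eim2(x)

    def forward(self, x: Tensor) -> Tensor:
        """Logits of shape (N, num_classes)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        body = self._head(x)
        summaries = []
        if "cbam" in self.cfg.enabled_branches:
            summaries.append(global_avg_pool(self.cbam(body)))
        if "mhsam" in self.cfg.enabled_branches:
            summaries.append(global_avg_pool(self.mhsam(body)))
        if "sam" in self.cfg.enabled_branches:
            summaries.append(self.sam(body))
        fused = summaries[0] if len(summaries) == 1 else concat(summaries, axis=1)
        z = self.drop1(self.ln(self.fc1(fused)).relu())
        z = self.drop2(self.fc2(z).relu())
        return self.fc3(z)

    def predict_proba(self, x) -> np.ndarray:
        """(N, num_classes) softmax probabilities (eval-style forward)."""
        with no_grad():
            logits = self.forward(x)
            return softmax(logits, axis=1).data

    def predict(self, x) -> list[Prediction]:
        probs = self.predict_proba(x)
        return [Prediction(p.copy(), int(p.argmax())) for p in probs]


def build_ablation_variant(cfg: NetworkConfig, drop: str | None = None,
                           keep_only: str | None = None) -> NetworkConfig:
    """Minus-one (``drop``) or only-one (``keep_only``) branch variant."""
    if (drop is None) == (keep_only is None):
        raise ConfigurationError("specify exactly one of drop / keep_only")
    if drop is not None:
        if drop not in BRANCHES:
            raise ConfigurationError(f"unknown branch {drop!r}")
        remaining = tuple(b for b in cfg.enabled_branches if b != drop)
        if not remaining:
            raise ConfigurationError("cannot drop the only enabled branch")
        return replace(cfg, enabled_branches=remaining)
    if keep_only not in BRANCHES:
        raise ConfigurationError(f"unknown branch {keep_only!r}")
    return replace(cfg, enabled_branches=(keep_only,))


def save_checkpoint(path: str | Path, model: StenosisNet) -> None:
    """Self-describing checkpoint: weights plus the embedded config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> StenosisNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("head_widths", "head_strides", "tail_widths",
                    "enabled_branches"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = NetworkConfig(**cfg_dict)
        model = StenosisNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
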