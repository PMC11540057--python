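"""Five-level multi-encoder / single-decoder segmentation network.

Each of the four MR modalities is processed by its own encoder branch
(residual blocks + stride-2 downsampling; a global-context attention
block at the two deepest levels).  At every level the four branch
outputs pass through the parameter-free wavelet fusion block and a 1x1x1
channel-reduction convolution, producing the decoder skip (levels 1-4)
or the bottleneck (level 5).  The decoder upsamples trilinearly,
concatenates the skip and applies a residual block, and a 1x1x1 head
with three sigmoid channels predicts the overlapping WT/TC/ET regions.

Built on the numpy autodiff engine in :mod:`wfseg.autodiff`; all
computation is deterministic given the construction seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError
from .gcam import bottleneck_width

NUM_MODALITIES = 4


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    channel_schedule defaults to base_channels doubling per level
    (16 -> 256 at base 16); gcam_levels are the encoder levels that get a
    global-context block; gcam_ratio is its bottleneck reduction; groups
    is the group-norm group count (clamped to the channel count).
    """

    base_channels: int = 16
    channel_schedule: tuple[int, ...] | None = None
    num_levels: int = 5
    gcam_levels: tuple[int, ...] = (4, 5)
    gcam_ratio: int = 4
    wavelet_name: str = "haar"
    groups: int = 8
    out_regions: int = 3
    high_freq_rule: str = "sum"
    gcam_zero_init: bool = True

    def schedule(self) -> tuple[int, ...]:
        if self.channel_schedule is not None:
            sched = tuple(self.channel_schedule)
        else:
            sched = tuple(self.base_channels * 2**i for i in range(self.num_levels))
        if len(sched) != self.num_levels:
            raise ConfigurationError(
                f"channel_schedule needs {self.num_levels} entries, got {len(sched)}"
            )
        if self.num_levels < 1:
            raise ConfigurationError("num_levels must be >= 1")
        if any(b >= a for b, a in zip(sched, sched[1:])):
            raise ConfigurationError(f"channel schedule must strictly increase: {sched}")
        return sched

    def validate(self) -> None:
        self.schedule()
        if self.gcam_ratio < 1:
            raise ConfigurationError("gcam_ratio must be >= 1")
        try:
            w = pywt.Wavelet(self.wavelet_name)
        except ValueError as exc:
            raise ConfigurationError(f"unknown wavelet {self.wavelet_name!r}") from exc
        if not w.orthogonal:
            raise ConfigurationError(
                "network wavelet must be orthogonal (gradient uses the transform adjoint)"
            )
        if self.high_freq_rule not in ("sum", "mean"):
            raise ConfigurationError("high_freq_rule must be 'sum' or 'mean' inside the network")

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.num_levels - 1)


@dataclass
class SegmentationOutput:
    """Sigmoid region probabilities (WT, TC, ET) plus raw logits."""

    probabilities: np.ndarray  # (3, D, H, W) in [0, 1]
    logits: np.ndarray
    prob_tensor: Tensor | None = None  # graph nodes, for training
    logit_tensor: Tensor | None = None


class Parameter(Tensor):
    def __init__(self, data, name: str):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Tiny container: children and parameters discovered by attribute scan."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(value) -> None:
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
            elif isinstance(value, Module):
                for v in value.__dict__.values():
                    visit(v)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    visit(item)
            elif isinstance(value, dict):
                for item in value.values():
                    visit(item)

        for value in self.__dict__.values():
            visit(value)
        return params

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, name: str = "conv", zero_init: bool = False):
        fan_in = cin * k**3
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0, scale, size=(cout, cin, k, k, k)), f"{name}.weight")
        self.bias = Parameter(np.zeros(cout), f"{name}.bias")
        self.stride = stride
        self.padding = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int, name: str = "gn"):
        while channels % groups:
            groups -= 1
        self.groups = max(groups, 1)
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return ad.group_norm(x, self.gamma, self.beta, self.groups)


class ResidualBlock(Module):
    """conv-norm-relu twice, plus identity (or 1x1x1-projected) skip."""

    def __init__(self, cin: int, cout: int, groups: int, rng, name: str = "res"):
        self.conv1 = Conv3d(cin, cout, 3, rng, name=f"{name}.conv1")
        self.norm1 = GroupNorm(cout, groups, f"{name}.norm1")
        self.conv2 = Conv3d(cout, cout, 3, rng, name=f"{name}.conv2")
        self.norm2 = GroupNorm(cout, groups, f"{name}.norm2")
        self.proj = None if cin == cout else Conv3d(cin, cout, 1, rng, name=f"{name}.proj")

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.relu(self.norm1(self.conv1(x)))
        y = ad.relu(self.norm2(self.conv2(y)))
        skip = x if self.proj is None else self.proj(x)
        return ad.add(y, skip)


class GCAMBlock(Module):
    """Global-context attention: pool, bottleneck transform, broadcast add."""

    def __init__(self, channels: int, ratio: int, rng, zero_init_out: bool = True,
                 name: str = "gcam"):
        hidden = bottleneck_width(channels, ratio)
        self.channels, self.hidden = channels, hidden
        self.key_w = Parameter(rng.normal(0, np.sqrt(1.0 / channels), size=(1, channels)), f"{name}.key_w")
        self.key_b = Parameter(np.zeros(1), f"{name}.key_b")
        self.w_in = Parameter(rng.normal(0, np.sqrt(2.0 / channels), size=(hidden, channels)), f"{name}.w_in")
        self.b_in = Parameter(np.zeros(hidden), f"{name}.b_in")
        self.ln_gamma = Parameter(np.ones(hidden), f"{name}.ln_gamma")
        self.ln_beta = Parameter(np.zeros(hidden), f"{name}.ln_beta")
        out_scale = 0.0 if zero_init_out else np.sqrt(2.0 / hidden)
        self.w_out = Parameter(rng.normal(0, out_scale, size=(channels, hidden)), f"{name}.w_out")
        self.b_out = Parameter(np.zeros(channels), f"{name}.b_out")

    def __call__(self, x: Tensor) -> Tensor:
        c = x.data.shape[0]
        n = int(np.prod(x.data.shape[1:]))
        flat = ad.reshape(x, (c, n))
        logits = ad.reshape(ad.add(ad.matmul(self.key_w, flat), ad.reshape(self.key_b, (1, 1))), (n,))
        attn = ad.reshape(ad.softmax(logits), (n, 1))
        ctx = ad.matmul(flat, attn)  # (C, 1)
        hidden = ad.add(ad.matmul(self.w_in, ctx), ad.reshape(self.b_in, (self.hidden, 1)))
        hidden = ad.layer_norm_vec(ad.reshape(hidden, (self.hidden,)), self.ln_gamma, self.ln_beta)
        hidden = ad.relu(hidden)
        update = ad.add(ad.matmul(self.w_out, ad.reshape(hidden, (self.hidden, 1))),
                        ad.reshape(self.b_out, (c, 1)))
        return ad.add(x, ad.reshape(update, (c, 1, 1, 1)))

    def param_count_formula(self) -> int:
        c, h = self.channels, self.hidden
        return c + 1 + c * h + h + 2 * h + h * c + c


class MultiEncoderUNet(Module):
    """The full late-fusion segmentation network."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.config.validate()
        rng = np.random.default_rng(seed)
        sched = self.config.schedule()
        L = self.config.num_levels
        g = self.config.groups

        # encoder branches: architecture shared, weights independent
        self.enc_blocks: list[list[ResidualBlock]] = []
        self.enc_gcam: list[dict[int, GCAMBlock]] = []
        self.enc_down: list[list[Conv3d]] = []
        for m in range(NUM_MODALITIES):
            blocks, gcams, downs = [], {}, []
            for lvl in range(1, L + 1):
                cin = 1 if lvl == 1 else sched[lvl - 1]
                blocks.append(ResidualBlock(cin, sched[lvl - 1], g, rng, f"enc{m}.l{lvl}"))
                if lvl in self.config.gcam_levels:
                    gcams[lvl] = GCAMBlock(
                        sched[lvl - 1], self.config.gcam_ratio, rng,
                        zero_init_out=self.config.gcam_zero_init, name=f"enc{m}.gcam{lvl}",
                    )
                if lvl < L:
                    downs.append(Conv3d(sched[lvl - 1], sched[lvl], 3, rng, stride=2,
                                        name=f"enc{m}.down{lvl}"))
            self.enc_blocks.append(blocks)
            self.enc_gcam.append(gcams)
            self.enc_down.append(downs)
        # per-level fusion channel reduction 4C -> C
        self.reduce = [
            Conv3d(4 * sched[lvl - 1], sched[lvl - 1], 1, rng, name=f"reduce.l{lvl}")
            for lvl in range(1, L + 1)
        ]

        # decoder
        self.up_conv = [
            Conv3d(sched[lvl], sched[lvl - 1], 1, rng, name=f"dec.up{lvl}")
            for lvl in range(L - 1, 0, -1)
        ]
        self.dec_blocks = [
            ResidualBlock(2 * sched[lvl - 1], sched[lvl - 1], g, rng, f"dec.l{lvl}")
            for lvl in range(L - 1, 0, -1)
        ]
        self.head = Conv3d(sched[0], self.config.out_regions, 1, rng, name="head")

    # ------------------------------------------------------------------
    def forward(self, vol: np.ndarray | Tensor, return_tensor: bool = False) -> SegmentationOutput:
        x = vol if isinstance(vol, Tensor) else Tensor(vol)
        if x.data.ndim != 4 or x.data.shape[0] != NUM_MODALITIES:
            raise ValueError(f"expected (4, D, H, W) input, got shape {x.data.shape}")
        factor = self.config.downsample_factor
        if any(d % factor for d in x.data.shape[1:]):
            raise ValueError(
                f"spatial dims {x.data.shape[1:]} must be divisible by {factor}"
            )
        L = self.config.num_levels

        # encoders
        per_level: list[list[Tensor]] = [[] for _ in range(L)]
        for m in range(NUM_MODALITIES):
            if x.requires_grad:
                h = Tensor(x.data[m : m + 1], parents=(x,), backward=_slice_bwd(x, m))
            else:
                h = Tensor(x.data[m : m + 1])
            for lvl in range(1, L + 1):
                h = self.enc_blocks[m][lvl - 1](h)
                if lvl in self.enc_gcam[m]:
                    h = self.enc_gcam[m][lvl](h)
                per_level[lvl - 1].append(h)
                if lvl < L:
                    h = self.enc_down[m][lvl - 1](h)

        # wavelet fusion + channel reduction at every level
        skips: list[Tensor] = []
        for lvl in range(1, L + 1):
            xs = per_level[lvl - 1]
            f = ad.wavelet_fusion(xs, self.config.wavelet_name, self.config.high_freq_rule)
            enhanced = [ad.add(xi, f) for xi in xs]
            fused = ad.concat(enhanced, axis=0)
            skips.append(self.reduce[lvl - 1](fused))

        # decoder
        h = skips[-1]
        for i, lvl in enumerate(range(L - 1, 0, -1)):
            h = self.up_conv[i](ad.upsample2x(h))
            h = ad.concat([h, skips[lvl - 1]], axis=0)
            h = self.dec_blocks[i](h)
        logits = self.head(h)
        probs = ad.sigmoid(logits)
        return SegmentationOutput(
            probabilities=np.asarray(probs.data),
            logits=np.asarray(logits.data),
            prob_tensor=probs if return_tensor else None,
            logit_tensor=logits if return_tensor else None,
        )

    __call__ = forward

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        params = self.parameters()
        names = [p.name for p in params]
        assert len(names) == len(set(names)), "parameter names must be unique"
        return {p.name: p.data.copy() for p in params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in checkpoint")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.data = np.asarray(state[p.name], dtype=p.data.dtype).copy()


def _slice_bwd(x: Tensor, m: int):
    def bwd(g):
        full = np.zeros_like(x.data)
        full[m : m + 1] = g
        x._accumulate(full)

    return bwd


def count_parameters(model: MultiEncoderUNet) -> dict[str, int]:
    """Exact parameter counts grouped by block kind, plus the total."""
    table: dict[str, int] = {}
    for p in model.parameters():
        group = p.name.split(".")[0]
        if group.startswith("enc"):
            group = "encoders" if "gcam" not in p.name else "gcam"
        elif group in ("dec", "reduce", "head"):
            group = {"dec": "decoder", "reduce": "fusion_reduce", "head": "head"}[group]
        table[group] = table.get(group, 0) + p.data.size
    table["total"] = sum(p.data.size for p in model.parameters())
    return table
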