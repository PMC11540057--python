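"""Global-context attention block (numpy reference implementation).

One attention map over all spatial positions is computed from a 1x1x1 key
projection and softmax-normalized; the weighted sum of features gives a
single per-channel context vector.  The context passes through a
bottleneck transform (1x1x1 down-projection, layer norm, ReLU, 1x1x1
up-projection) and the resulting channel vector is broadcast-added to
every position.  This is the "simplified non-local" style of global
attention: linear in the number of voxels, with a rank-0 spatial update.

The trainable network layer (:mod:`wfseg.network`) uses the same math on
autodiff tensors; this module is the plain-array reference against which
it is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


def bottleneck_width(channels: int, ratio: int) -> int:
    """Hidden width of the transform, ``max(1, C // r)``."""
    if ratio < 1:
        raise ConfigurationError(f"bottleneck ratio must be >= 1, got {ratio}")
    return max(1, channels // ratio)


@dataclass
class GcamParams:
    """Weights of one global-context block over C channels.

    key_w/key_b:   1x1x1 key projection C -> 1 (attention logits)
    w_in/b_in:     1x1x1 transform C -> C/r
    ln_gamma/ln_beta: layer-norm scale/shift over the C/r hidden axis
    w_out/b_out:   1x1x1 transform C/r -> C
    """

    key_w: np.ndarray  # (C,)
    key_b: float
    w_in: np.ndarray  # (C/r, C)
    b_in: np.ndarray  # (C/r,)
    ln_gamma: np.ndarray  # (C/r,)
    ln_beta: np.ndarray  # (C/r,)
    w_out: np.ndarray  # (C, C/r)
    b_out: np.ndarray  # (C,)
    ratio: int = 4

    @property
    def channels(self) -> int:
        return self.key_w.shape[0]

    @classmethod
    def init(
        cls,
        channels: int,
        ratio: int = 4,
        rng: np.random.Generator | None = None,
        zero_init_out: bool = True,
    ) -> "GcamParams":
        """He-style random init; output transform zeroed by default so the
        block starts as the identity."""
        rng = rng or np.random.default_rng(0)
        hidden = bottleneck_width(channels, ratio)
        w_out = np.zeros((channels, hidden))
        if not zero_init_out:
            w_out = rng.normal(0, np.sqrt(2.0 / hidden), size=(channels, hidden))
        return cls(
            key_w=rng.normal(0, np.sqrt(1.0 / channels), size=channels),
            key_b=0.0,
            w_in=rng.normal(0, np.sqrt(2.0 / channels), size=(hidden, channels)),
            b_in=np.zeros(hidden),
            ln_gamma=np.ones(hidden),
            ln_beta=np.zeros(hidden),
            w_out=w_out,
            b_out=np.zeros(channels),
            ratio=ratio,
        )

    def count(self) -> int:
        """Exact parameter count: keys + two transforms + layer norm."""
        c, h = self.channels, self.w_in.shape[0]
        return c + 1 + c * h + h + 2 * h + h * c + c


def context_pool(S: np.ndarray, key_w: np.ndarray, key_b: float = 0.0) -> np.ndarray:
    """Global attention pooling: softmax-weighted sum over positions.

    S is (C, N); returns the (C,) context vector.
    """
    S = np.asarray(S)
    if S.ndim != 2:
        raise ValueError(f"expected (C, N) features, got shape {S.shape}")
    logits = key_w @ S + key_b  # (N,)
    logits = logits - logits.max()
    w = np.exp(logits)
    w /= w.sum()
    return S @ w


def _layernorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean()
    var = x.var()
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def gcam_forward(S: np.ndarray, params: GcamParams) -> np.ndarray:
    """Apply the block to a (C, D, H, W) feature map."""
    S = np.asarray(S)
    if S.ndim != 4:
        raise ValueError(f"expected (C, D, H, W) features, got shape {S.shape}")
    C = S.shape[0]
    if params.channels != C:
        raise ConfigurationError(
            f"params built for {params.channels} channels, input has {C}"
        )
    flat = S.reshape(C, -1)
    ctx = context_pool(flat, params.key_w, params.key_b)
    hidden = params.w_in @ ctx + params.b_in
    hidden = _layernorm(hidden, params.ln_gamma, params.ln_beta)
    hidden = np.maximum(hidden, 0.0)
    update = params.w_out @ hidden + params.b_out  # (C,)
    return S + update[:, None, None, None]
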