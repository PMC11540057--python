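"""Wavelet fusion of per-modality feature maps.

The four modality feature maps at one network level are each decomposed by
a single-level 3D DWT; the four low-frequency approximations are averaged
(they carry the shared gross anatomy) while the seven detail bands are
summed (each modality contributes complementary edges and texture).  The
fused subbands are inverse-transformed to a single map F, which is added
back onto every modality's features before channel concatenation.  The
whole block is linear and has no trainable parameters.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .wavelet import HIGH_NAMES, SubbandSet, batched_dwt3, batched_idwt3, dwt3, idwt3

NUM_MODALITIES = 4

#: how the seven detail bands are combined across modalities
HIGH_FREQ_RULES = ("sum", "mean", "max")


def fuse_subbands(
    subband_sets: Sequence[SubbandSet], high_freq_rule: str = "sum"
) -> SubbandSet:
    """Fuse four subband sets: mean of the LLL bands, rule-combined highs."""
    if len(subband_sets) != NUM_MODALITIES:
        raise ValueError(f"expected {NUM_MODALITIES} subband sets, got {len(subband_sets)}")
    if high_freq_rule not in HIGH_FREQ_RULES:
        raise ConfigurationError(f"unknown high_freq_rule {high_freq_rule!r}")
    ref = subband_sets[0]
    for sb in subband_sets[1:]:
        if sb.lll.shape != ref.lll.shape or sb.original_shape != ref.original_shape:
            raise ValueError("subband sets have mismatched shapes")
        if sb.wavelet_name != ref.wavelet_name:
            raise ValueError("subband sets use different wavelets")

    fused = {"lll": np.mean([sb.lll for sb in subband_sets], axis=0)}
    for name in HIGH_NAMES:
        stack = np.stack([getattr(sb, name) for sb in subband_sets])
        if high_freq_rule == "sum":
            fused[name] = stack.sum(axis=0)
        elif high_freq_rule == "mean":
            fused[name] = stack.mean(axis=0)
        else:  # max-magnitude selection, sign preserved
            idx = np.abs(stack).argmax(axis=0)
            fused[name] = np.take_along_axis(stack, idx[None], axis=0)[0]
    return SubbandSet(**fused, wavelet_name=ref.wavelet_name, original_shape=ref.original_shape)


def wavelet_fuse(
    stack: np.ndarray, wavelet: str = "haar", high_freq_rule: str = "sum"
) -> np.ndarray:
    """Fused map F for a (4, C, D, H, W) per-modality feature stack.

    F = IDWT(fuse(DWT(X1), ..., DWT(X4))), applied channel-wise.
    """
    stack = _check_stack(stack)
    n_mod, n_ch = stack.shape[:2]
    fused_channels = []
    for c in range(n_ch):
        sets = [dwt3(stack[m, c], wavelet) for m in range(n_mod)]
        fused_channels.append(idwt3(fuse_subbands(sets, high_freq_rule)))
    return np.stack(fused_channels)


def wfm_forward(
    stack: np.ndarray, wavelet: str = "haar", high_freq_rule: str = "sum"
) -> np.ndarray:
    """Full fusion block: residual-add F to each modality, then concatenate.

    (4, C, D, H, W) -> (4C, D, H, W), channel blocks in fixed modality
    order T1, T1ce, T2, FLAIR.
    """
    stack = _check_stack(stack)
    fused = wavelet_fuse(stack, wavelet, high_freq_rule)
    enhanced = stack + fused[None]  # X_i' = X_i + F
    n_mod, n_ch = stack.shape[:2]
    return enhanced.reshape(n_mod * n_ch, *stack.shape[2:])


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim != 5 or stack.shape[0] != NUM_MODALITIES:
        raise ValueError(
            f"expected a ({NUM_MODALITIES}, C, D, H, W) stack, got shape {stack.shape}"
        )
    return stack
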