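"""Single-level separable 3D discrete wavelet analysis/synthesis.

A volume is decomposed into eight subbands — one low-frequency
approximation (LLL) and seven high-frequency detail bands — by filtering
along the x, y and z axes in turn.  Subband names encode the filter order:
the first letter is the x-axis filter (L = low-pass, H = high-pass), then
y, then z.  The default wavelet is the orthonormal Haar filter with
periodic boundary handling, which gives an exactly invertible,
energy-preserving transform on even extents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .errors import ConfigurationError

#: canonical subband order (x-filter letter first)
SUBBAND_NAMES = ("lll", "hll", "lhl", "hhl", "llh", "hlh", "lhh", "hhh")

#: high-frequency subbands (everything but the approximation)
HIGH_NAMES = SUBBAND_NAMES[1:]

# pywt.dwtn keys carry one letter per array axis ('a'/'d'); our names use
# 'l'/'h' in the same axis order.
_PYWT_KEY = {name: name.replace("l", "a").replace("h", "d") for name in SUBBAND_NAMES}

_MODE = "periodization"


@dataclass
class SubbandSet:
    """The eight subbands of one single-level 3D DWT."""

    lll: np.ndarray
    hll: np.ndarray
    lhl: np.ndarray
    hhl: np.ndarray
    llh: np.ndarray
    hlh: np.ndarray
    lhh: np.ndarray
    hhh: np.ndarray
    wavelet_name: str
    original_shape: tuple[int, int, int]

    def bands(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in SUBBAND_NAMES}

    @property
    def highs(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in HIGH_NAMES}

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands().values()}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {sorted(shapes)}")
        expected = tuple(-(-s // 2) for s in self.original_shape)  # ceil(n/2)
        if shapes.pop() != expected:
            raise ValueError(
                f"subband shape inconsistent with original_shape {self.original_shape}"
            )


def _wavelet(name: str) -> pywt.Wavelet:
    try:
        return pywt.Wavelet(name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {name!r}") from exc


def dwt3(volume: np.ndarray, wavelet: str = "haar") -> SubbandSet:
    """Single-level separable 3D DWT of ``volume``.

    Odd axis extents are handled by the periodized transform (the subband
    extent is ``ceil(n/2)``) and the original shape is recorded so that
    :func:`idwt3` can crop the reconstruction back.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    if volume.size == 0:
        raise ValueError("empty volume")
    w = _wavelet(wavelet)
    coeffs = pywt.dwtn(volume, w, mode=_MODE)
    bands = {name: coeffs[_PYWT_KEY[name]] for name in SUBBAND_NAMES}
    return SubbandSet(**bands, wavelet_name=wavelet, original_shape=volume.shape)


def idwt3(subbands: SubbandSet) -> np.ndarray:
    """Inverse of :func:`dwt3`; returns a volume of ``original_shape``."""
    w = _wavelet(subbands.wavelet_name)
    coeffs = {_PYWT_KEY[name]: band for name, band in subbands.bands().items()}
    rec = pywt.idwtn(coeffs, w, mode=_MODE)
    d, h, wd = subbands.original_shape
    return rec[:d, :h, :wd]


def batched_dwt3(stack: np.ndarray, wavelet: str = "haar") -> list[SubbandSet]:
    """Channel-wise :func:`dwt3` over a (C, D, H, W) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError(f"expected a (C, D, H, W) stack, got ndim={stack.ndim}")
    return [dwt3(stack[c], wavelet) for c in range(stack.shape[0])]


def batched_idwt3(subband_sets: Sequence[SubbandSet]) -> np.ndarray:
    """Inverse of :func:`batched_dwt3`: stacks channel reconstructions."""
    if len(subband_sets) == 0:
        raise ValueError("empty subband list")
    return np.stack([idwt3(sb) for sb in subband_sets])


def subband_energy(subbands: SubbandSet) -> float:
    """Total squared coefficient magnitude over all eight bands."""
    return float(sum((b.astype(np.float64) ** 2).sum() for b in subbands.bands().values()))
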