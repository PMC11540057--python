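"""NIfTI I/O, normalization, cropping, augmentation and label encoding.

Conventions follow skull-stripped BraTS volumes: four co-registered
modalities in fixed order (T1, T1ce, T2, FLAIR), integer labels
{0 background, 1 necrotic/non-enhancing core, 2 edema, 4 enhancing
tumor}, and zero intensity outside the brain mask.  Arrays are indexed
(modality, x, y, z) with the NIfTI affine preserved on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, InvalidLabelError

#: fixed modality order; also the BraTS file-name suffixes
MODALITIES = ("t1", "t1ce", "t2", "flair")

#: permitted label values
VALID_LABELS = frozenset({0, 1, 2, 4})


@dataclass
class MultimodalVolume:
    """Four aligned scalar channels plus an optional label volume."""

    channels: np.ndarray  # (4, D, H, W) float
    labels: np.ndarray | None = None  # (D, H, W) int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    case_id: str = "case"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != len(MODALITIES):
            raise ValueError(
                f"channels must be (4, D, H, W), got shape {self.channels.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.shape:
                raise ValueError(
                    f"labels shape {self.labels.shape} != channel shape {self.shape}"
                )
            _check_labels(self.labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]


@dataclass
class RegionMaskSet:
    """Nested evaluation regions: whole tumor ⊇ tumor core ⊇ enhancing."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wt", "tc", "et"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.wt.shape == self.tc.shape == self.et.shape):
            raise ValueError("region masks must share one shape")
        if np.any(self.et & ~self.tc) or np.any(self.tc & ~self.wt):
            raise ValueError("region nesting violated: require ET ⊆ TC ⊆ WT")

    def stacked(self) -> np.ndarray:
        """(3, D, H, W) float stack in WT, TC, ET order."""
        return np.stack([self.wt, self.tc, self.et]).astype(np.float32)


@dataclass
class NormalizationStats:
    """Foreground mean/std per modality, in MODALITIES order."""

    mu: np.ndarray  # (4,)
    sigma: np.ndarray  # (4,)


def _check_labels(labels: np.ndarray) -> None:
    bad = set(np.unique(labels)) - VALID_LABELS
    if bad:
        raise InvalidLabelError(f"unexpected label values: {sorted(int(b) for b in bad)}")


# ---------------------------------------------------------------------------
# normalization / cropping / augmentation


def zscore_normalize(
    vol: MultimodalVolume, return_stats: bool = False
) -> MultimodalVolume | tuple[MultimodalVolume, NormalizationStats]:
    """Z-score each modality over its nonzero (brain) voxels.

    Z = (m - mu) / sigma with population statistics over the foreground;
    background voxels stay exactly 0.
    """
    out = vol.channels.copy()
    mus, sigmas = np.zeros(4), np.zeros(4)
    for i, name in enumerate(MODALITIES):
        fg = vol.channels[i] != 0
        if not fg.any():
            raise DegenerateInputError(f"modality {name!r} has no nonzero voxels")
        vals = vol.channels[i][fg].astype(np.float64)
        mu, sigma = vals.mean(), vals.std()  # population std
        if sigma == 0:
            raise DegenerateInputError(f"modality {name!r} has constant foreground")
        out[i][fg] = ((vals - mu) / sigma).astype(np.float32)
        mus[i], sigmas[i] = mu, sigma
    normed = replace(vol, channels=out, labels=vol.labels)
    if return_stats:
        return normed, NormalizationStats(mu=mus, sigma=sigmas)
    return normed


def random_crop(vol: MultimodalVolume, size: Sequence[int], seed: int) -> MultimodalVolume:
    """Crop channels and labels with one shared uniformly drawn offset."""
    size = tuple(int(s) for s in size)
    if len(size) != 3 or any(s < 1 for s in size):
        raise ValueError(f"crop size must be 3 positive ints, got {size}")
    if any(s > d for s, d in zip(size, vol.shape)):
        raise ValueError(f"crop size {size} exceeds volume shape {vol.shape}")
    rng = np.random.default_rng(seed)
    offset = tuple(int(rng.integers(0, d - s + 1)) for s, d in zip(size, vol.shape))
    sl = tuple(slice(o, o + s) for o, s in zip(offset, size))
    labels = vol.labels[sl] if vol.labels is not None else None
    return replace(vol, channels=vol.channels[(slice(None), *sl)], labels=labels)


def augment(
    vol: MultimodalVolume,
    flip_p: float = 0.5,
    shift_factor: float = 0.1,
    seed: int = 0,
) -> MultimodalVolume:
    """Random mirror flips plus per-modality foreground intensity jitter.

    Each spatial axis is flipped independently with probability ``flip_p``
    (labels jointly with channels).  Each modality's foreground is then
    scaled by s ~ U(1-f, 1+f) and shifted by delta * sigma_fg with
    delta ~ U(-f, +f), where f = ``shift_factor`` and sigma_fg is the
    foreground standard deviation.  Labels are never altered in value.
    """
    if not 0.0 <= flip_p <= 1.0:
        raise ValueError(f"flip_p must be in [0, 1], got {flip_p}")
    if shift_factor < 0:
        raise ValueError(f"shift_factor must be >= 0, got {shift_factor}")
    rng = np.random.default_rng(seed)
    channels = vol.channels.copy()
    labels = None if vol.labels is None else vol.labels.copy()

    flips = rng.random(3) < flip_p
    for axis, do_flip in enumerate(flips):
        if do_flip:
            channels = np.flip(channels, axis=axis + 1)
            if labels is not None:
                labels = np.flip(labels, axis=axis)
    channels = np.ascontiguousarray(channels)
    if labels is not None:
        labels = np.ascontiguousarray(labels)

    if shift_factor > 0:
        for i in range(len(MODALITIES)):
            scale = rng.uniform(1 - shift_factor, 1 + shift_factor)
            delta = rng.uniform(-shift_factor, shift_factor)
            fg = channels[i] != 0
            if fg.any():
                sigma = channels[i][fg].std()
                channels[i][fg] = channels[i][fg] * scale + delta * sigma
    return replace(vol, channels=channels, labels=labels)


# ---------------------------------------------------------------------------
# region encoding


def encode_regions(labels: np.ndarray) -> RegionMaskSet:
    """Map BraTS labels to the nested WT/TC/ET evaluation masks."""
    labels = np.asarray(labels)
    _check_labels(labels)
    wt = np.isin(labels, (1, 2, 4))
    tc = np.isin(labels, (1, 4))
    et = labels == 4
    return RegionMaskSet(wt=wt, tc=tc, et=et)


def decode_regions(masks: RegionMaskSet) -> np.ndarray:
    """Inverse of :func:`encode_regions` with precedence ET > TC > WT.

    WT-only voxels become edema (2), TC-only voxels necrosis (1), ET
    voxels enhancing tumor (4).
    """
    labels = np.zeros(masks.wt.shape, dtype=np.int16)
    labels[masks.wt] = 2
    labels[masks.tc] = 1
    labels[masks.et] = 4
    return labels


# ---------------------------------------------------------------------------
# dataset splitting


def split_dataset(
    manifest: Sequence, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> tuple[list, list]:
    """Case-level shuffle split; |train| = round(n * r0/(r0+r1))."""
    cases = list(manifest)
    n = len(cases)
    if n < 2:
        raise ValueError(f"need at least 2 cases to split, got {n}")
    r_train, r_val = ratio
    if r_train <= 0 or r_val <= 0:
        raise ValueError(f"split ratio must be positive, got {ratio}")
    frac = r_train / (r_train + r_val)
    n_train = int(round(frac * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [cases[i] for i in perm[:n_train]]
    val = [cases[i] for i in perm[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_case(vol: MultimodalVolume, out_dir: str | Path) -> dict[str, str]:
    """Write BraTS-style files ``<case>_{t1,t1ce,t2,flair,seg}.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for i, name in enumerate(MODALITIES):
        path = out_dir / f"{vol.case_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.channels[i].astype(np.float32), vol.affine), path)
        files[name] = str(path)
    if vol.labels is not None:
        path = out_dir / f"{vol.case_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine), path)
        files["seg"] = str(path)
    return files


def load_case(case_dir: str | Path, case_id: str | None = None) -> MultimodalVolume:
    """Read a BraTS-style case directory written by :func:`save_case`."""
    case_dir = Path(case_dir)
    if case_id is None:
        seg = sorted(case_dir.glob("*_t1.nii.gz"))
        if not seg:
            raise FileNotFoundError(f"no *_t1.nii.gz under {case_dir}")
        case_id = seg[0].name[: -len("_t1.nii.gz")]
    channels, affine = [], None
    for name in MODALITIES:
        img = nib.load(case_dir / f"{case_id}_{name}.nii.gz")
        channels.append(np.asarray(img.dataobj, dtype=np.float32))
        affine = img.affine if affine is None else affine
    seg_path = case_dir / f"{case_id}_seg.nii.gz"
    labels = None
    if seg_path.exists():
        labels = np.asarray(nib.load(seg_path).dataobj).astype(np.int16)
    return MultimodalVolume(
        channels=np.stack(channels), labels=labels, affine=affine, case_id=case_id
    )


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
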