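"""Synthetic multimodal phantoms with BraTS-like nested tumor structure.

Each phantom is an ellipsoidal "brain" on a zero background containing
three concentric spherical tumor shells: edema (label 2) around a
necrotic/non-enhancing core shell (label 1) around a solid enhancing
center (label 4).  The nested WT ⊇ TC ⊇ ET evaluation regions are then
exactly the three spheres.  Per-modality contrast mimics clinical MR:
edema is bright on T2/FLAIR, the enhancing center is bright on T1ce, and
the core is dark on T1.  Gaussian noise is added inside the brain mask
only, so the background stays exactly zero.

The geometry is deliberately simple — axis-aligned ellipsoids with a
jittered common tumor center — so that voxel counts and region masks have
closed-form oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import InvalidSpecError
from .io_pipeline import MODALITIES, MultimodalVolume, save_case

#: per-modality mean intensity by tissue region (arbitrary MR-like units)
DEFAULT_CONTRAST: Mapping[str, Mapping[str, float]] = {
    "t1": {"brain": 1.0, "edema": 0.8, "necrosis": 0.5, "enhancing": 0.9},
    "t1ce": {"brain": 1.0, "edema": 0.9, "necrosis": 0.4, "enhancing": 1.8},
    "t2": {"brain": 1.0, "edema": 1.6, "necrosis": 1.4, "enhancing": 1.2},
    "flair": {"brain": 1.0, "edema": 1.8, "necrosis": 0.9, "enhancing": 1.2},
}

REGION_ORDER = ("brain", "edema", "necrosis", "enhancing")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise settings for one phantom family.

    region_radii are the voxel radii of the nested edema ⊃ core ⊃
    enhancing spheres (strictly decreasing).  brain_radius_frac scales
    the brain ellipsoid semi-axes relative to the half-extent of the
    volume.  center_jitter_frac jitters the common tumor center by up to
    that fraction of each half-extent.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    brain_radius_frac: float = 0.85
    region_radii: tuple[float, float, float] = (12.0, 8.0, 4.0)
    modality_contrast: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_CONTRAST
    )
    noise_sd: float = 0.05
    seed: int = 0
    center_jitter_frac: float = 0.05
    bias_field: bool = False

    def validate(self) -> None:
        shape = self.volume_shape
        if len(shape) != 3 or any(d < 16 or d % 2 for d in shape):
            raise InvalidSpecError(
                f"volume_shape dims must be even and >= 16, got {shape}"
            )
        r1, r2, r3 = self.region_radii
        if not (r1 > r2 > r3 > 0):
            raise InvalidSpecError(
                f"region radii must be strictly decreasing and positive, got {self.region_radii}"
            )
        half = np.array(shape) / 2.0
        brain_semi = self.brain_radius_frac * half
        jitter = self.center_jitter_frac * half
        if np.any(r1 + jitter > brain_semi):
            raise InvalidSpecError(
                "edema radius plus center jitter does not fit inside the brain mask"
            )
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        for name in MODALITIES:
            if name not in self.modality_contrast:
                raise InvalidSpecError(f"modality_contrast missing entry for {name!r}")


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi_axes))
    return d2 <= 1.0


def phantom_geometry(spec: PhantomSpec) -> dict:
    """Deterministic geometry (masks and center) for a spec.

    Exposed separately so tests can rebuild the exact ellipsoid
    memberships the generator used.
    """
    spec.validate()
    shape = spec.volume_shape
    rng = np.random.default_rng(spec.seed)
    half = np.array(shape) / 2.0
    center = half - 0.5 + rng.uniform(-1, 1, size=3) * spec.center_jitter_frac * half
    brain = _ellipsoid_mask(shape, half - 0.5, spec.brain_radius_frac * half)
    r1, r2, r3 = spec.region_radii
    return {
        "center": center,
        "brain": brain,
        "wt": _sphere_mask(shape, center, r1),
        "tc": _sphere_mask(shape, center, r2),
        "et": _sphere_mask(shape, center, r3),
    }


def generate_phantom(spec: PhantomSpec) -> MultimodalVolume:
    """Render one phantom; deterministic for a fixed spec (and seed)."""
    geo = phantom_geometry(spec)
    shape = spec.volume_shape
    rng = np.random.default_rng(spec.seed)
    rng.uniform(-1, 1, size=3)  # consume the center-jitter draws

    labels = np.zeros(shape, dtype=np.int16)
    labels[geo["wt"]] = 2
    labels[geo["tc"]] = 1
    labels[geo["et"]] = 4

    region_masks = {
        "brain": geo["brain"] & ~geo["wt"],
        "edema": geo["wt"] & ~geo["tc"],
        "necrosis": geo["tc"] & ~geo["et"],
        "enhancing": geo["et"],
    }
    channels = np.zeros((len(MODALITIES), *shape), dtype=np.float32)
    for i, name in enumerate(MODALITIES):
        contrast = spec.modality_contrast[name]
        for region in REGION_ORDER:
            channels[i][region_masks[region]] = contrast[region]
        if spec.noise_sd > 0:
            noise = rng.normal(0, spec.noise_sd, size=shape).astype(np.float32)
            channels[i][geo["brain"]] += noise[geo["brain"]]
        if spec.bias_field:
            channels[i][geo["brain"]] *= _bias_field(shape, rng)[geo["brain"]]
        channels[i][~geo["brain"]] = 0.0

    return MultimodalVolume(channels=channels, labels=labels, case_id=f"phantom_{spec.seed:05d}")


def _bias_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [0.9, 1.1] from a low-order cosine."""
    grids = np.meshgrid(*(np.linspace(0, np.pi, d) for d in shape), indexing="ij")
    phase = rng.uniform(0, 2 * np.pi, size=3)
    f = sum(np.cos(g + p) for g, p in zip(grids, phase)) / 3.0
    return (1.0 + 0.1 * f).astype(np.float32)


def generate_dataset(
    n: int, spec: PhantomSpec, out_dir: str | Path, prefix: str = "phantom"
) -> dict:
    """Write ``n`` phantom cases (seed_i = spec.seed + i) plus a manifest."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = []
    for i in range(n):
        case_seed = spec.seed + i
        case_spec = PhantomSpec(
            volume_shape=spec.volume_shape,
            brain_radius_frac=spec.brain_radius_frac,
            region_radii=spec.region_radii,
            modality_contrast=spec.modality_contrast,
            noise_sd=spec.noise_sd,
            seed=case_seed,
            center_jitter_frac=spec.center_jitter_frac,
            bias_field=spec.bias_field,
        )
        vol = generate_phantom(case_spec)
        case_id = f"{prefix}_{i:05d}"
        vol.case_id = case_id
        case_dir = out_dir / case_id
        files = save_case(vol, case_dir)
        cases.append({"case_id": case_id, "dir": str(case_dir), "seed": case_seed, "files": files})
    manifest = {
        "n": n,
        "volume_shape": list(spec.volume_shape),
        "base_seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "region_radii": list(spec.region_radii),
        "cases": cases,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
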