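"""Contrast-enhanced T1 MRI phantom with a known opening volume.

The phantom is Gaussian background noise inside an ellipsoidal brain mask,
with an ellipsoidal "enhancing lesion" of additive contrast standing in
for the gadolinium-permeated opening.  The true opening volume is exact:
the count of voxel centers inside the lesion ellipsoid times the voxel
volume.  A rectangular contralateral reference ROI is placed on the side
opposite the lesion, inside the brain mask and disjoint from the lesion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..mri_volume import RoiSpec, VolumeImage, save_volume

__all__ = ["MriPhantomSpec", "MriPhantom", "gen_mri_volume", "write_mri_nifti"]


@dataclass(frozen=True)
class MriPhantomSpec:
    """Phantom geometry and intensity settings.

    Lengths are mm; ``lesion_center`` and ``contra_center`` are offsets
    from the grid center.  The default contrast of 50 over a background sd
    of 5 gives a contrast-to-noise ratio of 10.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.4)
    background_mean: float = 100.0
    background_sd: float = 5.0
    brain_radii: tuple[float, float, float] = (2.1, 2.1, 1.8)
    lesion_center: tuple[float, float, float] = (-0.3, 0.0, 0.0)
    lesion_radii: tuple[float, float, float] = (1.7, 1.7, 1.55)
    lesion_contrast: float = 50.0
    contra_center: tuple[float, float, float] = (1.75, 0.0, 0.0)
    contra_size: tuple[float, float, float] = (0.6, 1.6, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if any(r <= 0 for r in self.lesion_radii + self.brain_radii):
            raise ValueError("radii must be > 0")
        extent = [s * v / 2.0 for s, v in zip(self.grid_shape, self.voxel_size)]
        for c, r, e in zip(self.lesion_center, self.lesion_radii, extent):
            if abs(c) + r > e:
                raise ValueError("lesion must fit inside the grid")


@dataclass(frozen=True)
class MriPhantom:
    volume: VolumeImage
    brain_mask: np.ndarray
    contralateral_roi: np.ndarray
    lesion_mask: np.ndarray
    true_volume_mm3: float

    @property
    def roi_spec(self) -> RoiSpec:
        return RoiSpec(brain_mask=self.brain_mask, contralateral_roi=self.contralateral_roi)


def _coordinate_grids(spec: MriPhantomSpec) -> list[np.ndarray]:
    # physical voxel-center coordinates relative to the grid center, mm
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]
    return list(np.meshgrid(*axes, indexing="ij"))


def _ellipsoid_mask(
    grids: list[np.ndarray],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    acc = np.zeros_like(grids[0])
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def gen_mri_volume(spec: MriPhantomSpec) -> MriPhantom:
    """Render the phantom; ground-truth volume is exact by construction."""
    rng = np.random.default_rng(spec.seed)
    grids = _coordinate_grids(spec)
    brain = _ellipsoid_mask(grids, (0.0, 0.0, 0.0), spec.brain_radii)
    lesion = _ellipsoid_mask(grids, spec.lesion_center, spec.lesion_radii)
    lesion &= brain
    contra = np.ones(spec.grid_shape, dtype=bool)
    for g, c, s in zip(grids, spec.contra_center, spec.contra_size):
        contra &= np.abs(g - c) <= s / 2.0
    contra &= brain
    if contra.sum() == 0:
        raise ValueError("contralateral ROI is empty; move it inside the brain mask")
    if np.any(contra & lesion):
        raise ValueError("lesion overlaps the contralateral ROI")
    voxels = np.full(spec.grid_shape, spec.background_mean, dtype=float)
    voxels += rng.standard_normal(spec.grid_shape) * spec.background_sd
    voxels[lesion] += spec.lesion_contrast
    voxel_volume = float(np.prod(spec.voxel_size))
    return MriPhantom(
        volume=VolumeImage(voxels=voxels, voxel_size=spec.voxel_size, slice_axis=2),
        brain_mask=brain,
        contralateral_roi=contra,
        lesion_mask=lesion,
        true_volume_mm3=float(lesion.sum()) * voxel_volume,
    )


def write_mri_nifti(out_dir, spec: MriPhantomSpec) -> Path:
    """Write volume + masks as NIfTI and the truth as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom = gen_mri_volume(spec)
    save_volume(out_dir / "t1.nii", phantom.volume.voxels, spec.voxel_size)
    save_volume(out_dir / "brain_mask.nii", phantom.brain_mask.astype(np.uint8), spec.voxel_size)
    save_volume(out_dir / "contra_roi.nii", phantom.contralateral_roi.astype(np.uint8), spec.voxel_size)
    save_volume(out_dir / "lesion_mask.nii", phantom.lesion_mask.astype(np.uint8), spec.voxel_size)
    truth = {
        "true_volume_mm3": phantom.true_volume_mm3,
        "lesion_voxels": int(phantom.lesion_mask.sum()),
        "lesion_contrast": spec.lesion_contrast,
        "background_sd": spec.background_sd,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return out_dir
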