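"""Digital phantoms: a water-equivalent cube and a pelvis-like body with
bony structures, plus rigid sub-voxel shifting for registration studies.

All volumes live on a regular grid in patient axes (LAT, LNG, VRT) with the
isocenter at the grid center.  Values are linear attenuation in 1/mm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MU_AIR",
    "MU_SOFT",
    "MU_WATER",
    "MU_BONE",
    "VoxelVolume",
    "PhantomSpec",
    "make_cube_phantom",
    "make_pelvis_phantom",
    "shift_volume",
]

# Nominal linear attenuation coefficients (1/mm) around 60-80 keV.  Only the
# relative contrast matters for the validation metrics.
MU_AIR = 0.0
MU_SOFT = 0.018
MU_WATER = 0.020
MU_BONE = 0.048


@dataclass(frozen=True)
class VoxelVolume:
    """3D attenuation grid.

    ``values`` is indexed (LAT, LNG, VRT); ``voxel_mm`` holds the per-axis
    spacings (dx, dy, dz) and ``origin_mm`` the position of the center of
    voxel (0, 0, 0).  ``orientation`` tags tomosynthesis output volumes
    ('coronal' | 'sagittal') and is None for plain CT-like volumes.

    Phantom/CT volumes hold non-negative linear attenuation (the generators
    guarantee it); reconstructed stacks may carry small negative ringing.
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    orientation: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={v.ndim}")
        if any(d <= 0 for d in self.voxel_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_mm}")
        if not np.all(np.isfinite(v)):
            raise ValueError("attenuation values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_mm", tuple(float(d) for d in self.voxel_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_mm[axis] * np.arange(n)

    def total_attenuation(self) -> float:
        return float(self.values.sum())

    def centroid_mm(self) -> np.ndarray:
        """Attenuation-weighted centroid in patient axes (mm)."""
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot compute centroid of an empty volume")
        out = np.empty(3)
        for ax in range(3):
            proj = self.values.sum(axis=tuple(a for a in range(3) if a != ax))
            out[ax] = float(np.dot(self.axis_centers_mm(ax), proj) / total)
        return out

    # -- raw + JSON persistence ------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.raw`` (float32, C order) and ``<path>.json``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        raw = path.with_suffix(".raw")
        self.values.astype(np.float32).tofile(raw)
        meta = {
            "shape": list(self.shape),
            "voxel_mm": list(self.voxel_mm),
            "origin_mm": list(self.origin_mm),
            "orientation": self.orientation,
            "dtype": "float32",
            "axis_order": ["LAT", "LNG", "VRT"],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelVolume":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        values = np.fromfile(path.with_suffix(".raw"), dtype=np.float32)
        values = values.reshape(meta["shape"]).astype(np.float64)
        return cls(
            values=values,
            voxel_mm=tuple(meta["voxel_mm"]),
            origin_mm=tuple(meta["origin_mm"]),
            orientation=meta.get("orientation"),
        )


def _centered_grid(shape: tuple[int, int, int], voxel_mm: tuple[float, float, float]):
    """1D voxel-center coordinates per axis for an isocenter-centered grid."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, voxel_mm)
    ]


def _centered_origin(shape, voxel_mm) -> tuple[float, float, float]:
    return tuple(-(n - 1) / 2.0 * d for n, d in zip(shape, voxel_mm))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for the built-in phantoms.

    ``kind`` is 'cube' or 'pelvis'.  The cube uses ``edge_mm``; the pelvis
    uses ``body_semiaxes_mm`` (LAT, LNG, VRT semi-axes of the soft-tissue
    ellipsoid) with bone/air structures scaled to the body.
    """

    kind: str = "cube"
    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    edge_mm: float = 50.0
    body_semiaxes_mm: tuple[float, float, float] = (52.0, 55.0, 40.0)
    mu_water: float = MU_WATER
    mu_soft: float = MU_SOFT
    mu_bone: float = MU_BONE
    mu_air: float = MU_AIR

    def __post_init__(self) -> None:
        if self.kind not in ("cube", "pelvis"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (self.mu_air < self.mu_soft <= self.mu_water < self.mu_bone):
            raise ValueError("attenuations must satisfy air < soft <= water < bone")


def _axis_occupancy(centers: np.ndarray, half_mm: float, d: float) -> np.ndarray:
    """Fraction of each voxel interval [c-d/2, c+d/2] inside [-half, +half]."""
    lo = np.maximum(centers - d / 2.0, -half_mm)
    hi = np.minimum(centers + d / 2.0, half_mm)
    return np.clip(hi - lo, 0.0, None) / d


def make_cube_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Axis-aligned water cube centered at isocenter on an air background.

    Edge voxels are weighted by the occupied fraction along each axis
    (separable partial-volume model), so grid-aligned faces are exact.
    """
    if spec.edge_mm < 0:
        raise ValueError("edge_mm must be non-negative")
    grids = _centered_grid(spec.shape, spec.voxel_mm)
    half = spec.edge_mm / 2.0
    for n, d, g in zip(spec.shape, spec.voxel_mm, grids):
        if spec.edge_mm > n * d:
            raise ValueError(
                f"cube edge {spec.edge_mm} mm exceeds grid extent {n * d} mm"
            )
    fx = _axis_occupancy(grids[0], half, spec.voxel_mm[0])
    fy = _axis_occupancy(grids[1], half, spec.voxel_mm[1])
    fz = _axis_occupancy(grids[2], half, spec.voxel_mm[2])
    values = spec.mu_water * fx[:, None, None] * fy[None, :, None] * fz[None, None, :]
    return VoxelVolume(values, spec.voxel_mm, _centered_origin(spec.shape, spec.voxel_mm))


def make_pelvis_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Pelvis-like phantom: elliptical soft-tissue body, bilateral bone
    cylinders ('hips'), a posterior midline bone column and an anterior air
    cavity.  Deterministic and mirror-symmetric about the sagittal midplane.
    """
    a, b, c = spec.body_semiaxes_mm
    grids = _centered_grid(spec.shape, spec.voxel_mm)
    for semi, n, d in zip((a, b, c), spec.shape, spec.voxel_mm):
        if 2 * semi > n * d:
            raise ValueError("pelvis body does not fit inside the grid")

    x = grids[0][:, None, None]
    y = grids[1][None, :, None]
    z = grids[2][None, None, :]

    body = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    values = np.where(body, spec.mu_soft, spec.mu_air)

    # Bone structures scaled to the body so they always fit inside it.
    hip_x, hip_z = 0.55 * a, -0.15 * c
    hip_r = 0.18 * min(a, c)
    hip_halflen = 0.55 * b
    for sx in (-1.0, 1.0):
        hip = ((x - sx * hip_x) ** 2 + (z - hip_z) ** 2 <= hip_r**2) & (
            np.abs(y) <= hip_halflen
        )
        if np.any(hip & ~body):
            raise ValueError("hip structure extends outside the body")
        values = np.where(hip, spec.mu_bone, values)

    spine_z = -0.55 * c
    spine_r = 0.16 * min(a, c)
    spine = (x**2 + (z - spine_z) ** 2 <= spine_r**2) & (np.abs(y) <= 0.55 * b)
    if np.any(spine & ~body):
        raise ValueError("spine structure extends outside the body")
    values = np.where(spine, spec.mu_bone, values)

    cavity_z = 0.45 * c
    cavity_r = 0.14 * min(a, c)
    cavity = (x**2 + (z - cavity_z) ** 2 <= cavity_r**2) & (np.abs(y) <= 0.4 * b)
    values = np.where(cavity & body, spec.mu_air, values)

    return VoxelVolume(values, spec.voxel_mm, _centered_origin(spec.shape, spec.voxel_mm))


def shift_volume(vol: VoxelVolume, shift_mm: tuple[float, float, float]) -> VoxelVolume:
    """Translate the content by ``shift_mm`` (LAT, LNG, VRT) with trilinear
    interpolation; voxels shifted in from outside the field are background
    (zero).  Logs a warning if more than 1% of the total attenuation leaves
    the field of view.
    """
    shift_vox = [s / d for s, d in zip(shift_mm, vol.voxel_mm)]
    if all(s == 0 for s in shift_vox):
        return replace(vol, values=vol.values.copy())
    shifted = ndimage.shift(
        vol.values, shift_vox, order=1, mode="constant", cval=0.0, prefilter=False
    )
    shifted = np.clip(shifted, 0.0, None)
    before = vol.values.sum()
    if before > 0:
        lost = 1.0 - shifted.sum() / before
        if lost > 0.01:
            logger.warning(
                "shift_volume: %.2f%% of total attenuation moved out of field "
                "(shift %s mm)",
                100.0 * lost,
                shift_mm,
            )
    return replace(vol, values=shifted)
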