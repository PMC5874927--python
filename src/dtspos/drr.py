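"""Digitally reconstructed radiographs: divergent-beam line integrals
through a voxel volume.

Two engines share one mathematical contract (fixed-step ray sampling with
trilinear interpolation, step <= min(voxel)/2, midpoint rule scaled by the
step length):

* :func:`drr_oracle` — a brute-force per-ray reference loop (compiled scalar
  code, each ray traced and accumulated independently);
* :func:`drr_fast`   — a batched engine that sets rays up as arrays and
  marches a whole detector row in lockstep with fastmath enabled.

They play the role of independent reference/accelerated implementations and
are compared via correlation and subtraction statistics downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numba import njit

from .geometry import ScanGeometry, detector_axes, source_position
from .phantoms import VoxelVolume

__all__ = [
    "ProjectionImage",
    "ProjectionSet",
    "drr_oracle",
    "drr_fast",
    "to_intensity",
    "to_line_integral",
]


@dataclass(frozen=True)
class ProjectionImage:
    """One detector image. ``pixels`` has shape (nu, nv); axis 0 is the
    horizontal detector axis u, axis 1 the vertical axis v (parallel LNG)."""

    pixels: np.ndarray
    angle_deg: float
    domain: str  # 'line_integral' | 'intensity'
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.shape != (self.geometry.detector_nu, self.geometry.detector_nv):
            raise ValueError(
                f"pixel grid {p.shape} does not match detector "
                f"{self.geometry.detector_nu}x{self.geometry.detector_nv}"
            )
        if self.domain not in ("line_integral", "intensity"):
            raise ValueError(f"unknown domain {self.domain!r}")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class ProjectionSet:
    """Ordered projection images, one per geometry angle, shared domain."""

    geometry: ScanGeometry
    images: tuple[ProjectionImage, ...]

    def __post_init__(self) -> None:
        if len(self.images) != self.geometry.n_angles:
            raise ValueError("number of images must match geometry angles")
        for img, ang in zip(self.images, self.geometry.angles_deg):
            if img.angle_deg != ang:
                raise ValueError("image angles must match geometry angles in order")
        domains = {img.domain for img in self.images}
        if len(domains) > 1:
            raise ValueError("projection set mixes domains")

    @property
    def domain(self) -> str:
        return self.images[0].domain

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> ProjectionImage:
        return self.images[i]

    # -- raw + JSON persistence ------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(self.images):
            img.pixels.astype(np.float32).tofile(d / f"proj_{i:04d}.raw")
        g = self.geometry
        meta = {
            "domain": self.domain,
            "angles_deg": [float(a) for a in g.angles_deg],
            "angular_spacing_deg": g.angular_spacing_deg,
            "sad_mm": g.sad_mm,
            "sdd_mm": g.sdd_mm,
            "detector": {"nu": g.detector_nu, "nv": g.detector_nv,
                         "pixel_mm": g.detector_pixel_mm},
            "dtype": "float32",
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ProjectionSet":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        det = meta["detector"]
        geom = ScanGeometry(
            sad_mm=meta["sad_mm"],
            sdd_mm=meta["sdd_mm"],
            detector_nu=det["nu"],
            detector_nv=det["nv"],
            detector_pixel_mm=det["pixel_mm"],
            angles_deg=np.asarray(meta["angles_deg"], dtype=float),
            angular_spacing_deg=meta["angular_spacing_deg"],
        )
        images = []
        for i, ang in enumerate(geom.angles_deg):
            raw = np.fromfile(d / f"proj_{i:04d}.raw", dtype=np.float32)
            pixels = raw.reshape(det["nu"], det["nv"]).astype(np.float64)
            images.append(
                ProjectionImage(pixels, float(ang), meta["domain"], geom)
            )
        return cls(geom, tuple(images))


def default_step_mm(vol: VoxelVolume) -> float:
    return min(vol.voxel_mm) / 2.0


def _volume_bounds(vol: VoxelVolume) -> tuple[np.ndarray, np.ndarray]:
    """Outer physical bounds (voxel edges) of the volume in mm."""
    lo = np.array([o - d / 2.0 for o, d in zip(vol.origin_mm, vol.voxel_mm)])
    hi = np.array(
        [
            o + (n - 0.5) * d
            for o, d, n in zip(vol.origin_mm, vol.voxel_mm, vol.shape)
        ]
    )
    return lo, hi


@njit(cache=True)
def _trilinear(vol, fx, fy, fz):
    """Trilinear sample with zero outside the grid (matches
    ``map_coordinates(order=1, mode='constant', cval=0)``)."""
    nx, ny, nz = vol.shape
    x0 = math.floor(fx)
    y0 = math.floor(fy)
    z0 = math.floor(fz)
    tx = fx - x0
    ty = fy - y0
    tz = fz - z0
    acc = 0.0
    for dx in range(2):
        xi = int(x0) + dx
        if xi < 0 or xi >= nx:
            continue
        wx = tx if dx == 1 else 1.0 - tx
        for dy in range(2):
            yi = int(y0) + dy
            if yi < 0 or yi >= ny:
                continue
            wy = ty if dy == 1 else 1.0 - ty
            for dz in range(2):
                zi = int(z0) + dz
                if zi < 0 or zi >= nz:
                    continue
                wz = tz if dz == 1 else 1.0 - tz
                acc += wx * wy * wz * vol[xi, yi, zi]
    return acc


@njit(cache=True)
def _drr_kernel(
    vol,
    origin,
    voxel,
    lo,
    hi,
    src,
    corner,
    u_hat,
    v_hat,
    pixel_mm,
    nu,
    nv,
    step,
):
    out = np.zeros((nu, nv))
    for iu in range(nu):
        for iv in range(nv):
            px = corner[0] + iu * pixel_mm * u_hat[0] + iv * pixel_mm * v_hat[0]
            py = corner[1] + iu * pixel_mm * u_hat[1] + iv * pixel_mm * v_hat[1]
            pz = corner[2] + iu * pixel_mm * u_hat[2] + iv * pixel_mm * v_hat[2]
            dx = px - src[0]
            dy = py - src[1]
            dz = pz - src[2]
            norm = math.sqrt(dx * dx + dy * dy + dz * dz)
            if norm == 0.0:
                continue
            dx /= norm
            dy /= norm
            dz /= norm
            t0 = 0.0
            t1 = 1e30
            hit = True
            for ax in range(3):
                if ax == 0:
                    d, s = dx, src[0]
                elif ax == 1:
                    d, s = dy, src[1]
                else:
                    d, s = dz, src[2]
                if d == 0.0:
                    if s < lo[ax] or s > hi[ax]:
                        hit = False
                        break
                else:
                    ta = (lo[ax] - s) / d
                    tb = (hi[ax] - s) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if not hit or t1 <= t0:
                continue
            n = int(math.ceil((t1 - t0) / step))
            if n < 1:
                continue
            dt = (t1 - t0) / n
            acc = 0.0
            for k in range(n):
                t = t0 + (k + 0.5) * dt
                fx = (src[0] + t * dx - origin[0]) / voxel[0]
                fy = (src[1] + t * dy - origin[1]) / voxel[1]
                fz = (src[2] + t * dz - origin[2]) / voxel[2]
                acc += _trilinear(vol, fx, fy, fz)
            out[iu, iv] = acc * dt
    return out


def drr_oracle(
    vol: VoxelVolume,
    geom: ScanGeometry,
    angle_deg: float,
    step_mm: float | None = None,
) -> ProjectionImage:
    """Reference per-ray DRR at one gantry angle (line-integral domain)."""
    step = default_step_mm(vol) if step_mm is None else float(step_mm)
    if step <= 0:
        raise ValueError("step_mm must be positive")
    src = source_position(geom, angle_deg)
    u_hat, v_hat, ray_hat = detector_axes(angle_deg)
    center = src + geom.sdd_mm * ray_hat
    corner = (
        center
        - (geom.detector_nu - 1) / 2.0 * geom.detector_pixel_mm * u_hat
        - (geom.detector_nv - 1) / 2.0 * geom.detector_pixel_mm * v_hat
    )
    lo, hi = _volume_bounds(vol)
    pixels = _drr_kernel(
        vol.values,
        np.asarray(vol.origin_mm),
        np.asarray(vol.voxel_mm),
        lo,
        hi,
        src,
        corner,
        u_hat,
        v_hat,
        geom.detector_pixel_mm,
        geom.detector_nu,
        geom.detector_nv,
        step,
    )
    return ProjectionImage(pixels, float(angle_deg), "line_integral", geom)


@njit(cache=True, fastmath=True)
def _drr_fast_kernel(
    vol,
    origin,
    voxel,
    lo,
    hi,
    src,
    corner,
    u_hat,
    v_hat,
    pixel_mm,
    nu,
    nv,
    step,
):
    """Batched engine: rays of one detector row are set up as arrays and
    marched in lockstep (all rays advance one step per inner pass), the
    computational pattern of a GPU thread block.  Same sampling contract as
    the per-ray reference kernel; fastmath reassociation makes the float
    accumulation differ at machine precision."""
    out = np.zeros((nu, nv))
    dx = np.empty(nv)
    dy = np.empty(nv)
    dz = np.empty(nv)
    t0a = np.empty(nv)
    dta = np.empty(nv)
    na = np.empty(nv, dtype=np.int64)
    acc = np.empty(nv)
    for iu in range(nu):
        bx = corner[0] + iu * pixel_mm * u_hat[0]
        by = corner[1] + iu * pixel_mm * u_hat[1]
        bz = corner[2] + iu * pixel_mm * u_hat[2]
        nmax = 0
        for iv in range(nv):
            px = bx + iv * pixel_mm * v_hat[0]
            py = by + iv * pixel_mm * v_hat[1]
            pz = bz + iv * pixel_mm * v_hat[2]
            ddx = px - src[0]
            ddy = py - src[1]
            ddz = pz - src[2]
            norm = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            na[iv] = 0
            if norm == 0.0:
                continue
            ddx /= norm
            ddy /= norm
            ddz /= norm
            dx[iv] = ddx
            dy[iv] = ddy
            dz[iv] = ddz
            t0 = 0.0
            t1 = 1e30
            hit = True
            for ax in range(3):
                if ax == 0:
                    d, s = ddx, src[0]
                elif ax == 1:
                    d, s = ddy, src[1]
                else:
                    d, s = ddz, src[2]
                if d == 0.0:
                    if s < lo[ax] or s > hi[ax]:
                        hit = False
                        break
                else:
                    ta = (lo[ax] - s) / d
                    tb = (hi[ax] - s) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if not hit or t1 <= t0:
                continue
            n = int(math.ceil((t1 - t0) / step))
            if n < 1:
                continue
            na[iv] = n
            t0a[iv] = t0
            dta[iv] = (t1 - t0) / n
            acc[iv] = 0.0
            if n > nmax:
                nmax = n
        for k in range(nmax):
            for iv in range(nv):
                if k < na[iv]:
                    t = t0a[iv] + (k + 0.5) * dta[iv]
                    fx = (src[0] + t * dx[iv] - origin[0]) / voxel[0]
                    fy = (src[1] + t * dy[iv] - origin[1]) / voxel[1]
                    fz = (src[2] + t * dz[iv] - origin[2]) / voxel[2]
                    acc[iv] += _trilinear(vol, fx, fy, fz)
        for iv in range(nv):
            if na[iv] > 0:
                out[iu, iv] = acc[iv] * dta[iv]
    return out


def drr_fast(
    vol: VoxelVolume, geom: ScanGeometry, step_mm: float | None = None
) -> ProjectionSet:
    """Fast DRR engine: same mathematical contract as :func:`drr_oracle`
    for every geometry angle, with rays batched and marched in lockstep.
    Bit-reproducible across runs."""
    step = default_step_mm(vol) if step_mm is None else float(step_mm)
    if step <= 0:
        raise ValueError("step_mm must be positive")
    lo, hi = _volume_bounds(vol)
    origin = np.asarray(vol.origin_mm)
    voxel = np.asarray(vol.voxel_mm)
    images = []
    for a in geom.angles_deg:
        src = source_position(geom, float(a))
        u_hat, v_hat, ray_hat = detector_axes(float(a))
        center = src + geom.sdd_mm * ray_hat
        corner = (
            center
            - (geom.detector_nu - 1) / 2.0 * geom.detector_pixel_mm * u_hat
            - (geom.detector_nv - 1) / 2.0 * geom.detector_pixel_mm * v_hat
        )
        pixels = _drr_fast_kernel(
            vol.values,
            origin,
            voxel,
            lo,
            hi,
            src,
            corner,
            u_hat,
            v_hat,
            geom.detector_pixel_mm,
            geom.detector_nu,
            geom.detector_nv,
            step,
        )
        images.append(ProjectionImage(pixels, float(a), "line_integral", geom))
    return ProjectionSet(geom, tuple(images))


def to_intensity(p: ProjectionImage, I0: float = 1.0) -> ProjectionImage:
    """Beer-Lambert conversion ``I = I0 * exp(-line_integral)``."""
    if p.domain != "line_integral":
        raise ValueError("to_intensity expects a line-integral projection")
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    if np.any(p.pixels < 0):
        raise ValueError("negative line integrals are invalid")
    return replace(p, pixels=I0 * np.exp(-p.pixels), domain="intensity")


def to_line_integral(p: ProjectionImage, I0: float = 1.0) -> ProjectionImage:
    """Logarithm conversion ``q = ln(I0 / I)``, inverse of :func:`to_intensity`."""
    if p.domain != "intensity":
        raise ValueError("to_line_integral expects an intensity projection")
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    bad = int(np.count_nonzero(p.pixels <= 0))
    if bad:
        raise ValueError(f"{bad} non-positive intensity pixels cannot be log-converted")
    return replace(p, pixels=np.log(I0 / p.pixels), domain="line_integral")
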