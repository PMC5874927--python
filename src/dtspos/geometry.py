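"""Cone-beam acquisition geometry for narrow-arc tomosynthesis imaging.

Coordinate conventions
----------------------
Patient axes form a right-handed frame centered at the isocenter:

* ``LAT`` (x): patient left-right,
* ``LNG`` (y): patient superior-inferior,
* ``VRT`` (z): patient anterior-posterior.

Gantry angle 0 deg places the X-ray source anterior to the patient, so the
central ray points along ``-VRT`` and produces the coronal view; 270 deg is a
lateral source producing the sagittal view.  Rotation is counterclockwise as
seen from the couch foot, i.e. successive angles of a default scan decrease.

The detector ``u`` axis is horizontal (in the rotation plane, aligned with
``+LAT`` at gantry 0 deg); ``v`` is parallel to ``LNG``.  Pixel (0, 0) is a
detector corner and rays are cast through pixel centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ScanGeometry",
    "make_full_fan_geometry",
    "select_arc",
    "projection_savings",
    "source_and_ray",
    "source_position",
    "detector_axes",
    "circular_distance_deg",
    "load_geometry_config",
]


def circular_distance_deg(a: np.ndarray | float, b: float) -> np.ndarray | float:
    """Unsigned circular distance between angles in degrees, in [0, 180]."""
    return np.abs((np.asarray(a) - b + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class ScanGeometry:
    """Circular cone-beam scan: source/detector distances, detector grid and
    the ordered gantry angles of the acquisition (or of a selected sub-arc).

    ``angular_spacing_deg`` is the per-view angular bin ``total_range / n``
    of the parent acquisition; sub-arcs inherit it.
    """

    sad_mm: float
    sdd_mm: float
    detector_nu: int
    detector_nv: int
    detector_pixel_mm: float
    angles_deg: np.ndarray
    angular_spacing_deg: float

    def __post_init__(self) -> None:
        if not (self.sdd_mm > self.sad_mm > 0):
            raise ValueError(
                f"require sdd_mm > sad_mm > 0, got sad={self.sad_mm}, sdd={self.sdd_mm}"
            )
        if self.detector_pixel_mm <= 0:
            raise ValueError("detector_pixel_mm must be positive")
        if self.detector_nu < 1 or self.detector_nv < 1:
            raise ValueError("detector grid must be at least 1x1")
        angles = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if angles.size == 0:
            raise ValueError("angles_deg must be non-empty")
        if angles.size > 1:
            d = np.diff(angles)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("angles_deg must be strictly monotone (unwrapped)")
        object.__setattr__(self, "angles_deg", angles)

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)

    @property
    def magnification(self) -> float:
        return self.sdd_mm / self.sad_mm

    @property
    def pixel_mm_at_iso(self) -> float:
        """Detector pixel size scaled back to the isocenter plane."""
        return self.detector_pixel_mm * self.sad_mm / self.sdd_mm

    def angles_wrapped_deg(self) -> np.ndarray:
        """Angles mapped onto [0, 360) for reporting."""
        return self.angles_deg % 360.0

    def with_angles(self, angles_deg: np.ndarray) -> "ScanGeometry":
        return replace(self, angles_deg=np.asarray(angles_deg, dtype=float))


def make_full_fan_geometry(
    start_deg: float,
    range_deg: float,
    n_projections: int,
    detector: tuple[int, int, float] = (512, 384, 0.776),
    sad_mm: float = 1000.0,
    sdd_mm: float = 1500.0,
    direction: str = "ccw",
) -> ScanGeometry:
    """Build an evenly spaced circular scan.

    ``detector`` is ``(nu, nv, pixel_mm)``.  Spacing follows the
    ``range / n`` convention (each view owns one angular bin), so a 200 deg
    scan with 375 views has spacing 200/375 = 0.533 deg.  ``direction='ccw'``
    makes successive angles decrease from ``start_deg`` (a clinical full-fan
    scan running e.g. from +20 deg down to -180 deg); ``'cw'`` increases.
    """
    if n_projections < 1:
        raise ValueError(f"n_projections must be >= 1, got {n_projections}")
    if range_deg <= 0:
        raise ValueError(f"range_deg must be positive, got {range_deg}")
    if direction not in ("ccw", "cw"):
        raise ValueError(f"direction must be 'ccw' or 'cw', got {direction!r}")
    spacing = float(range_deg) / n_projections
    sign = -1.0 if direction == "ccw" else 1.0
    angles = start_deg + sign * spacing * np.arange(n_projections, dtype=float)
    nu, nv, pixel = detector
    return ScanGeometry(
        sad_mm=sad_mm,
        sdd_mm=sdd_mm,
        detector_nu=int(nu),
        detector_nv=int(nv),
        detector_pixel_mm=float(pixel),
        angles_deg=angles,
        angular_spacing_deg=spacing,
    )


def select_arc(geom: ScanGeometry, center_deg: float, arc_deg: float) -> ScanGeometry:
    """Sub-geometry with the angles whose circular distance to ``center_deg``
    is at most ``arc_deg / 2``; order preserved, wrap (270 == -90) handled."""
    if arc_deg <= 0:
        raise ValueError(f"arc_deg must be positive, got {arc_deg}")
    dist = circular_distance_deg(geom.angles_deg, center_deg)
    mask = dist <= arc_deg / 2.0 + 1e-9
    if not np.any(mask):
        raise ValueError(
            f"no angles within the {arc_deg} deg window centered at {center_deg} deg"
        )
    return geom.with_angles(geom.angles_deg[mask])


def projection_savings(n_dts: int, n_full: int) -> float:
    """Percentage of projections saved by a DTS acquisition vs a full scan."""
    if n_full <= 0:
        raise ValueError("n_full must be positive")
    if not 0 <= n_dts <= n_full:
        raise ValueError(f"require 0 <= n_dts <= n_full, got {n_dts} > {n_full}")
    return 100.0 * (n_full - n_dts) / n_full


def source_position(geom: ScanGeometry, angle_deg: float) -> np.ndarray:
    """Source location in patient axes (mm) for a gantry angle."""
    t = np.deg2rad(angle_deg)
    return geom.sad_mm * np.array([-np.sin(t), 0.0, np.cos(t)])


def detector_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors ``(u_hat, v_hat, ray_hat)`` for a gantry angle.

    ``ray_hat`` points from source toward the detector (through isocenter).
    """
    t = np.deg2rad(angle_deg)
    u_hat = np.array([np.cos(t), 0.0, np.sin(t)])
    v_hat = np.array([0.0, 1.0, 0.0])
    ray_hat = np.array([np.sin(t), 0.0, -np.cos(t)])
    return u_hat, v_hat, ray_hat


def detector_pixel_position(
    geom: ScanGeometry, angle_deg: float, iu: float, iv: float
) -> np.ndarray:
    """Physical center of detector pixel (iu, iv) in patient axes (mm)."""
    u_hat, v_hat, ray_hat = detector_axes(angle_deg)
    src = source_position(geom, angle_deg)
    center = src + geom.sdd_mm * ray_hat
    du = (iu - (geom.detector_nu - 1) / 2.0) * geom.detector_pixel_mm
    dv = (iv - (geom.detector_nv - 1) / 2.0) * geom.detector_pixel_mm
    return center + du * u_hat + dv * v_hat


def source_and_ray(
    geom: ScanGeometry, angle_deg: float, pixel_uv: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Ray origin (source) and unit direction through a detector pixel center."""
    iu, iv = pixel_uv
    if not (0 <= iu < geom.detector_nu and 0 <= iv < geom.detector_nv):
        raise IndexError(
            f"pixel {pixel_uv} outside detector grid "
            f"{geom.detector_nu}x{geom.detector_nv}"
        )
    src = source_position(geom, angle_deg)
    target = detector_pixel_position(geom, angle_deg, iu, iv)
    d = target - src
    n = np.linalg.norm(d)
    if n == 0:
        raise RuntimeError("degenerate ray: source coincides with detector pixel")
    return src, d / n


def load_geometry_config(path: str | Path) -> dict:
    """Read a YAML/JSON scan-geometry config.

    Expected keys: ``sad_mm``, ``sdd_mm``, ``detector {nu, nv, pixel_mm}``,
    ``scan {start_deg, range_deg, n_projections}``, optional
    ``arcs [{center_deg, arc_deg}]``.  Returns ``{"geometry": ScanGeometry,
    "arcs": [...]}``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    det = cfg["detector"]
    scan = cfg["scan"]
    geom = make_full_fan_geometry(
        start_deg=float(scan["start_deg"]),
        range_deg=float(scan["range_deg"]),
        n_projections=int(scan["n_projections"]),
        detector=(int(det["nu"]), int(det["nv"]), float(det["pixel_mm"])),
        sad_mm=float(cfg.get("sad_mm", 1000.0)),
        sdd_mm=float(cfg.get("sdd_mm", 1500.0)),
        direction=scan.get("direction", "ccw"),
    )
    return {"geometry": geom, "arcs": cfg.get("arcs", [])}
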