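"""End-to-end validation studies: geometric accuracy of the cube phantom,
shift-recovery accuracy of the two-session registration, and reference/fast
engine comparisons.  These drive both the CLI ``validate`` commands and the
acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drr import ProjectionSet, drr_fast, drr_oracle, to_intensity
from .geometry import (
    ScanGeometry,
    circular_distance_deg,
    make_full_fan_geometry,
    select_arc,
)
from .metrics import correlation_coefficient, measure_edge_length, subtraction_stats
from .phantoms import (
    PhantomSpec,
    VoxelVolume,
    make_cube_phantom,
    make_pelvis_phantom,
    shift_volume,
)
from .recon import DTSVolumeSpec, FilterSpec, reconstruct_dts
from .registration import focal_image, two_session_registration

__all__ = [
    "StudyScale",
    "DESK_SCALE",
    "TEST_SCALE",
    "build_phantom",
    "full_geometry",
    "arc_projections",
    "onboard",
    "dts_spec",
    "geometric_accuracy_report",
    "registration_study",
    "engine_comparison",
    "acquisition_arithmetic",
]

_ARC_CENTER = {"coronal": 0.0, "sagittal": 270.0}


@dataclass(frozen=True)
class StudyScale:
    """Knobs that trade runtime for fidelity in the simulation studies.

    ``subsample`` keeps every k-th projection of a selected arc; the full-fan
    protocol itself (start/range/count) is fixed by the acquisition settings.
    """

    vol_shape: tuple[int, int, int] = (128, 128, 128)
    vol_voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    detector: tuple[int, int, float] = (256, 192, 1.552)
    scan_start_deg: float = 20.0
    scan_range_deg: float = 200.0
    scan_n: int = 375
    subsample: int = 4
    dts_pixel_mm: float = 0.5
    dts_slice_mm: float = 0.5
    dts_n_slices: int = 16
    dts_n_inplane: tuple[int, int] = (128, 128)
    cube_edge_mm: float = 50.0
    pelvis_semiaxes_mm: tuple[float, float, float] = (40.0, 45.0, 32.0)


DESK_SCALE = StudyScale()

# Reduced grids for the test suite; tolerances are unchanged.
TEST_SCALE = StudyScale(
    vol_shape=(96, 96, 96),
    detector=(192, 144, 2.0),
    subsample=6,
    dts_pixel_mm=0.75,
    dts_n_slices=8,
    dts_n_inplane=(96, 96),
)


def build_phantom(kind: str, scale: StudyScale) -> VoxelVolume:
    spec = PhantomSpec(
        kind=kind,
        shape=scale.vol_shape,
        voxel_mm=scale.vol_voxel_mm,
        edge_mm=scale.cube_edge_mm,
        body_semiaxes_mm=scale.pelvis_semiaxes_mm,
    )
    if kind == "cube":
        return make_cube_phantom(spec)
    return make_pelvis_phantom(spec)


def full_geometry(scale: StudyScale) -> ScanGeometry:
    return make_full_fan_geometry(
        start_deg=scale.scan_start_deg,
        range_deg=scale.scan_range_deg,
        n_projections=scale.scan_n,
        detector=scale.detector,
    )


def _subsampled_arc(
    geom: ScanGeometry, center_deg: float, arc_deg: float, subsample: int
) -> ScanGeometry:
    arc = select_arc(geom, center_deg, arc_deg)
    return arc.with_angles(arc.angles_deg[::subsample])


def subset_projections(
    pset: ProjectionSet, center_deg: float, arc_deg: float
) -> ProjectionSet:
    """Restrict a projection set to the angles of an arc window."""
    dist = circular_distance_deg(pset.geometry.angles_deg, center_deg)
    keep = [i for i, d in enumerate(dist) if d <= arc_deg / 2.0 + 1e-9]
    if not keep:
        raise ValueError(f"no projections within the {arc_deg} deg window")
    geom = pset.geometry.with_angles(pset.geometry.angles_deg[keep])
    return ProjectionSet(geom, tuple(pset.images[i] for i in keep))


def arc_projections(
    vol: VoxelVolume,
    scale: StudyScale,
    center_deg: float,
    arc_deg: float,
    engine: str = "fast",
) -> ProjectionSet:
    """DRRs of ``vol`` over a (subsampled) arc of the full-fan protocol."""
    geom = _subsampled_arc(full_geometry(scale), center_deg, arc_deg, scale.subsample)
    if engine == "fast":
        return drr_fast(vol, geom)
    images = tuple(drr_oracle(vol, geom, float(a)) for a in geom.angles_deg)
    return ProjectionSet(geom, images)


def onboard(pset: ProjectionSet, I0: float = 1.0) -> ProjectionSet:
    """Convert DRRs to the intensity domain, simulating onboard cone-beam
    projections (reconstruction then applies the logarithm conversion)."""
    return ProjectionSet(pset.geometry, tuple(to_intensity(p, I0) for p in pset.images))


def dts_spec(orientation: str, scale: StudyScale) -> DTSVolumeSpec:
    return DTSVolumeSpec(
        orientation=orientation,
        pixel_mm=scale.dts_pixel_mm,
        slice_thickness_mm=scale.dts_slice_mm,
        n_slices=scale.dts_n_slices,
        n_inplane=scale.dts_n_inplane,
    )


# ---------------------------------------------------------------------------
# geometric accuracy
# ---------------------------------------------------------------------------

def _measure_lengths(
    dts: VoxelVolume, edge_mm: float, n_lines: int = 5
) -> tuple[list[float], list[float]]:
    """Edge lengths along both in-plane axes of the focal plane, measured on
    ``n_lines`` profile lines evenly spaced across the central third of the
    object face."""
    img, pix = focal_image(dts, 1)
    offsets = np.linspace(-edge_mm / 6.0, edge_mm / 6.0, n_lines)
    first = [measure_edge_length(img, 0, o, pix) for o in offsets]
    second = [measure_edge_length(img, 1, o, pix) for o in offsets]
    return first, second


def geometric_accuracy_report(
    scale: StudyScale = DESK_SCALE,
    arcs: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0),
    engines: tuple[str, ...] = ("fast",),
    n_lines: int = 5,
    filt: FilterSpec = FilterSpec(window="none"),
) -> dict:
    """Cube-phantom edge lengths on coronal (LAT, LNG) and sagittal
    (LNG, VRT) focal planes per arc and engine, with means/SDs over the
    measurement lines and deviations from the true edge.

    The unapodized ramp is the default here: edge localization on noise-free
    synthetic projections needs no apodization, and the window's smoothing
    is what is under test downstream, not here.
    """
    cube = build_phantom("cube", scale)
    edge = scale.cube_edge_mm
    rows = []
    for engine in engines:
        for arc in arcs:
            cor = arc_projections(cube, scale, 0.0, arc, engine)
            sag = arc_projections(cube, scale, 270.0, arc, engine)
            dts_cor = reconstruct_dts(cor, dts_spec("coronal", scale), engine, filt=filt)
            dts_sag = reconstruct_dts(sag, dts_spec("sagittal", scale), engine, filt=filt)
            lat, lng_c = _measure_lengths(dts_cor, edge, n_lines)
            lng_s, vrt = _measure_lengths(dts_sag, edge, n_lines)
            row = {"arc_deg": arc, "engine": engine}
            for name, vals in (
                ("lat", lat), ("lng_cor", lng_c), ("lng_sag", lng_s), ("vrt", vrt)
            ):
                vals = np.asarray(vals)
                row[f"{name}_mean_mm"] = float(vals.mean())
                row[f"{name}_sd_mm"] = float(vals.std())
                row[f"{name}_dev_mm"] = float(np.abs(vals - edge).max())
            rows.append(row)
    max_dev = max(
        row[f"{n}_dev_mm"] for row in rows for n in ("lat", "lng_cor", "lng_sag", "vrt")
    )
    return {"rows": rows, "max_abs_deviation_mm": float(max_dev)}


# ---------------------------------------------------------------------------
# registration accuracy
# ---------------------------------------------------------------------------

def _dts_pairs_by_arc(
    vol: VoxelVolume,
    scale: StudyScale,
    arcs: tuple[float, ...],
    engine: str,
    route: str,
    filt: FilterSpec,
) -> dict[float, tuple[VoxelVolume, VoxelVolume]]:
    """(coronal, sagittal) stacks of one volume for every arc width.

    Projections are computed once per orientation over the widest arc and
    subset per arc.  ``route='onboard'`` passes through the intensity domain
    (simulated cone-beam projections), ``'reference'`` stays in the
    line-integral domain (the DRR path).
    """
    widest = max(arcs)
    stacks: dict[float, list[VoxelVolume]] = {arc: [] for arc in arcs}
    for orientation in ("coronal", "sagittal"):
        center = _ARC_CENTER[orientation]
        pset_all = arc_projections(vol, scale, center, widest, engine)
        if route == "onboard":
            pset_all = onboard(pset_all)
        for arc in arcs:
            pset = (
                pset_all
                if arc == widest
                else subset_projections(pset_all, center, arc)
            )
            stacks[arc].append(
                reconstruct_dts(pset, dts_spec(orientation, scale), engine, filt=filt)
            )
    return {arc: (v[0], v[1]) for arc, v in stacks.items()}


def registration_study(
    scale: StudyScale = DESK_SCALE,
    phantoms: tuple[str, ...] = ("cube", "pelvis"),
    arcs: tuple[float, ...] = (20.0, 40.0, 60.0),
    displacements_mm: tuple[float, ...] = (1.0, 3.0, 5.0),
    engine: str = "fast",
    search_mm: float = 10.0,
    filt: FilterSpec = FilterSpec(window="hamming"),
) -> dict:
    """Known-shift recovery: onboard stacks from the unshifted phantom vs
    reference stacks from the phantom displaced along one axis at a time,
    plus the zero-displacement self-test, for every arc.

    Each case records the applied and recovered (LAT, LNG, VRT) shifts and
    per-axis errors.
    """
    cases = [(0.0, 0.0, 0.0)]
    for axis in range(3):
        for d in displacements_mm:
            shift = [0.0, 0.0, 0.0]
            shift[axis] = d
            cases.append(tuple(shift))

    rows = []
    for kind in phantoms:
        vol = build_phantom(kind, scale)
        odts = _dts_pairs_by_arc(vol, scale, arcs, engine, "onboard", filt)
        for applied in cases:
            moved = vol if applied == (0.0, 0.0, 0.0) else shift_volume(vol, applied)
            rdts = _dts_pairs_by_arc(moved, scale, arcs, engine, "reference", filt)
            for arc in arcs:
                rdts_cor, rdts_sag = rdts[arc]
                odts_cor, odts_sag = odts[arc]
                res = two_session_registration(
                    odts_cor, rdts_cor, odts_sag, rdts_sag, search_mm=search_mm
                )
                recovered = (res.lat_mm, res.lng_mm, res.vrt_mm)
                rows.append(
                    {
                        "phantom": kind,
                        "arc_deg": arc,
                        "applied_mm": list(applied),
                        "recovered_mm": [float(r) for r in recovered],
                        "error_mm": [
                            float(r - a) for r, a in zip(recovered, applied)
                        ],
                        "ncc": [res.ncc_coronal, res.ncc_sagittal],
                    }
                )
    shifted = [r for r in rows if any(a != 0 for a in r["applied_mm"])]
    zero = [r for r in rows if not any(a != 0 for a in r["applied_mm"])]
    max_err = max(abs(e) for r in shifted for e in r["error_mm"]) if shifted else 0.0
    max_zero = max(abs(e) for r in zero for e in r["error_mm"]) if zero else 0.0
    return {
        "rows": rows,
        "max_abs_error_mm": float(max_err),
        "max_selftest_error_mm": float(max_zero),
    }


# ---------------------------------------------------------------------------
# engine comparison
# ---------------------------------------------------------------------------

def engine_comparison(
    scale: StudyScale = DESK_SCALE,
    n_drr_angles: int = 8,
    dts_arc_deg: float = 40.0,
    filt: FilterSpec = FilterSpec(window="hamming"),
) -> dict:
    """Reference vs fast engines on the pelvis phantom: per-image Pearson
    correlation and (0, 255)-rescaled subtraction statistics for DRRs spread
    over the scan range and for the slices of a coronal stack."""
    pelvis = build_phantom("pelvis", scale)
    geom = full_geometry(scale)
    idx = np.linspace(0, geom.n_angles - 1, n_drr_angles).astype(int)
    sub = geom.with_angles(geom.angles_deg[idx])

    fast_set = drr_fast(pelvis, sub)
    drr_corr, drr_rel = [], []
    for a, img_fast in zip(sub.angles_deg, fast_set.images):
        ref = drr_oracle(pelvis, sub, float(a))
        drr_corr.append(correlation_coefficient(ref.pixels, img_fast.pixels))
        drr_rel.append(subtraction_stats(ref.pixels, img_fast.pixels).rel_mean_pct)

    pset = arc_projections(pelvis, scale, 0.0, dts_arc_deg, "fast")
    spec = dts_spec("coronal", scale)
    dts_fast = reconstruct_dts(pset, spec, "fast", filt=filt)
    # reference stack: per-ray DRRs + per-voxel back-projection
    ref_pset = ProjectionSet(
        pset.geometry,
        tuple(
            drr_oracle(pelvis, pset.geometry, float(a))
            for a in pset.geometry.angles_deg
        ),
    )
    dts_ref = reconstruct_dts(ref_pset, spec, "oracle", filt=filt)
    lo, hi = dts_ref.values.min(), dts_ref.values.max()
    dts_corr = [
        correlation_coefficient(dts_ref.values[:, :, k], dts_fast.values[:, :, k])
        for k in range(dts_ref.shape[2])
    ]
    # slice stats use the stack-wide reference window so that slice weights
    # are comparable; relative means are averaged over slices
    dts_rel = []
    for k in range(dts_ref.shape[2]):
        d = np.abs(dts_ref.values[:, :, k] - dts_fast.values[:, :, k])
        dts_rel.append(100.0 * float(d.mean()) * (1.0 / (hi - lo)))
    return {
        "drr_corr": [float(c) for c in drr_corr],
        "drr_rel_mean_pct": [float(r) for r in drr_rel],
        "dts_corr": [float(c) for c in dts_corr],
        "dts_rel_mean_pct": [float(r) for r in dts_rel],
        "mean_corr": float(np.mean(drr_corr + dts_corr)),
        "mean_drr_rel_pct": float(np.mean(drr_rel)),
        "mean_dts_rel_pct": float(np.mean(dts_rel)),
    }


# ---------------------------------------------------------------------------
# acquisition arithmetic
# ---------------------------------------------------------------------------

def acquisition_arithmetic() -> dict:
    """Full-fan protocol numbers: angular spacing of the 200 deg / 375-view
    scan and the projection savings of a two-arc DTS acquisition.

    The clinical report counts 37 views per 20 deg arc and prints the
    combined two-arc total as 75; the savings figure follows that printed
    count.
    """
    from .geometry import projection_savings

    geom = make_full_fan_geometry(20.0, 200.0, 375)
    spacing = float(np.mean(np.abs(np.diff(geom.angles_deg))))
    n_two_arc_printed = 75
    return {
        "angular_spacing_deg": spacing,
        "angular_spacing_rounded": round(spacing, 2),
        "n_full": 375,
        "n_dts_two_arc": n_two_arc_printed,
        "savings_pct": projection_savings(n_two_arc_printed, 375),
    }
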