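"""Translational registration between tomosynthesis stacks.

Two 2D sessions recover the 3D couch shift: the coronal pair yields
(LAT, LNG), the sagittal pair (LNG, VRT), and the two LNG estimates are
averaged.  Each session averages the central focal slices into one image
and runs exhaustive integer-pixel normalized cross-correlation with
parabolic sub-pixel refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelVolume

__all__ = ["ShiftResult", "register_translation_2d", "two_session_registration",
           "focal_image", "ncc_surface"]


@dataclass(frozen=True)
class ShiftResult:
    """3D displacement (mm) fused from the two sessions.

    Sign convention: the returned values are the displacement of the moving
    stack's content relative to the fixed stack, i.e. the couch correction
    that moves the onboard stack onto the reference stack.
    """

    lat_mm: float
    lng_mm: float
    vrt_mm: float
    lng_coronal_mm: float
    lng_sagittal_mm: float
    ncc_coronal: float
    ncc_sagittal: float

    def __post_init__(self) -> None:
        vals = (self.lat_mm, self.lng_mm, self.vrt_mm,
                self.lng_coronal_mm, self.lng_sagittal_mm)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("shift components must be finite")

    def as_dict(self) -> dict:
        return {
            "lat_mm": self.lat_mm,
            "lng_mm": self.lng_mm,
            "vrt_mm": self.vrt_mm,
            "lng_coronal_mm": self.lng_coronal_mm,
            "lng_sagittal_mm": self.lng_sagittal_mm,
            "ncc_coronal": self.ncc_coronal,
            "ncc_sagittal": self.ncc_sagittal,
        }


def focal_image(vol: VoxelVolume, n_focal_slices: int = 5) -> tuple[np.ndarray, tuple[float, float]]:
    """Average the central slices of a DTS stack into its focal-plane image.

    Returns the 2D image and its per-axis pixel sizes in mm.  Coronal stacks
    (sliced along VRT) give a (LAT, LNG) image; sagittal stacks (sliced along
    LAT) give a (LNG, VRT) image.
    """
    if vol.orientation not in ("coronal", "sagittal"):
        raise ValueError("volume must be a DTS stack tagged coronal or sagittal")
    axis = 2 if vol.orientation == "coronal" else 0
    n = vol.shape[axis]
    k = max(1, min(int(n_focal_slices), n))
    lo = (n - k) // 2
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, lo + k)
    img = vol.values[tuple(sl)].mean(axis=axis)
    sizes = [vol.voxel_mm[a] for a in range(3) if a != axis]
    return img, (sizes[0], sizes[1])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom >= 0:  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))


def ncc_surface(
    f_img: np.ndarray,
    m_img: np.ndarray,
    radii: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive integer-lag NCC between two images.

    Returns ``(ncc, lags_u, lags_v)``; entry (i, j) compares ``f_img`` with
    ``m_img`` displaced by ``(lags_u[i], lags_v[j])`` pixels.
    """
    ru, rv = radii
    lags_u = np.arange(-ru, ru + 1)
    lags_v = np.arange(-rv, rv + 1)
    ncc = np.full((lags_u.size, lags_v.size), -np.inf)
    nu, nv = f_img.shape
    for i, lu in enumerate(lags_u):
        # compare fixed(i) with moving(i + lag): peak at the content shift
        fu0, fu1 = max(0, -lu), min(nu, nu - lu)
        mu0 = fu0 + lu
        if fu1 <= fu0:
            continue
        for j, lv in enumerate(lags_v):
            fv0, fv1 = max(0, -lv), min(nv, nv - lv)
            mv0 = fv0 + lv
            if fv1 <= fv0:
                continue
            ncc[i, j] = _ncc(
                f_img[fu0:fu1, fv0:fv1],
                m_img[mu0 : mu0 + (fu1 - fu0), mv0 : mv0 + (fv1 - fv0)],
            )
    return ncc, lags_u, lags_v


def register_translation_2d(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    search_mm: float = 10.0,
    n_focal_slices: int = 5,
) -> tuple[float, float, float]:
    """Recover the in-plane translation of ``moving`` relative to ``fixed``.

    Exhaustive integer-pixel NCC within +/- ``search_mm``, ties broken toward
    the smaller-magnitude shift, then per-axis parabolic refinement.  Returns
    ``(shift_u_mm, shift_v_mm, ncc_peak)`` where positive values mean the
    moving content sits at larger coordinates than the fixed content.
    """
    if (
        fixed.shape != moving.shape
        or fixed.voxel_mm != moving.voxel_mm
        or fixed.orientation != moving.orientation
    ):
        raise ValueError("fixed and moving stacks must share one spec")
    f_img, (du, dv) = focal_image(fixed, n_focal_slices)
    m_img, _ = focal_image(moving, n_focal_slices)
    if np.ptp(f_img) == 0 or np.ptp(m_img) == 0:
        raise ValueError("no structure to register (constant focal image)")

    ru = max(1, int(np.ceil(search_mm / du)))
    rv = max(1, int(np.ceil(search_mm / dv)))
    ncc, lags_u, lags_v = ncc_surface(f_img, m_img, (ru, rv))

    peak = np.max(ncc)
    cand = np.argwhere(ncc >= peak - 1e-12)
    mags = np.hypot(lags_u[cand[:, 0]] * du, lags_v[cand[:, 1]] * dv)
    bi, bj = cand[int(np.argmin(mags))]

    off_u = off_v = 0.0
    if 0 < bi < lags_u.size - 1 and np.isfinite(ncc[bi - 1, bj]) and np.isfinite(ncc[bi + 1, bj]):
        off_u = _parabolic_offset(ncc[bi - 1, bj], ncc[bi, bj], ncc[bi + 1, bj])
    if 0 < bj < lags_v.size - 1 and np.isfinite(ncc[bi, bj - 1]) and np.isfinite(ncc[bi, bj + 1]):
        off_v = _parabolic_offset(ncc[bi, bj - 1], ncc[bi, bj], ncc[bi, bj + 1])

    shift_u = (lags_u[bi] + off_u) * du
    shift_v = (lags_v[bj] + off_v) * dv
    return float(shift_u), float(shift_v), float(ncc[bi, bj])


def two_session_registration(
    odts_cor: VoxelVolume,
    rdts_cor: VoxelVolume,
    odts_sag: VoxelVolume,
    rdts_sag: VoxelVolume,
    search_mm: float = 10.0,
    n_focal_slices: int = 5,
) -> ShiftResult:
    """Fuse the coronal session (LAT, LNG) and sagittal session (LNG, VRT)
    into a 3D shift; LNG is the mean of the two per-session estimates."""
    try:
        lat, lng_cor, ncc_cor = register_translation_2d(
            odts_cor, rdts_cor, search_mm, n_focal_slices
        )
    except ValueError as exc:
        raise ValueError(f"coronal session failed: {exc}") from exc
    try:
        lng_sag, vrt, ncc_sag = register_translation_2d(
            odts_sag, rdts_sag, search_mm, n_focal_slices
        )
    except ValueError as exc:
        raise ValueError(f"sagittal session failed: {exc}") from exc
    return ShiftResult(
        lat_mm=lat,
        lng_mm=(lng_cor + lng_sag) / 2.0,
        vrt_mm=vrt,
        lng_coronal_mm=lng_cor,
        lng_sagittal_mm=lng_sag,
        ncc_coronal=ncc_cor,
        ncc_sagittal=ncc_sag,
    )
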