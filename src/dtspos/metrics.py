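"""Validation metrics: Pearson correlation between engine outputs,
rescaled subtraction-image statistics, and sub-pixel edge-length
measurement of the cube phantom on reconstructed planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "correlation_coefficient",
    "SubtractionStats",
    "subtraction_stats",
    "edge_length_from_profile",
    "measure_edge_length",
]


def correlation_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over all pixels, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    r = float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
    return float(np.clip(r, -1.0, 1.0))


@dataclass(frozen=True)
class SubtractionStats:
    """Statistics of |reference - test| after both images are windowed to
    (0, 255) with the reference image's min/max."""

    abs_mean: float
    abs_sd: float
    rel_mean_pct: float
    rel_sd_pct: float


def subtraction_stats(reference: np.ndarray, test: np.ndarray) -> SubtractionStats:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("reference and test images must have equal dims")
    lo, hi = reference.min(), reference.max()
    if hi == lo:
        raise ValueError("reference image has zero dynamic range")
    scale = 255.0 / (hi - lo)
    ref_w = (reference - lo) * scale
    test_w = (test - lo) * scale
    diff = np.abs(ref_w - test_w)
    abs_mean = float(diff.mean())
    abs_sd = float(diff.std())
    return SubtractionStats(
        abs_mean=abs_mean,
        abs_sd=abs_sd,
        rel_mean_pct=100.0 * abs_mean / 255.0,
        rel_sd_pct=100.0 * abs_sd / 255.0,
    )


def edge_length_from_profile(profile: np.ndarray, pixel_mm: float) -> float:
    """Distance between the two 50%-of-step-height edge crossings of a
    single-object 1D profile, with linear sub-pixel interpolation.

    The object extent is first estimated by thresholding at half of the
    profile's dynamic range; the plateau level is the median of the central
    50% of that extent and the background the median outside it.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 4:
        raise ValueError("profile must be a 1D array with at least 4 samples")
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise ValueError("flat profile: no object edges found")
    rough = p >= (lo + hi) / 2.0
    idx = np.flatnonzero(rough)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if len(runs) != 1:
        raise ValueError(
            f"ambiguous edges: found {len(runs)} objects along the profile"
        )
    i0, i1 = idx[0], idx[-1]
    width = i1 - i0 + 1
    c0 = i0 + width // 4
    c1 = i1 - width // 4
    plateau = float(np.median(p[c0 : c1 + 1]))
    outside = np.concatenate([p[:i0], p[i1 + 1 :]])
    if outside.size == 0:
        raise ValueError("object touches the profile ends; cannot estimate background")
    background = float(np.median(outside))
    level = background + 0.5 * (plateau - background)

    above = p >= level
    crossings = []
    for i in range(p.size - 1):
        if above[i] != above[i + 1]:
            # linear interpolation between samples i and i+1
            frac = (level - p[i]) / (p[i + 1] - p[i])
            crossings.append(i + frac)
    if len(crossings) != 2:
        raise ValueError(
            f"ambiguous edges: expected 2 level crossings, found {len(crossings)}"
        )
    return float((crossings[1] - crossings[0]) * pixel_mm)


def measure_edge_length(
    plane: np.ndarray,
    axis: int,
    line_offset_mm: float,
    pixel_mm: tuple[float, float],
) -> float:
    """Measure an object's extent along ``axis`` (0 or 1) of a 2D plane.

    The profile is taken along ``axis`` at ``line_offset_mm`` from the plane
    center in the perpendicular direction (nearest line).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("plane must be 2D")
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    other = 1 - axis
    n_other = plane.shape[other]
    row = int(round((n_other - 1) / 2.0 + line_offset_mm / pixel_mm[other]))
    if not 0 <= row < n_other:
        raise ValueError("line offset falls outside the plane")
    profile = plane[:, row] if axis == 0 else plane[row, :]
    return edge_length_from_profile(profile, pixel_mm[axis])
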