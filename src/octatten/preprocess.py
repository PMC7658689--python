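"""Denoising, B-scan flattening at Bruch's membrane, and fovea localisation.

The denoiser here is a simple per-B-scan median filter exposed behind a
generic interface: the pipeline accepts any speckle-reduction method that
maps a volume to a volume of the same shape.  Flattening shifts each
column by an integer number of voxels so Bruch's membrane lands on a
common row; shifts are recorded exactly, vacated voxels are zero-filled,
and no interpolation takes place, so intensities are preserved bit-exactly
and all downstream metrics are shift-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_store import LayerSurfaces, OCTVolume

__all__ = ["FlattenedVolume", "denoise", "flatten_at_bm", "locate_fovea"]


@dataclass
class FlattenedVolume:
    """A volume after per-column axial alignment of Bruch's membrane."""

    volume: OCTVolume
    shifts: np.ndarray  # (n_x, n_y), voxels added to each column's depth
    target_row: int


def denoise(volume: OCTVolume, kernel: int = 3) -> OCTVolume:
    """Median-filter each B-scan with an odd ``kernel x kernel`` window.

    ``kernel = 1`` is the identity; constants are fixed points; on
    homogeneous speckle the output variance drops below the input variance.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return volume.replace_intensity(volume.intensity.copy())
    filtered = ndimage.median_filter(volume.intensity, size=(kernel, kernel, 1), mode="nearest")
    return volume.replace_intensity(filtered)


def flatten_at_bm(
    volume: OCTVolume,
    surfaces: LayerSurfaces,
    target_row: int | None = None,
):
    """Shift each column so Bruch's membrane sits at ``target_row``.

    Returns ``(FlattenedVolume, LayerSurfaces)`` with the surfaces shifted
    by exactly the same per-column offsets.  The default target row is the
    median BM index (minimising total shift).  A shift that would push any
    surface outside the grid raises, naming the offending column.
    """
    bm = surfaces["BM"]
    n_z = volume.n_z
    if target_row is None:
        target_row = int(np.median(bm))
    if not (0 <= target_row < n_z):
        raise ValueError(f"target_row {target_row} outside axial range [0, {n_z})")
    shifts = target_row - bm  # positive -> move column content deeper

    shifted_surfaces = {}
    for name, arr in surfaces.surfaces.items():
        out = arr + shifts
        if np.any(out < 0) or np.any(out >= n_z):
            x, y = np.argwhere((out < 0) | (out >= n_z))[0]
            raise ValueError(
                f"flattening shift pushes surface {name} out of range at column (x={x}, y={y})"
            )
        shifted_surfaces[name] = out

    z = np.arange(n_z)[:, None, None]
    src = z - shifts[None]
    valid = (src >= 0) & (src < n_z)
    src = np.clip(src, 0, n_z - 1)
    flat = np.take_along_axis(volume.intensity, src, axis=0)
    flat = np.where(valid, flat, 0).astype(volume.intensity.dtype)

    fvol = FlattenedVolume(
        volume=volume.replace_intensity(flat),
        shifts=shifts,
        target_row=int(target_row),
    )
    return fvol, LayerSurfaces(shifted_surfaces, n_z=n_z)


def locate_fovea(
    surfaces: LayerSurfaces,
    dx: float,
    dy: float,
    dz: float = 1.0,
    max_region_fraction: float = 0.05,
) -> tuple:
    """Locate the fovea as the minimum of smoothed inner-retina thickness.

    The inner retina (ILM to the lower GCIPL boundary) thins sharply at
    the foveal pit.  The per-column thickness map is smoothed with a 3x3
    mean filter, the global-minimum region is extracted, and its centroid
    is returned in mm.  Several disjoint minima, or a minimum region
    covering more than ``max_region_fraction`` of the columns (a flat map
    with no pit), raise an error asking for an explicit centre override.
    """
    thickness = (surfaces["IPL_INL"] - surfaces["ILM"]).astype(float) * dz
    smooth = ndimage.uniform_filter(thickness, size=3, mode="nearest")
    minimum = smooth.min()
    region = smooth <= minimum + 1e-9
    labels, n_components = ndimage.label(region)
    if n_components != 1:
        raise ValueError(
            f"{n_components} disjoint thickness minima found; "
            "pass an explicit fovea centre"
        )
    if region.mean() > max_region_fraction:
        raise ValueError(
            "no unique inner-retina thickness minimum (flat map); "
            "pass an explicit fovea centre"
        )
    cx, cy = ndimage.center_of_mass(region)
    return (cx * dx / 1000.0, cy * dy / 1000.0)
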