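"""Fovea-centred quadrant grid and per-layer regional summaries.

The macula is analysed inside a square of configurable width (default
5.0 mm) centred at the fovea and split into four quadrants: superonasal
(SN), inferonasal (IN), superotemporal (ST) and inferotemporal (IT).
Nasal/temporal orientation depends on laterality: for a right eye (OD)
the nasal side lies at larger x, for a left eye (OS) at smaller x.
Columns exactly on a dividing midline are assigned to the superior /
nasal side.

Thickness is the number of voxels between a layer's bounding interfaces
multiplied by the axial spacing; attenuation and corrected-intensity
summaries are means over the valid voxels inside the layer band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_store import LAYER_BANDS, LayerSurfaces
from .optics import OpticalMaps

__all__ = [
    "QUADRANTS",
    "REGIONS",
    "QuadrantGrid",
    "SubjectMetrics",
    "build_quadrant_grid",
    "layer_thickness_map",
    "summarize_subject",
    "decrease_ratio",
]

QUADRANTS = ("SN", "IN", "ST", "IT")
REGIONS = QUADRANTS + ("average",)


@dataclass
class QuadrantGrid:
    """Per-column quadrant labels for one scan."""

    labels: np.ndarray  # (n_x, n_y) of {"SN","IN","ST","IT","outside"}
    fovea_mm: tuple
    width_mm: float
    laterality: str

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean column mask for a quadrant or for ``"average"`` (in-square)."""
        if region == "average":
            return self.labels != "outside"
        if region not in QUADRANTS:
            raise ValueError(f"unknown region {region!r}")
        return self.labels == region


@dataclass
class SubjectMetrics:
    """Per-layer, per-region summary indices for one eye.

    ``values[(layer, region)]`` maps to a dict with keys ``thickness_um``,
    ``attenuation_per_um`` and ``corrected_intensity_au``; missing metrics
    (regions with no valid voxels) are NaN.
    """

    subject_id: str
    group: str
    values: dict = field(default_factory=dict)

    def get(self, layer: str, region: str, index: str) -> float:
        key = {
            "thickness": "thickness_um",
            "attenuation": "attenuation_per_um",
            "intensity": "corrected_intensity_au",
        }[index]
        return self.values[(layer, region)][key]

    def to_rows(self) -> list:
        rows = []
        for (layer, region), vals in self.values.items():
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "group": self.group,
                    "layer": layer,
                    "region": region,
                    **vals,
                }
            )
        return rows


def build_quadrant_grid(
    n_x: int,
    n_y: int,
    dx: float,
    dy: float,
    fovea_mm,
    width_mm: float = 5.0,
    laterality: str = "OD",
) -> QuadrantGrid:
    """Label every column of an ``(n_x, n_y)`` en-face grid by quadrant.

    Column positions are ``x = i * dx`` and ``y = j * dy`` (µm, converted
    to mm); the y axis runs superior (small y) to inferior (large y).
    Mirroring the grid left-right (with the fovea mirrored too) while
    toggling laterality leaves every label unchanged.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    if not width_mm > 0:
        raise ValueError("width_mm must be positive")
    fx, fy = float(fovea_mm[0]), float(fovea_mm[1])
    x_mm = np.arange(n_x) * dx / 1000.0
    y_mm = np.arange(n_y) * dy / 1000.0
    if not (x_mm[0] <= fx <= x_mm[-1] and y_mm[0] <= fy <= y_mm[-1]):
        raise ValueError(f"fovea {fovea_mm} lies outside the scanned area")
    half = width_mm / 2.0
    if fx - half < x_mm[0] or fx + half > x_mm[-1] or fy - half < y_mm[0] or fy + half > y_mm[-1]:
        warnings.warn("analysis square extends beyond the scan and is clipped")

    dxm = x_mm[:, None] - fx  # (n_x, 1)
    dym = y_mm[None, :] - fy  # (1, n_y)
    inside = (np.abs(dxm) <= half) & (np.abs(dym) <= half)
    # midline tie-break: boundary columns go to the superior / nasal side
    superior = dym <= 0
    nasal = dxm >= 0 if laterality == "OD" else dxm <= 0

    labels = np.full((n_x, n_y), "outside", dtype="<U7")
    labels[inside & superior & nasal] = "SN"
    labels[inside & ~superior & nasal] = "IN"
    labels[inside & superior & ~nasal] = "ST"
    labels[inside & ~superior & ~nasal] = "IT"
    return QuadrantGrid(labels=labels, fovea_mm=(fx, fy), width_mm=width_mm, laterality=laterality)


def layer_thickness_map(surfaces: LayerSurfaces, layer: str, dz: float) -> np.ndarray:
    """Per-column layer thickness in µm: voxel count times axial spacing."""
    if layer not in LAYER_BANDS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {sorted(LAYER_BANDS)}")
    upper_name, lower_name = LAYER_BANDS[layer]
    counts = surfaces[lower_name] - surfaces[upper_name]
    if np.any(counts < 0):
        raise ValueError(f"layer {layer} has negative voxel counts (crossing surfaces)")
    return counts * float(dz)


def summarize_subject(
    maps: OpticalMaps,
    surfaces: LayerSurfaces,
    grid: QuadrantGrid,
    dz: float | None = None,
    subject_id: str = "anonymous",
    group: str = "unknown",
) -> SubjectMetrics:
    """Quadrant-wise thickness, attenuation and corrected-intensity means.

    The ``"average"`` region is the mean over all in-square columns (for
    thickness) and all in-square valid voxels (for the optical indices),
    i.e. a voxel-count-weighted combination of the four quadrants rather
    than a mean of quadrant means.
    """
    if dz is None:
        dz = maps.dz
    n_z = maps.mu.shape[0]
    if grid.labels.shape != maps.mu.shape[1:]:
        raise ValueError("grid and optical maps have mismatched column geometry")
    z = np.arange(n_z)[:, None, None]
    metrics = SubjectMetrics(subject_id=subject_id, group=group)
    for layer, (upper_name, lower_name) in LAYER_BANDS.items():
        upper = surfaces[upper_name][None]
        lower = surfaces[lower_name][None]
        band = (z >= upper) & (z < lower)  # half-open: `lower - upper` voxels
        band_valid = band & maps.valid
        thickness = layer_thickness_map(surfaces, layer, dz)
        for region in REGIONS:
            cols = grid.region_mask(region)
            vals = {}
            vals["thickness_um"] = float(np.mean(thickness[cols])) if cols.any() else float("nan")
            sel = band_valid & cols[None]
            n_valid = int(sel.sum())
            if n_valid > 0:
                vals["attenuation_per_um"] = float(maps.mu[sel].mean())
                vals["corrected_intensity_au"] = float(maps.corrected[sel].mean())
            else:
                vals["attenuation_per_um"] = float("nan")
                vals["corrected_intensity_au"] = float("nan")
            metrics.values[(layer, region)] = vals
    return metrics


def decrease_ratio(control_mean: float, patient_mean: float) -> float:
    """Percent decrease of the patient mean relative to the control mean.

    ``100 * (control - patient) / control``, rounded to two decimals.
    """
    if not control_mean > 0:
        raise ValueError("control mean must be positive")
    return round(100.0 * (control_mean - patient_mean) / control_mean, 2)
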