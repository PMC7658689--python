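"""Containers and on-disk formats for OCT volumes, layer surfaces and metrics.

Volumes are stored as multi-page TIFF (one page per B-scan) with a JSON
sidecar carrying voxel spacings, laterality and subject identity.  Layer
surfaces are CSV tables with columns ``x, y, surface, z_index`` (0-based
voxel indices, ``z = 0`` at the vitreous and increasing with depth).
Subject metrics are long-format CSV, one row per subject x layer x region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SURFACE_NAMES",
    "LAYER_BANDS",
    "OCTVolume",
    "LayerSurfaces",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_surfaces",
    "write_surfaces",
    "write_metrics_table",
    "read_metrics_table",
]

#: Retinal interfaces in anatomical depth order.  ``ILM`` is the inner
#: limiting membrane (upper RNFL boundary), ``RNFL_GCL`` the RNFL/ganglion
#: cell layer interface, ``IPL_INL`` the lower GCIPL boundary, then the
#: upper and lower retinal pigment epithelium boundaries and Bruch's
#: membrane.
SURFACE_NAMES = ("ILM", "RNFL_GCL", "IPL_INL", "RPE_upper", "RPE_lower", "BM")

#: Layers quantified downstream, as (upper surface, lower surface) pairs.
LAYER_BANDS = {
    "RNFL": ("ILM", "RNFL_GCL"),
    "GCIPL": ("RNFL_GCL", "IPL_INL"),
}

#: Default voxel spacing in micrometres (axial, lateral, slice).
DEFAULT_SPACING = (2.62, 11.72, 23.44)


class FormatError(ValueError):
    """Raised when an on-disk artefact is missing or inconsistent."""


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with acquisition metadata.

    Parameters
    ----------
    intensity
        Array of shape ``(n_z, n_x, n_y)`` — axial depth, lateral position
        within a B-scan, and B-scan slice.  Nonnegative, nominally within
        the 16-bit export range (0–65535) in arbitrary units.
    dz, dx, dy
        Voxel spacing in micrometres along z, x and y.
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    """

    intensity: np.ndarray
    dz: float = DEFAULT_SPACING[0]
    dx: float = DEFAULT_SPACING[1]
    dy: float = DEFAULT_SPACING[2]
    laterality: str = "OD"
    subject_id: str = "anonymous"
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3-D (z, x, y) array")
        if any(s < 8 for s in self.intensity.shape):
            raise ValueError(
                f"degenerate volume: each dimension must be >= 8, got {self.intensity.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        for name, value in (("dz", self.dz), ("dx", self.dx), ("dy", self.dy)):
            if not value > 0:
                raise ValueError(f"spacing {name} must be positive, got {value}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        if self.group not in ("patient", "control", "unknown"):
            raise ValueError(f"group must be patient|control|unknown, got {self.group!r}")

    @property
    def n_z(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_x(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_y(self) -> int:
        return self.intensity.shape[2]

    def replace_intensity(self, intensity: np.ndarray) -> "OCTVolume":
        """Return a copy of this volume with a new intensity grid."""
        return OCTVolume(
            intensity,
            dz=self.dz,
            dx=self.dx,
            dy=self.dy,
            laterality=self.laterality,
            subject_id=self.subject_id,
            group=self.group,
        )


@dataclass
class LayerSurfaces:
    """Per-column depth indices of the retinal interfaces.

    ``surfaces[name]`` is an integer array of shape ``(n_x, n_y)`` giving
    the 0-based axial voxel index of interface ``name`` at each lateral
    column.  Interfaces must be strictly increasing in the
    :data:`SURFACE_NAMES` order at every column.
    """

    surfaces: dict = field(default_factory=dict)
    n_z: int | None = None

    def __post_init__(self) -> None:
        missing = [n for n in SURFACE_NAMES if n not in self.surfaces]
        if missing:
            raise ValueError(f"missing surfaces: {missing}")
        arrays = {}
        shape = None
        for name in SURFACE_NAMES:
            arr = np.asarray(self.surfaces[name])
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"surface {name} indices must be integers")
                arr = np.round(arr).astype(np.int64)
            arr = arr.astype(np.int64)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all surfaces must share the same (n_x, n_y) shape")
            arrays[name] = arr
        self.surfaces = arrays
        self.validate()

    def validate(self) -> None:
        stack = np.stack([self.surfaces[n] for n in SURFACE_NAMES], axis=0)
        if np.any(stack < 0):
            raise ValueError("surface indices must be nonnegative")
        if self.n_z is not None and np.any(stack >= self.n_z):
            raise ValueError(f"surface indices must be < n_z = {self.n_z}")
        bad = np.any(np.diff(stack, axis=0) <= 0, axis=0)
        if np.any(bad):
            x, y = np.argwhere(bad)[0]
            raise ValueError(
                f"surfaces are not strictly increasing at column (x={x}, y={y})"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    @property
    def shape(self) -> tuple:
        return self.surfaces[SURFACE_NAMES[0]].shape

    def shifted(self, shift: np.ndarray, n_z: int | None = None) -> "LayerSurfaces":
        """Return surfaces with a per-column axial shift added."""
        shift = np.asarray(shift)
        return LayerSurfaces(
            {n: self.surfaces[n] + shift for n in SURFACE_NAMES},
            n_z=self.n_z if n_z is None else n_z,
        )


# ---------------------------------------------------------------------------
# Volumes: multi-page TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: OCTVolume, path) -> None:
    """Write ``volume`` as a multi-page TIFF plus a JSON metadata sidecar.

    Pages run along the slice (y) axis so each page is one B-scan
    ``(n_z, n_x)``.  The intensity dtype is preserved exactly; the writers
    are deterministic (identical inputs give byte-identical files).
    """
    path = Path(path)
    pages = np.ascontiguousarray(np.moveaxis(volume.intensity, 2, 0))
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "format": "octatten-volume-v1",
        "shape_zxy": list(volume.intensity.shape),
        "dtype": str(volume.intensity.dtype),
        "dz_um": volume.dz,
        "dx_um": volume.dx,
        "dy_um": volume.dy,
        "laterality": volume.laterality,
        "subject_id": volume.subject_id,
        "group": volume.group,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_volume(path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    required = ("shape_zxy", "dz_um", "dx_um", "dy_um", "laterality", "subject_id", "group")
    for key in required:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} is missing required key {key!r}")
    for key in ("dz_um", "dx_um", "dy_um"):
        if not meta[key] > 0:
            raise FormatError(f"sidecar key {key!r} must be positive, got {meta[key]}")
    pages = tifffile.imread(path)
    intensity = np.moveaxis(pages, 0, 2)
    if list(intensity.shape) != list(meta["shape_zxy"]):
        raise FormatError(
            f"TIFF shape {intensity.shape} does not match sidecar shape {meta['shape_zxy']}"
        )
    return OCTVolume(
        intensity,
        dz=meta["dz_um"],
        dx=meta["dx_um"],
        dy=meta["dy_um"],
        laterality=meta["laterality"],
        subject_id=meta["subject_id"],
        group=meta["group"],
    )


# ---------------------------------------------------------------------------
# Surfaces: long-format CSV


def write_surfaces(surfaces: LayerSurfaces, path) -> None:
    """Write surfaces as CSV with columns ``x, y, surface, z_index``."""
    nx, ny = surfaces.shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    frames = []
    for name in SURFACE_NAMES:
        frames.append(
            pd.DataFrame(
                {
                    "x": xs.ravel(),
                    "y": ys.ravel(),
                    "surface": name,
                    "z_index": surfaces[name].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\n")


def read_surfaces(path, n_z: int | None = None) -> LayerSurfaces:
    """Read surfaces from CSV, enforcing the ordering invariant."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"surfaces file not found: {path}")
    df = pd.read_csv(path)
    for col in ("x", "y", "surface", "z_index"):
        if col not in df.columns:
            raise FormatError(f"surfaces CSV {path} is missing column {col!r}")
    nx = int(df["x"].max()) + 1
    ny = int(df["y"].max()) + 1
    arrays = {}
    for name, sub in df.groupby("surface"):
        if name not in SURFACE_NAMES:
            raise FormatError(f"unknown surface name {name!r} in {path}")
        arr = np.full((nx, ny), -1, dtype=np.int64)
        arr[sub["x"].to_numpy(), sub["y"].to_numpy()] = sub["z_index"].to_numpy()
        if np.any(arr < 0):
            raise FormatError(f"surface {name} is not defined at every column in {path}")
        arrays[name] = arr
    return LayerSurfaces(arrays, n_z=n_z)


# ---------------------------------------------------------------------------
# Metrics tables


# ---------------------------------------------------------------------------
# Optical maps: TIFF pair + JSON


def write_optical_maps(maps, directory) -> None:
    """Write an ``OpticalMaps`` bundle (mu/corrected/valid TIFFs + JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("mu.tif", maps.mu.astype(np.float32)),
        ("corrected.tif", maps.corrected.astype(np.float32)),
        ("valid.tif", maps.valid.astype(np.uint8)),
    ):
        tifffile.imwrite(directory / name, np.ascontiguousarray(np.moveaxis(arr, 2, 0)))
    meta = {
        "format": "octatten-maps-v1",
        "dz_um": maps.dz,
        "z_choroid_lower": maps.z_choroid_lower.tolist(),
    }
    (directory / "maps.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_optical_maps(directory):
    """Read an ``OpticalMaps`` bundle written by :func:`write_optical_maps`."""
    from .optics import OpticalMaps

    directory = Path(directory)
    meta_path = directory / "maps.json"
    if not meta_path.exists():
        raise FormatError(f"missing optical-maps metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("dz_um", "z_choroid_lower"):
        if key not in meta:
            raise FormatError(f"maps.json is missing required key {key!r}")
    arrays = {}
    for name in ("mu", "corrected", "valid"):
        path = directory / f"{name}.tif"
        if not path.exists():
            raise FormatError(f"missing optical map file: {path}")
        arrays[name] = np.moveaxis(tifffile.imread(path), 0, 2)
    return OpticalMaps(
        mu=arrays["mu"].astype(float),
        corrected=arrays["corrected"].astype(float),
        valid=arrays["valid"].astype(bool),
        z_choroid_lower=np.asarray(meta["z_choroid_lower"], dtype=np.int64),
        dz=float(meta["dz_um"]),
    )


METRIC_COLUMNS = [
    "subject_id",
    "group",
    "layer",
    "region",
    "thickness_um",
    "attenuation_per_um",
    "corrected_intensity_au",
]


def write_metrics_table(records, path) -> None:
    """Write per-subject regional metrics as long-format CSV.

    ``records`` is an iterable of :class:`~octatten.regional.SubjectMetrics`.
    One row per subject x layer x region; duplicate triples are rejected.
    """
    rows = []
    for rec in records:
        rows.extend(rec.to_rows())
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    dup = df.duplicated(subset=["subject_id", "layer", "region"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            "duplicate subject/layer/region triple: "
            f"({first.subject_id}, {first.layer}, {first.region})"
        )
    df.to_csv(path, index=False, lineterminator="\n")


def read_metrics_table(path) -> pd.DataFrame:
    """Read a metrics CSV back into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"metrics file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metrics CSV {path} is missing columns {missing}")
    return df
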