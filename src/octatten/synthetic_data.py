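"""Layered retinal phantoms and synthetic two-group cohorts.

The forward model is the same single-scattering picture the estimators
invert: the probing beam attenuates exponentially with accumulated optical
depth, and each voxel backscatters a fraction of the *attenuated* power
proportional to its local attenuation coefficient,

    I(z) = alpha * mu(z) * dz * I0 * exp(-2 * sum_{u<z} mu(u) * dz),

optionally multiplied by unit-mean gamma speckle with shape ``L``.  Under
this model the tail-sum attenuation estimator is unbiased (up to
discretisation), which makes the phantom a proper oracle for the optics
stage.  The backscatter coupling ``alpha`` is identical across layers by
default, so layer contrast comes solely from ``mu``.

Cohort simulation has two modes: ``metrics`` draws per-subject regional
indices directly from group-wise Gaussian targets (defaults are the
published patient/control summary statistics), and ``image`` generates a
full phantom volume per subject whose pipeline-derived layer metrics have
expectations near the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

from . import study_defaults
from .io_store import LayerSurfaces, OCTVolume
from .regional import REGIONS, SubjectMetrics

__all__ = [
    "LayerSpec",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "simulate_ascan",
    "simulate_volume",
    "simulate_cohort",
    "load_phantom_spec",
    "load_cohort_spec",
]

LAYER_ORDER = (
    "vitreous",
    "RNFL",
    "GCIPL",
    "outer_retina",
    "RPE",
    "choroid",
    "below_choroid",
)


@dataclass
class LayerSpec:
    """One phantom layer: geometry and optical properties.

    ``thickness_sd_um`` is the standard deviation of a smooth lateral
    thickness field; ``pit_depth_um``/``pit_sigma_mm`` describe an optional
    radially symmetric Gaussian foveal depression.
    """

    thickness_um: float
    thickness_sd_um: float = 0.0
    mu_per_um: float = 0.0
    pit_depth_um: float = 0.0
    pit_sigma_mm: float = 0.35

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise ValueError("layer thickness must be positive")
        if self.thickness_sd_um < 0 or self.mu_per_um < 0 or self.pit_depth_um < 0:
            raise ValueError("thickness SD, mu and pit depth must be nonnegative")
        if self.pit_depth_um >= self.thickness_um:
            raise ValueError("pit depth must be smaller than the mean thickness")


def _default_layers() -> dict:
    # Mean thicknesses follow healthy macular anatomy; attenuation
    # coefficients are in the ~1e-3 /µm range typical of retinal tissue at
    # 1050 nm, with the RPE strongly scattering and the vitreous nearly
    # transparent.
    return {
        "vitreous": LayerSpec(150.0, 0.0, 1e-5),
        "RNFL": LayerSpec(38.8, 2.0, 0.0012, pit_depth_um=30.0, pit_sigma_mm=0.5),
        "GCIPL": LayerSpec(77.8, 3.0, 0.0012, pit_depth_um=60.0, pit_sigma_mm=0.4),
        "outer_retina": LayerSpec(160.0, 3.0, 0.0008),
        "RPE": LayerSpec(25.0, 1.0, 0.005),
        "choroid": LayerSpec(250.0, 10.0, 0.002),
        # scleral-like, strongly scattering: keeps the deep signal decaying
        # so the tail sums are close to fully attenuated within the grid
        "below_choroid": LayerSpec(500.0, 0.0, 0.003),
    }


@dataclass
class PhantomSpec:
    """Full description of a layered retinal phantom volume.

    Defaults reproduce the acquisition geometry of the study protocol
    (992 x 512 x 256 voxels at 2.62 x 11.72 x 23.44 µm); :meth:`desk`
    returns a reduced grid with the same voxel spacing for fast runs.
    """

    layers: dict = field(default_factory=_default_layers)
    alpha: float = 0.1
    i0: float = 1.0e8
    noise_l: float | None = 4.0
    dz: float = 2.62
    dx: float = 11.72
    dy: float = 23.44
    n_z: int = 992
    n_x: int = 512
    n_y: int = 256
    laterality: str = "OD"
    fovea_mm: tuple | None = None  # None -> grid centre

    def __post_init__(self) -> None:
        unknown = set(self.layers) - set(LAYER_ORDER)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")
        missing = set(LAYER_ORDER) - set(self.layers)
        if missing:
            raise ValueError(f"missing layers: {sorted(missing)}")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.noise_l is not None and self.noise_l < 1:
            raise ValueError("speckle shape L must be >= 1")
        if min(self.dz, self.dx, self.dy) <= 0:
            raise ValueError("voxel spacings must be positive")
        if min(self.n_z, self.n_x, self.n_y) < 8:
            raise ValueError("grid dimensions must each be >= 8")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """A reduced phantom for fast runs: native axial sampling but a
        coarser lateral grid covering the same ~6 x 6 mm field of view."""
        kwargs = dict(n_z=420, n_x=64, n_y=64, dx=93.76, dy=93.76)
        kwargs.update(overrides)
        return cls(**kwargs)

    def fovea_centre_mm(self) -> tuple:
        if self.fovea_mm is not None:
            return tuple(self.fovea_mm)
        return ((self.n_x // 2) * self.dx / 1000.0, (self.n_y // 2) * self.dy / 1000.0)


@dataclass
class GroundTruth:
    """True geometry and optics of a simulated phantom."""

    surfaces: LayerSurfaces
    mu_volume: np.ndarray  # (z, x, y), per µm
    thickness_maps: dict  # layer -> (x, y) µm
    fovea_mm: tuple


def simulate_ascan(mu_profile, alpha, i0, dz, noise_l=None, seed=None, rng=None):
    """Forward-simulate one attenuated A-scan from a true ``mu`` profile.

    Noiseless output is deterministic; with speckle the expectation equals
    the noiseless profile (unit-mean gamma multiplier of shape ``noise_l``).
    """
    mu = np.asarray(mu_profile, dtype=float)
    if np.any(mu < 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu profile must be finite and nonnegative")
    if not dz > 0:
        raise ValueError("dz must be positive")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    optical_depth = np.cumsum(mu * dz) - mu * dz  # sum over u < z
    signal = alpha * mu * dz * i0 * np.exp(-2.0 * optical_depth)
    if noise_l is not None:
        if noise_l < 1:
            raise ValueError("speckle shape L must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        signal = signal * rng.gamma(noise_l, 1.0 / noise_l, size=signal.shape)
    return signal


def _thickness_field(layer: LayerSpec, spec: PhantomSpec, rng) -> np.ndarray:
    """Smooth lateral thickness field (µm) with optional foveal pit."""
    nx, ny = spec.n_x, spec.n_y
    thick = np.full((nx, ny), layer.thickness_um)
    if layer.thickness_sd_um > 0:
        noise = rng.standard_normal((nx, ny))
        noise = ndimage.gaussian_filter(noise, sigma=2.0, mode="nearest")
        sd = noise.std()
        if sd > 0:
            thick = thick + noise / sd * layer.thickness_sd_um
    if layer.pit_depth_um > 0:
        fx, fy = spec.fovea_centre_mm()
        x_mm = np.arange(nx)[:, None] * spec.dx / 1000.0
        y_mm = np.arange(ny)[None, :] * spec.dy / 1000.0
        r2 = (x_mm - fx) ** 2 + (y_mm - fy) ** 2
        thick = thick - layer.pit_depth_um * np.exp(-r2 / (2.0 * layer.pit_sigma_mm**2))
    return np.maximum(thick, spec.dz)  # at least one voxel


def simulate_volume(spec: PhantomSpec, seed=None):
    """Generate one phantom volume and its ground truth.

    Returns ``(OCTVolume, GroundTruth)``.  Byte-identical across runs for
    a fixed seed; with zero thickness SDs and no speckle, all A-scans in a
    pit-free region are identical.
    """
    rng = np.random.default_rng(seed)
    counts = {}
    for name in LAYER_ORDER[:-1]:  # below_choroid fills the remainder
        field_um = _thickness_field(spec.layers[name], spec, rng)
        counts[name] = np.maximum(np.round(field_um / spec.dz).astype(np.int64), 1)

    ilm = counts["vitreous"]
    rnfl_gcl = ilm + counts["RNFL"]
    ipl_inl = rnfl_gcl + counts["GCIPL"]
    rpe_upper = ipl_inl + counts["outer_retina"]
    rpe_lower = rpe_upper + counts["RPE"]
    bm = rpe_lower + 1
    choroid_end = bm + counts["choroid"]
    if int(choroid_end.max()) > spec.n_z:
        raise ValueError(
            f"layer stack (max depth {int(choroid_end.max())} voxels) exceeds "
            f"the axial extent n_z = {spec.n_z}"
        )

    surfaces = LayerSurfaces(
        {
            "ILM": ilm,
            "RNFL_GCL": rnfl_gcl,
            "IPL_INL": ipl_inl,
            "RPE_upper": rpe_upper,
            "RPE_lower": rpe_lower,
            "BM": bm,
        },
        n_z=spec.n_z,
    )

    # per-voxel mu from the interface stack (RPE band runs through BM)
    thresholds = [ilm, rnfl_gcl, ipl_inl, rpe_upper, bm, choroid_end]
    mu_values = np.array(
        [spec.layers[name].mu_per_um for name in LAYER_ORDER], dtype=float
    )
    z = np.arange(spec.n_z)[:, None, None]
    layer_idx = np.zeros((spec.n_z, spec.n_x, spec.n_y), dtype=np.int8)
    for thr in thresholds:
        layer_idx += (z >= thr[None]).astype(np.int8)
    mu_volume = mu_values[layer_idx]

    optical_depth = np.cumsum(mu_volume * spec.dz, axis=0) - mu_volume * spec.dz
    intensity = spec.alpha * mu_volume * spec.dz * spec.i0 * np.exp(-2.0 * optical_depth)
    if spec.noise_l is not None:
        intensity = intensity * rng.gamma(spec.noise_l, 1.0 / spec.noise_l, size=intensity.shape)

    volume = OCTVolume(
        intensity.astype(np.float32),
        dz=spec.dz,
        dx=spec.dx,
        dy=spec.dy,
        laterality=spec.laterality,
    )
    thickness_maps = {
        "RNFL": counts["RNFL"] * spec.dz,
        "GCIPL": counts["GCIPL"] * spec.dz,
    }
    truth = GroundTruth(
        surfaces=surfaces,
        mu_volume=mu_volume.astype(np.float32),
        thickness_maps=thickness_maps,
        fovea_mm=spec.fovea_centre_mm(),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Two-group cohort targets: per layer/region/index Gaussian (mean, SD).

    ``targets[(layer, region, index, group)] = (mean, sd)``; defaults are
    the published patient/control summary statistics (38 patients, 43
    controls).
    """

    n_patients: int = study_defaults.N_PATIENTS
    n_controls: int = study_defaults.N_CONTROLS
    targets: dict = field(default_factory=lambda: dict(study_defaults.GROUP_SUMMARY))
    seed: int | None = None
    image_spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        for key, (mean, sd) in self.targets.items():
            if sd < 0:
                raise ValueError(f"negative SD for target {key}")


def _draw_metrics_subject(cspec: CohortSpec, subject_id: str, group: str, rng) -> SubjectMetrics:
    metrics = SubjectMetrics(subject_id=subject_id, group=group)
    for layer in study_defaults.LAYERS:
        for region in REGIONS:
            vals = {}
            for index, column in (
                ("thickness", "thickness_um"),
                ("attenuation", "attenuation_per_um"),
                ("intensity", "corrected_intensity_au"),
            ):
                mean, sd = cspec.targets[(layer, region, index, group)]
                vals[column] = float(rng.normal(mean, sd))
            metrics.values[(layer, region)] = vals
    return metrics


def simulate_cohort(cspec: CohortSpec, mode: str = "metrics", seed=None):
    """Simulate a two-group cohort.

    ``metrics`` mode returns a list of :class:`SubjectMetrics` drawn from
    the target Gaussians.  ``image`` mode returns a list of
    ``(subject_id, group, OCTVolume, GroundTruth)`` tuples whose RNFL /
    GCIPL thickness and attenuation means are drawn per subject from the
    layer-average targets and baked into per-subject phantoms.
    """
    if mode not in ("metrics", "image"):
        raise ValueError("mode must be 'metrics' or 'image'")
    if seed is None:
        seed = cspec.seed
    rng = np.random.default_rng(seed)
    roster = [("P%03d" % i, "patient") for i in range(cspec.n_patients)]
    roster += [("C%03d" % i, "control") for i in range(cspec.n_controls)]

    if mode == "metrics":
        return [_draw_metrics_subject(cspec, sid, grp, rng) for sid, grp in roster]

    base = cspec.image_spec if cspec.image_spec is not None else PhantomSpec.desk()
    out = []
    for sid, grp in roster:
        layers = dict(base.layers)
        for layer in ("RNFL", "GCIPL"):
            t_mean, t_sd = cspec.targets[(layer, "average", "thickness", grp)]
            m_mean, m_sd = cspec.targets[(layer, "average", "attenuation", grp)]
            thickness = max(float(rng.normal(t_mean, t_sd)), 2 * base.dz)
            mu = max(float(rng.normal(m_mean, m_sd)), 1e-6)
            old = layers[layer]
            layers[layer] = replace(
                old,
                thickness_um=thickness,
                mu_per_um=mu,
                pit_depth_um=min(old.pit_depth_um, 0.8 * thickness),
            )
        spec = replace(base, layers=layers)
        volume, truth = simulate_volume(spec, seed=rng.integers(0, 2**31 - 1))
        volume.subject_id = sid
        volume.group = grp
        out.append((sid, grp, volume, truth))
    return out


# ---------------------------------------------------------------------------
# Config files (YAML key-value hierarchy)


def _layer_from_dict(d: dict) -> LayerSpec:
    return LayerSpec(**d)


def load_phantom_spec(path) -> PhantomSpec:
    """Read a :class:`PhantomSpec` from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    layers_cfg = cfg.pop("layers", None)
    known = {f for f in PhantomSpec.__dataclass_fields__ if f != "layers"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown phantom config keys: {sorted(unknown)}")
    if "fovea_mm" in cfg and cfg["fovea_mm"] is not None:
        cfg["fovea_mm"] = tuple(cfg["fovea_mm"])
    if layers_cfg is None:
        return PhantomSpec(**cfg)
    layers = _default_layers()
    for name, d in layers_cfg.items():
        if name not in LAYER_ORDER:
            raise ValueError(f"unknown layer {name!r} in config")
        layers[name] = _layer_from_dict(d)
    return PhantomSpec(layers=layers, **cfg)


def load_cohort_spec(path) -> CohortSpec:
    """Read a :class:`CohortSpec` from a YAML config file.

    Target overrides are nested as ``targets: {layer: {region: {index:
    {group: [mean, sd]}}}}``; omitted entries keep the published defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    targets = dict(study_defaults.GROUP_SUMMARY)
    for layer, regions in (cfg.pop("targets", None) or {}).items():
        for region, indices in regions.items():
            for index, groups in indices.items():
                for group, pair in groups.items():
                    key = (layer, region, index, group)
                    if key not in targets:
                        raise ValueError(f"unknown cohort target {key}")
                    targets[key] = (float(pair[0]), float(pair[1]))
    known = {"n_patients", "n_controls", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortSpec(targets=targets, **cfg)
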