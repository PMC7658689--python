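"""End-to-end orchestration: simulate -> preprocess -> compensate -> metrics -> compare.

A run is described by a :class:`RunConfig` (schema-validated; unknown keys
rejected) and produces a run directory containing ``metrics.csv``,
``table1.csv``, ``table2.csv`` and a ``manifest.json`` recording the
config hash, seed and per-stage provenance.  No stage mutates its inputs
on disk; reruns with the same config are bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort_stats, io_store, optics, preprocess, regional, synthetic_data

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("octatten")


@dataclass
class RunConfig:
    """All pipeline parameters for one reproducible run."""

    seed: int = 0
    mode: str = "metrics"  # "metrics" | "image"
    n_patients: int = 38
    n_controls: int = 43
    dz_um: float = 2.62
    choroid_extension_voxels: int = 300
    denoise_kernel: int = 3
    quadrant_width_mm: float = 5.0
    significance_alpha: float = 0.05
    equal_variance_ttest: bool = True
    fovea: str = "auto"  # "auto" or "x,y" in mm
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides (image mode)

    def __post_init__(self) -> None:
        if self.mode not in ("metrics", "image"):
            raise ValueError("mode must be 'metrics' or 'image'")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if not self.dz_um > 0:
            raise ValueError("dz_um must be positive")
        if self.choroid_extension_voxels < 0:
            raise ValueError("choroid_extension_voxels must be >= 0")
        if self.denoise_kernel < 1 or self.denoise_kernel % 2 == 0:
            raise ValueError("denoise_kernel must be odd and >= 1")
        if not self.quadrant_width_mm > 0:
            raise ValueError("quadrant_width_mm must be positive")
        if not (0 < self.significance_alpha < 1):
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.fovea != "auto":
            parts = str(self.fovea).split(",")
            if len(parts) != 2:
                raise ValueError("fovea must be 'auto' or 'x,y' in mm")
            float(parts[0]), float(parts[1])

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_run_config(path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**cfg)


def _fovea_mm(config: RunConfig, surfaces, volume):
    if config.fovea != "auto":
        x, y = (float(v) for v in config.fovea.split(","))
        return (x, y)
    return preprocess.locate_fovea(surfaces, volume.dx, volume.dy, dz=volume.dz)


def _subject_metrics_from_volume(config, sid, group, volume, truth):
    den = preprocess.denoise(volume, kernel=config.denoise_kernel)
    flat, surfaces = preprocess.flatten_at_bm(den, truth.surfaces)
    maps = optics.compute_optical_maps(
        flat.volume,
        surfaces,
        dz=config.dz_um,
        choroid_extension=config.choroid_extension_voxels,
    )
    fovea = _fovea_mm(config, surfaces, volume)
    grid = regional.build_quadrant_grid(
        volume.n_x,
        volume.n_y,
        volume.dx,
        volume.dy,
        fovea,
        width_mm=config.quadrant_width_mm,
        laterality=volume.laterality,
    )
    return regional.summarize_subject(
        maps, surfaces, grid, dz=config.dz_um, subject_id=sid, group=group
    )


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline and write the run directory.

    Raises with the failing stage's name if any stage errors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cspec = synthetic_data.CohortSpec(
            n_patients=config.n_patients, n_controls=config.n_controls
        )
        if config.mode == "metrics":
            metrics = synthetic_data.simulate_cohort(cspec, mode="metrics", seed=config.seed)
        else:
            if config.phantom:
                cspec.image_spec = synthetic_data.PhantomSpec.desk(**config.phantom)
            cohort = synthetic_data.simulate_cohort(cspec, mode="image", seed=config.seed)
        timings[stage] = time.perf_counter() - t0

        if config.mode == "image":
            stage = "analyze"
            t0 = time.perf_counter()
            metrics = [
                _subject_metrics_from_volume(config, sid, grp, vol, truth)
                for sid, grp, vol, truth in cohort
            ]
            timings[stage] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        io_store.write_metrics_table(metrics, out_dir / "metrics.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "compare"
        t0 = time.perf_counter()
        table1 = cohort_stats.build_table1(metrics, alpha=config.significance_alpha)
        table2 = cohort_stats.build_table2(metrics, alpha=config.significance_alpha)
        cohort_stats.table1_to_frame(table1).to_csv(
            out_dir / "table1.csv", index=False, lineterminator="\n"
        )
        cohort_stats.table2_to_frame(table2).to_csv(
            out_dir / "table2.csv", index=False, lineterminator="\n"
        )
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": config.n_patients + config.n_controls,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "outputs": ["metrics.csv", "table1.csv", "table2.csv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    for stage_name, seconds in timings.items():
        log.info("stage %-8s %.3f s", stage_name, seconds)
    return out_dir
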