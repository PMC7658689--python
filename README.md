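# octatten

Depth-resolved attenuation compensation and regional quantification of
macular SD-OCT volumes, with the cohort statistics used to compare
patient and control eyes.

## The problem

Raw OCT intensity is a poor measure of tissue reflectivity: the probing
beam is attenuated by everything above the voxel being imaged, so deep
layers look dim regardless of their actual scattering. Under a
single-scattering model the attenuation can be undone per A-scan from the
measured profile `E_A(z)` alone:

```
E_R(z)  =  E_A(z) · Σ_u E_A(u) / Σ_{u>z} E_A(u)            (corrected intensity)
μ(z)    =  E_A(z) / (2 · Δz · Σ_{u>z} E_A(u))              (attenuation coefficient, µm⁻¹)
```

Signal above the inner limiting membrane is treated as noise and the
estimation band stops a configurable extension (default 300 voxels) below
the retinal pigment epithelium, covering the choroid while avoiding the
overcompensated bottom of the scan.

On top of the per-voxel optics, the package provides: B-scan flattening at
Bruch's membrane, fovea localisation, a fovea-centred 5-mm analysis square
split into superonasal / inferonasal / superotemporal / inferotemporal
quadrants (laterality-aware), per-layer thickness, attenuation and
corrected-intensity summaries for the RNFL and GCIPL, and cohort-level
statistics: Shapiro–Wilk-gated t / Mann–Whitney comparisons, standardized
beta regression, and ROC analysis with DeLong variance and pairwise AUC
tests. A synthetic phantom and cohort generator supplies ground truth for
every stage; no clinical data are required.

Intended users: researchers quantifying retinal optical properties from
layered OCT volumes and validating attenuation-based indices against
thickness.

## Worked example

```python
import numpy as np
from octatten import synthetic_data as sd, optics, preprocess, regional, cohort_stats

# one noiseless phantom eye at desk scale (native 2.62 µm axial sampling,
# 64×64 lateral columns over ~6×6 mm)
spec = sd.PhantomSpec.desk(noise_l=None)
volume, truth = sd.simulate_volume(spec, seed=7)
flat, surfaces = preprocess.flatten_at_bm(volume, truth.surfaces)
maps = optics.compute_optical_maps(flat.volume, surfaces)
fovea = preprocess.locate_fovea(surfaces, volume.dx, volume.dy, dz=volume.dz)
grid = regional.build_quadrant_grid(volume.n_x, volume.n_y, volume.dx, volume.dy,
                                    fovea, width_mm=5.0, laterality="OD")
m = regional.summarize_subject(maps, surfaces, grid)
for region in ("SN", "IN", "ST", "IT", "average"):
    v = m.values[("RNFL", region)]
    print(f"RNFL {region:>7}: {v['thickness_um']:6.2f} um, "
          f"{v['attenuation_per_um']:.5f} /um, {v['corrected_intensity_au']:8.1f} AU")
```

```
RNFL      SN:  36.90 um, 0.00122 /um,  31658.8 AU
RNFL      IN:  36.74 um, 0.00122 /um,  31658.9 AU
RNFL      ST:  36.13 um, 0.00122 /um,  31658.7 AU
RNFL      IT:  37.54 um, 0.00122 /um,  31657.8 AU
RNFL average:  36.82 um, 0.00122 /um,  31658.5 AU
```

The quadrant thicknesses vary with the phantom's lateral thickness field
and foveal pit; the recovered attenuation sits ~1.7% above the true
0.0012 µm⁻¹ (discretisation plus residual-tail bias; see
`docs/methods.md`). A metrics-level two-group cohort and its report
tables:

```python
cohort = sd.simulate_cohort(sd.CohortSpec(), mode="metrics", seed=7)
rows = cohort_stats.build_table1(cohort)   # 30 comparison rows
t2 = cohort_stats.build_table2(cohort)     # per-layer ROC + DeLong pairing
```

prints, for the superonasal RNFL thickness row,

```
RNFL SN thickness: patients 40.98+/-4.75, controls 46.35+/-5.03, t-test, P=0.0000, decrease=11.58%
RNFL AUCs: {'thickness': 0.817, 'attenuation': 0.787, 'intensity': 0.522} pair: ('thickness', 'attenuation') dAUC=0.030 P=0.673
```

i.e. the simulated patients show the expected superonasal thinning, and
thickness and attenuation are the two discriminating indices for the RNFL
whose AUCs the DeLong test then compares.

## Command line

```sh
octatten simulate   --mode metrics --seed 1 --out sim/
octatten preprocess --in eye.tif --surfaces eye_surfaces.csv --out pre/
octatten compensate --in pre/flattened.tif --surfaces pre/surfaces.csv --out maps/
octatten metrics    --maps maps/ --volume pre/flattened.tif --surfaces pre/surfaces.csv --out metrics.csv
octatten compare    --metrics metrics.csv --out report/
octatten run        --config run.yaml --out run/
```

## File formats

* **Volumes**: multi-page TIFF (one page per B-scan) plus a JSON sidecar
  with spacings, laterality, subject id and group. Array dtype is
  preserved exactly.
* **Surfaces**: CSV with columns `x, y, surface, z_index` (0-based voxel
  indices, z = 0 at the vitreous). Surface names, in depth order:
  `ILM, RNFL_GCL, IPL_INL, RPE_upper, RPE_lower, BM`.
* **Metrics**: long-format CSV, one row per subject × layer × region.

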