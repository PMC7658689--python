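"""Tests for the quadrant grid and regional summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octatten import optics, regional
from octatten import synthetic_data as sd
from octatten.io_store import LayerSurfaces
from conftest import flat_layers


GEOM = dict(n_x=64, n_y=64, dx=93.76, dy=93.76)


def centre_mm():
    return (32 * GEOM["dx"] / 1000.0, 32 * GEOM["dy"] / 1000.0)


class TestQuadrantGrid:
    def test_od_superonasal_is_superior_right(self):
        grid = regional.build_quadrant_grid(**GEOM, fovea_mm=centre_mm(), laterality="OD")
        fx_idx, fy_idx = 32, 32
        assert grid.labels[fx_idx + 5, fy_idx - 5] == "SN"  # nasal = larger x for OD
        assert grid.labels[fx_idx + 5, fy_idx + 5] == "IN"
        assert grid.labels[fx_idx - 5, fy_idx - 5] == "ST"
        assert grid.labels[fx_idx - 5, fy_idx + 5] == "IT"

    def test_os_swaps_nasal_temporal_only(self):
        od = regional.build_quadrant_grid(**GEOM, fovea_mm=centre_mm(), laterality="OD")
        os_ = regional.build_quadrant_grid(**GEOM, fovea_mm=centre_mm(), laterality="OS")
        swap = {"SN": "ST", "ST": "SN", "IN": "IT", "IT": "IN", "outside": "outside"}
        # the vertical midline keeps its nasal tie-break in both eyes, so
        # compare off-midline columns only
        off_midline = np.arange(GEOM["n_x"]) != 32
        assert np.all(
            os_.labels[off_midline] == np.vectorize(swap.get)(od.labels[off_midline])
        )

    def test_partition_is_disjoint_and_exhaustive(self):
        grid = regional.build_quadrant_grid(**GEOM, fovea_mm=centre_mm(), laterality="OD")
        inside = grid.region_mask("average")
        counts = sum(int(grid.region_mask(q).sum()) for q in regional.QUADRANTS)
        assert counts == int(inside.sum())
        # no double labels by construction of a single label array; check
        # each quadrant mask is inside the square
        for q in regional.QUADRANTS:
            assert not (grid.region_mask(q) & ~inside).any()

    def test_in_square_count_matches_brute_force(self):
        fovea = centre_mm()
        grid = regional.build_quadrant_grid(**GEOM, fovea_mm=fovea, width_mm=5.0)
        count = 0
        for i in range(GEOM["n_x"]):
            for j in range(GEOM["n_y"]):
                x = i * GEOM["dx"] / 1000.0
                y = j * GEOM["dy"] / 1000.0
                if abs(x - fovea[0]) <= 2.5 and abs(y - fovea[1]) <= 2.5:
                    count += 1
        assert int(grid.region_mask("average").sum()) == count

    @given(
        fi=st.integers(min_value=20, max_value=44),
        fj=st.integers(min_value=20, max_value=44),
        lat=st.sampled_from(["OD", "OS"]),
    )
    @settings(max_examples=30, deadline=None)
    def test_mirror_symmetry(self, fi, fj, lat):
        """Mirroring left-right (fovea included) and toggling laterality
        leaves every column's label unchanged."""
        n_x = GEOM["n_x"]
        fovea = (fi * GEOM["dx"] / 1000.0, fj * GEOM["dy"] / 1000.0)
        grid = regional.build_quadrant_grid(**GEOM, fovea_mm=fovea, width_mm=2.0, laterality=lat)
        m_fovea = ((n_x - 1 - fi) * GEOM["dx"] / 1000.0, fovea[1])
        other = "OS" if lat == "OD" else "OD"
        mirrored = regional.build_quadrant_grid(
            **GEOM, fovea_mm=m_fovea, width_mm=2.0, laterality=other
        )
        assert np.all(grid.labels == mirrored.labels[::-1, :])

    def test_fovea_outside_scan_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            regional.build_quadrant_grid(**GEOM, fovea_mm=(50.0, 1.0))

    def test_clipped_square_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            regional.build_quadrant_grid(**GEOM, fovea_mm=(0.5, 0.5), width_mm=5.0)


class TestThickness:
    def test_stated_rule_arithmetic(self):
        surf = LayerSurfaces(
            {
                "ILM": np.full((8, 8), 10),
                "RNFL_GCL": np.full((8, 8), 25),
                "IPL_INL": np.full((8, 8), 40),
                "RPE_upper": np.full((8, 8), 50),
                "RPE_lower": np.full((8, 8), 60),
                "BM": np.full((8, 8), 61),
            }
        )
        np.testing.assert_allclose(
            regional.layer_thickness_map(surf, "RNFL", dz=2.62), 39.3
        )
        np.testing.assert_allclose(
            regional.layer_thickness_map(surf, "GCIPL", dz=2.62), 15 * 2.62
        )

    def test_phantom_ground_truth_exact(self, pit_noiseless_spec):
        _, truth = sd.simulate_volume(pit_noiseless_spec, seed=9)
        for layer in ("RNFL", "GCIPL"):
            np.testing.assert_array_equal(
                regional.layer_thickness_map(truth.surfaces, layer, pit_noiseless_spec.dz),
                truth.thickness_maps[layer],
            )

    def test_unknown_layer_rejected(self, pit_noiseless_spec):
        _, truth = sd.simulate_volume(pit_noiseless_spec, seed=9)
        with pytest.raises(ValueError, match="unknown layer"):
            regional.layer_thickness_map(truth.surfaces, "ONL", 2.62)


class TestSummarizeSubject:
    def make_uniform(self):
        spec = sd.PhantomSpec.desk(layers=flat_layers(), noise_l=None, n_x=64, n_y=64)
        vol, truth = sd.simulate_volume(spec, seed=0)
        maps = optics.compute_optical_maps(vol, truth.surfaces)
        grid = regional.build_quadrant_grid(
            vol.n_x, vol.n_y, vol.dx, vol.dy, truth.fovea_mm, width_mm=5.0
        )
        return spec, vol, truth, maps, grid

    def test_uniform_phantom_reports_construction_values(self):
        spec, vol, truth, maps, grid = self.make_uniform()
        m = regional.summarize_subject(maps, truth.surfaces, grid)
        t_rnfl = truth.thickness_maps["RNFL"][0, 0]
        for region in regional.REGIONS:
            vals = m.values[("RNFL", region)]
            np.testing.assert_allclose(vals["thickness_um"], t_rnfl, rtol=1e-12)
            np.testing.assert_allclose(vals["attenuation_per_um"], 0.0012, rtol=0.03)

    def test_average_is_voxel_weighted_combination(self):
        spec, vol, truth, maps, grid = self.make_uniform()
        m = regional.summarize_subject(maps, truth.surfaces, grid)
        weights = {q: int(grid.region_mask(q).sum()) for q in regional.QUADRANTS}
        total = sum(weights.values())
        combo = sum(
            weights[q] * m.values[("GCIPL", q)]["thickness_um"] for q in regional.QUADRANTS
        ) / total
        np.testing.assert_allclose(m.values[("GCIPL", "average")]["thickness_um"], combo)

    def test_nasal_thinning_shows_in_nasal_quadrants_only(self):
        spec = sd.PhantomSpec.desk(layers=flat_layers(), noise_l=None, n_x=64, n_y=64)
        vol, truth = sd.simulate_volume(spec, seed=0)
        # thin the RNFL 10% on the nasal (larger-x, OD) half by editing the
        # ground-truth geometry directly
        surf = {n: truth.surfaces[n].copy() for n in truth.surfaces.surfaces}
        n_vox = surf["RNFL_GCL"][0, 0] - surf["ILM"][0, 0]
        thin = max(int(round(0.1 * n_vox)), 1)
        surf["ILM"][32:, :] += thin  # nasal half gets a thinner RNFL
        surfaces = LayerSurfaces(surf, n_z=spec.n_z)
        maps = optics.compute_optical_maps(vol, surfaces)
        grid = regional.build_quadrant_grid(
            vol.n_x, vol.n_y, vol.dx, vol.dy, truth.fovea_mm, width_mm=5.0, laterality="OD"
        )
        m = regional.summarize_subject(maps, surfaces, grid)
        t_full = (n_vox) * spec.dz
        t_thin = (n_vox - thin) * spec.dz
        for q, expected in (("SN", t_thin), ("IN", t_thin), ("ST", t_full), ("IT", t_full)):
            np.testing.assert_allclose(m.values[("RNFL", q)]["thickness_um"], expected, rtol=0.02)

    def test_region_without_valid_voxels_is_nan(self):
        spec, vol, truth, maps, grid = self.make_uniform()
        maps.valid[:] = False
        m = regional.summarize_subject(maps, truth.surfaces, grid)
        assert np.isnan(m.values[("RNFL", "SN")]["attenuation_per_um"])
        # thickness does not depend on voxel validity
        assert np.isfinite(m.values[("RNFL", "SN")]["thickness_um"])


class TestDecreaseRatio:
    @pytest.mark.parametrize(
        "control,patient,expected",
        [(45.73, 41.32, 9.64), (49.86, 43.37, 13.02), (28.88, 27.53, 4.67), (31.24, 29.47, 5.67)],
    )
    def test_published_quadrant_ratios(self, control, patient, expected):
        assert regional.decrease_ratio(control, patient) == expected

    def test_identity_is_zero(self):
        assert regional.decrease_ratio(37.5, 37.5) == 0.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            regional.decrease_ratio(0.0, 1.0)
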