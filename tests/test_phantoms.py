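"""Phantom geometry and the synthetic HAADF/EELS generators."""

import math

import numpy as np
import pytest
from scipy import stats

import blockface as bf
from blockface.errors import ConfigError, GeometryError
from blockface.phantoms import (
    Box,
    DEFAULT_STAIN_DEPTHS,
    ImplantProfile,
    depth_series_phantom,
    synth_eels_spectrum,
    synth_haadf_image,
    vesicle_phantom,
)


class TestDepthSeries:
    def test_five_regions_with_expected_depths(self):
        ph = depth_series_phantom()
        assert len(ph.regions) == 5
        assert tuple((b.z0, b.z1) for b in ph.regions) == DEFAULT_STAIN_DEPTHS
        # each region is a 5-nm-thick square of stained matrix
        for b in ph.regions:
            assert b.z1 - b.z0 == pytest.approx(5.0)
            assert b.material.fraction_of("Pb") == pytest.approx(0.03)

    def test_no_ga_matrix_is_plain_epon(self, epon):
        ph = depth_series_phantom(ga_fraction=0.0)
        assert ph.matrix.fraction_of("Ga") == 0.0
        assert {s: f for s, f in ((el.symbol, f) for el, f in ph.matrix.fractions)} == {
            s: f for s, f in ((el.symbol, f) for el, f in epon.fractions)
        }

    def test_zero_stain_is_matrix_everywhere(self):
        ph = depth_series_phantom(stain_fraction=0.0)
        b = ph.regions[0]
        probe = ((b.x0 + b.x1) / 2, 0.0, (b.z0 + b.z1) / 2)
        inside = ph.material_at(*probe)
        outside = ph.material_at(b.x0 - 10.0, 0.0, (b.z0 + b.z1) / 2)
        assert {el.symbol: f for el, f in inside.fractions} == {
            el.symbol: f for el, f in outside.fractions
        }

    def test_ga_matrix_composition(self):
        ph = depth_series_phantom(ga_fraction=0.5)
        assert ph.matrix.fraction_of("Ga") == pytest.approx(0.5)
        assert ph.matrix.fraction_of("C") == pytest.approx(0.04)

    def test_lookup_first_match_and_boundaries(self):
        ph = depth_series_phantom()
        b = ph.regions[2]
        assert ph.material_at((b.x0 + b.x1) / 2, 0.0, (b.z0 + b.z1) / 2) is b.material
        assert ph.material_at((b.x0 + b.x1) / 2, 0.0, b.z1 + 0.1) is ph.matrix

    def test_overlapping_boxes_rejected(self):
        with pytest.raises(GeometryError):
            depth_series_phantom(spacing=-10.0, depths=((0, 5), (0, 5)))

    def test_masks_disjoint_and_large_enough(self):
        ph = depth_series_phantom()
        scan = ph.default_scan()
        masks = ph.region_masks(scan)
        bg = ph.background_mask(scan)
        total = bg.astype(int)
        for m in masks:
            assert m.sum() >= 100
            total += m.astype(int)
        assert total.max() <= 1
        assert bg.sum() >= 100


class TestVesicle:
    def test_voxelized_shell_volume_close_to_analytic(self):
        ph = vesicle_phantom(ga_fraction=0.0)
        n_shell = int((ph.idx == 1).sum())
        v_shell = 4 / 3 * math.pi * (ph.shell["r_out"] ** 3 - ph.shell["r_in"] ** 3)
        v_voxel = n_shell * ph.voxel_size**3
        assert v_voxel == pytest.approx(v_shell, rel=0.15)  # voxelization error

    def test_inner_diameter(self):
        ph = vesicle_phantom()
        assert 2 * ph.shell["r_in"] == pytest.approx(30.0)

    def test_ga_in_matrix_and_shell_host(self, epon):
        ph = vesicle_phantom(ga_fraction=0.5)
        matrix, stained = ph.materials
        assert matrix.fraction_of("Ga") == pytest.approx(0.5)
        expected = bf.with_stain(bf.substitute_ga_for_c(epon, 0.5), 0.03)
        assert {el.symbol: f for el, f in stained.fractions} == pytest.approx(
            {el.symbol: f for el, f in expected.fractions}
        )

    def test_coarse_voxel_warns(self):
        with pytest.warns(UserWarning, match="poorly sampled"):
            vesicle_phantom(voxel_size=8.0)

    def test_voxel_and_analytic_lookup_agree_for_aligned_box(self, epon):
        # voxelize a box phantom by hand and compare lookups on voxel centers
        stained = bf.with_stain(epon, 0.03)
        box = Box(0.0, 30.0, 0.0, 30.0, 6.0, 12.0, stained)
        from blockface.phantoms import Phantom, VoxelPhantom

        analytic = Phantom(epon, (box,))
        h = 3.0
        n = 10
        idx = np.zeros((n, n, n), np.int64)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    c = ((i + 0.5) * h, (j + 0.5) * h, (k + 0.5) * h)
                    idx[i, j, k] = 1 if box.contains(*c) else 0
        vox = VoxelPhantom(idx, (epon, stained), h, 0.0, 0.0)
        for p in [(1.5, 1.5, 7.5), (16.5, 16.5, 7.5), (16.5, 16.5, 16.5)]:
            assert analytic.material_at(*p) is vox.material_at(*p)


class TestSynthHaadf:
    def test_zero_amplitude_is_statistically_flat(self):
        prof = ImplantProfile(0.0)
        img = synth_haadf_image(prof, shape=(32, 64), dose=500.0, seed=3)
        counts = img.counts[:, 20:].ravel()  # skip the vacuum margin
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, counts.size - 1)
        assert p > 0.01

    def test_doubling_dose_shrinks_relative_noise(self):
        prof = ImplantProfile(0.0)
        rel = []
        for dose in (1000.0, 2000.0):
            img = synth_haadf_image(prof, shape=(64, 64), dose=dose, seed=4)
            c = img.counts[:, 20:].astype(float)
            rel.append(c.std() / c.mean())
        assert rel[1] == pytest.approx(rel[0] / math.sqrt(2), rel=0.1)

    def test_metadata_records_generation_parameters(self):
        prof = ImplantProfile(0.25, onset_width=6.0, decay_length=50.0)
        img = synth_haadf_image(prof, dose=100.0, seed=5)
        assert img.meta["peak_ga_fraction"] == 0.25
        assert img.meta["decay_length_nm"] == 50.0
        assert img.meta["seed"] == 5

    def test_profile_shape_validation(self):
        with pytest.raises(ValueError):
            ImplantProfile(1.5)
        with pytest.raises(ValueError):
            ImplantProfile(0.3, onset_width=60.0, decay_length=50.0)


class TestSynthEels:
    def test_no_ga_means_no_step_at_1140(self):
        kw = dict(
            sigmas={"C": 100.0, "O": 50.0, "Ga": 40.0},
            background=(1.0, 3.0),
            dose=2e5,
            seed=6,
        )
        with_ga = synth_eels_spectrum({"C": 1.0, "Ga": 0.3}, **kw)
        without = synth_eels_spectrum({"C": 1.0, "Ga": 0.0}, **kw)
        def step(spec):
            e, c = spec.energy, spec.counts
            lo = c[(e >= 1100) & (e < 1140)].mean()
            hi = c[(e >= 1140) & (e < 1180)].mean()
            return hi - lo
        assert step(with_ga) > 10 * abs(step(without))

    def test_background_only_is_loglog_linear(self):
        spec = synth_eels_spectrum(
            {}, sigmas={}, background=(1.0, 2.5), dose=1e6, seed=7
        )
        slope, _ = np.polyfit(np.log(spec.energy), np.log(spec.counts), 1)
        assert slope == pytest.approx(-2.5, abs=0.05)

    def test_onset_outside_axis_rejected(self):
        with pytest.raises(ConfigError):
            synth_eels_spectrum(
                {"Ga": 1.0},
                sigmas={"Ga": 1.0},
                edges={"Ga": 1590.0},
                energy_range=(200.0, 1600.0),
            )

    def test_edge_counts_match_configuration(self):
        """The summed edge counts over the standard window equal
        abundance * sigma * dose in expectation."""
        spec = synth_eels_spectrum(
            {"C": 2.0},
            sigmas={"C": 50.0},
            background=(0.0, 3.0),
            dose=1e4,
            seed=8,
        )
        e = spec.energy
        win = (e >= 284.0) & (e < 384.0)
        total = spec.counts[win].sum()
        assert total == pytest.approx(2.0 * 50.0 * 1e4, rel=0.02)


class TestBoundaryDistances:
    def test_distance_to_box_entry_and_exit(self, epon):
        ph = depth_series_phantom()
        b = ph.regions[0]
        # straight down onto the first box from above the surface plane
        x_mid = (b.x0 + b.x1) / 2
        d = ph.distance_to_boundary((x_mid, 0.0, 2.0), (0.0, 0.0, 1.0))
        assert d == pytest.approx(3.0)  # box bottom at z = 5
        # inside the box heading up: surface plane at z = 0 is the boundary
        d = ph.distance_to_boundary((x_mid, 0.0, 2.0), (0.0, 0.0, -1.0))
        assert d == pytest.approx(2.0)
        # lateral approach toward the box face
        d = ph.distance_to_boundary((b.x0 - 10.0, 0.0, 2.5), (1.0, 0.0, 0.0))
        assert d == pytest.approx(10.0)

    def test_voxel_distance_steps_on_planes(self):
        ph = vesicle_phantom(ga_fraction=0.0)
        h = ph.voxel_size
        start = (ph.x0 + 0.5 * h, ph.x0 + 0.5 * h, 0.5 * h)
        d = ph.distance_to_boundary(start, (0.0, 0.0, 1.0))
        assert d == pytest.approx(0.5 * h)
        d = ph.distance_to_boundary(start, (1.0, 0.0, 0.0))
        assert d == pytest.approx(0.5 * h)
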