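"""Phantom geometry, spectral rendering and cohort generation."""

import numpy as np
import pytest
from scipy import ndimage

from spectralseg.core import BACKGROUND, CSF, GM, WM
from spectralseg.phantom import (
    CohortManifest,
    DegenerateGeometryError,
    GridSpec,
    PhantomGeometry,
    SpectralModel,
    generate_cohort,
    generate_label_volume,
    render_spectral_stack,
)

from conftest import TINY_GRID


class TestGenerateLabelVolume:
    def test_all_classes_present_and_deterministic(self, default_geometry, default_grid):
        lab1 = generate_label_volume(default_geometry, default_grid, seed=7)
        lab2 = generate_label_volume(default_geometry, default_grid, seed=7)
        counts = lab1.class_counts()
        assert set(np.unique(lab1.data)) == {BACKGROUND, WM, GM, CSF}
        assert all(counts[c] > 0 for c in (BACKGROUND, WM, GM, CSF))
        assert lab1.data.tobytes() == lab2.data.tobytes()

    def test_seed_changes_fold_phase(self, default_geometry, default_grid):
        lab1 = generate_label_volume(default_geometry, default_grid, seed=1)
        lab2 = generate_label_volume(default_geometry, default_grid, seed=2)
        assert not np.array_equal(lab1.data, lab2.data)

    def test_wm_core_volume_matches_analytic_ellipsoid(self):
        # unfolded WM core (20,16,12) mm minus a (6,4,4) mm ventricle at 1 mm
        # voxels: voxel count should track the analytic ellipsoid volumes
        geo = PhantomGeometry(
            head_semi_axes=(38.0, 34.0, 30.0), csf_shell_thickness=6.0,
            cortex_thickness=12.0, ventricle_semi_axes=(6.0, 4.0, 4.0),
            cortical_fold_amplitude=0.0)
        grid = GridSpec(shape=(96, 96, 80), spacing=(1.0, 1.0, 1.0))
        lab = generate_label_volume(geo, grid, seed=1)
        analytic = 4.0 / 3.0 * np.pi * (20 * 16 * 12 - 6 * 4 * 4)
        wm_count = int((lab.data == WM).sum())
        assert abs(wm_count - analytic) / analytic < 0.05

    def test_zero_fold_amplitude_gives_smooth_shell(self):
        geo = PhantomGeometry(cortical_fold_amplitude=0.0)
        grid = GridSpec()
        lab = generate_label_volume(geo, grid, seed=3)
        # GM/WM interface voxels must sit within one voxel of the analytic
        # WM ellipsoid surface (normalised radius 1); the WM/ventricle
        # interface is excluded — only the cortical boundary is smooth
        wm = lab.data == WM
        gm_neighbourhood = ndimage.binary_dilation(lab.data == GM)
        boundary = wm & gm_neighbourhood
        x, y, z = grid.coordinates()
        a, b, c = geo.wm_semi_axes
        rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)[boundary]
        voxel_diag = np.linalg.norm(grid.spacing)
        assert np.all(np.abs(rho - 1.0) <= voxel_diag / min(geo.wm_semi_axes))

    def test_degenerate_geometry_raises(self):
        # a sub-voxel CSF shell plus a sub-voxel ventricle collapses CSF on
        # a coarse grid
        geo = PhantomGeometry(head_semi_axes=(60.0, 60.0, 50.0),
                              csf_shell_thickness=0.25, cortex_thickness=10.0,
                              ventricle_semi_axes=(1.0, 1.0, 1.0),
                              cortical_fold_amplitude=0.0)
        grid = GridSpec(shape=(16, 16, 8), spacing=(10.0, 10.0, 14.0))
        with pytest.raises(DegenerateGeometryError):
            generate_label_volume(geo, grid, seed=0)

    def test_volume_conservation(self, default_geometry, default_grid):
        lab = generate_label_volume(default_geometry, default_grid, seed=5)
        assert sum(lab.class_counts().values()) == np.prod(default_grid.shape)


class TestGeometryValidation:
    @pytest.mark.parametrize("kwargs", [
        {"head_semi_axes": (0.0, 85.0, 55.0)},
        {"csf_shell_thickness": -1.0},
        {"csf_shell_thickness": 30.0, "cortex_thickness": 30.0},
        {"ventricle_semi_axes": (60.0, 12.0, 10.0)},   # outside the WM core
        {"cortical_fold_amplitude": -2.0},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomGeometry(**kwargs)

    def test_jitter_is_reproducible_and_bounded(self, default_geometry):
        g1 = default_geometry.jittered(np.random.default_rng(9))
        g2 = default_geometry.jittered(np.random.default_rng(9))
        g3 = default_geometry.jittered(np.random.default_rng(10))
        assert g1 == g2
        assert g1 != g3
        for got, base in zip(g1.head_semi_axes, default_geometry.head_semi_axes):
            assert abs(got / base - 1.0) <= 0.10 + 1e-12


class TestSpectralModel:
    def test_default_trends(self, default_spectral):
        sm = default_spectral
        contrasts = [sm.hu_table[lv][GM] - sm.hu_table[lv][WM] for lv in sm.levels]
        assert contrasts == sorted(contrasts, reverse=True)
        sds = [sm.noise_sd[lv] for lv in sm.levels]
        assert sds == sorted(sds, reverse=True)

    @pytest.mark.parametrize("kwargs", [
        # contrast increasing with keV
        {"hu_table": {50: {CSF: 7, WM: 31, GM: 40}, 70: {CSF: 9, WM: 29, GM: 39},
                      120: {CSF: 10, WM: 28, GM: 42}},
         "noise_sd": {50: 6, 70: 4, 120: 3}},
        # CSF not darkest
        {"hu_table": {50: {CSF: 35, WM: 31, GM: 44}, 70: {CSF: 9, WM: 29, GM: 38},
                      120: {CSF: 10, WM: 28, GM: 34}},
         "noise_sd": {50: 6, 70: 4, 120: 3}},
        # noise not decreasing
        {"noise_sd": {50: 3, 70: 4, 120: 6}},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpectralModel(**kwargs)


class TestRenderSpectralStack:
    def test_noiseless_rendering_is_exact(self, default_geometry):
        lab = generate_label_volume(default_geometry, TINY_GRID, seed=2)
        sm = SpectralModel(noise_sd={50: 0.0, 70: 0.0, 120: 0.0})
        stack = render_spectral_stack(lab, sm, seed=0)
        for lv in sm.levels:
            lut = sm.hu_lookup(lv)
            assert np.array_equal(stack[lv], lut[lab.data])

    def test_noise_sd_recovered(self, default_geometry, default_grid,
                                default_spectral):
        lab = generate_label_volume(default_geometry, default_grid, seed=2)
        stack = render_spectral_stack(lab, default_spectral, seed=4)
        wm_vox = stack[70][lab.data == WM]
        assert wm_vox.size >= 10_000
        assert abs(wm_vox.std() - 4.0) / 4.0 < 0.10

    def test_contrast_decreases_with_kev(self, default_geometry, default_grid,
                                         default_spectral):
        lab = generate_label_volume(default_geometry, default_grid, seed=2)
        stack = render_spectral_stack(lab, default_spectral, seed=4)
        contrast = [stack[lv][lab.data == GM].mean() - stack[lv][lab.data == WM].mean()
                    for lv in (50, 70, 120)]
        assert contrast[0] > contrast[1] > contrast[2]

    def test_deterministic_and_grid_congruent(self, default_geometry,
                                              default_spectral):
        lab = generate_label_volume(default_geometry, TINY_GRID, seed=2)
        s1 = render_spectral_stack(lab, default_spectral, seed=8)
        s2 = render_spectral_stack(lab, default_spectral, seed=8)
        for lv in s1.levels:
            assert np.array_equal(s1[lv], s2[lv])
        assert s1.matches_grid(lab)


class TestGenerateCohort:
    def test_files_manifest_and_jitter(self, tiny_cohort):
        assert len(tiny_cohort.case_ids) == 4
        assert len(set(tiny_cohort.case_ids)) == 4
        for cid in tiny_cohort.case_ids:
            paths = tiny_cohort.case_paths(cid)
            assert paths["labels"].exists()
            assert sorted(paths["vmi"]) == [50, 70, 120]
        # jitter produces distinct anatomy across cases
        labs = [tiny_cohort.load_case(cid)[1].data for cid in tiny_cohort.case_ids]
        assert not np.array_equal(labs[0], labs[1])

    def test_regeneration_is_byte_identical(self, tmp_path):
        m1 = generate_cohort(2, tmp_path / "a", grid=TINY_GRID, seed=21)
        m2 = generate_cohort(2, tmp_path / "b", grid=TINY_GRID, seed=21)
        for cid in m1.case_ids:
            f1 = m1.case_paths(cid)["labels"]
            f2 = m2.case_paths(cid)["labels"]
            assert f1.read_bytes() == f2.read_bytes()

    def test_manifest_round_trip(self, tiny_cohort, tmp_path):
        reloaded = CohortManifest.load(tiny_cohort._resolve("manifest.json"))
        assert reloaded.case_ids == tiny_cohort.case_ids
        stack, labels = reloaded.load_case("case_000")
        assert stack.matches_grid(labels)

    def test_invalid_case_count(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort(0, tmp_path, seed=1)
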