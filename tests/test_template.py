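import numpy as np
import pytest
import SimpleITK as sitk

from midseg.core_io import Contour, StructureSet, Volume3D, contour_to_mask
from midseg.errors import LocalizationError
from midseg.metrics import dice
from midseg.phantoms import MidbrainSpec, make_midbrain_phantom
from midseg.template_pipeline import (CropWindow, SpatialTransform,
                                      anchor_slice_from_support,
                                      build_template, crop_volume,
                                      locate_crop, map_boundaries_to_subject,
                                      segment_subject, compare_to_truth,
                                      synthetic_bspline_transform,
                                      SITKBackend, TemplateBuildConfig,
                                      TemplateBundle)


class TestAnchorRule:
    def test_one_two_three_slice_rules(self):
        assert anchor_slice_from_support([10]) == 10
        assert anchor_slice_from_support([9, 10]) == 9      # lower of two
        assert anchor_slice_from_support([9, 10, 11]) == 10  # middle of three
        assert anchor_slice_from_support([8, 9, 10, 11]) == 9

    def test_empty_support_rejected(self):
        with pytest.raises(LocalizationError):
            anchor_slice_from_support([])


def _identity_transform(vol):
    return SpatialTransform(sitk.Transform(3, sitk.sitkIdentity), vol, vol)


def _mini_bundle(ref_nm, rn_mask):
    """Bundle carrying just what locate_crop needs."""
    tiny = Volume3D(np.zeros((4, 4, 4)), (1, 1, 1))
    return TemplateBundle(
        nm_template=tiny, qsm_template=tiny, nm_local=tiny, qsm_local=tiny,
        nm_crop=tiny, qsm_crop=tiny, boundaries=StructureSet(),
        bg_rois=StructureSet(), ref_nm_full=ref_nm, ref_rn_mask=rn_mask,
        crop_start_ref=0)


class TestLocateCrop:
    @pytest.mark.parametrize("n_slices,expected_anchor", [(2, 29), (3, 29)])
    def test_rn_slice_rules_on_phantoms(self, n_slices, expected_anchor):
        ph = make_midbrain_phantom(MidbrainSpec(rn_n_slices=n_slices),
                                   warped=False)
        rn = ph.truth.combined_mask("RN", ph.nm.shape)
        bundle = _mini_bundle(ph.nm, rn)
        w = locate_crop(ph.nm, _identity_transform(ph.nm), bundle)
        assert w.anchor == expected_anchor
        assert w.start == expected_anchor - 9
        assert w.stop - w.start == 16

    def test_rn_near_top_rejected(self):
        ph = make_midbrain_phantom(warped=False)
        rn = ph.truth.combined_mask("RN", ph.nm.shape)
        rn_high = np.roll(rn, 31, axis=2)  # RN pushed to slice ~60
        bundle = _mini_bundle(ph.nm, rn_high)
        with pytest.raises(LocalizationError):
            locate_crop(ph.nm, _identity_transform(ph.nm), bundle)


class TestSpatialTransform:
    def test_synthetic_warp_point_roundtrip(self):
        ph = make_midbrain_phantom(seed=1, warped=False)
        T = synthetic_bspline_transform(ph.nm, amplitude_mm=1.0, seed=7)
        Tinv = T.inverse()
        pts = np.array([[x, y, z] for x in (24, 32, 40)
                        for y in (28, 36) for z in (27, 30)], float)
        back = Tinv.transform_points(T.transform_points(pts))
        assert np.linalg.norm(back - pts, axis=1).mean() < 0.25

    def test_linear_inverse_exact(self):
        vol = Volume3D(np.zeros((16, 16, 16)), (1, 1, 1))
        t = sitk.TranslationTransform(3, (2.0, -1.0, 0.5))
        T = SpatialTransform(t, vol, vol)
        pts = np.array([[4.0, 5.0, 6.0]])
        np.testing.assert_allclose(
            T.inverse().transform_points(T.transform_points(pts)), pts,
            atol=1e-9)


class TestBackend:
    def test_self_registration_near_identity(self, backend):
        ph = make_midbrain_phantom(seed=1, warped=False)
        T = backend.register(ph.nm, ph.nm, stages=("rigid", "affine"))
        pts = np.array([[28.0, 30.0, 29.0], [36.0, 34.0, 30.0]])
        assert np.linalg.norm(T.transform_points(pts) - pts, axis=1).mean() < 0.3

    def test_known_rigid_recovered(self, backend):
        ph = make_midbrain_phantom(seed=1, warped=False)
        rot = sitk.Euler3DTransform()
        rot.SetCenter(tuple(np.array(ph.nm.shape) * np.array(ph.nm.spacing) / 2))
        rot.SetRotation(0.0, 0.0, np.deg2rad(5.0))
        rot.SetTranslation((2.0 * 0.67, 1.0 * 0.67, 0.0))
        truth = SpatialTransform(rot, ph.nm, ph.nm)
        moved = truth.warp(ph.nm)
        T = backend.register(moved, ph.nm, stages=("rigid",))
        pts = np.array([[28.0, 30.0, 29.0], [36.0, 34.0, 30.0],
                        [32.0, 40.0, 29.0], [25.0, 25.0, 28.0]])
        err = np.linalg.norm(T.transform_points(pts)
                             - truth.transform_points(pts), axis=1)
        assert err.mean() < 0.5

    def test_known_smooth_warp_recovered(self, backend):
        """Deformable stage recovers a known smooth warp to sub-pixel."""
        ph = make_midbrain_phantom(seed=1, warped=False)
        crop = Volume3D(ph.nm.data[:, :, 20:36].copy(), ph.nm.spacing)
        W = synthetic_bspline_transform(crop, mesh=(4, 4, 2),
                                        amplitude_mm=1.2, seed=3)
        warped = W.warp(crop)
        T = backend.register(warped, crop, stages=("rigid_inplane", "demons"))
        pts = np.array([[x, y, z] for x in (24, 32, 40)
                        for y in (28, 36) for z in (6, 9, 12)], float)
        err = np.linalg.norm(T.transform_points(pts)[:, :2]
                             - W.transform_points(pts)[:, :2], axis=1)
        assert err.mean() < 0.7

    def test_unknown_stage_rejected(self, backend):
        ph = make_midbrain_phantom(seed=1, warped=False)
        with pytest.raises(ValueError):
            backend.register(ph.nm, ph.nm, stages=("diffeo",))


class TestBoundaryMapping:
    def test_pure_translation_equivariance(self, template_bundle):
        dx_mm = 2 * template_bundle.nm_crop.spacing[0]
        t = sitk.TranslationTransform(3, (dx_mm, 0.0, 0.0))
        T = SpatialTransform(t, template_bundle.nm_crop,
                             template_bundle.nm_crop)
        mapped = map_boundaries_to_subject(template_bundle, T)
        ident = map_boundaries_to_subject(
            template_bundle, _identity_transform(template_bundle.nm_crop))
        for key in ident.keys():
            a = ident.get(*key)[0].vertices
            b = mapped.get(*key)[0].vertices
            shift = b - a
            zf = template_bundle.zoom_factor
            assert np.allclose(shift[:, 0], 2 * zf, atol=1e-6)
            assert np.allclose(shift[:, 1], 0, atol=1e-6)


class TestTemplateBuild:
    def test_identical_subjects_average_to_subject(self, backend):
        ph = make_midbrain_phantom(seed=2, warped=False)
        subjects = [(ph.nm, ph.chi)] * 3
        bundle = build_template(subjects, ph.truth, backend,
                                config=TemplateBuildConfig(
                                    finalize_with_dpa=False))
        ref = crop_volume(ph.nm, CropWindow(20, 36, 29)).data
        rms = np.sqrt(np.mean((bundle.nm_crop.data - ref) ** 2))
        assert rms < 0.01 * np.abs(ref).mean()
        assert bundle.n_subjects_averaged == 3

    def test_single_subject_warns(self, backend, caplog):
        import logging
        ph = make_midbrain_phantom(seed=2, warped=False)
        with caplog.at_level(logging.WARNING):
            bundle = build_template([(ph.nm, ph.chi)], ph.truth, backend,
                                    config=TemplateBuildConfig(
                                        finalize_with_dpa=False))
        assert bundle.n_subjects_averaged == 1
        assert any("single subject" in r.message for r in caplog.records)

    def test_bundle_save_load_roundtrip(self, template_bundle, tmp_path):
        template_bundle.save(tmp_path / "bundle")
        back = TemplateBundle.load(tmp_path / "bundle")
        assert back.crop_start_ref == template_bundle.crop_start_ref
        assert back.nm_slice_window == tuple(template_bundle.nm_slice_window)
        assert len(back.boundaries) == len(template_bundle.boundaries)
        np.testing.assert_allclose(back.nm_crop.data,
                                   template_bundle.nm_crop.data, atol=1e-4)
        assert back.ref_rn_mask.sum() == template_bundle.ref_rn_mask.sum()


class TestPipelineProperties:
    def test_structure_exclusivity(self, cohort_results):
        """Final SN/RN/STN masks are pairwise disjoint on every slice."""
        for sub, res, _ in cohort_results:
            shape = sub.nm.shape
            sn = res.structures.combined_mask("SN", shape)
            rn = res.structures.combined_mask("RN", shape)
            stn = res.structures.combined_mask("STN", shape)
            assert not (sn & rn).any()
            assert not (sn & stn).any()
            assert not (rn & stn).any()

    def test_dual_mapping_beats_global_only(self, template_bundle,
                                            cohort_results):
        """The local deformation improves the mapped boundaries over
        global mapping + crop alone (paired sign test)."""
        from scipy.stats import binomtest
        from midseg.core_io import unzoom_points
        zf = template_bundle.zoom_factor
        wins = 0
        n = 0
        for sub, res, _ in cohort_results:
            if res.mapped is None:
                continue
            truth_crop = {}
            for lab in ("SN", "RN", "STN", "NM"):
                m = sub.truth.combined_mask(lab, sub.nm.shape)
                truth_crop[lab] = m[:, :, res.crop.start:res.crop.stop]
            shape2d = sub.nm.shape[:2]

            def mean_dice(structset, zoomed):
                ds = []
                for lab in ("SN", "RN", "STN", "NM"):
                    got = np.zeros(truth_crop[lab].shape, bool)
                    for hemi in ("L", "R"):
                        for c in structset.get(lab, hemi):
                            v = unzoom_points(c.vertices, zf) if zoomed \
                                else c.vertices
                            got[:, :, c.slice_index] |= contour_to_mask(
                                Contour(c.slice_index, v), shape2d)
                    if got.any() or truth_crop[lab].any():
                        ds.append(dice(got, truth_crop[lab]))
                return np.mean(ds)

            global_only = map_boundaries_to_subject(
                template_bundle,
                _identity_transform(template_bundle.nm_crop))
            d_global = mean_dice(global_only, zoomed=True)
            d_local = mean_dice(res.mapped, zoomed=True)
            n += 1
            wins += d_local > d_global
        assert binomtest(wins, n, 0.5, alternative="greater").pvalue < 0.05

    def test_refinement_translation_equivariance_exact(self):
        """The DPA refinement itself is exactly equivariant under
        whole-pixel translations of image and starting contour."""
        from midseg.boundary_dpa import DPAConfig, dpa_refine
        from midseg.phantoms import (PhantomSpec, enclosing_initial_contour,
                                     make_shape_phantom)
        spec = PhantomSpec(cnr=7, seed=4)
        img, _, _ = make_shape_phantom(spec)
        init = enclosing_initial_contour(spec, seed=11)
        out_a = dpa_refine(img, init, DPAConfig(adaptive_otsu=True))
        dx, dy = 3, 2
        big = np.full((img.shape[0] + 6, img.shape[1] + 6), img.min())
        big[:img.shape[0], :img.shape[1]] = img
        shifted = np.roll(big, (dx, dy), axis=(0, 1))
        out_b = dpa_refine(shifted, init.translated(dx, dy),
                           DPAConfig(adaptive_otsu=True))
        a = contour_to_mask(out_a, img.shape)
        b = contour_to_mask(out_b.translated(-dx, -dy), img.shape)
        np.testing.assert_array_equal(a, b)

    def test_whole_voxel_translation_near_equivariance(self, template_bundle,
                                                       backend):
        """Translating the subject by whole voxels translates the full
        pipeline output up to the (approximately covariant) registration."""
        sub = make_midbrain_phantom(seed=52, warped=True)
        res_a = segment_subject(sub.nm, sub.chi, template_bundle, backend)
        dx, dy = 2, 1
        nm_t = sub.nm.copy(data=np.roll(sub.nm.data, (dx, dy), axis=(0, 1)))
        chi_t = sub.chi.copy(data=np.roll(sub.chi.data, (dx, dy), axis=(0, 1)))
        res_b = segment_subject(nm_t, chi_t, template_bundle, backend)
        ds = []
        for lab in ("SN", "RN", "STN", "NM"):
            a = res_a.structures.combined_mask(lab, sub.nm.shape)
            b = res_b.structures.combined_mask(lab, sub.nm.shape)
            if a.any() or b.any():
                ds.append(dice(np.roll(a, (dx, dy), axis=(0, 1)), b))
        assert np.mean(ds) >= 0.90

    def test_zero_chi_fails_qsm_structures_only(self, template_bundle,
                                                backend):
        sub = make_midbrain_phantom(seed=51, warped=True)
        zero_chi = sub.chi.copy(data=np.zeros_like(sub.chi.data))
        res = segment_subject(sub.nm, zero_chi, template_bundle, backend)
        assert res.structures.get("NM", "L") or res.structures.get("NM", "R")
        for lab in ("SN", "RN", "STN"):
            assert not res.structures.get(lab, "L")
            assert not res.structures.get(lab, "R")
        assert any(k[0] in ("SN", "RN", "STN") for k in res.errors)
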