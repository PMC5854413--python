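import numpy as np
import pytest

from datquant.register import (
    AffineParams,
    DCTWarpField,
    NormalizationParams,
    RegistrationConfig,
    coregister_rigid,
    decompose_matrix_error,
    estimate_affine,
    estimate_nonlinear,
    normalise_estimate,
    normalise_write,
)
from datquant.synth import SubjectSpec, aligned_subject, make_synthetic_subject
from datquant.volume import VolumeImage, default_grid, resample_trilinear

FAST = RegistrationConfig(working_voxel_mm=6.0, n_iter_nonlinear=4)


@pytest.fixture(scope="module")
def template(grid2):
    """Aligned, noiseless healthy-subject tracer volume used as target."""
    spect, _, _ = aligned_subject(SubjectSpec(noise="none"), grid2)
    return spect


class TestAffineParams:
    def test_identity_params_give_identity_matrix(self):
        np.testing.assert_allclose(AffineParams().to_matrix(), np.eye(4), atol=1e-15)

    def test_translation_sits_in_last_column(self):
        M = AffineParams(tx=3, ty=-2, tz=7).to_matrix()
        np.testing.assert_allclose(M[:3, 3], [3, -2, 7])
        np.testing.assert_allclose(M[:3, :3], np.eye(3))

    def test_nonpositive_zoom_rejected(self):
        with pytest.raises(ValueError):
            AffineParams(zx=0.0)

    def test_vector_roundtrip(self):
        p = AffineParams(tx=1, rx=0.1, zy=1.05, sxy=0.02)
        assert AffineParams.from_vector(p.to_vector()).to_dict() == p.to_dict()


class TestEstimateAffine:
    def test_identity_when_source_equals_template(self, template):
        p, s, info = estimate_affine(template, template)
        assert abs(p.tx) <= 0.5 and abs(p.ty) <= 0.5 and abs(p.tz) <= 0.5
        assert max(abs(p.rx), abs(p.ry), abs(p.rz)) <= 0.005
        assert max(abs(p.zx - 1), abs(p.zy - 1), abs(p.zz - 1)) <= 0.005
        assert s == pytest.approx(1.0, abs=0.01)

    def test_pure_translation_recovery(self, grid2, template):
        shift = AffineParams(tx=6, ty=-4, tz=2)
        moved = resample_trilinear(template, grid2, shift.to_matrix())
        p, _, _ = estimate_affine(moved, template)
        # moved(x) = template(shift(x)) so the estimate must invert the shift
        err = decompose_matrix_error(shift.to_matrix() @ p.to_matrix())
        assert err["translation_mm"] <= 1.0

    def test_isotropic_zoom_recovery(self, grid2, template):
        zoom = AffineParams(zx=1.04, zy=1.04, zz=1.04)
        moved = resample_trilinear(template, grid2, zoom.to_matrix())
        p, _, _ = estimate_affine(moved, template)
        err = decompose_matrix_error(zoom.to_matrix() @ p.to_matrix())
        assert err["zoom_error"] <= 0.01

    def test_objective_trace_monotone_nonincreasing(self, grid2, template):
        mis = AffineParams(tx=5, ty=3, tz=-4, rx=0.06, rz=-0.04)
        moved = resample_trilinear(template, grid2, mis.to_matrix())
        _, _, info = estimate_affine(moved, template)
        for trace in info["traces"]:
            assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_constant_image_rejected(self, grid4):
        flat = VolumeImage(np.ones(grid4.dims), grid4.affine)
        with pytest.raises(ValueError, match="constant"):
            estimate_affine(flat, flat)


class TestEstimateNonlinear:
    def test_identity_source_yields_negligible_coefficients(self, template):
        warp, _ = estimate_nonlinear(template, template, AffineParams(), config=FAST)
        assert np.abs(warp.coefficients).max() <= 1e-3

    def test_infinite_regularization_is_pure_affine_limit(self, grid2, template):
        mis = AffineParams(tx=4.0)
        moved = resample_trilinear(template, grid2, mis.to_matrix())
        warp, _ = estimate_nonlinear(moved, template, mis, regularization=1e12, config=FAST)
        assert np.abs(warp.coefficients).max() <= 1e-6

    def test_zero_iterations_returns_zero_warp(self, template):
        warp, _ = estimate_nonlinear(template, template, AffineParams(), n_iter=0)
        assert not warp.coefficients.any()

    def test_low_frequency_warp_recovery(self, grid2, template):
        true = DCTWarpField(bbox_min=grid2.bbox_min, bbox_max=grid2.bbox_max)
        coef = np.zeros_like(true.coefficients)
        coef[:, :3, :3, :3] = np.random.default_rng(0).normal(0, 2.0, (3, 3, 3, 3))
        true.coefficients = coef
        warped = resample_trilinear(template, grid2, lambda x: x + true.displacement(x))
        _, info = estimate_nonlinear(warped, template, AffineParams())
        trace = info["trace"]
        assert trace[-1] <= 0.20 * trace[0]
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_basis_order_is_7x9x7_on_standard_box(self, grid2):
        warp = DCTWarpField(bbox_min=grid2.bbox_min, bbox_max=grid2.bbox_max, cutoff_mm=25.0)
        assert warp.orders == (7, 9, 7)

    def test_zero_coefficients_are_identity_displacement(self, grid2):
        warp = DCTWarpField(bbox_min=grid2.bbox_min, bbox_max=grid2.bbox_max)
        pts = np.array([[0.0, 0.0, 0.0], [10.0, -30.0, 40.0]])
        np.testing.assert_array_equal(warp.displacement(pts), 0.0)


class TestNormaliseEstimateWrite:
    def test_identity_case_and_serialization_roundtrip(self, grid2, template, tmp_path):
        params = normalise_estimate(template, template, FAST)
        out = normalise_write(template, params, grid2)
        assert out.shape == (91, 109, 91)
        np.testing.assert_allclose(out.data, template.data, atol=1e-6 * template.data.max())

        path = tmp_path / "params_sn.json"
        params.save(path)
        loaded = NormalizationParams.load(path)
        out2 = normalise_write(template, loaded, grid2)
        np.testing.assert_allclose(out2.data, out.data, atol=1e-6)

    def test_uniform_image_stays_uniform_under_warp(self, grid2):
        # no Jacobian modulation: intensities must not change with local volume
        warp = DCTWarpField(bbox_min=grid2.bbox_min, bbox_max=grid2.bbox_max)
        coef = np.zeros_like(warp.coefficients)
        coef[:, :2, :2, :2] = 2.0  # up to 16 mm of smooth displacement
        warp.coefficients = coef
        params = NormalizationParams(affine=AffineParams(), warp=warp)
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = (-130.0, -150.0, -130.0)
        big = VolumeImage(np.full((131, 151, 131), 2.5), aff)
        out = normalise_write(big, params, default_grid(2.0))
        np.testing.assert_allclose(out.data, 2.5, rtol=1e-9)

    def test_normalization_improves_striatal_overlap(self, grid2, template):
        from datquant.quantify import dice_coefficient
        from datquant.synth import make_label_atlas
        atlas = make_label_atlas(grid2)
        spec = SubjectSpec(seed=31, noise="none",
                           misalignment=AffineParams(tx=8, ty=-6, tz=4, rx=0.07, rz=-0.05),
                           spect_t1_offset=AffineParams())
        spect, _, truth, gt = make_synthetic_subject(spec, grid2)
        params = normalise_estimate(spect, template, FAST)
        mask_acq = resample_trilinear(
            VolumeImage(truth.mask("striatum").astype(float), grid2.affine),
            grid2, gt.misalignment).data > 0.5
        mask_img = VolumeImage(mask_acq.astype(float), grid2.affine)
        before = dice_coefficient(mask_acq, atlas.mask("striatum"))
        warped = normalise_write(mask_img, params, grid2).data > 0.5
        after = dice_coefficient(warped, atlas.mask("striatum"))
        assert after > before


class TestCoregisterRigid:
    def test_identity_for_equal_images(self, template):
        p = coregister_rigid(template, template, metric="msd")
        err = decompose_matrix_error(p.to_matrix())
        assert err["translation_mm"] <= 0.5
        assert err["rotation_rad"] <= 0.005

    def test_known_offset_recovery_nmi(self, grid2):
        spec = SubjectSpec(seed=11, noise="none",
                           misalignment=AffineParams(tx=4, ty=-6, tz=3, rx=0.04, rz=0.05),
                           spect_t1_offset=AffineParams(tx=3, ty=-2, tz=1.5, rx=0.03, rz=-0.02))
        spect, t1, _, gt = make_synthetic_subject(spec, grid2)
        q = coregister_rigid(spect, t1)
        err = decompose_matrix_error(gt.spect_offset @ q.to_matrix())
        assert err["translation_mm"] <= 1.0
        assert err["rotation_rad"] <= 0.01
        assert err["zoom_error"] <= 1e-12  # rigid: zooms frozen at 1

    def test_nmi_at_solution_not_worse_than_identity(self, grid2):
        from datquant.register import _nmi, _SampledSource, working_grid_for
        from datquant.volume import gaussian_smooth, world_grid
        spec = SubjectSpec(seed=12, noise="none",
                           spect_t1_offset=AffineParams(tx=2.5, ty=1.0, tz=-2.0, rz=0.03))
        spect, t1, _, _ = make_synthetic_subject(spec, grid2)
        q = coregister_rigid(spect, t1)
        wgrid = working_grid_for(t1, 4.0)
        ref = resample_trilinear(gaussian_smooth(t1, 4.0), wgrid).data.ravel()
        src = _SampledSource(spect, 4.0)
        xh = world_grid(wgrid)

        def nmi_at(p):
            M = p.to_matrix()
            return _nmi(ref, src.values(xh @ M[:3, :3].T + M[:3, 3]), 64)

        assert nmi_at(q) >= nmi_at(AffineParams()) - 1e-9

    def test_constant_image_rejected(self, grid4):
        flat = VolumeImage(np.zeros(grid4.dims), grid4.affine)
        with pytest.raises(ValueError, match="constant"):
            coregister_rigid(flat, flat)
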