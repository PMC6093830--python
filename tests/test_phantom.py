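"""Input functions, phantom geometry, rendering and cohort generation."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from taupvc import (
    InputFunctionParams,
    KineticParams,
    PhantomSpec,
    PlasmaInput,
    RegionGeometry,
    build_geometry,
    compute_vt,
    feng_input,
    generate_cohort,
    render_dynamic_phantom,
    simulate_region_tac,
)
from taupvc.exceptions import GeometryError, ParameterError
from taupvc.phantom import (
    CohortSpec,
    apply_metabolite_correction,
    default_param_distributions,
    draw_subject_params,
    parent_fraction,
    _face_adjacent,
)


class TestFengInput:
    def test_zero_at_delay_boundary(self):
        p = InputFunctionParams()
        assert feng_input(p, np.array([0.0, p.t0])).tolist() == [0.0, 0.0]

    def test_zero_coefficients_give_zero_curve(self):
        p = InputFunctionParams(A1=0.0, A2=0.0, A3=0.0)
        t = np.linspace(0, 100, 500)
        assert np.allclose(feng_input(p, t), 0.0)

    def test_peak_matches_dense_grid_maximisation(self):
        """Peak location/value agree with brute-force evaluation on a 1 ms grid."""
        p = InputFunctionParams()
        t = np.arange(p.t0, p.t0 + 5.0, 0.001 / 60.0)  # 1 ms steps
        dense = (
            (p.A1 * (t - p.t0) - p.A2 - p.A3) * np.exp(-p.l1 * (t - p.t0))
            + p.A2 * np.exp(-p.l2 * (t - p.t0))
            + p.A3 * np.exp(-p.l3 * (t - p.t0))
        )
        i = int(np.argmax(dense))
        curve = feng_input(p, t)
        j = int(np.argmax(curve))
        assert abs(t[i] - t[j]) < 1e-3  # within a millisecond-scale bin
        assert curve[j] == pytest.approx(dense[i], rel=1e-9)

    def test_eigenvalue_ordering_enforced(self):
        with pytest.raises(ParameterError):
            InputFunctionParams(l1=0.1, l2=0.12, l3=0.0104)

    def test_nonnegative_and_integrable(self):
        p = InputFunctionParams()
        t = np.linspace(0, 130, 10000)
        c = feng_input(p, t)
        assert (c >= 0).all()
        assert np.trapezoid(c, t) > 0


class TestMetaboliteCorrection:
    def test_unit_fraction_is_identity(self):
        p = InputFunctionParams(hill_a=0.0)
        t = np.linspace(0, 100, 300)
        c = feng_input(p, t)
        assert np.array_equal(apply_metabolite_correction(c, p, t), c)

    def test_asymptote(self):
        p = InputFunctionParams()
        assert parent_fraction(p, np.array([1e12]))[0] == pytest.approx(
            p.parent_fraction_asymptote, rel=1e-6
        )

    def test_hill_formula_at_30_min(self):
        p = InputFunctionParams()
        tb = 30.0**p.hill_b
        expected = 1.0 - p.hill_a * tb / (tb + p.hill_c)
        assert parent_fraction(p, np.array([30.0]))[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_non_increasing_from_one(self):
        p = InputFunctionParams()
        t = np.linspace(0, 130, 1000)
        f = parent_fraction(p, t)
        assert f[0] == 1.0
        assert (np.diff(f) <= 1e-15).all()


class TestGeometry:
    def test_labels_match_brute_force_membership(self):
        """Every label agrees with an explicit membership test per voxel."""
        spec = PhantomSpec(
            grid_shape=(24, 24, 24),
            geometry=RegionGeometry(hippo_semiaxes_mm=(8.0, 6.0, 5.0)),
            psf_fwhm_mm=0.0,
            noise_scale=0.0,
        )
        labels = build_geometry(spec)
        g = spec.geometry
        n = spec.grid_shape[0]
        coords = (np.arange(n) - (n - 1) / 2.0) * spec.voxel_size_mm[0]
        pts = np.array([(x, y, z) for x in coords for y in coords for z in coords])
        a, b, c = g.hippo_semiaxes_mm
        ell = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
        hippo = ell <= 1.0
        dmin = cdist(pts, pts[hippo]).min(axis=1)
        r = np.linalg.norm(pts, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = np.where(r > 0, pts[:, 1] / np.where(r > 0, r, 1.0), 0.0)
        cp = (~hippo) & (dmin > 0) & (dmin <= g.cp_thickness_mm + 1e-9) & (cosang >= g.cp_cap_cos)
        brute = np.zeros(len(pts), dtype=int)
        brute[hippo] = 1
        brute[cp] = 2
        assert np.array_equal(labels.ravel(), brute)

    def test_region_sizes_and_adjacency(self):
        labels = build_geometry(PhantomSpec())
        hippo, cp = labels == 1, labels == 2
        assert 0 < cp.sum() < hippo.sum()
        assert _face_adjacent(hippo, cp)
        assert not (hippo & cp).any()

    def test_far_masks_are_not_adjacent(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[1, 1, 1] = True
        b[8, 8, 8] = True
        assert not _face_adjacent(a, b)

    def test_zero_extent_cp_raises(self):
        spec = PhantomSpec(geometry=RegionGeometry(cp_thickness_mm=0.5))  # < voxel pitch
        with pytest.raises(GeometryError):
            build_geometry(spec)

    def test_out_of_bounds_hippocampus_raises(self):
        spec = PhantomSpec(
            grid_shape=(16, 16, 16),
            geometry=RegionGeometry(hippo_semiaxes_mm=(20.0, 8.0, 6.0)),
        )
        with pytest.raises(GeometryError):
            build_geometry(spec)


class TestSimulateRegionTac:
    def test_zero_input_zero_vb(self, frames):
        t = np.linspace(0, 130, 100)
        plasma = PlasmaInput(times=t, parent_plasma=np.zeros_like(t), whole_blood=np.zeros_like(t))
        p = KineticParams(K1=0.2, k2=0.1, VB=0.0)
        assert np.allclose(simulate_region_tac(p, plasma, frames), 0.0)

    def test_vb_to_one_limit_is_whole_blood(self, plasma, frames):
        """As VB -> 1 the TAC approaches the frame-averaged whole-blood curve."""
        from taupvc.kinetics import frame_average

        p = KineticParams(K1=1e-4, k2=1e-4, VB=1 - 1e-9)
        tac = simulate_region_tac(p, plasma, frames)
        wb = frame_average(plasma.times, plasma.whole_blood, frames)
        assert np.allclose(tac, wb, rtol=1e-4)


class TestRenderPhantom:
    def test_delta_psf_no_noise_voxels_equal_region_tacs(
        self, small_spec, plasma, mean_region_params
    ):
        img, truth = render_dynamic_phantom(small_spec, mean_region_params, plasma)
        for name, lab in [("background", 0), ("hippocampus", 1), ("choroid_plexus", 2)]:
            vox = img.voxel_data[truth.labels == lab, :]
            assert np.array_equal(vox, np.broadcast_to(truth.region_tacs[name], vox.shape))

    def test_same_seed_is_bit_identical(self, small_spec, plasma, mean_region_params):
        from dataclasses import replace

        spec = replace(small_spec, noise_scale=2.0, psf_fwhm_mm=6.0, seed=123)
        img1, _ = render_dynamic_phantom(spec, mean_region_params, plasma)
        img2, _ = render_dynamic_phantom(spec, mean_region_params, plasma)
        assert np.array_equal(img1.voxel_data, img2.voxel_data)

    def test_blur_conserves_total_activity(self, small_spec, plasma, mean_region_params):
        from dataclasses import replace

        spec = replace(small_spec, psf_fwhm_mm=6.0)
        img0, _ = render_dynamic_phantom(small_spec, mean_region_params, plasma)
        img1, _ = render_dynamic_phantom(spec, mean_region_params, plasma)
        tot0 = img0.voxel_data.sum(axis=(0, 1, 2))
        tot1 = img1.voxel_data.sum(axis=(0, 1, 2))
        sel = tot0 > 0
        assert np.all(np.abs(tot1[sel] - tot0[sel]) / tot0[sel] < 1e-3)

    def test_spill_in_matches_fine_grid_convolution_oracle(self, default_subject):
        """Blurred hippocampal mean: exceeds truth at late frames (the CP is
        hotter) and agrees with a 4x-resolution Gaussian convolution of the
        same piecewise-constant activity within 1%."""
        img, _, truth = default_subject
        spec_shape = truth.labels.shape
        hippo = truth.labels == 1
        f = img.n_frames - 1  # last frame: CP activity is far above hippocampus
        measured = img.voxel_data[..., f][hippo].mean()
        assert measured > truth.region_tacs["hippocampus"][f]

        # oracle: nearest-neighbour upsample x4, blur at fine pitch, block-average
        vals = np.zeros(3)
        for name, lab in [("background", 0), ("hippocampus", 1), ("choroid_plexus", 2)]:
            vals[lab] = truth.region_tacs[name][f]
        frame = vals[truth.labels]
        up = frame.repeat(4, axis=0).repeat(4, axis=1).repeat(4, axis=2)
        sigma_fine = (6.0 / 2.3548200450309493) / (np.asarray(img.voxel_size) / 4.0)
        up = ndimage.gaussian_filter(up, sigma_fine, mode="reflect")
        down = up.reshape(
            spec_shape[0], 4, spec_shape[1], 4, spec_shape[2], 4
        ).mean(axis=(1, 3, 5))
        oracle = down[hippo].mean()
        assert measured == pytest.approx(oracle, rel=0.01)

    def test_missing_region_params_raise(self, small_spec, plasma, mean_region_params):
        from taupvc.exceptions import ConfigurationError

        incomplete = {k: v for k, v in mean_region_params.items() if k != "choroid_plexus"}
        with pytest.raises(ConfigurationError):
            render_dynamic_phantom(small_spec, incomplete, plasma)


class TestCohort:
    def test_vt_ratio_matches_target_monte_carlo(self):
        """At n=1000 draws the empirical CP/hippo mean V_T ratio is within
        15% of the configured target."""
        dists = default_param_distributions(3.5)
        rng = np.random.default_rng(2024)
        h, c = [], []
        for _ in range(1000):
            params = draw_subject_params(dists, rng)
            h.append(compute_vt(params["hippocampus"]))
            c.append(compute_vt(params["choroid_plexus"]))
        ratio = np.mean(c) / np.mean(h)
        assert ratio == pytest.approx(3.5, rel=0.15)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(n_subjects=2)

    def test_negative_sd_rejected(self):
        from taupvc.phantom import TruncNormal

        with pytest.raises(ParameterError):
            TruncNormal(0.1, -0.01)

    def test_different_seeds_differ_and_same_seed_identical(self, small_spec):
        c1 = generate_cohort(CohortSpec(n_subjects=3, seed=1), small_spec, render=False)
        c2 = generate_cohort(CohortSpec(n_subjects=3, seed=2), small_spec, render=False)
        c3 = generate_cohort(CohortSpec(n_subjects=3, seed=1), small_spec, render=False)
        k1_1 = [s.true_params["hippocampus"].K1 for s in c1]
        assert k1_1 != [s.true_params["hippocampus"].K1 for s in c2]
        assert k1_1 == [s.true_params["hippocampus"].K1 for s in c3]

    def test_rendered_cohort_deterministic(self, small_spec):
        spec_cohort = CohortSpec(n_subjects=3, seed=5)
        a = generate_cohort(spec_cohort, small_spec)
        b = generate_cohort(spec_cohort, small_spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image.voxel_data, sb.image.voxel_data)
            assert sa.group == sb.group

    def test_true_vts_are_independent_draws(self):
        """Sample correlation of true hippocampal and CP V_T is chance-level
        at n=400 (|r| well below 0.15)."""
        subs = generate_cohort(
            CohortSpec(n_subjects=400, seed=9), PhantomSpec(), render=False
        )
        h = [compute_vt(s.true_params["hippocampus"]) for s in subs]
        c = [compute_vt(s.true_params["choroid_plexus"]) for s in subs]
        assert abs(np.corrcoef(h, c)[0, 1]) < 0.15
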