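"""Volume estimators: Teichholz, monoplane disks, slice summation, dispatch."""

import dataclasses

import numpy as np
import pytest

from lvquant import (
    GeometryError,
    PhantomParams,
    make_phantom,
    mmode_result,
    sample_cmr_stack,
    sample_long_axis,
    sample_mmode,
    sample_short_axis_stack,
    simpson_monoplane,
    slice_summation,
    teichholz_volume,
    volumetry_result,
)
from lvquant.emulate import ContourStack, MmodeTrace
CLOSED_FORM_R3_L6 = 2.0 / 3.0 * np.pi * 9.0 * 6.0  # semi-ellipsoid (2/3) pi R^2 L


class TestTeichholz:
    @pytest.mark.parametrize(
        "lvid, expected",
        [(0.0, 0.0), (4.0, 70.0), (2.4, 20.16)],
    )
    def test_hand_evaluated_values(self, lvid, expected):
        assert teichholz_volume(lvid) == pytest.approx(expected, rel=1e-12)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            teichholz_volume(-1.0)


class TestMmodeResult:
    def test_hand_evaluated_ef(self):
        r = mmode_result(MmodeTrace(lvid_d=4.0, lvid_s=2.4, slice_z=3.0, beam_azimuth=0.0))
        assert r.edv == pytest.approx(70.0)
        assert r.esv == pytest.approx(20.16)
        assert r.sv == pytest.approx(70.0 - 20.16)
        assert r.ef == pytest.approx(100 * (70.0 - 20.16) / 70.0, rel=1e-9)

    def test_no_contraction_zero_ef(self):
        r = mmode_result(MmodeTrace(lvid_d=4.0, lvid_s=4.0, slice_z=3.0, beam_azimuth=0.0))
        assert r.ef == 0.0

    def test_ef_strictly_decreasing_in_es_diameter(self):
        efs = [
            mmode_result(MmodeTrace(4.0, s, 3.0, 0.0)).ef for s in (1.0, 2.0, 3.0, 3.9)
        ]
        assert np.all(np.diff(efs) < 0)

    def test_zero_edv_reports_missing_ef(self):
        r = mmode_result(MmodeTrace(0.0, 0.0, 3.0, 0.0))
        assert np.isnan(r.ef)


class TestSimpsonMonoplane:
    def test_exact_for_solid_of_revolution(self, static_phantom):
        c = sample_long_axis(static_phantom, n_points=801)
        v = simpson_monoplane(c.points[0], n_disks=200)
        assert abs(v - CLOSED_FORM_R3_L6) / CLOSED_FORM_R3_L6 < 0.005

    def test_flat_contour_gives_zero(self):
        flat = np.column_stack([np.linspace(0, 6, 40), np.zeros(40)])
        assert simpson_monoplane(flat, n_disks=10) == 0.0

    def test_out_of_plane_akinesis_underestimates_es_volume(self):
        """A plane that misses the infarct sees only normal wall and
        under-reports the residual end-systolic volume."""
        from lvquant import InfarctSpec

        ph = make_phantom(
            PhantomParams(
                infarct=InfarctSpec(
                    apex_extent_fraction=0.7, angular_center=90.0,
                    angular_width=100.0, motion_class="akinetic",
                )
            )
        )
        c = sample_long_axis(ph, plane_azimuth=0.0)  # perpendicular to the sector
        es_est = simpson_monoplane(c.points[ph.es_phase], n_disks=200)
        es_truth = ph.truth_volumes().min()
        assert es_est < es_truth

    def test_too_few_disks_rejected(self, static_phantom):
        c = sample_long_axis(static_phantom)
        with pytest.raises(ValueError, match="n_disks"):
            simpson_monoplane(c.points[0], n_disks=2)


def _synthetic_stack(areas, thickness=1.0, n_vertices=64):
    """Stack of circular slices with the given areas (apex-to-base order)."""
    radii_1d = np.sqrt(np.asarray(areas) / np.pi)
    thetas = np.linspace(0, 360, n_vertices, endpoint=False)
    radii = radii_1d[:, None, None] * np.ones((1, 2, n_vertices))
    return ContourStack(
        slice_centers=np.arange(len(areas), dtype=float) * thickness + thickness / 2,
        thicknesses=np.full(len(areas), thickness),
        thetas=thetas,
        radii=radii,
    )


class TestSliceSummation:
    def test_three_unit_slices_arithmetic(self):
        # polygon areas approximate pi r^2 from below; compare to polygon area
        stack = _synthetic_stack([2.0, 2.0, 2.0], n_vertices=4096)
        assert slice_summation(stack, 0) == pytest.approx(6.0, rel=1e-5)

    def test_fine_stack_within_one_percent(self, static_phantom):
        stack = sample_short_axis_stack(static_phantom, step=0.2, start_z=0.1)
        v = slice_summation(stack, 0)
        assert abs(v - CLOSED_FORM_R3_L6) / CLOSED_FORM_R3_L6 < 0.01

    def test_cmr_stack_within_four_percent(self, static_phantom):
        stack = sample_cmr_stack(static_phantom)
        v = slice_summation(stack, 0)
        assert abs(v - CLOSED_FORM_R3_L6) / CLOSED_FORM_R3_L6 < 0.04

    def test_convergence_order_at_least_two(self, static_phantom):
        errs = []
        for h in (1.0, 0.5, 0.25):
            stack = sample_short_axis_stack(
                static_phantom, step=h, thickness=h, start_z=h / 2, n_vertices=2000
            )
            errs.append(abs(slice_summation(stack, 0) - CLOSED_FORM_R3_L6))
        assert errs[0] / errs[1] > 3.5
        assert errs[1] / errs[2] > 3.5

    def test_self_intersecting_polygon_names_the_slice(self):
        # vertices ordered as a pentagram (angularly unsorted, as a malformed
        # external contour file would produce) self-intersect
        thetas = np.array([0.0, 144.0, 288.0, 72.0, 216.0])
        radii = np.ones((1, 1, 5))
        stack = ContourStack(
            slice_centers=np.array([0.5]),
            thicknesses=np.array([1.0]),
            thetas=thetas,
            radii=radii,
        )
        with pytest.raises(GeometryError, match="slice 0"):
            slice_summation(stack, 0)

    def test_basal_truncation_underestimates(self, static_phantom):
        cut = sample_short_axis_stack(
            static_phantom, step=0.2, start_z=0.1, basal_truncation_z=0.8 * 6.0
        )
        assert slice_summation(cut, 0) < CLOSED_FORM_R3_L6


class TestVolumetryDispatch:
    def test_truth_modality_is_the_oracle(self, healthy_phantom):
        r = volumetry_result(healthy_phantom)
        v = healthy_phantom.truth_volumes()
        assert r.modality == "TRUTH"
        assert r.edv == pytest.approx(float(v.max()))
        assert r.esv == pytest.approx(float(v.min()))

    def test_zero_motion_phantom_reports_zero_ef_everywhere(self, static_phantom):
        results = [
            volumetry_result(static_phantom),
            volumetry_result(sample_cmr_stack(static_phantom)),
            volumetry_result(sample_short_axis_stack(static_phantom)),
            volumetry_result(sample_long_axis(static_phantom), n_disks=100),
            volumetry_result(sample_mmode(static_phantom)),
        ]
        for r in results:
            assert r.ef == pytest.approx(0.0, abs=1e-6)

    def test_similarity_motion_ef_exact_for_slice_and_disk_estimators(self, similarity_phantom):
        """Under an exact similarity contraction every geometric assumption
        holds, so the slice- and disk-based EFs equal the true EF."""
        truth = volumetry_result(similarity_phantom)
        for source, tol in (
            (sample_short_axis_stack(similarity_phantom), 1.0),
            (sample_cmr_stack(similarity_phantom), 2.0),
            (sample_long_axis(similarity_phantom), 1.0),
        ):
            r = volumetry_result(source, n_disks=200)
            assert r.ef == pytest.approx(truth.ef, abs=tol)

    def test_similarity_motion_teichholz_ef_residual_is_bounded(self, similarity_phantom):
        """Teichholz volume is nonlinear in diameter, so its EF differs from
        the true EF even under similarity motion -- but boundedly so."""
        truth = volumetry_result(similarity_phantom)
        r = volumetry_result(sample_mmode(similarity_phantom))
        residual = abs(r.ef - truth.ef)
        assert 0.5 < residual < 15.0

    def test_apical_akinesis_hurts_teichholz_more_than_slices(self, apical_akinetic_phantom):
        ph = apical_akinetic_phantom
        truth = volumetry_result(ph)
        t = volumetry_result(sample_mmode(ph, beam_azimuth=30.0))
        s = volumetry_result(sample_short_axis_stack(ph))
        assert abs(t.esv - truth.esv) > abs(s.esv - truth.esv)

    def test_ef_invariant_under_uniform_rescaling(self, healthy_phantom):
        scaled = make_phantom(
            dataclasses.replace(
                healthy_phantom.params,
                base_radius_ed=healthy_phantom.params.base_radius_ed * 1.5,
                long_axis_length_ed=healthy_phantom.params.long_axis_length_ed * 1.5,
                wall_thickness_ed=healthy_phantom.params.wall_thickness_ed * 1.5,
            )
        )
        for sampler in (
            lambda p: p,
            lambda p: sample_short_axis_stack(p, step=0.2 * (1.5 if p is scaled else 1.0)),
            lambda p: sample_long_axis(p),
        ):
            ef_a = volumetry_result(sampler(healthy_phantom), n_disks=100).ef
            ef_b = volumetry_result(sampler(scaled), n_disks=100).ef
            assert ef_b == pytest.approx(ef_a, abs=0.2)
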