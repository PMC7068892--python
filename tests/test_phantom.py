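"""Phantom geometry, ground-truth oracles, cohorts and rater noise."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvquant import (
    CohortSpec,
    ConfigurationError,
    InfarctSpec,
    ParameterError,
    PhantomParams,
    apply_rater_noise,
    generate_cohort,
    make_phantom,
    truth_volume,
)
CLOSED_FORM_R3_L6 = 2.0 / 3.0 * np.pi * 9.0 * 6.0  # semi-ellipsoid (2/3) pi R^2 L


class TestMakePhantom:
    def test_no_contraction_radii_identical_across_phases(self, static_phantom):
        theta = np.linspace(0, 360, 13)
        z = np.linspace(0.1, 5.9, 11)
        r0 = static_phantom.endo_radius(theta[:, None], z[None, :], 0)
        for p in range(1, static_phantom.n_phases):
            assert np.allclose(static_phantom.endo_radius(theta[:, None], z[None, :], p), r0)

    def test_closed_form_semi_ellipsoid_volume(self, static_phantom):
        v = truth_volume(static_phantom, 0)
        assert abs(v - CLOSED_FORM_R3_L6) / CLOSED_FORM_R3_L6 < 1e-6

    def test_globally_akinetic_heart_has_flat_volume_and_zero_ef(self):
        ph = make_phantom(
            PhantomParams(
                infarct=InfarctSpec(
                    apex_extent_fraction=1.0, angular_center=0.0,
                    angular_width=360.0, motion_class="akinetic",
                ),
                longitudinal_shortening=0.0,
            )
        )
        vols = ph.truth_volumes()
        assert np.allclose(vols, vols[0], rtol=1e-12)
        assert ph.truth_ef == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "field, value",
        [
            ("base_radius_ed", -1.0),
            ("long_axis_length_ed", 2.0),  # <= base radius
            ("wall_thickness_ed", 0.0),
            ("n_phases", 1),
            ("radial_contraction", 1.0),
            ("base_hyperkinesis_gain", 0.9),
        ],
    )
    def test_invalid_params_raise_naming_the_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            make_phantom(dataclasses.replace(PhantomParams(), **{field: value}))

    def test_invalid_infarct_spec_rejected(self):
        with pytest.raises(ParameterError, match="motion_class"):
            make_phantom(
                PhantomParams(
                    infarct=InfarctSpec(
                        apex_extent_fraction=0.5, angular_center=0,
                        angular_width=90, motion_class="hyperkinetic",
                    )
                )
            )


class TestTruthVolume:
    def test_volume_scales_quadratically_with_radius(self, static_phantom):
        k = 1.7
        scaled = make_phantom(
            dataclasses.replace(static_phantom.params, base_radius_ed=3.0 * k)
        )
        assert truth_volume(scaled, 0) == pytest.approx(k**2 * truth_volume(static_phantom, 0), rel=1e-9)

    def test_volume_non_increasing_from_ed_to_es(self, healthy_phantom):
        vols = healthy_phantom.truth_volumes()
        ed, es = healthy_phantom.ed_phase, healthy_phantom.es_phase
        assert ed < es
        segment = vols[ed : es + 1]
        assert np.all(np.diff(segment) <= 1e-9)
        assert vols.max() == vols[ed]

    def test_akinetic_sector_raises_es_volume(self, healthy_phantom, apical_akinetic_phantom):
        """Less contraction in the sector leaves more residual ES volume."""
        es_normal = healthy_phantom.truth_volumes().min()
        base = dataclasses.replace(
            apical_akinetic_phantom.params, base_hyperkinesis_gain=1.0
        )
        es_infarct = make_phantom(base).truth_volumes().min()
        assert es_infarct > es_normal


class TestScarFraction:
    def test_zero_iff_no_infarct(self, healthy_phantom, apical_akinetic_phantom):
        assert healthy_phantom.truth_scar_fraction == 0.0
        assert apical_akinetic_phantom.truth_scar_fraction > 0.0

    @pytest.mark.parametrize("attr, values", [
        ("angular_width", [60.0, 120.0, 200.0, 300.0]),
        ("apex_extent_fraction", [0.3, 0.5, 0.7, 0.9]),
    ])
    def test_strictly_increasing_in_sector_size(self, attr, values):
        base = InfarctSpec(apex_extent_fraction=0.6, angular_center=30.0,
                           angular_width=120.0, motion_class="akinetic")
        fracs = [
            make_phantom(
                PhantomParams(infarct=dataclasses.replace(base, **{attr: v}))
            ).truth_scar_fraction
            for v in values
        ]
        assert np.all(np.diff(fracs) > 0)


class TestCohort:
    def test_zero_subjects_rejected(self):
        with pytest.raises(ParameterError, match="n_subjects"):
            generate_cohort(CohortSpec(n_subjects=0))

    def test_unsupported_distribution_rejected(self):
        with pytest.raises(ConfigurationError, match="distribution"):
            generate_cohort(CohortSpec(scar_distribution="lognormal"))

    def test_scar_fractions_within_configured_range(self, default_cohort):
        fracs = np.array([p.truth_scar_fraction for p in default_cohort])
        assert len(default_cohort) == 32
        assert np.all(fracs >= 0.04 - 1e-6) and np.all(fracs <= 0.57 + 1e-6)
        # solved geometry reproduces the drawn targets
        assert np.all(fracs < 1.0)

    def test_same_seed_bit_identical_cohort(self):
        spec = CohortSpec(n_subjects=3, seed=11)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for pa, pb in zip(a, b):
            assert pa.params == pb.params
            assert pa.truth_scar_fraction == pb.truth_scar_fraction


class TestRaterNoise:
    def test_zero_noise_identity(self):
        v = np.array([10.0, 20.0, 30.0])
        r1, r2 = apply_rater_noise(v, bias=(0.0, 0.0), cv=0.0, seed=1)
        assert np.array_equal(r1, v) and np.array_equal(r2, v)

    def test_pure_bias_scales_one_rater(self):
        v = np.array([10.0, 20.0, 30.0])
        r1, r2 = apply_rater_noise(v, bias=(0.0, 0.1), cv=0.0, seed=1)
        assert np.array_equal(r1, v)
        assert np.allclose(r2, 1.1 * v)

    def test_deterministic_given_seed(self):
        v = np.linspace(40, 60, 8)
        a = apply_rater_noise(v, cv=0.05, seed=3)
        b = apply_rater_noise(v, cv=0.05, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_negative_cv_rejected(self):
        with pytest.raises(ParameterError):
            apply_rater_noise([1.0], cv=-0.1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    radius=st.floats(1.5, 4.0),
    length=st.floats(4.5, 9.0),
    s=st.floats(0.0, 0.5),
    ell=st.floats(0.0, 0.3),
    width=st.floats(30.0, 360.0),
    extent=st.floats(0.1, 1.0),
)
def test_surface_invariants_hold_for_random_phantoms(radius, length, s, ell, width, extent):
    """endo >= 0, epi > endo where the cavity exists, ED volume is the max."""
    params = PhantomParams(
        base_radius_ed=radius,
        long_axis_length_ed=max(length, radius + 1.0),
        radial_contraction=s,
        longitudinal_shortening=ell,
        n_phases=8,
        infarct=InfarctSpec(
            apex_extent_fraction=extent, angular_center=45.0,
            angular_width=width, motion_class="akinetic",
        ),
    )
    ph = make_phantom(params)
    theta = np.linspace(0, 360, 19)[:, None]
    for p in (0, ph.es_phase):
        z = np.linspace(0.01, ph.length(p) * 0.999, 17)[None, :]
        endo = ph.endo_radius(theta, z, p)
        epi = ph.epi_radius(theta, z, p)
        assert np.all(endo >= 0)
        assert np.all(epi > endo)
    vols = ph.truth_volumes()
    assert vols[ph.ed_phase] == vols.max()
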