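import numpy as np
import pytest

from lvquant import CohortSpec, InfarctSpec, PhantomParams, generate_cohort, make_phantom

CLOSED_FORM_R3_L6 = 2.0 / 3.0 * np.pi * 9.0 * 6.0  # semi-ellipsoid (2/3) pi R^2 L


@pytest.fixture(scope="session")
def static_phantom():
    """R = 3 mm, L = 6 mm, no motion: the closed-form reference geometry."""
    return make_phantom(
        PhantomParams(
            base_radius_ed=3.0,
            long_axis_length_ed=6.0,
            radial_contraction=0.0,
            longitudinal_shortening=0.0,
        )
    )


@pytest.fixture(scope="session")
def healthy_phantom():
    """Default mouse-scale morphology with uniform contraction."""
    return make_phantom(PhantomParams())


@pytest.fixture(scope="session")
def similarity_phantom():
    """Equal radial and longitudinal contraction: an exact similarity motion."""
    return make_phantom(
        PhantomParams(radial_contraction=0.1, longitudinal_shortening=0.1)
    )


@pytest.fixture(scope="session")
def apical_akinetic_phantom():
    """Anterolateral akinetic infarct reaching past the mid-papillary level."""
    return make_phantom(
        PhantomParams(
            infarct=InfarctSpec(
                apex_extent_fraction=0.65,
                angular_center=30.0,
                angular_width=150.0,
                motion_class="akinetic",
            ),
            base_hyperkinesis_gain=1.15,
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 32-subject infarct cohort (shared: expensive)."""
    return generate_cohort(CohortSpec(seed=7))
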