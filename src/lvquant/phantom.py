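"""Seeded 4D left-ventricle phantoms with analytic ground truth.

The cavity is modelled as a truncated semi-ellipsoid of revolution whose
endocardial radius is modulated in space (regional infarct dysfunction,
basal hyperkinesis) and time (raised-cosine contraction over one cardiac
cycle).  The phantom exposes exact/oracle quantities -- cavity volume by
fine quadrature, ejection fraction, and infarct ("scar") wall-volume
fraction -- against which every measurement-based estimator in this
package is judged.

Coordinate conventions
----------------------
Cylindrical coordinates ``(theta, z)`` about the long axis.  ``z = 0`` at
the apex, increasing toward the base; the cavity spans ``0 <= z <= L(p)``
where ``L(p)`` is the instantaneous apex-to-base length at phase ``p``.
``theta`` is in degrees with 0 = anterior, 90 = lateral, 180 = inferior,
270 = septal.  All lengths are mm, volumes uL (1 mm^3 = 1 uL), ejection
fraction and strain in percent.

The baseline (no-infarct) endocardium at phase ``p`` is::

    r(theta, z, p) = R(p) * sqrt(max(0, 1 - ((L(p) - z) / L(p))**2))

with ``R(p)`` and ``L(p)`` interpolating their end-diastolic values by the
radial-contraction and longitudinal-shortening fractions on a raised
cosine over the cycle.  End-diastole is the phase of maximum cavity
volume and end-systole the phase of minimum cavity volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "InfarctSpec",
    "PhantomParams",
    "Phantom",
    "CohortSpec",
    "make_phantom",
    "truth_volume",
    "generate_cohort",
    "apply_rater_noise",
    "MOTION_CLASSES",
]

MOTION_CLASSES = ("akinetic", "dyskinetic", "aneurysmal")

#: quadrature resolution for the volume/scar oracles
_N_GAUSS_Z = 96
_N_THETA = 720


class ParameterError(ValueError):
    """A phantom parameter violates its invariant (message names the field)."""


class ConfigurationError(ValueError):
    """An unsupported configuration choice (e.g. unknown distribution name)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InfarctSpec:
    """A contiguous dysfunctional sector of the ventricular wall.

    The region covers ``apex_extent_fraction`` of the long axis measured
    from the apex and ``angular_width`` degrees centred on
    ``angular_center``.  ``motion_class`` sets the local contraction:
    akinetic walls do not move, dyskinetic walls bulge outward at
    end-systole, aneurysmal walls carry a static outward bulge at every
    phase and do not contract.  Region edges are blended with a cosine
    taper over ``transition_width`` degrees so that emulated contours stay
    smooth.
    """

    apex_extent_fraction: float
    angular_center: float
    angular_width: float
    motion_class: str = "akinetic"
    transition_width: float = 15.0
    dyskinetic_fraction: float = 0.5   # |s_local| relative to normal s, sign < 0
    bulge_fraction: float = 0.15       # static outward bulge for aneurysms

    def validate(self) -> None:
        if not 0.0 < self.apex_extent_fraction <= 1.0:
            raise ParameterError(
                f"apex_extent_fraction must be in (0, 1], got {self.apex_extent_fraction}"
            )
        if not 0.0 < self.angular_width <= 360.0:
            raise ParameterError(
                f"angular_width must be in (0, 360], got {self.angular_width}"
            )
        if self.motion_class not in MOTION_CLASSES:
            raise ParameterError(
                f"motion_class must be one of {MOTION_CLASSES}, got {self.motion_class!r}"
            )
        if self.transition_width < 0:
            raise ParameterError(
                f"transition_width must be >= 0, got {self.transition_width}"
            )
        if self.dyskinetic_fraction <= 0:
            raise ParameterError(
                f"dyskinetic_fraction must be > 0, got {self.dyskinetic_fraction}"
            )
        if self.bulge_fraction < 0:
            raise ParameterError(
                f"bulge_fraction must be >= 0, got {self.bulge_fraction}"
            )


@dataclass(frozen=True)
class PhantomParams:
    """Morphology and kinetics of one phantom heart.

    Defaults are a post-infarction mouse left ventricle: equatorial
    endocardial radius 2.3 mm and apex-to-base length 6.2 mm give an
    end-diastolic cavity of ~69 uL, and 20 phases per cycle match a cine
    CMR acquisition.
    """

    base_radius_ed: float = 2.3
    long_axis_length_ed: float = 6.2
    wall_thickness_ed: float = 1.0
    n_phases: int = 20
    radial_contraction: float = 0.30
    longitudinal_shortening: float = 0.12
    infarct: InfarctSpec | None = None
    base_hyperkinesis_gain: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.base_radius_ed <= 0:
            raise ParameterError(f"base_radius_ed must be > 0, got {self.base_radius_ed}")
        if self.long_axis_length_ed <= self.base_radius_ed:
            raise ParameterError(
                "long_axis_length_ed must exceed base_radius_ed, got "
                f"{self.long_axis_length_ed} <= {self.base_radius_ed}"
            )
        if self.wall_thickness_ed <= 0:
            raise ParameterError(
                f"wall_thickness_ed must be > 0, got {self.wall_thickness_ed}"
            )
        if self.n_phases < 2:
            raise ParameterError(f"n_phases must be >= 2, got {self.n_phases}")
        if not 0.0 <= self.radial_contraction < 1.0:
            raise ParameterError(
                f"radial_contraction must be in [0, 1), got {self.radial_contraction}"
            )
        if not 0.0 <= self.longitudinal_shortening < 1.0:
            raise ParameterError(
                "longitudinal_shortening must be in [0, 1), got "
                f"{self.longitudinal_shortening}"
            )
        if self.base_hyperkinesis_gain < 1.0:
            raise ParameterError(
                f"base_hyperkinesis_gain must be >= 1, got {self.base_hyperkinesis_gain}"
            )
        if self.infarct is not None:
            self.infarct.validate()


# ---------------------------------------------------------------------------
# the phantom
# ---------------------------------------------------------------------------


def _raised_cosine(n_phases: int) -> np.ndarray:
    """Contraction fraction c(p) in [0, 1]; c=0 at phase 0, c=1 mid-cycle."""
    p = np.arange(n_phases)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * p / n_phases))


class Phantom:
    """Time-resolved parametric endocardial/epicardial surface.

    Use :func:`make_phantom` to construct one.  Radius methods broadcast
    over array-valued ``theta`` and ``z``; ``phase`` is a scalar index.
    """

    def __init__(self, params: PhantomParams):
        params.validate()
        self.params = params
        self._c = _raised_cosine(params.n_phases)
        self._volumes: np.ndarray | None = None
        self._scar_fraction: float | None = None
        # quadrature nodes (shared by volume and scar oracles)
        nodes, weights = leggauss(_N_GAUSS_Z)
        self._gl_zeta = 0.5 * (nodes + 1.0)           # map [-1,1] -> [0,1]
        self._gl_w = 0.5 * weights
        self._theta = np.linspace(0.0, 360.0, _N_THETA, endpoint=False)

    # -- kinematics ---------------------------------------------------------

    @property
    def n_phases(self) -> int:
        return self.params.n_phases

    def contraction(self, phase: int) -> float:
        """Raised-cosine contraction fraction at ``phase`` (0 at phase 0)."""
        return float(self._c[self._check_phase(phase)])

    def length(self, phase: int) -> float:
        """Instantaneous apex-to-base cavity length L(p) in mm."""
        p = self.params
        return p.long_axis_length_ed * (1.0 - p.longitudinal_shortening * self.contraction(phase))

    def _check_phase(self, phase: int) -> int:
        phase = int(phase)
        if not 0 <= phase < self.params.n_phases:
            raise IndexError(f"phase {phase} out of range [0, {self.params.n_phases})")
        return phase

    # -- infarct / contraction fields (normalized coordinates) --------------

    def infarct_weight(self, theta_deg, zeta) -> np.ndarray:
        """Blended membership weight of the infarct sector, in [0, 1].

        ``zeta = z / L(p)`` is the material long-axis coordinate.  The
        weight is 1 deep inside the sector, 0 outside, with cosine tapers
        of ``transition_width`` degrees at the angular edges and an
        equivalent normalized taper at the basal edge.
        """
        theta_deg = np.asarray(theta_deg, dtype=float)
        zeta = np.asarray(zeta, dtype=float)
        spec = self.params.infarct
        if spec is None:
            return np.zeros(np.broadcast(theta_deg, zeta).shape)

        # angular factor
        half = spec.angular_width / 2.0
        delta = np.abs((theta_deg - spec.angular_center + 180.0) % 360.0 - 180.0)
        t_ang = min(spec.transition_width, half) if spec.transition_width > 0 else 0.0
        if t_ang > 0:
            w_theta = np.where(
                delta <= half - t_ang,
                1.0,
                np.where(
                    delta >= half,
                    0.0,
                    0.5 * (1.0 + np.cos(np.pi * (delta - (half - t_ang)) / t_ang)),
                ),
            )
        else:
            w_theta = (delta < half).astype(float)
        if spec.angular_width >= 360.0:
            w_theta = np.ones_like(w_theta)

        # longitudinal factor: region runs from the apex (zeta=0) up to the
        # extent fraction, tapered on the inside of the basal edge
        a = spec.apex_extent_fraction
        t_z = min(spec.transition_width / 360.0, a) if spec.transition_width > 0 else 0.0
        if t_z > 0:
            w_z = np.where(
                zeta <= a - t_z,
                1.0,
                np.where(
                    zeta >= a,
                    0.0,
                    0.5 * (1.0 + np.cos(np.pi * (zeta - (a - t_z)) / t_z)),
                ),
            )
        else:
            w_z = (zeta < a).astype(float)
        if a >= 1.0:
            w_z = np.ones_like(w_z)
        return w_theta * w_z

    def _local_contraction(self, theta_deg, zeta) -> np.ndarray:
        """End-systolic radial contraction fraction s(theta, zeta)."""
        p = self.params
        zeta = np.asarray(zeta, dtype=float)
        # basal-hyperkinesis ramp over the basal third
        if p.base_hyperkinesis_gain > 1.0:
            tau = 0.05
            ramp = np.clip((zeta - (2.0 / 3.0 - tau)) / (2.0 * tau), 0.0, 1.0)
            ramp = 0.5 * (1.0 - np.cos(np.pi * ramp))
            s_normal = p.radial_contraction * (1.0 + (p.base_hyperkinesis_gain - 1.0) * ramp)
        else:
            s_normal = np.full_like(zeta, p.radial_contraction)
        spec = p.infarct
        if spec is None:
            return np.broadcast_to(s_normal, np.broadcast(np.asarray(theta_deg), zeta).shape).copy()
        if spec.motion_class == "akinetic":
            s_inf = 0.0
        elif spec.motion_class == "dyskinetic":
            s_inf = -spec.dyskinetic_fraction * p.radial_contraction
        else:  # aneurysmal: static, no contraction
            s_inf = 0.0
        w = self.infarct_weight(theta_deg, zeta)
        return (1.0 - w) * s_normal + w * s_inf

    # -- surfaces -----------------------------------------------------------

    def _ed_base_radius(self, theta_deg, zeta) -> np.ndarray:
        """End-diastolic endocardial radius at material coordinate zeta."""
        p = self.params
        zeta = np.asarray(zeta, dtype=float)
        shape = np.sqrt(np.clip(zeta * (2.0 - zeta), 0.0, None))
        r = p.base_radius_ed * shape
        spec = p.infarct
        if spec is not None and spec.motion_class == "aneurysmal" and spec.bulge_fraction > 0:
            r = r * (1.0 + spec.bulge_fraction * self.infarct_weight(theta_deg, zeta))
        return r * np.ones(np.broadcast(np.asarray(theta_deg), zeta).shape)

    def endo_radius(self, theta_deg, z_mm, phase: int) -> np.ndarray:
        """Endocardial radius (mm) at ``(theta, z)`` and cardiac ``phase``.

        Zero outside the instantaneous cavity extent ``[0, L(p)]``.
        """
        phase = self._check_phase(phase)
        theta_deg = np.asarray(theta_deg, dtype=float)
        z = np.asarray(z_mm, dtype=float)
        L = self.length(phase)
        zeta = z / L
        inside = (zeta >= 0.0) & (zeta <= 1.0)
        zeta_c = np.clip(zeta, 0.0, 1.0)
        r_ed = self._ed_base_radius(theta_deg, zeta_c)
        s = self._local_contraction(theta_deg, zeta_c)
        r = r_ed * (1.0 - s * self._c[phase])
        return np.where(inside, np.clip(r, 0.0, None), 0.0)

    def epi_radius(self, theta_deg, z_mm, phase: int) -> np.ndarray:
        """Epicardial radius (mm), from wall cross-section conservation.

        The squared-radius annulus ``epi^2 - endo^2`` at each material
        point is held at its end-diastolic value (incompressible wall per
        cross section), so the wall thickens as the cavity contracts.
        """
        phase = self._check_phase(phase)
        theta_deg = np.asarray(theta_deg, dtype=float)
        z = np.asarray(z_mm, dtype=float)
        L = self.length(phase)
        zeta = np.clip(z / L, 0.0, 1.0)
        r_ed = self._ed_base_radius(theta_deg, zeta)
        wt = self.params.wall_thickness_ed
        annulus = (r_ed + wt) ** 2 - r_ed**2
        endo = self.endo_radius(theta_deg, z_mm, phase)
        return np.sqrt(endo**2 + annulus)

    # -- ground-truth oracles -----------------------------------------------

    def truth_volume(self, phase: int) -> float:
        """Cavity volume (uL) at ``phase`` by Gauss-Legendre x trapezoid quadrature."""
        return float(self.truth_volumes()[self._check_phase(phase)])

    def truth_volumes(self) -> np.ndarray:
        """Cavity volume (uL) at every phase (cached)."""
        if self._volumes is None:
            vols = np.empty(self.params.n_phases)
            theta = self._theta[:, None]
            for p in range(self.params.n_phases):
                L = self.length(p)
                z = self._gl_zeta[None, :] * L
                r = self.endo_radius(theta, z, p)
                # V = int_0^L int_0^2pi r^2/2 dtheta dz
                integrand = 0.5 * r**2
                dtheta = 2.0 * np.pi / _N_THETA
                vols[p] = float(np.sum(integrand * self._gl_w[None, :]) * L * dtheta)
            self._volumes = vols
        return self._volumes

    @property
    def ed_phase(self) -> int:
        """Phase index of maximum cavity volume (end-diastole)."""
        return int(np.argmax(self.truth_volumes()))

    @property
    def es_phase(self) -> int:
        """Phase index of minimum cavity volume (end-systole)."""
        return int(np.argmin(self.truth_volumes()))

    @property
    def truth_ef(self) -> float:
        """Ground-truth ejection fraction in percent."""
        v = self.truth_volumes()
        edv, esv = float(v.max()), float(v.min())
        return 100.0 * (edv - esv) / edv if edv > 0 else float("nan")

    @property
    def truth_scar_fraction(self) -> float:
        """Wall-volume fraction inside the infarct sector at end-diastole.

        Computed as the infarct-weight-weighted share of the wall volume
        integral ``(epi^2 - endo^2)/2`` over ``(theta, z)`` at ED.
        """
        if self._scar_fraction is None:
            if self.params.infarct is None:
                self._scar_fraction = 0.0
            else:
                p_ed = self.ed_phase
                L = self.length(p_ed)
                theta = self._theta[:, None]
                zeta = self._gl_zeta[None, :]
                z = zeta * L
                endo = self.endo_radius(theta, z, p_ed)
                epi = self.epi_radius(theta, z, p_ed)
                dens = 0.5 * (epi**2 - endo**2)
                w = self.infarct_weight(theta, zeta)
                num = np.sum(w * dens * self._gl_w[None, :])
                den = np.sum(dens * self._gl_w[None, :])
                self._scar_fraction = float(num / den)
        return self._scar_fraction


def make_phantom(params: PhantomParams) -> Phantom:
    """Validate ``params`` and build the phantom."""
    return Phantom(params)


def truth_volume(phantom: Phantom, phase: int) -> float:
    """Ground-truth cavity volume (uL) at ``phase``; see :meth:`Phantom.truth_volume`."""
    return phantom.truth_volume(phase)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a seeded infarct cohort.

    Defaults emulate a surviving post-ligation mouse cohort: 32 subjects,
    histology-scale scar fractions drawn from a truncated normal with
    mean 21.5% and SD 16.3% clipped to [4%, 57%], anterolateral infarcts,
    mildly hyperkinetic base.  Per-subject morphology jitter is normal
    around the :class:`PhantomParams` defaults.
    """

    n_subjects: int = 32
    scar_distribution: str = "truncnorm"
    scar_mean: float = 0.215
    scar_sd: float = 0.163
    scar_range: tuple[float, float] = (0.04, 0.57)
    base_radius: tuple[float, float] = (2.3, 0.12)         # (mean, sd) mm
    long_axis_length: tuple[float, float] = (6.2, 0.25)    # mm
    wall_thickness: tuple[float, float] = (1.0, 0.05)      # mm
    radial_contraction: tuple[float, float] = (0.30, 0.02)
    longitudinal_shortening: tuple[float, float] = (0.12, 0.01)
    base_hyperkinesis_gain: float = 1.15
    angular_center: tuple[float, float] = (30.0, 20.0)     # deg, anterolateral
    # scar-fraction thresholds where wall-motion severity escalates:
    # akinetic below the first, dyskinetic between, aneurysmal above the second
    motion_class_thresholds: tuple[float, float] = (0.30, 0.45)
    n_phases: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.scar_distribution not in ("truncnorm", "uniform"):
            raise ConfigurationError(
                f"unsupported scar distribution {self.scar_distribution!r}; "
                "expected 'truncnorm' or 'uniform'"
            )
        lo, hi = self.scar_range
        if not 0.0 <= lo < hi < 1.0:
            raise ParameterError(f"scar_range must satisfy 0 <= lo < hi < 1, got {self.scar_range}")
        t_lo, t_hi = self.motion_class_thresholds
        if not 0.0 < t_lo < t_hi < 1.0:
            raise ParameterError(
                f"motion_class_thresholds must satisfy 0 < lo < hi < 1, got {self.motion_class_thresholds}"
            )


def _draw_scar_targets(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.scar_range
    if spec.scar_distribution == "uniform":
        return rng.uniform(lo, hi, size=spec.n_subjects)
    a = (lo - spec.scar_mean) / spec.scar_sd
    b = (hi - spec.scar_mean) / spec.scar_sd
    dist = stats.truncnorm(a, b, loc=spec.scar_mean, scale=spec.scar_sd)
    return dist.rvs(size=spec.n_subjects, random_state=rng)


def _solve_infarct_geometry(
    base: PhantomParams, target: float, extent: float, motion_class: str,
    angular_center: float,
) -> InfarctSpec:
    """Find the angular width (and if needed a larger apex extent) whose
    blended sector holds ``target`` of the end-diastolic wall volume."""

    def scar_at(width: float, ext: float) -> float:
        spec = InfarctSpec(
            apex_extent_fraction=ext,
            angular_center=angular_center,
            angular_width=width,
            motion_class=motion_class,
        )
        return Phantom(dataclasses.replace(base, infarct=spec)).truth_scar_fraction

    ext = extent
    f_full = scar_at(360.0, ext)
    if f_full < target:
        # widen the apex extent until a full-circumference sector suffices
        if scar_at(360.0, 1.0) <= target:
            ext = 1.0
        else:
            ext = optimize.brentq(lambda e: scar_at(360.0, e) - target, ext, 1.0, xtol=1e-3)
        width = 360.0
    else:
        width = optimize.brentq(lambda w: scar_at(w, ext) - target, 1.0, 360.0, xtol=1e-2)
    return InfarctSpec(
        apex_extent_fraction=float(ext),
        angular_center=float(angular_center),
        angular_width=float(width),
        motion_class=motion_class,
    )


def generate_cohort(spec: CohortSpec) -> list[Phantom]:
    """Generate a deterministic, seeded cohort of infarcted phantoms.

    Scar-fraction targets are drawn from the named distribution and the
    infarct sector geometry is solved (by bisection on the wall-volume
    oracle) so that each phantom's ``truth_scar_fraction`` matches its
    target.  The same seed yields a bit-identical cohort.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    targets = _draw_scar_targets(spec, rng)
    phantoms: list[Phantom] = []
    for i in range(spec.n_subjects):
        t = float(targets[i])
        params = PhantomParams(
            base_radius_ed=float(max(rng.normal(*spec.base_radius), 1.0)),
            long_axis_length_ed=float(max(rng.normal(*spec.long_axis_length), 4.0)),
            wall_thickness_ed=float(max(rng.normal(*spec.wall_thickness), 0.3)),
            n_phases=spec.n_phases,
            radial_contraction=float(np.clip(rng.normal(*spec.radial_contraction), 0.05, 0.6)),
            longitudinal_shortening=float(np.clip(rng.normal(*spec.longitudinal_shortening), 0.0, 0.4)),
            base_hyperkinesis_gain=spec.base_hyperkinesis_gain,
            seed=int(spec.seed * 1000 + i) % (2**31),
        )
        # Proximal-ligation infarcts run from the apex past the mid-papillary
        # level; larger scars reach further toward the base.
        extent = float(np.clip(0.55 + 0.45 * t + rng.normal(0.0, 0.04), 0.50, 0.98))
        # severity escalates with transmural extent: large chronic infarcts
        # thin, expand, and ultimately bulge
        t_lo, t_hi = spec.motion_class_thresholds
        motion_class = "akinetic" if t < t_lo else ("dyskinetic" if t < t_hi else "aneurysmal")
        center = float(rng.normal(*spec.angular_center))
        infarct = _solve_infarct_geometry(params, t, extent, motion_class, center)
        phantoms.append(Phantom(dataclasses.replace(params, infarct=infarct)))
    return phantoms


# ---------------------------------------------------------------------------
# two-rater measurement noise
# ---------------------------------------------------------------------------


def apply_rater_noise(
    values: Sequence[float],
    bias: tuple[float, float] = (0.0, 0.0),
    cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate two raters reading the same series of measurements.

    Rater ``r``'s reading of a value ``v`` is ``v * (1 + b_r + cv * eps)``
    with ``eps`` standard normal, independent per reading.  Returns the
    two parallel noisy series; deterministic given ``seed``.
    """
    if cv < 0:
        raise ParameterError(f"cv must be >= 0, got {cv}")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((2, values.size))
    out = [values * (1.0 + bias[r] + cv * eps[r]) for r in (0, 1)]
    return out[0], out[1]
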