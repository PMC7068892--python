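"""Sample a phantom the way each acquisition modality samples a heart.

Three acquisition geometries are emulated, each producing the measurement
primitive its estimator consumes:

* an M-mode line through a fixed short-axis level (two opposed radii
  along one beam azimuth) -> :class:`MmodeTrace`;
* a single long-axis imaging plane -> :class:`LongAxisContour`;
* a stack of short-axis planes (fine 0.2 mm steps for gated 4D
  ultrasound, 1 mm slices for cine CMR) -> :class:`ContourStack`.

Emulation is deterministic: boundary points are exact evaluations of the
phantom surface, with no speckle or tracing noise.  Gating is assumed
perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom

__all__ = [
    "SamplingError",
    "MmodeTrace",
    "LongAxisContour",
    "ContourStack",
    "sample_mmode",
    "sample_long_axis",
    "sample_short_axis_stack",
    "sample_cmr_stack",
]


class SamplingError(RuntimeError):
    """The requested acquisition geometry does not intersect the ventricle."""


# ---------------------------------------------------------------------------
# measurement primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MmodeTrace:
    """Internal diameters read off an M-mode line.

    ``lvid_d`` / ``lvid_s`` are the end-diastolic / end-systolic internal
    diameters (mm) along the beam; ``lvid_by_phase`` keeps the full
    diameter-vs-phase trace the extremes were read from.
    """

    lvid_d: float
    lvid_s: float
    slice_z: float
    beam_azimuth: float
    lvid_by_phase: np.ndarray | None = None


@dataclass(frozen=True)
class LongAxisContour:
    """Phase-indexed closed endocardial boundary in a long-axis plane.

    ``points[p]`` is an ``(n, 2)`` array of ``(x, y)`` vertices at phase
    ``p``: x runs along the long axis (x = 0 at the apex), y transverse
    (positive toward ``plane_azimuth``).  Vertices run from one basal
    corner through the apex to the other basal corner; the closing basal
    chord is implicit.  Vertices are material points under the phantom's
    motion (fixed fraction of the instantaneous long-axis length), which
    is what a speckle-tracked boundary provides.
    """

    points: tuple[np.ndarray, ...]
    plane_azimuth: float
    surface: str = "endo"

    @property
    def n_phases(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ContourStack:
    """Per-slice, per-phase closed endocardial polygons.

    The common currency of the slice-based estimators.  ``radii`` has
    shape ``(n_slices, n_phases, n_vertices)``; vertex ``j`` sits at
    ``thetas[j]`` degrees, so vertices share a theta parameterization
    across slices and phases.  ``slice_centers`` are distances from the
    apex (mm).  A slice whose center lies beyond the instantaneous cavity
    extent at some phase has all-zero radii there (an empty polygon, as a
    contoured frame shows once the base has descended past the slice).
    """

    slice_centers: np.ndarray
    thicknesses: np.ndarray
    thetas: np.ndarray
    radii: np.ndarray
    acquisition: str = "4D"
    epi_radii: np.ndarray | None = None

    def __post_init__(self):
        if self.radii.ndim != 3 or self.radii.shape[0] != self.slice_centers.size:
            raise ValueError("radii must have shape (n_slices, n_phases, n_vertices)")
        if np.any(np.diff(self.slice_centers) <= 0):
            raise ValueError("slice centers must be strictly increasing")
        if np.any(self.thicknesses <= 0):
            raise ValueError("slice thicknesses must be > 0")

    @property
    def n_slices(self) -> int:
        return int(self.slice_centers.size)

    @property
    def n_phases(self) -> int:
        return int(self.radii.shape[1])

    @property
    def n_vertices(self) -> int:
        return int(self.radii.shape[2])

    def vertices(self, slice_index: int, phase: int, surface: str = "endo") -> np.ndarray:
        """(n_vertices, 2) polygon vertices of one slice at one phase."""
        r = self._surface(surface)[slice_index, phase]
        t = np.deg2rad(self.thetas)
        return np.column_stack([r * np.cos(t), r * np.sin(t)])

    def _surface(self, surface: str) -> np.ndarray:
        if surface == "endo":
            return self.radii
        if surface == "epi":
            if self.epi_radii is None:
                raise ValueError("stack was sampled without the epicardial surface")
            return self.epi_radii
        raise ValueError(f"unknown surface {surface!r}")


# ---------------------------------------------------------------------------
# sampling operations
# ---------------------------------------------------------------------------


def sample_mmode(
    phantom: Phantom,
    slice_z: float | None = None,
    beam_azimuth: float = 0.0,
    phase_policy: str = "modality",
) -> MmodeTrace:
    """Read LV internal diameters along an M-mode beam.

    ``slice_z`` defaults to half the end-diastolic long-axis length (the
    mid-papillary level).  The internal diameter at each phase is the sum
    of the two opposed endocardial radii along the beam.  Under the
    default ``phase_policy="modality"`` the ED/ES diameters are the
    max/min of the trace, as an operator reads them; ``"truth"`` reads
    them at the phantom's true ED/ES phases.
    """
    if slice_z is None:
        slice_z = 0.5 * phantom.params.long_axis_length_ed
    lengths = [phantom.length(p) for p in range(phantom.n_phases)]
    if not 0.0 < slice_z < min(lengths):
        raise SamplingError(
            f"slice_z={slice_z} mm lies outside the ventricle at some phase "
            f"(instantaneous extent down to {min(lengths):.3f} mm)"
        )
    lvid = np.array(
        [
            float(
                phantom.endo_radius(beam_azimuth, slice_z, p)
                + phantom.endo_radius(beam_azimuth + 180.0, slice_z, p)
            )
            for p in range(phantom.n_phases)
        ]
    )
    if phase_policy == "truth":
        d, s = lvid[phantom.ed_phase], lvid[phantom.es_phase]
    elif phase_policy == "modality":
        d, s = float(lvid.max()), float(lvid.min())
    else:
        raise ValueError(f"unknown phase_policy {phase_policy!r}")
    return MmodeTrace(
        lvid_d=float(d), lvid_s=float(s), slice_z=float(slice_z),
        beam_azimuth=float(beam_azimuth), lvid_by_phase=lvid,
    )


def sample_long_axis(
    phantom: Phantom,
    plane_azimuth: float = 0.0,
    n_points: int = 201,
    surface: str = "endo",
) -> LongAxisContour:
    """Trace the boundary seen by a single long-axis imaging plane.

    The plane contains the long axis; its two half-planes sit at
    ``plane_azimuth`` and ``plane_azimuth + 180`` degrees.  Boundary
    points are radius evaluations on a uniform grid of the normalized
    long-axis coordinate, joined at the apex.
    """
    if n_points < 16:
        raise ValueError(f"n_points must be >= 16, got {n_points}")
    radius_fn = phantom.endo_radius if surface == "endo" else phantom.epi_radius
    if surface not in ("endo", "epi"):
        raise ValueError(f"unknown surface {surface!r}")
    m = n_points // 2
    zeta = np.linspace(0.0, 1.0, m + 1)
    contours = []
    for p in range(phantom.n_phases):
        L = phantom.length(p)
        z = zeta * L
        r_a = np.asarray(radius_fn(plane_azimuth, z, p))
        r_b = np.asarray(radius_fn(plane_azimuth + 180.0, z, p))
        # base (side A) -> apex -> base (side B); apex point shared
        xs = np.concatenate([z[::-1], z[1:]])
        ys = np.concatenate([r_a[::-1], -r_b[1:]])
        contours.append(np.column_stack([xs, ys]))
    return LongAxisContour(points=tuple(contours), plane_azimuth=float(plane_azimuth),
                           surface=surface)


def sample_short_axis_stack(
    phantom: Phantom,
    step: float = 0.2,
    thickness: float | None = None,
    start_z: float = 0.1,
    max_slices: int | None = None,
    basal_truncation_z: float | None = None,
    n_vertices: int = 360,
    acquisition: str = "4D",
    include_epi: bool = False,
    slab_average: bool = False,
) -> ContourStack:
    """Acquire a stack of short-axis endocardial polygons.

    Slice centers sit at ``start_z + k*step`` (distance from the apex)
    for as long as the slab ``center - thickness/2`` stays below the
    basal limit -- the maximum cavity extent over the cycle, or
    ``basal_truncation_z`` when the base cannot be visualized.  Defaults
    are the fine gated-4D geometry (0.2 mm steps = slice thickness); see
    :func:`sample_cmr_stack` for the 1 mm / 8-slice cine-CMR geometry.

    With ``slab_average`` the polygon radii are root-mean-square radii
    through the slab thickness instead of center-point evaluations, so
    the polygon area equals the slab-average cross-sectional area.  This
    emulates the through-slab partial-volume appearance of thick-slice
    imaging (in particular the basal slab a descending base only partly
    fills); thin-slice acquisitions are indistinguishable either way.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    thickness = step if thickness is None else thickness
    if thickness <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    limit = max(phantom.length(p) for p in range(phantom.n_phases))
    if basal_truncation_z is not None:
        limit = min(limit, basal_truncation_z)
    centers = []
    z = start_z
    while z - thickness / 2.0 < limit and (max_slices is None or len(centers) < max_slices):
        if z > 0:
            centers.append(z)
        z += step
    if not centers:
        raise SamplingError(
            f"no slices produced: start_z={start_z}, step={step}, basal limit={limit:.3f} mm"
        )
    centers = np.asarray(centers)
    thetas = np.linspace(0.0, 360.0, n_vertices, endpoint=False)
    radii = np.empty((centers.size, phantom.n_phases, n_vertices))
    epi = np.empty_like(radii) if include_epi else None
    if slab_average:
        # 5-point Gauss-Legendre through the in-cavity part of each slab;
        # RMS radius preserves the slab-average area
        gl_x, gl_w = np.polynomial.legendre.leggauss(5)
    for p in range(phantom.n_phases):
        if slab_average:
            lo = np.clip(centers - thickness / 2.0, 0.0, None)
            hi = np.minimum(centers + thickness / 2.0, phantom.length(p))
            width = np.clip(hi - lo, 0.0, None)
            acc = np.zeros((centers.size, n_vertices))
            acc_epi = np.zeros_like(acc) if include_epi else None
            for x, w in zip(gl_x, gl_w):
                z = (lo + 0.5 * (x + 1.0) * width)[:, None]
                frac = (0.5 * w * width / thickness)[:, None]
                acc += frac * phantom.endo_radius(thetas[None, :], z, p) ** 2
                if include_epi:
                    inside = width[:, None] > 0
                    acc_epi += frac * np.where(
                        inside, phantom.epi_radius(thetas[None, :], z, p), 0.0
                    ) ** 2
            radii[:, p, :] = np.sqrt(acc)
            if include_epi:
                epi[:, p, :] = np.sqrt(acc_epi)
        else:
            radii[:, p, :] = phantom.endo_radius(thetas[None, :], centers[:, None], p)
            if include_epi:
                inside = centers[:, None] <= phantom.length(p)
                epi[:, p, :] = np.where(
                    inside, phantom.epi_radius(thetas[None, :], centers[:, None], p), 0.0
                )
    return ContourStack(
        slice_centers=centers,
        thicknesses=np.full(centers.size, float(thickness)),
        thetas=thetas,
        radii=radii,
        acquisition=acquisition,
        epi_radii=epi,
    )


def sample_cmr_stack(phantom: Phantom, include_epi: bool = False, n_vertices: int = 360) -> ContourStack:
    """Cine-CMR geometry: eight contiguous 1 mm short-axis slices.

    Thick slices are sampled with through-slab partial-volume averaging
    (see :func:`sample_short_axis_stack`).
    """
    return sample_short_axis_stack(
        phantom,
        step=1.0,
        thickness=1.0,
        start_z=0.5,
        max_slices=8,
        n_vertices=n_vertices,
        acquisition="CMR",
        include_epi=include_epi,
        slab_average=True,
    )
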