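"""The four LV volume estimators and their derived EF/SV.

* Teichholz cubed-diameter formula from an M-mode internal diameter,
  ``V = 7.0/(2.4 + D) * D^3`` (D in mm, V in uL) -- an ellipsoid
  calibration, accurate only while the ventricle is one;
* monoplane method of disks (Simpson) from a single long-axis contour;
* slice summation ``V = sum_i A_i * h_i`` over a short-axis stack, used
  both for the fine 4D-ultrasound stack and the 1 mm cine-CMR stack;
* the phantom quadrature oracle (modality tag ``TRUTH``).

EF is ``100 * (EDV - ESV) / EDV`` for every modality.  Unless forced to
the phantom's true phases, each modality picks its own ED/ES frames as
the extremes of its own volume (or diameter) trace, mirroring how an
operator selects frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

from .emulate import ContourStack, LongAxisContour, MmodeTrace
from .phantom import Phantom

__all__ = [
    "GeometryError",
    "VolumetryResult",
    "teichholz_volume",
    "mmode_result",
    "simpson_monoplane",
    "slice_summation",
    "volumetry_result",
    "MODALITIES",
]

MODALITIES = ("MMODE", "US2D", "US4D", "CMR", "TRUTH")


class GeometryError(ValueError):
    """A contour is degenerate or self-intersecting where it must not be."""


@dataclass(frozen=True)
class VolumetryResult:
    """EDV/ESV/SV/EF for one subject under one modality.

    ``sv = edv - esv`` and ``ef = 100*(edv-esv)/edv``; ``ef`` is NaN
    (missing) when ``edv`` is zero.
    """

    modality: str
    edv: float
    esv: float
    sv: float
    ef: float

    @classmethod
    def from_volumes(cls, modality: str, edv: float, esv: float) -> "VolumetryResult":
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
        if esv < 0 or edv < 0:
            raise ValueError(f"volumes must be >= 0, got edv={edv}, esv={esv}")
        sv = edv - esv
        ef = 100.0 * sv / edv if edv > 0 else float("nan")
        return cls(modality=modality, edv=float(edv), esv=float(esv), sv=float(sv), ef=float(ef))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def teichholz_volume(lvid: float) -> float:
    """Teichholz volume (uL) from an internal diameter (mm)."""
    lvid = float(lvid)
    if lvid < 0:
        raise ValueError(f"lvid must be >= 0, got {lvid}")
    return 7.0 / (2.4 + lvid) * lvid**3


def mmode_result(trace: MmodeTrace) -> VolumetryResult:
    """EDV/ESV/EF from an M-mode trace via the Teichholz formula."""
    edv = teichholz_volume(trace.lvid_d)
    esv = teichholz_volume(trace.lvid_s)
    return VolumetryResult.from_volumes("MMODE", edv, esv)


def _shoelace_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def simpson_monoplane(contour: np.ndarray, n_disks: int = 20) -> float:
    """Monoplane method-of-disks volume (uL) from one closed contour.

    The long axis runs from the apex vertex (minimal x) to the midpoint
    of the basal boundary (the polygon edge whose midpoint lies furthest
    along x).  The axis is cut into ``n_disks`` equal-height disks; each
    disk's diameter is the chord of the contour perpendicular to the axis
    at the disk center, and ``V = sum (pi/4) d_i^2 (L/n)``.
    """
    if n_disks < 4:
        raise ValueError(f"n_disks must be >= 4, got {n_disks}")
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise GeometryError("contour must be an (n, 3+) x 2 array of vertices")
    area = _shoelace_area(pts)
    if area == 0.0:
        return 0.0
    poly = Polygon(pts)
    if not poly.is_valid:
        raise GeometryError("contour is not a simple polygon")

    apex = pts[np.argmin(pts[:, 0])]
    # basal boundary: edge whose midpoint lies furthest from the apex along x
    mids = 0.5 * (pts + np.roll(pts, -1, axis=0))
    base_mid = mids[np.argmax(mids[:, 0])]
    axis = base_mid - apex
    L_axis = float(np.hypot(*axis))
    if L_axis == 0.0:
        raise GeometryError("degenerate long axis (apex coincides with base midpoint)")
    u = axis / L_axis
    v = np.array([-u[1], u[0]])  # perpendicular
    h = L_axis / n_disks
    reach = 4.0 * (L_axis + math.sqrt(area))
    volume = 0.0
    for i in range(n_disks):
        c = apex + u * (i + 0.5) * h
        line = LineString([c - v * reach, c + v * reach])
        chord = poly.intersection(line)
        d = float(chord.length)
        if d == 0.0 and 0 < i < n_disks - 1:
            raise GeometryError(f"no chord found for interior disk {i}")
        volume += math.pi / 4.0 * d**2 * h
    return volume


def _contour_volumes_by_phase(contour: LongAxisContour, n_disks: int) -> np.ndarray:
    return np.array([simpson_monoplane(contour.points[p], n_disks) for p in range(contour.n_phases)])


def slice_summation(stack: ContourStack, phase: int) -> float:
    """Stacked-slice volume (uL): sum of polygon area x slice thickness.

    Degenerate (all-zero) polygons -- slices the base has descended past
    at this phase -- contribute zero.  A self-intersecting polygon raises
    :class:`GeometryError` naming the slice.
    """
    if stack.n_slices == 0:
        raise ValueError("stack is empty")
    total = 0.0
    for i in range(stack.n_slices):
        pts = stack.vertices(i, phase)
        area = _shoelace_area(pts)
        if area > 0.0 and not Polygon(pts).is_valid:
            raise GeometryError(f"slice {i} polygon is self-intersecting at phase {phase}")
        total += area * float(stack.thicknesses[i])
    return total


def _stack_volumes_by_phase(stack: ContourStack) -> np.ndarray:
    return np.array([slice_summation(stack, p) for p in range(stack.n_phases)])


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def volumetry_result(
    source: MmodeTrace | LongAxisContour | ContourStack | Phantom,
    modality: str | None = None,
    n_disks: int = 20,
    phases: tuple[int, int] | None = None,
) -> VolumetryResult:
    """Compute EDV/ESV/SV/EF from a measurement primitive.

    Dispatches on the source type: an :class:`MmodeTrace` feeds the
    Teichholz estimator, a :class:`LongAxisContour` the monoplane method
    of disks, a :class:`ContourStack` the slice summation (modality tag
    taken from its acquisition), and a :class:`Phantom` the quadrature
    oracle (``TRUTH``).  ``phases=(ed, es)`` forces specific frames;
    otherwise each modality uses the extremes of its own volume trace.
    """
    if isinstance(source, MmodeTrace):
        return mmode_result(source)
    if isinstance(source, LongAxisContour):
        vols = _contour_volumes_by_phase(source, n_disks)
        modality = modality or "US2D"
    elif isinstance(source, ContourStack):
        vols = _stack_volumes_by_phase(source)
        modality = modality or ("CMR" if source.acquisition == "CMR" else "US4D")
    elif isinstance(source, Phantom):
        vols = source.truth_volumes()
        modality = modality or "TRUTH"
    else:
        raise TypeError(f"cannot compute volumetry from {type(source).__name__}")
    if phases is not None:
        edv, esv = float(vols[phases[0]]), float(vols[phases[1]])
    else:
        edv, esv = float(vols.max()), float(vols.min())
    return VolumetryResult.from_volumes(modality, edv, esv)
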