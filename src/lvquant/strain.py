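"""Global and segmental strain summaries and the SD dyssynchrony index.

Longitudinal strain is the percent change of endocardial boundary arc
length in a long-axis plane relative to end-diastole; circumferential
strain the percent change of a short-axis slice perimeter; radial strain
the percent change of mean wall thickness (positive for thickening).
"Peak" strain is the signed extremum of largest magnitude over the
cycle.  The dyssynchrony index is the standard deviation of the six
long-axis segmental peak longitudinal strains; it vanishes for any
spatially uniform motion.

Segments are material: the end-diastolic arc is split into six
equal-length intervals and each interval is tracked by its boundary
parameter across phases (the surrogate for speckle tracking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emulate import ContourStack, LongAxisContour, sample_long_axis, sample_short_axis_stack
from .phantom import Phantom
from .volumetry import GeometryError, _shoelace_area

__all__ = [
    "StrainResult",
    "longitudinal_strain",
    "circumferential_strain",
    "radial_strain",
    "strain_result",
]

N_SEGMENTS = 6


@dataclass(frozen=True)
class StrainResult:
    """Strain summaries for one subject (all in percent).

    ``gls``/``grs_long`` come from the long-axis plane, ``gcs``/
    ``grs_short`` from the mid short-axis slice; ``dyssynchrony_sd`` is
    the SD of the six segmental peak longitudinal strains.
    """

    gls: float
    grs_long: float
    gcs: float
    grs_short: float
    dyssynchrony_sd: float
    segmental_longitudinal: tuple[float, ...] = ()


def _signed_extremum(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(values[np.argmax(np.abs(values))])


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    """Per-edge lengths of the open boundary polyline (basal chord excluded)."""
    d = np.diff(points, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def longitudinal_strain(
    contour: LongAxisContour, ed_phase: int | None = None
) -> tuple[float, np.ndarray]:
    """Global and six-segment peak longitudinal strain from one plane.

    Returns ``(gls, segmental_peaks)``.  Boundary length is measured
    along the open endocardial polyline (the basal closing chord is not
    myocardium).  ED defaults to the phase of maximal enclosed area.
    Segment boundaries are equal sixths of the ED arc length, assigned at
    edge granularity and held fixed (material) across phases.
    """
    if contour.n_phases < 2:
        raise ValueError("longitudinal strain needs at least 2 phases")
    if ed_phase is None:
        areas = [_shoelace_area(p) for p in contour.points]
        ed_phase = int(np.argmax(areas))
    ed_edges = _arc_lengths(contour.points[ed_phase])
    total_ed = float(ed_edges.sum())
    if total_ed <= 0:
        raise GeometryError("degenerate contour: zero boundary length at end-diastole")
    # assign each ED edge to one of six equal-arc-length segments
    mid = np.cumsum(ed_edges) - 0.5 * ed_edges
    seg_of_edge = np.minimum((mid / total_ed * N_SEGMENTS).astype(int), N_SEGMENTS - 1)
    seg_ed = np.array([ed_edges[seg_of_edge == s].sum() for s in range(N_SEGMENTS)])
    if np.any(seg_ed <= 0):
        raise GeometryError("degenerate contour: an empty longitudinal segment")

    global_strain = np.empty(contour.n_phases)
    seg_strain = np.empty((contour.n_phases, N_SEGMENTS))
    for p in range(contour.n_phases):
        edges = _arc_lengths(contour.points[p])
        global_strain[p] = 100.0 * (edges.sum() - total_ed) / total_ed
        for s in range(N_SEGMENTS):
            seg_strain[p, s] = 100.0 * (edges[seg_of_edge == s].sum() - seg_ed[s]) / seg_ed[s]
    gls = _signed_extremum(global_strain)
    peaks = np.array([_signed_extremum(seg_strain[:, s]) for s in range(N_SEGMENTS)])
    return gls, peaks


def circumferential_strain(stack: ContourStack, slice_index: int | None = None,
                           ed_phase: int | None = None) -> float:
    """Peak circumferential strain (%) of one short-axis slice.

    Perimeter-based, relative to the ED perimeter; the slice defaults to
    the mid-ventricular one (center closest to half the stack extent).
    """
    if stack.n_phases < 2:
        raise ValueError("circumferential strain needs at least 2 phases")
    if slice_index is None:
        target = 0.5 * (stack.slice_centers[0] + stack.slice_centers[-1])
        slice_index = int(np.argmin(np.abs(stack.slice_centers - target)))
    perims = np.empty(stack.n_phases)
    for p in range(stack.n_phases):
        pts = stack.vertices(slice_index, p)
        d = pts - np.roll(pts, 1, axis=0)
        perims[p] = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if ed_phase is None:
        ed_phase = int(np.argmax(perims))
    p_ed = perims[ed_phase]
    if p_ed <= 0:
        raise GeometryError("degenerate slice: zero perimeter at end-diastole")
    return _signed_extremum(100.0 * (perims - p_ed) / p_ed)


def _mean_thickness_by_phase(endo: LongAxisContour, epi: LongAxisContour) -> np.ndarray:
    if endo.n_phases != epi.n_phases:
        raise ValueError("endo and epi contours must share the phase grid")
    out = np.empty(endo.n_phases)
    for p in range(endo.n_phases):
        d = epi.points[p] - endo.points[p]
        out[p] = float(np.mean(np.hypot(d[:, 0], d[:, 1])))
    return out


def radial_strain(endo: LongAxisContour | ContourStack,
                  epi: LongAxisContour | None = None,
                  slice_index: int | None = None,
                  ed_phase: int | None = None) -> float:
    """Peak radial (wall-thickening) strain in percent.

    ``100 * (thickness(ES) - thickness(ED)) / thickness(ED)`` with the
    mean wall thickness taken from paired endocardial and epicardial
    boundaries (matched vertices for a long-axis pair; matched theta
    rays for a short-axis stack sampled with its epicardium).  Positive
    for thickening.
    """
    if isinstance(endo, ContourStack):
        stack = endo
        if stack.epi_radii is None:
            raise ValueError("stack was sampled without the epicardial surface")
        if slice_index is None:
            target = 0.5 * (stack.slice_centers[0] + stack.slice_centers[-1])
            slice_index = int(np.argmin(np.abs(stack.slice_centers - target)))
        th = np.mean(stack.epi_radii[slice_index] - stack.radii[slice_index], axis=1)
    else:
        if epi is None:
            raise ValueError("epicardial contour required for radial strain")
        th = _mean_thickness_by_phase(endo, epi)
    if ed_phase is None:
        ed_phase = int(np.argmin(th))  # thinnest wall = most dilated cavity
    t_ed = th[ed_phase]
    if t_ed <= 0:
        raise GeometryError("degenerate wall: zero thickness at end-diastole")
    return _signed_extremum(100.0 * (th - t_ed) / t_ed)


def strain_result(
    phantom: Phantom,
    plane_azimuth: float = 0.0,
    n_points: int = 201,
    stack: ContourStack | None = None,
) -> StrainResult:
    """Assemble the full strain summary for one phantom.

    Long-axis quantities come from the plane at ``plane_azimuth``;
    short-axis quantities from the mid slice of ``stack`` (a fine stack
    sampled with its epicardium is acquired if none is given).
    """
    endo = sample_long_axis(phantom, plane_azimuth, n_points=n_points)
    epi = sample_long_axis(phantom, plane_azimuth, n_points=n_points, surface="epi")
    gls, peaks = longitudinal_strain(endo, ed_phase=phantom.ed_phase)
    grs_long = radial_strain(endo, epi, ed_phase=phantom.ed_phase)
    if stack is None:
        stack = sample_short_axis_stack(phantom, include_epi=True, n_vertices=180)
    gcs = circumferential_strain(stack, ed_phase=phantom.ed_phase)
    grs_short = radial_strain(stack, ed_phase=phantom.ed_phase)
    sd = float(np.std(peaks, ddof=1))
    return StrainResult(
        gls=gls,
        grs_long=grs_long,
        gcs=gcs,
        grs_short=grs_short,
        dyssynchrony_sd=sd,
        segmental_longitudinal=tuple(float(v) for v in peaks),
    )
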