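"""16-segment wall-motion scoring and the wall motion score index (WMSI).

Three short-axis levels taken 1, 3 and 5 mm from the apex are scored:
the most apical level is divided into 4 quadrants (anterior, lateral,
inferior, septal) and the mid and basal levels into 6 sextants each
(A, AL, IL, I, IS, AS), for 16 segments in all.  Segments are graded
1 (normal) to 5 (aneurysmal) and the WMSI is the unweighted mean of the
16 grades.

Visual grading is replaced by a quantitative surrogate: the fractional
endocardial excursion of each segment between end-diastole and
end-systole, normalized by a reference ("remote zone") excursion, is
thresholded into the five grades.  An aneurysm is flagged when a
segment's end-diastolic radius bulges beyond the slice's typical radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emulate import ContourStack
from .volumetry import GeometryError, _stack_volumes_by_phase

__all__ = [
    "APICAL_LABELS",
    "SEXTANT_LABELS",
    "WmsiConfig",
    "SegmentScore",
    "SegmentScoreSet",
    "select_wmsi_slices",
    "segment_excursion",
    "score_segment",
    "wmsi",
    "score_stack",
]

#: quadrant labels of the apical level, centred on 0, 90, 180, 270 degrees
APICAL_LABELS = ("A", "L", "I", "S")
#: sextant labels of the mid and basal levels, centred on 0..300 degrees
SEXTANT_LABELS = ("A", "AL", "IL", "I", "IS", "AS")
LEVELS = ("apical", "mid", "basal")
#: target slice distances from the apex, mm
LEVEL_TARGETS = {"apical": 1.0, "mid": 3.0, "basal": 5.0}


@dataclass(frozen=True)
class WmsiConfig:
    """Thresholds of the excursion-based auto-scorer.

    ``q`` is a segment's fractional excursion relative to the reference:
    normal when ``q >= normal_q``, hypokinetic down to ``hypo_q``,
    akinetic while ``|q| < hypo_q``, dyskinetic when ``q <= -hypo_q``;
    aneurysmal whenever the end-diastolic bulge flag is set.  The flag
    fires when the segment's mean ED radius exceeds the slice median by
    more than ``bulge_threshold``.  ``reference_fe``, when set, is the
    cohort-nominal normal excursion; by default the reference is the mean
    excursion of the best-contracting (remote) quartile of segments.
    """

    normal_q: float = 0.55
    hypo_q: float = 0.20
    bulge_threshold: float = 0.10
    reference_fe: float | None = None


@dataclass(frozen=True)
class SegmentScore:
    level: str
    label: str
    fe: float
    score: int


@dataclass(frozen=True)
class SegmentScoreSet:
    """Exactly 16 labeled segment scores: 4 apical + 6 mid + 6 basal."""

    segments: tuple[SegmentScore, ...]

    def __post_init__(self):
        if len(self.segments) != 16:
            raise ValueError(f"expected exactly 16 segments, got {len(self.segments)}")
        counts = {lvl: sum(s.level == lvl for s in self.segments) for lvl in LEVELS}
        if counts != {"apical": 4, "mid": 6, "basal": 6}:
            raise ValueError(f"expected 4 apical + 6 mid + 6 basal segments, got {counts}")

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.segments])

    @property
    def wmsi(self) -> float:
        return wmsi([s.score for s in self.segments])


def wmsi(scores) -> float:
    """Unweighted mean of the 16 segment motion grades; bounded in [1, 5]."""
    scores = np.asarray(scores, dtype=float)
    if scores.size != 16:
        raise ValueError(f"WMSI needs exactly 16 segment scores, got {scores.size}")
    if np.any((scores < 1) | (scores > 5)):
        raise ValueError("segment scores must lie in 1..5")
    return float(scores.mean())


def select_wmsi_slices(stack: ContourStack) -> tuple[int, int, int]:
    """Indices of the slices nearest 1, 3 and 5 mm from the apex.

    Ties between two equidistant centers break toward the apex.  The
    stack must span at least 5 mm of the long axis; shorter acquisitions
    raise with a pointer to the acquisition settings.
    """
    centers = np.asarray(stack.slice_centers, dtype=float)
    span = centers.max() - centers.min() + float(np.max(stack.thicknesses))
    if span < 5.0 - 1e-9:
        raise ValueError(
            f"stack spans only {span:.2f} mm but wall-motion scoring needs the "
            "1/3/5 mm levels; extend start_z/step/max_slices in the acquisition settings"
        )
    picks = []
    for level in LEVELS:
        target = LEVEL_TARGETS[level]
        dist = np.abs(centers - target)
        best = np.min(dist)
        # tie -> lower center (toward the apex)
        picks.append(int(np.flatnonzero(np.isclose(dist, best))[0]))
    return tuple(picks)  # type: ignore[return-value]


def segment_excursion(r_ed: np.ndarray, r_es: np.ndarray, thetas: np.ndarray,
                      theta_lo: float, theta_hi: float) -> float:
    """Mean fractional radial excursion over one angular segment.

    ``FE = mean over the segment of (r_ED - r_ES) / r_ED`` with the two
    radius profiles sharing the theta parameterization.  The segment is
    the wrapped interval ``[theta_lo, theta_hi)``.
    """
    r_ed = np.asarray(r_ed, dtype=float)
    r_es = np.asarray(r_es, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    width = (theta_hi - theta_lo) % 360.0 or 360.0
    rel = (thetas - theta_lo) % 360.0
    mask = rel < width
    if not np.any(mask):
        raise ValueError("segment angular range contains no vertices")
    if np.any(r_ed[mask] <= 0):
        raise GeometryError("end-diastolic radius vanishes inside the segment")
    return float(np.mean((r_ed[mask] - r_es[mask]) / r_ed[mask]))


def score_segment(fe: float, aneurysm_flag: bool, normal_reference_fe: float,
                  config: WmsiConfig = WmsiConfig()) -> int:
    """Grade one segment 1-5 from its relative excursion."""
    if normal_reference_fe <= 0:
        raise ValueError(f"normal_reference_fe must be > 0, got {normal_reference_fe}")
    if aneurysm_flag:
        return 5
    q = fe / normal_reference_fe
    if q >= config.normal_q:
        return 1
    if q >= config.hypo_q:
        return 2
    if q > -config.hypo_q:
        return 3
    return 4


def _level_segments(level: str) -> list[tuple[str, float, float]]:
    if level == "apical":
        centers = (0.0, 90.0, 180.0, 270.0)
        labels = APICAL_LABELS
        half = 45.0
    else:
        centers = tuple(60.0 * k for k in range(6))
        labels = SEXTANT_LABELS
        half = 30.0
    return [(lab, c - half, c + half) for lab, c in zip(labels, centers)]


def score_stack(
    stack: ContourStack,
    config: WmsiConfig = WmsiConfig(),
    phases: tuple[int, int] | None = None,
) -> SegmentScoreSet:
    """Score all 16 segments of a short-axis stack.

    ED/ES default to the extremes of the stack's own volume trace.  The
    reference excursion, unless configured, is the mean of the top
    quartile of the 16 segmental excursions (the remote zone); aneurysm
    flags come from the end-diastolic bulge test.
    """
    if phases is None:
        vols = _stack_volumes_by_phase(stack)
        ed, es = int(np.argmax(vols)), int(np.argmin(vols))
    else:
        ed, es = phases
    idx = select_wmsi_slices(stack)
    entries: list[tuple[str, str, float, bool]] = []
    for level, i in zip(LEVELS, idx):
        r_ed = stack.radii[i, ed]
        r_es = stack.radii[i, es]
        ref_radius = float(np.median(r_ed))
        for label, lo, hi in _level_segments(level):
            fe = segment_excursion(r_ed, r_es, stack.thetas, lo, hi)
            rel = (stack.thetas - lo) % 360.0
            mask = rel < ((hi - lo) % 360.0 or 360.0)
            bulge = float(np.mean(r_ed[mask])) > (1.0 + config.bulge_threshold) * ref_radius
            entries.append((level, label, fe, bulge))
    fes = np.array([e[2] for e in entries])
    if config.reference_fe is not None:
        ref = config.reference_fe
    else:
        top = np.sort(fes)[-4:]  # best-contracting quartile of 16 segments
        ref = float(np.mean(top))
    if ref <= 0:
        raise GeometryError("no contracting remote zone found to normalize excursions")
    segs = tuple(
        SegmentScore(level=lvl, label=lab, fe=float(fe),
                     score=score_segment(float(fe), bulge, ref, config))
        for (lvl, lab, fe, bulge) in entries
    )
    return SegmentScoreSet(segments=segs)
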