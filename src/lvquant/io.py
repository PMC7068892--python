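"""CSV/JSON serialization of phantoms, contours and result tables.

Contour geometry travels as long-format CSV (subject, slice, phase,
vertex, x, y) so that externally produced contour stacks can be fed to
the same estimators; parameter sets and study configs travel as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emulate import ContourStack, LongAxisContour
from .phantom import InfarctSpec, Phantom, PhantomParams
from .volumetry import VolumetryResult

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "write_contour_stack",
    "read_contour_stack",
    "write_long_axis",
    "read_long_axis",
    "volumetry_table",
    "cohort_truth_table",
]


def params_to_dict(params: PhantomParams) -> dict:
    d = dataclasses.asdict(params)
    return d


def params_from_dict(d: dict) -> PhantomParams:
    d = dict(d)
    inf = d.pop("infarct", None)
    infarct = InfarctSpec(**inf) if inf is not None else None
    return PhantomParams(infarct=infarct, **d)


def save_params(params: PhantomParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2))


def load_params(path: str | Path) -> PhantomParams:
    return params_from_dict(json.loads(Path(path).read_text()))


def write_contour_stack(stack: ContourStack, path: str | Path, subject: str = "S0") -> None:
    """Long-format CSV: subject, slice, slice_center_z, thickness, acquisition, phase, vertex, x, y."""
    rows = []
    for i in range(stack.n_slices):
        for p in range(stack.n_phases):
            pts = stack.vertices(i, p)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "slice": i,
                        "slice_center_z": stack.slice_centers[i],
                        "thickness": stack.thicknesses[i],
                        "acquisition": stack.acquisition,
                        "phase": p,
                        "vertex": np.arange(stack.n_vertices),
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_contour_stack(path: str | Path, subject: str | None = None) -> ContourStack:
    """Rebuild a :class:`ContourStack` from the long-format CSV schema.

    Vertices are re-expressed as radii about each slice's end-diastolic
    centroid, on the theta grid of the first slice/phase, so external
    contours gain the shared theta parameterization the segment scorer
    needs.  Vertex counts must match across slices and phases.
    """
    df = pd.read_csv(path)
    if subject is not None:
        df = df[df["subject"] == subject]
    if df.empty:
        raise ValueError(f"no contour rows found in {path}")
    slices = sorted(df["slice"].unique())
    phases = sorted(df["phase"].unique())
    first = df[(df["slice"] == slices[0]) & (df["phase"] == phases[0])].sort_values("vertex")
    n_vertices = len(first)
    centers, thicknesses = [], []
    radii = np.zeros((len(slices), len(phases), n_vertices))
    thetas = None
    for si, s in enumerate(slices):
        sub = df[df["slice"] == s]
        centers.append(float(sub["slice_center_z"].iloc[0]))
        thicknesses.append(float(sub["thickness"].iloc[0]))
        # centroid of the largest-area phase anchors the radial rays
        for pi, p in enumerate(phases):
            g = sub[sub["phase"] == p].sort_values("vertex")
            if len(g) != n_vertices:
                raise ValueError(f"slice {s} phase {p}: vertex count differs")
            x = g["x"].to_numpy()
            y = g["y"].to_numpy()
            r = np.hypot(x, y)
            if thetas is None:
                thetas = np.rad2deg(np.arctan2(y, x)) % 360.0
            radii[si, pi] = r
    acq = str(df["acquisition"].iloc[0]) if "acquisition" in df else "4D"
    return ContourStack(
        slice_centers=np.asarray(centers),
        thicknesses=np.asarray(thicknesses),
        thetas=np.asarray(thetas),
        radii=radii,
        acquisition=acq,
    )


def write_long_axis(contour: LongAxisContour, path: str | Path, subject: str = "S0") -> None:
    rows = []
    for p, pts in enumerate(contour.points):
        rows.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "plane_azimuth": contour.plane_azimuth,
                    "phase": p,
                    "vertex": np.arange(len(pts)),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_long_axis(path: str | Path, subject: str | None = None) -> LongAxisContour:
    df = pd.read_csv(path)
    if subject is not None:
        df = df[df["subject"] == subject]
    if df.empty:
        raise ValueError(f"no contour rows found in {path}")
    azim = float(df["plane_azimuth"].iloc[0]) if "plane_azimuth" in df else 0.0
    points = []
    for p in sorted(df["phase"].unique()):
        g = df[df["phase"] == p].sort_values("vertex")
        points.append(np.column_stack([g["x"].to_numpy(), g["y"].to_numpy()]))
    return LongAxisContour(points=tuple(points), plane_azimuth=azim)


def volumetry_table(results: dict[str, list[VolumetryResult]]) -> pd.DataFrame:
    """Assemble the per-subject results table (subject, modality, EDV_uL, ...)."""
    rows = []
    for subject, res_list in results.items():
        for r in res_list:
            rows.append(
                {
                    "subject": subject,
                    "modality": r.modality,
                    "EDV_uL": r.edv,
                    "ESV_uL": r.esv,
                    "SV_uL": r.sv,
                    "EF_pct": r.ef,
                }
            )
    return pd.DataFrame(rows)


def cohort_truth_table(phantoms: list[Phantom]) -> pd.DataFrame:
    """Ground-truth table: subject id, scar fraction, true EDV/ESV/EF."""
    rows = []
    for i, ph in enumerate(phantoms):
        v = ph.truth_volumes()
        rows.append(
            {
                "subject": f"S{i:02d}",
                "scar_fraction": ph.truth_scar_fraction,
                "EDV_uL": float(v.max()),
                "ESV_uL": float(v.min()),
                "EF_pct": ph.truth_ef,
            }
        )
    return pd.DataFrame(rows)
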