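"""Conformational metrics: superposed RMSD, radius of gyration, RMSF.

RMSD time series are computed against the first frame after an optimal
proper rigid-body (Kabsch) superposition of the Cα selection; the
radius of gyration is mass-weighted; per-residue RMSF is measured about
the window-mean structure after one re-superposition pass, and the
"total RMSF" summary is the sum (not mean) over residues.

All computation is in Å; series and tables can be reported in nm via
``units="nm"`` where the conventional literature unit is nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import EmptyInputError, GeometryError, MassError, SelectionError
from .structure_io import Structure, SpeciesMap, Trajectory

__all__ = [
    "Superposition",
    "MetricSeries",
    "RMSFTable",
    "superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rmsf_per_residue",
    "select_calpha",
]

_NM_PER_A = 0.1


@dataclass
class Superposition:
    """Optimal proper rigid transform mapping mobile onto reference.

    ``apply(x)`` computes ``(x - mobile_centroid) @ rotation.T +
    reference_centroid``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.mobile_centroid) @ self.rotation.T + self.reference_centroid


@dataclass
class MetricSeries:
    """A per-frame scalar metric (rmsd or rg) with times in ps."""

    metric: str
    times: np.ndarray
    values: np.ndarray
    units: str = "A"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, f"{self.metric}_{self.units}": self.values})

    def in_nm(self) -> "MetricSeries":
        if self.units == "nm":
            return self
        return MetricSeries(self.metric, self.times, self.values * _NM_PER_A, "nm")


@dataclass
class RMSFTable:
    """Per-residue RMSF over a time window, plus the summed total."""

    residue_indices: np.ndarray
    rmsf: np.ndarray
    window: tuple[float, float]
    units: str = "nm"

    @property
    def total_rmsf(self) -> float:
        return float(np.sum(self.rmsf))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_index": self.residue_indices, f"rmsf_{self.units}": self.rmsf}
        )


def _check_geometry(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")


def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Weighted least-squares proper rigid-body fit of mobile onto reference.

    Returns the rotation (det +1, reflections corrected), translation and
    the minimised RMSD in Å.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise GeometryError("reference and mobile must have the same shape")
    _check_geometry(reference)
    _check_geometry(mobile)
    if weights is None:
        w = np.ones(len(reference))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(reference),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    ref_c = np.average(reference, axis=0, weights=w)
    mob_c = np.average(mobile, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c, weights=w)
    R = rot.as_matrix()
    moved = (mobile - mob_c) @ R.T + ref_c
    rmsd = float(np.sqrt(np.average(np.sum((moved - reference) ** 2, axis=1), weights=w)))
    translation = ref_c - R @ mob_c
    return Superposition(
        rotation=R,
        translation=translation,
        rmsd=rmsd,
        mobile_centroid=mob_c,
        reference_centroid=ref_c,
    )


def select_calpha(structure: Structure, species: SpeciesMap | None = None) -> np.ndarray:
    """Indices of Cα atoms (optionally restricted to the protein species)."""
    mask = np.array([str(n).upper() == "CA" for n in structure.names])
    mask &= np.array([str(e).upper() == "C" for e in structure.elements])
    if species is not None:
        mask &= species.species == "protein"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError("no Cα atoms in selection")
    return idx


def rmsd_series(
    traj: Trajectory,
    selection: np.ndarray,
    reference_frame: int = 0,
    units: str = "A",
) -> MetricSeries:
    """Superposed RMSD of the selection against a reference frame, per frame."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise SelectionError("empty selection")
    ref = traj.frames[reference_frame][selection]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        values[k] = superpose(ref, traj.frames[k][selection]).rmsd
    series = MetricSeries("rmsd", traj.times.copy(), values, "A")
    return series.in_nm() if units == "nm" else series


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration in Å."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("no atoms")
    total = masses.sum()
    if total <= 0:
        raise MassError("total mass must be positive")
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.sum(masses * np.sum((coords - com) ** 2, axis=1)) / total))


def rg_series(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    units: str = "A",
) -> MetricSeries:
    """Radius-of-gyration time series (mass-weighted, element masses)."""
    masses = traj.parent.masses
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise SelectionError("empty selection")
        masses = masses[selection]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        coords = traj.frames[k] if selection is None else traj.frames[k][selection]
        values[k] = radius_of_gyration(coords, masses)
    series = MetricSeries("rg", traj.times.copy(), values, "A")
    return series.in_nm() if units == "nm" else series


def rmsf_per_residue(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[float, float] | None = None,
    last_fraction: float | None = None,
    units: str = "nm",
) -> RMSFTable:
    """Per-residue RMSF of the selection about the window-mean structure.

    Frames in the window are first superposed on the initial window
    frame, averaged, then re-superposed once on that mean before the
    fluctuations are measured (the standard single-iteration scheme).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise SelectionError("empty selection")
    idx = traj.window_indices(window=window, last_fraction=last_fraction)
    if idx.size < 2:
        from .errors import WindowError

        raise WindowError("RMSF window must contain at least 2 frames")

    sub = traj.frames[idx][:, selection, :]
    first = sub[0]
    aligned = np.array([superpose(first, fr).apply(fr) for fr in sub])
    mean = aligned.mean(axis=0)
    aligned = np.array([superpose(mean, fr).apply(fr) for fr in sub])
    mean = aligned.mean(axis=0)
    rmsf_a = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    res_idx = traj.parent.residue_indices[selection]
    if units == "nm":
        rmsf_vals = rmsf_a * _NM_PER_A
    elif units == "A":
        rmsf_vals = rmsf_a
    else:
        raise ValueError("units must be 'nm' or 'A'")
    t0, t1 = float(traj.times[idx[0]]), float(traj.times[idx[-1]])
    return RMSFTable(residue_indices=res_idx, rmsf=rmsf_vals, window=(t0, t1), units=units)
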