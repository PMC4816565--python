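"""Preferential-interaction statistics around a solvated protein.

Two complementary views of the solvation structure:

* radial distribution functions g(r) of a solvent role atom (water
  oxygen, DMF carbon, trehalose hydroxyl oxygen) as a function of the
  minimum-image distance from the protein's centre of mass, normalised
  by shell volume and the role's bulk number density; and

* the normalised water-oxygen ratio g_NOW over minimum-distance shells
  of the protein surface,

      g_NOW = [n_OW / (n_OW + n_CD + n_OT)] * [(N_OW + N_CD + N_OT) / N_OW]

  where the lower-case n are time-averaged counts of role atoms whose
  minimum distance to any protein heavy atom falls in a shell band and
  the upper-case N are whole-box totals.  g_NOW > 1 in a shell means
  the protein is preferentially hydrated there (water over-represented
  relative to the bulk composition); g_NOW < 1 means water is displaced
  by cosolvents.

Shells are half-open bands (r_lo, r_hi], by default 0.5 Å steps from
0.5 to 10.0 Å.  Shells with no solvent at all are reported as NaN
(undefined), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    MassError,
    PBCError,
    SelectionError,
    ValidationError,
)
from .geometry import min_distance_to_set, minimum_image, pair_distances
from .structure_io import SpeciesMap, Trajectory

__all__ = [
    "RDFResult",
    "ShellProfile",
    "ROLE_ATTRS",
    "center_of_mass",
    "rdf_from_com",
    "min_distance_to_protein",
    "g_now_profile",
    "gnow_from_counts",
    "default_shell_edges",
]

#: Species-role name -> SpeciesMap attribute carrying the role mask.
ROLE_ATTRS = {
    "water_oxygen": "is_water_oxygen",
    "dmf_carbon": "is_dmf_carbon",
    "trehalose_hydroxyl_oxygen": "is_trehalose_hydroxyl_oxygen",
}


def default_shell_edges(step: float = 0.5, r_max: float = 10.0, r_min: float = 0.5) -> np.ndarray:
    """Shell band edges in Å: r_min, r_min+step, ..., r_max."""
    n = int(round((r_max - r_min) / step))
    return r_min + step * np.arange(n + 1)


@dataclass
class RDFResult:
    """Radial distribution of one role around the protein COM."""

    role: str
    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    frames_averaged: int
    bulk_density: float

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_mid_A": self.r_mid, "g_r": self.g})


@dataclass
class ShellProfile:
    """Time-averaged per-shell role counts and the g_NOW profile."""

    shell_edges: np.ndarray
    n_ow: np.ndarray
    n_cd: np.ndarray
    n_ot: np.ndarray
    totals: dict[str, float]
    g_now: np.ndarray
    frames_averaged: int
    cumulative: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shell_lo_A": self.shell_edges[:-1],
                "shell_hi_A": self.shell_edges[1:],
                "n_OW": self.n_ow,
                "n_CD": self.n_cd,
                "n_OT": self.n_ot,
                "g_NOW": self.g_now,
            }
        )

    def occupied(self) -> np.ndarray:
        """Mask of shells containing any solvent (g_NOW defined)."""
        return (self.n_ow + self.n_cd + self.n_ot) > 0


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position (Å)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("no atoms")
    if masses.sum() <= 0:
        raise MassError("total mass must be positive")
    return np.average(coords, axis=0, weights=masses)


def _role_indices(species: SpeciesMap, role: str) -> np.ndarray:
    try:
        mask = getattr(species, ROLE_ATTRS[role])
    except KeyError:
        raise ValueError(f"unknown role {role!r}; one of {sorted(ROLE_ATTRS)}") from None
    return np.flatnonzero(mask)


def _protein_heavy_indices(traj: Trajectory, species: SpeciesMap) -> np.ndarray:
    heavy = np.array([str(e).upper() != "H" for e in traj.parent.elements])
    idx = np.flatnonzero((species.species == "protein") & heavy)
    if idx.size == 0:
        raise SelectionError("no protein heavy atoms in species map")
    return idx


def rdf_from_com(
    traj: Trajectory,
    species: SpeciesMap,
    role: str,
    bins: np.ndarray | None = None,
    window_last: float = 0.6,
) -> RDFResult:
    """g(r) of a role atom around the protein centre of mass.

    Distances use the minimum-image convention; normalisation is by
    spherical-shell volume and the role's bulk number density in the
    box.  Frames averaged default to the final 60 % of the trajectory.
    """
    role_idx = _role_indices(species, role)
    if role_idx.size == 0:
        raise SelectionError(f"no atoms with role {role!r}")
    if traj.box is None:
        raise PBCError("rdf_from_com requires a periodic box")
    if bins is None:
        bins = np.arange(0.0, 15.0 + 1e-9, 0.5)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    prot_idx = np.flatnonzero(species.species == "protein")
    if prot_idx.size == 0:
        raise SelectionError("no protein atoms for COM")
    masses = traj.parent.masses[prot_idx]

    frames = traj.window_indices(last_fraction=window_last)
    counts = np.zeros(len(bins) - 1)
    volume = 0.0
    for k in frames:
        box = traj.frame_box(k)
        if bins[-1] > 0.5 * np.min(box):
            raise PBCError(
                f"outermost bin edge {bins[-1]:.2f} Å exceeds half the smallest "
                f"box edge ({0.5 * np.min(box):.2f} Å)"
            )
        com = center_of_mass(traj.frames[k][prot_idx], masses)
        d = pair_distances(traj.frames[k][role_idx], com, box)
        counts += np.histogram(d, bins=bins)[0]
        volume += float(np.prod(box))
    n_frames = len(frames)
    mean_counts = counts / n_frames
    mean_volume = volume / n_frames
    rho_bulk = role_idx.size / mean_volume
    shell_vol = (4.0 / 3.0) * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    g = mean_counts / (rho_bulk * shell_vol)
    return RDFResult(
        role=role,
        bin_edges=bins,
        g=g,
        counts=mean_counts,
        frames_averaged=n_frames,
        bulk_density=rho_bulk,
    )


def min_distance_to_protein(
    frame: np.ndarray,
    protein_indices: np.ndarray,
    target_indices: np.ndarray,
    box: np.ndarray | None,
) -> np.ndarray:
    """Minimum-image distance from each target atom to the nearest protein atom."""
    protein_indices = np.asarray(protein_indices, dtype=int)
    target_indices = np.asarray(target_indices, dtype=int)
    if protein_indices.size == 0:
        raise SelectionError("empty protein selection")
    if target_indices.size == 0:
        raise SelectionError("empty target selection")
    return min_distance_to_set(frame[target_indices], frame[protein_indices], box)


def gnow_from_counts(
    n_ow: float, n_cd: float, n_ot: float, N_ow: float, N_cd: float, N_ot: float
) -> float:
    """g_NOW from shell counts and box totals; NaN when the shell is empty."""
    if N_ow <= 0:
        raise ValidationError("no water oxygens in the box (N_OW must be > 0)")
    local = n_ow + n_cd + n_ot
    if local <= 0:
        return float("nan")
    return (n_ow / local) * ((N_ow + N_cd + N_ot) / N_ow)


def g_now_profile(
    traj: Trajectory,
    species: SpeciesMap,
    shells: np.ndarray | None = None,
    window_last: float | None = None,
    cumulative: bool = False,
) -> ShellProfile:
    """Time-averaged g_NOW over minimum-distance shells of the protein.

    Per frame, each water oxygen, DMF carbon and trehalose hydroxyl
    oxygen is assigned to the shell band (r_lo, r_hi] containing its
    minimum distance to any protein heavy atom; counts are averaged
    over frames before the ratio is formed.  With ``cumulative=True``
    a shell instead counts every role atom with minimum distance
    <= r_hi.
    """
    if shells is None:
        shells = default_shell_edges()
    shells = np.asarray(shells, dtype=float)
    if np.any(np.diff(shells) <= 0):
        raise ValueError("shell edges must be strictly increasing")

    idx_ow = _role_indices(species, "water_oxygen")
    if idx_ow.size == 0:
        raise ValidationError("no water in system (N_OW must be > 0)")
    idx_cd = _role_indices(species, "dmf_carbon")
    idx_ot = _role_indices(species, "trehalose_hydroxyl_oxygen")
    prot_idx = _protein_heavy_indices(traj, species)

    frames = traj.window_indices(last_fraction=window_last) if window_last else np.arange(traj.n_frames)
    n_bands = len(shells) - 1
    acc = {key: np.zeros(n_bands) for key in ("ow", "cd", "ot")}
    for k in frames:
        box = traj.frame_box(k)
        prot = traj.frames[k][prot_idx]
        for key, idx in (("ow", idx_ow), ("cd", idx_cd), ("ot", idx_ot)):
            if idx.size == 0:
                continue
            d = min_distance_to_set(traj.frames[k][idx], prot, box)
            if cumulative:
                acc[key] += np.array([(d <= hi).sum() for hi in shells[1:]], dtype=float)
            else:
                # half-open bands (lo, hi]
                acc[key] += np.histogram(np.nextafter(d, -np.inf), bins=shells)[0]
    n_frames = len(frames)
    n_ow = acc["ow"] / n_frames
    n_cd = acc["cd"] / n_frames
    n_ot = acc["ot"] / n_frames
    totals = {
        "N_OW": float(idx_ow.size),
        "N_CD": float(idx_cd.size),
        "N_OT": float(idx_ot.size),
    }
    g = np.array(
        [
            gnow_from_counts(a, b, c, totals["N_OW"], totals["N_CD"], totals["N_OT"])
            for a, b, c in zip(n_ow, n_cd, n_ot)
        ]
    )
    return ShellProfile(
        shell_edges=shells,
        n_ow=n_ow,
        n_cd=n_cd,
        n_ot=n_ot,
        totals=totals,
        g_now=g,
        frames_averaged=n_frames,
        cumulative=cumulative,
    )
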