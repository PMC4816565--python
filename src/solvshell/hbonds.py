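"""Geometric hydrogen-bond detection and species-pair censuses.

A hydrogen bond is scored between a flagged donor heavy atom D and an
acceptor heavy atom A when the (minimum-image) D–A distance is within
the distance cutoff and, when hydrogens are available, the H–D–A angle
of some hydrogen covalently attached to D is within the angle cutoff.
The defaults, 3.5 Å and 30°, are the conventional geometric criterion.
For hydrogen-less structures (crystal coordinates, united-atom role
fixtures) the angle test is skipped and the distance criterion alone
applies.

Bonds are classified by the species of the two partners' molecules —
protein (labelled CRL), DMF, trehalose, water — into the pair classes
the census tabulates: CRL-CRL, CRL-DMF, CRL-Tre, DMF-Tre and "other".

An optional empirical per-bond energy estimator maps geometry onto a
kJ/mol scale.  It is a 12-10 well with an angular cos² weight,

    E(d, θ) = E0 · (5 (d0/d)^12 − 6 (d0/d)^10) · cos²θ,   d0 = 2.8 Å,
    E0 = 28 kJ/mol,

reported as a positive magnitude.  It is a reproduction aid for
tabulating bond strengths on a conventional scale, not a force-field
energy; the well peaks at d0 and decays monotonically beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import WindowError
from .geometry import minimum_image
from .structure_io import SpeciesMap, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "HBondCensus",
    "PAIR_CLASSES",
    "detect_hbonds",
    "census",
    "hbond_energy",
]

PAIR_CLASSES = ("CRL-CRL", "CRL-DMF", "CRL-Tre", "DMF-Tre", "other")

_SPECIES_LABEL = {
    "protein": "CRL",
    "dmf": "DMF",
    "trehalose": "Tre",
    "water": "W",
    "ion": "ion",
}

_CLASS_BY_PAIR = {
    frozenset(["CRL"]): "CRL-CRL",
    frozenset(["CRL", "DMF"]): "CRL-DMF",
    frozenset(["CRL", "Tre"]): "CRL-Tre",
    frozenset(["DMF", "Tre"]): "DMF-Tre",
}


@dataclass
class HBondCriteria:
    """Geometric cutoffs: donor–acceptor distance (Å), H–D–A angle (deg)."""

    distance_cutoff: float = 3.5
    angle_cutoff: float = 30.0
    use_hydrogens: bool = True
    weak_cd_donors: bool = False  # opt-in C-H donors (e.g. DMF methyls)

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_cutoff > 90:
            raise ValueError("angle cutoff must be <= 90 degrees")


@dataclass
class HBondRecord:
    donor: int
    acceptor: int
    distance: float
    angle: float | None
    pair_class: str
    hydrogen: int | None = None


@dataclass
class HBondCensus:
    """Per-frame pair-class counts with mean ± SD over the window."""

    per_frame: pd.DataFrame  # columns: frame plus one per pair class
    mean: dict[str, float]
    sd: dict[str, float]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_class": list(self.mean),
                "mean": list(self.mean.values()),
                "sd": [self.sd[c] for c in self.mean],
            }
        )


def _pair_class(species_a: str, species_b: str) -> str:
    la = _SPECIES_LABEL.get(species_a, "other")
    lb = _SPECIES_LABEL.get(species_b, "other")
    return _CLASS_BY_PAIR.get(frozenset([la, lb]), "other")


def _covalent_adjacency(structure: Structure) -> list[set[int]]:
    """Bonded-neighbour sets by distance (heavy-heavy <1.8 Å, X-H <1.25 Å)."""
    coords = structure.coordinates
    is_h = np.array([str(e).upper() == "H" for e in structure.elements])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=1.8, output_type="ndarray")
    adj: list[set[int]] = [set() for _ in range(structure.n_atoms)]
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        limit = 1.25 if (is_h[i] or is_h[j]) else 1.8
        if d <= limit:
            adj[i].add(int(j))
            adj[j].add(int(i))
    return adj


def _topologically_close(adj: list[set[int]], i: int, j: int) -> bool:
    """True for 1-2 and 1-3 neighbours (share a bond or a bonded atom)."""
    if j in adj[i]:
        return True
    return bool(adj[i] & adj[j])


def detect_hbonds(
    structure: Structure,
    species: SpeciesMap,
    criteria: HBondCriteria | None = None,
    coordinates: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> list[HBondRecord]:
    """All donor–acceptor pairs satisfying the geometric criteria.

    ``coordinates`` overrides the structure's own coordinates (used by
    :func:`census` to evaluate trajectory frames); ``box`` enables
    minimum-image distances.  Pairs that are covalently 1-2 or 1-3
    bonded are excluded, as are donor==acceptor self-pairs.  If the
    species map flags no donors or no acceptors the result is empty
    (with a warning), not an error.
    """
    criteria = criteria or HBondCriteria()
    coords = structure.coordinates if coordinates is None else np.asarray(coordinates, dtype=float)
    if box is None:
        box = structure.box

    donor_mask = species.is_hbond_donor.copy()
    if criteria.weak_cd_donors:
        # C-H weak donors: any carbon with an attached hydrogen
        donor_mask |= np.array(
            [str(e).upper() == "C" for e in structure.elements]
        ) & _has_attached_h(structure, coords)
    donors = np.flatnonzero(donor_mask)
    acceptors = np.flatnonzero(species.is_hbond_acceptor)
    if donors.size == 0 or acceptors.size == 0:
        warnings.warn("no donors or no acceptors flagged; empty hydrogen-bond set")
        return []

    adj = _covalent_adjacency(structure.with_coordinates(coords) if coordinates is not None else structure)
    h_idx = np.flatnonzero(species.is_polar_hydrogen)
    have_h = criteria.use_hydrogens and h_idx.size > 0
    h_by_donor: dict[int, list[int]] = {}
    if have_h:
        for h in h_idx:
            for nb in adj[h]:
                h_by_donor.setdefault(nb, []).append(int(h))

    # neighbour search among acceptors around each donor
    if box is not None:
        boxa = np.asarray(box, dtype=float)
        acc_w = np.mod(coords[acceptors], boxa)
        acc_w[acc_w == boxa] = 0.0
        don_w = np.mod(coords[donors], boxa)
        don_w[don_w == boxa] = 0.0
        tree = cKDTree(acc_w, boxsize=boxa)
        neighbour_lists = tree.query_ball_point(don_w, r=criteria.distance_cutoff)
    else:
        tree = cKDTree(coords[acceptors])
        neighbour_lists = tree.query_ball_point(coords[donors], r=criteria.distance_cutoff)

    records: list[HBondRecord] = []
    for di, neighbours in zip(donors, neighbour_lists):
        for aj in neighbours:
            ai = int(acceptors[aj])
            di = int(di)
            if ai == di or _topologically_close(adj, di, ai):
                continue
            delta = minimum_image(coords[ai] - coords[di], box)
            dist = float(np.linalg.norm(delta))
            if dist > criteria.distance_cutoff or dist < 1e-6:
                continue
            angle: float | None = None
            hydrogen: int | None = None
            if have_h:
                attached = h_by_donor.get(di, [])
                if attached:
                    best = None
                    for h in attached:
                        dh = minimum_image(coords[h] - coords[di], box)
                        cosang = np.dot(dh, delta) / (
                            np.linalg.norm(dh) * dist
                        )
                        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                        if best is None or ang < best[0]:
                            best = (ang, h)
                    angle, hydrogen = best
                    if angle > criteria.angle_cutoff:
                        continue
                # donors without an explicit H fall back to distance-only
            records.append(
                HBondRecord(
                    donor=di,
                    acceptor=ai,
                    distance=dist,
                    angle=angle,
                    pair_class=_pair_class(
                        str(species.species[di]), str(species.species[ai])
                    ),
                    hydrogen=hydrogen,
                )
            )
    return records


def _has_attached_h(structure: Structure, coords: np.ndarray) -> np.ndarray:
    is_h = np.array([str(e).upper() == "H" for e in structure.elements])
    out = np.zeros(structure.n_atoms, dtype=bool)
    if not np.any(is_h):
        return out
    tree = cKDTree(coords[is_h])
    d, _ = tree.query(coords, k=1)
    out = d <= 1.25
    out[is_h] = False
    return out


def census(
    traj: Trajectory,
    species: SpeciesMap,
    criteria: HBondCriteria | None = None,
    window: tuple[float, float] | None = None,
    last_fraction: float | None = None,
    backbone_only_protein: bool = False,
) -> HBondCensus:
    """Per-frame hydrogen-bond counts by pair class, with mean ± SD.

    The SD is the population standard deviation over frames (a single
    frame therefore has SD 0 in every class).  With
    ``backbone_only_protein`` the intra-protein (CRL-CRL) class counts
    only backbone–backbone bonds (amide N donors to carbonyl O
    acceptors) — the secondary-structure census — instead of all
    protein–protein bonds.
    """
    idx = traj.window_indices(window=window, last_fraction=last_fraction)
    if idx.size == 0:
        raise WindowError("empty census window")
    backbone = np.array(
        [str(n).upper() in {"N", "O", "OXT"} for n in traj.parent.names]
    )
    rows = []
    for k in idx:
        bonds = detect_hbonds(
            traj.parent,
            species,
            criteria,
            coordinates=traj.frames[k],
            box=traj.frame_box(k),
        )
        counts = dict.fromkeys(PAIR_CLASSES, 0)
        for b in bonds:
            if (
                backbone_only_protein
                and b.pair_class == "CRL-CRL"
                and not (backbone[b.donor] and backbone[b.acceptor])
            ):
                continue
            counts[b.pair_class] += 1
        counts["frame"] = int(k)
        rows.append(counts)
    per_frame = pd.DataFrame(rows)[["frame", *PAIR_CLASSES]]
    mean = {c: float(per_frame[c].mean()) for c in PAIR_CLASSES}
    sd = {c: float(per_frame[c].std(ddof=0)) for c in PAIR_CLASSES}
    return HBondCensus(per_frame=per_frame, mean=mean, sd=sd)


def hbond_energy(
    record: HBondRecord,
    e0: float = 28.0,
    d0: float = 2.8,
) -> float:
    """Empirical bond-strength magnitude (kJ/mol) from distance and angle.

    12-10 well times cos² of the H–D–A angle (1 when no hydrogen was
    resolved), reported positive; maximal at ideal geometry (d = d0,
    θ = 0) and monotonically decreasing with distance beyond d0.
    Distances outside [2.0, 4.5] Å are outside the estimator's
    calibration and trigger a warning.
    """
    d = record.distance
    if not 2.0 <= d <= 4.5:
        warnings.warn(
            f"donor-acceptor distance {d:.2f} Å outside the estimator's "
            "calibrated range [2.0, 4.5] Å"
        )
    x = d0 / d
    well = -(5.0 * x**12 - 6.0 * x**10)  # depth 1 at d = d0
    theta = 0.0 if record.angle is None else np.radians(record.angle)
    return float(e0 * max(well, 0.0) * np.cos(theta) ** 2)
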