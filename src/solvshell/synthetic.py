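"""Synthetic systems with planted ground truth.

Everything the analysis pipeline consumes can be generated here with
known answers: toy poly-alanine proteins, solvated ternary boxes whose
per-species radial density profile around the protein is controlled
(planting preferential hydration or exclusion), trajectories with
controlled rigid-body motion / jitter / drift, hydrogen-bond fixtures
with exact per-class bond counts, and noisy two-state fluorescence
curves with known ΔG° and m-value.

The generators provide statistical, not physical, ground truth: no
force field, no excluded volume between solvent atoms, no equilibration.
Solvent species are represented by their counted role atoms only (one O
per water, one carbonyl C per DMF, 8 hydroxyl O per trehalose on a
rigid ring template).  All randomness flows from an explicit seed and
outputs are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FeasibilityError, PackingError, ValidationError
from .geometry import min_distance_to_set
from .structure_io import Atom, Structure, Trajectory
from .thermo import DEFAULT_TEMPERATURE, R_GAS, UnfoldingCurve

__all__ = [
    "SpeciesDensity",
    "SolvationProfileSpec",
    "TwoStateSpec",
    "make_toy_protein",
    "solvate_with_profile",
    "make_trajectory",
    "resample_solvent_frames",
    "make_hbond_fixture",
    "simulate_fluorescence_curve",
]

#: Pure-water oxygen number density at ambient conditions, atoms/Å^3.
WATER_OXYGEN_DENSITY = 0.0334
#: Molecules/Å^3 per mol/L (Avogadro / 1e27 Å^3 per litre).
MOLAR_TO_PER_A3 = 6.02214076e-4


@dataclass
class SpeciesDensity:
    """Bulk molecule density (molecules/Å^3) and near-protein enrichment.

    ``enrichment`` multiplies the density at minimum distances to the
    protein below ``d_shell``; 1.0 means bulk-like everywhere.
    """

    density: float
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.density < 0 or self.enrichment < 0:
            raise ValidationError("densities and enrichment factors must be >= 0")


@dataclass
class SolvationProfileSpec:
    """Recipe for a solvated box with a controlled radial profile.

    The enrichment function is piecewise constant: factor ``e_s`` for
    minimum distance d <= ``d_shell`` (default 4 Å), 1 beyond.  No
    solvent is placed within ``r_excl`` (default 2 Å) of any protein
    atom.
    """

    water: SpeciesDensity
    dmf: SpeciesDensity = field(default_factory=lambda: SpeciesDensity(0.0))
    trehalose: SpeciesDensity = field(default_factory=lambda: SpeciesDensity(0.0))
    box_edge: float = 60.0
    d_shell: float = 4.0
    r_excl: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValidationError("box edge must be positive")
        if not self.r_excl < self.d_shell:
            raise ValidationError("r_excl must be smaller than d_shell")


@dataclass
class TwoStateSpec:
    """Recipe for a synthetic two-state fluorescence curve.

    The defaults describe a well-conditioned titration over the 0-40 %
    v/v denaturant range: midpoint at 20 % and both baselines several
    noise SDs away from the anchors, so the log-transformed signal is
    informative at every grid point.
    """

    delta_g0: float = 5.0  # kJ/mol, stability in water
    m_value: float = 0.25  # kJ/mol per % v/v
    f_n: float = 100.0
    f_d: float = 300.0
    temperature: float = DEFAULT_TEMPERATURE
    noise_sd: float = 0.0
    c_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 41.0, 5.0))
    trehalose_molar: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        if self.m_value <= 0:
            raise ValidationError("m-value must be positive for a denaturant")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")
        if self.c_grid.size == 0:
            raise ValidationError("concentration grid must be non-empty")
        if np.unique(self.c_grid).size < 2 and self.c_grid.size > 1:
            raise ValidationError("concentration grid holds only duplicates")


# ---------------------------------------------------------------------------
# Toy protein
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Å (Cα helix radius)
_EXTENDED_STEP = 3.5  # Å per residue


def make_toy_protein(n_residues: int, geometry: str = "helix") -> Structure:
    """Ideal poly-alanine backbone (N, CA, C, O per residue).

    ``helix`` uses the ideal α-helix geometry (1.5 Å rise, 100°/residue
    twist); ``extended`` a straight 3.5 Å/residue chain.  Donor (N) and
    acceptor (O) atoms are assignable by the default species rules.
    """
    if n_residues < 4:
        raise ValidationError("need at least 4 residues for a sensible backbone")
    if geometry not in {"helix", "extended"}:
        raise ValidationError("geometry must be 'helix' or 'extended'")
    atoms: list[Atom] = []
    serial = 1
    # backbone atom offsets relative to the residue's Cα, chosen small
    # enough to keep ideal-geometry spacing; chemically crude but the
    # metrics under test only need masses, names and positions.
    offsets = {
        "N": np.array([-1.20, 0.50, -0.40]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.25, 0.45, 0.35]),
        "O": np.array([1.60, 1.60, 0.55]),
    }
    for i in range(n_residues):
        if geometry == "helix":
            theta = np.radians(_HELIX_TWIST * i)
            ca = np.array(
                [
                    _HELIX_RADIUS * np.cos(theta),
                    _HELIX_RADIUS * np.sin(theta),
                    _HELIX_RISE * i,
                ]
            )
        else:
            ca = np.array([_EXTENDED_STEP * i, 0.3 * (-1) ** i, 0.0])
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ALA",
                    residue_index=i + 1,
                    coordinates=ca + offsets[name],
                    chain_id="A",
                )
            )
            serial += 1
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Solvated boxes with controlled radial profiles
# ---------------------------------------------------------------------------

#: Rigid template of the 8 hydroxyl oxygens of a trehalose molecule:
#: two rings of four, mimicking the O2/O3/O4/O6 positions of the two
#: glucose units (only the counted role atoms are represented).
def _trehalose_oh_template() -> tuple[list[str], np.ndarray]:
    names = ["O2", "O3", "O4", "O6", "O2'", "O3'", "O4'", "O6'"]
    ring1 = np.array(
        [
            [1.4 * np.cos(a), 1.4 * np.sin(a), -1.2]
            for a in np.radians([0.0, 90.0, 180.0, 270.0])
        ]
    )
    ring2 = np.array(
        [
            [1.4 * np.cos(a), 1.4 * np.sin(a), 1.2]
            for a in np.radians([45.0, 135.0, 225.0, 315.0])
        ]
    )
    return names, np.vstack([ring1, ring2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _sample_species_positions(
    rng: np.random.Generator,
    density: SpeciesDensity,
    box: np.ndarray,
    protein_coords: np.ndarray,
    d_shell: float,
    r_excl: float,
) -> np.ndarray:
    """Inhomogeneous Poisson placement by thinning a homogeneous field.

    Candidate points are drawn at the majorising rate density*max(e,1)
    and accepted with probability e(d)/max(e,1), where e(d) is the
    enrichment factor at the candidate's minimum distance to the
    protein; candidates within r_excl are rejected outright.
    """
    if density.density == 0:
        return np.empty((0, 3))
    volume = float(np.prod(box))
    rate = density.density * max(density.enrichment, 1.0)
    n_candidates = rng.poisson(rate * volume)
    if n_candidates == 0:
        return np.empty((0, 3))
    pts = rng.uniform(0.0, 1.0, size=(n_candidates, 3)) * box
    d = min_distance_to_set(pts, protein_coords, box)
    factor = np.where(d <= d_shell, density.enrichment, 1.0)
    accept_p = factor / max(density.enrichment, 1.0)
    keep = (d >= r_excl) & (rng.uniform(size=n_candidates) < accept_p)
    return pts[keep]


def _check_realised_counts(
    name: str,
    placed_d: np.ndarray,
    density: SpeciesDensity,
    shell_volume: float,
    bulk_volume: float,
    d_shell: float,
) -> None:
    """Realised near/bulk counts must sit within 4 Poisson SDs of target."""
    expected_near = density.density * density.enrichment * shell_volume
    expected_bulk = density.density * bulk_volume
    near = int(np.sum(placed_d <= d_shell))
    bulk = int(np.sum(placed_d > d_shell))
    for label, got, exp in (("near", near, expected_near), ("bulk", bulk, expected_bulk)):
        if exp == 0:
            if got != 0:
                raise FeasibilityError(
                    f"{name}: {got} atoms in a region with zero expected density"
                )
            continue
        if abs(got - exp) > 4.0 * np.sqrt(exp):
            raise FeasibilityError(
                f"{name} ({label} region): realised count {got} deviates from "
                f"expectation {exp:.1f} by more than 4 Poisson SDs"
            )


def solvate_with_profile(
    protein: Structure, spec: SolvationProfileSpec
) -> Structure:
    """Solvate a protein in a cubic box with planted radial density profiles.

    The protein is centred in the box; water oxygens, DMF carbonyl
    carbons and trehalose hydroxyl-oxygen templates are placed by
    inhomogeneous Poisson sampling honouring each species' enrichment
    factor inside ``d_shell`` and the hard exclusion radius ``r_excl``.
    Realised per-region counts are checked against their Poisson
    expectation at generation time.
    """
    box = np.array([spec.box_edge] * 3)
    prot_coords = protein.coordinates
    extent = prot_coords.max(axis=0) - prot_coords.min(axis=0)
    if np.any(extent + 2 * spec.d_shell + 20.0 > spec.box_edge):
        raise FeasibilityError(
            f"protein extent {extent.round(1)} Å plus shell does not fit the "
            f"{spec.box_edge} Å box with a >10 Å margin per side"
        )
    centred = prot_coords - prot_coords.mean(axis=0) + box / 2.0

    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    serial = 1
    for at, xyz in zip(protein.atoms(), centred):
        at.serial = serial
        at.coordinates = xyz
        at.chain_id = "A"
        atoms.append(at)
        serial += 1

    # region volumes for the generation-time count check (Monte-Carlo
    # estimate of the shell volume, same rng stream -> deterministic)
    probe = rng.uniform(0.0, 1.0, size=(200000, 3)) * box
    probe_d = min_distance_to_set(probe, centred, box)
    volume = float(np.prod(box))
    shell_volume = volume * float(
        np.mean((probe_d > spec.r_excl) & (probe_d <= spec.d_shell))
    )
    bulk_volume = volume * float(np.mean(probe_d > spec.d_shell))

    def add_atoms(
        positions: np.ndarray, resname: str, atom_names: list[str], element: str
    ) -> None:
        nonlocal serial
        res_index = 1 + (len({(a.chain_id, a.residue_index) for a in atoms if a.chain_id == "S"}))
        for pos_group in positions:
            for name, xyz in zip(atom_names, np.atleast_2d(pos_group)):
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name=resname,
                        residue_index=res_index,
                        coordinates=xyz,
                        chain_id="S",
                    )
                )
                serial += 1
            res_index += 1

    water_pts = _sample_species_positions(
        rng, spec.water, box, centred, spec.d_shell, spec.r_excl
    )
    _check_realised_counts(
        "water",
        min_distance_to_set(water_pts, centred, box) if len(water_pts) else np.empty(0),
        spec.water,
        shell_volume,
        bulk_volume,
        spec.d_shell,
    )
    add_atoms(water_pts[:, None, :], "SOL", ["OW"], "O")

    dmf_pts = _sample_species_positions(
        rng, spec.dmf, box, centred, spec.d_shell, spec.r_excl
    )
    _check_realised_counts(
        "dmf",
        min_distance_to_set(dmf_pts, centred, box) if len(dmf_pts) else np.empty(0),
        spec.dmf,
        shell_volume,
        bulk_volume,
        spec.d_shell,
    )
    add_atoms(dmf_pts[:, None, :], "DMF", ["C"], "C")

    tre_pts = _sample_species_positions(
        rng, spec.trehalose, box, centred, spec.d_shell, spec.r_excl
    )
    _check_realised_counts(
        "trehalose",
        min_distance_to_set(tre_pts, centred, box) if len(tre_pts) else np.empty(0),
        spec.trehalose,
        shell_volume,
        bulk_volume,
        spec.d_shell,
    )
    oh_names, oh_template = _trehalose_oh_template()
    tre_groups = []
    for centre in tre_pts:
        rot = _random_rotation(rng)
        tre_groups.append(centre + oh_template @ rot.T)
    if tre_groups:
        add_atoms(np.array(tre_groups), "TRE", oh_names, "O")

    return Structure(atoms, box=box)


def _sample_exact_positions(
    rng: np.random.Generator,
    n: int,
    enrichment: float,
    box: np.ndarray,
    protein_coords: np.ndarray,
    d_shell: float,
    r_excl: float,
) -> np.ndarray:
    """Exactly ``n`` i.i.d. positions from the normalised profile density.

    Conditional on its count, an inhomogeneous Poisson sample is i.i.d.
    from the normalised intensity, so rejection sampling until ``n``
    acceptances reproduces the profile exactly.
    """
    if n == 0:
        return np.empty((0, 3))
    out: list[np.ndarray] = []
    needed = n
    e_max = max(enrichment, 1.0)
    while needed > 0:
        batch = max(4 * needed, 256)
        pts = rng.uniform(0.0, 1.0, size=(batch, 3)) * box
        d = min_distance_to_set(pts, protein_coords, box)
        factor = np.where(d <= d_shell, enrichment, 1.0)
        keep = (d >= r_excl) & (rng.uniform(size=batch) < factor / e_max)
        accepted = pts[keep]
        out.append(accepted[:needed])
        needed -= min(len(accepted), needed)
    return np.vstack(out)


def resample_solvent_frames(
    system: Structure,
    spec: SolvationProfileSpec,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """Frames whose solvent is re-drawn from the planted profile each frame.

    Emulates trajectory snapshots saved far enough apart in time that
    the solvent has fully decorrelated (diffusive limit): the protein
    stays fixed while every water, DMF and trehalose molecule is placed
    afresh from the same radial profile, keeping atom counts congruent
    with ``system`` (which must come from :func:`solvate_with_profile`
    with the same ``spec``).  Frame 0 is the input configuration.
    """
    if n_frames < 1:
        raise ValidationError("need at least 1 frame")
    rng = np.random.default_rng(seed)
    resnames = np.array([str(r) for r in system.residue_names], dtype=object)
    prot_idx = np.flatnonzero(~np.isin(resnames, ("SOL", "DMF", "TRE")))
    wat_idx = np.flatnonzero(resnames == "SOL")
    dmf_idx = np.flatnonzero(resnames == "DMF")
    tre_idx = np.flatnonzero(resnames == "TRE")
    if tre_idx.size % 8 != 0:
        raise ValidationError("trehalose atoms must come in 8-oxygen templates")
    n_tre = tre_idx.size // 8
    prot = system.coordinates[prot_idx]
    box = system.box
    _, oh_template = _trehalose_oh_template()

    frames = np.empty((n_frames, system.n_atoms, 3))
    frames[0] = system.coordinates
    for k in range(1, n_frames):
        coords = system.coordinates.copy()
        coords[wat_idx] = _sample_exact_positions(
            rng, wat_idx.size, spec.water.enrichment, box, prot, spec.d_shell, spec.r_excl
        )
        coords[dmf_idx] = _sample_exact_positions(
            rng, dmf_idx.size, spec.dmf.enrichment, box, prot, spec.d_shell, spec.r_excl
        )
        if n_tre:
            centres = _sample_exact_positions(
                rng, n_tre, spec.trehalose.enrichment, box, prot, spec.d_shell, spec.r_excl
            )
            groups = np.array(
                [c + oh_template @ _random_rotation(rng).T for c in centres]
            )
            coords[tre_idx] = groups.reshape(-1, 3)
        frames[k] = coords
    return Trajectory(system, frames, times=np.arange(n_frames, dtype=float))


# ---------------------------------------------------------------------------
# Trajectories with controlled motion
# ---------------------------------------------------------------------------

def make_trajectory(
    base: Structure,
    motion: str = "static",
    n_frames: int = 1,
    seed: int = 0,
    sigma: float = 0.5,
    rate: float = 0.01,
    dt: float = 1.0,
) -> Trajectory:
    """Trajectory of ``n_frames`` frames with a prescribed motion model.

    * ``static``  — identical frames;
    * ``rigid``   — a random proper rotation + translation per frame
      (superposed metrics must see zero deviation);
    * ``jitter``  — i.i.d. Gaussian displacement, SD ``sigma`` Å per
      coordinate, about the base positions (frame 0 is unperturbed);
    * ``drift``   — coordinates scaled about their centroid by
      (1 + rate·t), forcing exactly proportional Rg growth.
    """
    if n_frames < 1:
        raise ValidationError("need at least 1 frame")
    if sigma < 0 or rate < 0:
        raise ValidationError("sigma and rate must be >= 0")
    rng = np.random.default_rng(seed)
    coords = base.coordinates
    frames = np.empty((n_frames, base.n_atoms, 3))
    if motion == "static":
        frames[:] = coords
    elif motion == "rigid":
        frames[0] = coords
        centroid = coords.mean(axis=0)
        for k in range(1, n_frames):
            rot = _random_rotation(rng)
            shift = rng.uniform(-5.0, 5.0, size=3)
            frames[k] = (coords - centroid) @ rot.T + centroid + shift
    elif motion == "jitter":
        frames[0] = coords
        for k in range(1, n_frames):
            frames[k] = coords + rng.normal(scale=sigma, size=coords.shape)
    elif motion == "drift":
        centroid = coords.mean(axis=0)
        for k in range(n_frames):
            frames[k] = centroid + (coords - centroid) * (1.0 + rate * k)
    else:
        raise ValidationError(
            "motion must be one of 'static', 'rigid', 'jitter', 'drift'"
        )
    times = dt * np.arange(n_frames)
    return Trajectory(base, frames, times=times)


# ---------------------------------------------------------------------------
# Hydrogen-bond fixtures with exact planted counts
# ---------------------------------------------------------------------------

_FIXTURE_TEMPLATES = {
    # pair class -> (donor residue/name/element, acceptor residue/name/element)
    "CRL-CRL": (("ALA", "N", "N"), ("ALA", "O", "O")),
    "CRL-DMF": (("ALA", "N", "N"), ("DMF", "O", "O")),
    "CRL-Tre": (("ALA", "N", "N"), ("TRE", "O2", "O")),
    "DMF-Tre": (("TRE", "O2", "O"), ("DMF", "O", "O")),
}


def make_hbond_fixture(
    k_bonds: dict[str, int],
    n_decoys: int = 0,
    seed: int = 0,
    spacing: float = 10.0,
) -> Structure:
    """Structure containing exactly ``k_bonds[class]`` hydrogen bonds per class.

    Each planted bond is an isolated donor–H–acceptor triple at 2.8 Å
    donor–acceptor distance and 10° H–D–A angle, placed on a grid with
    ``spacing`` Å pitch so triples cannot cross-bond.  Decoys violate
    the default criteria alternately by distance (3.6 Å > cutoff at
    ideal angle is still < 3.5 — we use 4.0 Å) or by angle (60°).
    """
    unknown = set(k_bonds) - set(_FIXTURE_TEMPLATES)
    if unknown:
        raise ValidationError(f"unsupported pair classes: {sorted(unknown)}")
    if any(k < 0 for k in k_bonds.values()) or n_decoys < 0:
        raise ValidationError("counts must be >= 0")
    if spacing < 8.0:
        raise PackingError("triple spacing below 8 Å risks cross-bonds")

    rng = np.random.default_rng(seed)
    n_sites = sum(k_bonds.values()) + n_decoys
    side = int(np.ceil(n_sites ** (1.0 / 3.0))) if n_sites else 1
    grid = [
        np.array([i, j, k], dtype=float) * spacing + spacing / 2.0
        for i in range(side)
        for j in range(side)
        for k in range(side)
    ]

    atoms: list[Atom] = []
    serial = 1
    res_counter = {"ALA": 0, "DMF": 0, "TRE": 0}

    def add(resname: str, name: str, element: str, xyz: np.ndarray, res_index: int, chain: str) -> None:
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_index=res_index,
                coordinates=xyz,
                chain_id=chain,
            )
        )
        serial += 1

    def place_triple(pair_class: str, origin: np.ndarray, d_da: float, angle_deg: float) -> None:
        (d_res, d_name, d_el), (a_res, a_name, a_el) = _FIXTURE_TEMPLATES[pair_class]
        rot = _random_rotation(rng)
        donor = origin
        h_dir = rot @ np.array([1.0, 0.0, 0.0])
        theta = np.radians(angle_deg)
        a_dir = rot @ np.array([np.cos(theta), np.sin(theta), 0.0])
        res_counter[d_res] += 1
        d_chain = "A" if d_res == "ALA" else "S"
        add(d_res, d_name, d_el, donor, res_counter[d_res], d_chain)
        add(d_res, "H" if d_el == "N" else "HO2", "H", donor + 1.0 * h_dir, res_counter[d_res], d_chain)
        res_counter[a_res] += 1
        a_chain = "A" if a_res == "ALA" else "S"
        add(a_res, a_name, a_el, donor + d_da * a_dir, res_counter[a_res], a_chain)

    site = 0
    for pair_class in ("CRL-CRL", "CRL-DMF", "CRL-Tre", "DMF-Tre"):
        for _ in range(k_bonds.get(pair_class, 0)):
            place_triple(pair_class, grid[site], 2.8, 10.0)
            site += 1
    decoy_classes = list(_FIXTURE_TEMPLATES)
    for i in range(n_decoys):
        pair_class = decoy_classes[i % len(decoy_classes)]
        if i % 2 == 0:
            place_triple(pair_class, grid[site], 4.0, 10.0)  # distance violation
        else:
            place_triple(pair_class, grid[site], 2.8, 60.0)  # angle violation
        site += 1

    if not atoms:
        # k = 0 everywhere and no decoys: a lone water far from anything
        add("SOL", "OW", "O", grid[0], 1, "S")
    # one empty grid layer keeps periodic images of edge triples apart
    box_edge = max((side + 1) * spacing, 20.0)
    return Structure(atoms, box=np.array([box_edge] * 3))


# ---------------------------------------------------------------------------
# Two-state fluorescence curves
# ---------------------------------------------------------------------------

def simulate_fluorescence_curve(spec: TwoStateSpec) -> UnfoldingCurve:
    """Noisy two-state curve F(c) with planted (ΔG°, m).

    F(c) = F_N + (F_D − F_N) · f_D(c) + ε,  f_D = K/(1+K),
    K(c) = exp(−ΔG(c)/RT),  ΔG(c) = ΔG° − m·c.  With ``noise_sd`` 0 the
    curve inverts exactly back to the planted line.
    """
    rng = np.random.default_rng(spec.seed)
    dg = spec.delta_g0 - spec.m_value * spec.c_grid  # kJ/mol
    k = np.exp(-dg * 1000.0 / (R_GAS * spec.temperature))
    f_d_frac = k / (1.0 + k)
    f = spec.f_n + (spec.f_d - spec.f_n) * f_d_frac
    if spec.noise_sd > 0:
        f = f + rng.normal(scale=spec.noise_sd, size=f.shape)
    return UnfoldingCurve(
        dmf_pct=spec.c_grid.copy(),
        f_obs=f,
        f_n=spec.f_n,
        f_d=spec.f_d,
        temperature=spec.temperature,
        trehalose_molar=spec.trehalose_molar,
    )
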