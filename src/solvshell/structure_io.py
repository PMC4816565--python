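"""Structures, trajectories and species classification.

Containers for solvated protein systems (protein + water + DMF +
trehalose + ions) and readers/writers for the two text formats the
pipeline consumes: a PDB subset (ATOM/HETATM, MODEL/ENDMDL, CRYST1,
REMARK 2, TER, END) and XYZ trajectories whose comment line may carry a
``t= <ps>`` time stamp.  PDB parsing and writing are delegated to
:mod:`gemmi`; coordinates are kept in Å (PDB native) throughout.

Species classification maps residue names onto the five species the
downstream analyses distinguish (protein, water, DMF, trehalose, ion)
and flags the per-atom roles the solvation-shell statistics count:
water oxygens, DMF carbons and trehalose hydroxyl oxygens, plus
hydrogen-bond donor/acceptor roles.
"""

from __future__ import annotations

import io as _io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ClassificationError,
    CongruenceError,
    EmptyInputError,
    ParseError,
)

__all__ = [
    "Atom",
    "Structure",
    "SpeciesMap",
    "Trajectory",
    "DEFAULT_SPECIES_RULES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "classify_species",
    "count_residues",
]

#: Standard amino-acid residue names (protein species by default).
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER "
    "THR TRP TYR VAL MSE HSD HSE HSP HID HIE HIP".split()
)

#: Default residue-name -> species rules.  Users may override or extend
#: via the ``rules`` argument of :func:`classify_species` or a two-column
#: CSV (residue_name,species).
DEFAULT_SPECIES_RULES: dict[str, str] = {
    **{name: "protein" for name in AMINO_ACIDS},
    "HOH": "water",
    "SOL": "water",
    "WAT": "water",
    "DMF": "dmf",
    "TRE": "trehalose",
    "TRH": "trehalose",
    "NA": "ion",
    "CL": "ion",
    "K": "ion",
    "MG": "ion",
    "CA2": "ion",
    "SOD": "ion",
    "CLA": "ion",
}

_ELEMENT_RE = re.compile(r"[A-Za-z]")


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from a PDB atom name."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return "X"
    two = stripped[:2].capitalize()
    # Two-letter symbols only when unambiguous (Cl, Na, Mg, Fe, Zn ...);
    # protein atom names like "CA" (C-alpha) must map to carbon.
    if two in {"Cl", "Na", "Mg", "Fe", "Zn", "Mn", "Br"} and name.strip()[:2].isalpha():
        if name.strip().upper() in {"CA", "CB", "CD", "CE", "CG", "CZ", "NA"}:
            return stripped[0].upper()
        return two
    return stripped[0].upper()


def element_mass(element: str) -> float:
    """Atomic mass (u) of an element symbol, via gemmi's element table."""
    el = gemmi.Element(element)
    if el.weight <= 0:
        raise ValueError(f"unknown element {element!r}")
    return float(el.weight)


@dataclass
class Atom:
    """A single atom: identity, residue membership, position and mass."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    coordinates: np.ndarray
    mass: float | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be a finite 3-vector")
        if self.mass is None:
            self.mass = element_mass(self.element)
        if self.mass <= 0:
            raise ValueError("mass must be positive")


class Structure:
    """An ordered collection of atoms with optional periodic box.

    Stored internally as parallel numpy arrays for speed; :meth:`atoms`
    yields :class:`Atom` views for record-oriented access.

    Parameters
    ----------
    atoms:
        Iterable of :class:`Atom` in file order.
    box:
        Orthorhombic box edge lengths (3,) in Å, or None.
    metadata:
        Free-form dict; readers populate ``resolution`` (Å, from
        REMARK 2) and ``n_models`` when available.
    """

    def __init__(
        self,
        atoms: Iterable[Atom],
        box: Sequence[float] | None = None,
        metadata: dict | None = None,
    ) -> None:
        atoms = list(atoms)
        if not atoms:
            raise EmptyInputError("structure must contain at least one atom")
        self.serials = np.array([a.serial for a in atoms], dtype=int)
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_indices = np.array([a.residue_index for a in atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.coordinates = np.array([a.coordinates for a in atoms], dtype=float)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None:
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive edge lengths (Å)")
        self.metadata = dict(metadata or {})

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.serials)

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_index=int(self.residue_indices[i]),
            coordinates=self.coordinates[i].copy(),
            mass=float(self.masses[i]),
            chain_id=str(self.chain_ids[i]),
        )

    def atoms(self) -> Iterable[Atom]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    def residue_ids(self) -> np.ndarray:
        """Integer molecule/residue id per atom (chain+index unique)."""
        keys = [
            (c, int(r)) for c, r in zip(self.chain_ids, self.residue_indices)
        ]
        _, ids = np.unique(
            np.array([f"{c}|{r}" for c, r in keys], dtype=object), return_inverse=True
        )
        # np.unique sorts; re-map to order of first appearance for stability
        order: dict[int, int] = {}
        out = np.empty(len(ids), dtype=int)
        for i, u in enumerate(ids):
            if u not in order:
                order[u] = len(order)
            out[i] = order[u]
        return out

    def select(self, mask: np.ndarray) -> "Structure":
        """Sub-structure of atoms where ``mask`` is True (file order kept)."""
        idx = np.flatnonzero(np.asarray(mask))
        if idx.size == 0:
            raise EmptyInputError("selection is empty")
        return Structure([self.atom(int(i)) for i in idx], box=self.box,
                         metadata=self.metadata)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        out = Structure(list(self.atoms()), box=self.box, metadata=self.metadata)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != out.coordinates.shape:
            raise CongruenceError("coordinate array shape mismatch")
        out.coordinates = coords.copy()
        return out


@dataclass
class SpeciesMap:
    """Per-atom species labels and role flags for a :class:`Structure`.

    ``species`` holds one of {"protein", "water", "dmf", "trehalose",
    "ion"} per atom; the boolean arrays flag the role atoms the
    solvation and hydrogen-bond analyses count.
    """

    species: np.ndarray
    is_water_oxygen: np.ndarray
    is_dmf_carbon: np.ndarray
    is_trehalose_hydroxyl_oxygen: np.ndarray
    is_hbond_donor: np.ndarray
    is_hbond_acceptor: np.ndarray
    is_polar_hydrogen: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.species)
        for name in (
            "is_water_oxygen",
            "is_dmf_carbon",
            "is_trehalose_hydroxyl_oxygen",
            "is_hbond_donor",
            "is_hbond_acceptor",
            "is_polar_hydrogen",
        ):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != (n,):
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)

    def counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.species, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))


class Trajectory:
    """Ordered coordinate frames congruent with a parent :class:`Structure`."""

    def __init__(
        self,
        parent: Structure,
        frames: np.ndarray,
        times: Sequence[float] | None = None,
        box: np.ndarray | None = None,
    ) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != parent.n_atoms or frames.shape[2] != 3:
            raise CongruenceError(
                f"frames must have shape (n_frames, {parent.n_atoms}, 3); "
                f"got {frames.shape}"
            )
        self.parent = parent
        self.frames = frames
        if times is None:
            times = np.arange(frames.shape[0], dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.times.shape != (frames.shape[0],):
            raise CongruenceError("times length must equal number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if box is None:
            box = parent.box
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.shape == (3,):
                box = np.tile(box, (frames.shape[0], 1))
            if box.shape != (frames.shape[0], 3):
                raise CongruenceError("box must be (3,) or (n_frames, 3)")
        self.box = box

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_box(self, i: int) -> np.ndarray | None:
        return None if self.box is None else self.box[i]

    def window_indices(
        self,
        window: tuple[float, float] | None = None,
        last_fraction: float | None = None,
    ) -> np.ndarray:
        """Frame indices inside a (t_start, t_end] time window.

        Exactly one of ``window`` (ps) or ``last_fraction`` (final
        fraction of frames) may be given; None selects all frames.
        """
        from .errors import WindowError

        if window is not None and last_fraction is not None:
            raise WindowError("give either a time window or a fraction, not both")
        if window is not None:
            t0, t1 = window
            idx = np.flatnonzero((self.times >= t0) & (self.times <= t1))
            if idx.size == 0:
                raise WindowError(
                    f"window [{t0}, {t1}] ps outside trajectory times "
                    f"[{self.times[0]}, {self.times[-1]}] ps"
                )
            return idx
        if last_fraction is not None:
            if not 0 < last_fraction <= 1:
                raise WindowError("last_fraction must be in (0, 1]")
            start = int(np.ceil((1 - last_fraction) * self.n_frames))
            return np.arange(min(start, self.n_frames - 1), self.n_frames)
        return np.arange(self.n_frames)


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _looks_like_path(source: str) -> bool:
    return "\n" not in source and os.path.exists(source)


def _gemmi_structure(text: str) -> gemmi.Structure:
    try:
        return gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise ParseError(str(exc)) from exc


def _atoms_from_model(model: gemmi.Model) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                element = at.element.name if at.element.name != "X" else _element_from_name(at.name)
                mass = gemmi.Element(element).weight
                if mass <= 0:
                    element = _element_from_name(at.name)
                    mass = gemmi.Element(element).weight
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=element,
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        coordinates=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        mass=float(mass) if mass > 0 else None,
                        chain_id=chain.name or "A",
                    )
                )
    return atoms


def read_structure(source: str) -> Structure:
    """Read a PDB-format file path or text into a :class:`Structure`.

    The first MODEL is returned for multi-model files; the model count
    is stored in ``metadata["n_models"]``.  CRYST1 becomes the periodic
    box (orthorhombic edges); REMARK 2 resolution, when present, is kept
    as ``metadata["resolution"]`` in Å.
    """
    text = open(source).read() if _looks_like_path(source) else source
    st = _gemmi_structure(text)
    if len(st) == 0:
        raise EmptyInputError("no models / atoms found in PDB input")
    atoms = _atoms_from_model(st[0])
    if not atoms:
        raise EmptyInputError("no ATOM/HETATM records found")
    box = None
    cell = st.cell
    if cell and cell.a > 1.0 and cell.b > 1.0 and cell.c > 1.0:
        box = np.array([cell.a, cell.b, cell.c])
    metadata: dict = {"n_models": len(st)}
    if st.resolution and st.resolution > 0:
        metadata["resolution"] = float(st.resolution)
    return Structure(atoms, box=box, metadata=metadata)


def write_structure(structure: Structure, path: str | None = None) -> str:
    """Write a :class:`Structure` as PDB text; return the text.

    Coordinates are printed at PDB precision (1e-3 Å); CRYST1 is
    emitted when the structure has a box.
    """
    st = gemmi.Structure()
    st.name = "solvshell"
    if structure.box is not None:
        a, b, c = structure.box
        st.cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
        st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple[int, str] | None] = {}
    for at in structure.atoms():
        if at.chain_id not in chains:
            chains[at.chain_id] = gemmi.Chain(at.chain_id)
            current[at.chain_id] = None
        chain = chains[at.chain_id]
        key = (at.residue_index, at.residue_name)
        if current[at.chain_id] != key:
            res = gemmi.Residue()
            res.name = at.residue_name
            res.seqid = gemmi.SeqId(at.residue_index, " ")
            res.het_flag = "A" if at.residue_name in AMINO_ACIDS else "H"
            chain.add_residue(res)
            current[at.chain_id] = key
        g_at = gemmi.Atom()
        g_at.name = at.name
        g_at.element = gemmi.Element(at.element)
        g_at.pos = gemmi.Position(*at.coordinates)
        g_at.serial = at.serial
        g_at.occ = 1.0
        g_at.b_iso = 0.0
        chain[-1].add_atom(g_at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Trajectory reading / writing
# ---------------------------------------------------------------------------

_XYZ_TIME_RE = re.compile(r"t\s*=\s*([0-9.eE+-]+)")


def _read_xyz_frames(text: str, n_atoms: int):
    lines = text.splitlines()
    frames: list[np.ndarray] = []
    times: list[float | None] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count") from exc
        if count != n_atoms:
            raise CongruenceError(
                f"frame {frame_no}: {count} atoms, parent structure has {n_atoms}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _XYZ_TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else None)
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise ParseError(f"frame {frame_no}: truncated coordinate block")
        coords = np.empty((count, 3))
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: expected 'element x y z'")
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"line {i + 3 + j}: bad coordinate field") from exc
        frames.append(coords)
        i += 2 + count
        frame_no += 1
    return frames, times


def read_trajectory(source: str, parent: Structure) -> Trajectory:
    """Read an XYZ or multi-model PDB trajectory congruent with ``parent``.

    Frame times come from ``t= <ps>`` comment annotations when every
    frame has one; otherwise they default to 0, 1, 2, ... ps.
    """
    text = open(source).read() if _looks_like_path(source) else source
    stripped = text.lstrip()
    first = stripped.splitlines()[0] if stripped else ""
    if first[:6] in {"MODEL ", "ATOM  ", "HETATM", "CRYST1", "REMARK", "HEADER"} or first.startswith("MODEL"):
        st = _gemmi_structure(text)
        frames = []
        for k, model in enumerate(st):
            atoms = _atoms_from_model(model)
            if len(atoms) != parent.n_atoms:
                raise CongruenceError(
                    f"frame {k}: {len(atoms)} atoms, parent has {parent.n_atoms}"
                )
            frames.append(np.array([a.coordinates for a in atoms]))
        if not frames:
            raise EmptyInputError("no models in trajectory input")
        return Trajectory(parent, np.array(frames))
    frames, times = _read_xyz_frames(text, parent.n_atoms)
    if not frames:
        raise EmptyInputError("no frames in trajectory input")
    if all(t is not None for t in times):
        times_arr = np.array(times, dtype=float)
    else:
        times_arr = np.arange(len(frames), dtype=float)
    return Trajectory(parent, np.array(frames), times=times_arr)


def write_trajectory(traj: Trajectory, path: str | None = None, precision: int = 6) -> str:
    """Write a trajectory as XYZ text with ``t=`` time comments."""
    parent = traj.parent
    out = _io.StringIO()
    for k in range(traj.n_frames):
        out.write(f"{parent.n_atoms}\n")
        out.write(f"frame {k} t= {traj.times[k]:.6f} ps\n")
        for el, xyz in zip(parent.elements, traj.frames[k]):
            out.write(
                f"{el} {xyz[0]:.{precision}f} {xyz[1]:.{precision}f} {xyz[2]:.{precision}f}\n"
            )
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Species classification
# ---------------------------------------------------------------------------

#: Trehalose oxygens carrying a hydroxyl by standard glucopyranose naming:
#: O2/O3/O4/O6 on each ring (primes or residue-local suffixes allowed);
#: ring O5 and the glycosidic O1 are excluded.
_TREHALOSE_HYDROXYL_RE = re.compile(r"^O[2346]['B12]?$")

#: Heavy-atom donors per residue template (crystal structures lack H).
_PROTEIN_DONOR_NAMES = {
    "N", "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2", "NZ",
    "OG", "OG1", "OH", "SG",
}
_PROTEIN_ACCEPTOR_NAMES = {
    "O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
    "ND1", "NE2", "SD",
}


def load_species_rules(path: str) -> dict[str, str]:
    """Read a residue_name,species CSV into a rules mapping."""
    rules: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("residue_name"):
                continue
            resname, species = [p.strip() for p in line.split(",")[:2]]
            rules[resname.upper()] = species.lower()
    return rules


def classify_species(
    structure: Structure,
    rules: Mapping[str, str] | None = None,
    strict: bool = True,
    dmf_carbon: str = "carbonyl",
) -> SpeciesMap:
    """Assign one species per atom and flag analysis roles.

    Parameters
    ----------
    rules:
        residue-name -> species overrides merged over the defaults.
    strict:
        If True, unknown residue names raise
        :class:`~solvshell.errors.ClassificationError`; otherwise they
        are labelled "ion" (inert for every analysis here).
    dmf_carbon:
        "carbonyl" counts only the formyl carbon of each DMF molecule
        (atom named C or C1), keeping one counted atom per molecule as
        for water oxygen; "all" counts every DMF carbon.
    """
    if dmf_carbon not in {"carbonyl", "all"}:
        raise ValueError("dmf_carbon must be 'carbonyl' or 'all'")
    merged = dict(DEFAULT_SPECIES_RULES)
    if rules:
        merged.update({k.upper(): v.lower() for k, v in rules.items()})

    resnames = np.array([str(r).upper() for r in structure.residue_names], dtype=object)
    unknown = sorted({r for r in resnames if r not in merged})
    if unknown and strict:
        raise ClassificationError(
            "unknown residue names (add rules or set strict=False): "
            + ", ".join(unknown)
        )
    species = np.array(
        [merged.get(r, "ion") for r in resnames], dtype=object
    )

    elements = np.array([str(e).upper() for e in structure.elements], dtype=object)
    names = np.array([str(n).upper() for n in structure.names], dtype=object)
    is_h = elements == "H"

    is_water_oxygen = (species == "water") & (elements == "O")
    if dmf_carbon == "carbonyl":
        is_dmf_carbon = _dmf_carbonyl_mask(structure, species, elements)
    else:
        is_dmf_carbon = (species == "dmf") & (elements == "C")
    is_tre_oh = (species == "trehalose") & (elements == "O") & np.array(
        [bool(_TREHALOSE_HYDROXYL_RE.match(n)) for n in names]
    )

    # Donor / acceptor roles.  With hydrogens present, a donor is any
    # N/O/S with a covalently attached H (assigned by the detector at
    # bond-search time); the flags below mark chemically admissible
    # heavy atoms so detection also works for H-less crystal structures.
    is_donor = np.zeros(structure.n_atoms, dtype=bool)
    is_acceptor = np.zeros(structure.n_atoms, dtype=bool)
    polar_h = np.zeros(structure.n_atoms, dtype=bool)

    protein = species == "protein"
    is_donor |= protein & np.isin(names, tuple(_PROTEIN_DONOR_NAMES))
    is_acceptor |= protein & np.isin(names, tuple(_PROTEIN_ACCEPTOR_NAMES))

    water = species == "water"
    is_donor |= water & (elements == "O")
    is_acceptor |= water & (elements == "O")

    # DMF: the formyl oxygen accepts; no conventional donor hydrogens
    # (C-H weak donors are handled by the detector's opt-in flag).
    is_acceptor |= (species == "dmf") & (elements == "O")

    # Trehalose: hydroxyl O both donates and accepts; ring/glycosidic O accept.
    tre = species == "trehalose"
    is_donor |= is_tre_oh
    is_acceptor |= tre & (elements == "O")

    # Polar hydrogens: H bonded to N/O/S (distance criterion, <= 1.25 Å).
    if np.any(is_h):
        from scipy.spatial import cKDTree

        heavy_idx = np.flatnonzero(np.isin(elements, ("N", "O", "S")))
        h_idx = np.flatnonzero(is_h)
        if heavy_idx.size:
            tree = cKDTree(structure.coordinates[heavy_idx])
            d, _ = tree.query(structure.coordinates[h_idx], k=1)
            polar_h[h_idx[d <= 1.25]] = True

    return SpeciesMap(
        species=species,
        is_water_oxygen=is_water_oxygen,
        is_dmf_carbon=is_dmf_carbon,
        is_trehalose_hydroxyl_oxygen=is_tre_oh,
        is_hbond_donor=is_donor,
        is_hbond_acceptor=is_acceptor,
        is_polar_hydrogen=polar_h,
    )


def _dmf_carbonyl_mask(
    structure: Structure, species: np.ndarray, elements: np.ndarray
) -> np.ndarray:
    """One counted carbon per DMF molecule: the formyl (carbonyl) carbon.

    Identified as the carbon covalently bonded to the molecule's oxygen
    (<1.6 Å); for reduced representations without an oxygen the single
    carbon, or the one conventionally named C, is taken.
    """
    mask = np.zeros(structure.n_atoms, dtype=bool)
    dmf_idx = np.flatnonzero(species == "dmf")
    if dmf_idx.size == 0:
        return mask
    rid = structure.residue_ids()
    names = np.array([str(n).upper() for n in structure.names], dtype=object)
    for r in np.unique(rid[dmf_idx]):
        members = np.flatnonzero(rid == r)
        carbons = members[elements[members] == "C"]
        if carbons.size == 0:
            continue
        oxygens = members[elements[members] == "O"]
        chosen = None
        if oxygens.size:
            for c in carbons:
                d = np.linalg.norm(
                    structure.coordinates[oxygens] - structure.coordinates[c], axis=1
                )
                if np.any(d < 1.6):
                    chosen = c
                    break
        if chosen is None:
            named = carbons[names[carbons] == "C"]
            chosen = named[0] if named.size else carbons[0]
        mask[chosen] = True
    return mask


def count_residues(structure: Structure, residue_name: str) -> int:
    """Number of residues with the given name (e.g. TRP) in the structure."""
    target = residue_name.upper()
    seen = set()
    for c, ri, rn in zip(
        structure.chain_ids, structure.residue_indices, structure.residue_names
    ):
        if str(rn).upper() == target:
            seen.add((c, int(ri)))
    return len(seen)
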