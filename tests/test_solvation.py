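import numpy as np
import pytest

from oracles import (
    allpairs_min_distance,
    brute_rdf_counts,
    direct_center_of_mass,
)
from solvshell.errors import MassError, PBCError, SelectionError, ValidationError
from solvshell.geometry import min_distance_to_set
from solvshell.solvation import (
    center_of_mass,
    default_shell_edges,
    g_now_profile,
    gnow_from_counts,
    min_distance_to_protein,
    rdf_from_com,
)
from solvshell.structure_io import Atom, Structure, Trajectory, classify_species
from solvshell.synthetic import make_toy_protein, make_trajectory


class TestCenterOfMass:
    def test_two_equal_masses_at_plus_minus_x(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        np.testing.assert_allclose(center_of_mass(coords, np.ones(2)), [0, 0, 0])

    def test_single_atom_is_its_position(self):
        np.testing.assert_allclose(
            center_of_mass(np.array([[2.0, 3.0, 4.0]]), np.array([12.0])),
            [2.0, 3.0, 4.0],
        )

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-10, 10, (50, 3))
        masses = rng.uniform(1, 16, 50)
        np.testing.assert_allclose(
            center_of_mass(coords, masses),
            direct_center_of_mass(coords, masses),
            atol=1e-12,
        )

    def test_zero_mass_raises(self):
        with pytest.raises(MassError):
            center_of_mass(np.zeros((2, 3)), np.zeros(2))


class TestMinDistance:
    def test_three_four_five(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        d = min_distance_to_protein(frame, np.array([0]), np.array([1]), None)
        assert d[0] == pytest.approx(5.0)

    def test_periodic_image_closer_than_direct(self):
        box = np.array([10.0, 10.0, 10.0])
        frame = np.array([[0.5, 5.0, 5.0], [9.5, 5.0, 5.0]])
        d = min_distance_to_protein(frame, np.array([0]), np.array([1]), box)
        assert d[0] == pytest.approx(1.0)  # across the boundary, not 9.0

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(1)
        box = np.array([20.0, 25.0, 30.0])
        prot = rng.uniform(0, 20, (20, 3))
        targets = rng.uniform(0, 20, (30, 3))
        fast = min_distance_to_set(targets, prot, box)
        slow = allpairs_min_distance(targets, prot, box)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_empty_protein_selection_raises(self):
        with pytest.raises(SelectionError):
            min_distance_to_protein(
                np.zeros((2, 3)), np.array([], dtype=int), np.array([0]), None
            )


def _com_centred_system(role_coords, box_edge=40.0):
    """Protein of 4 heavy atoms at the box centre plus water role atoms."""
    box = np.array([box_edge] * 3)
    centre = box / 2
    prot = [
        Atom(i + 1, n, n[0], "ALA", 1, centre + off, chain_id="A")
        for i, (n, off) in enumerate(
            [
                ("N", np.array([-0.7, 0.0, 0.0])),
                ("CA", np.array([0.7, 0.0, 0.0])),
                ("C", np.array([0.0, 0.8, 0.0])),
                ("O", np.array([0.0, 0.0, 0.9])),
            ]
        )
    ]
    waters = [
        Atom(
            len(prot) + i + 1,
            "OW",
            "O",
            "SOL",
            i + 1,
            xyz,
            chain_id="S",
        )
        for i, xyz in enumerate(role_coords)
    ]
    return Structure(prot + waters, box=box)


class TestRdfFromCom:
    def test_uniform_placement_approaches_one(self):
        rng = np.random.default_rng(2)
        box_edge = 40.0
        base = _com_centred_system(rng.uniform(0, box_edge, (5000, 3)))
        frames = np.array(
            [base.coordinates] * 1
            + [
                np.vstack(
                    [base.coordinates[:4], rng.uniform(0, box_edge, (5000, 3))]
                )
                for _ in range(19)
            ]
        )
        traj = Trajectory(base, frames)
        sp = classify_species(base)
        res = rdf_from_com(traj, sp, "water_oxygen", bins=np.arange(0.0, 16.0, 1.0))
        far = res.r_mid > 5.0
        assert 0.9 <= float(np.mean(res.g[far])) <= 1.1

    def test_spherical_shell_lands_in_single_bin(self):
        rng = np.random.default_rng(3)
        directions = rng.normal(size=(200, 3))
        directions /= np.linalg.norm(directions, axis=1)[:, None]
        scaffold = _com_centred_system(np.array([[20.0, 20.0, 20.0]]))
        com = center_of_mass(scaffold.coordinates[:4], scaffold.masses[:4])
        base = _com_centred_system(com + 8.4 * directions)
        traj = Trajectory(base, base.coordinates[None])
        sp = classify_species(base)
        res = rdf_from_com(traj, sp, "water_oxygen", bins=np.arange(0.0, 16.0, 1.0), window_last=1.0)
        occupied = np.flatnonzero(res.counts > 0)
        assert occupied.tolist() == [8]  # the [8, 9) Å bin holds the shell

    def test_counts_match_brute_force_histogram(self):
        rng = np.random.default_rng(4)
        base = _com_centred_system(rng.uniform(0, 40, (50, 3)))
        frames = np.array(
            [
                np.vstack([base.coordinates[:4], rng.uniform(0, 40, (50, 3))])
                for _ in range(3)
            ]
        )
        traj = Trajectory(base, frames)
        sp = classify_species(base)
        bins = np.arange(0.0, 16.0, 0.5)
        res = rdf_from_com(traj, sp, "water_oxygen", bins=bins, window_last=1.0)
        coms = [
            direct_center_of_mass(f[:4], base.masses[:4]) for f in frames
        ]
        brute = brute_rdf_counts(
            [f[4:] for f in frames], coms, bins, base.box
        )
        np.testing.assert_allclose(res.counts * res.frames_averaged, brute, atol=1e-9)

    def test_uniform_rdf_integrates_to_total_count(self):
        rng = np.random.default_rng(5)
        base = _com_centred_system(rng.uniform(0, 40, (3000, 3)))
        traj = Trajectory(base, base.coordinates[None])
        sp = classify_species(base)
        bins = np.arange(0.0, 16.0, 0.5)
        res = rdf_from_com(traj, sp, "water_oxygen", bins=bins, window_last=1.0)
        shell_vol = (4 / 3) * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
        integral = float(np.sum(res.g * res.bulk_density * shell_vol))
        inside = 3000 * (4 / 3) * np.pi * 15.0**3 / 40.0**3
        assert integral == pytest.approx(inside, rel=0.1)

    def test_bins_beyond_half_box_raise(self):
        base = _com_centred_system(np.array([[10.0, 10.0, 10.0]]))
        traj = Trajectory(base, base.coordinates[None])
        sp = classify_species(base)
        with pytest.raises(PBCError):
            rdf_from_com(traj, sp, "water_oxygen", bins=np.arange(0.0, 30.0, 1.0))


class TestGnow:
    def test_worked_shell_arithmetic(self):
        # n_OW=8, n_CD=2, n_OT=0 against box totals 80/120/0:
        # (8/10) * (200/80) = 2.0 exactly
        assert gnow_from_counts(8, 2, 0, 80, 120, 0) == pytest.approx(2.0)

    def test_empty_shell_is_nan_not_zero(self):
        assert np.isnan(gnow_from_counts(0, 0, 0, 80, 120, 0))

    def test_no_water_raises(self):
        with pytest.raises(ValidationError):
            gnow_from_counts(1, 0, 0, 0, 10, 0)

    def test_water_only_system_identically_one(self, helix20):
        rng = np.random.default_rng(6)
        box = np.array([50.0] * 3)
        centred = helix20.coordinates - helix20.coordinates.mean(axis=0) + box / 2
        prot = [
            Atom(i + 1, n, e, "ALA", ri, xyz, chain_id="A")
            for i, (n, e, ri, xyz) in enumerate(
                zip(helix20.names, helix20.elements, helix20.residue_indices, centred)
            )
        ]
        waters = [
            Atom(len(prot) + i + 1, "OW", "O", "SOL", i + 1, xyz, chain_id="S")
            for i, xyz in enumerate(rng.uniform(0, 50, (800, 3)))
        ]
        system = Structure(prot + waters, box=box)
        sp = classify_species(system)
        traj = make_trajectory(system, "jitter", n_frames=5, seed=7, sigma=0.5)
        profile = g_now_profile(traj, sp)
        occ = profile.occupied()
        np.testing.assert_allclose(profile.g_now[occ], 1.0, atol=1e-12)

    def test_shell_conservation_single_frame(self, uniform_box):
        system, sp = uniform_box
        traj = Trajectory(system, system.coordinates[None])
        profile = g_now_profile(traj, sp)
        prot = np.flatnonzero(
            (sp.species == "protein")
            & np.array([str(e).upper() != "H" for e in system.elements])
        )
        for key, mask in (
            ("n_ow", sp.is_water_oxygen),
            ("n_cd", sp.is_dmf_carbon),
            ("n_ot", sp.is_trehalose_hydroxyl_oxygen),
        ):
            d = min_distance_to_set(
                system.coordinates[np.flatnonzero(mask)],
                system.coordinates[prot],
                system.box,
            )
            in_range = int(np.sum((d > 0.5) & (d <= 10.0)))
            assert float(np.sum(getattr(profile, key))) == pytest.approx(in_range)

    def test_invariant_under_solvent_duplication(self):
        # duplicating every solvent atom scales all counts; ratios cancel
        rng = np.random.default_rng(8)
        box = np.array([30.0] * 3)
        prot = [
            Atom(1, "CA", "C", "ALA", 1, box / 2, chain_id="A"),
            Atom(2, "N", "N", "ALA", 1, box / 2 + [1.4, 0, 0], chain_id="A"),
            Atom(3, "C", "C", "ALA", 1, box / 2 + [0, 1.4, 0], chain_id="A"),
        ]
        wat = rng.uniform(0, 30, (150, 3))
        dmf = rng.uniform(0, 30, (40, 3))

        def build(mult):
            atoms = list(prot)
            serial = 4
            ri = 1
            for xyz in np.repeat(wat, mult, axis=0):
                atoms.append(Atom(serial, "OW", "O", "SOL", ri, xyz, chain_id="S"))
                serial += 1
                ri += 1
            for xyz in np.repeat(dmf, mult, axis=0):
                atoms.append(Atom(serial, "C", "C", "DMF", ri, xyz, chain_id="S"))
                serial += 1
                ri += 1
            return Structure(atoms, box=box)

        profiles = []
        for mult in (1, 2):
            system = build(mult)
            sp = classify_species(system)
            traj = Trajectory(system, system.coordinates[None])
            profiles.append(g_now_profile(traj, sp))
        occ = profiles[0].occupied()
        np.testing.assert_allclose(
            profiles[0].g_now[occ], profiles[1].g_now[occ], atol=1e-12
        )

    def test_default_shell_edges_are_half_angstrom_steps(self):
        edges = default_shell_edges()
        assert edges[0] == 0.5
        assert edges[-1] == 10.0
        np.testing.assert_allclose(np.diff(edges), 0.5)

    def test_cumulative_counts_are_running_sums(self, uniform_box):
        system, sp = uniform_box
        traj = Trajectory(system, system.coordinates[None])
        banded = g_now_profile(traj, sp)
        cumulative = g_now_profile(traj, sp, cumulative=True)
        np.testing.assert_allclose(
            cumulative.n_ow, np.cumsum(banded.n_ow), atol=1e-9
        )
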