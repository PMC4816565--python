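import numpy as np
import pytest

from oracles import brute_force_hbonds, hbond_energy_formula
from solvshell.hbonds import (
    HBondCriteria,
    HBondRecord,
    census,
    detect_hbonds,
    hbond_energy,
)
from solvshell.structure_io import Atom, Structure, Trajectory, classify_species
from solvshell.synthetic import make_hbond_fixture, make_trajectory


def _water_dimer(oo_distance: float, hda_angle_deg: float) -> Structure:
    """Two waters: donor O with H aimed (within the angle) at acceptor O."""
    theta = np.radians(hda_angle_deg)
    atoms = [
        Atom(1, "OW", "O", "SOL", 1, np.array([0.0, 0.0, 0.0]), chain_id="S"),
        Atom(
            2,
            "HW1",
            "H",
            "SOL",
            1,
            0.96 * np.array([np.cos(theta), np.sin(theta), 0.0]),
            chain_id="S",
        ),
        Atom(3, "OW", "O", "SOL", 2, np.array([oo_distance, 0.0, 0.0]), chain_id="S"),
        # acceptor's own hydrogen points away so it cannot donate back
        Atom(4, "HW1", "H", "SOL", 2, np.array([oo_distance + 0.96, 0.0, 0.0]), chain_id="S"),
    ]
    return Structure(atoms)


class TestDetectHbonds:
    def test_ideal_dimer_gives_exactly_one_bond(self):
        st = _water_dimer(2.8, 5.0)
        bonds = detect_hbonds(st, classify_species(st))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8)
        assert bonds[0].angle == pytest.approx(5.0, abs=1e-6)

    def test_long_dimer_gives_no_bond(self):
        st = _water_dimer(4.0, 5.0)
        assert detect_hbonds(st, classify_species(st)) == []

    def test_bent_dimer_rejected_by_angle(self):
        st = _water_dimer(2.8, 60.0)
        assert detect_hbonds(st, classify_species(st)) == []

    def test_no_donors_warns_and_returns_empty(self):
        atoms = [
            Atom(1, "C", "C", "DMF", 1, np.array([0.0, 0, 0]), chain_id="S"),
            Atom(2, "O", "O", "DMF", 1, np.array([1.2, 0, 0]), chain_id="S"),
        ]
        st = Structure(atoms)
        with pytest.warns(UserWarning, match="no donors"):
            assert detect_hbonds(st, classify_species(st)) == []

    def test_matches_allpairs_oracle_on_random_mixture(self):
        rng = np.random.default_rng(0)
        atoms = []
        serial = 1
        box = np.array([18.0] * 3)
        for i in range(30):
            pos = rng.uniform(0, 18, 3)
            h_dir = rng.normal(size=3)
            h_dir /= np.linalg.norm(h_dir)
            atoms.append(Atom(serial, "OW", "O", "SOL", i + 1, pos, chain_id="S"))
            serial += 1
            atoms.append(
                Atom(serial, "HW1", "H", "SOL", i + 1, pos + 0.96 * h_dir, chain_id="S")
            )
            serial += 1
        st = Structure(atoms, box=box)
        sp = classify_species(st)
        bonds = detect_hbonds(st, sp)
        got = {(b.donor, b.acceptor) for b in bonds}
        expected = brute_force_hbonds(
            st.coordinates,
            [str(e) for e in st.elements],
            np.flatnonzero(sp.is_hbond_donor),
            np.flatnonzero(sp.is_hbond_acceptor),
            box,
        )
        assert got == expected
        assert len(expected) > 0  # the fixture must actually exercise bonds

    def test_invariant_under_global_rigid_motion(self):
        st = _water_dimer(2.9, 12.0)
        sp = classify_species(st)
        before = {(b.donor, b.acceptor) for b in detect_hbonds(st, sp)}
        rng = np.random.default_rng(1)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = st.with_coordinates(st.coordinates @ q.T + np.array([5.0, -3.0, 2.0]))
        after = {(b.donor, b.acceptor) for b in detect_hbonds(moved, sp)}
        assert before == after

    def test_widening_distance_cutoff_never_loses_bonds(self):
        rng = np.random.default_rng(2)
        atoms = []
        for i in range(20):
            atoms.append(
                Atom(i + 1, "OW", "O", "SOL", i + 1, rng.uniform(0, 12, 3), chain_id="S")
            )
        st = Structure(atoms)
        sp = classify_species(st)
        narrow = {(b.donor, b.acceptor) for b in detect_hbonds(st, sp, HBondCriteria(3.0))}
        wide = {(b.donor, b.acceptor) for b in detect_hbonds(st, sp, HBondCriteria(3.5))}
        assert narrow <= wide

    def test_distance_only_mode_without_hydrogens(self):
        # crystal-structure style input: no H anywhere, angle test skipped
        atoms = [
            Atom(1, "N", "N", "ALA", 1, np.array([0.0, 0, 0]), chain_id="A"),
            Atom(2, "O", "O", "ALA", 5, np.array([2.9, 0, 0]), chain_id="A"),
        ]
        st = Structure(atoms)
        bonds = detect_hbonds(st, classify_species(st))
        assert len(bonds) == 1
        assert bonds[0].angle is None


class TestCensus:
    def test_water_only_box_has_zero_tracked_classes(self):
        rng = np.random.default_rng(3)
        atoms = [
            Atom(i + 1, "OW", "O", "SOL", i + 1, rng.uniform(0, 15, 3), chain_id="S")
            for i in range(40)
        ]
        st = Structure(atoms, box=np.array([15.0] * 3))
        traj = make_trajectory(st, "static", n_frames=2)
        result = census(traj, classify_species(st))
        for cls in ("CRL-CRL", "CRL-DMF", "CRL-Tre", "DMF-Tre"):
            assert result.mean[cls] == 0.0

    @pytest.mark.parametrize(
        "wanted",
        [
            {"CRL-DMF": 5},
            {"CRL-CRL": 3, "CRL-Tre": 2, "DMF-Tre": 4},
        ],
    )
    def test_fixture_counts_recovered_exactly(self, wanted):
        fixture = make_hbond_fixture(wanted, n_decoys=50, seed=4)
        traj = make_trajectory(fixture, "static", n_frames=3)
        result = census(traj, classify_species(fixture))
        for cls in ("CRL-CRL", "CRL-DMF", "CRL-Tre", "DMF-Tre"):
            assert result.mean[cls] == wanted.get(cls, 0)
            assert result.sd[cls] == 0.0

    def test_single_frame_sd_is_zero(self):
        fixture = make_hbond_fixture({"CRL-DMF": 2}, n_decoys=5, seed=5)
        traj = make_trajectory(fixture, "static", n_frames=1)
        result = census(traj, classify_species(fixture))
        assert all(v == 0.0 for v in result.sd.values())

    def test_mean_within_min_max_of_frames(self):
        fixture = make_hbond_fixture({"CRL-DMF": 4}, n_decoys=10, seed=6)
        traj = make_trajectory(fixture, "jitter", n_frames=10, seed=7, sigma=0.15)
        result = census(traj, classify_species(fixture))
        for cls in ("CRL-CRL", "CRL-DMF", "CRL-Tre", "DMF-Tre"):
            col = result.per_frame[cls]
            assert col.min() <= result.mean[cls] <= col.max()


class TestOptionalModes:
    def test_weak_ch_donors_opt_in(self):
        # a DMF methyl C-H aimed at a water oxygen: invisible under the
        # conventional criterion, scored when weak donors are enabled
        atoms = [
            Atom(1, "C2", "C", "DMF", 1, np.array([0.0, 0, 0]), chain_id="S"),
            Atom(2, "H21", "H", "DMF", 1, np.array([1.09, 0, 0]), chain_id="S"),
            Atom(3, "OW", "O", "SOL", 2, np.array([3.2, 0.2, 0]), chain_id="S"),
        ]
        st = Structure(atoms)
        sp = classify_species(st)
        assert detect_hbonds(st, sp) == []
        bonds = detect_hbonds(st, sp, HBondCriteria(weak_cd_donors=True))
        assert len(bonds) == 1
        assert bonds[0].donor == 0

    def test_backbone_only_census_drops_sidechain_bonds(self):
        # one backbone N->O bond and one sidechain OG->O bond between
        # distant residues; the backbone-only census keeps just the first
        atoms = [
            Atom(1, "N", "N", "ALA", 1, np.array([0.0, 0, 0]), chain_id="A"),
            Atom(2, "O", "O", "ALA", 5, np.array([2.9, 0, 0]), chain_id="A"),
            Atom(3, "OG", "O", "SER", 10, np.array([20.0, 0, 0]), chain_id="A"),
            Atom(4, "O", "O", "ALA", 15, np.array([22.9, 0, 0]), chain_id="A"),
        ]
        st = Structure(atoms)
        sp = classify_species(st)
        traj = make_trajectory(st, "static", n_frames=1)
        full = census(traj, sp)
        bb = census(traj, sp, backbone_only_protein=True)
        assert full.mean["CRL-CRL"] == 2
        assert bb.mean["CRL-CRL"] == 1


class TestHbondEnergy:
    def test_ideal_geometry_is_maximal(self):
        geometries = [(2.8, 0.0), (2.6, 0.0), (3.0, 10.0), (3.5, 30.0), (3.2, 20.0)]
        energies = [
            hbond_energy(HBondRecord(0, 1, d, a, "CRL-DMF")) for d, a in geometries
        ]
        assert np.argmax(energies) == 0
        assert energies[0] == pytest.approx(28.0)

    def test_weaker_than_ideal_at_cutoff_geometry(self):
        ideal = hbond_energy(HBondRecord(0, 1, 2.8, 0.0, "CRL-DMF"))
        edge = hbond_energy(HBondRecord(0, 1, 3.5, 30.0, "CRL-DMF"))
        assert edge < ideal

    def test_monotone_decreasing_beyond_optimum(self):
        distances = np.linspace(2.8, 3.5, 10)
        energies = [
            hbond_energy(HBondRecord(0, 1, float(d), 0.0, "CRL-DMF")) for d in distances
        ]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_ordering_matches_independent_formula_evaluation(self):
        rng = np.random.default_rng(8)
        geometries = [
            (float(d), float(a))
            for d, a in zip(rng.uniform(2.4, 3.5, 20), rng.uniform(0, 30, 20))
        ]
        ours = [hbond_energy(HBondRecord(0, 1, d, a, "other")) for d, a in geometries]
        independent = [hbond_energy_formula(d, a) for d, a in geometries]
        assert np.argsort(ours).tolist() == np.argsort(independent).tolist()
        np.testing.assert_allclose(ours, independent, rtol=1e-12)

    def test_out_of_calibration_distance_warns(self):
        with pytest.warns(UserWarning, match="calibrated range"):
            hbond_energy(HBondRecord(0, 1, 4.8, 0.0, "other"))
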