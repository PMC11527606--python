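import math

import numpy as np
import pytest

from poregate import ChannelSpec, ContactPlan, generate_trajectory, select
from poregate.networks import (
    ContactCriteria,
    PairFractionTable,
    detect_contacts_frame,
    difference_table,
    ligand_contact_profile,
    pair_fractions,
    top_differences,
)
from poregate.traj_io import FrameWindow, Topology, Trajectory


def make_toy(atoms, coords):
    """atoms: list of (name, resid, resname, chain)."""
    names, resids, resnames, chains = zip(*atoms)
    topo = Topology(list(names), list(resids), list(resnames), list(chains))
    return topo, np.asarray(coords, dtype=float)


class TestDetectContactsFrame:
    def test_salt_bridge_below_cutoff(self):
        topo, coords = make_toy(
            [("NZ", 1, "LYS", "A"), ("OE1", 5, "GLU", "A")],
            [[0, 0, 0], [3.4, 0, 0]],
        )
        crit = ContactCriteria.salt_bridge(4.0)
        found = detect_contacts_frame(coords, topo, crit)
        assert found == {(("A", 1, "LYS"), ("A", 5, "GLU"))}

    def test_salt_bridge_above_cutoff(self):
        topo, coords = make_toy(
            [("NZ", 1, "LYS", "A"), ("OE1", 5, "GLU", "A")],
            [[0, 0, 0], [4.5, 0, 0]],
        )
        assert detect_contacts_frame(coords, topo, ContactCriteria.salt_bridge(4.0)) == set()

    def test_adjacent_residues_excluded(self):
        topo, coords = make_toy(
            [("NZ", 1, "LYS", "A"), ("OE1", 2, "GLU", "A")],
            [[0, 0, 0], [3.0, 0, 0]],
        )
        assert detect_contacts_frame(coords, topo, ContactCriteria.salt_bridge(4.0)) == set()
        # same resid pair on different chains is a real pair
        topo2, coords2 = make_toy(
            [("NZ", 1, "LYS", "A"), ("OE1", 2, "GLU", "B")],
            [[0, 0, 0], [3.0, 0, 0]],
        )
        assert len(detect_contacts_frame(coords2, topo2, ContactCriteria.salt_bridge(4.0))) == 1

    def test_hbond_angle_gate(self):
        # donor-acceptor 3.4 A but D-H...A angle 90 deg -> rejected at 135
        atoms = [("OG", 1, "SER", "A"), ("HG", 1, "SER", "A"), ("OD1", 5, "ASN", "A")]
        coords_bad = [[0, 0, 0], [0, 1.0, 0], [3.4, 0, 0]]  # angle(D-H-A) = 90
        topo, c = make_toy(atoms, coords_bad)
        crit = ContactCriteria.hbond(3.5, 135.0)
        assert detect_contacts_frame(c, topo, crit) == set()
        coords_good = [[0, 0, 0], [1.0, 0, 0], [3.4, 0, 0]]  # angle = 180
        assert len(detect_contacts_frame(np.asarray(coords_good), topo, crit)) == 1

    def test_hydrophobic_uses_sidechain_carbons_only(self):
        atoms = [
            ("CA", 1, "LEU", "A"),
            ("CD1", 1, "LEU", "A"),
            ("CA", 5, "VAL", "A"),
            ("CG1", 5, "VAL", "A"),
        ]
        # backbone CAs close, side-chain carbons far -> no contact
        coords = [[0, 0, 0], [10, 0, 0], [2.0, 0, 0], [20, 0, 0]]
        topo, c = make_toy(atoms, coords)
        assert detect_contacts_frame(c, topo, ContactCriteria.hydrophobic(4.5)) == set()
        # side chains close -> contact
        c2 = np.asarray([[0, 0, 0], [10, 0, 0], [2.0, 0, 0], [12, 0, 0]], dtype=float)
        assert len(detect_contacts_frame(c2, topo, ContactCriteria.hydrophobic(4.5))) == 1

    def test_histidine_basic_only_when_protonated(self):
        atoms_hip = [("ND1", 1, "HIP", "A"), ("OE1", 5, "GLU", "A")]
        topo, c = make_toy(atoms_hip, [[0, 0, 0], [3.0, 0, 0]])
        assert len(detect_contacts_frame(c, topo, ContactCriteria.salt_bridge(4.0))) == 1
        atoms_his = [("ND1", 1, "HIS", "A"), ("OE1", 5, "GLU", "A")]
        topo2, c2 = make_toy(atoms_his, [[0, 0, 0], [3.0, 0, 0]])
        assert detect_contacts_frame(c2, topo2, ContactCriteria.salt_bridge(4.0)) == set()

    def test_matches_brute_force_oracle(self):
        # ~20-atom random toy frame vs an independent all-pairs evaluation
        rng = np.random.default_rng(4)
        atoms = []
        residues = [
            (1, "LYS", "A", ["NZ"]),
            (3, "GLU", "A", ["OE1", "OE2"]),
            (5, "ASP", "B", ["OD1", "OD2"]),
            (7, "ARG", "B", ["NE", "NH1", "NH2"]),
            (9, "LYS", "C", ["NZ"]),
            (11, "GLU", "C", ["OE1"]),
        ]
        for resid, resname, chain, names in residues:
            for nm in names:
                atoms.append((nm, resid, resname, chain))
        coords = rng.uniform(0, 12, size=(len(atoms), 3))
        topo, c = make_toy(atoms, coords)
        crit = ContactCriteria.salt_bridge(4.0)
        found = detect_contacts_frame(c, topo, crit)

        # oracle: plain python loops over basic/acidic residue groups
        basic = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}
        acidic = {"GLU": {"OE1", "OE2"}, "ASP": {"OD1", "OD2"}}
        expected = set()
        for i in range(topo.n_atoms):
            for j in range(topo.n_atoms):
                ri = (topo.chains[i], int(topo.resids[i]), topo.resnames[i])
                rj = (topo.chains[j], int(topo.resids[j]), topo.resnames[j])
                if ri == rj or (ri[0] == rj[0] and abs(ri[1] - rj[1]) <= 1):
                    continue
                if topo.names[i] not in basic.get(topo.resnames[i], set()):
                    continue
                if topo.names[j] not in acidic.get(topo.resnames[j], set()):
                    continue
                if math.dist(c[i], c[j]) <= 4.0:
                    expected.add(tuple(sorted((ri, rj))))
        assert found == expected


class TestPairFractions:
    @pytest.mark.parametrize("fraction", [0.10, 0.50, 0.75, 1.00])
    @pytest.mark.parametrize("ctype", ["salt_bridge", "hbond", "hydrophobic"])
    def test_planted_fraction_recovered_exactly(self, spec, ctype, fraction):
        plan = ContactPlan((("A", 2), ("C", 2)), ctype, fraction)
        traj, _ = generate_trajectory(spec, contacts=[plan], n_frames=200, seed=8)
        crit = {
            "salt_bridge": ContactCriteria.salt_bridge(),
            "hbond": ContactCriteria.hbond(),
            "hydrophobic": ContactCriteria.hydrophobic(),
        }[ctype]
        table = pair_fractions(traj, crit)
        assert len(table.entries) == (1 if fraction > 0 else 0)
        if fraction > 0:
            assert next(iter(table.entries.values())) == fraction

    def test_static_frame_fraction_one(self):
        topo, coords = make_toy(
            [("NZ", 1, "LYS", "A"), ("OE1", 5, "GLU", "A")],
            [[0, 0, 0], [3.4, 0, 0]],
        )
        traj = Trajectory(topo, np.repeat(coords[None], 50, axis=0))
        table = pair_fractions(traj, ContactCriteria.salt_bridge())
        assert list(table.entries.values()) == [1.0]

    def test_never_formed_pair_absent_reads_zero(self, spec):
        plan = ContactPlan((("A", 2), ("C", 2)), "salt_bridge", 0.0)
        traj, _ = generate_trajectory(spec, contacts=[plan], n_frames=20)
        table = pair_fractions(traj, ContactCriteria.salt_bridge())
        assert table.entries == {}
        assert table.fraction(((("A", 2, "LYS")), ("C", 2, "GLU"))) == 0.0

    def test_rigid_motion_invariance(self, spec):
        plan = ContactPlan((("A", 2), ("C", 2)), "hydrophobic", 0.5)
        traj, _ = generate_trajectory(spec, contacts=[plan], n_frames=40, seed=1)
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        moved = Trajectory(traj.topology, traj.coordinates @ rot.T + 11.0)
        crit = ContactCriteria.hydrophobic()
        assert pair_fractions(traj, crit).entries == pair_fractions(moved, crit).entries


class TestDifferenceTable:
    def _table(self, label, entries):
        return PairFractionTable(label, "salt_bridge", FrameWindow(0, 10), entries)

    def test_identity(self):
        p = (("A", 1, "LYS"), ("B", 2, "GLU"))
        t = self._table("x", {p: 0.9})
        diff = difference_table(t, t)
        assert diff.entries == {p: 0.0}

    def test_sign_convention_and_missing_as_zero(self):
        p = (("A", 1, "LYS"), ("B", 2, "GLU"))
        q = (("C", 3, "LYS"), ("D", 4, "GLU"))
        apo = self._table("apo", {p: 0.9})
        holo = self._table("holo", {p: 0.2, q: 0.6})
        diff = difference_table(apo, holo)
        assert diff.entries[p] == pytest.approx(-0.7)
        assert diff.entries[q] == pytest.approx(0.6)

    def test_antisymmetric(self):
        p = (("A", 1, "LYS"), ("B", 2, "GLU"))
        q = (("C", 3, "LYS"), ("D", 4, "GLU"))
        a = self._table("a", {p: 0.8, q: 0.1})
        b = self._table("b", {p: 0.3, q: 0.7})
        fwd = difference_table(a, b)
        rev = difference_table(b, a)
        for key in fwd.entries:
            assert fwd.entries[key] == pytest.approx(-rev.entries[key])

    def test_type_mismatch_raises(self):
        a = self._table("a", {})
        b = PairFractionTable("b", "hbond", FrameWindow(0, 10), {})
        with pytest.raises(ValueError, match="mismatch"):
            difference_table(a, b)

    def test_planted_difference_exact(self, spec):
        pair = (("A", 2), ("C", 2))
        t1, _ = generate_trajectory(
            spec, contacts=[ContactPlan(pair, "salt_bridge", 0.9)], n_frames=200, seed=1
        )
        t2, _ = generate_trajectory(
            spec, contacts=[ContactPlan(pair, "salt_bridge", 0.2)], n_frames=200, seed=2
        )
        crit = ContactCriteria.salt_bridge()
        diff = difference_table(
            pair_fractions(t1, crit, system_label="apo"),
            pair_fractions(t2, crit, system_label="holo"),
        )
        assert list(diff.entries.values()) == [pytest.approx(-0.7)]


class TestTopDifferences:
    def _diff(self, values):
        from poregate.networks import DifferenceTable

        entries = {
            (("A", i, "LYS"), ("B", i, "GLU")): v for i, v in enumerate(values, 1)
        }
        return DifferenceTable("apo", "holo", "salt_bridge", entries)

    def test_sorted_by_abs_descending(self):
        diff = self._diff([-0.9, 0.5, -0.5])
        ranked = top_differences(diff, k=2)
        assert ranked[0][1] == -0.9
        assert abs(ranked[1][1]) == 0.5

    def test_threshold_strict(self):
        diff = self._diff([-0.9, 0.5])
        assert top_differences(diff, threshold=0.95) == []
        assert len(top_differences(diff, threshold=0.9)) == 1

    def test_deterministic_tie_break(self):
        diff = self._diff([0.5, -0.5, 0.5])
        r1 = top_differences(diff)
        r2 = top_differences(diff)
        assert r1 == r2
        assert [p for p, _ in r1] == sorted(diff.entries)

    def test_k_validation(self):
        with pytest.raises(ValueError, match="k"):
            top_differences(self._diff([0.1]), k=0)
        with pytest.raises(ValueError, match="empty"):
            top_differences(self._diff([]))


class TestLigandContacts:
    def test_parked_ligand_full_contact(self):
        spec = ChannelSpec(n_ligands=1)
        traj, _ = generate_trajectory(spec, n_frames=30)
        topo = traj.topology
        # move ligand bead 3 A from residue A1's CA in every frame
        ca = next(
            i for i in range(topo.n_atoms) if topo.chains[i] == "A" and topo.resids[i] == 1 and topo.names[i] == "CA"
        )
        lig = int(np.nonzero(topo.is_ligand)[0][0])
        coords = traj.coordinates.copy()
        coords[:, lig] = coords[:, ca] + np.array([0, 0, 3.0])
        traj = Trajectory(topo, coords)
        profile = ligand_contact_profile(
            traj, select(topo, "ligand"), select(topo, "protein", "residue"), cutoff=4.5
        )
        assert profile.per_residue_percent[("A", 1, "GLY")] == 100.0

    def test_far_ligand_all_zero(self):
        spec = ChannelSpec(n_ligands=1)
        traj, _ = generate_trajectory(spec, n_frames=10)
        topo = traj.topology
        lig = int(np.nonzero(topo.is_ligand)[0][0])
        coords = traj.coordinates.copy()
        coords[:, lig] = 500.0
        traj = Trajectory(topo, coords)
        profile = ligand_contact_profile(
            traj, select(topo, "ligand"), select(topo, "protein", "residue")
        )
        assert all(v == 0.0 for v in profile.per_residue_percent.values())

    def test_planted_contact_schedule(self):
        spec = ChannelSpec(n_ligands=1)
        traj, _ = generate_trajectory(spec, n_frames=100)
        topo = traj.topology
        ca = next(
            i for i in range(topo.n_atoms) if topo.chains[i] == "A" and topo.resids[i] == 1 and topo.names[i] == "CA"
        )
        lig = int(np.nonzero(topo.is_ligand)[0][0])
        coords = traj.coordinates.copy()
        coords[:, lig] = 500.0
        near = coords[:, ca] + np.array([0, 0, 3.0])
        coords[:40, lig] = near[:40]  # 40% of frames in contact
        traj = Trajectory(topo, coords)
        profile = ligand_contact_profile(
            traj, select(topo, "ligand"), select(topo, "protein", "residue")
        )
        assert profile.per_residue_percent[("A", 1, "GLY")] == pytest.approx(40.0)

    def test_empty_ligand_raises(self, spec):
        traj, _ = generate_trajectory(spec, n_frames=5)
        with pytest.warns(UserWarning):
            empty = select(traj.topology, "resname ZZZ")
        with pytest.raises(ValueError, match="ligand"):
            ligand_contact_profile(
                traj, empty, select(traj.topology, "protein", "residue")
            )
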