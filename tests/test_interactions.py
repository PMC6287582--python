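import numpy as np
import pytest

import oracles
from rinmd.errors import ConfigurationError
from rinmd.fixtures import make_dipeptide_pair, make_random_system
from rinmd.interactions import (
    COULOMB_CONSTANT,
    InteractionCriteria,
    InteractionType as T,
    coulomb_energy,
    detect_all,
    detect_calpha,
    detect_cation_pi,
    detect_coulomb,
    detect_disulfides,
    detect_hbonds,
    detect_pi_pi,
    detect_salt_bridges,
    detect_vdw,
    lj_energy,
)

CRIT = InteractionCriteria()


# ---------------------------------------------------------------------------
# Planted-geometry boundary behavior (positives, negatives, exact thresholds)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "itype,geometry,n_expected",
    [
        # C-alpha contacts: d <= 8 inclusive
        (T.CALPHA, {"distance": 7.5}, 1),
        (T.CALPHA, {"distance": 8.0}, 1),
        (T.CALPHA, {"distance": 8.5}, 0),
        # Hydrogen bonds: d(D, A) <= 3 and angle >= 120
        (T.HBOND, {"distance": 2.9, "angle": 180.0}, 1),
        (T.HBOND, {"distance": 2.9, "angle": 90.0}, 0),
        (T.HBOND, {"distance": 2.9, "angle": 119.0}, 0),
        (T.HBOND, {"distance": 2.9, "angle": 125.0}, 1),
        (T.HBOND, {"distance": 3.0, "angle": 180.0}, 1),
        (T.HBOND, {"distance": 3.4, "angle": 180.0}, 0),
        # Salt bridges: min N-O distance <= 6
        (T.SALT_BRIDGE, {"distance": 3.5}, 1),
        (T.SALT_BRIDGE, {"distance": 6.0}, 1),
        (T.SALT_BRIDGE, {"distance": 6.5}, 0),
        # Disulfides: S-S <= 3, |chi| in [60, 90]
        (T.DISULFIDE, {"distance": 2.05, "dihedral": 85.0}, 1),
        (T.DISULFIDE, {"distance": 2.05, "dihedral": -85.0}, 1),
        (T.DISULFIDE, {"distance": 2.05, "dihedral": 30.0}, 0),
        (T.DISULFIDE, {"distance": 2.05, "dihedral": 65.0}, 1),
        (T.DISULFIDE, {"distance": 2.05, "dihedral": 55.0}, 0),
        (T.DISULFIDE, {"distance": 2.05, "dihedral": 95.0}, 0),
        (T.DISULFIDE, {"distance": 3.2, "dihedral": 85.0}, 0),
        # pi-pi: centroid distance <= 6
        (T.PI_PI, {"distance": 4.5}, 1),
        (T.PI_PI, {"distance": 6.0}, 1),
        (T.PI_PI, {"distance": 6.2}, 0),
        # cation-pi: distance <= 7, angle in [0,60] U [120,180]
        (T.CATION_PI, {"distance": 4.0, "angle": 0.0}, 1),
        (T.CATION_PI, {"distance": 5.0, "angle": 90.0}, 0),
        (T.CATION_PI, {"distance": 4.0, "angle": 175.0}, 1),
        (T.CATION_PI, {"distance": 4.0, "angle": 60.0}, 1),
        (T.CATION_PI, {"distance": 4.0, "angle": 70.0}, 0),
        (T.CATION_PI, {"distance": 7.0, "angle": 0.0}, 1),
        (T.CATION_PI, {"distance": 7.5, "angle": 0.0}, 0),
        # Arg-Arg: guanidinium centroids <= 5
        (T.ARG_ARG, {"distance": 4.0}, 1),
        (T.ARG_ARG, {"distance": 5.0}, 1),
        (T.ARG_ARG, {"distance": 5.5}, 0),
    ],
)
def test_planted_geometry_detection(itype, geometry, n_expected):
    fp = make_dipeptide_pair(itype, geometry=None, **geometry)
    detector = {
        T.CALPHA: detect_calpha,
        T.HBOND: detect_hbonds,
        T.SALT_BRIDGE: detect_salt_bridges,
        T.DISULFIDE: detect_disulfides,
        T.PI_PI: detect_pi_pi,
        T.CATION_PI: detect_cation_pi,
        T.ARG_ARG: detect_arg_arg_wrap,
    }[itype]
    records = detector(fp.system, 0, CRIT)
    assert len(records) == n_expected
    if n_expected and "distance" in geometry:
        assert records[0].descriptors["distance"] == pytest.approx(
            geometry["distance"], abs=1e-6
        )


def detect_arg_arg_wrap(system, frame, criteria):
    from rinmd.interactions import detect_arg_arg

    return detect_arg_arg(system, frame, criteria)


def test_hbond_angle_threshold_inclusive_at_exact_boundary():
    """A D-H...A angle of exactly 90 deg (machine-exact: orthogonal vectors)
    is accepted when the angle threshold is exactly 90 deg."""
    from rinmd.structure_io import AtomRecord, MolecularSystem

    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, "A"),
        AtomRecord(2, "HN", "H", "ALA", 1, "A"),
        AtomRecord(3, "O", "O", "ALA", 5, "A"),
    ]
    # H at origin, D straight up, A straight out: dot product exactly zero
    coords = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
    system = MolecularSystem(atoms, frames=[coords], bonds={(0, 1)})
    crit_incl = InteractionCriteria(hb_angle_min=90.0)
    assert len(detect_hbonds(system, 0, crit_incl)) == 1
    crit_above = InteractionCriteria(hb_angle_min=90.0 + 1e-9)
    assert detect_hbonds(system, 0, crit_above) == []


def test_disulfide_dihedral_band_inclusive_at_exact_boundary():
    """A CB-S-S-CB torsion of exactly 90 deg (machine-exact construction)
    sits inside the closed [60, 90] band."""
    from rinmd.structure_io import AtomRecord, MolecularSystem

    atoms = []
    for seq, names in ((1, ("SG", "CB")), (9, ("SG", "CB"))):
        for n in names:
            atoms.append(
                AtomRecord(len(atoms) + 1, n, n[0], "CYS", seq, "A")
            )
    coords = np.array(
        [[0.0, 0.0, 0.0], [0.0, 1.81, 0.0],  # SG1, CB1
         [2.05, 0.0, 0.0], [2.05, 0.0, 1.81]]  # SG2, CB2: torsion exactly 90
    )
    system = MolecularSystem(atoms, frames=[coords])
    assert len(detect_disulfides(system, 0, CRIT)) == 1
    tight = InteractionCriteria(ss_dihedral_lo=60.0, ss_dihedral_hi=89.999999)
    assert detect_disulfides(system, 0, tight) == []


def test_planted_disulfide_reports_signed_dihedral():
    fp = make_dipeptide_pair(T.DISULFIDE, dihedral=-85.0)
    rec = detect_disulfides(fp.system)[0]
    assert abs(rec.descriptors["dihedral"]) == pytest.approx(85.0, abs=1e-6)


def test_hbond_direction_stored_donor_first():
    fp = make_dipeptide_pair(T.HBOND)
    rec = detect_hbonds(fp.system)[0]
    donor_atom = fp.system.atoms[rec.atoms[0]]
    assert donor_atom.name == "N"
    assert rec.residue_i.residue_seq == donor_atom.residue_seq


def test_hbond_without_hydrogens_warns_and_returns_empty(helix):
    bald = helix.copy()
    keep = [i for i, a in enumerate(bald.atoms) if not a.is_hydrogen]
    from rinmd.structure_io import MolecularSystem

    bald = MolecularSystem(
        [bald.atoms[i] for i in keep], frames=[bald.coords(0)[keep]]
    )
    assert detect_hbonds(bald) == []


def test_calpha_sequence_neighbors_excluded(helix):
    recs = detect_calpha(helix)
    seps = {abs(r.residue_i.residue_seq - r.residue_j.residue_seq) for r in recs}
    assert recs and min(seps) > 2


def test_helix_hbond_ladder_matches_triple_enumeration(helix):
    records = detect_hbonds(helix)
    ladder = {(r.residue_i.residue_seq, r.residue_j.residue_seq) for r in records}
    # donor residue i+4 bonds back to acceptor carbonyl of residue i
    assert ladder == {(i + 4, i) for i in range(1, 9)}
    got = {r.atoms for r in records}
    assert got == oracles.brute_hbond_triples(helix)


# ---------------------------------------------------------------------------
# Exhaustive-enumeration equivalence on dense random systems
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [2, 5, 21])
def test_detectors_equal_brute_force_on_random_fixture(seed):
    system = make_random_system(30, seed=seed, box=14.0)
    assert oracles.pairs_from_records(detect_calpha(system)) == oracles.brute_calpha(system)
    assert oracles.pairs_from_records(detect_salt_bridges(system)) == (
        oracles.brute_salt_bridges(system)
    )
    assert oracles.pairs_from_records(detect_pi_pi(system)) == oracles.brute_pi_pi(system)
    assert oracles.pairs_from_records(detect_cation_pi(system)) == (
        oracles.brute_cation_pi(system)
    )
    from rinmd.interactions import detect_arg_arg

    assert oracles.pairs_from_records(detect_arg_arg(system)) == oracles.brute_arg_arg(system)
    assert {r.atoms for r in detect_hbonds(system)} == oracles.brute_hbond_triples(system)
    assert oracles.pairs_from_records(detect_coulomb(system)) == (
        oracles.brute_coulomb_edges(system)
    )
    assert oracles.pairs_from_records(detect_vdw(system)) == oracles.brute_vdw_edges(system)


def test_disulfides_equal_brute_force_on_cys_cluster():
    system = make_random_system(12, seed=3, box=7.0, kinds=("CYS",))
    got = oracles.pairs_from_records(detect_disulfides(system))
    assert got == oracles.brute_disulfides(system)


def test_rigid_transform_invariance_of_detection():
    system = make_random_system(25, seed=13, box=14.0)
    rng = np.random.default_rng(99)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    moved = system.copy()
    moved.frames[0] = system.coords(0) @ q.T + rng.uniform(-30, 30, 3)
    for sys_ in (system, moved):
        sys_.has_charges = True
    before = [(r.type, r.pair()) for r in detect_all(system)]
    after = [(r.type, r.pair()) for r in detect_all(moved)]
    assert before == after


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

class TestCoulomb:
    def test_unit_charges_closed_form(self):
        fp = make_dipeptide_pair(T.COULOMB, q1=1.0, q2=-1.0, distance=3.32)
        e = coulomb_energy(fp.system, 0, 0, 1, CRIT)
        assert e == pytest.approx(COULOMB_CONSTANT * -1.0 / 3.32, abs=1e-10)
        assert e == pytest.approx(-100.019, abs=1e-3)

    def test_inverse_r_law(self):
        e1 = coulomb_energy(make_dipeptide_pair(T.COULOMB, distance=3.0).system, 0, 0, 1, CRIT)
        e2 = coulomb_energy(make_dipeptide_pair(T.COULOMB, distance=6.0).system, 0, 0, 1, CRIT)
        assert abs(e2) == pytest.approx(abs(e1) / 2.0, abs=1e-10)

    def test_matches_double_loop_oracle_on_random_residues(self):
        system = make_random_system(8, seed=42, box=10.0)
        rng = np.random.default_rng(0)
        for a in system.atoms:
            a.charge = float(rng.uniform(-1, 1))
        for i in range(4):
            for j in range(i + 1, 5):
                assert coulomb_energy(system, 0, i, j, CRIT) == pytest.approx(
                    oracles.brute_coulomb(system, 0, i, j), abs=1e-10
                )

    def test_unassigned_charges_is_configuration_error(self, helix):
        with pytest.raises(ConfigurationError):
            detect_coulomb(helix)


class TestLennardJones:
    def test_minimum_energy_is_minus_epsilon(self):
        fp = make_dipeptide_pair(T.VDW)  # planted at r = Rmin_ab
        e = lj_energy(fp.system, 0, 0, 1, CRIT)
        eps_ab = fp.system.atoms[0].lj_epsilon
        assert e == pytest.approx(-eps_ab, abs=1e-12)
        assert detect_vdw(fp.system)[0].descriptors["energy"] == pytest.approx(e)

    def test_closed_form_at_double_rmin(self):
        rmin_ab = 2.0 * 2.000
        fp = make_dipeptide_pair(T.VDW, distance=2 * rmin_ab)
        e = lj_energy(fp.system, 0, 0, 1, CRIT)
        eps_ab = fp.system.atoms[0].lj_epsilon
        assert e == pytest.approx(eps_ab * (2.0 ** -12 - 2 * 2.0 ** -6), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        system = make_random_system(8, seed=17, box=10.0)
        for i in range(4):
            for j in range(i + 1, 5):
                assert lj_energy(system, 0, i, j, CRIT) == pytest.approx(
                    oracles.brute_lj(system, 0, i, j), abs=1e-10
                )


# ---------------------------------------------------------------------------
# detect_all composition
# ---------------------------------------------------------------------------

class TestDetectAll:
    def test_single_type_equals_individual_detector(self, dense_random_system):
        only = detect_all(dense_random_system, enabled_types={T.CALPHA})
        alone = detect_calpha(dense_random_system)
        assert [(r.type, r.pair(), r.atoms) for r in only] == sorted(
            [(r.type, r.pair(), r.atoms) for r in alone]
        )

    def test_empty_enabled_set(self, dense_random_system):
        assert detect_all(dense_random_system, enabled_types=()) == []

    def test_union_of_detectors(self, dense_random_system):
        combined = detect_all(dense_random_system)
        by_type = {}
        for rec in combined:
            by_type.setdefault(rec.type, []).append((rec.pair(), rec.atoms))
        detectors = {
            T.CALPHA: detect_calpha,
            T.HBOND: detect_hbonds,
            T.SALT_BRIDGE: detect_salt_bridges,
            T.DISULFIDE: detect_disulfides,
            T.CATION_PI: detect_cation_pi,
            T.PI_PI: detect_pi_pi,
            T.COULOMB: detect_coulomb,
            T.VDW: detect_vdw,
        }
        from rinmd.interactions import detect_arg_arg

        detectors[T.ARG_ARG] = detect_arg_arg
        for t, det in detectors.items():
            expect = sorted((r.pair(), r.atoms) for r in det(dense_random_system))
            assert sorted(by_type.get(t, [])) == expect

    def test_deterministic_order(self, dense_random_system):
        a = detect_all(dense_random_system)
        b = detect_all(dense_random_system)
        assert [(r.type, r.pair(), r.atoms) for r in a] == [
            (r.type, r.pair(), r.atoms) for r in b
        ]
        types = [r.type for r in a]
        assert types == sorted(types)


def test_his_protonation_drives_cation_vs_pi():
    from rinmd.interactions import his_state
    from rinmd.structure_io import AtomRecord, MolecularSystem

    def his(resname, with_hd1, with_he2):
        names = [("CG", "C"), ("ND1", "N"), ("CD2", "C"), ("CE1", "C"), ("NE2", "N")]
        if with_hd1:
            names.append(("HD1", "H"))
        if with_he2:
            names.append(("HE2", "H"))
        atoms = [
            AtomRecord(serial=i + 1, name=n, element=e, residue_name=resname,
                       residue_seq=1, chain_id="A")
            for i, (n, e) in enumerate(names)
        ]
        ang = np.radians(90.0 + 72.0 * np.arange(5))
        xyz = np.column_stack([1.16 * np.cos(ang), 1.16 * np.sin(ang), np.zeros(5)])
        extra = [[0.0, 2.2, 0.0]] * (len(names) - 5)
        coords = np.vstack([xyz] + ([np.array(extra)] if extra else []))
        return MolecularSystem(atoms, frames=[coords])

    assert his_state(his("HIS", True, True), 0) == "cation"
    assert his_state(his("HIS", True, False), 0) == "pi"
    assert his_state(his("HIS", False, False), 0) == "pi"
    assert his_state(his("HSP", False, False), 0) == "cation"
    assert his_state(his("HSE", True, True), 0) == "pi"
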