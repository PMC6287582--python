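"""Synthetic structures, topologies and trajectories with planted interactions.

Every generator builds idealized residue fragments (standard bond lengths and
angles, assembled with explicit rotation/translation) posed so that exactly
the requested interaction holds at exactly the requested descriptor values.
Generated systems can be written as PDB + PSF + DCD + CHARMM parameter files,
exercising the same readers used for real data. With a fixed seed the
generated files are byte-identical across runs.

Planted geometries keep a margin of at least 0.2 angstrom / 5 degrees to the
detection threshold so that detection is unambiguous and noise-robust.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .correlation import ATOMIC_MASSES
from .errors import GenerationError
from .interactions import InteractionCriteria, InteractionType
from .structure_io import (
    AtomRecord,
    MolecularSystem,
    assign_nonbonded_params,
    bundled_parameter_path,
    write_dcd,
    write_pdb,
)

MIN_MARGIN_D = 0.2  # angstrom between planted value and threshold
BREAK_EXTRA = 2.0  # angstrom beyond the threshold for the "broken" pose


@dataclass
class PlantedInteraction:
    """One scheduled interaction in a synthetic trajectory."""

    type: InteractionType
    geometry: dict[str, float]
    presence: np.ndarray  # boolean, one entry per frame

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)


@dataclass
class FixturePair:
    """A two-residue system realizing one interaction, plus bookkeeping."""

    system: MolecularSystem
    type: InteractionType
    expected: dict[str, float]
    residue2_atoms: np.ndarray  # atom indices moved to break the interaction
    break_shift: np.ndarray  # displacement that breaks the interaction
    margin: float  # threshold minus planted metric (angstrom)


# -- atom record helpers -----------------------------------------------------

def _rec(name, element, atom_type, charge, resname, seq, chain="A"):
    return AtomRecord(
        serial=0,
        name=name,
        element=element,
        residue_name=resname,
        residue_seq=seq,
        chain_id=chain,
        charge=charge,
        atom_type=atom_type,
    )


def _finish(atoms, coords, bonds=None) -> MolecularSystem:
    for i, a in enumerate(atoms):
        a.serial = i + 1
    system = MolecularSystem(atoms, frames=[np.asarray(coords, dtype=float)], bonds=bonds)
    system.has_charges = True
    assign_nonbonded_params(system, bundled_parameter_path(), assign_charges=False)
    return system


def _phe_ring(seq, chain="A"):
    """PHE fragment: ring centered on the local origin, normal along +z."""
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    angles = (90.0, 150.0, 30.0, 210.0, 330.0, 270.0)
    atoms, coords = [], []
    for n, ang in zip(names, angles):
        atoms.append(_rec(n, "C", "CA", -0.115 if n != "CG" else 0.0, "PHE", seq, chain))
        coords.append(
            [1.39 * math.cos(math.radians(ang)), 1.39 * math.sin(math.radians(ang)), 0.0]
        )
    atoms.append(_rec("CB", "C", "CT2", -0.18, "PHE", seq, chain))
    coords.append([0.0, 2.9, 0.0])
    atoms.append(_rec("CA", "C", "CT1", 0.07, "PHE", seq, chain))
    coords.append([0.0, 4.1, 0.9])
    return atoms, np.array(coords)


def _guanidinium(seq, chain="A"):
    """ARG fragment: planar guanidinium whose centroid is the local origin."""
    atoms = [
        _rec("CZ", "C", "C", 0.64, "ARG", seq, chain),
        _rec("NE", "N", "NC2", -0.70, "ARG", seq, chain),
        _rec("NH1", "N", "NC2", -0.80, "ARG", seq, chain),
        _rec("NH2", "N", "NC2", -0.80, "ARG", seq, chain),
        _rec("CA", "C", "CT1", 0.07, "ARG", seq, chain),
    ]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.33, 0.0, 0.0],
            [1.33 * math.cos(math.radians(120)), 1.33 * math.sin(math.radians(120)), 0.0],
            [1.33 * math.cos(math.radians(240)), 1.33 * math.sin(math.radians(240)), 0.0],
            [4.3, 0.0, 1.2],
        ]
    )
    # shift so that the CZ/NE/NH1/NH2 centroid sits exactly at the origin
    coords[:4] -= coords[:4].mean(axis=0)
    return atoms, coords


def _build_pair(itype: InteractionType, criteria: InteractionCriteria, **geom) -> FixturePair:
    """Pose two residue fragments so `itype` holds at the requested values."""
    c = criteria
    t = itype
    if t == InteractionType.CALPHA:
        d = float(geom.get("distance", 7.5))
        atoms = [
            _rec("CA", "C", "CT1", 0.07, "ALA", 1),
            _rec("CB", "C", "CT3", -0.27, "ALA", 1),
            _rec("CA", "C", "CT1", 0.07, "ALA", 10),
            _rec("CB", "C", "CT3", -0.27, "ALA", 10),
        ]
        coords = [[0, 0, 0], [0, 1.53, 0], [d, 0, 0], [d, 1.53, 0]]
        res2 = np.array([2, 3])
        margin = c.calpha_d - d
        direction = np.array([1.0, 0.0, 0.0])
        expected = {"distance": d}
    elif t == InteractionType.HBOND:
        d = float(geom.get("distance", 2.8))
        theta = float(geom.get("angle", 180.0))
        d_dh = 1.0
        disc = d * d - (d_dh * math.sin(math.radians(theta))) ** 2
        if disc < 0:
            raise GenerationError("requested H-bond geometry is unsatisfiable")
        ha = d_dh * math.cos(math.radians(theta)) + math.sqrt(disc)
        if ha <= 0:
            raise GenerationError("requested H-bond geometry is unsatisfiable")
        h = np.zeros(3)
        n = np.array([d_dh, 0.0, 0.0])
        a = ha * np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta)), 0.0])
        u = a / np.linalg.norm(a)
        c_at = a + 1.23 * u
        atoms = [
            _rec("N", "N", "NH1", -0.47, "ALA", 1),
            _rec("HN", "H", "H", 0.31, "ALA", 1),
            _rec("CA", "C", "CT1", 0.16, "ALA", 1),
            _rec("O", "O", "O", -0.51, "ALA", 10),
            _rec("C", "C", "C", 0.51, "ALA", 10),
            _rec("CA", "C", "CT1", 0.0, "ALA", 10),
        ]
        coords = [n, h, n + np.array([0.8, -1.2, 0.0]), a, c_at, c_at + np.array([1.2, 0.9, 0.0])]
        bonds = {(0, 1), (0, 2), (3, 4), (4, 5)}
        res2 = np.array([3, 4, 5])
        margin = c.hb_d - d
        expected = {"distance": d, "angle": theta}
        fp = FixturePair(
            _finish(atoms, coords, bonds), t, expected, res2,
            _break_vector(res2_dir=u, margin=c.hb_d - d), margin,
        )
        return fp
    elif t == InteractionType.SALT_BRIDGE:
        d = float(geom.get("distance", 3.5))
        arg_atoms, arg_coords = _guanidinium(1)
        nh1 = arg_coords[2]
        base = nh1 + np.array([0.0, d, 0.0])
        atoms = arg_atoms + [
            _rec("OE1", "O", "OC", -0.76, "GLU", 10),
            _rec("CD", "C", "CC", 0.62, "GLU", 10),
            _rec("OE2", "O", "OC", -0.76, "GLU", 10),
            _rec("CA", "C", "CT1", 0.07, "GLU", 10),
        ]
        coords = list(arg_coords) + [
            base,
            base + np.array([0.0, 1.25, 0.0]),
            base + np.array([1.08, 1.87, 0.0]),
            base + np.array([0.0, 4.0, 1.0]),
        ]
        res2 = np.arange(len(arg_atoms), len(atoms))
        margin = c.sb_d - d
        direction = np.array([0.0, 1.0, 0.0])
        expected = {"distance": d}
    elif t == InteractionType.DISULFIDE:
        d = float(geom.get("distance", 2.05))
        chi = float(geom.get("dihedral", 85.0))
        ang_css = 103.0
        sg1 = np.zeros(3)
        sg2 = np.array([d, 0.0, 0.0])
        cb1 = sg1 + 1.81 * np.array(
            [math.cos(math.radians(ang_css)), math.sin(math.radians(ang_css)), 0.0]
        )
        direction = (
            math.cos(math.radians(ang_css)) * np.array([-1.0, 0.0, 0.0])
            + math.sin(math.radians(ang_css))
            * (
                math.cos(math.radians(chi)) * np.array([0.0, 1.0, 0.0])
                + math.sin(math.radians(chi)) * np.array([0.0, 0.0, 1.0])
            )
        )
        cb2 = sg2 + 1.81 * direction
        atoms = [
            _rec("SG", "S", "S", -0.23, "CYS", 1),
            _rec("CB", "C", "CT2", -0.11, "CYS", 1),
            _rec("CA", "C", "CT1", 0.07, "CYS", 1),
            _rec("SG", "S", "S", -0.23, "CYS", 10),
            _rec("CB", "C", "CT2", -0.11, "CYS", 10),
            _rec("CA", "C", "CT1", 0.07, "CYS", 10),
        ]
        coords = [sg1, cb1, cb1 + np.array([-1.0, 1.2, 0.0]), sg2, cb2, cb2 + np.array([1.0, 1.2, 0.0])]
        res2 = np.array([3, 4, 5])
        margin = c.ss_d - d
        direction = np.array([1.0, 0.0, 0.0])
        expected = {"distance": d, "dihedral": chi}
    elif t == InteractionType.PI_PI:
        d = float(geom.get("distance", 4.5))
        a1, c1 = _phe_ring(1)
        a2, c2 = _phe_ring(10)
        atoms = a1 + a2
        coords = list(c1) + list(c2 + np.array([0.0, 0.0, d]))
        res2 = np.arange(len(a1), len(atoms))
        margin = c.pipi_d - d
        direction = np.array([0.0, 0.0, 1.0])
        expected = {"distance": d, "normal_angle": 0.0}
    elif t == InteractionType.CATION_PI:
        d = float(geom.get("distance", 4.0))
        theta = float(geom.get("angle", 0.0))
        a1, c1 = _phe_ring(1)
        pos = d * np.array(
            [math.sin(math.radians(theta)), 0.0, math.cos(math.radians(theta))]
        )
        atoms = a1 + [
            _rec("NZ", "N", "NH3", -0.30, "LYS", 10),
            _rec("CE", "C", "CT2", 0.21, "LYS", 10),
            _rec("CA", "C", "CT1", 0.07, "LYS", 10),
        ]
        coords = list(c1) + [pos, pos + np.array([1.0, 1.0, 0.5]), pos + np.array([2.4, 2.4, 1.2])]
        res2 = np.arange(len(a1), len(atoms))
        margin = c.catpi_d - d
        direction = pos / np.linalg.norm(pos)
        expected = {"distance": d, "angle": theta}
    elif t == InteractionType.ARG_ARG:
        d = float(geom.get("distance", 4.0))
        a1, c1 = _guanidinium(1)
        a2, c2 = _guanidinium(10)
        atoms = a1 + a2
        coords = list(c1) + list(c2 + np.array([0.0, 0.0, d]))
        res2 = np.arange(len(a1), len(atoms))
        margin = c.argarg_d - d
        direction = np.array([0.0, 0.0, 1.0])
        expected = {"distance": d}
    elif t == InteractionType.COULOMB:
        d = float(geom.get("distance", 3.32))
        q1 = float(geom.get("q1", 1.0))
        q2 = float(geom.get("q2", -1.0))
        atoms = [
            _rec("NZ", "N", "NH3", q1, "LYS", 1),
            _rec("OD1", "O", "OC", q2, "ASP", 10),
        ]
        coords = [[0, 0, 0], [d, 0, 0]]
        res2 = np.array([1])
        margin = c.coulomb_cutoff - d
        direction = np.array([1.0, 0.0, 0.0])
        from .interactions import COULOMB_CONSTANT

        expected = {"energy": COULOMB_CONSTANT * q1 * q2 / (c.dielectric * d)}
    elif t == InteractionType.VDW:
        eps = 0.450  # sulfur in the bundled table: deep enough for an edge
        rmin_ab = 2.0 * 2.000
        d = float(geom.get("distance", rmin_ab))
        atoms = [
            _rec("SD", "S", "S", 0.0, "MET", 1),
            _rec("SD", "S", "S", 0.0, "MET", 10),
        ]
        coords = [[0, 0, 0], [d, 0, 0]]
        res2 = np.array([1])
        margin = c.coulomb_cutoff - d
        direction = np.array([1.0, 0.0, 0.0])
        sr6 = (rmin_ab / d) ** 6
        expected = {"energy": eps * (sr6 ** 2 - 2 * sr6)}
    else:
        raise GenerationError(f"no pair constructor for {t}")

    system = _finish(atoms, coords)
    return FixturePair(system, t, expected, res2, _break_vector(direction, margin), margin)


def _break_vector(res2_dir: np.ndarray, margin: float) -> np.ndarray:
    return (max(margin, 0.0) + BREAK_EXTRA) * res2_dir / np.linalg.norm(res2_dir)


def make_dipeptide_pair(
    itype: InteractionType,
    criteria: InteractionCriteria | None = None,
    out_dir=None,
    prefix: str = "pair",
    **geometry,
) -> FixturePair:
    """Two residues posed so exactly the requested interaction holds.

    Negative plants (geometry violating the criterion) are allowed: the
    returned system is built as requested and simply yields no detection.
    If `out_dir` is given, PDB/PSF/parameter files are written there.
    """
    c = criteria or InteractionCriteria()
    fp = _build_pair(InteractionType(itype), c, **geometry)
    if out_dir is not None:
        write_fixture_files(fp.system, out_dir, prefix)
    return fp


# ---------------------------------------------------------------------------
# File writing
# ---------------------------------------------------------------------------

def write_psf(system: MolecularSystem, path, ext: bool = False) -> None:
    """Write an X-PLOR-style PSF (standard or EXT column widths)."""
    wid = 10 if ext else 8
    lines = ["PSF EXT" if ext else "PSF", ""]
    lines.append(f"{1:{wid}d} !NTITLE")
    lines.append(" REMARKS synthetic topology written by rinmd")
    lines.append("")
    lines.append(f"{system.n_atoms:{wid}d} !NATOM")
    for i, a in enumerate(system.atoms, start=1):
        mass = ATOMIC_MASSES.get(a.element, 12.011)
        lines.append(
            f"{i:{wid}d} {a.chain_id:<8s} {a.residue_seq:<8d} {a.residue_name:<8s} "
            f"{a.name:<8s} {(a.atom_type or a.element):<8s} {a.charge:14.6f}{mass:14.4f}{0:12d}"
        )
    lines.append("")
    bonds = sorted(system.bonds)
    lines.append(f"{len(bonds):{wid}d} !NBOND: bonds")
    row = []
    for i, j in bonds:
        row += [i + 1, j + 1]
        if len(row) == 8:
            lines.append("".join(f"{x:{wid}d}" for x in row))
            row = []
    if row:
        lines.append("".join(f"{x:{wid}d}" for x in row))
    lines.append("")
    lines.append(f"{0:{wid}d} !NTHETA: angles")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_files(system: MolecularSystem, out_dir, prefix: str,
                        dcd: bool = False, endian: str = "<") -> dict[str, Path]:
    """Write PDB (frame 0), PSF, parameter file and optionally a DCD."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": out_dir / f"{prefix}.pdb",
        "psf": out_dir / f"{prefix}.psf",
        "prm": out_dir / f"{prefix}.prm",
    }
    write_pdb(system, paths["pdb"])
    write_psf(system, paths["psf"])
    shutil.copyfile(bundled_parameter_path(), paths["prm"])
    if dcd:
        paths["dcd"] = out_dir / f"{prefix}.dcd"
        write_dcd(paths["dcd"], system.frames, endian=endian)
    return paths


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFixture:
    system: MolecularSystem  # with all frames populated
    planted: list[PlantedInteraction]
    pair_residues: list[tuple]  # ResidueKey pairs, one per plant

    def write(self, out_dir, prefix: str = "traj", endian: str = "<") -> dict[str, Path]:
        return write_fixture_files(self.system, out_dir, prefix, dcd=True, endian=endian)


def make_trajectory(
    planted: Sequence[PlantedInteraction],
    n_frames: int,
    noise: float = 0.0,
    seed: int = 0,
    criteria: InteractionCriteria | None = None,
) -> TrajectoryFixture:
    """Trajectory in which each planted pair toggles between a formed and a
    broken pose according to its presence schedule.

    Pairs are laid out 60 angstrom apart so they cannot cross-interact.
    Gaussian coordinate noise of the given standard deviation is added to
    every atom; it must stay well below every planted margin
    (6 sigma <= margin) or generation fails.
    """
    c = criteria or InteractionCriteria()
    if not planted:
        raise GenerationError("no planted interactions given")
    rng = np.random.default_rng(seed)
    pairs: list[FixturePair] = []
    all_atoms: list[AtomRecord] = []
    base_coords: list[np.ndarray] = []
    moved_atoms: list[np.ndarray] = []
    shifts: list[np.ndarray] = []
    offset_atoms = 0
    for p_idx, plant in enumerate(planted):
        if len(plant.presence) != n_frames:
            raise GenerationError(
                f"plant {p_idx}: schedule length {len(plant.presence)} != n_frames {n_frames}"
            )
        fp = _build_pair(InteractionType(plant.type), c, **plant.geometry)
        if fp.margin < MIN_MARGIN_D:
            raise GenerationError(
                f"plant {p_idx}: margin {fp.margin:.3f} A below the {MIN_MARGIN_D} A minimum"
            )
        if noise > 0 and 6.0 * noise > fp.margin:
            raise GenerationError(
                f"plant {p_idx}: noise {noise} A exceeds margin {fp.margin:.3f} A / 6"
            )
        offset = np.array([60.0 * p_idx, 0.0, 0.0])
        for a in fp.system.atoms:
            all_atoms.append(
                AtomRecord(
                    serial=0,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_seq=a.residue_seq + 20 * p_idx,
                    chain_id=a.chain_id,
                    charge=a.charge,
                    lj_epsilon=a.lj_epsilon,
                    lj_rmin_half=a.lj_rmin_half,
                    atom_type=a.atom_type,
                )
            )
        base_coords.append(fp.system.coords(0) + offset)
        moved_atoms.append(fp.residue2_atoms + offset_atoms)
        shifts.append(fp.break_shift)
        offset_atoms += fp.system.n_atoms
        pairs.append(fp)
    for i, a in enumerate(all_atoms):
        a.serial = i + 1
    base = np.vstack(base_coords)

    frames = []
    for f in range(n_frames):
        xyz = base.copy()
        for p_idx, plant in enumerate(planted):
            if not plant.presence[f]:
                xyz[moved_atoms[p_idx]] += shifts[p_idx]
        if noise > 0:
            xyz += rng.normal(0.0, noise, size=xyz.shape)
        frames.append(xyz)

    system = MolecularSystem(all_atoms, frames=frames)
    system.has_charges = True
    system.has_lj = True
    # record the residue pair of each plant for downstream assertions
    pair_keys = []
    cursor = 0
    for p_idx, fp in enumerate(pairs):
        keys = [
            system.residue_keys[int(system.atom_residue_index[cursor])],
            system.residue_keys[int(system.atom_residue_index[cursor + fp.system.n_atoms - 1])],
        ]
        pair_keys.append(tuple(keys))
        cursor += fp.system.n_atoms
    return TrajectoryFixture(system=system, planted=list(planted), pair_residues=pair_keys)


def correlated_schedules(
    n_frames: int, rho: float, p: float = 0.5, seed: int = 0, n_schedules: int = 2
) -> np.ndarray:
    """Bernoulli(p) presence schedules with pairwise correlation rho to the first.

    Construction: schedule 0 is the shared driver; each other schedule copies
    the driver with probability rho and redraws independently otherwise, which
    gives corr(schedule 0, schedule k) = rho exactly in expectation.
    """
    if not (0.0 <= rho <= 1.0):
        raise GenerationError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    driver = rng.random(n_frames) < p
    out = [driver]
    for _ in range(n_schedules - 1):
        fresh = rng.random(n_frames) < p
        copy_mask = rng.random(n_frames) < rho
        out.append(np.where(copy_mask, driver, fresh))
    return np.asarray(out, dtype=bool)


def decaying_correlation_schedules(
    n_pairs: int, frames_per_window: int, seed: int = 0, p: float = 0.5
) -> np.ndarray:
    """Schedules over 3 windows with planted correlation decaying to zero.

    Window 0: all pairs follow one shared driver (maximal coupling);
    window 1: half of the pairs follow the driver; window 2: all independent.
    Used to emulate an initially concerted conformational change whose
    coordination is lost over time.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for w, frac in enumerate((1.0, 0.5, 0.0)):
        driver = rng.random(frames_per_window) < p
        n_coupled = int(round(frac * n_pairs))
        block = []
        for k in range(n_pairs):
            if k < n_coupled:
                block.append(driver.copy())
            else:
                block.append(rng.random(frames_per_window) < p)
        windows.append(np.asarray(block))
    return np.concatenate(windows, axis=1)


# ---------------------------------------------------------------------------
# Random systems (for exhaustive-enumeration cross-checks)
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _fragment(kind: str, seq: int, chain: str = "A"):
    """Small residue fragment in local coordinates."""
    if kind == "ALA":
        return (
            [_rec("CA", "C", "CT1", 0.07, "ALA", seq, chain),
             _rec("CB", "C", "CT3", -0.27, "ALA", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [0.0, 1.53, 0.0]]),
        )
    if kind == "DONOR":
        return (
            [_rec("N", "N", "NH1", -0.47, "GLY", seq, chain),
             _rec("HN", "H", "H", 0.31, "GLY", seq, chain),
             _rec("CA", "C", "CT2", 0.16, "GLY", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [-0.8, 1.2, 0.0]]),
        )
    if kind == "ACCEPTOR":
        return (
            [_rec("O", "O", "O", -0.51, "SER", seq, chain),
             _rec("C", "C", "C", 0.51, "SER", seq, chain),
             _rec("CA", "C", "CT1", 0.0, "SER", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [1.23, 0.0, 0.0], [2.0, 1.2, 0.0]]),
        )
    if kind == "ARG":
        return _guanidinium(seq, chain)
    if kind == "LYS":
        return (
            [_rec("NZ", "N", "NH3", -0.30, "LYS", seq, chain),
             _rec("CE", "C", "CT2", 0.21, "LYS", seq, chain),
             _rec("CA", "C", "CT1", 0.07, "LYS", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [1.3, 0.8, 0.0], [3.5, 2.0, 1.0]]),
        )
    if kind == "ASP":
        return (
            [_rec("OD1", "O", "OC", -0.76, "ASP", seq, chain),
             _rec("OD2", "O", "OC", -0.76, "ASP", seq, chain),
             _rec("CG", "C", "CC", 0.62, "ASP", seq, chain),
             _rec("CA", "C", "CT1", 0.07, "ASP", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [2.16, 0.0, 0.0], [1.08, 0.62, 0.0],
                      [1.08, 2.1, 1.0]]),
        )
    if kind == "GLU":
        return (
            [_rec("OE1", "O", "OC", -0.76, "GLU", seq, chain),
             _rec("OE2", "O", "OC", -0.76, "GLU", seq, chain),
             _rec("CD", "C", "CC", 0.62, "GLU", seq, chain),
             _rec("CA", "C", "CT1", 0.07, "GLU", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [2.16, 0.0, 0.0], [1.08, 0.62, 0.0],
                      [1.08, 2.6, 1.2]]),
        )
    if kind == "CYS":
        return (
            [_rec("SG", "S", "S", -0.23, "CYS", seq, chain),
             _rec("CB", "C", "CT2", -0.11, "CYS", seq, chain),
             _rec("CA", "C", "CT1", 0.07, "CYS", seq, chain)],
            np.array([[0.0, 0.0, 0.0], [1.05, 1.47, 0.0], [0.6, 2.3, 1.2]]),
        )
    if kind == "PHE":
        return _phe_ring(seq, chain)
    if kind == "HSD":
        names = ("CG", "ND1", "CD2", "CE1", "NE2")
        elements = ("C", "N", "C", "C", "N")
        types = ("CPH1", "NR1", "CPH1", "CPH2", "NR2")
        atoms = [
            _rec(n, e, t, 0.0, "HSD", seq, chain)
            for n, e, t in zip(names, elements, types)
        ]
        ang = np.radians(90.0 + 72.0 * np.arange(5))
        coords = np.column_stack(
            [1.16 * np.cos(ang), 1.16 * np.sin(ang), np.zeros(5)]
        )
        return atoms, coords
    raise GenerationError(f"unknown fragment kind {kind!r}")


RANDOM_FRAGMENT_KINDS = (
    "ALA", "DONOR", "ACCEPTOR", "ARG", "LYS", "ASP", "GLU", "CYS", "PHE", "HSD",
)


def make_random_system(
    n_residues: int = 30,
    seed: int = 0,
    box: float = 25.0,
    kinds: Sequence[str] = RANDOM_FRAGMENT_KINDS,
) -> MolecularSystem:
    """Residue fragments at random positions/orientations in a cubic box.

    Produces a dense mix of all chemistry classes so that every detector has
    hits and misses; used to cross-check detectors against exhaustive
    enumeration.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for r in range(n_residues):
        kind = kinds[int(rng.integers(len(kinds)))]
        frag_atoms, frag_coords = _fragment(kind, seq=r + 1)
        rot = _random_rotation(rng)
        shift = rng.uniform(0.0, box, size=3)
        atoms.extend(frag_atoms)
        coords.extend(list(frag_coords @ rot.T + shift))
    return _finish(atoms, coords)


# ---------------------------------------------------------------------------
# Multi-chain assemblies
# ---------------------------------------------------------------------------

def make_assembly(
    n_chains: int,
    n_assemblies: int,
    inter_chain_planted: Sequence[tuple[str, str]] = (),
    inter_assembly_planted: Sequence[tuple[str, str]] = (),
    intra_per_chain: int = 1,
    criteria: InteractionCriteria | None = None,
) -> tuple[MolecularSystem, dict[str, int]]:
    """Multi-chain system with known intra/inter-chain/inter-assembly H-bonds.

    Chains are labelled A, B, ...; assemblies are contiguous blocks of chains.
    Each (x, y) entry of the planted lists adds one hydrogen bond between a
    donor residue of chain x and an acceptor residue of chain y. Returns the
    system and the chain -> assembly-index map.
    """
    if n_chains < 2:
        raise GenerationError("an assembly fixture needs at least 2 chains")
    if n_chains > 26:
        raise GenerationError("at most 26 single-letter chains supported")
    c = criteria or InteractionCriteria()
    chains = [chr(ord("A") + i) for i in range(n_chains)]
    per = max(1, math.ceil(n_chains / n_assemblies))
    assembly_map = {ch: i // per for i, ch in enumerate(chains)}

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    bonds: set[tuple[int, int]] = set()
    seq_counter = {ch: 0 for ch in chains}

    def add_hb(chain_d: str, chain_a: str, origin: np.ndarray):
        """One planted N-H...O hydrogen bond (2.8 A, linear) at `origin`."""
        seq_counter[chain_d] += 1
        seq_d = seq_counter[chain_d]
        seq_counter[chain_a] += 1
        seq_a = seq_counter[chain_a]
        base = len(atoms)
        n = origin + np.array([1.0, 0.0, 0.0])
        h = origin
        a_pos = origin + np.array([-1.8, 0.0, 0.0])  # d(N, O) = 2.8
        c_pos = a_pos + np.array([-1.23, 0.0, 0.0])
        atoms.extend(
            [
                _rec("N", "N", "NH1", -0.47, "ALA", seq_d, chain_d),
                _rec("HN", "H", "H", 0.31, "ALA", seq_d, chain_d),
                _rec("CA", "C", "CT1", 0.16, "ALA", seq_d, chain_d),
                _rec("O", "O", "O", -0.51, "ALA", seq_a, chain_a),
                _rec("C", "C", "C", 0.51, "ALA", seq_a, chain_a),
                _rec("CA", "C", "CT1", 0.0, "ALA", seq_a, chain_a),
            ]
        )
        coords.extend([n, h, n + np.array([0.8, 1.3, 0.0]), a_pos, c_pos,
                       c_pos + np.array([-1.2, 0.9, 0.0])])
        bonds.update({(base, base + 1), (base, base + 2), (base + 3, base + 4),
                      (base + 4, base + 5)})

    slot = 0
    for ch in chains:
        for _ in range(intra_per_chain):
            add_hb(ch, ch, np.array([60.0 * slot, 0.0, 0.0]))
            slot += 1
    for x, y in list(inter_chain_planted) + list(inter_assembly_planted):
        if x not in assembly_map or y not in assembly_map:
            raise GenerationError(f"planted chains {x!r}/{y!r} outside the assembly")
        add_hb(x, y, np.array([60.0 * slot, 0.0, 0.0]))
        slot += 1

    # residue atoms must be contiguous: sort atoms by (chain, seq) blockwise
    order = sorted(
        range(len(atoms)),
        key=lambda i: (atoms[i].chain_id, atoms[i].residue_seq, i),
    )
    remap = {old: new for new, old in enumerate(order)}
    atoms_sorted = [atoms[i] for i in order]
    coords_sorted = np.array([coords[i] for i in order])
    bonds_sorted = {(min(remap[i], remap[j]), max(remap[i], remap[j])) for i, j in bonds}
    system = _finish(atoms_sorted, coords_sorted, bonds_sorted)
    return system, assembly_map
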