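"""Detection of the nine residue-residue interaction classes in one frame.

Each detector evaluates an explicit geometric or energetic criterion over a
single coordinate frame and returns one InteractionRecord per hit, carrying
the descriptors that define the interaction (distances in angstrom, angles in
degrees, energies in kcal/mol).

Default thresholds:

==============  =========================================================
C-alpha         d(CA_i, CA_j) <= 8 A, |sequence separation| > 2 in-chain
Hydrogen bond   d(donor, acceptor) <= 3 A and D-H...A angle >= 120 deg
Salt bridge     min basic-N -- acidic-O distance <= 6 A
Disulfide       d(SG, SG) <= 3 A and |chi(CB-S-S-CB)| in [60, 90] deg
pi-pi           aromatic ring centroid distance <= 6 A
Cation-pi       ring centroid -- cation <= 7 A, normal angle in
                [0, 60] U [120, 180] deg
Arg-Arg         guanidinium centroid distance <= 5 A
Coulomb         |sum 332.0636 q_a q_b / (eps_r r)| >= 1 kcal/mol within 12 A
van der Waals   12-6 Lennard-Jones sum <= -0.1 kcal/mol within 12 A
==============  =========================================================

All "<=" thresholds are inclusive. Every detector is equivalent to exhaustive
enumeration over its candidate pairs (no spatial pruning shortcuts that could
drop boundary cases).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import angle, dihedral, distance, folded_angle, ring_descriptor
from .structure_io import MolecularSystem, ResidueKey

logger = logging.getLogger("rinmd")

COULOMB_CONSTANT = 332.0636  # kcal/mol * angstrom / e^2


class InteractionType(enum.IntEnum):
    CALPHA = 1
    HBOND = 2
    SALT_BRIDGE = 3
    DISULFIDE = 4
    CATION_PI = 5
    PI_PI = 6
    ARG_ARG = 7
    COULOMB = 8
    VDW = 9


ALL_TYPES = tuple(InteractionType)


@dataclass(frozen=True)
class InteractionCriteria:
    """Tunable thresholds for all detectors (angstrom / degrees / kcal/mol)."""

    calpha_d: float = 8.0
    hb_d: float = 3.0
    hb_angle_min: float = 120.0
    sb_d: float = 6.0
    ss_d: float = 3.0
    ss_dihedral_lo: float = 60.0
    ss_dihedral_hi: float = 90.0
    pipi_d: float = 6.0
    catpi_d: float = 7.0
    catpi_angle_bands: tuple[tuple[float, float], ...] = ((0.0, 60.0), (120.0, 180.0))
    argarg_d: float = 5.0
    coulomb_cutoff: float = 12.0
    coulomb_energy_thr: float = 1.0
    vdw_energy_thr: float = -0.1
    seq_exclusion_calpha: int = 2
    dielectric: float = 1.0

    def __post_init__(self):
        for name in ("calpha_d", "hb_d", "sb_d", "ss_d", "pipi_d", "catpi_d",
                     "argarg_d", "coulomb_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 <= self.ss_dihedral_lo <= self.ss_dihedral_hi <= 180):
            raise ConfigurationError("disulfide dihedral band must satisfy 0 <= a <= b <= 180")
        for lo, hi in self.catpi_angle_bands:
            if not (0 <= lo <= hi <= 180):
                raise ConfigurationError("cation-pi angle bands must lie in [0, 180]")


@dataclass
class InteractionRecord:
    """One detected interaction in one frame.

    residue_i/residue_j are ordered i < j by residue ordering, except for
    hydrogen bonds where residue_i is the donor and residue_j the acceptor.
    """

    type: InteractionType
    residue_i: ResidueKey
    residue_j: ResidueKey
    atoms: tuple[int, ...]
    descriptors: dict[str, float]
    frame_index: int = 0

    def pair(self) -> tuple[ResidueKey, ResidueKey]:
        """Unordered residue pair in canonical order."""
        a, b = self.residue_i, self.residue_j
        return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Residue chemistry tables
# ---------------------------------------------------------------------------

RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    # Trp is treated as one fused 9-atom pi system (single centroid/normal)
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

BASIC_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS+": ("ND1", "NE2"),
}

ACIDIC_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

_HIS_NAMES = {"HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"}
GUANIDINIUM_ATOMS = ("CZ", "NH1", "NH2", "NE")

# Hydrogen-bond chemistry (configurable in principle via these module tables):
# donors are N/O/S heavy atoms carrying at least one hydrogen; acceptors are
# any oxygen, nitrogens with no bound hydrogen, and the MET/CYS sulfurs.
HB_DONOR_ELEMENTS = frozenset({"N", "O", "S"})
HB_ACCEPTOR_S_RESIDUES = frozenset({"MET", "CYS"})


def his_state(system: MolecularSystem, res_index: int) -> str | None:
    """'cation', 'pi' or None. Protonation from residue name or H inventory.

    HSP/HIP are cationic by name, HSD/HSE/HID/HIE neutral by name; a plain
    HIS is cationic iff both ring nitrogens carry a hydrogen (HD1 and HE2).
    A HIS with no hydrogens at all is treated as a neutral pi system.
    """
    name = system.residue_keys[res_index].residue_name.upper()
    if name not in _HIS_NAMES:
        return None
    if name in ("HSP", "HIP"):
        return "cation"
    if name in ("HSD", "HSE", "HID", "HIE"):
        return "pi"
    names = system.residue_atom_names(res_index)
    return "cation" if ("HD1" in names and "HE2" in names) else "pi"


def _canon_res(name: str) -> str:
    name = name.upper()
    return "HIS" if name in _HIS_NAMES else name


def residue_adjacency(system: MolecularSystem) -> set[tuple[int, int]]:
    """Covalently adjacent residue pairs.

    From the bond table when available (PSF input); otherwise a sequence
    proxy: same chain and author numbering differing by one.
    """
    adj: set[tuple[int, int]] = set()
    if system.bonds:
        res_of = system.atom_residue_index
        for a, b in system.bonds:
            ra, rb = int(res_of[a]), int(res_of[b])
            if ra != rb:
                adj.add((min(ra, rb), max(ra, rb)))
        return adj
    for ri in range(system.n_residues):
        for rj in range(ri + 1, system.n_residues):
            ki, kj = system.residue_keys[ri], system.residue_keys[rj]
            if ki.chain_id == kj.chain_id and abs(ki.residue_seq - kj.residue_seq) == 1:
                adj.add((ri, rj))
    return adj


def _ordered(system, ri: int, rj: int) -> tuple[int, int]:
    ki, kj = system.residue_keys[ri], system.residue_keys[rj]
    return (ri, rj) if ki <= kj else (rj, ri)


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_calpha(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """C-alpha contacts: CA-CA distance <= d, excluding near-in-sequence pairs."""
    c = criteria or InteractionCriteria()
    xyz = system.coords(frame)
    ca: list[tuple[int, int]] = []  # (residue index, CA atom index)
    for r in range(system.n_residues):
        i = system.atom_index(r, "CA")
        if i is None:
            logger.warning("residue %s lacks a CA atom; skipped for C-alpha contacts",
                           system.residue_keys[r].label())
            continue
        ca.append((r, i))
    out = []
    for a in range(len(ca)):
        ra, ia = ca[a]
        for b in range(a + 1, len(ca)):
            rb, ib = ca[b]
            ka, kb = system.residue_keys[ra], system.residue_keys[rb]
            if ka.chain_id == kb.chain_id and abs(ka.residue_seq - kb.residue_seq) <= c.seq_exclusion_calpha:
                continue
            d = distance(xyz[ia], xyz[ib])
            if d <= c.calpha_d:
                ri, rj = _ordered(system, ra, rb)
                out.append(
                    InteractionRecord(
                        InteractionType.CALPHA,
                        system.residue_keys[ri],
                        system.residue_keys[rj],
                        (ia, ib) if ri == ra else (ib, ia),
                        {"distance": d},
                        frame,
                    )
                )
    return out


def _hb_donors_acceptors(system: MolecularSystem):
    """Donor (heavy atom, [H indices]) list and acceptor atom list."""
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    for i, a in enumerate(system.atoms):
        if a.is_hydrogen:
            continue
        if a.element in HB_DONOR_ELEMENTS:
            hs = system.bonded_hydrogens(i)
            if a.element == "O" or a.element == "N":
                if hs:
                    donors.append((i, hs))
                if a.element == "O" or (a.element == "N" and not hs):
                    acceptors.append(i)
            elif a.element == "S":
                if hs:
                    donors.append((i, hs))
                if _canon_res(a.residue_name) in HB_ACCEPTOR_S_RESIDUES:
                    acceptors.append(i)
    return donors, acceptors


def detect_hbonds(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Hydrogen bonds: d(D, A) <= d and D-H...A angle at H >= a.

    One record per (donor, hydrogen, acceptor) triple; residue_i is the donor
    residue (direction is preserved).
    """
    c = criteria or InteractionCriteria()
    if not any(a.is_hydrogen for a in system.atoms):
        logger.warning("hydrogen-bond detection requested but the system has no hydrogens")
        return []
    xyz = system.coords(frame)
    donors, acceptors = _hb_donors_acceptors(system)
    out = []
    for d_idx, h_list in donors:
        rd = int(system.atom_residue_index[d_idx])
        for a_idx in acceptors:
            ra = int(system.atom_residue_index[a_idx])
            if ra == rd:
                continue
            dda = distance(xyz[d_idx], xyz[a_idx])
            if dda > c.hb_d:
                continue
            for h_idx in h_list:
                ang = angle(xyz[d_idx] - xyz[h_idx], xyz[a_idx] - xyz[h_idx])
                if ang >= c.hb_angle_min:
                    out.append(
                        InteractionRecord(
                            InteractionType.HBOND,
                            system.residue_keys[rd],
                            system.residue_keys[ra],
                            (d_idx, h_idx, a_idx),
                            {"distance": dda, "angle": ang},
                            frame,
                        )
                    )
    return out


def detect_salt_bridges(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Salt bridges: min distance between basic N and acidic O groups <= d."""
    c = criteria or InteractionCriteria()
    xyz = system.coords(frame)
    basic: list[tuple[int, list[int]]] = []
    acidic: list[tuple[int, list[int]]] = []
    for r in range(system.n_residues):
        res = _canon_res(system.residue_keys[r].residue_name)
        if res in ("ARG", "LYS"):
            names = BASIC_GROUP_ATOMS[res]
        elif res == "HIS" and his_state(system, r) == "cation":
            names = BASIC_GROUP_ATOMS["HIS+"]
        else:
            names = ()
        if names:
            atoms = [system.atom_index(r, n) for n in names]
            atoms = [a for a in atoms if a is not None]
            if atoms:
                basic.append((r, atoms))
        if res in ACIDIC_GROUP_ATOMS:
            atoms = [system.atom_index(r, n) for n in ACIDIC_GROUP_ATOMS[res]]
            atoms = [a for a in atoms if a is not None]
            if atoms:
                acidic.append((r, atoms))
    out = []
    for rb, n_atoms in basic:
        for ra, o_atoms in acidic:
            if rb == ra:
                continue
            best = None
            for n_i in n_atoms:
                for o_i in o_atoms:
                    d = distance(xyz[n_i], xyz[o_i])
                    if best is None or d < best[0]:
                        best = (d, n_i, o_i)
            if best is not None and best[0] <= c.sb_d:
                ri, rj = _ordered(system, rb, ra)
                out.append(
                    InteractionRecord(
                        InteractionType.SALT_BRIDGE,
                        system.residue_keys[ri],
                        system.residue_keys[rj],
                        (best[1], best[2]),
                        {"distance": best[0]},
                        frame,
                    )
                )
    return out


def detect_disulfides(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Disulfide bonds: SG-SG <= d and |CB-S-S-CB dihedral| within [a, b]."""
    c = criteria or InteractionCriteria()
    xyz = system.coords(frame)
    cys = []
    for r in range(system.n_residues):
        if _canon_res(system.residue_keys[r].residue_name) in ("CYS", "CYX"):
            sg = system.atom_index(r, "SG")
            cb = system.atom_index(r, "CB")
            if sg is None:
                continue
            cys.append((r, sg, cb))
    out = []
    for a in range(len(cys)):
        ra, sga, cba = cys[a]
        for b in range(a + 1, len(cys)):
            rb, sgb, cbb = cys[b]
            d = distance(xyz[sga], xyz[sgb])
            if d > c.ss_d:
                continue
            if cba is None or cbb is None:
                logger.warning(
                    "disulfide candidate %s-%s skipped: missing CB",
                    system.residue_keys[ra].label(), system.residue_keys[rb].label(),
                )
                continue
            chi = dihedral(xyz[cba], xyz[sga], xyz[sgb], xyz[cbb])
            if c.ss_dihedral_lo <= abs(chi) <= c.ss_dihedral_hi:
                ri, rj = _ordered(system, ra, rb)
                out.append(
                    InteractionRecord(
                        InteractionType.DISULFIDE,
                        system.residue_keys[ri],
                        system.residue_keys[rj],
                        (cba, sga, sgb, cbb) if ri == ra else (cbb, sgb, sga, cba),
                        {"distance": d, "dihedral": chi},
                        frame,
                    )
                )
    return out


def aromatic_rings(system: MolecularSystem, frame: int = 0):
    """(residue index, RingDescriptor) for Phe/Tyr/Trp and neutral His rings."""
    xyz = system.coords(frame)
    rings = []
    for r in range(system.n_residues):
        res = _canon_res(system.residue_keys[r].residue_name)
        if res not in RING_ATOMS:
            continue
        if res == "HIS" and his_state(system, r) != "pi":
            continue  # protonated His is a cation, not a pi system
        idx = [system.atom_index(r, n) for n in RING_ATOMS[res]]
        if any(i is None for i in idx):
            logger.warning("residue %s has an incomplete aromatic ring; skipped",
                           system.residue_keys[r].label())
            continue
        rings.append((r, ring_descriptor(xyz[np.asarray(idx)], idx)))
    return rings


def cation_sites(system: MolecularSystem, frame: int = 0):
    """(residue index, position) of side-chain cations: Arg CZ, Lys NZ, His+ ring-N midpoint."""
    xyz = system.coords(frame)
    sites = []
    for r in range(system.n_residues):
        res = _canon_res(system.residue_keys[r].residue_name)
        if res == "ARG":
            i = system.atom_index(r, "CZ")
            if i is not None:
                sites.append((r, xyz[i], (i,)))
        elif res == "LYS":
            i = system.atom_index(r, "NZ")
            if i is not None:
                sites.append((r, xyz[i], (i,)))
        elif res == "HIS" and his_state(system, r) == "cation":
            i = system.atom_index(r, "ND1")
            j = system.atom_index(r, "NE2")
            if i is not None and j is not None:
                sites.append((r, 0.5 * (xyz[i] + xyz[j]), (i, j)))
    return sites


def detect_pi_pi(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """pi-pi interactions: ring centroid-centroid distance <= d.

    The inter-normal angle (folded to [0, 90]) is reported as a descriptor
    but not used as a filter.
    """
    c = criteria or InteractionCriteria()
    rings = aromatic_rings(system, frame)
    out = []
    for a in range(len(rings)):
        ra, da = rings[a]
        for b in range(a + 1, len(rings)):
            rb, db = rings[b]
            if ra == rb:
                continue
            d = distance(da.centroid, db.centroid)
            if d <= c.pipi_d:
                ri, rj = _ordered(system, ra, rb)
                first, second = (da, db) if ri == ra else (db, da)
                out.append(
                    InteractionRecord(
                        InteractionType.PI_PI,
                        system.residue_keys[ri],
                        system.residue_keys[rj],
                        tuple(first.member_atom_indices) + tuple(second.member_atom_indices),
                        {"distance": d, "normal_angle": folded_angle(da.normal, db.normal)},
                        frame,
                    )
                )
    return out


def detect_cation_pi(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Cation-pi: centroid-cation distance <= d and normal angle in the bands.

    The angle between the ring normal and the centroid-to-cation vector is
    accepted in [0, 60] or [120, 180] degrees; because the normal's sign is
    arbitrary the two bands are mirror images of each other.
    """
    c = criteria or InteractionCriteria()
    rings = aromatic_rings(system, frame)
    cations = cation_sites(system, frame)
    out = []
    for rr, ring in rings:
        for rc, pos, cat_atoms in cations:
            if rr == rc:
                continue
            d = distance(ring.centroid, pos)
            if d > c.catpi_d:
                continue
            v = pos - ring.centroid
            if np.linalg.norm(v) == 0.0:
                continue
            ang = angle(ring.normal, v)
            if any(lo <= ang <= hi for lo, hi in c.catpi_angle_bands):
                ri, rj = _ordered(system, rr, rc)
                out.append(
                    InteractionRecord(
                        InteractionType.CATION_PI,
                        system.residue_keys[ri],
                        system.residue_keys[rj],
                        tuple(ring.member_atom_indices) + tuple(cat_atoms),
                        {"distance": d, "angle": ang},
                        frame,
                    )
                )
    return out


def detect_arg_arg(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Arg-Arg pairing: guanidinium centroid (CZ, NH1, NH2, NE) distance <= d."""
    c = criteria or InteractionCriteria()
    xyz = system.coords(frame)
    groups = []
    for r in range(system.n_residues):
        if _canon_res(system.residue_keys[r].residue_name) != "ARG":
            continue
        idx = [system.atom_index(r, n) for n in GUANIDINIUM_ATOMS]
        if any(i is None for i in idx):
            logger.warning("arginine %s has an incomplete guanidinium group; skipped",
                           system.residue_keys[r].label())
            continue
        groups.append((r, xyz[np.asarray(idx)].mean(axis=0), tuple(idx)))
    out = []
    for a in range(len(groups)):
        ra, ca_, ia = groups[a]
        for b in range(a + 1, len(groups)):
            rb, cb_, ib = groups[b]
            d = distance(ca_, cb_)
            if d <= c.argarg_d:
                ri, rj = _ordered(system, ra, rb)
                out.append(
                    InteractionRecord(
                        InteractionType.ARG_ARG,
                        system.residue_keys[ri],
                        system.residue_keys[rj],
                        (ia + ib) if ri == ra else (ib + ia),
                        {"distance": d},
                        frame,
                    )
                )
    return out


def coulomb_energy(
    system: MolecularSystem,
    frame: int,
    res_i: int,
    res_j: int,
    criteria: InteractionCriteria | None = None,
) -> float:
    """Inter-residue Coulomb energy: 332.0636 sum q_a q_b / (eps_r r_ab).

    Only atom pairs within the cutoff contribute.
    """
    c = criteria or InteractionCriteria()
    if not system.has_charges:
        raise ConfigurationError("Coulomb energy requested but charges are not assigned")
    xyz = system.coords(frame)
    ai = system.residue_atom_indices[res_i]
    aj = system.residue_atom_indices[res_j]
    q = system.charge_array()
    diff = xyz[ai][:, None, :] - xyz[aj][None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    mask = r <= c.coulomb_cutoff
    if not mask.any():
        return 0.0
    qq = q[ai][:, None] * q[aj][None, :]
    with np.errstate(divide="ignore"):
        e = COULOMB_CONSTANT * qq / (c.dielectric * r)
    return float(e[mask].sum())


def lj_energy(
    system: MolecularSystem,
    frame: int,
    res_i: int,
    res_j: int,
    criteria: InteractionCriteria | None = None,
) -> float:
    """Inter-residue 12-6 Lennard-Jones energy with CHARMM combination rules.

    eps_ab = sqrt(eps_a eps_b), Rmin_ab = Rmin/2_a + Rmin/2_b; pairs beyond
    the cutoff are skipped.
    """
    c = criteria or InteractionCriteria()
    if not system.has_lj:
        raise ConfigurationError("LJ energy requested but parameters are not assigned")
    xyz = system.coords(frame)
    ai = system.residue_atom_indices[res_i]
    aj = system.residue_atom_indices[res_j]
    eps = np.array([a.lj_epsilon for a in system.atoms])
    rm2 = np.array([a.lj_rmin_half for a in system.atoms])
    diff = xyz[ai][:, None, :] - xyz[aj][None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    mask = (r <= c.coulomb_cutoff) & (r > 0)
    if not mask.any():
        return 0.0
    eps_ab = np.sqrt(eps[ai][:, None] * eps[aj][None, :])
    rmin_ab = rm2[ai][:, None] + rm2[aj][None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (rmin_ab / r) ** 6
        e = eps_ab * (sr6 ** 2 - 2.0 * sr6)
    return float(e[mask].sum())


def _residue_pair_candidates(system: MolecularSystem, frame: int, cutoff: float):
    """Residue pairs whose bounding spheres can contain atoms within cutoff."""
    xyz = system.coords(frame)
    centers = np.array([xyz[idx].mean(axis=0) for idx in system.residue_atom_indices])
    radii = np.array(
        [np.linalg.norm(xyz[idx] - centers[r], axis=1).max()
         for r, idx in enumerate(system.residue_atom_indices)]
    )
    n = system.n_residues
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) <= cutoff + radii[i] + radii[j]:
                yield i, j


def detect_coulomb(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Coulomb edges: |inter-residue electrostatic energy| >= threshold.

    Covalently adjacent residue pairs are excluded (their energy is dominated
    by through-bond terms the model does not describe).
    """
    c = criteria or InteractionCriteria()
    if not system.has_charges:
        raise ConfigurationError("Coulomb detection requested but charges are not assigned")
    adjacency = residue_adjacency(system)
    out = []
    for i, j in _residue_pair_candidates(system, frame, c.coulomb_cutoff):
        if (i, j) in adjacency:
            continue
        e = coulomb_energy(system, frame, i, j, c)
        if abs(e) >= c.coulomb_energy_thr:
            ri, rj = _ordered(system, i, j)
            out.append(
                InteractionRecord(
                    InteractionType.COULOMB,
                    system.residue_keys[ri],
                    system.residue_keys[rj],
                    (),
                    {"energy": e, "sign": 1.0 if e > 0 else -1.0},
                    frame,
                )
            )
    return out


def detect_vdw(
    system: MolecularSystem, frame: int = 0, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """van der Waals edges: inter-residue LJ energy <= threshold (attractive)."""
    c = criteria or InteractionCriteria()
    if not system.has_lj:
        raise ConfigurationError("vdW detection requested but LJ parameters are not assigned")
    adjacency = residue_adjacency(system)
    out = []
    for i, j in _residue_pair_candidates(system, frame, c.coulomb_cutoff):
        if (i, j) in adjacency:
            continue
        e = lj_energy(system, frame, i, j, c)
        if e <= c.vdw_energy_thr:
            ri, rj = _ordered(system, i, j)
            out.append(
                InteractionRecord(
                    InteractionType.VDW,
                    system.residue_keys[ri],
                    system.residue_keys[rj],
                    (),
                    {"energy": e},
                    frame,
                )
            )
    return out


_DETECTORS = {
    InteractionType.CALPHA: detect_calpha,
    InteractionType.HBOND: detect_hbonds,
    InteractionType.SALT_BRIDGE: detect_salt_bridges,
    InteractionType.DISULFIDE: detect_disulfides,
    InteractionType.CATION_PI: detect_cation_pi,
    InteractionType.PI_PI: detect_pi_pi,
    InteractionType.ARG_ARG: detect_arg_arg,
    InteractionType.COULOMB: detect_coulomb,
    InteractionType.VDW: detect_vdw,
}


def record_sort_key(rec: InteractionRecord):
    return (
        int(rec.type),
        (rec.residue_i.chain_id, rec.residue_i.residue_seq, rec.residue_i.insertion_code),
        (rec.residue_j.chain_id, rec.residue_j.residue_seq, rec.residue_j.insertion_code),
        rec.atoms,
    )


def detect_all(
    system: MolecularSystem,
    frame: int = 0,
    criteria: InteractionCriteria | None = None,
    enabled_types=None,
) -> list[InteractionRecord]:
    """Run the enabled detectors on one frame, in a deterministic order."""
    enabled = ALL_TYPES if enabled_types is None else tuple(enabled_types)
    records: list[InteractionRecord] = []
    for t in sorted(set(enabled)):
        records.extend(_DETECTORS[InteractionType(t)](system, frame, criteria))
    records.sort(key=record_sort_key)
    return records
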