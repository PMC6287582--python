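"""Reading protein structures and trajectories into a MolecularSystem.

Supported inputs: PDB coordinate files (static structures, possibly
multi-MODEL), CHARMM/X-PLOR PSF topologies (standard and EXT widths),
CHARMM/NAMD binary DCD trajectories (either endianness) and the NONBONDED
section of CHARMM parameter files. File parsing is delegated to MDAnalysis;
this module adds the pre-processing contract: heteroatom stripping, altloc
resolution, charge assignment from the topology, and Lennard-Jones / charge
assignment from force-field tables for static input.

Units throughout: angstrom, kcal/mol, elementary charges, degrees.
"""

from __future__ import annotations

import copy
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import charmm_templates
from .errors import (
    ConfigurationError,
    EmptySystemError,
    FormatError,
    TopologyInconsistencyError,
    UnsupportedDialectError,
)

# The 20 standard amino acids plus common protonation/bonding variants that
# must survive heteroatom stripping (a protonated histidine is still protein).
STANDARD_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX",
    }
)

_ELEMENTS = frozenset({"C", "N", "O", "S", "H", "P"})


def guess_element(name: str) -> str:
    """Element symbol from a PDB/PSF atom name (protein chemistry only)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    first = stripped[0].upper()
    return first if first in _ELEMENTS else first


@dataclass
class AtomRecord:
    """One atom: identity, residue membership and per-atom parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    insertion_code: str = ""
    charge: float = 0.0
    lj_epsilon: float = 0.0  # stored as a magnitude (CHARMM prints it negative)
    lj_rmin_half: float = 0.0
    atom_type: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Unique residue identity; orders by (chain, sequence number, icode)."""

    chain_id: str
    residue_seq: int
    insertion_code: str = ""
    residue_name: str = field(default="", compare=False)

    def label(self) -> str:
        base = f"{self.chain_id}:{self.residue_name}:{self.residue_seq}"
        return base + (f":{self.insertion_code}" if self.insertion_code else "")


class MolecularSystem:
    """Atoms, residue grouping and one or more coordinate frames.

    Residues are derived by grouping consecutive atoms sharing
    (chain, residue number, insertion code, residue name); the grouping must
    partition the atom list with unique keys.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        frames: Sequence[np.ndarray] | None = None,
        bonds: Iterable[tuple[int, int]] | None = None,
        frame_times: Sequence[float] | None = None,
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        self.frames: list[np.ndarray] = []
        self.frame_times: list[float] | None = list(frame_times) if frame_times else None
        self.bonds: set[tuple[int, int]] = set()
        if bonds:
            for i, j in bonds:
                self.bonds.add((min(i, j), max(i, j)))
        self.has_charges = False
        self.has_lj = False
        self._build_residues()
        if frames is not None:
            for f in frames:
                self.add_frame(f)

    # -- construction -----------------------------------------------------
    def _build_residues(self) -> None:
        keys: list[ResidueKey] = []
        spans: list[np.ndarray] = []
        current: ResidueKey | None = None
        bucket: list[int] = []
        for idx, a in enumerate(self.atoms):
            key = ResidueKey(a.chain_id, a.residue_seq, a.insertion_code, a.residue_name)
            if key != current:
                if bucket:
                    keys.append(current)  # type: ignore[arg-type]
                    spans.append(np.asarray(bucket, dtype=int))
                current = key
                bucket = []
            bucket.append(idx)
        if bucket:
            keys.append(current)  # type: ignore[arg-type]
            spans.append(np.asarray(bucket, dtype=int))
        if len({(k.chain_id, k.residue_seq, k.insertion_code) for k in keys}) != len(keys):
            raise TopologyInconsistencyError(
                "atoms of one residue are not contiguous or residue keys repeat"
            )
        self.residue_keys: list[ResidueKey] = keys
        self.residue_atom_indices: list[np.ndarray] = spans
        self.atom_residue_index = np.empty(len(self.atoms), dtype=int)
        for r, span in enumerate(spans):
            self.atom_residue_index[span] = r

    def add_frame(self, coords: np.ndarray, time: float | None = None) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyInconsistencyError(
                f"frame has shape {coords.shape}, expected ({len(self.atoms)}, 3)"
            )
        if not np.all(np.isfinite(coords)):
            raise FormatError("frame contains non-finite coordinates")
        self.frames.append(coords)
        if time is not None:
            if self.frame_times is None:
                self.frame_times = []
            self.frame_times.append(time)

    # -- basic queries -----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, frame: int = 0) -> np.ndarray:
        return self.frames[frame]

    def atom_index(self, residue_index: int, name: str) -> int | None:
        for i in self.residue_atom_indices[residue_index]:
            if self.atoms[i].name == name:
                return int(i)
        return None

    def residue_atom_names(self, residue_index: int) -> set[str]:
        return {self.atoms[i].name for i in self.residue_atom_indices[residue_index]}

    def charge_array(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def bonded_hydrogens(self, atom_index: int) -> list[int]:
        """Hydrogens attached to a heavy atom, from bonds or a 1.3 A fallback.

        Without a bond table (static PDB input) a hydrogen is paired with the
        nearest heavy atom of its own residue within 1.3 A in frame 0.
        """
        if self.bonds:
            out = [
                j if i == atom_index else i
                for (i, j) in self.bonds
                if (i == atom_index or j == atom_index)
            ]
            return [k for k in out if self.atoms[k].is_hydrogen]
        res = self.atom_residue_index[atom_index]
        xyz = self.frames[0]
        out = []
        for h in self.residue_atom_indices[res]:
            h = int(h)
            if not self.atoms[h].is_hydrogen:
                continue
            if np.linalg.norm(xyz[h] - xyz[atom_index]) <= 1.3:
                # nearest heavy atom wins when several are within range
                d_this = np.linalg.norm(xyz[h] - xyz[atom_index])
                closer = False
                for heavy in self.residue_atom_indices[res]:
                    heavy = int(heavy)
                    if heavy == atom_index or self.atoms[heavy].is_hydrogen:
                        continue
                    if np.linalg.norm(xyz[h] - xyz[heavy]) < d_this - 1e-9:
                        closer = True
                        break
                if not closer:
                    out.append(h)
        return out

    def copy(self) -> "MolecularSystem":
        new = MolecularSystem(
            [replace(a) for a in self.atoms],
            frames=[f.copy() for f in self.frames],
            bonds=set(self.bonds),
            frame_times=list(self.frame_times) if self.frame_times else None,
        )
        new.has_charges = self.has_charges
        new.has_lj = self.has_lj
        return new


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _scan_pdb_for_bad_line(path: Path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    return lineno
    return None


def read_pdb(path) -> MolecularSystem:
    """Read a PDB file (all MODELs become frames; altlocs resolved).

    ATOM and HETATM records are both kept: heteroatom removal is the separate
    :func:`strip_non_protein` step. Charges and LJ parameters are left at zero
    until :func:`assign_nonbonded_params`. Of alternate locations, the highest
    occupancy wins (ties: lowest altloc identifier).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        bad = _scan_pdb_for_bad_line(path)
        if bad is not None:
            raise FormatError(f"unparseable coordinate record at line {bad} of {path}") from exc
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    n = len(u.atoms)
    if n == 0:
        raise FormatError(f"{path} contains no ATOM/HETATM records")

    def attr(name, default):
        try:
            return getattr(u.atoms, name)
        except Exception:
            return [default] * n

    names = [str(x).strip() for x in attr("names", "")]
    resnames = [str(x).strip() for x in attr("resnames", "UNK")]
    resids = [int(x) for x in attr("resids", 0)]
    icodes = [str(x).strip() for x in attr("icodes", "")]
    chains = [str(x).strip() for x in attr("chainIDs", "")]
    segids = [str(x).strip() for x in attr("segids", "")]
    chains = [c if c else s for c, s in zip(chains, segids)]
    altlocs = [str(x).strip() for x in attr("altLocs", "")]
    occupancies = [float(x) for x in attr("occupancies", 1.0)]
    serials = [int(x) for x in attr("ids", 0)]
    try:
        elements = [str(x).strip().capitalize() for x in u.atoms.elements]
    except Exception:
        elements = [guess_element(nm) for nm in names]
    elements = [e if e else guess_element(nm) for e, nm in zip(elements, names)]

    # Altloc resolution: one conformer per (residue, atom-name) site.
    keep = np.ones(n, dtype=bool)
    sites: dict[tuple, list[int]] = {}
    for i in range(n):
        if altlocs[i]:
            sites.setdefault(
                (chains[i], resids[i], icodes[i], resnames[i], names[i]), []
            ).append(i)
    for members in sites.values():
        if len(members) > 1:
            best = min(members, key=lambda i: (-occupancies[i], altlocs[i]))
            for i in members:
                keep[i] = i == best

    idx = np.flatnonzero(keep)
    atoms = [
        AtomRecord(
            serial=serials[i],
            name=names[i],
            element=elements[i],
            residue_name=resnames[i],
            residue_seq=resids[i],
            chain_id=chains[i],
            insertion_code=icodes[i],
        )
        for i in idx
    ]
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(np.asarray(ts.positions, dtype=float)[idx])
    return MolecularSystem(atoms, frames=frames)


def write_pdb(system: MolecularSystem, path, frame: int = 0) -> None:
    """Write one frame as a PDB file (via MDAnalysis)."""
    u = to_mdanalysis(system, frame=frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def to_mdanalysis(system: MolecularSystem, frame: int = 0):
    """Build an in-memory MDAnalysis Universe mirroring the system."""
    import MDAnalysis as mda

    n = system.n_atoms
    resindex = system.atom_residue_index
    n_res = system.n_residues
    # map residues to segments by chain
    chain_order: list[str] = []
    for k in system.residue_keys:
        if k.chain_id not in chain_order:
            chain_order.append(k.chain_id)
    seg_of_chain = {c: i for i, c in enumerate(chain_order)}
    residue_segindex = [seg_of_chain[k.chain_id] for k in system.residue_keys]
    u = mda.Universe.empty(
        n,
        n_residues=n_res,
        n_segments=len(chain_order),
        atom_resindex=resindex,
        residue_segindex=residue_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in system.atoms])
    u.add_TopologyAttr("elements", [a.element for a in system.atoms])
    u.add_TopologyAttr("types", [a.atom_type or a.element for a in system.atoms])
    u.add_TopologyAttr("charges", [a.charge for a in system.atoms])
    u.add_TopologyAttr("resnames", [k.residue_name for k in system.residue_keys])
    u.add_TopologyAttr("resids", [k.residue_seq for k in system.residue_keys])
    u.add_TopologyAttr("icodes", [k.insertion_code for k in system.residue_keys])
    u.add_TopologyAttr("segids", chain_order)
    u.add_TopologyAttr("chainIDs", [a.chain_id for a in system.atoms])
    u.add_TopologyAttr("occupancies", [1.0] * n)
    u.add_TopologyAttr("tempfactors", [0.0] * n)
    if system.bonds:
        u.add_TopologyAttr("bonds", sorted(system.bonds))
    if system.frames:
        u.atoms.positions = system.frames[frame].astype(np.float32)
    return u


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

def _psf_charges_float64(path: Path, n_atoms: int) -> np.ndarray | None:
    """Re-read the PSF charge column at float64 so charge sums are exact."""
    charges = []
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        if "!NATOM" in line:
            declared = int(line.split()[0])
            start = i + 1
            break
    if start is None:
        return None
    for line in lines[start:]:
        if not line.strip():
            break
        parts = line.split()
        if len(parts) < 8:
            break
        try:
            charges.append(float(parts[6]))
        except ValueError:
            return None
        if len(charges) == declared:
            break
    if len(charges) != n_atoms:
        return None
    return np.asarray(charges, dtype=float)


def read_psf(path) -> MolecularSystem:
    """Read a CHARMM/X-PLOR PSF topology (standard or EXT widths).

    Returns a system with atoms, residue grouping, segment ids, per-atom
    charges and atom types, and the bond list -- but no coordinate frames.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if not head.startswith("PSF"):
        raise FormatError(f"{path} does not start with a PSF header")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), to_guess=())
    except Exception as exc:
        msg = str(exc)
        if "format" in msg.lower() or "dialect" in msg.lower():
            raise UnsupportedDialectError(f"unsupported PSF dialect in {path}: {msg}") from exc
        raise FormatError(f"could not parse PSF file {path}: {msg}") from exc

    n = len(u.atoms)
    charges = _psf_charges_float64(path, n)
    if charges is None:
        charges = np.asarray(u.atoms.charges, dtype=float)
    atoms = []
    for i, a in enumerate(u.atoms):
        name = str(a.name).strip()
        atoms.append(
            AtomRecord(
                serial=int(a.id),
                name=name,
                element=guess_element(name),
                residue_name=str(a.resname).strip(),
                residue_seq=int(a.resid),
                chain_id=str(a.segid).strip(),
                insertion_code="",
                charge=float(charges[i]),
                atom_type=str(a.type).strip(),
            )
        )
    bonds = set()
    try:
        for b in u.bonds:
            i, j = (int(b.atoms[0].index), int(b.atoms[1].index))
            bonds.add((min(i, j), max(i, j)))
    except Exception:
        pass
    system = MolecularSystem(atoms, bonds=bonds)
    system.has_charges = True
    return system


# ---------------------------------------------------------------------------
# DCD
# ---------------------------------------------------------------------------

def _dcd_header_peek(path: Path) -> tuple[str, int]:
    """Return (endianness character, fixed-atom count) from the DCD header."""
    with open(path, "rb") as fh:
        raw = fh.read(92)
    if len(raw) < 92:
        raise FormatError(f"{path} is too short to be a DCD file")
    for endian in ("<", ">"):
        (marker,) = struct.unpack(endian + "i", raw[:4])
        if marker == 84:
            (namnf,) = struct.unpack(endian + "i", raw[8 + 4 * 8 : 8 + 4 * 9])
            return endian, namnf
    raise FormatError(f"{path} does not have a valid DCD header record")


def read_dcd(
    path,
    system: MolecularSystem,
    stride: int = 1,
    first: int = 0,
    last: int | None = None,
) -> MolecularSystem:
    """Append frames [first, last] sampled every `stride` from a DCD file.

    Both little- and big-endian files are accepted; unit-cell records are
    skipped. Trajectories with fixed-atom blocks are rejected.
    """
    from MDAnalysis.lib.formats.libdcd import DCDFile

    path = Path(path)
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    _, namnf = _dcd_header_peek(path)
    if namnf != 0:
        raise UnsupportedDialectError(
            f"{path} uses DCD fixed-atom blocks (namnf={namnf}), which are unsupported"
        )
    with DCDFile(str(path)) as f:
        if f.header["natoms"] != system.n_atoms:
            raise TopologyInconsistencyError(
                f"DCD has {f.header['natoms']} atoms, system has {system.n_atoms}"
            )
        n_avail = f.n_frames
        stop = n_avail if last is None else last + 1
        if first < 0 or stop > n_avail or first >= stop:
            raise ConfigurationError(
                f"frame range [{first}, {stop - 1}] outside available 0..{n_avail - 1}"
            )
        try:
            data = f.readframes(start=first, stop=stop, step=stride, order="fac")
        except Exception as exc:
            raise FormatError(
                f"truncated DCD {path}: last complete frame is {n_avail - 1}"
            ) from exc
    for xyz in data.xyz:
        system.add_frame(np.asarray(xyz, dtype=float))
    return system


def write_dcd(path, frames: Sequence[np.ndarray], endian: str = "<", delta: float = 1.0) -> None:
    """Write a CHARMM-format DCD file with explicit byte order.

    `endian` is "<" (little) or ">" (big). No unit-cell or fixed-atom blocks
    are written. Coordinates are stored as float32.
    """
    frames = [np.asarray(f, dtype=np.float32) for f in frames]
    if not frames:
        raise ConfigurationError("cannot write a DCD with zero frames")
    natoms = frames[0].shape[0]
    if endian not in ("<", ">"):
        raise ConfigurationError("endian must be '<' or '>'")

    def record(payload: bytes) -> bytes:
        m = struct.pack(endian + "i", len(payload))
        return m + payload + m

    icntrl = [0] * 20
    icntrl[0] = len(frames)  # NSET
    icntrl[1] = 1  # ISTART
    icntrl[2] = 1  # NSAVC
    icntrl[3] = len(frames)  # NSTEP
    icntrl[19] = 24  # CHARMM version flag
    header = b"CORD"
    for k, v in enumerate(icntrl):
        if k == 9:
            header += struct.pack(endian + "f", float(delta))
        else:
            header += struct.pack(endian + "i", v)
    title = b"* generated by rinmd".ljust(80)
    title_rec = struct.pack(endian + "i", 1) + title
    with open(path, "wb") as fh:
        fh.write(record(header))
        fh.write(record(title_rec))
        fh.write(record(struct.pack(endian + "i", natoms)))
        for f in frames:
            for axis in range(3):
                fh.write(record(np.ascontiguousarray(f[:, axis]).astype(endian + "f4").tobytes()))


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def strip_non_protein(
    system: MolecularSystem, extra_resnames: Iterable[str] = ()
) -> MolecularSystem:
    """Keep only atoms of the 20 standard amino acids and protonation variants.

    Residue and atom indexing is re-derived; input order is preserved.
    Idempotent. Raises EmptySystemError if nothing remains.
    """
    allowed = STANDARD_RESNAMES | {r.upper() for r in extra_resnames}
    keep = np.array([a.residue_name.upper() in allowed for a in system.atoms], dtype=bool)
    if not keep.any():
        raise EmptySystemError("no protein residues remain after heteroatom removal")
    idx = np.flatnonzero(keep)
    remap = {int(old): new for new, old in enumerate(idx)}
    atoms = [copy.copy(system.atoms[i]) for i in idx]
    bonds = {
        (remap[i], remap[j])
        for (i, j) in system.bonds
        if i in remap and j in remap
    }
    new = MolecularSystem(
        atoms,
        frames=[f[idx] for f in system.frames],
        bonds=bonds,
        frame_times=list(system.frame_times) if system.frame_times else None,
    )
    new.has_charges = system.has_charges
    new.has_lj = system.has_lj
    return new


def parse_charmm_nonbonded(path) -> dict[str, tuple[float, float]]:
    """Parse the NONBONDED section of a CHARMM parameter file.

    Returns {atom type: (epsilon magnitude kcal/mol, Rmin/2 angstrom)}.
    """
    section_keywords = {
        "BONDS", "ANGLES", "DIHEDRALS", "IMPROPER", "IMPROPERS", "CMAP",
        "NBFIX", "HBOND", "END", "RETURN",
    }
    table: dict[str, tuple[float, float]] = {}
    in_section = False
    continuation = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!")[0].rstrip()
            if not line.strip() or line.lstrip().startswith("*"):
                continue
            token0 = line.split()[0].upper()
            if token0.startswith("NONBONDED"):
                in_section = True
                continuation = line.rstrip().endswith("-")
                continue
            if not in_section:
                continue
            if continuation:  # options wrapped onto following lines
                continuation = line.rstrip().endswith("-")
                continue
            if token0 in section_keywords:
                break
            if token0.startswith("CUTNB"):  # stray option line
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"malformed NONBONDED line {lineno}: {raw.rstrip()!r}")
            try:
                eps = float(parts[2])
                rmin2 = float(parts[3])
            except ValueError as exc:
                raise FormatError(
                    f"malformed NONBONDED line {lineno}: {raw.rstrip()!r}"
                ) from exc
            table[parts[0]] = (abs(eps), rmin2)
    if not table:
        raise FormatError(f"no NONBONDED section found in {path}")
    return table


def bundled_parameter_path() -> Path:
    """Path of the parameter table distributed with the package."""
    return Path(__file__).parent / "data" / "nonbonded_minimal.prm"


def assign_nonbonded_params(
    system: MolecularSystem, param_path=None, assign_charges: bool | None = None
) -> MolecularSystem:
    """Assign Lennard-Jones parameters (and, for static input, charges).

    Atom types come from the PSF when present; otherwise from the bundled
    residue-template table, which then also supplies partial charges.
    Epsilon is stored as a magnitude. Mutates and returns `system`.
    """
    if param_path is None:
        param_path = bundled_parameter_path()
    table = parse_charmm_nonbonded(param_path)

    if assign_charges is None:
        assign_charges = not system.has_charges
    unmapped_template: list[str] = []
    for a in system.atoms:
        if not a.atom_type:
            hit = charmm_templates.lookup(a.residue_name, a.name)
            if hit is None:
                unmapped_template.append(f"{a.residue_name}/{a.name}")
                continue
            a.atom_type = hit[0]
            if assign_charges:
                a.charge = hit[1]
    if unmapped_template:
        raise ConfigurationError(
            "no template atom type for: " + ", ".join(sorted(set(unmapped_template)))
        )

    missing = sorted({a.atom_type for a in system.atoms if a.atom_type not in table})
    if missing:
        raise ConfigurationError(
            f"atom types missing from {param_path}: " + ", ".join(missing)
        )
    for a in system.atoms:
        eps, rmin2 = table[a.atom_type]
        a.lj_epsilon = eps
        a.lj_rmin_half = rmin2
    system.has_lj = True
    if assign_charges:
        system.has_charges = True
    return system
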