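import logging

import numpy as np
import pytest
from hypothesis import settings

from rinmd.fixtures import make_random_system

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("rinmd").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dense_random_system():
    """30 residue fragments packed in a 14 A box: hits for most detectors."""
    return make_random_system(30, seed=2, box=14.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20, 20, size=3)


def build_helix(n_residues=10, phi=-55.0, psi=-52.0):
    """Ideal poly-alanine alpha-helix backbone (N, HN, CA, C, O per residue).

    The default helical torsions give an i -> i+4 amide-to-carbonyl ladder
    with d(N, O) = 2.91 A and a nearly linear N-H...O angle.

    Atoms are placed by internal coordinates (NeRF): standard bond lengths
    N-CA 1.458, CA-C 1.525, C-N 1.329, C=O 1.231, N-H 1.0; trans peptide
    (omega 180); the amide H is anti to the carbonyl O across the C-N bond.
    """
    from rinmd.structure_io import AtomRecord, MolecularSystem

    def place(a, b, c, bond, theta_deg, phi_deg):
        theta = np.radians(theta_deg)
        phi_ = np.radians(phi_deg)
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n = np.cross(ab, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d2 = np.array(
            [
                -bond * np.cos(theta),
                bond * np.sin(theta) * np.cos(phi_),
                bond * np.sin(theta) * np.sin(phi_),
            ]
        )
        return c + d2[0] * bc + d2[1] * m + d2[2] * n

    coords = {}
    # seed first residue
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([1.458, 0.0, 0.0])
    coords[(0, "C")] = coords[(0, "CA")] + 1.525 * np.array(
        [np.cos(np.radians(180 - 111.2)), np.sin(np.radians(180 - 111.2)), 0.0]
    )
    for i in range(n_residues):
        if i > 0:
            coords[(i, "N")] = place(
                coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
                1.329, 116.2, psi,
            )
            coords[(i, "CA")] = place(
                coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
                1.458, 121.7, 180.0,
            )
            coords[(i, "C")] = place(
                coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
                1.525, 111.2, phi,
            )
        nxt_n = place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")], 1.329, 116.2, psi
        )
        coords[(i, "O")] = place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")], 1.231, 120.8,
            psi + 180.0,
        )
        if i > 0:
            coords[(i, "HN")] = place(
                coords[(i - 1, "O")], coords[(i - 1, "C")], coords[(i, "N")],
                1.0, 119.5, 180.0,
            )
        del nxt_n
    atoms = []
    xyz = []
    serial = 1
    for i in range(n_residues):
        for name, elem in (("N", "N"), ("HN", "H"), ("CA", "C"), ("C", "C"), ("O", "O")):
            if (i, name) not in coords:
                continue
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=elem, residue_name="ALA",
                    residue_seq=i + 1, chain_id="A",
                )
            )
            xyz.append(coords[(i, name)])
            serial += 1
    return MolecularSystem(atoms, frames=[np.array(xyz)])


@pytest.fixture(scope="session")
def helix():
    return build_helix(12)
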