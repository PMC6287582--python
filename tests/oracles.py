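"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain double loops straight from the criterion
definitions, with no shared code paths with the package detectors (other than
the public MolecularSystem accessors), so that agreement is meaningful.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

HIS_NAMES = {"HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"}

RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def _canon(resname):
    resname = resname.upper()
    return "HIS" if resname in HIS_NAMES else resname


def _his_cationic(system, r):
    name = system.residue_keys[r].residue_name.upper()
    if name in ("HSP", "HIP"):
        return True
    if name in ("HSD", "HSE", "HID", "HIE"):
        return False
    names = system.residue_atom_names(r)
    return "HD1" in names and "HE2" in names


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def pairs_from_records(records):
    """Canonical comparable set: {(label_i, label_j)} (unordered pairs)."""
    out = set()
    for rec in records:
        a, b = rec.pair()
        out.add((a.label(), b.label()))
    return out


def brute_calpha(system, frame=0, d_max=8.0, seq_excl=2):
    xyz = system.coords(frame)
    hits = set()
    n = system.n_residues
    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = system.residue_keys[i], system.residue_keys[j]
            ai = system.atom_index(i, "CA")
            aj = system.atom_index(j, "CA")
            if ai is None or aj is None:
                continue
            if ki.chain_id == kj.chain_id and abs(ki.residue_seq - kj.residue_seq) <= seq_excl:
                continue
            if _dist(xyz[ai], xyz[aj]) <= d_max:
                a, b = sorted([ki, kj])
                hits.add((a.label(), b.label()))
    return hits


def _hydrogens_of(system, heavy, xyz):
    """Hydrogens attached to `heavy`: bond table, or nearest-heavy within 1.3 A."""
    if system.bonds:
        return [
            (j if i == heavy else i)
            for (i, j) in system.bonds
            if (i == heavy or j == heavy)
            and system.atoms[j if i == heavy else i].is_hydrogen
        ]
    out = []
    res = int(system.atom_residue_index[heavy])
    for h in system.residue_atom_indices[res]:
        h = int(h)
        if not system.atoms[h].is_hydrogen:
            continue
        dh = _dist(xyz[h], xyz[heavy])
        if dh > 1.3:
            continue
        nearest = min(
            (
                _dist(xyz[h], xyz[int(k)])
                for k in system.residue_atom_indices[res]
                if int(k) != h and not system.atoms[int(k)].is_hydrogen
            ),
            default=np.inf,
        )
        if dh <= nearest + 1e-9:
            out.append(h)
    return out


def brute_hbond_triples(system, frame=0, d_max=3.0, angle_min=120.0):
    """All (donor atom, hydrogen, acceptor atom) triples passing the criterion."""
    xyz = system.coords(frame)
    donors, acceptors = [], []
    for i, a in enumerate(system.atoms):
        if a.is_hydrogen:
            continue
        hs = _hydrogens_of(system, i, xyz)
        if a.element in ("N", "O", "S") and hs:
            donors.append((i, hs))
        if a.element == "O":
            acceptors.append(i)
        elif a.element == "N" and not hs:
            acceptors.append(i)
        elif a.element == "S" and _canon(a.residue_name) in ("MET", "CYS"):
            acceptors.append(i)
    triples = set()
    for d, hs in donors:
        for acc in acceptors:
            if system.atom_residue_index[d] == system.atom_residue_index[acc]:
                continue
            if _dist(xyz[d], xyz[acc]) > d_max:
                continue
            for h in hs:
                u = xyz[d] - xyz[h]
                v = xyz[acc] - xyz[h]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang >= angle_min:
                    triples.add((d, h, acc))
    return triples


def brute_salt_bridges(system, frame=0, d_max=6.0):
    xyz = system.coords(frame)
    basic, acidic = [], []
    for r in range(system.n_residues):
        res = _canon(system.residue_keys[r].residue_name)
        if res == "ARG":
            names = ("NE", "NH1", "NH2")
        elif res == "LYS":
            names = ("NZ",)
        elif res == "HIS" and _his_cationic(system, r):
            names = ("ND1", "NE2")
        else:
            names = ()
        atoms = [system.atom_index(r, n) for n in names]
        atoms = [a for a in atoms if a is not None]
        if atoms:
            basic.append((r, atoms))
        names = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}.get(res, ())
        atoms = [system.atom_index(r, n) for n in names]
        atoms = [a for a in atoms if a is not None]
        if atoms:
            acidic.append((r, atoms))
    hits = set()
    for rb, ns in basic:
        for ra, os_ in acidic:
            if rb == ra:
                continue
            dmin = min(_dist(xyz[n], xyz[o]) for n in ns for o in os_)
            if dmin <= d_max:
                a, b = sorted([system.residue_keys[rb], system.residue_keys[ra]])
                hits.add((a.label(), b.label()))
    return hits


def _ring_centroid_normal(system, r, xyz):
    res = _canon(system.residue_keys[r].residue_name)
    names = RINGS.get(res)
    if names is None:
        return None
    if res == "HIS" and _his_cationic(system, r):
        return None
    idx = [system.atom_index(r, n) for n in names]
    if any(i is None for i in idx):
        return None
    pts = xyz[np.asarray(idx)]
    centroid = pts.mean(axis=0)
    # independent normal estimate: cross product of two ring chords
    # (exact for the planar rings used in fixtures)
    normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    normal /= np.linalg.norm(normal)
    return centroid, normal


def brute_pi_pi(system, frame=0, d_max=6.0):
    xyz = system.coords(frame)
    rings = []
    for r in range(system.n_residues):
        cn = _ring_centroid_normal(system, r, xyz)
        if cn is not None:
            rings.append((r, cn[0]))
    hits = set()
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            if _dist(rings[a][1], rings[b][1]) <= d_max:
                ka, kb = sorted(
                    [system.residue_keys[rings[a][0]], system.residue_keys[rings[b][0]]]
                )
                hits.add((ka.label(), kb.label()))
    return hits


def brute_cation_pi(system, frame=0, d_max=7.0):
    xyz = system.coords(frame)
    cations = []
    for r in range(system.n_residues):
        res = _canon(system.residue_keys[r].residue_name)
        if res == "ARG":
            i = system.atom_index(r, "CZ")
            if i is not None:
                cations.append((r, xyz[i]))
        elif res == "LYS":
            i = system.atom_index(r, "NZ")
            if i is not None:
                cations.append((r, xyz[i]))
        elif res == "HIS" and _his_cationic(system, r):
            i, j = system.atom_index(r, "ND1"), system.atom_index(r, "NE2")
            if i is not None and j is not None:
                cations.append((r, 0.5 * (xyz[i] + xyz[j])))
    hits = set()
    for r in range(system.n_residues):
        cn = _ring_centroid_normal(system, r, xyz)
        if cn is None:
            continue
        centroid, normal = cn
        for rc, pos in cations:
            if rc == r:
                continue
            if _dist(centroid, pos) > d_max:
                continue
            v = pos - centroid
            cosang = np.dot(normal, v) / np.linalg.norm(v)
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang <= 60.0 or ang >= 120.0:
                ka, kb = sorted([system.residue_keys[r], system.residue_keys[rc]])
                hits.add((ka.label(), kb.label()))
    return hits


def brute_arg_arg(system, frame=0, d_max=5.0):
    xyz = system.coords(frame)
    groups = []
    for r in range(system.n_residues):
        if _canon(system.residue_keys[r].residue_name) != "ARG":
            continue
        idx = [system.atom_index(r, n) for n in ("CZ", "NH1", "NH2", "NE")]
        if any(i is None for i in idx):
            continue
        groups.append((r, xyz[np.asarray(idx)].mean(axis=0)))
    hits = set()
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            if _dist(groups[a][1], groups[b][1]) <= d_max:
                ka, kb = sorted(
                    [system.residue_keys[groups[a][0]], system.residue_keys[groups[b][0]]]
                )
                hits.add((ka.label(), kb.label()))
    return hits


def brute_coulomb(system, frame, res_i, res_j, cutoff=12.0, dielectric=1.0):
    xyz = system.coords(frame)
    total = 0.0
    for a in system.residue_atom_indices[res_i]:
        for b in system.residue_atom_indices[res_j]:
            r = _dist(xyz[int(a)], xyz[int(b)])
            if r <= cutoff:
                total += 332.0636 * system.atoms[int(a)].charge * system.atoms[int(b)].charge / (
                    dielectric * r
                )
    return total


def brute_lj(system, frame, res_i, res_j, cutoff=12.0):
    xyz = system.coords(frame)
    total = 0.0
    for a in system.residue_atom_indices[res_i]:
        for b in system.residue_atom_indices[res_j]:
            a, b = int(a), int(b)
            r = _dist(xyz[a], xyz[b])
            if 0 < r <= cutoff:
                eps = math.sqrt(system.atoms[a].lj_epsilon * system.atoms[b].lj_epsilon)
                rmin = system.atoms[a].lj_rmin_half + system.atoms[b].lj_rmin_half
                total += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    return total


def _adjacent(system, i, j):
    if system.bonds:
        res_of = system.atom_residue_index
        return any(
            {int(res_of[a]), int(res_of[b])} == {i, j} for a, b in system.bonds
        )
    ki, kj = system.residue_keys[i], system.residue_keys[j]
    return ki.chain_id == kj.chain_id and abs(ki.residue_seq - kj.residue_seq) == 1


def brute_coulomb_edges(system, frame=0, cutoff=12.0, thr=1.0, dielectric=1.0):
    hits = set()
    for i in range(system.n_residues):
        for j in range(i + 1, system.n_residues):
            if _adjacent(system, i, j):
                continue
            if abs(brute_coulomb(system, frame, i, j, cutoff, dielectric)) >= thr:
                a, b = sorted([system.residue_keys[i], system.residue_keys[j]])
                hits.add((a.label(), b.label()))
    return hits


def brute_vdw_edges(system, frame=0, cutoff=12.0, thr=-0.1):
    hits = set()
    for i in range(system.n_residues):
        for j in range(i + 1, system.n_residues):
            if _adjacent(system, i, j):
                continue
            if brute_lj(system, frame, i, j, cutoff) <= thr:
                a, b = sorted([system.residue_keys[i], system.residue_keys[j]])
                hits.add((a.label(), b.label()))
    return hits


def brute_disulfides(system, frame=0, d_max=3.0, lo=60.0, hi=90.0):
    xyz = system.coords(frame)
    cys = []
    for r in range(system.n_residues):
        if _canon(system.residue_keys[r].residue_name) in ("CYS", "CYX"):
            sg, cb = system.atom_index(r, "SG"), system.atom_index(r, "CB")
            if sg is not None and cb is not None:
                cys.append((r, sg, cb))
    hits = set()
    for x in range(len(cys)):
        for y in range(x + 1, len(cys)):
            ra, sga, cba = cys[x]
            rb, sgb, cbb = cys[y]
            if _dist(xyz[sga], xyz[sgb]) > d_max:
                continue
            b1 = xyz[sga] - xyz[cba]
            b2 = xyz[sgb] - xyz[sga]
            b3 = xyz[cbb] - xyz[sgb]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.linalg.norm(b2))
            chi = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
            if lo <= abs(chi) <= hi:
                a, b = sorted([system.residue_keys[ra], system.residue_keys[rb]])
                hits.add((a.label(), b.label()))
    return hits


# ---------------------------------------------------------------------------
# Graph centralities (textbook formulas, BFS-based)
# ---------------------------------------------------------------------------

def bfs_distances_and_counts(adj, source):
    """Shortest-path distances and path counts from `source` (unweighted)."""
    n = len(adj)
    dist = [math.inf] * n
    sigma = [0] * n
    dist[source] = 0
    sigma[source] = 1
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] == math.inf:
                dist[v] = dist[u] + 1
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def textbook_centralities(adj):
    """degree/betweenness/closeness on an adjacency list (normalized as usual).

    Betweenness uses the pair-counting identity sigma_st(v) =
    sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t). Closeness uses the
    Wasserman-Faust within-component scaling. O(n^3); test-sized graphs only.
    """
    n = len(adj)
    dist = []
    sigma = []
    for s in range(n):
        d, sg = bfs_distances_and_counts(adj, s)
        dist.append(d)
        sigma.append(sg)
    degree = [len(adj[v]) / (n - 1) for v in range(n)]
    closeness = []
    for v in range(n):
        reach = [u for u in range(n) if u != v and dist[v][u] < math.inf]
        if reach:
            total = sum(dist[v][u] for u in reach)
            closeness.append((len(reach) / total) * (len(reach) / (n - 1)))
        else:
            closeness.append(0.0)
    betweenness = [0.0] * n
    for v in range(n):
        acc = 0.0
        for s in range(n):
            if s == v:
                continue
            for t in range(s + 1, n):
                if t == v or sigma[s][t] == 0:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    acc += sigma[s][v] * sigma[v][t] / sigma[s][t]
        norm = (n - 1) * (n - 2) / 2
        betweenness[v] = acc / norm if norm > 0 else 0.0
    return degree, betweenness, closeness


def textbook_pearson(x, y):
    """Pearson r from the covariance/sigma formula, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0 or sy == 0:
        return math.nan
    return cov / (sx * sy)
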