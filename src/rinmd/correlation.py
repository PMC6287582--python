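"""Interaction-count time series, Pearson correlation matrices and the
center-of-mass collective variable.

Each residue is represented, for one interaction type, by the vector of the
number of such interactions it participates in per frame. Pearson correlation
between these vectors identifies residue pairs whose interactions form and
break in a coordinated way. Zero-variance series have no defined correlation:
those entries are marked NaN (written as "NA"), never silently zeroed, and
are excluded from correlated-pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .interactions import InteractionRecord, InteractionType
from .structure_io import MolecularSystem, ResidueKey

# Standard atomic masses (u) for the elements occurring in proteins.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
}


@dataclass
class InteractionCountSeries:
    """Per-residue, per-frame counts of one interaction type."""

    type: InteractionType
    counts: np.ndarray  # (n_residues, n_frames) int
    labels: list[ResidueKey]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]


@dataclass
class CorrelationMatrix:
    """Pearson correlations between residue interaction-count series.

    Undefined entries (zero-variance series over the window) are NaN.
    """

    type: InteractionType
    r: np.ndarray  # (n, n) with NaN where undefined
    labels: list[ResidueKey]
    window: tuple[int, int]


def count_series(
    frame_records: Sequence[Sequence[InteractionRecord]],
    itype: InteractionType,
    nodes: Sequence[ResidueKey],
) -> InteractionCountSeries:
    """counts[res, f] = number of records of `itype` in frame f involving res.

    Involvement is undirected: a hydrogen bond increments both the donor and
    the acceptor residue.
    """
    index = {k: i for i, k in enumerate(nodes)}
    counts = np.zeros((len(nodes), len(frame_records)), dtype=int)
    for f, records in enumerate(frame_records):
        for rec in records:
            if rec.type != itype:
                continue
            counts[index[rec.residue_i], f] += 1
            counts[index[rec.residue_j], f] += 1
    return InteractionCountSeries(type=itype, counts=counts, labels=list(nodes))


def pearson_matrix(
    series: InteractionCountSeries, window: tuple[int, int] | None = None
) -> CorrelationMatrix:
    """Pearson correlation matrix over a closed frame-index window.

    Rows with zero variance over the window yield NaN rows/columns
    (correlation is undefined there); the diagonal is 1 for non-constant rows.
    """
    n_frames = series.n_frames
    if window is None:
        window = (0, n_frames - 1)
    first, last = window
    if first < 0 or last >= n_frames or last - first + 1 < 2:
        raise ConfigurationError(
            f"window {window} invalid: need >= 2 frames inside 0..{n_frames - 1}"
        )
    x = series.counts[:, first : last + 1].astype(float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    defined = norms > 0
    r = np.full((x.shape[0], x.shape[0]), np.nan)
    if defined.any():
        sub = centered[defined] / norms[defined, None]
        block = np.clip(sub @ sub.T, -1.0, 1.0)
        idx = np.flatnonzero(defined)
        r[np.ix_(idx, idx)] = block
        r[idx, idx] = 1.0
    return CorrelationMatrix(type=series.type, r=r, labels=series.labels, window=window)


def correlated_pair_counts(
    matrix: CorrelationMatrix, thresholds: Sequence[float]
) -> dict[float, int]:
    """Number of unordered residue pairs with |r| >= cutoff, per cutoff.

    The diagonal and undefined (NaN) entries are excluded.
    """
    iu = np.triu_indices_from(matrix.r, k=1)
    vals = matrix.r[iu]
    vals = vals[~np.isnan(vals)]
    return {float(t): int(np.count_nonzero(np.abs(vals) >= t)) for t in thresholds}


def pair_count_rates(
    matrices: Sequence[CorrelationMatrix], thresholds: Sequence[float]
) -> tuple[list[dict[float, int]], list[dict[float, float | None]]]:
    """Correlated-pair counts per window and their rates vs the first window.

    The rate for a cutoff is count_window / count_first; when the first window
    has zero pairs the rate is undefined and reported as None (not infinity).
    """
    counts = [correlated_pair_counts(m, thresholds) for m in matrices]
    ref = counts[0]
    rates: list[dict[float, float | None]] = []
    for c in counts:
        rates.append(
            {
                t: (c[t] / ref[t] if ref[t] > 0 else None)
                for t in (float(x) for x in thresholds)
            }
        )
    return counts, rates


def center_of_mass(system: MolecularSystem, atom_indices, frame: int) -> np.ndarray:
    xyz = system.coords(frame)
    idx = np.asarray(atom_indices, dtype=int)
    masses = np.array(
        [ATOMIC_MASSES.get(system.atoms[i].element, 12.011) for i in idx]
    )
    return (masses[:, None] * xyz[idx]).sum(axis=0) / masses.sum()


def collective_variable_d0(
    system: MolecularSystem,
    group_definitions: Sequence[Sequence[int]],
    frames: Sequence[int] | None = None,
    reference_atoms: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame mean distance between group centers of mass and a reference COM.

    D0(f) = (1/N) sum_n || COM(group_n, f) - COM(reference, f) ||, where the
    reference selection defaults to all atoms of the system. Groups are lists
    of atom indices (e.g. the atoms of each beta strand).
    """
    if not group_definitions:
        raise ConfigurationError("need at least one group")
    for g in group_definitions:
        if len(g) == 0:
            raise ConfigurationError("empty group in collective variable definition")
    if frames is None:
        frames = range(system.n_frames)
    if reference_atoms is None:
        reference_atoms = np.arange(system.n_atoms)
    frames = list(frames)
    out = np.empty(len(frames))
    for k, f in enumerate(frames):
        ref = center_of_mass(system, reference_atoms, f)
        dists = [
            np.linalg.norm(center_of_mass(system, g, f) - ref) for g in group_definitions
        ]
        out[k] = float(np.mean(dists))
    return out


def residue_atom_group(system: MolecularSystem, residue_indices: Sequence[int]) -> np.ndarray:
    """Atom indices of a residue selection (for group definitions)."""
    return np.concatenate([system.residue_atom_indices[r] for r in residue_indices])


def write_correlation(matrix: CorrelationMatrix, path, heatmap_path=None) -> None:
    """Write the matrix as labelled TSV ("NA" for undefined entries).

    Optionally renders a heatmap image (cosmetic; requires matplotlib).
    """
    labels = [k.label() for k in matrix.labels]
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            cells = [
                "NA" if np.isnan(v) else f"{v:.6f}" for v in matrix.r[i]
            ]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
    if heatmap_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(matrix.r, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"{matrix.type.name} interaction-count correlation")
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.savefig(heatmap_path, dpi=120)
        plt.close(fig)


def read_correlation(path, itype: InteractionType = InteractionType.HBOND) -> CorrelationMatrix:
    """Read a TSV matrix written by :func:`write_correlation`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([np.nan if c == "NA" else float(c) for c in parts[1:]])
    keys = []
    for lab in header:
        bits = lab.split(":")
        keys.append(
            ResidueKey(
                chain_id=bits[0],
                residue_seq=int(bits[2]),
                insertion_code=bits[3] if len(bits) > 3 else "",
                residue_name=bits[1],
            )
        )
    r = np.asarray(rows, dtype=float)
    return CorrelationMatrix(type=itype, r=r, labels=keys, window=(0, 0))
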