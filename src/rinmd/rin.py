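"""Residue interaction network assembly and analysis.

Per-frame interaction records become residue-level multigraphs (one edge per
residue pair and interaction type, with the within-frame multiplicity kept as
a count attribute). Frame graphs are aggregated into a consensus network in
which an edge survives if it is present in at least a chosen fraction of the
frames (its persistence); geometric descriptors are summarised as
mean/min/max over the frames where the edge exists.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, TopologyInconsistencyError
from .interactions import InteractionRecord, InteractionType
from .structure_io import MolecularSystem, ResidueKey

EDGE_CLASSES = ("INTRA_CHAIN", "INTER_CHAIN", "INTER_ASSEMBLY")


def build_frame_graph(
    records: Sequence[InteractionRecord],
    frame: int,
    nodes: Sequence[ResidueKey],
) -> nx.MultiGraph:
    """Multigraph of one frame: one edge per (residue pair, interaction type).

    All residues appear as nodes (isolated ones included). Several
    interactions of the same type between one pair (e.g. two hydrogen bonds)
    collapse to one edge with a `count` attribute; descriptors are averaged
    within the frame.
    """
    g = nx.MultiGraph(frame=frame)
    for k in nodes:
        g.add_node(k, resname=k.residue_name, chain=k.chain_id)
    grouped: dict[tuple, list[InteractionRecord]] = {}
    for rec in records:
        if rec.frame_index != frame:
            raise TopologyInconsistencyError(
                f"record from frame {rec.frame_index} passed to frame {frame} graph"
            )
        a, b = rec.pair()
        grouped.setdefault((a, b, rec.type), []).append(rec)
    for (a, b, itype), recs in grouped.items():
        desc_names = sorted(set().union(*(r.descriptors.keys() for r in recs)))
        desc = {
            name: float(np.mean([r.descriptors[name] for r in recs if name in r.descriptors]))
            for name in desc_names
        }
        g.add_edge(a, b, key=itype.name, type=itype.name, count=len(recs), descriptors=desc)
    return g


@dataclass
class ConsensusRIN:
    """Residue-level consensus multigraph over a trajectory.

    Edge attributes: `type`, `persistence` (fraction of frames present, in
    (0, 1]), `frame_count`, `count_mean` (mean within-frame multiplicity) and
    `<descriptor>_mean/_min/_max` statistics.
    """

    graph: nx.MultiGraph
    n_frames: int
    node_attributes: dict[ResidueKey, dict] = field(default_factory=dict)

    @property
    def nodes(self) -> list[ResidueKey]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[ResidueKey, ResidueKey, str, dict]]:
        return [(u, v, k, d) for u, v, k, d in self.graph.edges(keys=True, data=True)]


def build_consensus(
    frame_graphs: Sequence[nx.MultiGraph], persistence_min: float = 0.0
) -> ConsensusRIN:
    """Aggregate frame multigraphs, keeping edges present in >= persistence_min.

    Persistence is stored as the exact fraction frames-present / n-frames.
    Descriptor statistics are taken over the frames where the edge exists.
    The result is invariant to the order of the frame graphs.
    """
    if not frame_graphs:
        raise ConfigurationError("need at least one frame graph")
    node_set = set(frame_graphs[0].nodes)
    for g in frame_graphs[1:]:
        if set(g.nodes) != node_set:
            raise TopologyInconsistencyError("frame graphs have inconsistent node sets")
    n_frames = len(frame_graphs)
    presence: dict[tuple, int] = {}
    counts: dict[tuple, list[int]] = {}
    descs: dict[tuple, dict[str, list[float]]] = {}
    for g in frame_graphs:
        for u, v, k, d in g.edges(keys=True, data=True):
            a, b = (u, v) if u <= v else (v, u)
            key = (a, b, k)
            presence[key] = presence.get(key, 0) + 1
            counts.setdefault(key, []).append(d.get("count", 1))
            store = descs.setdefault(key, {})
            for name, val in d.get("descriptors", {}).items():
                store.setdefault(name, []).append(val)
    out = nx.MultiGraph()
    ordered_nodes = sorted(node_set)
    for k in ordered_nodes:
        out.add_node(k, resname=k.residue_name, chain=k.chain_id)
    for (a, b, k) in sorted(presence, key=lambda t: (t[0], t[1], t[2])):
        n_present = presence[(a, b, k)]
        frac = n_present / n_frames
        if frac < persistence_min or n_present == 0:
            continue
        attrs = {
            "type": k,
            "persistence": frac,
            "frame_count": n_present,
            "count_mean": float(np.mean(counts[(a, b, k)])),
        }
        for name, vals in sorted(descs[(a, b, k)].items()):
            attrs[f"{name}_mean"] = float(np.mean(vals))
            attrs[f"{name}_min"] = float(np.min(vals))
            attrs[f"{name}_max"] = float(np.max(vals))
        out.add_edge(a, b, key=k, **attrs)
    return ConsensusRIN(graph=out, n_frames=n_frames)


def consensus_from_records(
    per_frame_records: Sequence[Sequence[InteractionRecord]],
    nodes: Sequence[ResidueKey],
    persistence_min: float = 0.0,
) -> ConsensusRIN:
    """Convenience: frame graphs + consensus in one call."""
    graphs = [
        build_frame_graph(recs, f, nodes) for f, recs in enumerate(per_frame_records)
    ]
    return build_consensus(graphs, persistence_min)


def classify_edges(
    rin: ConsensusRIN, assembly_map: Mapping[str, object] | None = None
) -> pd.DataFrame:
    """Label each edge INTRA_CHAIN / INTER_CHAIN / INTER_ASSEMBLY in place.

    Same chain -> INTRA_CHAIN; different chains in the same assembly ->
    INTER_CHAIN; different assemblies -> INTER_ASSEMBLY (only when an
    assembly map chain->label is supplied). Returns the count table with one
    row per interaction type and one column per class.
    """
    table: dict[str, dict[str, int]] = {}
    for u, v, k, d in rin.graph.edges(keys=True, data=True):
        if u.chain_id == v.chain_id:
            cls = "INTRA_CHAIN"
        elif assembly_map is None:
            cls = "INTER_CHAIN"
        else:
            for c in (u.chain_id, v.chain_id):
                if c not in assembly_map:
                    raise ConfigurationError(f"chain {c!r} missing from assembly map")
            cls = (
                "INTER_CHAIN"
                if assembly_map[u.chain_id] == assembly_map[v.chain_id]
                else "INTER_ASSEMBLY"
            )
        d["edge_class"] = cls
        table.setdefault(k, {c: 0 for c in EDGE_CLASSES})[cls] += 1
    rows = sorted(table, key=lambda name: InteractionType[name])
    df = pd.DataFrame(
        [[table[r][c] for c in EDGE_CLASSES] for r in rows],
        index=rows,
        columns=list(EDGE_CLASSES),
        dtype=int,
    )
    return df


def simple_projection(rin: ConsensusRIN) -> nx.Graph:
    """Collapse parallel typed edges; weight = number of distinct types."""
    g = nx.Graph()
    g.add_nodes_from(rin.graph.nodes)
    for u, v in {(u, v) if u <= v else (v, u) for u, v, _ in rin.graph.edges(keys=True)}:
        g.add_edge(u, v, weight=len(rin.graph[u][v]))
    return g


def centralities(rin: ConsensusRIN) -> dict[ResidueKey, dict[str, float]]:
    """Node centralities on the simple-graph projection of the consensus RIN.

    Multigraph shortest paths are ill-defined, so betweenness/closeness/
    eigenvector are computed on the projection (parallel typed edges
    collapsed, weight = number of interaction types). Closeness follows the
    within-component convention; eigenvector centrality is taken from the
    leading eigenvector of the adjacency matrix.
    """
    if rin.graph.number_of_nodes() == 0:
        raise ConfigurationError("cannot compute centralities of an empty network")
    g = simple_projection(rin)
    deg = nx.degree_centrality(g)
    wdeg = {n: float(sum(d["weight"] for _, _, d in g.edges(n, data=True))) for n in g}
    btw = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g)
    n = g.number_of_nodes()
    adj = nx.to_numpy_array(g, nodelist=list(g.nodes), weight=None)
    if adj.any():
        vals, vecs = np.linalg.eigh(adj)
        vec = np.abs(vecs[:, int(np.argmax(vals))])
        vec = vec / np.linalg.norm(vec)
    else:
        vec = np.zeros(n)
    eig = {node: float(vec[i]) for i, node in enumerate(g.nodes)}
    return {
        node: {
            "degree": deg[node],
            "weighted_degree": wdeg[node],
            "betweenness": btw[node],
            "closeness": clo[node],
            "eigenvector": eig[node],
        }
        for node in g.nodes
    }


# ---------------------------------------------------------------------------
# Node attributes: SASA and secondary structure
# ---------------------------------------------------------------------------

def compute_sasa(system: MolecularSystem, frame: int = 0, point_number: int = 92,
                 probe_radius: float = 1.4) -> dict[ResidueKey, float]:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Computed with biotite's Shrake-Rupley implementation on the given frame;
    hydrogen atoms are ignored by the radius set.
    """
    import biotite.structure as struc

    arr = struc.AtomArray(system.n_atoms)
    arr.coord = system.coords(frame).astype(np.float32)
    arr.atom_name = np.array([a.name for a in system.atoms])
    arr.res_name = np.array([a.residue_name for a in system.atoms])
    arr.res_id = np.array([a.residue_seq for a in system.atoms])
    arr.chain_id = np.array([a.chain_id for a in system.atoms])
    arr.element = np.array([a.element for a in system.atoms])
    arr.hetero = np.zeros(system.n_atoms, dtype=bool)
    atom_sasa = struc.sasa(
        arr, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
    )
    atom_sasa = np.nan_to_num(atom_sasa)
    out: dict[ResidueKey, float] = {}
    for r, key in enumerate(system.residue_keys):
        out[key] = float(atom_sasa[system.residue_atom_indices[r]].sum())
    return out


def run_dssp(system: MolecularSystem, dssp_path: str, frame: int = 0) -> dict[ResidueKey, dict]:
    """Secondary structure and accessibility from an external DSSP executable."""
    from .structure_io import write_pdb

    with tempfile.TemporaryDirectory() as tmp:
        pdb = Path(tmp) / "model.pdb"
        write_pdb(system, pdb, frame=frame)
        proc = subprocess.run(
            [dssp_path, str(pdb)], capture_output=True, text=True, check=True
        )
    out: dict[ResidueKey, dict] = {}
    in_table = False
    lookup = {
        (k.chain_id, k.residue_seq, k.insertion_code): k for k in system.residue_keys
    }
    for line in proc.stdout.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 38 or line[13] == "!":
            continue
        try:
            resseq = int(line[5:10])
        except ValueError:
            continue
        chain = line[11].strip()
        icode = line[10].strip()
        key = lookup.get((chain, resseq, icode))
        if key is not None:
            out[key] = {"secondary_structure": line[16].strip(), "sasa": float(line[34:38])}
    return out


def annotate_nodes(
    rin: ConsensusRIN,
    system: MolecularSystem,
    frame: int = 0,
    dssp_path: str | None = None,
) -> None:
    """Attach SASA (and, via DSSP, secondary structure) node attributes."""
    if dssp_path:
        info = run_dssp(system, dssp_path, frame=frame)
        for key, vals in info.items():
            if key in rin.graph:
                rin.graph.nodes[key].update(vals)
    else:
        sasa = compute_sasa(system, frame=frame)
        for key, val in sasa.items():
            if key in rin.graph:
                rin.graph.nodes[key]["sasa"] = val


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def _node_id(k: ResidueKey) -> str:
    return k.label()


def _graph_for_writing(rin: ConsensusRIN, types: Iterable[str] | None = None) -> nx.MultiGraph:
    g = nx.MultiGraph(n_frames=rin.n_frames)
    for k in rin.graph.nodes:
        attrs = dict(rin.graph.nodes[k])
        g.add_node(
            _node_id(k),
            chain=k.chain_id,
            resseq=k.residue_seq,
            icode=k.insertion_code,
            resname=k.residue_name,
            **{a: v for a, v in attrs.items() if a not in ("chain", "resname")},
        )
    for u, v, k, d in rin.graph.edges(keys=True, data=True):
        if types is not None and k not in types:
            continue
        g.add_edge(_node_id(u), _node_id(v), key=k, **d)
    return g


def write_network(rin: ConsensusRIN, out_dir, prefix: str = "rin") -> dict[str, Path]:
    """Write GraphML + TSV files: one per interaction type plus a global one.

    GraphML files round-trip through :func:`read_network`; the TSV node and
    edge tables import directly into Cytoscape.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    present_types = sorted(
        {k for _, _, k in rin.graph.edges(keys=True)}, key=lambda n: InteractionType[n]
    )
    p = out_dir / f"{prefix}_global.graphml"
    nx.write_graphml(_graph_for_writing(rin), p, named_key_ids=True)
    written["global"] = p
    for t in present_types:
        p = out_dir / f"{prefix}_{t.lower()}.graphml"
        nx.write_graphml(_graph_for_writing(rin, types=[t]), p, named_key_ids=True)
        written[t] = p

    node_rows = []
    for k in rin.graph.nodes:
        row = {
            "node": _node_id(k),
            "chain": k.chain_id,
            "resseq": k.residue_seq,
            "icode": k.insertion_code,
            "resname": k.residue_name,
        }
        row.update(
            {a: v for a, v in rin.graph.nodes[k].items() if a not in ("chain", "resname")}
        )
        node_rows.append(row)
    nodes_path = out_dir / f"{prefix}_nodes.tsv"
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False, float_format="%.6f")
    written["nodes"] = nodes_path

    edge_rows = []
    for u, v, k, d in sorted(
        rin.graph.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
    ):
        row = {"source": _node_id(u), "target": _node_id(v), "type": k}
        row.update({a: val for a, val in d.items() if a != "type"})
        edge_rows.append(row)
    edges_path = out_dir / f"{prefix}_edges.tsv"
    pd.DataFrame(edge_rows).to_csv(edges_path, sep="\t", index=False, float_format="%.6f")
    written["edges"] = edges_path
    return written


def read_network(path) -> ConsensusRIN:
    """Read a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(path, force_multigraph=True)
    out = nx.MultiGraph()
    mapping: dict[str, ResidueKey] = {}
    for n, d in sorted(g.nodes(data=True)):
        key = ResidueKey(
            chain_id=str(d.get("chain", "")),
            residue_seq=int(d.get("resseq", 0)),
            insertion_code=str(d.get("icode", "") or ""),
            residue_name=str(d.get("resname", "")),
        )
        mapping[n] = key
        extra = {
            a: v for a, v in d.items() if a not in ("chain", "resseq", "icode", "resname")
        }
        out.add_node(key, resname=key.residue_name, chain=key.chain_id, **extra)
    for u, v, k, d in g.edges(keys=True, data=True):
        out.add_edge(mapping[u], mapping[v], key=d.get("type", k), **d)
    n_frames = int(g.graph.get("n_frames", 1))
    return ConsensusRIN(graph=out, n_frames=n_frames)
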