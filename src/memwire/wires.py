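"""Water-wire detection via the minimum-spanning-tree minimax-gap method.

Per frame: water oxygens (and optionally AA carboxylate oxygens) inside a
cylinder centered on the protein are collected, their pairwise minimum-image
O-O distances up to a cutoff form a weighted graph, and the unique path
between two bulk endpoint waters through a minimum spanning tree of that
graph realizes the minimax path — the path whose largest O-O gap is the
smallest achievable over all paths.  A wire is "formed" when that largest
gap is at or below the formation threshold (0.33 nm by default): a proxy for
the longest hop a Grotthuss-shuttled proton would need to make.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from .geometry import center_of_mass, is_orthorhombic, lateral_distance, minimum_image_distance
from .model import Frame, MolecularSystem, SpeciesTag, Trajectory

__all__ = [
    "WireSearchConfig",
    "GapGraph",
    "WaterWire",
    "WireStats",
    "select_cylinder_oxygens",
    "build_gap_graph",
    "select_bulk_endpoints",
    "minimax_path",
    "assign_unit",
    "analyze_frame",
    "classify_and_summarize",
]


@dataclass(frozen=True)
class WireSearchConfig:
    """Geometry and thresholds of the wire search.  Distances in nm.

    ``membrane_halfwidth_z`` anchors the bulk definition: waters with
    ``|z - COM_z| >= membrane_halfwidth_z + bulk_margin_z`` count as bulk.
    The cylinder must extend past that bound on both sides.
    """

    cylinder_radius: float = 1.5
    cylinder_z_halflength: float = 3.4
    graph_cutoff: float = 1.0
    gap_threshold: float = 0.33
    include_aa_carboxylate_oxygens: bool = True
    membrane_halfwidth_z: float = 1.7
    bulk_margin_z: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.gap_threshold < self.graph_cutoff:
            raise ValueError("need 0 < gap_threshold < graph_cutoff")
        if self.cylinder_z_halflength <= self.membrane_halfwidth_z + self.bulk_margin_z:
            raise ValueError("cylinder must extend past the bulk margin on both sides")

    @property
    def bulk_z(self) -> float:
        return self.membrane_halfwidth_z + self.bulk_margin_z


@dataclass
class GapGraph:
    """Sparse O-O distance graph: nodes are atom indices, edges <= cutoff."""

    nodes: np.ndarray  # atom indices of the selected oxygens
    edges: np.ndarray  # (n_edges, 2) positions into ``nodes``
    weights: np.ndarray  # nm

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class WaterWire:
    """Minimax source-to-sink path of one frame."""

    frame_index: int
    path: list[int]  # atom indices, source first; empty if unconnectable
    gaps: np.ndarray  # per-edge O-O distances along the path
    max_gap: float  # inf when source and sink are disconnected under the cutoff
    unit_assignment: str = "unassigned"
    constriction_edge: tuple[int, int] | None = None  # atom-index pair of the largest gap

    @property
    def formed(self) -> bool:
        return math.isfinite(self.max_gap)


@dataclass
class WireStats:
    """Per-frame series and summary statistics of the wire search."""

    max_gaps: np.ndarray  # nm per frame; inf for unconnectable frames
    formed: np.ndarray  # boolean per frame (max_gap <= threshold)
    units: list[str]
    times: np.ndarray  # ps
    frame_interval: float  # ps
    formation_frequency: float = 0.0
    lifetimes_ns: np.ndarray = field(default_factory=lambda: np.array([]))
    unit_counts: dict[str, int] = field(default_factory=dict)
    unit_fractions: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_frames": int(len(self.max_gaps)),
            "formation_frequency": float(self.formation_frequency),
            "n_wires_formed": int(self.formed.sum()),
            "lifetimes_ns": self.lifetimes_ns.tolist(),
            "max_lifetime_ns": float(self.lifetimes_ns.max()) if len(self.lifetimes_ns) else 0.0,
            "unit_counts": self.unit_counts,
            "unit_fractions": self.unit_fractions,
        }


# ---------------------------------------------------------------------------
# per-frame steps
# ---------------------------------------------------------------------------

def _protein_com(system: MolecularSystem, frame: Frame) -> np.ndarray:
    return center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)


def select_cylinder_oxygens(
    frame: Frame, system: MolecularSystem, config: WireSearchConfig, com: np.ndarray | None = None
) -> np.ndarray:
    """Atom indices of water O (and optional AA carboxylate O) in the search
    cylinder: lateral distance to the protein-COM axis <= cylinder_radius and
    |z - COM_z| <= cylinder_z_halflength."""
    com = _protein_com(system, frame) if com is None else com
    cand = system.water_oxygen_indices()
    if config.include_aa_carboxylate_oxygens:
        aa = system.species_indices(SpeciesTag.AA)
        aa_ox = aa[np.char.startswith(np.char.upper(system.names[aa].astype(str)), "O")]
        cand = np.concatenate([cand, aa_ox])
    pos = frame.coordinates[cand]
    lat = lateral_distance(pos, com, frame.box)
    dz = np.abs(pos[:, 2] - com[2])
    keep = (lat <= config.cylinder_radius) & (dz <= config.cylinder_z_halflength)
    return np.sort(cand[keep])


def build_gap_graph(nodes: np.ndarray, frame: Frame, config: WireSearchConfig) -> GapGraph:
    """All node pairs with minimum-image distance <= graph_cutoff.

    Uses a periodic KD-tree for orthorhombic boxes; the edge content is
    identical to thresholding the dense minimum-image distance matrix.
    """
    nodes = np.asarray(nodes, dtype=int)
    pos = frame.coordinates[nodes]
    if is_orthorhombic(frame.box):
        lengths = np.diag(frame.box)
        wrapped = np.mod(pos, lengths)
        # guard against fp landing exactly on the upper boundary
        wrapped = np.where(wrapped >= lengths, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=lengths)
        pairs = tree.query_pairs(config.graph_cutoff, output_type="ndarray")
        if len(pairs):
            w = minimum_image_distance(pos[pairs[:, 0]], pos[pairs[:, 1]], frame.box)
        else:
            w = np.empty(0)
    else:
        d = minimum_image_distance(pos[:, None, :], pos[None, :, :], frame.box)
        iu, ju = np.triu_indices(len(nodes), k=1)
        keep = d[iu, ju] <= config.graph_cutoff
        pairs = np.column_stack([iu[keep], ju[keep]])
        w = d[iu, ju][keep]
    return GapGraph(nodes=nodes, edges=pairs.reshape(-1, 2), weights=np.asarray(w, dtype=float))


def select_bulk_endpoints(
    frame: Frame,
    nodes: np.ndarray,
    system: MolecularSystem,
    config: WireSearchConfig,
    com: np.ndarray | None = None,
) -> tuple[int, int] | None:
    """Deterministic bulk endpoints: on each side, among waters beyond the
    bulk margin, the one laterally nearest the protein-COM axis (ties broken
    by lowest atom index).  Returns None when either side has no bulk water.
    AA carboxylate oxygens are never endpoints."""
    com = _protein_com(system, frame) if com is None else com
    nodes = np.asarray(nodes, dtype=int)
    water = nodes[system.species[nodes] == SpeciesTag.WATER.value]
    pos = frame.coordinates[water]
    dz = pos[:, 2] - com[2]
    lat = lateral_distance(pos, com, frame.box)
    picks = []
    for side in (+1, -1):
        mask = side * dz >= config.bulk_z
        if not mask.any():
            return None
        cand = water[mask]
        cl = lat[mask]
        best = np.lexsort((cand, cl))[0]  # primary: lateral distance; tie: atom index
        picks.append(int(cand[best]))
    return picks[0], picks[1]


def minimax_path(graph: GapGraph, source: int, sink: int, frame_index: int = 0) -> WaterWire:
    """Source-to-sink path through an MST of the gap graph.

    By the classical minimax property of minimum spanning trees, the largest
    edge on this path equals the minimum over all source-sink paths of the
    path's largest edge.  Disconnected endpoints give an empty path with
    ``max_gap = inf`` (gaps above the graph cutoff are not measurable).
    """
    nodes = graph.nodes
    node_pos = {int(a): i for i, a in enumerate(nodes)}
    if source not in node_pos or sink not in node_pos:
        raise ValueError("source and sink must be graph nodes")
    if source == sink:
        return WaterWire(frame_index, [source], np.array([]), 0.0)
    n = graph.n_nodes
    if len(graph.edges) == 0:
        return WaterWire(frame_index, [], np.array([]), math.inf)
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    mat = coo_matrix((graph.weights, (i, j)), shape=(n, n))
    mst = minimum_spanning_tree(mat)  # upper-triangular CSR
    mst = mst + mst.T
    mst_csr = mst.tocsr()

    # walk the tree from source to sink (iterative DFS; the tree path is unique)
    src, dst = node_pos[source], node_pos[sink]
    parent = np.full(n, -1, dtype=int)
    parent[src] = src
    stack = [src]
    indptr, indices = mst_csr.indptr, mst_csr.indices
    while stack:
        u = stack.pop()
        if u == dst:
            break
        for v in indices[indptr[u] : indptr[u + 1]]:
            if parent[v] < 0:
                parent[v] = u
                stack.append(v)
    if parent[dst] < 0:
        return WaterWire(frame_index, [], np.array([]), math.inf)
    rev = [dst]
    while rev[-1] != src:
        rev.append(int(parent[rev[-1]]))
    path_local = rev[::-1]
    gaps = np.array([mst_csr[u, v] for u, v in zip(path_local, path_local[1:])])
    k = int(np.argmax(gaps))
    wire = WaterWire(
        frame_index,
        [int(nodes[u]) for u in path_local],
        gaps,
        float(gaps.max()),
        constriction_edge=(int(nodes[path_local[k]]), int(nodes[path_local[k + 1]])),
    )
    return wire


def assign_unit(
    wire: WaterWire, system: MolecularSystem, frame: Frame, com: np.ndarray | None = None
) -> str:
    """Label a formed wire by the helix pair whose inter-axis midline is
    laterally nearest the midpoint of the wire's constriction edge;
    ``cavity-axis`` when the protein-COM axis is nearer than any midline."""
    if not wire.formed or wire.constriction_edge is None:
        return "unassigned"
    com = _protein_com(system, frame) if com is None else com
    a, b = wire.constriction_edge
    mid = 0.5 * (frame.coordinates[a] + frame.coordinates[b])
    helices = system.helices
    n = len(helices)
    best_label, best_d = "cavity-axis", float(lateral_distance(mid, com, frame.box))
    for k in range(n):
        ha, hb = helices[k], helices[(k + 1) % n]
        axis_a = center_of_mass(system.helix_atoms(ha.helix_id), frame.coordinates, system.masses)
        axis_b = center_of_mass(system.helix_atoms(hb.helix_id), frame.coordinates, system.masses)
        midline = 0.5 * (axis_a + axis_b)
        d = float(lateral_distance(mid, midline, frame.box))
        if d < best_d - 1e-12:
            best_label, best_d = f"{ha.helix_id}/{hb.helix_id}", d
    return best_label


# ---------------------------------------------------------------------------
# trajectory-level driver
# ---------------------------------------------------------------------------

def analyze_frame(
    frame: Frame, system: MolecularSystem, config: WireSearchConfig, frame_index: int = 0
) -> WaterWire:
    """Full single-frame wire search; unconnectable frames get max_gap = inf."""
    com = _protein_com(system, frame)
    nodes = select_cylinder_oxygens(frame, system, config, com)
    if len(nodes) < 2:
        return WaterWire(frame_index, [], np.array([]), math.inf)
    endpoints = select_bulk_endpoints(frame, nodes, system, config, com)
    if endpoints is None:
        return WaterWire(frame_index, [], np.array([]), math.inf)
    graph = build_gap_graph(nodes, frame, config)
    wire = minimax_path(graph, endpoints[0], endpoints[1], frame_index)
    if wire.formed and wire.max_gap <= config.gap_threshold:
        wire.unit_assignment = assign_unit(wire, system, frame, com)
    return wire


def classify_and_summarize(
    traj: Trajectory, config: WireSearchConfig | None = None, stride: int = 1,
    return_wires: bool = False,
) -> WireStats | tuple[WireStats, list[WaterWire]]:
    """Run the wire search over a trajectory and summarize.

    A frame counts as wire-formed iff its minimax gap is <= the threshold.
    Lifetimes are maximal runs of consecutive formed frames times the frame
    interval (at the analyzed stride); unit fractions are over formed frames.
    """
    config = WireSearchConfig() if config is None else config
    system = traj.system
    idx = range(0, traj.n_frames, stride)
    wires = [analyze_frame(traj.frames[i], system, config, i) for i in idx]
    max_gaps = np.array([w.max_gap for w in wires])
    formed = max_gaps <= config.gap_threshold
    units = [w.unit_assignment for w in wires]
    interval = traj.frame_interval * stride
    lifetimes = np.array(_run_lengths(formed), dtype=float) * interval / 1000.0  # ns
    counts: dict[str, int] = {}
    for u, f in zip(units, formed):
        if f:
            counts[u] = counts.get(u, 0) + 1
    total = max(int(formed.sum()), 1)
    stats = WireStats(
        max_gaps=max_gaps,
        formed=formed,
        units=units,
        times=np.array([traj.frames[i].time for i in idx]),
        frame_interval=interval,
        formation_frequency=float(formed.mean()) if len(formed) else 0.0,
        lifetimes_ns=lifetimes,
        unit_counts=counts,
        unit_fractions={k: v / total for k, v in counts.items()},
    )
    return (stats, wires) if return_wires else stats


def _run_lengths(flags: np.ndarray) -> list[int]:
    runs, n = [], 0
    for f in flags:
        if f:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs
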