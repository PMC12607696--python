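"""Fatty-acid / lipid binding classification at interhelical sites.

A probe (AA, POPC or cardiolipin) is *bound* at a site when its tail crosses
a quadrilateral surface spanning the gap between the two flanking helices
(two triangles sharing an edge) while simultaneously contacting heavy atoms
of residues from both helices within 0.5 nm.  *Deep* states additionally
have the head group (AA carboxylate / POPC phosphate) within 1.3 nm of the
protein center of mass; *cavity-bound* states have every heavy atom of the
probe inside the central cavity.  Maximal runs of deep frames become binding
events with residence times in multiples of the frame interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    center_of_mass,
    lateral_distance,
    minimum_image_displacement,
    minimum_image_distance,
    pairwise_minimum_image_distances,
)
from .model import Frame, MolecularSystem, SpeciesTag, Trajectory

__all__ = [
    "BindingConfig",
    "InterhelicalSite",
    "LipidProbe",
    "BindingState",
    "BindingEventRecord",
    "ContactFrequencyTable",
    "segment_intersects_triangle",
    "tail_intersects_surface",
    "in_contact",
    "classify_binding",
    "classify_trajectory",
    "extract_events",
    "contact_frequencies",
    "replicate_divergence",
    "cardiolipin_excursions",
    "default_sites",
    "probes_from_system",
]


@dataclass(frozen=True)
class BindingConfig:
    contact_cutoff: float = 0.5  # nm, heavy-atom contact distance (strict <)
    deep_radius: float = 1.3  # nm, head-to-COM distance bounding "deep"
    cavity_radius: float = 1.3  # nm, lateral radius of the central cavity cylinder
    cavity_z_halflength: float = 1.9  # nm, cavity extent along the membrane normal
    gap_tolerance_frames: int = 0  # merge deep runs interrupted by <= this many frames


@dataclass(frozen=True)
class InterhelicalSite:
    """Binding site between two consecutive TM helices.

    ``triangle_anchors`` are two triples of atom indices; per frame their
    positions define two triangles that share an edge, forming the
    quadrilateral surface spanning the interhelical gap.
    """

    site_id: str  # e.g. "TM1/TM2"
    triangle_anchors: tuple[tuple[int, int, int], tuple[int, int, int]]
    helix_a_residues: frozenset[int]
    helix_b_residues: frozenset[int]

    def __post_init__(self) -> None:
        shared = set(self.triangle_anchors[0]) & set(self.triangle_anchors[1])
        if len(shared) != 2:
            raise ValueError(f"{self.site_id}: the two triangles must share exactly one edge")


@dataclass(frozen=True)
class LipidProbe:
    molecule_id: int
    species: SpeciesTag
    head_atom: int  # AA carboxylate O/C or POPC phosphate P
    tail_chains: tuple[tuple[int, ...], ...]  # ordered head->terminal, >=1 chain
    heavy_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.head_atom not in self.heavy_atoms:
            raise ValueError("head_atom must be a heavy atom of the probe")


@dataclass
class BindingState:
    frame_index: int
    probe_id: int
    site: str
    bound: bool
    deep: bool
    cavity_bound: bool
    head_depth: float  # nm, 3-D minimum-image head-to-protein-COM distance


@dataclass
class BindingEventRecord:
    probe_id: int
    site: str
    start_frame: int
    end_frame: int  # inclusive
    residence_ns: float
    min_head_depth: float
    open_ended: bool = False


@dataclass
class ContactFrequencyTable:
    site: str
    frequencies: dict[int, float]  # residue index -> fraction of bound frames in contact
    n_bound_frames: int


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

_EPS = 1e-9


def segment_intersects_triangle(
    p0: np.ndarray, p1: np.ndarray, tri: np.ndarray, eps: float = _EPS
) -> bool:
    """Boundary-inclusive segment-triangle intersection (Moller-Trumbore)."""
    v0, v1, v2 = tri
    d = p1 - p0
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(d, e2)
    a = float(e1 @ h)
    if abs(a) < eps:  # segment parallel to the triangle plane
        return False
    f = 1.0 / a
    s = p0 - v0
    u = f * float(s @ h)
    if u < -eps or u > 1.0 + eps:
        return False
    q = np.cross(s, e1)
    v = f * float(d @ q)
    if v < -eps or u + v > 1.0 + eps:
        return False
    t = f * float(e2 @ q)
    return -eps <= t <= 1.0 + eps


def tail_intersects_surface(
    tail: np.ndarray, site: InterhelicalSite, frame: Frame
) -> bool:
    """True iff any consecutive tail segment crosses either gap triangle.

    Tail positions are mapped to their minimum image relative to the triangle
    centroid before the test, so a probe on the far periodic image is handled.
    """
    tail = np.asarray(tail, dtype=float)
    for anchors in site.triangle_anchors:
        tri = frame.coordinates[list(anchors)]
        e1 = tri[1] - tri[0]
        e2 = tri[2] - tri[0]
        if 0.5 * np.linalg.norm(np.cross(e1, e2)) < 1e-6:
            raise ValueError(f"degenerate gap triangle at site {site.site_id}")
        centroid = tri.mean(axis=0)
        rel = centroid + minimum_image_displacement(tail, centroid, frame.box)
        for k in range(len(rel) - 1):
            if segment_intersects_triangle(rel[k], rel[k + 1], tri):
                return True
    return False


def in_contact(
    probe: LipidProbe,
    residues: frozenset[int] | set[int],
    frame: Frame,
    system: MolecularSystem,
    cutoff: float = 0.5,
) -> bool:
    """True iff any probe heavy atom is within ``cutoff`` (strict) of any
    heavy atom of the residue set, under minimum image."""
    res_atoms = system.residue_atoms(residues)
    res_atoms = res_atoms[system.heavy_mask[res_atoms]]
    probe_atoms = np.asarray(probe.heavy_atoms, dtype=int)
    if len(res_atoms) == 0 or len(probe_atoms) == 0:
        return False
    d = pairwise_minimum_image_distances(
        frame.coordinates[probe_atoms], frame.coordinates[res_atoms], frame.box
    )
    return bool(d.min() < cutoff)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _head_depth(probe: LipidProbe, frame: Frame, com: np.ndarray) -> float:
    return float(minimum_image_distance(frame.coordinates[probe.head_atom], com, frame.box))


def _cavity_bound(
    probe: LipidProbe, frame: Frame, com: np.ndarray, config: BindingConfig
) -> bool:
    atoms = np.asarray(probe.heavy_atoms, dtype=int)
    pos = frame.coordinates[atoms]
    lat = lateral_distance(pos, com, frame.box)
    dz = np.abs(pos[:, 2] - com[2])
    inside = np.all((lat <= config.cavity_radius) & (dz <= config.cavity_z_halflength))
    return bool(inside) and _head_depth(probe, frame, com) <= config.deep_radius


def classify_binding(
    probe: LipidProbe,
    site: InterhelicalSite,
    frame: Frame,
    system: MolecularSystem,
    config: BindingConfig | None = None,
    frame_index: int = 0,
    com: np.ndarray | None = None,
) -> BindingState:
    """Per-frame state of one probe at one interhelical site.

    bound  <=> tail crosses the gap surface AND contacts both helices;
    deep   <=> head within deep_radius of the protein COM AND (bound here or
               cavity-bound);
    cavity <=> every heavy atom inside the central-cavity cylinder (which
               implies the head is within deep_radius, hence cavity => deep).
    """
    config = BindingConfig() if config is None else config
    com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses) if com is None else com
    depth = _head_depth(probe, frame, com)
    cavity = _cavity_bound(probe, frame, com, config)
    bound = False
    for chain in probe.tail_chains:
        if tail_intersects_surface(frame.coordinates[list(chain)], site, frame):
            bound = True
            break
    if bound:
        bound = in_contact(probe, site.helix_a_residues, frame, system, config.contact_cutoff) and in_contact(
            probe, site.helix_b_residues, frame, system, config.contact_cutoff
        )
    deep = depth <= config.deep_radius and (bound or cavity)
    return BindingState(frame_index, probe.molecule_id, site.site_id, bound, deep, cavity, depth)


def classify_trajectory(
    traj: Trajectory,
    sites: list[InterhelicalSite],
    probes: list[LipidProbe],
    config: BindingConfig | None = None,
) -> list[BindingState]:
    """States for every (frame, probe, site), plus a ``cavity`` pseudo-site
    per probe so cavity-bound episodes form events of their own."""
    config = BindingConfig() if config is None else config
    system = traj.system
    out: list[BindingState] = []
    for fi, frame in enumerate(traj.frames):
        com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)
        for probe in probes:
            cavity = _cavity_bound(probe, frame, com, config)
            depth = _head_depth(probe, frame, com)
            for site in sites:
                st = classify_binding(probe, site, frame, system, config, fi, com)
                out.append(st)
            out.append(
                BindingState(fi, probe.molecule_id, "cavity", cavity, cavity, cavity, depth)
            )
    return out


def extract_events(
    states: list[BindingState],
    frame_interval: float,
    gap_tolerance_frames: int = 0,
    n_frames: int | None = None,
) -> list[BindingEventRecord]:
    """Maximal runs of deep frames per (probe, site) become events.

    At an interhelical site a frame joins a run when the probe is deep AND
    bound at that site (a cavity-bound probe is deep everywhere but belongs
    only to its ``cavity`` pseudo-site run).  Runs separated by at most
    ``gap_tolerance_frames`` other frames merge; events still running at the
    last frame are flagged open-ended.  ``frame_interval`` is in ps;
    residence times are reported in ns.
    """
    by_key: dict[tuple[int, str], list[BindingState]] = {}
    last_frame = -1
    for st in states:
        by_key.setdefault((st.probe_id, st.site), []).append(st)
        last_frame = max(last_frame, st.frame_index)
    if n_frames is not None:
        last_frame = n_frames - 1
    events: list[BindingEventRecord] = []
    for (probe_id, site), series in by_key.items():
        series.sort(key=lambda s: s.frame_index)
        runs: list[list[BindingState]] = []
        cur: list[BindingState] = []
        for st in series:
            if st.deep and st.bound:
                if cur and st.frame_index - cur[-1].frame_index > gap_tolerance_frames + 1:
                    runs.append(cur)
                    cur = []
                cur.append(st)
        if cur:
            runs.append(cur)
        for run in runs:
            s, e = run[0].frame_index, run[-1].frame_index
            events.append(
                BindingEventRecord(
                    probe_id=probe_id,
                    site=site,
                    start_frame=s,
                    end_frame=e,
                    residence_ns=(e - s + 1) * frame_interval / 1000.0,
                    min_head_depth=float(min(st.head_depth for st in run)),
                    open_ended=e == last_frame,
                )
            )
    events.sort(key=lambda ev: (ev.start_frame, ev.probe_id, ev.site))
    return events


def contact_frequencies(
    traj: Trajectory,
    states: list[BindingState],
    probe: LipidProbe,
    site: InterhelicalSite,
    config: BindingConfig | None = None,
) -> ContactFrequencyTable:
    """Per-residue contact frequency over the frames where the probe is bound
    at the site, normalized by the bound-frame count.  All protein residues
    are scored, not only those of the flanking helices."""
    config = BindingConfig() if config is None else config
    system = traj.system
    bound_frames = [
        st.frame_index
        for st in states
        if st.probe_id == probe.molecule_id and st.site == site.site_id and st.bound
    ]
    if not bound_frames:
        raise ValueError(f"no bound frames for probe {probe.molecule_id} at {site.site_id}")
    prot = system.protein_atom_set
    prot_heavy = prot[system.heavy_mask[prot]]
    prot_res = system.residue_indices[prot_heavy]
    probe_atoms = np.asarray(probe.heavy_atoms, dtype=int)
    residues = np.unique(prot_res)
    hits = {int(r): 0 for r in residues}
    for fi in bound_frames:
        frame = traj.frames[fi]
        d = pairwise_minimum_image_distances(
            frame.coordinates[probe_atoms], frame.coordinates[prot_heavy], frame.box
        ).min(axis=0)
        touched = np.unique(prot_res[d < config.contact_cutoff])
        for r in touched:
            hits[int(r)] += 1
    n = len(bound_frames)
    return ContactFrequencyTable(
        site=site.site_id,
        frequencies={r: hits[r] / n for r in hits},
        n_bound_frames=n,
    )


# ---------------------------------------------------------------------------
# replicate diagnostics and cardiolipin excursions
# ---------------------------------------------------------------------------

def replicate_divergence(
    traj_a: Trajectory,
    traj_b: Trajectory,
    head_atom: int,
    threshold: float = 4.8,
) -> tuple[np.ndarray, int | None]:
    """Per-frame minimum-image distance between the same probe head atom in
    two replicate trajectories, plus the first frame at which it exceeds the
    divergence threshold (None if never reached).

    Both trajectories are assumed protein-centered with identical atom
    indexing; mismatched lengths compare over the common prefix.
    """
    n = min(traj_a.n_frames, traj_b.n_frames)
    if traj_a.n_frames != traj_b.n_frames:
        warnings.warn(
            f"replicates differ in length ({traj_a.n_frames} vs {traj_b.n_frames}); "
            f"comparing the first {n} frames",
            stacklevel=2,
        )
    dists = np.array(
        [
            minimum_image_distance(
                traj_a.frames[i].coordinates[head_atom],
                traj_b.frames[i].coordinates[head_atom],
                traj_a.frames[i].box,
            )
            for i in range(n)
        ]
    )
    above = np.flatnonzero(dists > threshold)
    return dists, (int(above[0]) if len(above) else None)


def cardiolipin_excursions(
    traj: Trajectory, lateral_threshold: float = 3.0
) -> tuple[dict[int, list[tuple[int, int]]], np.ndarray]:
    """Per-cardiolipin maximal intervals with lateral COM distance from the
    protein COM above the threshold, plus the per-frame furthest-cardiolipin
    distance series."""
    system = traj.system
    cl_atoms = system.species_indices(SpeciesTag.CARDIOLIPIN)
    if len(cl_atoms) == 0:
        return {}, np.zeros(traj.n_frames)
    mols = np.unique(system.molecule_ids[cl_atoms])
    per_lipid = np.zeros((len(mols), traj.n_frames))
    for fi, frame in enumerate(traj.frames):
        com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)
        for mi, mol in enumerate(mols):
            sel = cl_atoms[system.molecule_ids[cl_atoms] == mol]
            lipid_com = center_of_mass(sel, frame.coordinates, system.masses)
            per_lipid[mi, fi] = lateral_distance(lipid_com, com, frame.box)
    intervals: dict[int, list[tuple[int, int]]] = {}
    for mi, mol in enumerate(mols):
        above = per_lipid[mi] > lateral_threshold
        runs: list[tuple[int, int]] = []
        start = None
        for fi, flag in enumerate(above):
            if flag and start is None:
                start = fi
            elif not flag and start is not None:
                runs.append((start, fi - 1))
                start = None
        if start is not None:
            runs.append((start, traj.n_frames - 1))
        intervals[int(mol)] = runs
    return intervals, per_lipid.max(axis=0)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def default_sites(system: MolecularSystem, frame: Frame) -> list[InterhelicalSite]:
    """One site per consecutive helix pair; the quadrilateral anchors are the
    Calpha-like atoms of the lowest- and highest-z residues of each helix."""
    sites: list[InterhelicalSite] = []
    n = len(system.helices)
    for k in range(n):
        ha, hb = system.helices[k], system.helices[(k + 1) % n]
        a_bot, a_top = _end_atoms(system, frame, ha.helix_id)
        b_bot, b_top = _end_atoms(system, frame, hb.helix_id)
        sites.append(
            InterhelicalSite(
                site_id=f"{ha.helix_id}/{hb.helix_id}",
                triangle_anchors=((a_bot, a_top, b_top), (a_bot, b_top, b_bot)),
                helix_a_residues=frozenset(ha.residues),
                helix_b_residues=frozenset(hb.residues),
            )
        )
    return sites


def _end_atoms(system: MolecularSystem, frame: Frame, helix_id: str) -> tuple[int, int]:
    atoms = system.helix_atoms(helix_id)
    z = frame.coordinates[atoms, 2]
    return int(atoms[np.argmin(z)]), int(atoms[np.argmax(z)])


def probes_from_system(system: MolecularSystem, species: tuple[SpeciesTag, ...] = (SpeciesTag.AA, SpeciesTag.POPC)) -> list[LipidProbe]:
    """Build probes from residue atom order: first matching head atom (AA
    carboxylate O*/C*, POPC/cardiolipin P*), remaining heavy atoms as one
    ordered tail chain."""
    probes: list[LipidProbe] = []
    for tag in species:
        atoms = system.species_indices(tag)
        for mol in np.unique(system.molecule_ids[atoms]):
            sel = atoms[system.molecule_ids[atoms] == mol]
            sel = sel[system.heavy_mask[sel]]
            names = system.names[sel]
            if tag == SpeciesTag.AA:
                head_cand = [a for a, nm in zip(sel, names) if nm.upper().startswith(("O", "C1"))]
            else:
                head_cand = [a for a, nm in zip(sel, names) if nm.upper().startswith("P")]
            head = int(head_cand[0]) if head_cand else int(sel[0])
            probes.append(
                LipidProbe(
                    molecule_id=int(mol),
                    species=tag,
                    head_atom=head,
                    tail_chains=(tuple(int(a) for a in sel),),
                    heavy_atoms=tuple(int(a) for a in sel),
                )
            )
    return probes
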