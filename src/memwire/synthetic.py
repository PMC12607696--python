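"""Seeded toy membrane-protein systems with plantable ground truth.

The generator builds a pseudo-protein of vertical bead helices arranged on a
ring, embedded in a two-leaflet bead membrane (POPC-like 3-bead lipids and
deprotonated arachidonic-acid-like 5-bead chains, head bead charge -1), with
single-bead water slabs on both sides and counter-ion beads keeping the
system electroneutral.  It is not a physical model: there is no force field
and no dynamics.  Its purpose is to give every analysis stage (water wires,
binding, enrichment, electrostatics) an input whose ground truth is known by
construction, emitted as a sidecar record.

Planting functions return ``(trajectory, record)`` where the record holds
the planted truth in JSON-serializable form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import AtomRecord, Frame, HelixAnnotation, MolecularSystem, SpeciesTag, Trajectory

__all__ = [
    "SyntheticSpec",
    "SyntheticSystem",
    "PlantedWireSchedule",
    "PlantedBindingEvent",
    "generate_system",
    "plant_wire_schedule",
    "plant_binding_event",
    "plant_enrichment",
    "write_ground_truth",
]


@dataclass
class SyntheticSpec:
    """Parameters of the toy system.  Distances in nm, times in ps."""

    n_helices: int = 6
    helix_radius_ring: float = 0.9
    helix_half_length: float = 1.9
    beads_per_helix: int = 9  # odd, so each helix has a bead at z = 0
    leaflet_z: float = 1.7  # phosphate planes at COM_z +/- leaflet_z
    lipid_ring_inner: float = 1.6  # innermost lipid lattice radius
    lipid_spacing: float = 0.55
    n_popc_per_leaflet: int = 48
    n_aa_per_leaflet: int = 8
    n_cardiolipin: int = 0
    # |z - COM_z| interval filled with water; the outer edge stays > 0.5 the
    # graph cutoff away from the periodic z boundary so the two reservoirs do
    # not touch through the periodic image
    water_slab_z: tuple[float, float] = (2.0, 2.9)
    water_spacing: float = 0.28
    water_jitter: float = 0.004
    box: tuple[float, float, float] = (6.0, 6.0, 7.0)
    seed: int = 0
    frame_interval: float = 200.0
    n_frames: int = 1

    def validate(self) -> None:
        if min(self.box) <= 0:
            raise ValueError("box lengths must be positive")
        if self.n_helices < 2 or self.beads_per_helix < 2:
            raise ValueError("need at least 2 helices of 2 beads")
        if self.n_popc_per_leaflet < 0 or self.n_aa_per_leaflet < 0 or self.n_cardiolipin < 0:
            raise ValueError("counts must be >= 0")
        if min(self.box[0], self.box[1]) / 2 < self.helix_radius_ring + 1.0:
            raise ValueError("box too small: protein ring needs a 1 nm lateral margin")
        if not (0 < self.water_slab_z[0] < self.water_slab_z[1] <= self.box[2] / 2):
            raise ValueError("water slab must lie inside the box half-height")


@dataclass
class SyntheticLayout:
    """Construction details needed by the planting functions."""

    com: np.ndarray  # box center = protein COM
    helix_axes_xy: np.ndarray  # (n_helices, 2) lateral axis positions
    water_indices: np.ndarray  # atom indices of water beads
    water_home: np.ndarray  # (n_water, 3) generated water positions
    water_z_inner: float  # innermost water lattice plane offset from COM_z
    lipid_sites: dict[str, np.ndarray]  # leaflet -> (n_sites, 2) lateral site coords
    lipid_heads: dict[str, dict[str, np.ndarray]]  # leaflet -> species -> head atom indices
    aa_atoms: dict[int, np.ndarray]  # AA molecule number (0-based) -> its 5 atom indices
    aa_leaflet: dict[int, str]
    n_channel_reserved: int = 0  # waters already claimed by planted wires


@dataclass
class SyntheticSystem:
    spec: SyntheticSpec
    system: MolecularSystem
    trajectory: Trajectory
    layout: SyntheticLayout
    ground_truth: dict = field(default_factory=dict)


@dataclass
class PlantedWireSchedule:
    """Per-frame wire presence flags and the gap geometry to plant."""

    present: list[bool]
    gap_when_present: float = 0.30
    gap_when_absent: float = 0.50

    def __post_init__(self) -> None:
        if not self.gap_when_present <= 0.33 < self.gap_when_absent:
            raise ValueError("need gap_when_present <= 0.33 < gap_when_absent")

    @classmethod
    def bernoulli(
        cls, n_frames: int, p: float, seed: int, gap_when_present: float = 0.30, gap_when_absent: float = 0.50
    ) -> "PlantedWireSchedule":
        rng = np.random.default_rng(seed)
        return cls((rng.random(n_frames) < p).tolist(), gap_when_present, gap_when_absent)


@dataclass
class PlantedBindingEvent:
    aa_id: int  # 0-based AA molecule number
    site: str  # "TMi/TMj" or "cavity"
    start_frame: int
    end_frame: int  # inclusive
    planted_depth: float  # nm, 3-D head-to-COM distance

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("event must have start_frame <= end_frame")
        if self.site != "cavity" and self.planted_depth < 0.55:
            raise ValueError("interhelical events need planted_depth >= 0.55 nm")


# ---------------------------------------------------------------------------
# system generation
# ---------------------------------------------------------------------------

def _hex_sites(box_xy: tuple[float, float], spacing: float, center: np.ndarray,
               r_inner: float, r_outer: float) -> np.ndarray:
    """Square-lattice lateral sites inside an annulus around the center."""
    nx = int(box_xy[0] / spacing)
    ny = int(box_xy[1] / spacing)
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    pts = np.array([(x, y) for x in xs for y in ys])
    r = np.linalg.norm(pts - center[None, :], axis=1)
    return pts[(r >= r_inner) & (r <= r_outer)]


def generate_system(spec: SyntheticSpec) -> SyntheticSystem:
    """Build the toy system and a static base trajectory.

    Deterministic for a fixed seed: two calls give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bx, by, bz = spec.box
    com = np.array([bx / 2, by / 2, bz / 2])

    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    helices: list[HelixAnnotation] = []
    atom_i = 0
    res_i = 0
    mol_i = 0

    # -- protein: n vertical bead columns on a ring, one residue per bead --
    angles = 2 * np.pi * np.arange(spec.n_helices) / spec.n_helices
    axes_xy = com[:2] + spec.helix_radius_ring * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    zs = np.linspace(-spec.helix_half_length, spec.helix_half_length, spec.beads_per_helix)
    for h in range(spec.n_helices):
        up = h % 2 == 0  # antiparallel bundle: even helices run matrix -> IMS
        order = zs if up else zs[::-1]
        first_res = res_i
        for z in order:
            records.append(
                AtomRecord(atom_i, "CA", "C", res_i, "HEL", mol_i, SpeciesTag.PROTEIN, 0.0, 110.0)
            )
            coords.append(np.array([axes_xy[h, 0], axes_xy[h, 1], com[2] + z]))
            atom_i += 1
            res_i += 1
        helices.append(
            HelixAnnotation(f"TM{h + 1}", (first_res, res_i - 1), "IMS" if up else "matrix")
        )
    mol_i += 1

    # -- lipid lattice sites per leaflet --
    r_outer = min(bx, by) / 2 - 0.05
    sites = _hex_sites((bx, by), spec.lipid_spacing, com[:2], spec.lipid_ring_inner, r_outer)
    n_per_leaflet = spec.n_popc_per_leaflet + spec.n_aa_per_leaflet
    n_cl_c = spec.n_cardiolipin  # cardiolipins sit in the C leaflet near the protein
    if n_per_leaflet + n_cl_c > len(sites):
        raise ValueError(
            f"overfull box: {n_per_leaflet + n_cl_c} lipids per leaflet but only {len(sites)} sites"
        )

    lipid_sites: dict[str, np.ndarray] = {}
    lipid_heads: dict[str, dict[str, list[int]]] = {"C": {"POPC": [], "AA": [], "CL": []}, "M": {"POPC": [], "AA": [], "CL": []}}
    aa_atoms: dict[int, np.ndarray] = {}
    aa_leaflet: dict[int, str] = {}
    aa_counter = 0

    for leaflet, zsign in (("C", +1.0), ("M", -1.0)):
        order = np.argsort(np.linalg.norm(sites - com[None, :2], axis=1), kind="stable")
        my_sites = sites[order]
        lipid_sites[leaflet] = my_sites
        head_z = com[2] + zsign * spec.leaflet_z
        cursor = 0
        # cardiolipins first, at the innermost sites ("just under 2 nm")
        n_cl = n_cl_c if leaflet == "C" else 0
        for _ in range(n_cl):
            xy = my_sites[cursor]
            cursor += 1
            records.append(AtomRecord(atom_i, "P", "P", res_i, "TLCL", mol_i, SpeciesTag.CARDIOLIPIN, -2.0, 120.0))
            coords.append(np.array([xy[0], xy[1], head_z]))
            lipid_heads[leaflet]["CL"].append(atom_i)
            atom_i += 1
            for k in range(4):
                records.append(AtomRecord(atom_i, f"C{k+1}", "C", res_i, "TLCL", mol_i, SpeciesTag.CARDIOLIPIN, 0.0, 40.0))
                coords.append(np.array([xy[0], xy[1], head_z - zsign * 0.25 * (k + 1)]))
                atom_i += 1
            res_i += 1
            mol_i += 1
        # remaining lipid species interleaved pseudo-randomly but seeded
        species_list = ["POPC"] * spec.n_popc_per_leaflet + ["AA"] * spec.n_aa_per_leaflet
        rng.shuffle(species_list)
        for sp in species_list:
            xy = my_sites[cursor]
            cursor += 1
            if sp == "POPC":
                records.append(AtomRecord(atom_i, "P", "P", res_i, "POPC", mol_i, SpeciesTag.POPC, 0.0, 123.0))
                coords.append(np.array([xy[0], xy[1], head_z]))
                lipid_heads[leaflet]["POPC"].append(atom_i)
                atom_i += 1
                for k in range(2):
                    records.append(AtomRecord(atom_i, f"C{k+1}", "C", res_i, "POPC", mol_i, SpeciesTag.POPC, 0.0, 100.0))
                    coords.append(np.array([xy[0], xy[1], head_z - zsign * 0.4 * (k + 1)]))
                    atom_i += 1
            else:  # AA: carboxylate head bead (charge -1) + 4 tail beads
                first = atom_i
                records.append(AtomRecord(atom_i, "OC", "O", res_i, "ARAN", mol_i, SpeciesTag.AA, -1.0, 44.0))
                coords.append(np.array([xy[0], xy[1], head_z]))
                lipid_heads[leaflet]["AA"].append(atom_i)
                atom_i += 1
                for k in range(4):
                    records.append(AtomRecord(atom_i, f"C{k+1}", "C", res_i, "ARAN", mol_i, SpeciesTag.AA, 0.0, 55.0))
                    coords.append(np.array([xy[0], xy[1], head_z - zsign * 0.3 * (k + 1)]))
                    atom_i += 1
                aa_atoms[aa_counter] = np.arange(first, atom_i)
                aa_leaflet[aa_counter] = leaflet
                aa_counter += 1
            res_i += 1
            mol_i += 1

    # -- water slabs on a jittered lattice --
    zlo, zhi = spec.water_slab_z
    nxy = int(bx / spec.water_spacing)
    xs = (np.arange(nxy) + 0.5) * spec.water_spacing
    ys = (np.arange(int(by / spec.water_spacing)) + 0.5) * spec.water_spacing
    zlevels = np.arange(zlo, zhi + 1e-9, spec.water_spacing)
    water_home: list[np.ndarray] = []
    water_idx_start = atom_i
    for zsign in (+1.0, -1.0):
        for z in zlevels:
            for x in xs:
                for y in ys:
                    water_home.append(np.array([x, y, com[2] + zsign * z]))
    water_home_arr = np.array(water_home)
    water_home_arr += rng.uniform(-spec.water_jitter, spec.water_jitter, water_home_arr.shape)
    for w in range(len(water_home_arr)):
        records.append(AtomRecord(atom_i, "O", "O", res_i, "HOH", mol_i, SpeciesTag.WATER, 0.0, 18.0))
        coords.append(water_home_arr[w])
        atom_i += 1
        res_i += 1
        mol_i += 1
    water_indices = np.arange(water_idx_start, atom_i)

    # -- counter-ions in a far corner of the top slab, away from the axis --
    n_ions = 2 * spec.n_aa_per_leaflet + 2 * n_cl_c
    corner = np.array([0.45, 0.45, com[2] + zhi - 0.1])
    for k in range(n_ions):
        records.append(AtomRecord(atom_i, "K", "K", res_i, "ION", mol_i, SpeciesTag.ION, +1.0, 39.1))
        coords.append(corner + np.array([0.35 * (k % 4), 0.35 * (k // 4), 0.0]))
        atom_i += 1
        res_i += 1
        mol_i += 1

    system = MolecularSystem(records, helices)
    assert abs(system.total_charge()) < 1e-9, "generated system must be electroneutral"
    base = np.array(coords)
    frames = [
        Frame(base.copy(), np.diag([bx, by, bz]), time=i * spec.frame_interval)
        for i in range(spec.n_frames)
    ]
    traj = Trajectory(system, frames, frame_interval=spec.frame_interval)
    layout = SyntheticLayout(
        com=com,
        helix_axes_xy=axes_xy,
        water_indices=water_indices,
        water_home=water_home_arr,
        water_z_inner=float(zlevels[0]),
        lipid_sites=lipid_sites,
        lipid_heads={lf: {sp: np.array(v, dtype=int) for sp, v in d.items()} for lf, d in lipid_heads.items()},
        aa_atoms=aa_atoms,
        aa_leaflet=aa_leaflet,
    )
    gt = {"seed": spec.seed, "n_frames": spec.n_frames, "planted_wires": [], "planted_events": [], "planted_enrichment": None}
    return SyntheticSystem(spec, system, traj, layout, gt)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _channel_xy(sysd: SyntheticSystem, helix_pair: tuple[str, str]) -> np.ndarray:
    """Lateral midline point between two helices, snapped to the water lattice."""
    ids = [int(h[2:]) - 1 for h in helix_pair]
    p = sysd.layout.helix_axes_xy[ids].mean(axis=0)
    s = sysd.spec.water_spacing
    snapped = (np.floor(p / s) + 0.5) * s
    return snapped


def _chain_positions(sysd: SyntheticSystem, xy: np.ndarray, spacing: float,
                     kink_lateral: float = 0.0) -> np.ndarray:
    """Single-file water positions spanning the membrane at lateral ``xy``.

    End points coincide with water-lattice sites in the slabs so the chain is
    always connected to bulk with gaps no larger than the chain spacing.
    """
    com_z = sysd.layout.com[2]
    z0 = sysd.layout.water_z_inner
    bottom = np.array([xy[0], xy[1], com_z - z0])
    top = np.array([xy[0], xy[1], com_z + z0])
    if kink_lateral > 0:
        mid = np.array([xy[0] + kink_lateral, xy[1], com_z])
        legs = [(bottom, mid), (mid, top)]
    else:
        legs = [(bottom, top)]
    pts = [bottom]
    for a, b in legs:
        d = np.linalg.norm(b - a)
        n = max(1, math.ceil(d / spacing - 1e-12))
        for k in range(1, n + 1):
            pts.append(a + (b - a) * k / n)
    return np.array(pts)


def plant_wire_schedule(
    sysd: SyntheticSystem,
    schedule: PlantedWireSchedule,
    helix_pair: tuple[str, str] = ("TM4", "TM5"),
    kink_lateral: float = 0.0,
) -> tuple[Trajectory, dict]:
    """Thread a single-file water chain through the channel between two helices.

    Present frames get consecutive O-O spacings <= ``gap_when_present``;
    absent frames have enough mid-chain waters parked back in bulk that the
    smallest achievable crossing gap is >= ``gap_when_absent``.
    """
    traj = sysd.trajectory
    if len(schedule.present) > traj.n_frames:
        raise ValueError("schedule longer than trajectory")
    xy = _channel_xy(sysd, helix_pair)
    chain = _chain_positions(sysd, xy, schedule.gap_when_present, kink_lateral)
    spacing = float(np.max(np.linalg.norm(np.diff(chain, axis=0), axis=1)))
    n_chain = len(chain)
    lay = sysd.layout
    pool_lo = len(lay.water_indices) - lay.n_channel_reserved - n_chain
    if pool_lo < 0:
        raise ValueError("not enough waters to build the channel chain")
    chan_waters = lay.water_indices[pool_lo : pool_lo + n_chain]
    lay.n_channel_reserved += n_chain
    home = lay.water_home[pool_lo : pool_lo + n_chain]

    # hole size in absent frames: remove middle waters until the gap is wide enough
    n_remove = max(1, math.ceil(schedule.gap_when_absent / spacing - 1e-12) - 1)
    mid = n_chain // 2
    removed = slice(mid - (n_remove - 1) // 2, mid - (n_remove - 1) // 2 + n_remove)

    for fi, flag in enumerate(schedule.present):
        c = traj.frames[fi].coordinates
        c[chan_waters] = chain
        if not flag:
            c[chan_waters[removed]] = home[removed]

    record = {
        "kind": "wire",
        "helix_pair": list(helix_pair),
        "present": [bool(x) for x in schedule.present],
        "realized_fraction": float(np.mean(schedule.present[: traj.n_frames])) if schedule.present else 0.0,
        "gap_when_present": spacing,
        "gap_when_absent": schedule.gap_when_absent,
        "channel_xy": xy.tolist(),
        "channel_water_indices": chan_waters.tolist(),
        "run_lengths": _run_lengths(schedule.present),
    }
    sysd.ground_truth["planted_wires"].append(record)
    return traj, record


def _run_lengths(flags: list[bool]) -> list[int]:
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


def plant_binding_event(sysd: SyntheticSystem, event: PlantedBindingEvent) -> tuple[Trajectory, dict]:
    """Thread an AA through an interhelical gap (or park it in the cavity).

    During the event the carboxylate sits ``planted_depth`` from the protein
    COM with the tail crossing the site's gap surface and contacting both
    helices; outside the event the AA rests at its membrane home site, at
    least 1 nm from the protein surface.
    """
    traj = sysd.trajectory
    lay = sysd.layout
    spec = sysd.spec
    if event.aa_id not in lay.aa_atoms:
        raise ValueError(f"no AA molecule {event.aa_id}")
    if event.end_frame >= traj.n_frames:
        raise ValueError("event extends past the trajectory")
    for rec in sysd.ground_truth["planted_events"]:
        if rec["aa_id"] == event.aa_id and not (
            event.end_frame < rec["start_frame"] or event.start_frame > rec["end_frame"]
        ):
            raise ValueError(f"conflicting events for AA {event.aa_id}")

    atoms = lay.aa_atoms[event.aa_id]
    com = lay.com
    d = event.planted_depth

    if event.site == "cavity":
        head = com + np.array([0.0, 0.0, d])
        tail = [com + np.array([0.15, 0.0, d - 0.3 * (k + 1)]) for k in range(4)]
    else:
        ha, hb = event.site.split("/")
        ids = [int(h[2:]) - 1 for h in (ha, hb)]
        u = lay.helix_axes_xy[ids].mean(axis=0) - com[:2]
        u = u / np.linalg.norm(u)
        r_head = 0.5
        dz = math.sqrt(max(d * d - r_head * r_head, 0.0))
        head = np.array([com[0] + r_head * u[0], com[1] + r_head * u[1], com[2] + dz])
        gap_center = np.array([*(com[:2] + np.linalg.norm(lay.helix_axes_xy[ids].mean(axis=0) - com[:2]) * u), com[2]])
        outer = np.array([*(com[:2] + (spec.helix_radius_ring + 0.8) * u), com[2] - 0.2])
        tail = [
            0.5 * head + 0.5 * gap_center,
            gap_center,
            0.5 * gap_center + 0.5 * outer,
            outer,
        ]
    placed = np.vstack([head] + tail)

    # home (unbound) position: outermost site of the AA's leaflet
    leaflet = lay.aa_leaflet[event.aa_id]
    zsign = +1.0 if leaflet == "C" else -1.0
    far_xy = lay.lipid_sites[leaflet][-1]
    head_z = com[2] + zsign * spec.leaflet_z
    home = np.vstack(
        [np.array([far_xy[0], far_xy[1], head_z])]
        + [np.array([far_xy[0], far_xy[1], head_z - zsign * 0.3 * (k + 1)]) for k in range(4)]
    )

    for fi in range(traj.n_frames):
        c = traj.frames[fi].coordinates
        c[atoms] = placed if event.start_frame <= fi <= event.end_frame else home

    record = {
        "kind": "binding",
        "aa_id": event.aa_id,
        "site": event.site,
        "start_frame": event.start_frame,
        "end_frame": event.end_frame,
        "n_frames": event.end_frame - event.start_frame + 1,
        "planted_depth": d,
        "deep": bool(d <= 1.3),
    }
    sysd.ground_truth["planted_events"].append(record)
    return traj, record


def plant_enrichment(
    sysd: SyntheticSystem,
    fold: float,
    ring: tuple[float, float] = (0.0, 1.0),
    leaflet: str = "C",
) -> tuple[Trajectory, dict]:
    """Re-place lipid heads each frame so the near-surface ring has an
    expected AA mole fraction ``fold`` times the fraction everywhere else.

    Construction: occupied lattice sites are fixed; each frame the number of
    ring AA is Binomial(n_ring_sites, fold*x0) with x0 chosen so the total AA
    count and the off-ring mole fraction both equal their nominal values, so
    the expected ring/bulk ratio is exactly ``fold``.
    """
    if fold < 0:
        raise ValueError("fold must be >= 0")
    traj = sysd.trajectory
    lay = sysd.layout
    spec = sysd.spec
    rng = np.random.default_rng(spec.seed + 77_001)

    surface_r = spec.helix_radius_ring  # C-side helix ends sit on the ring
    sites = lay.lipid_sites[leaflet]
    n_lipids = spec.n_popc_per_leaflet + spec.n_aa_per_leaflet
    occupied = sites[:n_lipids]  # innermost sites, deterministic
    dist = np.linalg.norm(occupied - lay.com[None, :2], axis=1) - surface_r
    ring_mask = (dist >= ring[0]) & (dist < ring[1])
    m_ring = int(ring_mask.sum())
    m_out = int(n_lipids - m_ring)
    n_aa = spec.n_aa_per_leaflet
    if m_ring == 0 or m_out == 0:
        raise ValueError("ring and bulk must both contain occupied sites")
    x0 = n_aa / (fold * m_ring + m_out)
    p_ring = fold * x0
    if p_ring > 1.0:
        raise ValueError("fold too large: the ring cannot hold the required AA")

    aa_heads = lay.lipid_heads[leaflet]["AA"]
    popc_heads = lay.lipid_heads[leaflet]["POPC"]
    zsign = +1.0 if leaflet == "C" else -1.0
    head_z = lay.com[2] + zsign * spec.leaflet_z
    ring_sites = np.flatnonzero(ring_mask)
    out_sites = np.flatnonzero(~ring_mask)
    sys_atoms = sysd.system
    aa_tail_offsets = np.array([[0.0, 0.0, -zsign * 0.3 * (k + 1)] for k in range(4)])
    popc_tail_offsets = np.array([[0.0, 0.0, -zsign * 0.4 * (k + 1)] for k in range(2)])

    realized_ring_aa = 0
    realized_ring_tot = 0
    for fi in range(traj.n_frames):
        k = int(np.clip(rng.binomial(m_ring, p_ring), max(0, n_aa - m_out), min(n_aa, m_ring)))
        ring_pick = rng.choice(ring_sites, size=k, replace=False)
        out_pick = rng.choice(out_sites, size=n_aa - k, replace=False)
        aa_sites = np.concatenate([ring_pick, out_pick]).astype(int)
        popc_sites = np.setdiff1d(np.arange(n_lipids), aa_sites)
        c = traj.frames[fi].coordinates
        for head, s in zip(aa_heads, aa_sites):
            pos = np.array([occupied[s, 0], occupied[s, 1], head_z])
            c[head] = pos
            c[head + 1 : head + 5] = pos[None, :] + aa_tail_offsets
        for head, s in zip(popc_heads, popc_sites):
            pos = np.array([occupied[s, 0], occupied[s, 1], head_z])
            c[head] = pos
            c[head + 1 : head + 3] = pos[None, :] + popc_tail_offsets
        realized_ring_aa += k
        realized_ring_tot += m_ring

    record = {
        "kind": "enrichment",
        "leaflet": leaflet,
        "fold": fold,
        "ring": list(ring),
        "x0": x0,
        "m_ring": m_ring,
        "m_out": m_out,
        "surface_radius": surface_r,
        "realized_ring_fraction": realized_ring_aa / max(realized_ring_tot, 1),
    }
    sysd.ground_truth["planted_enrichment"] = record
    return traj, record


def write_ground_truth(sysd: SyntheticSystem, path: str | Path) -> None:
    """Emit the sidecar ground-truth record as JSON."""
    payload = dict(sysd.ground_truth)
    payload["spec"] = asdict(sysd.spec)
    Path(path).write_text(json.dumps(payload, indent=2))
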