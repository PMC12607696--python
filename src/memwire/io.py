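"""Structure and trajectory I/O (PDB, GRO, multi-frame GRO) via MDTraj.

MDTraj handles the column-level format details; this module maps its
topology onto the package's :class:`~memwire.model.MolecularSystem`,
inferring species tags from residue names through a configurable mapping.
Binary trajectory formats (XTC/DCD) are supported through the same adapter:
any MDTraj-loadable file converts via :func:`from_mdtraj`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import mdtraj as md
import mdtraj.core.element as _elem
import numpy as np

from .model import AtomRecord, Frame, HelixAnnotation, MolecularSystem, SpeciesTag, Trajectory

__all__ = [
    "DEFAULT_SPECIES_MAP",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "from_mdtraj",
    "to_mdtraj",
    "apply_charge_map",
]


class StructureParseError(ValueError):
    """Raised when a structure/trajectory file fails to parse."""


#: residue-name -> species tag used when ingesting files
DEFAULT_SPECIES_MAP: dict[str, SpeciesTag] = {
    "HOH": SpeciesTag.WATER,
    "SOL": SpeciesTag.WATER,
    "TIP3": SpeciesTag.WATER,
    "WAT": SpeciesTag.WATER,
    "POPC": SpeciesTag.POPC,
    "POP": SpeciesTag.POPC,  # PDB 3-character residue-name truncation
    "ARAN": SpeciesTag.AA,
    "ARA": SpeciesTag.AA,
    "AA": SpeciesTag.AA,
    "TLCL": SpeciesTag.CARDIOLIPIN,
    "TLCL2": SpeciesTag.CARDIOLIPIN,
    "CDL": SpeciesTag.CARDIOLIPIN,
    "HEL": SpeciesTag.PROTEIN,  # synthetic helix beads
    "K": SpeciesTag.ION,
    "POT": SpeciesTag.ION,
    "CL": SpeciesTag.ION,
    "CLA": SpeciesTag.ION,
    "NA": SpeciesTag.ION,
    "SOD": SpeciesTag.ION,
    "ION": SpeciesTag.ION,
}


def _tag_for(residue: "md.core.topology.Residue", species_map: Mapping[str, SpeciesTag]) -> SpeciesTag:
    name = residue.name.strip()
    if name in species_map:
        return species_map[name]
    if residue.is_protein:
        return SpeciesTag.PROTEIN
    if residue.is_water:
        return SpeciesTag.WATER
    warnings.warn(f"unknown residue name {name!r}: tagged as 'other'", stacklevel=3)
    return SpeciesTag.OTHER


def _system_from_topology(
    top: "md.Topology", species_map: Mapping[str, SpeciesTag]
) -> MolecularSystem:
    records: list[AtomRecord] = []
    tag_cache: dict[int, SpeciesTag] = {}
    mol_counter = 0
    protein_mol_assigned = False
    res_mol: dict[int, int] = {}
    for res in top.residues:
        tag_cache[res.index] = _tag_for(res, species_map)
    # protein residues share one molecule id; every other residue is its own molecule
    for res in top.residues:
        if tag_cache[res.index] == SpeciesTag.PROTEIN:
            if not protein_mol_assigned:
                protein_mol_id = mol_counter
                mol_counter += 1
                protein_mol_assigned = True
            res_mol[res.index] = protein_mol_id
        else:
            res_mol[res.index] = mol_counter
            mol_counter += 1
    for atom in top.atoms:
        el = atom.element
        symbol = el.symbol if el is not None and el.symbol != "VS" else _guess_symbol(atom.name)
        mass = el.mass if el is not None and el.mass > 0 else 1.0
        records.append(
            AtomRecord(
                atom_index=atom.index,
                name=atom.name,
                element=symbol,
                residue_index=atom.residue.index,
                residue_name=atom.residue.name,
                molecule_id=res_mol[atom.residue.index],
                species_tag=tag_cache[atom.residue.index],
                charge=0.0,
                mass=float(mass),
            )
        )
    return MolecularSystem(records)


def _guess_symbol(atom_name: str) -> str:
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(
    path: str | Path,
    species_map: Mapping[str, SpeciesTag] | None = None,
) -> tuple[MolecularSystem, Frame]:
    """Read a PDB or GRO file; the format is taken from the extension."""
    path = Path(path)
    species_map = DEFAULT_SPECIES_MAP if species_map is None else species_map
    try:
        traj = md.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise StructureParseError(f"{path}: {exc}") from exc
    system = _system_from_topology(traj.topology, species_map)
    box = traj.unitcell_vectors[0] if traj.unitcell_vectors is not None else np.eye(3) * 1e6
    time = float(traj.time[0]) if traj.time is not None else 0.0
    return system, Frame(traj.xyz[0].astype(float), box.astype(float), time)


def read_trajectory(
    path: str | Path,
    species_map: Mapping[str, SpeciesTag] | None = None,
    top: str | Path | None = None,
) -> Trajectory:
    """Read a multi-frame GRO (or any MDTraj-supported trajectory with ``top``)."""
    path = Path(path)
    species_map = DEFAULT_SPECIES_MAP if species_map is None else species_map
    try:
        traj = md.load(str(path)) if top is None else md.load(str(path), top=str(top))
    except Exception as exc:  # noqa: BLE001
        raise StructureParseError(f"{path}: {exc}") from exc
    return from_mdtraj(traj, species_map)


def from_mdtraj(traj: "md.Trajectory", species_map: Mapping[str, SpeciesTag] | None = None) -> Trajectory:
    """Adapter: wrap any MDTraj trajectory (XTC, DCD, GRO, ...) as a Trajectory."""
    species_map = DEFAULT_SPECIES_MAP if species_map is None else species_map
    system = _system_from_topology(traj.topology, species_map)
    times = traj.time if traj.time is not None else np.arange(traj.n_frames, dtype=float)
    if traj.n_frames > 1 and times[1] <= times[0]:  # missing/constant times in file
        times = np.arange(traj.n_frames, dtype=float)
    frames = [
        Frame(traj.xyz[i].astype(float), traj.unitcell_vectors[i].astype(float), float(times[i]))
        for i in range(traj.n_frames)
    ]
    interval = float(times[1] - times[0]) if traj.n_frames > 1 else 1.0
    return Trajectory(system, frames, frame_interval=interval)


def _topology_from_system(system: MolecularSystem) -> "md.Topology":
    top = md.Topology()
    chain = top.add_chain()
    current_res = None
    res = None
    for atom in system.atoms:
        if atom.residue_index != current_res:
            res = top.add_residue(atom.residue_name, chain, resSeq=atom.residue_index + 1)
            current_res = atom.residue_index
        try:
            el = _elem.get_by_symbol(atom.element.capitalize())
        except KeyError:
            el = _elem.virtual
        top.add_atom(atom.name, el, res)
    return top


def to_mdtraj(traj: Trajectory) -> "md.Trajectory":
    top = _topology_from_system(traj.system)
    xyz = np.stack([f.coordinates for f in traj.frames]).astype(np.float32)
    vectors = np.stack([f.box for f in traj.frames]).astype(np.float32)
    out = md.Trajectory(xyz, top, time=np.array([f.time for f in traj.frames]))
    out.unitcell_vectors = vectors
    return out


def write_structure(system: MolecularSystem, frame: Frame, path: str | Path) -> None:
    """Write a single frame as PDB or GRO (format from the extension)."""
    traj = to_mdtraj(Trajectory(system, [frame], frame_interval=1.0))
    traj.save(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame GRO trajectory."""
    to_mdtraj(traj).save(str(path))


def apply_charge_map(
    system: MolecularSystem,
    charges: Mapping[tuple[str, str], float] | Mapping[str, float],
    by_atom: bool = True,
) -> MolecularSystem:
    """Return a copy of ``system`` with charges assigned from a mapping.

    With ``by_atom`` the keys are ``(residue_name, atom_name)`` pairs;
    otherwise a flat ``residue_name -> charge`` map assigns the whole charge
    to the first atom of each residue.
    """
    records = []
    seen_res: set[int] = set()
    for a in system.atoms:
        q = a.charge
        if by_atom:
            q = float(charges.get((a.residue_name, a.name), a.charge))  # type: ignore[arg-type]
        else:
            if a.residue_index not in seen_res:
                q = float(charges.get(a.residue_name, 0.0))  # type: ignore[arg-type]
                seen_res.add(a.residue_index)
            else:
                q = 0.0
        records.append(
            AtomRecord(
                atom_index=a.atom_index,
                name=a.name,
                element=a.element,
                residue_index=a.residue_index,
                residue_name=a.residue_name,
                molecule_id=a.molecule_id,
                species_tag=a.species_tag,
                charge=q,
                mass=a.mass,
            )
        )
    return MolecularSystem(records, system.helices)
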