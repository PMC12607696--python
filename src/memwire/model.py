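"""Core data model for periodic molecular systems and trajectories.

Conventions used throughout the package: coordinates in nm, times in ps,
charges in elementary charge units (e), masses in atomic mass units.  Atom,
residue and frame indices are 0-based everywhere; 1-based numbering appears
only at file-format boundaries (GRO/PDB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpeciesTag",
    "AtomRecord",
    "HelixAnnotation",
    "Frame",
    "MolecularSystem",
    "Trajectory",
]


class SpeciesTag(str, Enum):
    """Chemical species category of an atom's parent molecule."""

    PROTEIN = "protein"
    WATER = "water"
    POPC = "POPC"
    AA = "AA"  # arachidonic acid (deprotonated, net charge -1)
    CARDIOLIPIN = "cardiolipin"
    ION = "ion"
    OTHER = "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom (or coarse bead) of the system.

    ``is_heavy`` is True for every element other than hydrogen; hydrogen-free
    bead models therefore consist entirely of heavy atoms.
    """

    atom_index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    molecule_id: int
    species_tag: SpeciesTag = SpeciesTag.OTHER
    charge: float = 0.0
    mass: float = 1.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def __post_init__(self) -> None:
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.atom_index}: charge must be finite")
        if not self.mass > 0:
            raise ValueError(f"atom {self.atom_index}: mass must be > 0")


@dataclass(frozen=True)
class HelixAnnotation:
    """A transmembrane helix: inclusive residue-index range and topology.

    ``c_terminal_end`` records which side of the membrane the C-terminal end
    of the helix points to ("IMS" = intermembrane-space / C side, "matrix" =
    M side).
    """

    helix_id: str  # "TM1" .. "TM6"
    residue_range: tuple[int, int]  # inclusive, 0-based
    c_terminal_end: str = "IMS"

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"{self.helix_id}: empty residue range {self.residue_range}")
        if self.c_terminal_end not in ("IMS", "matrix"):
            raise ValueError(f"{self.helix_id}: c_terminal_end must be 'IMS' or 'matrix'")

    @property
    def residues(self) -> range:
        return range(self.residue_range[0], self.residue_range[1] + 1)


class Frame:
    """Coordinates (nm) of every atom at one time point, plus the box.

    The box is a 3x3 matrix of lattice vectors (rows), GROMACS-reduced for
    triclinic cells; its determinant must be positive.
    """

    __slots__ = ("coordinates", "box", "time")

    def __init__(self, coordinates: np.ndarray, box: np.ndarray, time: float = 0.0):
        coordinates = np.asarray(coordinates, dtype=float)
        box = np.asarray(box, dtype=float)
        if coordinates.ndim != 2 or coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(coordinates)):
            raise ValueError("coordinates must be finite")
        if box.shape == (3,):
            box = np.diag(box)
        if box.shape != (3, 3):
            raise ValueError("box must be a 3x3 lattice-vector matrix")
        if np.linalg.det(box) <= 0:
            raise ValueError("box determinant must be positive")
        self.coordinates = coordinates
        self.box = box
        self.time = float(time)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


class MolecularSystem:
    """Topology of the system: atoms, helix annotations, cached index arrays."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        helices: Sequence[HelixAnnotation] = (),
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise ValueError(
                    f"atom_index must be contiguous and 0-based: found {a.atom_index} at position {i}"
                )
        self.helices: list[HelixAnnotation] = list(helices)
        self._check_helix_overlap()

        n = len(self.atoms)
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.species = np.array([a.species_tag.value for a in self.atoms])
        self.residue_indices = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=int)
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.names = np.array([a.name for a in self.atoms])
        self.protein_atom_set = np.flatnonzero(self.species == SpeciesTag.PROTEIN.value)
        if n and self.helices:
            prot_res = set(self.residue_indices[self.protein_atom_set].tolist())
            for h in self.helices:
                missing = [r for r in h.residues if r not in prot_res]
                if missing:
                    raise ValueError(
                        f"{h.helix_id}: residues {missing[:5]} have no protein atoms"
                    )

    def _check_helix_overlap(self) -> None:
        seen: set[int] = set()
        for h in self.helices:
            rr = set(h.residues)
            if rr & seen:
                raise ValueError(f"helix residue ranges overlap at {sorted(rr & seen)[:5]}")
            seen |= rr

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # -- selections -------------------------------------------------------

    def species_indices(self, tag: SpeciesTag) -> np.ndarray:
        return np.flatnonzero(self.species == tag.value)

    def water_oxygen_indices(self) -> np.ndarray:
        """Oxygen (or single-bead water) atoms of all water molecules."""
        w = self.species == SpeciesTag.WATER.value
        names = np.char.upper(self.names.astype(str))
        ox = np.char.startswith(names, "O") | np.char.startswith(names, "W")
        sel = np.flatnonzero(w & ox)
        if sel.size == 0:  # bead waters with arbitrary names: one bead per molecule
            sel = np.flatnonzero(w)
        return sel

    def residue_atoms(self, residues: Iterable[int]) -> np.ndarray:
        rset = np.asarray(sorted(set(residues)), dtype=int)
        return np.flatnonzero(np.isin(self.residue_indices, rset))

    def helix_by_id(self, helix_id: str) -> HelixAnnotation:
        for h in self.helices:
            if h.helix_id == helix_id:
                return h
        raise KeyError(f"no helix annotation {helix_id!r}")

    def helix_atoms(self, helix_id: str) -> np.ndarray:
        h = self.helix_by_id(helix_id)
        sel = self.residue_atoms(h.residues)
        return sel[np.isin(sel, self.protein_atom_set)]

    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class Trajectory:
    """An ordered sequence of frames over one molecular system."""

    system: MolecularSystem
    frames: list[Frame] = field(default_factory=list)
    frame_interval: float = 1.0  # ps between saved frames

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def copy(self) -> "Trajectory":
        return Trajectory(self.system, [f.copy() for f in self.frames], self.frame_interval)
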