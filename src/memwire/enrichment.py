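"""Leaflet-resolved radial AA mole-fraction profiles and enrichment ratios.

The protein is approximated as a cylinder.  In the outer (C) leaflet its
radius is the time-averaged largest lateral distance from the protein COM
axis to the C-side ends of the TM helices; in the inner (M) leaflet a fixed
2 nm radius is used.  Lipids are positioned by their head atoms (AA
carboxylate, POPC phosphate); the mole fraction AA/(AA+POPC) is accumulated
in annuli of distance from the cylinder surface with counts pooled over
frames, which makes the count-weighted bin average equal the global mole
fraction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import probes_from_system
from .geometry import center_of_mass, lateral_distance
from .model import Frame, MolecularSystem, SpeciesTag, Trajectory

__all__ = [
    "RadialProfile",
    "assign_leaflet",
    "bilayer_midplane",
    "surface_radius",
    "radial_mole_fraction",
    "enrichment_ratio",
    "aggregate_profiles",
]

M_LEAFLET_SURFACE_RADIUS = 2.0  # nm, fixed inner-leaflet cylinder radius


@dataclass
class RadialProfile:
    """Pooled-count mole-fraction profile for one leaflet of one trajectory."""

    leaflet: str
    bin_edges: np.ndarray  # nm, distance from the protein cylinder surface
    n_aa: np.ndarray  # pooled AA head counts per bin
    n_total: np.ndarray  # pooled AA+POPC head counts per bin
    surface_radius: float
    near_ring: tuple[float, float] = (0.0, 1.0)
    bulk_region: tuple[float, float] | None = None
    replicate_mean: np.ndarray | None = None  # across-replicate aggregation
    replicate_sd: np.ndarray | None = None

    @property
    def mole_fraction(self) -> np.ndarray:
        """Per-bin AA/(AA+POPC); NaN where the annulus is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_aa / self.n_total, np.nan)

    @property
    def global_mole_fraction(self) -> float:
        return float(self.n_aa.sum() / self.n_total.sum())

    def _interval_fraction(self, lo: float, hi: float) -> float:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        mask = (centers >= lo) & (centers < hi)
        total = self.n_total[mask].sum()
        if total == 0:
            raise ValueError(f"no lipids in radial interval [{lo}, {hi}) nm")
        return float(self.n_aa[mask].sum() / total)


def bilayer_midplane(frame: Frame, system: MolecularSystem) -> float:
    """Mean z of all POPC phosphates: the leaflet-assignment reference."""
    popc = system.species_indices(SpeciesTag.POPC)
    p_atoms = popc[np.char.startswith(np.char.upper(system.names[popc].astype(str)), "P")]
    if len(p_atoms) == 0:
        raise ValueError("no POPC phosphate atoms to define the bilayer midplane")
    return float(frame.coordinates[p_atoms, 2].mean())


def assign_leaflet(head_z: float | np.ndarray, midplane: float) -> np.ndarray:
    """'C' above the midplane, 'M' at or below it (tie rule: M)."""
    return np.where(np.asarray(head_z) > midplane, "C", "M")


def surface_radius(
    system: MolecularSystem,
    frames: list[Frame] | Trajectory,
    leaflet: str,
    m_radius: float = M_LEAFLET_SURFACE_RADIUS,
) -> float:
    """Protein cylinder radius for the given leaflet.

    C leaflet: time-averaged maximum lateral distance from the protein COM
    axis to the C-side terminal residue of each TM helix.  M leaflet: fixed
    ``m_radius`` (2 nm by default).
    """
    if leaflet == "M":
        return m_radius
    if not system.helices:
        raise ValueError("surface_radius needs helix annotations")
    frames = list(frames)
    per_frame = []
    for frame in frames:
        com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)
        radii = []
        for h in system.helices:
            res = h.residue_range[1] if h.c_terminal_end == "IMS" else h.residue_range[0]
            atoms = system.residue_atoms([res])
            atoms = atoms[np.isin(atoms, system.protein_atom_set)]
            ca = [a for a in atoms if system.names[a].upper().startswith("CA")] or list(atoms)
            pos = frame.coordinates[ca].mean(axis=0)
            radii.append(float(lateral_distance(pos, com, frame.box)))
        per_frame.append(max(radii))
    return float(np.mean(per_frame))


def _lipid_heads(system: MolecularSystem) -> tuple[np.ndarray, np.ndarray]:
    probes = probes_from_system(system, (SpeciesTag.AA, SpeciesTag.POPC))
    aa = np.array([p.head_atom for p in probes if p.species == SpeciesTag.AA], dtype=int)
    popc = np.array([p.head_atom for p in probes if p.species == SpeciesTag.POPC], dtype=int)
    return aa, popc


def radial_mole_fraction(
    traj: Trajectory,
    leaflet: str,
    bin_width: float = 0.1,
    surface_r: float | None = None,
    near_ring: tuple[float, float] = (0.0, 1.0),
    bulk_region: tuple[float, float] | None = None,
) -> RadialProfile:
    """Pooled-count AA mole fraction vs distance from the protein surface.

    Distances are lateral-minus-surface-radius, clamped at zero (lipids over
    the cylinder footprint land in the first bin).  The default bulk region
    is the outermost 0.5 nm of radii fully contained in the box under PBC.
    """
    if traj.n_frames == 0:
        raise ValueError("need at least one frame")
    system = traj.system
    aa_heads, popc_heads = _lipid_heads(system)
    if surface_r is None:
        surface_r = surface_radius(system, traj.frames, leaflet)
    box = traj.frames[0].box
    r_max = min(box[0, 0], box[1, 1]) / 2 - surface_r
    if r_max <= bin_width:
        raise ValueError("box too small for a radial profile outside the protein surface")
    if bulk_region is None:
        bulk_region = (r_max - 0.5, r_max)
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    n_aa = np.zeros(len(edges) - 1)
    n_tot = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        mid = bilayer_midplane(frame, system)
        com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)
        for heads, is_aa in ((aa_heads, True), (popc_heads, False)):
            if len(heads) == 0:
                continue
            pos = frame.coordinates[heads]
            labels = assign_leaflet(pos[:, 2], mid)
            sel = pos[labels == leaflet]
            if len(sel) == 0:
                continue
            d = np.clip(lateral_distance(sel, com, box) - surface_r, 0.0, None)
            counts, _ = np.histogram(d, bins=edges)
            n_tot += counts
            if is_aa:
                n_aa += counts
    if n_tot.sum() == 0:
        raise ValueError(f"no lipid heads found in leaflet {leaflet!r}")
    return RadialProfile(
        leaflet=leaflet,
        bin_edges=edges,
        n_aa=n_aa,
        n_total=n_tot,
        surface_radius=float(surface_r),
        near_ring=near_ring,
        bulk_region=bulk_region,
    )


def enrichment_ratio(profile: RadialProfile) -> float:
    """(near-ring mole fraction) / (bulk mole fraction), both count-weighted.

    Raises when either region is empty or the bulk fraction is zero — the
    ratio is undefined, not infinite.
    """
    near = profile._interval_fraction(*profile.near_ring)
    if profile.bulk_region is None:
        raise ValueError("profile has no bulk region")
    bulk = profile._interval_fraction(*profile.bulk_region)
    if bulk == 0:
        raise ValueError("bulk mole fraction is zero: enrichment ratio undefined")
    return near / bulk


def aggregate_profiles(profiles: list[RadialProfile]) -> RadialProfile:
    """Across-replicate mean and standard deviation of per-bin mole fractions.

    The pooled counts of the first profile are kept; mean/sd are computed
    bin-wise over the replicates (population sd, so identical copies give 0).
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ValueError("replicate profiles must share bin edges")
    stack = np.vstack([p.mole_fraction for p in profiles])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins are legitimate
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0)
    out = RadialProfile(
        leaflet=profiles[0].leaflet,
        bin_edges=edges,
        n_aa=sum(p.n_aa for p in profiles),
        n_total=sum(p.n_total for p in profiles),
        surface_radius=profiles[0].surface_radius,
        near_ring=profiles[0].near_ring,
        bulk_region=profiles[0].bulk_region,
    )
    out.replicate_mean = mean
    out.replicate_sd = sd
    return out
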