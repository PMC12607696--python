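"""Reciprocal-space PME electrostatic potential on a grid, and wire-averaged
potential profiles along the membrane normal.

Only the smooth (reciprocal, Gaussian-smeared) component of the periodic
Coulomb potential is computed — the k-space part of an Ewald decomposition
with smearing factor exp(-k^2/(4 beta^2))/k^2 and the k=0 mode excluded,
which makes the grid mean exactly zero and implicitly neutralizes any net
charge with a uniform background.  Short-range (real-space) terms are
deliberately omitted: they would be singular on a grid, and their absence is
restated in output metadata.  Charges are spread with 4th-order cardinal
B-splines (smooth PME); potentials are reported in kT/e at the simulation
temperature, convertible to volts.

``direct_reciprocal_sum`` is a slow direct k-space summation of the same
quantity, kept as an independent reference evaluator for validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy.ndimage import map_coordinates

from .geometry import center_of_mass
from .model import MolecularSystem, SpeciesTag, Trajectory

__all__ = [
    "COULOMB_KJ_MOL_NM_E2",
    "KB_KJ_MOL_K",
    "ChargeConfiguration",
    "SmoothedPotentialField",
    "WirePotentialProfile",
    "PotentialConfig",
    "bspline4_weights",
    "reciprocal_potential_field",
    "potential_at_points",
    "direct_reciprocal_sum",
    "wire_potential_profile",
    "kT_per_e_to_volts",
]

#: 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_KJ_MOL_NM_E2 = 138.935458
#: Boltzmann constant in kJ mol^-1 K^-1
KB_KJ_MOL_K = _const.R / 1000.0

_SPLINE_ORDER = 4


@dataclass
class ChargeConfiguration:
    """Point charges in a periodic box (positions nm, charges e)."""

    positions: np.ndarray
    charges: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if box.shape == (3,):
            box = np.diag(box)
        if np.linalg.det(box) <= 0:
            raise ValueError("non-positive box")
        self.box = box
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise ValueError("positions and charges must be finite")


@dataclass
class SmoothedPotentialField:
    """Periodic reciprocal-space potential on a grid, in kT/e."""

    values: np.ndarray  # (K1, K2, K3)
    box: np.ndarray
    spacing: tuple[float, float, float]
    ewald_beta: float
    temperature: float
    metadata: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class WirePotentialProfile:
    z_centers: np.ndarray  # nm, relative to protein COM z
    mean_kT_e: np.ndarray  # NaN on bins no wire node visited
    n_samples: np.ndarray
    per_wire_maxima: np.ndarray  # kT/e, one per analyzed wire
    maxima_mean: float
    maxima_sd: float
    temperature: float

    @property
    def mean_volts(self) -> np.ndarray:
        return kT_per_e_to_volts(self.mean_kT_e, self.temperature)


@dataclass(frozen=True)
class PotentialConfig:
    spacing: float = 0.1  # nm, maximum grid spacing
    beta: float = 2.5  # nm^-1, Ewald smearing parameter
    temperature: float = 310.15  # K
    stride: int = 10  # analyze every stride-th wire-containing frame
    bin_width: float = 0.1  # nm, z-profile bin width
    bulk_z: float = 2.2  # nm, |z - COM_z| beyond which water is "bulk" reference


# ---------------------------------------------------------------------------
# B-spline machinery
# ---------------------------------------------------------------------------

def _m_spline(n: int, x: np.ndarray) -> np.ndarray:
    """Cardinal B-spline M_n on [0, n] (Essmann recursion)."""
    x = np.asarray(x, dtype=float)
    if n == 2:
        return np.where((x >= 0) & (x <= 2), 1.0 - np.abs(x - 1.0), 0.0)
    return (x / (n - 1)) * _m_spline(n - 1, x) + ((n - x) / (n - 1)) * _m_spline(n - 1, x - 1.0)


def bspline4_weights(frac: np.ndarray) -> np.ndarray:
    """Order-4 spreading weights for fractional offsets ``frac`` in [0, 1).

    Returns shape (len(frac), 4): the weights of grid points
    floor(u)-3 .. floor(u) for u with fractional part ``frac``; they sum to 1.
    """
    frac = np.asarray(frac, dtype=float)
    offs = frac[:, None] + np.arange(3, -1, -1)[None, :]  # u - g for g = floor(u)-3 .. floor(u)
    return _m_spline(_SPLINE_ORDER, offs)


def _b_factor(K: int) -> np.ndarray:
    """Euler exponential-spline factor b(m) for order-4 interpolation."""
    m = np.arange(K)
    k = np.arange(_SPLINE_ORDER - 1)
    denom = (_m_spline(_SPLINE_ORDER, k + 1.0)[None, :] * np.exp(2j * np.pi * m[:, None] * k[None, :] / K)).sum(axis=1)
    return np.exp(2j * np.pi * (_SPLINE_ORDER - 1) * m / K) / denom


def _spread_charges(frac_pos: np.ndarray, charges: np.ndarray, K: tuple[int, int, int]) -> np.ndarray:
    """Scatter charges onto the grid with order-4 B-splines (periodic)."""
    Q = np.zeros(K)
    u = frac_pos * np.array(K)[None, :]
    base = np.floor(u).astype(int)
    w = [bspline4_weights(u[:, d] - base[:, d]) for d in range(3)]
    offsets = np.arange(-3, 1)
    idx = [(base[:, d][:, None] + offsets[None, :]) % K[d] for d in range(3)]
    for a in range(4):
        for b in range(4):
            wab = w[0][:, a] * w[1][:, b]
            for c in range(4):
                np.add.at(Q, (idx[0][:, a], idx[1][:, b], idx[2][:, c]), charges * wab * w[2][:, c])
    return Q


def _k_vectors(box: np.ndarray, K: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """|k|^2 grid (fftfreq layout) and the integer index grids."""
    recip = 2 * np.pi * np.linalg.inv(box).T  # rows k_i with k_i . a_j = 2 pi delta_ij
    ms = [np.fft.fftfreq(k) * k for k in K]
    m1, m2, m3 = np.meshgrid(*ms, indexing="ij")
    kx = m1 * recip[0, 0] + m2 * recip[1, 0] + m3 * recip[2, 0]
    ky = m1 * recip[0, 1] + m2 * recip[1, 1] + m3 * recip[2, 1]
    kz = m1 * recip[0, 2] + m2 * recip[1, 2] + m3 * recip[2, 2]
    return kx * kx + ky * ky + kz * kz, np.stack([m1, m2, m3])


def reciprocal_potential_field(
    config: ChargeConfiguration,
    spacing: float = 0.1,
    beta: float = 2.5,
    temperature: float = 310.15,
) -> SmoothedPotentialField:
    """Smooth-PME reciprocal potential on a grid, in kT/e.

    Grid dimensions are chosen so the actual spacing is <= ``spacing`` along
    every axis.  The k=0 mode is excluded, so the grid mean is exactly zero
    and net charge is neutralized by a uniform background.
    """
    if spacing <= 0 or beta <= 0:
        raise ValueError("spacing and beta must be positive")
    if spacing > 1.0 / (2.0 * beta):
        warnings.warn(
            f"grid spacing {spacing} nm is coarse for beta={beta}/nm; "
            "the smeared Gaussian may be under-resolved",
            stacklevel=2,
        )
    box = config.box
    lengths = np.linalg.norm(box, axis=1)
    K = tuple(int(math.ceil(L / spacing)) for L in lengths)
    inv = np.linalg.inv(box)
    frac = (config.positions @ inv) % 1.0
    Q = _spread_charges(frac, config.charges, K)
    k2, mgrid = _k_vectors(box, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.exp(-k2 / (4.0 * beta * beta)) / k2
    G[0, 0, 0] = 0.0
    B = (
        _b_factor(K[0])[mgrid[0].astype(int) % K[0]]
        * _b_factor(K[1])[mgrid[1].astype(int) % K[1]]
        * _b_factor(K[2])[mgrid[2].astype(int) % K[2]]
    )
    V = float(np.linalg.det(box))
    prefac = COULOMB_KJ_MOL_NM_E2 * 4.0 * np.pi / V
    S = np.conj(np.fft.fftn(Q)) * B  # SPME approximation to the structure factor
    phi = np.real(np.fft.fftn(prefac * G * S))
    phi /= KB_KJ_MOL_K * temperature  # kJ/mol/e -> kT/e
    return SmoothedPotentialField(
        values=phi,
        box=box,
        spacing=tuple(L / k for L, k in zip(lengths, K)),
        ewald_beta=beta,
        temperature=temperature,
        metadata={
            "component": "reciprocal (smoothed) PME potential only",
            "short_range_terms": "omitted",
            "k0_mode": "excluded (uniform neutralizing background)",
            "spline_order": _SPLINE_ORDER,
        },
    )


def potential_at_points(field: SmoothedPotentialField, points: np.ndarray) -> np.ndarray:
    """Periodic tricubic B-spline interpolation of the grid at the points.

    Exactly reproduces grid values at grid nodes.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(field.box)
    frac = (pts @ inv) % 1.0
    coords = (frac * np.array(field.grid_shape)[None, :]).T
    return map_coordinates(field.values, coords, order=3, mode="grid-wrap", prefilter=True)


def direct_reciprocal_sum(
    config: ChargeConfiguration,
    points: np.ndarray,
    beta: float = 2.5,
    temperature: float = 310.15,
    tol: float = 1e-10,
) -> np.ndarray:
    """Direct k-space Ewald sum of the reciprocal potential at the points.

    Reference evaluator: exact up to the k-vector truncation, chosen so the
    smallest retained Gaussian factor is below ``tol``.  O(n_k * n_points);
    use on small systems only.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    box = config.box
    k_cut = 2.0 * beta * math.sqrt(-math.log(tol))
    lengths = np.linalg.norm(box, axis=1)
    mmax = [int(math.ceil(k_cut * L / (2 * np.pi))) for L in lengths]
    ms = [np.arange(-m, m + 1) for m in mmax]
    recip = 2 * np.pi * np.linalg.inv(box).T
    m1, m2, m3 = np.meshgrid(*ms, indexing="ij")
    M = np.stack([m1.ravel(), m2.ravel(), m3.ravel()], axis=1)
    M = M[np.any(M != 0, axis=1)]
    kvec = M @ recip
    k2 = np.einsum("ij,ij->i", kvec, kvec)
    keep = k2 <= k_cut * k_cut
    kvec, k2 = kvec[keep], k2[keep]
    G = np.exp(-k2 / (4 * beta * beta)) / k2
    nz = config.charges != 0.0  # zero charges contribute nothing to S(k)
    S = (config.charges[None, nz] * np.exp(1j * (kvec @ config.positions[nz].T))).sum(axis=1)
    V = float(np.linalg.det(box))
    prefac = COULOMB_KJ_MOL_NM_E2 * 4.0 * np.pi / V
    out = np.empty(len(pts))
    chunk = 256
    for i in range(0, len(pts), chunk):
        phase = np.exp(-1j * (pts[i : i + chunk] @ kvec.T))  # (n_pts, n_k)
        out[i : i + chunk] = prefac * np.real(phase @ (G * S))
    return out / (KB_KJ_MOL_K * temperature)


def kT_per_e_to_volts(x: float | np.ndarray, temperature: float = 310.15) -> float | np.ndarray:
    """Convert a potential from kT/e to volts at the given temperature."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return x * _const.k * temperature / _const.e


# ---------------------------------------------------------------------------
# wire-averaged profiles
# ---------------------------------------------------------------------------

def wire_potential_profile(
    traj: Trajectory,
    wires: list,
    config: PotentialConfig | None = None,
) -> WirePotentialProfile:
    """Average the reciprocal potential at wire-node oxygens over wires.

    Every ``stride``-th wire-containing frame is analyzed: the field of that
    frame's charges is evaluated at the wire's node positions, a per-frame
    bulk-water reference (mean potential over bulk oxygens) is subtracted,
    and values are binned by z - COM_z.  Per-wire maxima are also collected.
    """
    config = PotentialConfig() if config is None else config
    system = traj.system
    formed = [w for w in wires if w.path and math.isfinite(w.max_gap)]
    picked = formed[:: config.stride]
    if not picked:
        raise ValueError("no wire-containing frames after striding")
    water_ox = system.water_oxygen_indices()
    z_samples: list[np.ndarray] = []
    v_samples: list[np.ndarray] = []
    maxima: list[float] = []
    for wire in picked:
        frame = traj.frames[wire.frame_index]
        com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)
        fld = reciprocal_potential_field(
            ChargeConfiguration(frame.coordinates, system.charges, frame.box),
            spacing=config.spacing,
            beta=config.beta,
            temperature=config.temperature,
        )
        bulk = water_ox[np.abs(frame.coordinates[water_ox, 2] - com[2]) >= config.bulk_z]
        if len(bulk) == 0:
            raise ValueError(f"frame {wire.frame_index}: no bulk waters for the reference")
        ref = float(potential_at_points(fld, frame.coordinates[bulk]).mean())
        nodes = np.asarray(wire.path, dtype=int)
        vals = potential_at_points(fld, frame.coordinates[nodes]) - ref
        z_samples.append(frame.coordinates[nodes, 2] - com[2])
        v_samples.append(vals)
        maxima.append(float(vals.max()))
    z_all = np.concatenate(z_samples)
    v_all = np.concatenate(v_samples)
    lo = math.floor(z_all.min() / config.bin_width) * config.bin_width
    hi = math.ceil(z_all.max() / config.bin_width) * config.bin_width
    edges = np.arange(lo, hi + config.bin_width * 0.5, config.bin_width)
    which = np.clip(np.digitize(z_all, edges) - 1, 0, len(edges) - 2)
    mean = np.full(len(edges) - 1, np.nan)
    n = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        sel = which == b
        n[b] = sel.sum()
        if n[b]:
            mean[b] = v_all[sel].mean()
    maxima_arr = np.array(maxima)
    return WirePotentialProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_kT_e=mean,
        n_samples=n,
        per_wire_maxima=maxima_arr,
        maxima_mean=float(maxima_arr.mean()),
        maxima_sd=float(maxima_arr.std()),
        temperature=config.temperature,
    )
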