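"""Periodic geometry primitives: minimum-image displacements and distances,
mass-weighted centers, and in-plane (membrane-lateral) distances.

All routines accept orthorhombic or GROMACS-reduced triclinic boxes.  For
triclinic cells the minimum image is found by rounding fractional
coordinates and then searching the 27 neighbouring images, which is exact
for lattice-reduced cells.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "is_orthorhombic",
    "minimum_image_displacement",
    "minimum_image_distance",
    "center_of_mass",
    "lateral_distance",
    "lateral_displacement",
    "pairwise_minimum_image_distances",
    "make_whole",
]

_SHIFTS_3D = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)
_SHIFTS_2D = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)


def _validate_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape == (3,):
        box = np.diag(box)
    if box.shape != (3, 3):
        raise ValueError("box must be a 3x3 lattice-vector matrix")
    if np.linalg.det(box) <= 0:
        raise ValueError("degenerate box: determinant must be > 0")
    return box


def is_orthorhombic(box: np.ndarray) -> bool:
    box = np.asarray(box, dtype=float)
    if box.shape == (3,):
        return True
    off = box - np.diag(np.diag(box))
    return bool(np.all(np.abs(off) < 1e-12))


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest periodic-image displacement vector(s) from ``b`` to ``a``.

    ``a`` and ``b`` broadcast against each other; the result has the
    broadcast shape with a trailing axis of length 3.
    """
    box = _validate_box(box)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if is_orthorhombic(box):
        lengths = np.diag(box)
        return d - lengths * np.round(d / lengths)
    inv = np.linalg.inv(box)
    frac = d @ inv
    frac -= np.round(frac)
    base = frac @ box
    # exact minimum over the 27 neighbouring images (reduced cells)
    cand = base[..., None, :] + _SHIFTS_3D @ box  # (..., 27, 3)
    norms = np.einsum("...ij,...ij->...i", cand, cand)
    idx = np.argmin(norms, axis=-1)
    return np.take_along_axis(cand, idx[..., None, None], axis=-2)[..., 0, :]


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


def lateral_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement restricted to the membrane (xy) plane.

    Assumes the membrane normal is the z lattice axis, with the a and b
    lattice vectors lying in the xy plane (GROMACS-reduced convention).
    """
    box = _validate_box(box)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = (a - b)[..., :2]
    box2 = box[:2, :2]
    if abs(box[1, 0]) < 1e-12:  # rectangular in-plane lattice
        lengths = np.diag(box2)
        return d - lengths * np.round(d / lengths)
    inv = np.linalg.inv(box2)
    frac = d @ inv
    frac -= np.round(frac)
    base = frac @ box2
    cand = base[..., None, :] + _SHIFTS_2D @ box2
    norms = np.einsum("...ij,...ij->...i", cand, cand)
    idx = np.argmin(norms, axis=-1)
    return np.take_along_axis(cand, idx[..., None, None], axis=-2)[..., 0, :]


def lateral_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """In-plane (x,y) minimum-image distance, used for membrane-lateral radii."""
    return np.linalg.norm(lateral_displacement(a, b, box), axis=-1)


def center_of_mass(selection: np.ndarray, coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms.

    The selection is assumed whole (unwrapped within one periodic image); run
    :func:`make_whole` first if molecules may be split across the boundary.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("center_of_mass of an empty selection is undefined")
    m = np.asarray(masses, dtype=float)[sel]
    x = np.asarray(coordinates, dtype=float)[sel]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def pairwise_minimum_image_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Dense (len(a), len(b)) matrix of minimum-image distances."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return minimum_image_distance(a[:, None, :], b[None, :, :], box)


def make_whole(coordinates: np.ndarray, box: np.ndarray, molecule_ids: np.ndarray) -> np.ndarray:
    """Unwrap each molecule so consecutive atoms sit in the same image.

    Atoms within a molecule are assumed ordered along its connectivity (true
    for the file formats and generators used here); the first atom anchors
    the molecule and each subsequent atom is placed at its minimum-image
    position relative to the previous one.
    """
    coords = np.array(coordinates, dtype=float, copy=True)
    mol = np.asarray(molecule_ids)
    # boundaries where molecule id changes
    starts = np.flatnonzero(np.r_[True, mol[1:] != mol[:-1]])
    ends = np.r_[starts[1:], len(mol)]
    for s, e in zip(starts, ends):
        for i in range(s + 1, e):
            coords[i] = coords[i - 1] + minimum_image_displacement(
                coords[i], coords[i - 1], box
            )
    return coords
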