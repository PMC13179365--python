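"""Optimal rigid-body superposition (Kabsch) and RMSD between structures.

Atoms are paired by (residue number, atom name) over a selectable atom-name
set, so structures with different residue content are compared over their
common ordered subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError
from .frames import Frame


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation (det = +1)
    translation: np.ndarray  # (3,), applied after rotation
    rmsd: float  # A over the matched set
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of *mobile* onto *reference* (paired rows).

    Returns (rotation, translation, rmsd); a proper rotation is enforced by
    flipping the sign of the smallest singular direction when the optimal
    orthogonal transform would be a reflection.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DataError("coordinate arrays must be matching (n, 3)")
    if mobile.shape[0] < 3:
        raise DataError("need at least 3 paired atoms for superposition")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    x = mobile - mob_center
    y = reference - ref_center
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_center - rotation @ mob_center
    moved = x @ rotation.T + ref_center
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def kabsch_superpose(
    reference: Frame,
    mobile: Frame,
    atom_names: tuple[str, ...] = ("CA",),
) -> SuperpositionResult:
    """Superpose *mobile* onto *reference* over matched atoms.

    Atoms are paired by residue number and atom name over ``atom_names``
    (default Calpha only), in the reference's residue order.
    """
    names = set(atom_names)
    ref_keys = [
        (rn, an)
        for rn, an in zip(reference.resnums.tolist(), reference.atom_names.tolist())
        if an in names
    ]
    pairs = [key for key in ref_keys if mobile.has_atom(*key)]
    if len(pairs) < 3:
        raise DataError(f"only {len(pairs)} matched atoms; need at least 3")
    ref_xyz = np.array([reference.atom(*k) for k in pairs])
    mob_xyz = np.array([mobile.atom(*k) for k in pairs])
    rotation, translation, rmsd = kabsch(mob_xyz, ref_xyz)
    return SuperpositionResult(rotation, translation, rmsd, len(pairs))
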