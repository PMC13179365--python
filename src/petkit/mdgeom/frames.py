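"""Flat atom-table representation of a single trajectory frame."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DataError


@dataclass
class Frame:
    """One frame: parallel arrays of residue/atom labels and coordinates (A).

    ``(residue number, atom name)`` pairs must be unique within a frame and
    are the selection keys used throughout the geometry code. ``box`` holds
    orthorhombic box lengths (3-vector, A) when periodic analyses apply.
    """

    resnums: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray  # (n_atoms, 3)
    index: int = 0
    box: np.ndarray | None = None
    _lookup: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.resnums.size
        if not (self.resnames.size == n and self.atom_names.size == n):
            raise DataError("label arrays differ in length")
        if self.coords.shape != (n, 3):
            raise DataError(f"coords must have shape ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise DataError("box must be a positive 3-vector of lengths")
        keys = list(zip(self.resnums.tolist(), self.atom_names.tolist()))
        if len(set(keys)) != n:
            raise DataError("(residue number, atom name) pairs must be unique")
        self._lookup = {k: i for i, k in enumerate(keys)}

    @property
    def n_atoms(self) -> int:
        return self.resnums.size

    def has_atom(self, resnum: int, atom_name: str) -> bool:
        return (resnum, atom_name) in self._lookup

    def atom(self, resnum: int, atom_name: str) -> np.ndarray:
        """Coordinates of one atom addressed by (residue number, atom name)."""
        try:
            return self.coords[self._lookup[(resnum, atom_name)]]
        except KeyError:
            raise DataError(f"atom {atom_name!r} of residue {resnum} not in frame") from None

    def select(self, resnum: int | None = None, atom_names=None) -> np.ndarray:
        """Boolean mask over atoms by residue number and/or atom-name set."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resnum is not None:
            mask &= self.resnums == resnum
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([a in names for a in self.atom_names])
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """A copy with coordinates rigidly moved: x -> R x + t."""
        return Frame(
            self.resnums.copy(),
            self.resnames.copy(),
            self.atom_names.copy(),
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
            index=self.index,
            box=None if self.box is None else self.box.copy(),
        )
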