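"""Catalytic-state classification of enzyme-substrate frames.

Frames are labeled by two distances: the nucleophile-to-electrophile
distance between the catalytic serine OG and the attacked ester carbonyl
carbon, and the oxyanion-hole distance between the backbone N of the
residue following the serine and the carbonyl oxygen. A frame is

* ``in_oxyanion``      if N-O < 5.0 A (pre-reactive, carbonyl in the hole);
* ``near_active_site`` if OG-C < 5.5 A and 5.0 <= N-O < 7.5 A (bound but
  not pre-reactive);
* ``other``            otherwise.

Bounds are strict on the upper end and inclusive on the lower, so the two
bound states are disjoint; a tie at exactly 5.0 A is near_active_site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ..errors import DataError
from .frames import Frame

STATE_IN_OXYANION = "in_oxyanion"
STATE_NEAR_ACTIVE_SITE = "near_active_site"
STATE_OTHER = "other"
STATES = (STATE_IN_OXYANION, STATE_NEAR_ACTIVE_SITE, STATE_OTHER)


@dataclass(frozen=True)
class AtomSelectionMap:
    """(residue number, atom name) selectors for the classification atoms.

    Defaults follow the catalytic numbering of the parent hydrolase
    (Ser131 OG nucleophile, Met132 backbone N oxyanion donor) and a
    substrate residue 500 whose attacked ester carbonyl is C1=O1; the
    substrate atom names are an assumption and fully configurable.
    """

    ser_og: tuple[int, str] = (131, "OG")
    oxyanion_n: tuple[int, str] = (132, "N")
    carbonyl_c: tuple[int, str] = (500, "C1")
    carbonyl_o: tuple[int, str] = (500, "O1")


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance thresholds (A) defining the catalytic sub-states."""

    d_ser_carbonyl_max: float = 5.5
    d_oxyanion_in: float = 5.0
    d_oxyanion_near: tuple[float, float] = (5.0, 7.5)
    salt_bridge_cutoff: float = 4.0
    triad_ser_his_max: float = 3.5
    triad_his_asp_max: float = 3.5

    def __post_init__(self) -> None:
        cutoffs = (
            self.d_ser_carbonyl_max,
            self.d_oxyanion_in,
            *self.d_oxyanion_near,
            self.salt_bridge_cutoff,
            self.triad_ser_his_max,
            self.triad_his_asp_max,
        )
        if any(c <= 0 for c in cutoffs):
            raise DataError("all distance cutoffs must be positive")
        lo, hi = self.d_oxyanion_near
        if lo >= hi:
            raise DataError("near-range lower bound must be below its upper bound")
        if lo != self.d_oxyanion_in:
            raise DataError(
                "near-range lower bound must equal the in-state upper bound "
                "(states must be disjoint)"
            )


@dataclass
class StateFractions:
    """Per-trajectory occupancy vector over the three states."""

    in_oxyanion: float
    near_active_site: float
    other: float
    n_frames: int

    def __post_init__(self) -> None:
        total = self.in_oxyanion + self.near_active_site + self.other
        if not np.isclose(total, 1.0):
            raise DataError(f"state fractions must sum to 1, got {total}")


def classify_frame(
    frame: Frame,
    criteria: GeometricCriteria | None = None,
    selection: AtomSelectionMap | None = None,
) -> str:
    """Deterministic state label of one frame (see module docstring)."""
    criteria = criteria or GeometricCriteria()
    selection = selection or AtomSelectionMap()
    for name, (resnum, atom) in (
        ("ser_og", selection.ser_og),
        ("oxyanion_n", selection.oxyanion_n),
        ("carbonyl_c", selection.carbonyl_c),
        ("carbonyl_o", selection.carbonyl_o),
    ):
        if not frame.has_atom(resnum, atom):
            raise DataError(f"selector {name}=({resnum}, {atom!r}) matches no atom in frame")

    d_no = float(
        np.linalg.norm(frame.atom(*selection.oxyanion_n) - frame.atom(*selection.carbonyl_o))
    )
    d_ogc = float(
        np.linalg.norm(frame.atom(*selection.ser_og) - frame.atom(*selection.carbonyl_c))
    )
    if d_no < criteria.d_oxyanion_in:
        return STATE_IN_OXYANION
    lo, hi = criteria.d_oxyanion_near
    if d_ogc < criteria.d_ser_carbonyl_max and lo <= d_no < hi:
        return STATE_NEAR_ACTIVE_SITE
    return STATE_OTHER


def state_fractions(
    trajectory: list[Frame],
    criteria: GeometricCriteria | None = None,
    selection: AtomSelectionMap | None = None,
) -> StateFractions:
    """Occupancy of each state over a trajectory (counts / n_frames)."""
    if not trajectory:
        raise DataError("empty trajectory")
    counts = Counter(classify_frame(f, criteria, selection) for f in trajectory)
    n = len(trajectory)
    return StateFractions(
        in_oxyanion=counts[STATE_IN_OXYANION] / n,
        near_active_site=counts[STATE_NEAR_ACTIVE_SITE] / n,
        other=counts[STATE_OTHER] / n,
        n_frames=n,
    )


#: Side-chain nitrogen / carboxylate oxygen names used for salt bridges.
BASIC_SIDECHAIN_N = ("NZ", "NH1", "NH2", "NE", "ND1", "NE2")
ACIDIC_SIDECHAIN_O = ("OD1", "OD2", "OE1", "OE2")


def min_n_o_distance(frame: Frame, basic_resnum: int, acidic_resnum: int) -> float:
    """Minimum side-chain N-O distance between a basic and an acidic residue."""
    n_mask = frame.select(basic_resnum, BASIC_SIDECHAIN_N)
    o_mask = frame.select(acidic_resnum, ACIDIC_SIDECHAIN_O)
    if not n_mask.any():
        raise DataError(f"residue {basic_resnum} has no side-chain nitrogen atoms")
    if not o_mask.any():
        raise DataError(f"residue {acidic_resnum} has no carboxylate oxygen atoms")
    n_xyz = frame.coords[n_mask]
    o_xyz = frame.coords[o_mask]
    diffs = n_xyz[:, None, :] - o_xyz[None, :, :]
    return float(np.sqrt((diffs**2).sum(axis=-1)).min())


def salt_bridge_occupancy(
    trajectory: list[Frame],
    basic_resnum: int,
    acidic_resnum: int,
    cutoff: float = 4.0,
) -> float:
    """Fraction of frames whose minimum side-chain N-O distance is <= cutoff."""
    if not trajectory:
        raise DataError("empty trajectory")
    if cutoff <= 0:
        raise DataError("cutoff must be positive")
    hits = sum(
        min_n_o_distance(f, basic_resnum, acidic_resnum) <= cutoff for f in trajectory
    )
    return hits / len(trajectory)


def triad_competent(
    frame: Frame,
    criteria: GeometricCriteria | None = None,
    ser_resnum: int = 131,
    his_resnum: int = 209,
    asp_resnum: int = 177,
) -> bool:
    """Whether the Ser/His/Asp triad is in a catalytically competent layout.

    Artifact definition: simultaneous Ser OG-His NE2 and His ND1-Asp
    carboxylate-O distance criteria (defaults 3.5 A each).
    """
    criteria = criteria or GeometricCriteria()
    d_ser_his = float(
        np.linalg.norm(frame.atom(ser_resnum, "OG") - frame.atom(his_resnum, "NE2"))
    )
    o_mask = frame.select(asp_resnum, ("OD1", "OD2"))
    if not o_mask.any():
        raise DataError(f"residue {asp_resnum} has no carboxylate oxygens")
    nd1 = frame.atom(his_resnum, "ND1")
    d_his_asp = float(np.sqrt(((frame.coords[o_mask] - nd1) ** 2).sum(axis=1)).min())
    return d_ser_his <= criteria.triad_ser_his_max and d_his_asp <= criteria.triad_his_asp_max
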