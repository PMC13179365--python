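"""Elementary geometric measures on frames: distances, angles, dihedrals,
backbone torsions, and hydrogen-bond geometry including the out-of-plane
angle of an acceptor's amide plane."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError
from .frames import Frame


def distance(p1, p2) -> float:
    return float(np.linalg.norm(np.asarray(p2, float) - np.asarray(p1, float)))


def angle(p1, p2, p3) -> float:
    """Angle at p2 in degrees, in [0, 180]."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DataError("coincident points give an undefined angle")
    cos = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise DataError("degenerate (collinear) points give an undefined dihedral")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def phi_psi(trajectory_frame: Frame, resnum: int) -> tuple[float, float]:
    """Backbone (phi, psi) of a residue; needs C(i-1) and N(i+1) neighbors."""
    f = trajectory_frame
    for key, (rn, an) in {
        "C of preceding residue": (resnum - 1, "C"),
        "backbone N": (resnum, "N"),
        "backbone CA": (resnum, "CA"),
        "backbone C": (resnum, "C"),
        "N of following residue": (resnum + 1, "N"),
    }.items():
        if not f.has_atom(rn, an):
            raise DataError(f"cannot compute phi/psi of residue {resnum}: missing {key}")
    phi = dihedral(f.atom(resnum - 1, "C"), f.atom(resnum, "N"), f.atom(resnum, "CA"), f.atom(resnum, "C"))
    psi = dihedral(f.atom(resnum, "N"), f.atom(resnum, "CA"), f.atom(resnum, "C"), f.atom(resnum + 1, "N"))
    return phi, psi


@dataclass(frozen=True)
class HBondGeometry:
    """Distance (H...acceptor, A), angle at H (donor-H...acceptor, deg), and
    the signed out-of-plane angle (deg) of H relative to the acceptor's
    amide N-C=O plane."""

    distance: float
    angle: float
    out_of_plane: float


def hbond_geometry(donor, hydrogen, acceptor, plane_atoms) -> HBondGeometry:
    """H-bond geometry with an amide-plane out-of-plane angle.

    ``plane_atoms`` are three non-collinear points defining the acceptor
    group's plane (e.g. amide N, C, O). The out-of-plane angle is 90 deg
    minus the angle between the plane normal and the acceptor->H direction;
    its sign follows the normal's orientation (H on the normal side gives a
    positive angle).
    """
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    a, b, c = (np.asarray(p, float) for p in plane_atoms)
    normal = np.cross(b - a, c - a)
    norm = np.linalg.norm(normal)
    if norm < 1e-10:
        raise DataError("plane atoms are collinear; plane undefined")
    normal = normal / norm

    direction = hydrogen - acceptor
    dn = np.linalg.norm(direction)
    if dn == 0:
        raise DataError("hydrogen and acceptor coincide")
    cos = np.clip(np.dot(direction / dn, normal), -1.0, 1.0)
    out_of_plane = 90.0 - float(np.degrees(np.arccos(cos)))
    return HBondGeometry(
        distance=distance(hydrogen, acceptor),
        angle=angle(donor, hydrogen, acceptor),
        out_of_plane=out_of_plane,
    )
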