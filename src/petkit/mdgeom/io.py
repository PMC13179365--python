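"""Trajectory I/O: multi-model PDB (via Biopython) and a per-frame CSV dialect.

The CSV dialect is long-format with columns
``frame,resnum,resname,atom,x,y,z`` plus optional ``box_x,box_y,box_z``
(constant within a frame); it survives text-only round trips and carries
box dimensions, which the PDB path does not.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from ..errors import DataError
from .frames import Frame


def read_multimodel_pdb(path) -> list[Frame]:
    """Read a (possibly multi-MODEL) PDB file into a list of frames."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("traj", str(path))
    frames: list[Frame] = []
    for model in structure:
        resnums, resnames, atom_names, coords = [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    resnums.append(residue.id[1])
                    resnames.append(residue.resname.strip())
                    atom_names.append(atom.get_name())
                    coords.append(atom.coord)
        if not resnums:
            continue
        frames.append(
            Frame(
                np.array(resnums),
                np.array(resnames, dtype=object),
                np.array(atom_names, dtype=object),
                np.array(coords, dtype=float),
                index=model.id,
            )
        )
    if not frames:
        raise DataError(f"no atoms found in {path}")
    return frames


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_multimodel_pdb(frames: list[Frame], path) -> None:
    """Write frames as MODEL/ENDMDL blocks (box dimensions are not stored)."""
    if not frames:
        raise DataError("no frames to write")
    builder = StructureBuilder()
    builder.init_structure("traj")
    for i, frame in enumerate(frames):
        builder.init_model(i)
        builder.init_chain("A")
        builder.init_seg(" ")
        current_res = None
        serial = 1
        for resnum, resname, name, xyz in zip(
            frame.resnums, frame.resnames, frame.atom_names, frame.coords
        ):
            if current_res != resnum:
                builder.init_residue(str(resname)[:3], " ", int(resnum), " ")
                current_res = resnum
            builder.init_atom(
                str(name),
                np.asarray(xyz, dtype=float),
                0.0,
                1.0,
                " ",
                str(name).center(4)[:4],
                serial,
                element=_element_of(str(name)),
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_xyz_csv(path) -> list[Frame]:
    """Read the long-format per-frame CSV dialect."""
    df = pd.read_csv(path)
    required = {"frame", "resnum", "resname", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise DataError(f"trajectory CSV must have columns {sorted(required)}")
    has_box = {"box_x", "box_y", "box_z"}.issubset(df.columns)
    frames = []
    for idx, group in df.groupby("frame", sort=True):
        box = None
        if has_box and not group[["box_x", "box_y", "box_z"]].isna().any().any():
            box = group[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(dtype=float)
        frames.append(
            Frame(
                group["resnum"].to_numpy(dtype=int),
                group["resname"].to_numpy(dtype=object),
                group["atom"].to_numpy(dtype=object),
                group[["x", "y", "z"]].to_numpy(dtype=float),
                index=int(idx),
                box=box,
            )
        )
    if not frames:
        raise DataError(f"no frames found in {path}")
    return frames


def write_xyz_csv(frames: list[Frame], path) -> None:
    if not frames:
        raise DataError("no frames to write")
    parts = []
    for frame in frames:
        part = pd.DataFrame(
            {
                "frame": frame.index,
                "resnum": frame.resnums,
                "resname": frame.resnames,
                "atom": frame.atom_names,
                "x": frame.coords[:, 0],
                "y": frame.coords[:, 1],
                "z": frame.coords[:, 2],
            }
        )
        if frame.box is not None:
            part["box_x"], part["box_y"], part["box_z"] = frame.box
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
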