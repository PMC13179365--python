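"""Radial distribution function of water oxygens around a reference site."""

from __future__ import annotations

import numpy as np

from ..errors import DataError
from .frames import Frame


def _site_water_distances(frame: Frame, site: tuple[int, str], water_mask: np.ndarray) -> np.ndarray:
    ref = frame.atom(*site)
    diffs = frame.coords[water_mask] - ref
    if frame.box is not None:
        diffs -= frame.box * np.round(diffs / frame.box)  # minimum image, orthorhombic
    return np.sqrt((diffs**2).sum(axis=1))


def water_rdf(
    frames: list[Frame],
    site: tuple[int, str],
    water_atom_name: str = "OW",
    r_max: float = 10.0,
    n_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """g(r) of water oxygens around one reference site, averaged over frames.

    With periodic frames (``frame.box`` set) the histogram is normalized by
    the ideal-gas shell count at the box's water number density. Without a
    box, an open-boundary mode normalizes by shell volume and the mean
    density over the sampled range.

    Returns ``(bin_centers, g)``.
    """
    if not frames:
        raise DataError("no frames given")
    if r_max <= 0 or n_bins < 2:
        raise DataError("need positive r_max and at least 2 bins")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    hist = np.zeros(n_bins)
    density_sum = 0.0
    for frame in frames:
        water_mask = frame.select(atom_names=(water_atom_name,))
        n_w = int(water_mask.sum())
        if n_w == 0:
            raise DataError(f"frame {frame.index}: no atoms named {water_atom_name!r}")
        d = _site_water_distances(frame, site, water_mask)
        hist += np.histogram(d, bins=edges)[0]
        if frame.box is not None:
            density_sum += n_w / float(np.prod(frame.box))

    n_frames = len(frames)
    if density_sum > 0:
        rho = density_sum / n_frames
    else:
        # open boundary: mean density of the waters inside the sampled sphere
        rho = (hist.sum() / n_frames) / (4.0 / 3.0 * np.pi * r_max**3)
    expected = rho * shell_volumes * n_frames
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, hist / expected, 0.0)
    return centers, g
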