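"""Seeded generators for every input the analysis modules consume.

Each generator takes an explicit integer seed (or ``numpy`` Generator) and
is bit-reproducible for a fixed configuration; no global random state is
touched. The generators reproduce the *statistical structure* the
estimators assume - they are not physical simulations.

Default noise magnitudes (1% multiplicative for impedance, 5% CV for
kinetic rates, 0.002 ratio units for melt curves) are artifact choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eis, thermal, titration
from .errors import DataError
from .kinetics import inverse_mm
from .mdgeom.frames import Frame
from .mdgeom.states import (
    STATE_IN_OXYANION,
    STATE_NEAR_ACTIVE_SITE,
    STATE_OTHER,
    AtomSelectionMap,
    GeometricCriteria,
    classify_frame,
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# impedance spectroscopy


def gen_eis_timeseries(
    rate_um_per_h: float = 21.0,
    d0_um: float = 225.0,
    duration_h: float = 20.0,
    sample_interval_min: float = 3.0,
    n_frequencies: int = 51,
    f_min_hz: float = 1e3,
    f_max_hz: float = 1e6,
    circuit: eis.RandlesParams | None = None,
    geometry: eis.FilmGeometry | None = None,
    noise: float = 0.01,
    min_thickness_um: float = 1.0,
    seed=0,
) -> list[eis.ImpedanceSpectrum]:
    """Impedance sweeps of a film thinning linearly at ``rate_um_per_h``.

    The film thickness follows ``d(t) = d0 - rate*t`` floored at
    ``min_thickness_um``; capacitance follows the parallel-plate law and
    spectra the Randles model with the given R_s/R_ct. Noise is
    multiplicative Gaussian applied independently to real and imaginary
    parts.
    """
    if rate_um_per_h < 0:
        raise DataError("degradation rate must be non-negative")
    if noise < 0:
        raise DataError("noise level must be non-negative")
    rng = _rng(seed)
    geometry = geometry or eis.FilmGeometry()
    base = circuit or eis.RandlesParams(R_s=100.0, R_ct=1e6, C_film=1e-12)
    freqs = np.logspace(np.log10(f_min_hz), np.log10(f_max_hz), n_frequencies)
    times = np.arange(0.0, duration_h + 1e-9, sample_interval_min / 60.0)

    spectra = []
    for t in times:
        d = max(d0_um - rate_um_per_h * t, min_thickness_um)
        c = float(eis.thickness_to_capacitance(d, geometry))
        z = eis.randles_impedance(eis.RandlesParams(base.R_s, base.R_ct, c), freqs)
        if noise > 0:
            z = z.real * (1.0 + noise * rng.standard_normal(z.size)) + 1j * z.imag * (
                1.0 + noise * rng.standard_normal(z.size)
            )
        spectra.append(eis.ImpedanceSpectrum(float(t), freqs, z))
    return spectra


# ---------------------------------------------------------------------------
# inverse Michaelis-Menten kinetics

DEFAULT_ENZYME_GRID_UM = np.array([0.0, 0.025, 0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 0.6])


def gen_kinetics(
    inv_vmax: float,
    inv_km: float,
    enzyme_grid_um=None,
    cv: float = 0.05,
    n_replicates: int = 2,
    seed=0,
) -> pd.DataFrame:
    """Duplicate rate-vs-[E] datasets obeying the inverse MM law.

    Multiplicative Gaussian noise with coefficient of variation ``cv`` is
    applied to the model rates; the zero-enzyme anchor stays exactly zero.
    """
    if cv < 0:
        raise DataError("CV must be non-negative")
    rng = _rng(seed)
    grid = DEFAULT_ENZYME_GRID_UM if enzyme_grid_um is None else np.asarray(enzyme_grid_um, float)
    rows = []
    for rep in range(1, n_replicates + 1):
        v = inverse_mm(grid, inv_vmax, inv_km)
        if cv > 0:
            v = v * (1.0 + cv * rng.standard_normal(grid.size))
        v = np.where(grid == 0, 0.0, v)
        rows.append(pd.DataFrame({"enzyme_um": grid, "rate_nmol_g_s": v, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# thermal unfolding


def gen_melt(
    tm_c: float,
    dh_vh_kj_mol: float = 400.0,
    folded: thermal.Baseline | None = None,
    unfolded: thermal.Baseline | None = None,
    noise_sd: float = 0.002,
    ramp_c: tuple[float, float] = thermal.DEFAULT_RAMP_C,
    step_c: float = thermal.DEFAULT_STEP_C,
    seed=0,
) -> thermal.MeltCurve:
    """Two-state ratio melt curve on the given ramp (default 20-95 degC)."""
    model = thermal.TwoStateMeltModel(
        tm_c=tm_c,
        dh_vh_kj_mol=dh_vh_kj_mol,
        folded=folded or thermal.Baseline(0.8),
        unfolded=unfolded or thermal.Baseline(1.1),
        noise_sd=noise_sd,
    )
    return thermal.simulate_melt(model, thermal.default_grid(ramp_c, step_c), _rng(seed))


# ---------------------------------------------------------------------------
# pH-stat titration


def gen_titration(
    config: titration.ReactorConfig | None = None,
    target_percent: float = 90.0,
    target_time_h: float = 31.8,
    final_percent: float = 95.0,
    shape: float = 1.5,
    duration_h: float = 48.0,
    dt_h: float = 0.5,
    seed=0,
) -> titration.TitrationSeries:
    """Monotone NaOH consumption from a Weibull-saturation mass curve.

    The curve ``p(t) = p_inf * (1 - exp(-(t/tau)^shape))`` is calibrated so
    it crosses ``target_percent`` exactly at ``target_time_h``; the percent
    curve is converted to hydrolyzed mass and then to cumulative NaOH by the
    exact stoichiometric inverse. Deterministic by construction (the seed is
    accepted for interface symmetry).
    """
    del seed  # curve is deterministic; noise would break monotonicity
    config = config or titration.ReactorConfig()
    if not 0 < target_percent < final_percent:
        raise DataError("need 0 < target_percent < final_percent")
    tau = target_time_h / (-np.log(1.0 - target_percent / final_percent)) ** (1.0 / shape)
    times = np.arange(0.0, duration_h + 1e-9, dt_h)
    percent = final_percent * (1.0 - np.exp(-((times / tau) ** shape)))
    mass = percent / 100.0 * config.pet_mass_g
    naoh = titration.pet_mass_to_naoh(mass, config)
    return titration.TitrationSeries(times, naoh)


# ---------------------------------------------------------------------------
# trajectories and structures


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_trajectory(
    occupancies: dict[str, float],
    n_frames: int = 2000,
    criteria: GeometricCriteria | None = None,
    selection: AtomSelectionMap | None = None,
    seed=0,
) -> tuple[list[Frame], list[str]]:
    """Frames with prescribed catalytic-state occupancies.

    State labels are drawn i.i.d. with the given occupancies; atom
    coordinates are then sampled inside each state's defining distance
    region, and every emitted frame is verified to classify back to its
    label. Returns ``(frames, labels)``.
    """
    criteria = criteria or GeometricCriteria()
    selection = selection or AtomSelectionMap()
    states = list(occupancies)
    probs = np.array([occupancies[s] for s in states], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise DataError("occupancies must be non-negative and sum to 1")
    unknown = set(states) - {STATE_IN_OXYANION, STATE_NEAR_ACTIVE_SITE, STATE_OTHER}
    if unknown:
        raise DataError(f"unknown state labels: {sorted(unknown)}")
    rng = _rng(seed)
    labels = [states[i] for i in rng.choice(len(states), size=n_frames, p=probs)]

    og = np.array([0.0, 0.0, 0.0])
    n_bb = np.array([3.0, 0.0, 0.0])  # Ser OG to next-residue backbone N
    lo, hi = criteria.d_oxyanion_near
    frames = []
    for i, label in enumerate(labels):
        if label == STATE_IN_OXYANION:
            d_no = rng.uniform(2.5, criteria.d_oxyanion_in - 0.1)
            d_ogc = rng.uniform(2.5, criteria.d_ser_carbonyl_max + 2.0)
        elif label == STATE_NEAR_ACTIVE_SITE:
            d_no = rng.uniform(lo + 0.05, hi - 0.05)
            d_ogc = rng.uniform(2.5, criteria.d_ser_carbonyl_max - 0.1)
        else:
            d_no = rng.uniform(hi + 0.1, hi + 5.0)
            d_ogc = rng.uniform(criteria.d_ser_carbonyl_max + 0.5, criteria.d_ser_carbonyl_max + 6.0)
        u_c, u_o = _random_unit_vectors(rng, 2)
        carbonyl_c = og + d_ogc * u_c
        carbonyl_o = n_bb + d_no * u_o
        frame = Frame(
            resnums=np.array(
                [selection.ser_og[0], selection.oxyanion_n[0], selection.carbonyl_c[0], selection.carbonyl_o[0]]
            ),
            resnames=np.array(["SER", "MET", "MHE", "MHE"], dtype=object),
            atom_names=np.array(
                [selection.ser_og[1], selection.oxyanion_n[1], selection.carbonyl_c[1], selection.carbonyl_o[1]],
                dtype=object,
            ),
            coords=np.vstack([og, n_bb, carbonyl_c, carbonyl_o]),
            index=i,
        )
        assert classify_frame(frame, criteria, selection) == label
        frames.append(frame)
    return frames, labels


def gen_salt_bridge_trajectory(
    occupancy: float = 0.45,
    n_frames: int = 2000,
    cutoff: float = 4.0,
    basic_resnum: int = 148,
    acidic_resnum: int = 233,
    seed=0,
) -> tuple[list[Frame], np.ndarray]:
    """Lys/Asp frames whose minimum N-O distance is sub-cutoff with
    probability ``occupancy`` (i.i.d. per frame).

    Returns ``(frames, contact_flags)``.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise DataError("occupancy must be in [0, 1]")
    rng = _rng(seed)
    contacts = rng.random(n_frames) < occupancy
    frames = []
    for i, contact in enumerate(contacts):
        d = rng.uniform(2.6, cutoff - 0.05) if contact else rng.uniform(cutoff + 1.0, 9.0)
        direction = _random_unit_vectors(rng, 1)[0]
        nz = np.zeros(3)
        od1 = nz + d * direction
        od2 = od1 + 0.8 * direction  # strictly farther along the same ray
        frames.append(
            Frame(
                resnums=np.array([basic_resnum, acidic_resnum, acidic_resnum]),
                resnames=np.array(["LYS", "ASP", "ASP"], dtype=object),
                atom_names=np.array(["NZ", "OD1", "OD2"], dtype=object),
                coords=np.vstack([nz, od1, od2]),
                index=i,
            )
        )
    return frames, contacts


def gen_base_structure(n_residues: int = 50, seed=0) -> Frame:
    """A toy Calpha-trace structure (self-avoiding-ish random walk, 3.8 A steps)."""
    rng = _rng(seed)
    steps = _random_unit_vectors(rng, n_residues - 1) * 3.8
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    n = coords.shape[0]
    return Frame(
        resnums=np.arange(1, n + 1),
        resnames=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        coords=coords,
    )


def gen_perturbed_structure(
    base: Frame,
    jitter_sigma: float | None = None,
    target_rmsd: float | None = None,
    seed=0,
) -> tuple[Frame, float]:
    """A rigidly moved, jittered copy of *base* with known expected RMSD.

    Either ``jitter_sigma`` (per-coordinate Gaussian SD) or ``target_rmsd``
    (which sets sigma = rmsd/sqrt(3)) must be given. The copy is jittered
    first, then subjected to a random proper rotation and translation.
    Returns ``(perturbed, expected_rmsd)`` where expected_rmsd =
    sigma*sqrt(3).
    """
    if (jitter_sigma is None) == (target_rmsd is None):
        raise DataError("give exactly one of jitter_sigma or target_rmsd")
    sigma = jitter_sigma if jitter_sigma is not None else target_rmsd / np.sqrt(3.0)
    if sigma < 0:
        raise DataError("jitter must be non-negative")
    rng = _rng(seed)
    coords = base.coords + rng.normal(0.0, sigma, size=base.coords.shape)
    # random proper rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    translation = rng.uniform(-20.0, 20.0, size=3)
    frame = Frame(
        base.resnums.copy(),
        base.resnames.copy(),
        base.atom_names.copy(),
        coords @ q.T + translation,
        index=base.index,
    )
    return frame, float(sigma * np.sqrt(3.0))


def gen_water_box(
    n_waters: int = 5000,
    box: tuple[float, float, float] = (40.0, 40.0, 40.0),
    n_frames: int = 3,
    site_resnum: int = 115,
    seed=0,
) -> list[Frame]:
    """Frames of uniformly random water oxygens in a periodic box, with one
    reference site at the box center (ideal-gas control for the RDF)."""
    rng = _rng(seed)
    box_arr = np.asarray(box, dtype=float)
    frames = []
    for i in range(n_frames):
        waters = rng.uniform(0.0, 1.0, size=(n_waters, 3)) * box_arr
        coords = np.vstack([box_arr / 2.0, waters])
        frames.append(
            Frame(
                resnums=np.concatenate([[site_resnum], np.arange(1000, 1000 + n_waters)]),
                resnames=np.array(["THR"] + ["HOH"] * n_waters, dtype=object),
                atom_names=np.array(["OG1"] + ["OW"] * n_waters, dtype=object),
                coords=coords,
                index=i,
                box=box_arr,
            )
        )
    return frames
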