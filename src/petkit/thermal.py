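"""Two-state thermal unfolding: melt-curve simulation and Tm extraction.

Intrinsic-fluorescence melting experiments record the 350/330 nm emission
ratio on a temperature ramp (default 20-95 degC at 1 degC steps). The
synthetic model is a van't Hoff two-state transition with linear folded and
unfolded baselines; the extractor is the standard first-derivative-peak
estimator with 3-point quadratic interpolation, independent of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import R as GAS_CONSTANT_J

from .errors import DataError

DEFAULT_RAMP_C = (20.0, 95.0)
DEFAULT_STEP_C = 1.0


@dataclass(frozen=True)
class Baseline:
    """Linear signal baseline a + b*(T - Tref) in ratio units."""

    intercept: float
    slope: float = 0.0
    t_ref_c: float = 20.0

    def __call__(self, temp_c) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(temp_c, dtype=float) - self.t_ref_c)


@dataclass
class TwoStateMeltModel:
    tm_c: float
    dh_vh_kj_mol: float  # van't Hoff enthalpy
    folded: Baseline = field(default_factory=lambda: Baseline(0.8))
    unfolded: Baseline = field(default_factory=lambda: Baseline(1.1))
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dh_vh_kj_mol <= 0:
            raise DataError("van't Hoff enthalpy must be positive")
        if self.noise_sd < 0:
            raise DataError("noise SD must be non-negative")


@dataclass
class MeltCurve:
    temperatures_c: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperatures_c.size < 20:
            raise DataError("melt curve needs at least 20 points")
        if self.temperatures_c.size != self.ratio.size:
            raise DataError("temperature and ratio arrays differ in length")
        if np.any(np.diff(self.temperatures_c) <= 0):
            raise DataError("temperatures must be strictly increasing")


@dataclass
class TmResult:
    """Apparent Tm; ``is_upper_bound`` mirrors '>ramp max' reporting."""

    tm_c: float
    is_upper_bound: bool = False
    ambiguous: bool = False

    def __str__(self) -> str:
        if self.is_upper_bound:
            return f">{self.tm_c:.1f} °C"
        return f"{self.tm_c:.2f} °C"


def fraction_unfolded(temp_c, tm_c: float, dh_vh_kj_mol: float) -> np.ndarray:
    """Two-state van't Hoff unfolded fraction; temperatures in Celsius."""
    t_k = np.asarray(temp_c, dtype=float) + 273.15
    tm_k = tm_c + 273.15
    exponent = (dh_vh_kj_mol * 1e3 / GAS_CONSTANT_J) * (1.0 / t_k - 1.0 / tm_k)
    return 1.0 / (1.0 + np.exp(exponent))


def default_grid(
    ramp_c: tuple[float, float] = DEFAULT_RAMP_C, step_c: float = DEFAULT_STEP_C
) -> np.ndarray:
    lo, hi = ramp_c
    return np.arange(lo, hi + 0.5 * step_c, step_c)


def simulate_melt(
    model: TwoStateMeltModel,
    grid_c: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> MeltCurve:
    """Ratio curve: baseline mixture weighted by the unfolded fraction plus noise."""
    grid = default_grid() if grid_c is None else np.asarray(grid_c, dtype=float)
    if not grid.min() <= model.tm_c <= grid.max():
        raise DataError(
            f"Tm {model.tm_c} degC outside the ramp [{grid.min()}, {grid.max()}] degC"
        )
    f = fraction_unfolded(grid, model.tm_c, model.dh_vh_kj_mol)
    ratio = (1.0 - f) * model.folded(grid) + f * model.unfolded(grid)
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        ratio = ratio + rng.normal(0.0, model.noise_sd, size=grid.size)
    return MeltCurve(grid, ratio)


def extract_tm(
    curve: MeltCurve,
    smooth_window: int = 9,
    peak_half_width: int = 4,
    flat_tol: float = 1e-12,
) -> TmResult:
    """Apparent Tm as the first-derivative peak of the ratio signal.

    The ratio is lightly smoothed (Savitzky-Golay, quadratic, default
    9-point window), d(ratio)/dT is taken by central differences, and the
    peak is refined by a quadratic fit over ``peak_half_width`` grid points
    on each side of the discrete argmax. Smoothing and the parabola vertex
    are both affine-equivariant, so the estimate is invariant under affine
    transforms of the signal.

    A peak within one grid step of the ramp end is reported as a bound
    (``is_upper_bound=True``), mirroring the instrument's '>ramp max'
    convention. A flat curve (no peak) raises :class:`DataError`; multiple
    equal maxima return the first and set the ``ambiguous`` flag.
    """
    from scipy.signal import savgol_filter

    t, y = curve.temperatures_c, curve.ratio
    window = min(smooth_window, t.size if t.size % 2 else t.size - 1)
    deriv = np.gradient(savgol_filter(y, window, 2) if window >= 5 else y, t)
    if np.ptp(deriv) <= flat_tol:
        raise DataError("melt curve has no derivative peak (flat signal)")
    peak_value = deriv.max()
    peaks = np.nonzero(deriv == peak_value)[0]
    i = int(peaks[0])
    ambiguous = peaks.size > 1

    if t[i] >= t[-1] - (t[-1] - t[-2]):
        return TmResult(float(t[-1]), is_upper_bound=True, ambiguous=ambiguous)
    if i == 0:
        return TmResult(float(t[0]), is_upper_bound=False, ambiguous=ambiguous)

    lo, hi = max(i - peak_half_width, 0), min(i + peak_half_width + 1, t.size)
    a, b, _ = np.polyfit(t[lo:hi], deriv[lo:hi], 2)
    tm = float(t[i])
    if a < 0:
        vertex = float(-b / (2.0 * a))
        if t[lo] <= vertex <= t[hi - 1]:
            tm = vertex
    return TmResult(tm, is_upper_bound=False, ambiguous=ambiguous)


def read_melt_csv(path) -> MeltCurve:
    """Read temp_c plus either ratio or raw f330/f350 channel columns."""
    import pandas as pd

    df = pd.read_csv(path)
    if "temp_c" not in df.columns:
        raise DataError("melt CSV must have a temp_c column")
    if "ratio" in df.columns:
        ratio = df["ratio"].to_numpy(dtype=float)
    elif {"f330", "f350"}.issubset(df.columns):
        f330 = df["f330"].to_numpy(dtype=float)
        if np.any(f330 == 0):
            raise DataError("f330 channel contains zeros; ratio undefined")
        ratio = df["f350"].to_numpy(dtype=float) / f330
    else:
        raise DataError("melt CSV must have a ratio column or f330/f350 channels")
    return MeltCurve(df["temp_c"].to_numpy(dtype=float), ratio)
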