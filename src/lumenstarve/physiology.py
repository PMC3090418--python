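"""Physiological rate estimators for light/dark starvation experiments.

Covers four measurement designs:

* **ATP shift assays** — alternating 5.5-minute dark/light periods with
  a luminescence (or ATP-per-cell) reading 5 minutes into each period;
  the light effect is the percent increase of each light reading over
  the immediately preceding dark reading, summarized as mean +/- sample
  s.d. of the last few dark-to-light shifts.  A luciferase standard
  curve converts luminescence to ATP amount.
* **Radiotracer uptake** — replicated filter counts (DPM) over time for
  live cells and a formalin-killed control; the uptake rate is the OLS
  slope of the control-corrected mean counts, and light and dark rates
  are contrasted as a percent difference.
* **Respiration** — sparse dissolved-O2 and cell-count time series in
  sealed bottles; per-interval volumetric drawdown rates and per-cell
  rates (normalized by the geometric mean of the bounding densities).
* **Cell volume** — sphere or spherocylinder volume from SEM length and
  width measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ShiftSeries",
    "ShiftResult",
    "UptakeSeries",
    "RateEstimate",
    "OxygenGrowthSeries",
    "CellDimensions",
    "fit_standard_curve",
    "shift_percent_increase",
    "uptake_rate",
    "uptake_percent_difference",
    "respiration_rates",
    "respiration_rate_ratio",
    "cell_volume",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS line luminescence = slope * ATP + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def atp_from_luminescence(self, luminescence: float) -> float:
        return (luminescence - self.intercept) / self.slope


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit the ATP standard curve from (ATP amount, luminescence) pairs."""
    if len(standards) < 3:
        raise ValueError("need >= 3 standards")
    atp = np.asarray([s[0] for s in standards], dtype=float)
    lum = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(atp).size < 2:
        raise ValueError("standards are degenerate (all same ATP amount)")
    fit = stats.linregress(atp, lum)
    if fit.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


@dataclass
class ShiftSeries:
    """Alternating dark/light measurements taken 5 min into each period."""

    times_min: np.ndarray
    phases: tuple[str, ...]
    values: np.ndarray  # ATP per cell (or luminescence per cell)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times_min) == len(self.phases) == len(self.values)):
            raise ValueError("times, phases and values must align")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if prev == cur:
                raise ValueError("phases must strictly alternate dark/light")
        if any(p not in ("dark", "light") for p in self.phases):
            raise ValueError("phases must be 'dark' or 'light'")


@dataclass(frozen=True)
class ShiftResult:
    percents: tuple[float, ...]  # every dark->light shift, in series order
    mean: float                  # over the last n_last shifts
    sd: float                    # sample s.d. (n-1) over the last n_last shifts


def shift_percent_increase(
    series: ShiftSeries, n_last: int = 3, dark_reference: str = "preceding"
) -> ShiftResult:
    """Percent ATP increase at each dark-to-light shift.

    Each shift's percent is 100 * (light - dark_ref) / dark_ref where
    the reference is the immediately preceding dark reading (default) or
    the mean of the flanking dark readings.  The summary mean and sample
    standard deviation cover the last ``n_last`` shifts.
    """
    if dark_reference not in ("preceding", "flanking_mean"):
        raise ValueError("dark_reference must be 'preceding' or 'flanking_mean'")
    percents: list[float] = []
    for i in range(1, len(series.phases)):
        if series.phases[i] != "light":
            continue
        prev_dark = series.values[i - 1]
        if dark_reference == "flanking_mean" and i + 1 < len(series.values):
            ref = 0.5 * (prev_dark + series.values[i + 1])
        else:
            ref = prev_dark
        if ref <= 0:
            raise ValueError("dark reference value must be positive")
        percents.append(100.0 * (series.values[i] - ref) / ref)
    if len(percents) < n_last:
        raise ValueError(f"series has {len(percents)} dark->light shifts, need >= {n_last}")
    tail = np.asarray(percents[-n_last:])
    sd = float(tail.std(ddof=1)) if n_last > 1 else 0.0
    return ShiftResult(tuple(percents), float(tail.mean()), sd)


@dataclass
class UptakeSeries:
    """Radiotracer counts over time for live cells and a killed control.

    ``live`` and ``control`` are timepoints x replicates arrays of DPM.
    """

    times_min: np.ndarray
    live: np.ndarray
    control: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.live = np.atleast_2d(np.asarray(self.live, dtype=float))
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        if self.live.shape[0] != len(self.times_min) or self.control.shape[0] != len(self.times_min):
            raise ValueError("count arrays must have one row per timepoint")
        if len(self.times_min) < 3:
            raise ValueError("need >= 3 timepoints")


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    stderr: float
    intercept: float


def uptake_rate(series: UptakeSeries) -> RateEstimate:
    """OLS slope of control-corrected mean counts versus time (DPM/min).

    The killed-control mean is subtracted per timepoint before the fit;
    the standard error comes from the regression residuals.
    """
    corrected = series.live.mean(axis=1) - series.control.mean(axis=1)
    fit = stats.linregress(series.times_min, corrected)
    return RateEstimate(float(fit.slope), float(fit.stderr), float(fit.intercept))


def uptake_percent_difference(light_rate: float, dark_rate: float) -> float:
    """Percent by which the light uptake rate exceeds the dark rate."""
    if dark_rate <= 0:
        raise ValueError("dark rate must be positive")
    return 100.0 * (light_rate - dark_rate) / dark_rate


@dataclass
class OxygenGrowthSeries:
    """Dissolved O2 and cell density over a growth curve.

    ``o2`` and ``cells`` are timepoints x replicate-bottle arrays
    (µmol/L and cells/mL).
    """

    times_h: np.ndarray
    o2: np.ndarray
    cells: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.o2 = np.atleast_2d(np.asarray(self.o2, dtype=float))
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=float))
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if (self.o2 < 0).any():
            raise ValueError("O2 concentrations must be non-negative")


def respiration_rates(series: OxygenGrowthSeries, density_mean: str = "geometric") -> pd.DataFrame:
    """Per-interval volumetric and per-cell respiration rates.

    For each consecutive pair of timepoints the volumetric rate is
    -d[O2]/dt in µmol L^-1 h^-1 (replicate bottles averaged) and the
    per-cell rate divides by the geometric mean (default) of the
    bounding mean cell densities, reported in amol cell^-1 h^-1
    (1 µmol L^-1 h^-1 at 10^9 cells/L is 1 amol cell^-1 h^-1).
    """
    if density_mean not in ("geometric", "arithmetic"):
        raise ValueError("density_mean must be 'geometric' or 'arithmetic'")
    t = series.times_h
    if len(t) < 2:
        raise ValueError("need >= 2 timepoints")
    o2_mean = series.o2.mean(axis=1)
    cells_mean = series.cells.mean(axis=1)
    rows = []
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        vol_rate = -(o2_mean[i + 1] - o2_mean[i]) / dt
        if density_mean == "geometric":
            dens = math.sqrt(cells_mean[i] * cells_mean[i + 1])
        else:
            dens = 0.5 * (cells_mean[i] + cells_mean[i + 1])
        # µmol/L/h -> amol/cell/h: divide by cells/L, scale to 1e-18 mol
        per_cell = vol_rate / (dens * 1e3) * 1e12 if dens > 0 else float("nan")
        rows.append(
            {
                "t_start_h": float(t[i]),
                "t_end_h": float(t[i + 1]),
                "volumetric_umol_L_h": float(vol_rate),
                "per_cell_amol_h": float(per_cell),
                "mean_density_cells_ml": float(dens),
            }
        )
    return pd.DataFrame(rows)


def respiration_rate_ratio(
    light: OxygenGrowthSeries, dark: OxygenGrowthSeries, basis: str = "volumetric"
) -> pd.DataFrame:
    """Paired light:dark respiration-rate ratio per interval.

    Requires matching timepoints; ``basis`` selects volumetric or
    per-cell rates.
    """
    if not np.allclose(light.times_h, dark.times_h):
        raise ValueError("light and dark series must share timepoints")
    col = {"volumetric": "volumetric_umol_L_h", "per_cell": "per_cell_amol_h"}[basis]
    lr = respiration_rates(light)
    dr = respiration_rates(dark)
    out = lr[["t_start_h", "t_end_h"]].copy()
    out["light_rate"] = lr[col]
    out["dark_rate"] = dr[col]
    out["light_dark_ratio"] = lr[col] / dr[col]
    return out


@dataclass(frozen=True)
class CellDimensions:
    """SEM length/width of a cell in µm plus a geometric shape model."""

    length_um: float
    width_um: float
    shape: str = "spherocylinder"

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("dimensions must be positive")
        if self.shape not in ("sphere", "spherocylinder"):
            raise ValueError("shape must be 'sphere' or 'spherocylinder'")
        if self.shape == "spherocylinder" and self.length_um < self.width_um:
            raise ValueError("spherocylinder requires length >= width")


def cell_volume(dim: CellDimensions) -> float:
    """Cell volume in µm³.

    Sphere: (4/3) π (W/2)³ with the width as diameter.  Spherocylinder
    (cylinder of length L - W capped by hemispheres of diameter W):
    π (W/2)² (L - W) + (4/3) π (W/2)³; equals the sphere at L = W.
    """
    r = dim.width_um / 2.0
    cap = (4.0 / 3.0) * math.pi * r**3
    if dim.shape == "sphere":
        return cap
    return math.pi * r**2 * (dim.length_um - dim.width_um) + cap
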