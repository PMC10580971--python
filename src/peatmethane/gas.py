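"""Methane kinetics: chamber fluxes, bottle incubation rates, qPCR quantification.

Three measurement chains, each a linear regression wrapped in explicit unit
accounting:

* static-chamber flux  F = (dc/dt) * (M/V0) * (P/P0) * (T0/T) * H, reported
  in mg CH4 m^-2 h^-1;
* closed-bottle potential methane production/oxidation: the headspace series
  is first corrected for the N2 back-fill dilution applied at every sampling
  (all removed aliquots are added back in a cumulative mass balance), then
  the slope of CH4 amount vs time is normalised to ug CH4 per g dry peat per
  day via the ideal gas law at the incubation temperature;
* qPCR standard curves: Cq vs log10(copies) least squares, amplification
  efficiency 10^(-1/slope) - 1, with the 90-110% efficiency / R^2 > 0.99
  quality gate, and absolute abundances as copies per g fresh peat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "M_CH4",
    "MOLAR_VOLUME_STP",
    "T_STANDARD",
    "P_STANDARD",
    "GAS_CONSTANT",
    "ChamberSeries",
    "IncubationSeries",
    "FluxResult",
    "RateResult",
    "StandardCurve",
    "QuantificationResult",
    "ppm_to_ug",
    "ug_to_ppm",
    "flux_to_ppm_slope",
    "chamber_flux",
    "dilution_correct",
    "potential_rate",
    "fit_standard_curve",
    "quantify_abundance",
]

M_CH4 = 16.04               # g/mol
MOLAR_VOLUME_STP = 22.414   # L/mol at T0, P0
T_STANDARD = 273.15         # K
P_STANDARD = 101.325        # kPa
GAS_CONSTANT = 8.31446      # J mol^-1 K^-1 == L kPa mol^-1 K^-1


# --------------------------------------------------------------------------
# series containers
# --------------------------------------------------------------------------

def _as_increasing(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least 2 time points")
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    return t


@dataclass
class ChamberSeries:
    """Static-chamber CH4 concentration time series."""

    times_h: np.ndarray
    ch4_ppm: np.ndarray
    chamber_height_m: float
    temperature_k: float
    pressure_kpa: float

    def __post_init__(self) -> None:
        self.times_h = _as_increasing(self.times_h)
        self.ch4_ppm = np.asarray(self.ch4_ppm, dtype=float)
        if len(self.ch4_ppm) != len(self.times_h):
            raise ValueError("ch4 and times length mismatch")
        if self.chamber_height_m <= 0:
            raise ValueError("chamber height must be positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.pressure_kpa <= 0:
            raise ValueError("pressure must be positive (kPa)")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_h": self.times_h, "ch4_ppm": self.ch4_ppm}).to_csv(
            path, index=False
        )


@dataclass
class IncubationSeries:
    """Closed-bottle headspace CH4 series with sampling/dilution bookkeeping."""

    times_h: np.ndarray
    ch4_ppm: np.ndarray
    headspace_ml: float
    removal_ml: float
    sampling_times_h: np.ndarray
    peat_fresh_mass_g: float
    water_content: float
    dilution_corrected: bool = False

    def __post_init__(self) -> None:
        self.times_h = _as_increasing(self.times_h)
        self.ch4_ppm = np.asarray(self.ch4_ppm, dtype=float)
        if len(self.ch4_ppm) != len(self.times_h):
            raise ValueError("ch4 and times length mismatch")
        if not 0 <= self.removal_ml < self.headspace_ml:
            raise ValueError("need headspace volume > removal volume >= 0")
        self.sampling_times_h = np.asarray(self.sampling_times_h, dtype=float)
        in_series = np.isin(self.sampling_times_h, self.times_h)
        if not in_series.all():
            bad = self.sampling_times_h[~in_series][:3]
            raise ValueError(f"sampling times not in series: {bad}")
        if self.peat_fresh_mass_g <= 0:
            raise ValueError("peat fresh mass must be positive")
        if not 0 <= self.water_content < 1:
            raise ValueError("water content must be a fraction in [0, 1)")

    @property
    def dry_mass_g(self) -> float:
        return self.peat_fresh_mass_g * (1.0 - self.water_content)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_h": self.times_h, "ch4_ppm": self.ch4_ppm}).to_csv(
            path, index=False
        )


# --------------------------------------------------------------------------
# unit conversions (centralised so they round-trip exactly)
# --------------------------------------------------------------------------

def ppm_to_ug(
    ppm: np.ndarray | float, volume_ml: float, temperature_k: float, pressure_kpa: float
):
    """CH4 mixing ratio (ppm) in a gas volume -> mass of CH4 in micrograms."""
    total_mol = pressure_kpa * (volume_ml / 1000.0) / (GAS_CONSTANT * temperature_k)
    return np.asarray(ppm, dtype=float) * 1e-6 * total_mol * M_CH4 * 1e6


def ug_to_ppm(
    ug: np.ndarray | float, volume_ml: float, temperature_k: float, pressure_kpa: float
):
    total_mol = pressure_kpa * (volume_ml / 1000.0) / (GAS_CONSTANT * temperature_k)
    return np.asarray(ug, dtype=float) / (1e-6 * total_mol * M_CH4 * 1e6)


def _flux_factor(height_m: float, temperature_k: float, pressure_kpa: float) -> float:
    """mg CH4 m^-2 h^-1 produced by a 1 ppm/h concentration slope.

    The chamber air column holds 1000*H/V0 mol m^-2 at standard conditions,
    scaled by (P/P0)*(T0/T) for field conditions; 1 ppm/h of that column is
    1e-6 * column mol CH4 m^-2 h^-1, converted to mg with M = 16.04 g/mol.
    """
    mol_per_m2 = (
        1000.0
        * height_m
        / MOLAR_VOLUME_STP
        * (pressure_kpa / P_STANDARD)
        * (T_STANDARD / temperature_k)
    )
    return 1e-6 * mol_per_m2 * M_CH4 * 1000.0


def flux_to_ppm_slope(
    flux_mg_m2_h: float, height_m: float, temperature_k: float, pressure_kpa: float
) -> float:
    """Invert the flux formula: mg m^-2 h^-1 -> ppm/h concentration slope."""
    return flux_mg_m2_h / _flux_factor(height_m, temperature_k, pressure_kpa)


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class FluxResult:
    value: float                  # mg CH4 m^-2 h^-1
    units: str
    slope_ppm_h: float
    intercept_ppm: float
    r_squared: float
    n_points: int
    qc_flags: list = field(default_factory=list)


@dataclass
class RateResult:
    value: float                  # ug CH4 g^-1 dry weight d^-1
    units: str
    mode: str
    slope_ug_h: float
    intercept_ug: float
    r_squared: float
    n_points: int
    qc_flags: list = field(default_factory=list)


@dataclass
class StandardCurve:
    slope: float                  # Cq per log10(copies); negative
    intercept: float              # Cq at 1 copy
    r_squared: float
    efficiency: float
    qc_pass: bool
    qc_flags: list = field(default_factory=list)
    cq_range: tuple = (np.nan, np.nan)


@dataclass
class QuantificationResult:
    copies_per_g: float
    copies_in_reaction: float
    flags: list = field(default_factory=list)


# --------------------------------------------------------------------------
# chamber flux
# --------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 1.0
    return res.slope, res.intercept, r2, res.pvalue


def chamber_flux(series: ChamberSeries, trim_start_h: float = 0.0) -> FluxResult:
    """Static-chamber CH4 flux in mg m^-2 h^-1.

    dc/dt is the OLS slope of ppm vs hours over all recorded points (an
    optional dead-band trim after closure is available but defaults to 0);
    the conversion uses M = 16.04 g/mol, V0 = 22.414 L/mol, T0 = 273.15 K,
    P0 = 101.325 kPa. A regression R^2 below 0.9 sets a QC flag; the value
    is still reported.
    """
    mask = series.times_h >= trim_start_h
    t, c = series.times_h[mask], series.ch4_ppm[mask]
    if len(t) < 3:
        raise ValueError("chamber flux needs at least 3 concentration points")
    slope, intercept, r2, _ = _ols(t, c)
    flux = slope * _flux_factor(
        series.chamber_height_m, series.temperature_k, series.pressure_kpa
    )
    flags = []
    if r2 < 0.9:
        flags.append("low_r_squared")
    if len(t) < 5:
        flags.append("short_series")
    return FluxResult(
        value=float(flux),
        units="mg CH4 m-2 h-1",
        slope_ppm_h=float(slope),
        intercept_ppm=float(intercept),
        r_squared=float(r2),
        n_points=int(len(t)),
        qc_flags=flags,
    )


# --------------------------------------------------------------------------
# incubation rates
# --------------------------------------------------------------------------

def dilution_correct(series: IncubationSeries) -> IncubationSeries:
    """Add removed aliquots back: cumulative mass balance over sampling events.

    The corrected CH4 amount at point k is C_k*V plus the sum of C_j*v over
    all sampling events j strictly before t_k (each withdrawal removed C_j*v
    of concentration-volume, replaced by CH4-free N2). Corrected
    concentration is that amount divided by V; identity when v = 0.
    """
    v, vol = series.removal_ml, series.headspace_ml
    if v == 0:
        corrected = series.ch4_ppm.copy()
    else:
        samp = np.sort(series.sampling_times_h)
        conc_at = {t: series.ch4_ppm[np.searchsorted(series.times_h, t)] for t in samp}
        corrected = np.empty_like(series.ch4_ppm)
        for k, t in enumerate(series.times_h):
            removed = sum(conc_at[tj] * v for tj in samp if tj < t)
            corrected[k] = (series.ch4_ppm[k] * vol + removed) / vol
    return IncubationSeries(
        times_h=series.times_h.copy(),
        ch4_ppm=corrected,
        headspace_ml=vol,
        removal_ml=v,
        sampling_times_h=series.sampling_times_h.copy(),
        peat_fresh_mass_g=series.peat_fresh_mass_g,
        water_content=series.water_content,
        dilution_corrected=True,
    )


def potential_rate(
    series: IncubationSeries,
    mode: str,
    temperature_k: float = 293.15,
    pressure_kpa: float = 101.325,
) -> RateResult:
    """Potential methane production or oxidation, ug CH4 g^-1 dry weight d^-1.

    The dilution-corrected headspace concentration is converted to a CH4
    mass via the ideal gas law at the incubation temperature (20 C default)
    and regressed against time; production is the positive accumulation
    slope, oxidation the positive consumption rate (-slope). A slope whose
    sign contradicts *mode* at p < 0.05 sets a "sign_mismatch" QC flag; the
    signed value is still reported.
    """
    if mode not in {"production", "oxidation"}:
        raise ValueError("mode must be 'production' or 'oxidation'")
    if not series.dilution_corrected and series.removal_ml > 0:
        raise ValueError("series must be dilution-corrected before rate estimation")
    ug = ppm_to_ug(series.ch4_ppm, series.headspace_ml, temperature_k, pressure_kpa)
    slope, intercept, r2, pval = _ols(series.times_h, ug)
    per_day_per_g = slope * 24.0 / series.dry_mass_g
    value = per_day_per_g if mode == "production" else -per_day_per_g
    flags = []
    expected_sign = 1.0 if mode == "production" else -1.0
    if slope * expected_sign < 0 and pval < 0.05:
        flags.append("sign_mismatch")
    if r2 < 0.9:
        flags.append("low_r_squared")
    return RateResult(
        value=float(value),
        units="ug CH4 g-1 dw d-1",
        mode=mode,
        slope_ug_h=float(slope),
        intercept_ug=float(intercept),
        r_squared=float(r2),
        n_points=int(len(series.times_h)),
        qc_flags=flags,
    )


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

def fit_standard_curve(cq_table: pd.DataFrame) -> StandardCurve:
    """Fit Cq vs log10(copies) and derive amplification efficiency.

    efficiency = 10^(-1/slope) - 1; the curve passes QC iff
    0.90 <= efficiency <= 1.10 and R^2 > 0.99.
    """
    if not {"log10_quantity", "cq"} <= set(cq_table.columns):
        raise ValueError("cq table needs columns 'log10_quantity' and 'cq'")
    if len(cq_table) < 3:
        raise ValueError("need at least 3 dilution points")
    x = cq_table["log10_quantity"].to_numpy(dtype=float)
    y = cq_table["cq"].to_numpy(dtype=float)
    slope, intercept, r2, _ = _ols(x, y)
    if slope >= 0:
        raise ValueError(
            f"standard-curve slope is non-negative ({slope:.3f}); "
            "Cq must decrease with template quantity"
        )
    eff = 10.0 ** (-1.0 / slope) - 1.0
    flags = []
    # boundary tolerance: 90% / 110% are inclusive despite float round-off
    if not 0.90 - 1e-9 <= eff <= 1.10 + 1e-9:
        flags.append("efficiency out of 90-110% range")
    if not r2 > 0.99:
        flags.append("r_squared <= 0.99")
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        efficiency=float(eff),
        qc_pass=not flags,
        qc_flags=flags,
        cq_range=(float(y.min()), float(y.max())),
    )


def quantify_abundance(
    curve: StandardCurve,
    cq: float,
    eluate_volume_ul: float,
    template_volume_ul: float,
    fresh_mass_g: float,
) -> QuantificationResult:
    """Absolute gene abundance as copies per g fresh peat.

    copies in the reaction = 10^((cq - intercept)/slope), scaled by the
    eluate/template volume ratio and divided by the extracted fresh mass.
    A Cq outside the fitted dilution range sets an extrapolation flag; a
    failed standard-curve QC attaches a warning flag.
    """
    if template_volume_ul <= 0 or eluate_volume_ul <= 0 or fresh_mass_g <= 0:
        raise ValueError("volumes and mass must be positive")
    copies_rxn = 10.0 ** ((cq - curve.intercept) / curve.slope)
    per_g = copies_rxn * (eluate_volume_ul / template_volume_ul) / fresh_mass_g
    flags = []
    if not curve.qc_pass:
        flags.append("standard_curve_qc_failed")
    lo, hi = curve.cq_range
    if np.isfinite(lo) and not (lo <= cq <= hi):
        flags.append("extrapolated_beyond_standards")
    return QuantificationResult(
        copies_per_g=float(per_g),
        copies_in_reaction=float(copies_rxn),
        flags=flags,
    )
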