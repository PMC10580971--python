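"""Synthetic data with known ground truth.

Generators for every input the pipeline consumes:

* OTU tables assembled neutrally (Sloan beta-binomial sampling with a known
  migration rate m) or under niche filtering (Gaussian environmental
  response with a known selection width sigma);
* static-chamber CH4 concentration series with a known flux;
* closed-bottle headspace CH4 series with known production/consumption and
  explicit N2-dilution events at each sampling;
* qPCR 10-fold dilution standard curves with a known amplification
  efficiency.

Every generator is bit-reproducible under a fixed seed, so each downstream
estimator has a ground-truth recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .community import OTUTable
from .gas import (
    GAS_CONSTANT,
    ChamberSeries,
    IncubationSeries,
    flux_to_ppm_slope,
)

__all__ = [
    "NeutralSimConfig",
    "NicheSimConfig",
    "GasSimConfig",
    "logseries_metacommunity",
    "simulate_neutral_table",
    "simulate_niche_table",
    "simulate_chamber_series",
    "simulate_incubation_series",
    "simulate_qpcr_curve",
]


# --------------------------------------------------------------------------
# metacommunity rank-abundance
# --------------------------------------------------------------------------

def logseries_metacommunity(n_taxa: int, mean_abundance: float = 200.0) -> np.ndarray:
    """Deterministic Fisher log-series relative abundances for *n_taxa* taxa.

    The log-series shape parameter x is solved so that the distribution's
    mean abundance equals *mean_abundance*; taxon abundances are then the
    distribution's quantiles at (i + 0.5)/n_taxa, normalised to sum to 1.
    This reproduces the long rare tail typical of amplicon rank-abundance
    curves without any sampling noise.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if mean_abundance <= 1.0:
        raise ValueError("mean_abundance must exceed 1")

    def mean_of(x: float) -> float:
        return -x / ((1.0 - x) * np.log1p(-x))

    x = brentq(lambda v: mean_of(v) - mean_abundance, 1e-9, 1.0 - 1e-12, xtol=1e-15)
    # log-series pmf over k = 1.. until the CDF is numerically exhausted
    kmax = 100
    while True:
        k = np.arange(1, kmax + 1)
        pmf = -(x**k) / (k * np.log1p(-x))
        cdf = np.cumsum(pmf)
        if cdf[-1] > 1.0 - 1e-12 or kmax > 10_000_000:
            break
        kmax *= 4
    q = (np.arange(n_taxa) + 0.5) / n_taxa
    abund = k[np.searchsorted(cdf, q, side="left").clip(max=len(k) - 1)]
    abund = abund[::-1].astype(float)  # most abundant first
    return abund / abund.sum()


def _resolve_metacommunity(p, n_taxa: int) -> np.ndarray:
    if isinstance(p, str):
        if p != "log-series":
            raise ValueError(f"unknown metacommunity spec {p!r}")
        return logseries_metacommunity(n_taxa)
    p = np.asarray(p, dtype=float)
    if len(p) != n_taxa:
        raise ValueError("metacommunity abundance vector length != n_taxa")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("metacommunity abundances must be non-negative and sum to 1")
    if (p >= 1.0 - 1e-12).any():
        raise ValueError("degenerate metacommunity: a single taxon holds all abundance")
    return p


# --------------------------------------------------------------------------
# neutral (Sloan) generator
# --------------------------------------------------------------------------

@dataclass
class NeutralSimConfig:
    """Sloan neutral-assembly sampling model.

    Per sample, each taxon's local relative abundance is drawn from
    Beta(N*m*p_i, N*m*(1-p_i)) — the stationary distribution of the neutral
    birth-death-immigration process at community size N and migration rate m
    — and counts are then drawn multinomially at depth N.
    """

    n_taxa: int = 100
    n_samples: int = 48
    reads_per_sample: int = 1000
    migration_rate: float = 0.1
    metacommunity: object = "log-series"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.reads_per_sample < 100:
            raise ValueError("reads_per_sample must be >= 100")
        if not 0.0 < self.migration_rate <= 1.0:
            raise ValueError("migration rate m must be in (0, 1]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def simulate_neutral_table(cfg: NeutralSimConfig) -> OTUTable:
    """Draw an OTU table from the Sloan neutral model at known m."""
    p = _resolve_metacommunity(cfg.metacommunity, cfg.n_taxa)
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.reads_per_sample, cfg.migration_rate
    a = n * m * p
    b = n * m * (1.0 - p)
    counts = np.empty((cfg.n_taxa, cfg.n_samples), dtype=np.int64)
    for j in range(cfg.n_samples):
        q = rng.beta(a, b)
        tot = q.sum()
        if tot <= 0:  # pragma: no cover - beta draws are positive a.s.
            q = p
            tot = 1.0
        counts[:, j] = rng.multinomial(n, q / tot)
    taxa = [f"OTU{i + 1:04d}" for i in range(cfg.n_taxa)]
    samples = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    return OTUTable(pd.DataFrame(counts, index=taxa, columns=samples))


# --------------------------------------------------------------------------
# niche-filtered generator
# --------------------------------------------------------------------------

@dataclass
class NicheSimConfig:
    """Gaussian environmental filtering of a shared species pool.

    Taxon j's sampling weight in sample i is
    base_j * exp(-(env_i - opt_j)^2 / (2 sigma^2)); smaller sigma means
    stronger selection. env_values is one environmental value per sample
    (e.g. water table level in cm).
    """

    n_taxa: int = 100
    n_samples: int = 48
    reads_per_sample: int = 1000
    env_values: Sequence[float] = ()
    taxon_optima: Sequence[float] | None = None
    sigma: float = 1.0
    metacommunity: object = "log-series"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.env_values) != self.n_samples:
            raise ValueError("env_values must give one value per sample")
        if self.taxon_optima is not None and len(self.taxon_optima) != self.n_taxa:
            raise ValueError("taxon_optima must give one optimum per taxon")


def simulate_niche_table(cfg: NicheSimConfig) -> OTUTable:
    """Draw an OTU table under Gaussian niche filtering at known sigma."""
    base = _resolve_metacommunity(cfg.metacommunity, cfg.n_taxa)
    env = np.asarray(cfg.env_values, dtype=float)
    if cfg.taxon_optima is None:
        lo, hi = env.min(), env.max()
        optima = np.linspace(lo, hi, cfg.n_taxa)
    else:
        optima = np.asarray(cfg.taxon_optima, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    counts = np.empty((cfg.n_taxa, cfg.n_samples), dtype=np.int64)
    samples = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    for j in range(cfg.n_samples):
        w = base * np.exp(-((env[j] - optima) ** 2) / (2.0 * cfg.sigma**2))
        tot = w.sum()
        if tot <= 0.0:
            raise ValueError(
                f"all taxon weights underflowed to zero for sample {samples[j]!r}; "
                "sigma too small relative to the env/optima spread"
            )
        counts[:, j] = rng.multinomial(cfg.reads_per_sample, w / tot)
    taxa = [f"OTU{i + 1:04d}" for i in range(cfg.n_taxa)]
    return OTUTable(pd.DataFrame(counts, index=taxa, columns=samples))


# --------------------------------------------------------------------------
# gas series
# --------------------------------------------------------------------------

@dataclass
class GasSimConfig:
    """Linear gas accumulation/consumption with analyzer noise.

    ``true_rate`` is the chamber flux in mg CH4 m^-2 h^-1 for chamber series,
    or the headspace concentration change in ppm h^-1 for bottle series.
    """

    true_rate: float = 0.5
    duration_h: float = 0.5
    sampling_interval_h: float = 2.0 / 60.0
    noise_sd_ppm: float = 0.0
    initial_ppm: float = 1.9
    # chamber geometry / conditions
    chamber_height_m: float = 0.2
    temperature_k: float = 298.15
    pressure_kpa: float = 101.325
    # bottle geometry
    headspace_ml: float = 90.0
    removal_ml: float = 0.5
    peat_fresh_mass_g: float = 10.0
    water_content: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("duration and sampling interval must be positive")
        if self.noise_sd_ppm < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.chamber_height_m <= 0:
            raise ValueError("chamber height must be positive")
        if not 0 <= self.removal_ml < self.headspace_ml:
            raise ValueError("need headspace volume > removal volume >= 0")


def simulate_chamber_series(cfg: GasSimConfig) -> ChamberSeries:
    """Chamber concentration series whose OLS slope encodes ``true_rate``.

    The ppm/h slope is the exact inverse of the flux formula at the stated
    temperature, pressure and chamber height, so a noiseless series round-
    trips through the flux computation to machine precision.
    """
    slope = flux_to_ppm_slope(
        cfg.true_rate, cfg.chamber_height_m, cfg.temperature_k, cfg.pressure_kpa
    )
    times = np.arange(0.0, cfg.duration_h + 1e-12, cfg.sampling_interval_h)
    rng = np.random.default_rng(cfg.seed)
    ch4 = cfg.initial_ppm + slope * times
    if cfg.noise_sd_ppm > 0:
        ch4 = ch4 + rng.normal(0.0, cfg.noise_sd_ppm, size=len(times))
    return ChamberSeries(
        times_h=times,
        ch4_ppm=ch4,
        chamber_height_m=cfg.chamber_height_m,
        temperature_k=cfg.temperature_k,
        pressure_kpa=cfg.pressure_kpa,
    )


def simulate_incubation_series(cfg: GasSimConfig) -> IncubationSeries:
    """Closed-bottle series with N2-dilution events at every sampling.

    Between samplings the headspace concentration changes linearly at
    ``true_rate`` (ppm/h; negative = consumption). At each sampling the
    measured (pre-dilution) concentration is recorded, a gas aliquot of
    ``removal_ml`` is withdrawn, and the bottle is back-filled with N2, so
    the concentration carried forward is scaled by (V - v)/V.
    """
    times = np.arange(0.0, cfg.duration_h + 1e-12, cfg.sampling_interval_h)
    rng = np.random.default_rng(cfg.seed)
    v, vol = cfg.removal_ml, cfg.headspace_ml
    measured = np.empty(len(times))
    conc = cfg.initial_ppm
    prev_t = 0.0
    for k, t in enumerate(times):
        conc += cfg.true_rate * (t - prev_t)
        prev_t = t
        obs = conc
        if cfg.noise_sd_ppm > 0:
            obs += rng.normal(0.0, cfg.noise_sd_ppm)
        measured[k] = obs
        conc *= (vol - v) / vol  # aliquot out, N2 back in
    return IncubationSeries(
        times_h=times,
        ch4_ppm=measured,
        headspace_ml=vol,
        removal_ml=v,
        sampling_times_h=times.copy(),
        peat_fresh_mass_g=cfg.peat_fresh_mass_g,
        water_content=cfg.water_content,
    )


# --------------------------------------------------------------------------
# qPCR standard curves
# --------------------------------------------------------------------------

def simulate_qpcr_curve(
    efficiency: float,
    intercept: float = 38.0,
    n_dilutions: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    top_log10_quantity: float = 7.0,
) -> pd.DataFrame:
    """10-fold serial-dilution standard curve at a known efficiency.

    Cq = intercept - log10(Q) / log10(1 + efficiency); perfect doubling
    (efficiency 1.0) gives the textbook slope of -3.3219 cycles per decade.
    Returns a DataFrame with columns ``log10_quantity`` and ``cq``.
    """
    if not 0.0 < efficiency <= 1.1:
        raise ValueError("efficiency must be in (0, 1.1]")
    if n_dilutions < 3:
        raise ValueError("need at least 3 dilution points to fit a standard curve")
    logq = top_log10_quantity - np.arange(n_dilutions, dtype=float)
    slope = -1.0 / np.log10(1.0 + efficiency)
    cq = intercept + slope * logq
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cq = cq + rng.normal(0.0, noise_sd, size=n_dilutions)
    return pd.DataFrame({"log10_quantity": logq, "cq": cq})
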