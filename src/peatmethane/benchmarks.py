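"""Ground-truth recovery experiments on synthetic data.

Each function runs one self-contained study: generate data with a known
truth through :mod:`peatmethane.synthetic`, push it through the estimator
under scrutiny, and report how well the truth is recovered. They are used
by the analysis drivers and by the validation suite; all randomness is
controlled by explicit seed arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .assembly import compute_mst, fit_ncm
from .community import DistanceMatrix, OTUTable, beta_dissimilarity, permanova
from .gas import chamber_flux, dilution_correct, potential_rate, ppm_to_ug
from .synthetic import (
    GasSimConfig,
    NeutralSimConfig,
    NicheSimConfig,
    simulate_chamber_series,
    simulate_incubation_series,
    simulate_neutral_table,
    simulate_niche_table,
)

__all__ = [
    "ncm_recovery",
    "mst_discrimination",
    "permanova_type_one_error",
    "gas_roundtrips",
]


def ncm_recovery(
    seeds=range(10),
    migration_rates=(0.05, 0.1, 0.2, 0.5),
    n_taxa: int = 100,
    n_samples: int = 200,
    reads_per_sample: int = 1000,
) -> pd.DataFrame:
    """Fit the neutral model to its own sampling output over an m grid.

    Returns one row per (m, seed) with the fitted migration rate, its
    relative error, and the fit R^2.
    """
    rows = []
    for m in migration_rates:
        for seed in seeds:
            table = simulate_neutral_table(
                NeutralSimConfig(
                    n_taxa=n_taxa, n_samples=n_samples,
                    reads_per_sample=reads_per_sample,
                    migration_rate=m, seed=int(seed),
                )
            )
            fit = fit_ncm(table)
            rows.append(
                {
                    "true_m": m,
                    "seed": int(seed),
                    "fitted_m": fit.m,
                    "rel_error": abs(fit.m - m) / m,
                    "r_squared": fit.r_squared,
                }
            )
    return pd.DataFrame(rows)


def mst_discrimination(
    seeds=range(1, 11),
    n_taxa: int = 100,
    group_size: int = 12,
    reads_per_sample: int = 1000,
    n_randomizations: int = 1000,
    niche_sigma: float = 0.2,
    migration_rate: float = 0.1,
) -> pd.DataFrame:
    """Within-group MST on neutral vs strongly niche-filtered tables.

    Two groups of *group_size* samples; the niche regime places the groups
    at opposite environmental values (+-1) with taxon optima split between
    them, so within-group pairs are far more similar than the null expects.
    Returns one row per (regime, seed) with the mean MST in percent.
    """
    n_samples = 2 * group_size
    groups = np.repeat(["A", "B"], group_size)
    env = np.repeat([-1.0, 1.0], group_size)
    optima = np.repeat([-1.0, 1.0], (n_taxa + 1) // 2)[:n_taxa]
    rows = []
    for seed in seeds:
        seed = int(seed)
        neutral = simulate_neutral_table(
            NeutralSimConfig(
                n_taxa=n_taxa, n_samples=n_samples,
                reads_per_sample=reads_per_sample,
                migration_rate=migration_rate, seed=seed,
            )
        )
        niche = simulate_niche_table(
            NicheSimConfig(
                n_taxa=n_taxa, n_samples=n_samples,
                reads_per_sample=reads_per_sample,
                env_values=env, taxon_optima=optima,
                sigma=niche_sigma, seed=seed,
            )
        )
        for regime, table in (("neutral", neutral), ("niche", niche)):
            res = compute_mst(table, groups, n_randomizations, seed=seed)
            rows.append(
                {"regime": regime, "seed": seed, "mst_pct": res.overall_mean_pct}
            )
    return pd.DataFrame(rows)


def permanova_type_one_error(
    n_replicates: int = 500,
    n_permutations: int = 199,
    group_size: int = 6,
    n_taxa: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of PERMANOVA under exchangeable (null) data.

    Each replicate draws iid per-sample abundance vectors, computes
    Bray-Curtis distances, and assigns arbitrary balanced group labels; the
    fraction of p-values below *alpha* estimates the empirical type-I error.
    """
    rng = np.random.default_rng(seed)
    n = 2 * group_size
    labels = np.repeat(["a", "b"], group_size)
    rejections = 0
    for _ in range(n_replicates):
        counts = rng.poisson(10.0, size=(n_taxa, n))
        counts[counts == 0] = 1
        x = counts.T.astype(float)
        d = squareform(pdist(x, "braycurtis"))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(n)], "bray_curtis")
        res = permanova(dm, labels, n_permutations,
                        seed=int(rng.integers(2**31 - 1)))
        if res.p_value < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_permutations": n_permutations,
        "alpha": alpha,
    }


def gas_roundtrips(seed: int = 0) -> dict:
    """Noiseless flux/rate round-trips plus the hand unit-analysis case."""
    out = {}

    # chamber: noiseless inverse construction
    cfg = GasSimConfig(true_rate=0.73, noise_sd_ppm=0.0, temperature_k=288.15,
                       seed=seed)
    res = chamber_flux(simulate_chamber_series(cfg))
    out["chamber_roundtrip_rel_error"] = abs(res.value - 0.73) / 0.73

    # hand case: 1 ppm/h, H = 0.2 m, standard T and P
    t = np.linspace(0.0, 0.5, 16)
    from .gas import ChamberSeries
    hand = chamber_flux(ChamberSeries(t, 1.9 + t, 0.2, 273.15, 101.325))
    out["chamber_unit_case_mg_m2_h"] = hand.value

    # incubation: production with dilution events
    icfg = GasSimConfig(true_rate=8.0, duration_h=72.0, sampling_interval_h=24.0,
                        noise_sd_ppm=0.0, headspace_ml=90.0, removal_ml=0.5,
                        initial_ppm=1.9, peat_fresh_mass_g=10.0, water_content=0.9,
                        seed=seed)
    rate = potential_rate(
        dilution_correct(simulate_incubation_series(icfg)), "production"
    )
    truth = float(ppm_to_ug(8.0, 90.0, 293.15, 101.325)) * 24.0 / 1.0
    out["incubation_roundtrip_rel_error"] = abs(rate.value - truth) / truth
    out["incubation_rate_ug_g_dw_d"] = rate.value
    return out
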