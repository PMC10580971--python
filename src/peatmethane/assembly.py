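"""Community-assembly statistics: Sloan neutral model, MST, niche breadth.

The Sloan neutral community model predicts a taxon's occurrence frequency
across samples from its mean relative abundance: local relative abundances
follow Beta(N*m*pbar, N*m*(1-pbar)) with N the reads per rarefied sample and
m the migration rate. "Occurring" means at least one read at depth N; the
default detection model evaluates that probability exactly under
beta-binomial sampling, 1 - B(a, b+N)/B(a, b), while the classical
continuous approximation 1 - BetaCDF(1/N; a, b) is available as
``detection="beta_cdf"``. Nm is fitted by bounded least squares against the
observed occurrence frequencies; taxa are partitioned into above / within /
below the 95% band around the prediction.

The modified stochasticity ratio (MST) compares each within-group pair's
observed Jaccard dissimilarity D against a null expectation E from
randomized communities: MST = D/E when D <= E, else (1-D)/(1-E). It is 1
when observation matches the null exactly and approaches 0 at either
deterministic extreme; 50% is the conventional boundary between more
deterministic (<50%) and more stochastic (>50%) assembly.

Levins niche breadth B_j = 1 / sum_i P_ij^2, with P_ij the share of taxon
j's reads found in sample i: B = 1 for a strict specialist, B = number of
samples for a perfect generalist.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import betaln

from .community import OTUTable

logger = logging.getLogger(__name__)

__all__ = [
    "NCMFit",
    "PartitionSummary",
    "MSTResult",
    "NicheBreadthResult",
    "sloan_predicted_frequency",
    "fit_ncm",
    "partition_taxa",
    "compute_mst",
    "niche_breadth",
]

_Z95 = stats.norm.ppf(0.975)


# --------------------------------------------------------------------------
# Sloan neutral community model
# --------------------------------------------------------------------------

@dataclass
class NCMFit:
    nm: float                    # fitted N*m
    m: float                     # migration rate, Nm/N
    n_reads: int                 # rarefied depth N
    detection_limit: float       # d = 1/N
    r_squared: float             # 1 - SSE/SST; may be negative
    n_samples: int
    taxa: pd.DataFrame           # per-taxon records incl. partition labels

    def summary(self) -> dict:
        return {
            "Nm": self.nm,
            "m": self.m,
            "N": self.n_reads,
            "detection_limit": self.detection_limit,
            "R2": self.r_squared,
            "n_taxa": int(len(self.taxa)),
            "n_samples": self.n_samples,
        }


def sloan_predicted_frequency(
    nm: float,
    mean_rel_abund,
    n_reads: int,
    detection: str = "exact",
):
    """Occurrence frequency predicted by the Sloan model at a given Nm.

    ``detection="exact"`` is the probability of drawing at least one read in
    a beta-binomial sample of depth N, 1 - B(a, b+N)/B(a, b);
    ``detection="beta_cdf"`` is the continuous approximation
    1 - BetaCDF(1/N; a, b) used by the classical fitting scripts. The exact
    form removes the upward Nm bias the approximation shows on data sampled
    at finite depth.
    """
    p = np.asarray(mean_rel_abund, dtype=float)
    a = nm * p
    b = nm * (1.0 - p)
    if detection == "exact":
        with np.errstate(invalid="ignore"):
            out = -np.expm1(betaln(a, b + n_reads) - betaln(a, b))
        out = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, out))
        return np.clip(out, 0.0, 1.0)
    if detection == "beta_cdf":
        with np.errstate(invalid="ignore"):
            out = stats.beta.sf(1.0 / n_reads, a, b)
        return np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, out))
    raise ValueError(f"unknown detection model {detection!r}")


def _wilson_interval(p_hat: np.ndarray, n: int, z: float = _Z95):
    """Wilson score interval around a proportion at sample size n."""
    denom = 1.0 + z**2 / n
    centre = p_hat + z**2 / (2 * n)
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n + z**2 / (4 * n**2))
    return (centre - half) / denom, (centre + half) / denom


def fit_ncm(table: OTUTable, detection: str = "exact") -> NCMFit:
    """Fit the Sloan neutral model to occurrence frequency vs abundance.

    Requires a rarefied table (equal column sums). Nm is estimated by
    minimising the sum of squared deviations between observed and predicted
    occurrence frequencies over a log-spaced grid refined by bounded scalar
    minimisation; the 95% band around the prediction uses Wilson score
    intervals at n = number of samples. *detection* selects the exact
    beta-binomial occurrence probability (default) or the classical
    continuous approximation at d = 1/N ("beta_cdf").
    """
    depths = table.sample_depths().to_numpy()
    if not (depths == depths[0]).all():
        raise ValueError(
            "table is not rarefied: sample depths range "
            f"{depths.min()}-{depths.max()}; rarefy to a common depth first"
        )
    n_reads = int(depths[0])
    counts = table.counts.to_numpy()
    nonzero = counts.sum(axis=1) > 0
    if nonzero.sum() < 20:
        raise ValueError("need at least 20 taxa with nonzero counts for a stable fit")
    counts = counts[nonzero]
    taxon_ids = np.asarray(table.taxon_ids)[nonzero]
    n_samples = table.n_samples

    pbar = (counts / n_reads).mean(axis=1)
    obs_freq = (counts > 0).mean(axis=1)
    d = 1.0 / n_reads

    def sse(log_nm: float) -> float:
        pred = sloan_predicted_frequency(np.exp(log_nm), pbar, n_reads, detection)
        return float(((obs_freq - pred) ** 2).sum())

    # coarse log grid, then bounded refinement around the best cell
    grid = np.log(np.logspace(np.log10(0.1), np.log10(10.0 * n_reads), 200))
    sse_grid = np.array([sse(g) for g in grid])
    i = int(np.argmin(sse_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"NCM fit did not converge: {res}")
    best = res.x if res.fun <= sse_grid[i] else grid[i]
    nm = float(np.exp(best))

    pred = sloan_predicted_frequency(nm, pbar, n_reads, detection)
    sse_val = float(((obs_freq - pred) ** 2).sum())
    sst = float(((obs_freq - obs_freq.mean()) ** 2).sum())
    r2 = 1.0 - sse_val / sst if sst > 0 else float("nan")
    lower, upper = _wilson_interval(pred, n_samples)
    # tolerance guards the saturated ends (pred ~ 1 gives upper = 1 - O(eps))
    tol = 1e-9
    partition = np.where(obs_freq > upper + tol, "above",
                         np.where(obs_freq < lower - tol, "below", "within"))
    taxa = pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "mean_rel_abundance": pbar,
            "observed_frequency": obs_freq,
            "predicted_frequency": pred,
            "lower95": lower,
            "upper95": upper,
            "partition": partition,
        }
    ).set_index("taxon_id")
    return NCMFit(
        nm=nm,
        m=nm / n_reads,
        n_reads=n_reads,
        detection_limit=d,
        r_squared=float(r2),
        n_samples=n_samples,
        taxa=taxa,
    )


@dataclass
class PartitionSummary:
    taxon_fractions: pd.Series     # above/within/below, sums to 1
    sequence_fractions: pd.Series  # abundance-weighted, sums to 1


def partition_taxa(fit: NCMFit, table: OTUTable) -> PartitionSummary:
    """Fractions of taxa and of sequences above/within/below the 95% band."""
    labels = ["above", "within", "below"]
    part = fit.taxa["partition"]
    missing = set(part.index) - set(table.taxon_ids)
    if missing:
        raise ValueError(f"fit and table disagree on taxa: {sorted(missing)[:5]}")
    taxon_frac = part.value_counts(normalize=True).reindex(labels, fill_value=0.0)
    totals = table.counts.sum(axis=1).loc[part.index]
    seq_frac = totals.groupby(part).sum().reindex(labels, fill_value=0.0)
    seq_frac = seq_frac / totals.sum()
    return PartitionSummary(
        taxon_fractions=taxon_frac.astype(float),
        sequence_fractions=seq_frac.astype(float),
    )


# --------------------------------------------------------------------------
# modified stochasticity ratio
# --------------------------------------------------------------------------

@dataclass
class MSTResult:
    pairs: pd.DataFrame           # sample_i, sample_j, group, observed_d, null_e, mst
    group_means_pct: pd.Series    # per group, percent scale
    overall_mean_pct: float
    null_model: str
    n_randomizations: int
    seed: int
    n_excluded_pairs: int = 0


def _null_incidence(
    presence: np.ndarray, sample_ids, seed: int, n_rand: int
) -> np.ndarray:
    """Randomized incidence matrices: per-sample richness fixed, taxon
    inclusion probability proportional to whole-table occurrence frequency.

    Weighted sampling without replacement via the exponential-race trick
    (smallest Exp(1)/w key wins). Randomness is keyed to each sample's ID
    and to frequency-sorted taxon slots, so the result is exactly invariant
    to taxon relabeling and to sample reordering, and deterministic given
    *seed*. Returns a boolean array of shape (n_rand, n_samples, n_taxa).
    """
    n_taxa, n_samples = presence.shape
    freq = presence.mean(axis=1)
    richness = presence.sum(axis=0)
    eligible = np.flatnonzero(freq > 0)
    # canonical slot order: frequency descending (equal-weight slots are
    # exchangeable, so tie order cannot affect pairwise overlap counts)
    eligible = eligible[np.argsort(-freq[eligible], kind="stable")]
    w_el = freq[eligible]
    out = np.zeros((n_rand, n_samples, n_taxa), dtype=bool)
    for s in range(n_samples):
        tag = zlib.crc32(str(sample_ids[s]).encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([seed, tag])
        keys = rng.exponential(1.0, size=(n_rand, len(eligible))) / w_el
        k = richness[s]
        if k == 0:
            continue
        top = np.argpartition(keys, k - 1, axis=1)[:, :k]
        for r in range(n_rand):
            out[r, s, eligible[top[r]]] = True
    return out


def compute_mst(
    table: OTUTable,
    groups,
    n_randomizations: int = 1000,
    seed: int = 0,
    null_model: str = "frequency-weighted fixed-richness",
) -> MSTResult:
    """Modified stochasticity ratio on Jaccard (incidence) dissimilarity.

    For each within-group sample pair the null expectation E is the mean
    Jaccard dissimilarity over *n_randomizations* randomized communities
    (per-sample richness preserved, taxa drawn with probability proportional
    to their occurrence frequency across the whole table). MST = D/E when
    D <= E, else (1-D)/(1-E); pairs with degenerate E (0 or 1) are excluded
    and counted. Group means are reported on the percent scale.
    """
    if n_randomizations < 100:
        raise ValueError("need at least 100 randomizations")
    labels = np.asarray(groups)
    if len(labels) != table.n_samples:
        raise ValueError("group labels do not match table samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts < 3).any():
        bad = uniq[counts < 3][0]
        raise ValueError(f"group {bad!r} has fewer than 3 samples")

    presence = table.counts.to_numpy() > 0
    nulls = _null_incidence(presence, table.sample_ids, seed, n_randomizations)

    obs = presence.T  # samples x taxa
    rows = []
    n_excluded = 0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        for i, j in combinations(idx, 2):
            inter = (obs[i] & obs[j]).sum()
            union = (obs[i] | obs[j]).sum()
            if union == 0:
                n_excluded += 1
                logger.warning("pair (%s,%s): both samples empty; excluded",
                               table.sample_ids[i], table.sample_ids[j])
                continue
            d_obs = 1.0 - inter / union
            n_inter = (nulls[:, i, :] & nulls[:, j, :]).sum(axis=1)
            n_union = (nulls[:, i, :] | nulls[:, j, :]).sum(axis=1)
            with np.errstate(invalid="ignore"):
                d_null = 1.0 - n_inter / n_union
            e = float(np.nanmean(d_null))
            if e <= 0.0 or e >= 1.0:
                n_excluded += 1
                logger.warning("pair (%s,%s): degenerate null expectation E=%.3f; excluded",
                               table.sample_ids[i], table.sample_ids[j], e)
                continue
            mst = d_obs / e if d_obs <= e else (1.0 - d_obs) / (1.0 - e)
            rows.append(
                {
                    "sample_i": table.sample_ids[i],
                    "sample_j": table.sample_ids[j],
                    "group": g,
                    "observed_d": d_obs,
                    "null_e": e,
                    "mst": mst,
                }
            )
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise ValueError("no valid within-group pairs for MST")
    group_means = pairs.groupby("group")["mst"].mean() * 100.0
    return MSTResult(
        pairs=pairs,
        group_means_pct=group_means,
        overall_mean_pct=float(pairs["mst"].mean() * 100.0),
        null_model=null_model,
        n_randomizations=n_randomizations,
        seed=seed,
        n_excluded_pairs=n_excluded,
    )


# --------------------------------------------------------------------------
# Levins niche breadth
# --------------------------------------------------------------------------

@dataclass
class NicheBreadthResult:
    per_taxon: pd.Series          # Levins B per included taxon
    community_mean: float         # arithmetic mean over included taxa
    min_occurrence: int
    n_excluded_zero: int = 0


def niche_breadth(table: OTUTable, min_occurrence: int = 1) -> NicheBreadthResult:
    """Levins niche breadth per taxon and its community arithmetic mean.

    P_ij is the share of taxon j's total reads found in sample i and
    B_j = 1/sum_i P_ij^2. Taxa occurring in fewer than *min_occurrence*
    samples are excluded from the community mean; zero-count taxa are
    dropped and logged.
    """
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info("niche_breadth: excluding %d zero-count taxa", int(zero.sum()))
    keep = ~zero
    shares = counts[keep] / totals[keep, None]
    b = 1.0 / (shares**2).sum(axis=1)
    occ = (counts[keep] > 0).sum(axis=1)
    ids = np.asarray(table.taxon_ids)[keep]
    included = occ >= min_occurrence
    if not included.any():
        raise ValueError("no taxa meet the min_occurrence threshold")
    per_taxon = pd.Series(b[included], index=ids[included], name="levins_b")
    return NicheBreadthResult(
        per_taxon=per_taxon,
        community_mean=float(per_taxon.mean()),
        min_occurrence=min_occurrence,
        n_excluded_zero=int(zero.sum()),
    )
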