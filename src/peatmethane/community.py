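"""OTU-table data model, diversity, dissimilarity, ordination and PERMANOVA.

The central container is :class:`OTUTable`, a validated non-negative integer
count matrix (taxa x samples) backed by a pandas DataFrame. Everything
downstream — rarefaction, alpha diversity, Bray-Curtis/Jaccard dissimilarity,
principal coordinate analysis and one-way PERMANOVA — operates on it.

Conventions (documented because the literature is not uniform):

* Shannon diversity is reported in natural-log units (nats), so that Pielou's
  evenness is exactly H / ln(S_obs).
* "Simpson" is the Gini-Simpson index 1 - sum(p^2), the common ecological
  convention of the vegan toolchain.
* Rarefaction is a single without-replacement draw at the requested depth;
  the seed is recorded so downstream results are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "OTUTable",
    "SampleMetadata",
    "DistanceMatrix",
    "PCoAResult",
    "PermanovaResult",
    "read_otu_table",
    "read_metadata",
    "rarefy",
    "alpha_diversity",
    "beta_dissimilarity",
    "pcoa",
    "permanova",
]


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

@dataclass
class OTUTable:
    """Non-negative integer count matrix, taxa as rows, samples as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        if df.shape[1] < 2:
            raise ValueError("OTU table needs at least 2 samples")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate taxon ID: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("OTU table contains non-numeric counts")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("OTU table counts must be integers")
        df = df.astype(np.int64)
        df.index.name = None
        df.columns.name = None
        self.counts = df

    # -- convenience views -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised relative abundances (per-sample fractions)."""
        depths = self.counts.sum(axis=0)
        if (depths == 0).any():
            empty = depths.index[depths == 0][0]
            raise ValueError(f"sample {empty!r} has zero reads")
        return self.counts / depths

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def drop_empty_taxa(self) -> "OTUTable":
        keep = self.counts.sum(axis=1) > 0
        return OTUTable(self.counts.loc[keep])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OTUTable":
        return read_otu_table(path)


@dataclass
class SampleMetadata:
    """Per-sample study design and physicochemistry.

    Required columns: ``sample_id``, ``site``, ``depth_layer``,
    ``water_table_level`` (cm relative to the peat surface; positive above).
    Additional physicochemical columns (pH, EC, TOC, TN, WC, ions) are kept
    as-is.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"sample_id", "site", "depth_layer", "water_table_level"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample ID in metadata: {dup!r}")
        wtl = df["water_table_level"].astype(float)
        if ((wtl <= -100) | (wtl >= 100)).any():
            raise ValueError("water_table_level outside plausible (-100, 100) cm range")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_labels(self, column: str, sample_ids: list[str]) -> np.ndarray:
        """Group labels for *sample_ids*, in that order."""
        lookup = self.table.set_index("sample_id")[column]
        missing = [s for s in sample_ids if s not in lookup.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return lookup.loc[sample_ids].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def validate_against(self, table: OTUTable) -> None:
        meta_ids = set(self.sample_ids)
        tbl_ids = set(table.sample_ids)
        if not tbl_ids <= meta_ids:
            raise ValueError(
                f"samples missing from metadata: {sorted(tbl_ids - meta_ids)[:5]}"
            )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_SAMPLE_ROW_HEADERS = {"sample_id", "sample", "samples"}


def read_otu_table(path: str | Path) -> OTUTable:
    """Read a TSV OTU table; first column taxon IDs, remaining columns samples.

    Orientation is auto-detected from the header of the first column: a
    header naming samples (``sample_id``) means samples-as-rows and the
    matrix is transposed; anything else (``taxon_id``, ``#OTU ID``, ...) is
    taken as taxa-as-rows. The decision is logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path} as a TSV OTU table: {exc}") from exc
    header = (df.index.name or "").strip().lower()
    if header in _SAMPLE_ROW_HEADERS:
        logger.info("OTU table %s is samples-as-rows (header %r); transposing", path, header)
        df = df.T
    else:
        logger.info("OTU table %s read taxa-as-rows (header %r)", path, header)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric count in {path} at taxon {row!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OTUTable(df)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleMetadata(df)


# --------------------------------------------------------------------------
# rarefaction
# --------------------------------------------------------------------------

def rarefy(table: OTUTable, depth: int, seed: int) -> OTUTable:
    """Subsample every sample without replacement to exactly *depth* reads.

    Uses a multivariate hypergeometric draw per sample, so each column of the
    result sums to *depth* exactly and no count ever exceeds the original.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    depths = table.sample_depths()
    short = depths[depths < depth]
    if len(short):
        raise ValueError(
            "rarefaction depth %d exceeds reads in samples: %s"
            % (depth, ", ".join(f"{s}({int(d)})" for s, d in short.items()))
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j in range(table.n_samples):
        col = table.counts.iloc[:, j].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OTUTable(pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids))


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def alpha_diversity(table: OTUTable) -> pd.DataFrame:
    """Shannon (nats), Gini-Simpson, Pielou evenness and observed richness.

    Pielou's evenness is defined as 0 for single-taxon samples (H = ln 1 = 0
    makes the ratio 0/0 otherwise).
    """
    depths = table.sample_depths()
    if (depths == 0).any():
        empty = depths.index[depths == 0][0]
        raise ValueError(f"sample {empty!r} is empty; alpha diversity undefined")
    rows = []
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        counts = counts[counts > 0]
        p = counts / counts.sum()
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        richness = int(len(counts))
        pielou = float(shannon / np.log(richness)) if richness > 1 else 0.0
        rows.append(
            {
                "sample_id": sample,
                "shannon": shannon,
                "simpson": simpson,
                "pielou_evenness": pielou,
                "observed_richness": richness,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# --------------------------------------------------------------------------
# beta dissimilarity
# --------------------------------------------------------------------------

def beta_dissimilarity(table: OTUTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis (on counts) or Jaccard (presence/absence)."""
    if metric not in {"bray_curtis", "jaccard"}:
        raise ValueError(f"unknown metric {metric!r}")
    x = table.counts.to_numpy().T.astype(float)  # samples x taxa
    depths = x.sum(axis=1)
    empty = np.flatnonzero(depths == 0)
    if len(empty) >= 2:
        ids = [table.sample_ids[i] for i in empty]
        raise ValueError(f"dissimilarity undefined between empty samples: {ids}")
    n = x.shape[0]
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
            tots = depths[i] + depths[i + 1 :]
            d[i, i + 1 :] = 1.0 - 2.0 * mins / tots
    else:
        b = x > 0
        for i in range(n):
            inter = (b[i] & b[i + 1 :]).sum(axis=1)
            union = (b[i] | b[i + 1 :]).sum(axis=1)
            d[i, i + 1 :] = 1.0 - inter / union
    d = d + d.T
    return DistanceMatrix(d, table.sample_ids, metric)


# --------------------------------------------------------------------------
# PCoA (classical metric scaling)
# --------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame          # samples x axes
    explained: np.ndarray              # fraction of positive eigenvalue mass
    eigenvalues: np.ndarray            # positive eigenvalues, descending
    n_negative_eigenvalues: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# explained fractions: "
                + " ".join(f"{e:.6f}" for e in self.explained)
                + "\n"
            )
            self.coordinates.to_csv(fh, sep="\t")


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> PCoAResult:
    """Classical (Gower) scaling of a dissimilarity matrix.

    Eigendecomposition of -0.5 * J D^2 J with J the centring matrix; axes
    ordered by eigenvalue, negative eigenvalues dropped (their count logged),
    explained fractions taken over the positive eigenvalue mass.
    """
    d = dm.values
    if np.allclose(d, 0.0):
        raise ValueError("degenerate configuration: all distances are zero")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_neg = int((evals < -eps).sum())
    if n_neg:
        logger.info("pcoa: dropping %d negative eigenvalues (min %.3g)", n_neg, evals.min())
    pos = evals > eps
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        explained=lam / lam.sum(),
        eigenvalues=lam,
        n_negative_eigenvalues=n_neg,
    )


# --------------------------------------------------------------------------
# one-way PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int
    group_sizes: dict = field(default_factory=dict)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA pseudo-F with a permutation p-value.

    The among/within sums of squares are formed directly from the distance
    matrix (Anderson's decomposition); the p-value is
    (#{permuted F >= observed} + 1) / (n_permutations + 1). Deterministic
    given *seed*.
    """
    labels = np.asarray(groups)
    if len(labels) != dm.n:
        raise ValueError("group labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2][0]
        raise ValueError(f"group {bad!r} has fewer than 2 samples")
    d2 = dm.values**2
    n, a = dm.n, len(uniq)

    def f_stat(lab: np.ndarray) -> float:
        ss_t, ss_w = _permanova_ss(d2, lab, uniq)
        ss_a = ss_t - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(labels)
    ss_t, ss_w = _permanova_ss(d2, labels, uniq)
    r2 = (ss_t - ss_w) / ss_t
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if f_stat(labels[rng.permutation(n)]) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={str(g): int(c) for g, c in zip(uniq, counts)},
    )
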