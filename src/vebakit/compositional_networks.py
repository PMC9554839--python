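"""Compositional data analysis and differential co-occurrence networks.

Sequencing counts are compositional: only relative information is
meaningful.  The analysis chain here is the standard log-ratio one —

1. CLR transform with a pseudo-count of ``1/m²`` (m = number of features):
   ``clr_j = ln(x_j + 1/m²) − mean_k ln(x_k + 1/m²)``, so each sample row
   sums to zero.
2. Aitchison distance between samples = Euclidean distance on CLR rows.
3. ρ proportionality between features:
   ``ρ = 1 − var(A_x − A_y) / (var A_x + var A_y) = 2·cov(A_x, A_y) /
   (var A_x + var A_y)``, bounded in [−1, 1].
4. Ensemble co-occurrence networks: bootstrap the samples, recompute all
   pairwise ρ per iteration, and average element-wise over iterations.
5. Differential connectivity ``D = ρ_a − ρ_b`` between two condition
   networks, keeping edges positive in both conditions with |D| above a
   cutoff (default 0.1).

Features present in fewer than a prevalence cutoff of samples (default 40%)
are dropped before network inference; ``1 − ρ`` gives a dissimilarity used
for average-linkage hierarchical clustering of features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .feature_compression import validate_counts

__all__ = [
    "Composition",
    "AssociationNetwork",
    "clr_transform",
    "aitchison_distance",
    "rho_proportionality",
    "rho_matrix",
    "ensemble_network",
    "differential_network",
    "prevalence_filter",
    "rho_dissimilarity_linkage",
]


@dataclass(frozen=True)
class Composition:
    """CLR-transformed counts; every row sums to zero (± 1e-9)."""

    clr: pd.DataFrame
    pseudo_count: float

    def __post_init__(self) -> None:
        row_sums = self.clr.sum(axis=1).to_numpy()
        if row_sums.size and np.max(np.abs(row_sums)) > 1e-9:
            raise ValueError("CLR rows do not sum to zero")


@dataclass(frozen=True)
class AssociationNetwork:
    """Symmetric feature × feature ρ matrix for one condition."""

    condition: str
    rho: pd.DataFrame
    n_iterations: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        mat = self.rho.to_numpy()
        if mat.shape[0] != mat.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-9, equal_nan=True):
            raise ValueError("association matrix must be symmetric")

    @property
    def features(self) -> list:
        return list(self.rho.columns)


def clr_transform(counts: pd.DataFrame) -> Composition:
    """Centered log-ratio transform with pseudo-count ``1/m²``."""
    validate_counts(counts)
    m = counts.shape[1]
    if m < 2:
        raise ValueError("CLR requires at least 2 features")
    pseudo = 1.0 / (m * m)
    logged = np.log(counts.to_numpy(dtype=float) + pseudo)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return Composition(
        clr=pd.DataFrame(clr, index=counts.index, columns=counts.columns),
        pseudo_count=pseudo,
    )


def aitchison_distance(a, b) -> float:
    """Euclidean distance between two CLR-transformed sample rows."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def rho_proportionality(a_x, a_y) -> float:
    """ρ proportionality between two CLR feature vectors over samples.

    ``ρ = 1 − var(A_x − A_y)/(var A_x + var A_y)`` with the unbiased (n−1)
    variance estimator; identical to ``2 cov/(var+var)``.  Undefined (raises)
    when both variances are zero.
    """
    x = np.asarray(a_x, dtype=float)
    y = np.asarray(a_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must share sample dimension")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var_x = np.var(x, ddof=1)
    var_y = np.var(y, ddof=1)
    if var_x + var_y == 0:
        raise ValueError("zero total variance: rho undefined")
    return float(1.0 - np.var(x - y, ddof=1) / (var_x + var_y))


def rho_matrix(clr: pd.DataFrame) -> pd.DataFrame:
    """All pairwise ρ values from a CLR matrix (samples × features).

    Vectorized through the covariance matrix: ρ_ij = 2 C_ij / (C_ii + C_jj).
    Pairs whose summed variance is zero come out NaN; the diagonal is exactly 1.
    """
    cov = np.cov(clr.to_numpy(dtype=float), rowvar=False, ddof=1)
    var = np.diag(cov)
    denom = var[:, None] + var[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, 2.0 * cov / denom, np.nan)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=clr.columns, columns=clr.columns)


def ensemble_network(
    counts: pd.DataFrame,
    n_iterations: int = 1000,
    seed: Optional[int] = None,
    condition: str = "",
    resample: bool = True,
) -> AssociationNetwork:
    """Bootstrap-ensemble co-occurrence network.

    Each iteration resamples the samples with replacement, CLR-transforms
    the resample, and computes all pairwise ρ; the final network is the
    element-wise mean over iterations (NaN-aware, since a bootstrap draw can
    leave a feature variance-free).  ``resample=False`` with
    ``n_iterations=1`` degenerates to the plain pairwise-ρ network.
    Deterministic given ``seed``.
    """
    validate_counts(counts)
    n_samples = counts.shape[0]
    if n_samples < 4:
        raise ValueError(f"need at least 4 samples, got {n_samples}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    acc = np.zeros((counts.shape[1], counts.shape[1]), dtype=float)
    valid = np.zeros_like(acc)
    for _ in range(n_iterations):
        if resample:
            idx = rng.integers(0, n_samples, size=n_samples)
            # a bootstrap draw repeats samples; drop ids so the draw is a valid table
            draw = counts.iloc[idx].reset_index(drop=True)
        else:
            draw = counts
        rho = rho_matrix(clr_transform(draw).clr).to_numpy()
        mask = np.isfinite(rho)
        acc[mask] += rho[mask]
        valid += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rho = np.where(valid > 0, acc / valid, np.nan)
    np.fill_diagonal(mean_rho, 1.0)
    mean_rho = (mean_rho + mean_rho.T) / 2.0  # guard against fp asymmetry
    return AssociationNetwork(
        condition=condition,
        rho=pd.DataFrame(mean_rho, index=counts.columns, columns=counts.columns),
        n_iterations=n_iterations,
        seed=seed,
    )


def differential_network(
    net_a: AssociationNetwork,
    net_b: AssociationNetwork,
    min_diff: float = 0.1,
) -> pd.DataFrame:
    """Differential connectivity edge table between two condition networks.

    For each unordered feature pair, D = ρ_a − ρ_b.  Edges are retained when
    the association is positive in *both* conditions (negative ρ is
    non-trivial to interpret) and |D| ≥ ``min_diff``; the sign of D is
    preserved.  Columns: source, target, rho_a, rho_b, diff.
    """
    if list(net_a.features) != list(net_b.features):
        raise ValueError("feature sets differ between networks")
    rows = []
    ra, rb = net_a.rho, net_b.rho
    for x, y in itertools.combinations(net_a.features, 2):
        rho_a = ra.at[x, y]
        rho_b = rb.at[x, y]
        if not (np.isfinite(rho_a) and np.isfinite(rho_b)):
            continue
        diff = rho_a - rho_b
        if rho_a > 0 and rho_b > 0 and abs(diff) >= min_diff:
            rows.append((x, y, rho_a, rho_b, diff))
    return pd.DataFrame(rows, columns=["source", "target", "rho_a", "rho_b", "diff"])


def prevalence_filter(counts: pd.DataFrame, min_prevalence: float = 0.4) -> pd.DataFrame:
    """Drop features present (count > 0) in fewer than ``min_prevalence`` of samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence {min_prevalence} outside [0,1]")
    validate_counts(counts)
    prevalence = (counts > 0).mean(axis=0)
    return counts.loc[:, prevalence >= min_prevalence]


def rho_dissimilarity_linkage(
    network: AssociationNetwork,
) -> tuple[pd.DataFrame, np.ndarray]:
    """``1 − ρ`` dissimilarity matrix plus its average-linkage merge tree.

    Returns ``(dissimilarity DataFrame in [0, 2], scipy linkage matrix)``.
    """
    rho = network.rho.to_numpy()
    if not np.all(np.isfinite(rho)):
        raise ValueError("non-finite entries in association matrix")
    dissim = 1.0 - rho
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip(dissim, 0.0, None)  # fp guard; ρ ≤ 1 by construction
    condensed = squareform(dissim, checks=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        merge_tree = linkage(condensed, method="average")
    frame = pd.DataFrame(dissim, index=network.features, columns=network.features)
    return frame, merge_tree
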