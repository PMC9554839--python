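"""Counts aggregation along the feature hierarchy and compression ratios.

Counts tables (samples × features, non-negative) are aggregated by summing
member features with respect to a grouping — contigs into MAGs, MAGs into
SLCs, ORFs into SSOs, or SLCs into coarser taxon labels.  The feature
compression ratio FCR = 1 − N_clusters/N_features quantifies the fraction of
dimensionality removed by a clustering; the functional variant is identical
but counts only ORFs that landed in an orthogroup.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "validate_counts",
    "aggregate_counts",
    "fcr",
    "functional_fcr",
    "format_fcr_percent",
    "aggregate_taxon_features",
]


def validate_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a samples × features counts table: non-negative, unique ids."""
    if matrix.index.has_duplicates:
        raise ValueError("duplicate sample ids")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate feature ids")
    values = matrix.to_numpy()
    if values.size and (np.nanmin(values) < 0):
        raise ValueError("negative counts")
    return matrix


def aggregate_counts(
    matrix: pd.DataFrame,
    grouping: Mapping[str, str],
    drop_ungrouped: bool = False,
) -> pd.DataFrame:
    """Sum feature columns with respect to their clustered grouping.

    ``grouping`` maps feature -> group.  With ``drop_ungrouped=False`` every
    feature must be grouped (per-sample totals are then conserved); with
    ``drop_ungrouped=True`` ungrouped features are excluded, as for SSO
    aggregation where only clustered ORFs participate.  Output columns are
    the groups, sorted.
    """
    validate_counts(matrix)
    ungrouped = [f for f in matrix.columns if f not in grouping]
    if ungrouped and not drop_ungrouped:
        raise ValueError(
            f"{len(ungrouped)} features lack a group (first: {ungrouped[0]!r}); "
            "pass drop_ungrouped=True to exclude them"
        )
    kept = [f for f in matrix.columns if f in grouping]
    out = matrix[kept].T.groupby(lambda f: grouping[f]).sum().T
    return out.sort_index(axis=1)


def fcr(n_features: int, n_clusters: int) -> float:
    """Feature compression ratio ``1 − n_clusters / n_features``.

    E.g. 200 MAGs collapsing into 50 SLCs gives 1 − 50/200 = 0.75: the
    clusters carry roughly the same information in 75% fewer dimensions.
    """
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    if n_clusters <= 0 or n_clusters > n_features:
        raise ValueError(
            f"n_clusters must be in (0, n_features]; got {n_clusters} of {n_features}"
        )
    return 1.0 - n_clusters / n_features


def functional_fcr(n_clustered_orfs: int, n_ssos: int) -> float:
    """FCR over clustered ORFs only.

    The caller must already have excluded unclustered ORFs from
    ``n_clustered_orfs``: 1100 total ORFs of which 1000 cluster into 100
    SSOs gives 1 − 100/1000 = 0.9.
    """
    return fcr(n_clustered_orfs, n_ssos)


def format_fcr_percent(ratio: float, decimals: int = 1) -> str:
    """Render an FCR as a percent string, rounding half-even (``'77.9%'``)."""
    quant = np.round(ratio * 100.0, decimals)
    return f"{quant:.{decimals}f}%"


def aggregate_taxon_features(
    slc_counts: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate SLC-level counts by a coarser taxon label.

    Used to group prokaryotic SLCs by genus and viral SLCs by order-level
    classification before network analysis; requires a total label map.
    """
    return aggregate_counts(slc_counts, labels, drop_ungrouped=False)
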