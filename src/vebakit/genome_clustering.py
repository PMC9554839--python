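"""Species-level clustering of genomes and orthogroup bookkeeping.

Genomes become nodes of a graph whose edges are pairwise average nucleotide
identity (ANI) values; keeping only edges at or above a threshold (default
95%, the conventional species boundary) and taking connected components
yields species-level clusters (SLC).  Per-domain cluster-id prefixes are
PSLC / ESLC / VSLC.  Proteins are partitioned by SLC so orthogroup detection
can run per-SLC panproteome, and the resulting SLC-specific orthogroups
(SSO) get globally unique namespaced ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ANIEdge",
    "ClusterMap",
    "cluster_slc",
    "partition_proteins_by_slc",
    "assign_sso_ids",
    "marker_matrix_filter",
]


@dataclass(frozen=True)
class ANIEdge:
    """Pairwise ANI between two genomes, percent identity in [0, 100].

    Interpretation is symmetric; asymmetric pairs (a→b vs b→a, as emitted by
    ANI tools) are symmetrized by the maximum during clustering.
    """

    genome_a: str
    genome_b: str
    ani: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ani <= 100.0:
            raise ValueError(f"ANI {self.ani} outside [0,100]")


@dataclass(frozen=True)
class ClusterMap:
    """Total feature -> cluster assignment with deterministic dense ids."""

    assignments: Mapping[str, str]
    prefix: str = ""

    def members(self, cluster_id: str) -> list[str]:
        return sorted(f for f, c in self.assignments.items() if c == cluster_id)

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["feature_id", "cluster_id"]
        )


def cluster_slc(
    genomes: Sequence[str],
    edges: Sequence[ANIEdge],
    threshold: float = 95.0,
    prefix: str = "PSLC",
) -> ClusterMap:
    """Connected-component species-level clustering at an ANI threshold.

    Every listed genome appears in the result; isolated genomes become
    singleton clusters.  Cluster ids are assigned by descending cluster size,
    then by lexicographically smallest member, numbered from 0 (``PSLC0``,
    ``PSLC1``, ...), so ids are deterministic.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold {threshold} outside (0,100]")
    genome_set = set(genomes)
    if len(genome_set) != len(genomes):
        raise ValueError("duplicate genome ids")
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    for e in edges:
        if e.genome_a not in genome_set or e.genome_b not in genome_set:
            raise ValueError(f"edge references unknown genome: {e.genome_a}–{e.genome_b}")
        if e.genome_a == e.genome_b:
            continue  # self-edges ignored
        # symmetrize asymmetric pairs by the maximum
        prev = graph.get_edge_data(e.genome_a, e.genome_b, default=None)
        ani = e.ani if prev is None else max(e.ani, prev["ani"])
        graph.add_edge(e.genome_a, e.genome_b, ani=ani)
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes)
    kept.add_edges_from(
        (a, b) for a, b, d in graph.edges(data=True) if d["ani"] >= threshold
    )
    components = [sorted(c) for c in nx.connected_components(kept)]
    components.sort(key=lambda c: (-len(c), c[0]))
    assignments = {
        genome: f"{prefix}{i}" for i, comp in enumerate(components) for genome in comp
    }
    return ClusterMap(assignments=assignments, prefix=prefix)


def partition_proteins_by_slc(
    protein_to_genome: Mapping[str, str], cluster_map: ClusterMap
) -> dict[str, list[str]]:
    """Group proteins by the SLC of their source genome (a disjoint cover)."""
    partition: dict[str, list[str]] = {}
    for protein, genome in sorted(protein_to_genome.items()):
        cluster = cluster_map.assignments.get(genome)
        if cluster is None:
            raise ValueError(f"protein {protein!r}: genome {genome!r} not clustered")
        partition.setdefault(cluster, []).append(protein)
    return partition


def assign_sso_ids(
    orthogroups: Mapping[str, Mapping[str, str]],
) -> tuple[dict[str, str], list[str]]:
    """Namespace per-SLC orthogroup labels into globally unique SSO ids.

    ``orthogroups`` maps cluster id -> (protein -> local orthogroup label);
    the SSO id is ``cluster_id + "_" + local label``.  Returns
    ``(protein -> SSO id, proteins flagged unclustered)``; unclustered
    proteins (local label ``None``) are excluded — only proteins in SSOs
    participate in functional feature compression.
    """
    sso_ids: dict[str, str] = {}
    unclustered: list[str] = []
    for cluster_id in sorted(orthogroups):
        local = orthogroups[cluster_id]
        label_owner: dict[str, str] = {}
        for protein in sorted(local):
            label = local[protein]
            if label is None:
                unclustered.append(protein)
                continue
            label_owner.setdefault(label, protein)
            if protein in sso_ids:
                raise ValueError(f"protein {protein!r} appears in multiple SLCs")
            sso_ids[protein] = f"{cluster_id}_{label}"
    return sso_ids, unclustered


def marker_matrix_filter(
    presence: pd.DataFrame,
    min_markers_ratio: float,
    min_genomes_ratio: float,
) -> tuple[list, list]:
    """Filter a genomes × markers presence matrix for phylogeny input.

    First drop non-informative markers present in fewer than
    ``min_genomes_ratio`` of genomes, then drop poor-quality genomes holding
    fewer than ``min_markers_ratio`` of the *retained* markers (one pass, no
    iteration to a fixpoint).  Returns ``(kept genome index, kept marker
    columns)``.
    """
    for name, ratio in (("min_markers_ratio", min_markers_ratio),
                        ("min_genomes_ratio", min_genomes_ratio)):
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"{name} {ratio} outside [0,1]")
    if presence.size == 0:
        raise ValueError("empty presence matrix")
    mat = presence.astype(bool)
    marker_prevalence = mat.mean(axis=0)
    kept_markers = [m for m in mat.columns if marker_prevalence[m] >= min_genomes_ratio]
    if kept_markers:
        genome_coverage = mat[kept_markers].mean(axis=1)
    else:
        genome_coverage = pd.Series(0.0, index=mat.index)
    kept_genomes = [g for g in mat.index if genome_coverage[g] >= min_markers_ratio]
    return kept_genomes, kept_markers
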