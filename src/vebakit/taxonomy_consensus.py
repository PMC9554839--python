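"""Leniency-weighted consensus taxonomy for genomes and genome clusters.

A genome's proteins each come with a lineage hit (an ordered list of taxon
labels, coarse to fine) and an alignment score (bitscore or percent
identity).  Consensus classification accumulates score mass over every
lineage *prefix* observed among the hits, weighting level-``i`` prefixes by a
scaling factor s_i determined by the leniency parameter, and assigns the
genome to the highest-scoring prefix.

The scaling factors here are ``s_i = i**(1/leniency)`` for levels
``i = 1..N``: leniency 1 rewards depth linearly (1, 2, 3, ...), while large
leniency flattens the array toward all-ones so coarse ranks — backed by the
sum of all their descendants' scores — win.  High leniency therefore yields
higher-order (shallower) taxonomic assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ProteinTaxonHit",
    "ConsensusAssignment",
    "leniency_weights",
    "consensus_genome_classification",
    "consensus_cluster_classification",
    "consensus_habitat",
]


@dataclass(frozen=True)
class ProteinTaxonHit:
    """One protein's best lineage hit.

    ``lineage`` runs from coarsest (level 1) to finest level; ``score`` is a
    non-negative alignment score.  ``marker_id`` links the hit to an optional
    marker-specific noise cutoff.
    """

    protein_id: str
    genome_id: str
    lineage: tuple[str, ...]
    score: float
    marker_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.lineage) == 0:
            raise ValueError(f"empty lineage for protein {self.protein_id!r}")
        if self.score < 0:
            raise ValueError(f"negative score for protein {self.protein_id!r}")


@dataclass(frozen=True)
class ConsensusAssignment:
    genome_id: str
    lineage_prefix: tuple[str, ...]
    level: int
    score: float
    score_table: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    classified: bool = True

    @property
    def lineage_string(self) -> str:
        return ";".join(self.lineage_prefix)


def leniency_weights(n_levels: int, leniency: float) -> np.ndarray:
    """Scaling factors ``s_i = i**(1/leniency)`` for levels ``i = 1..n_levels``.

    Strictly increasing in ``i`` and flattening toward all-ones as
    ``leniency -> inf``.
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if not leniency > 0:
        raise ValueError(f"leniency must be positive, got {leniency}")
    levels = np.arange(1, n_levels + 1, dtype=float)
    return levels ** (1.0 / leniency)


def _prefix_scores(
    hits: Sequence[ProteinTaxonHit], leniency: float
) -> dict[tuple[str, ...], float]:
    n_levels = max(len(h.lineage) for h in hits)
    weights = leniency_weights(n_levels, leniency)
    table: dict[tuple[str, ...], float] = {}
    for h in hits:
        for i in range(1, len(h.lineage) + 1):
            prefix = tuple(h.lineage[:i])
            table[prefix] = table.get(prefix, 0.0) + h.score * weights[i - 1]
    return table


def consensus_genome_classification(
    hits: Sequence[ProteinTaxonHit],
    leniency: float = 1.0,
    score_cutoffs: Optional[Mapping[str, float]] = None,
    genome_id: Optional[str] = None,
) -> ConsensusAssignment:
    """Assign a genome to the highest-scoring weighted lineage prefix.

    Hits whose score falls below their marker's noise cutoff (when
    ``score_cutoffs`` is supplied and the marker is listed) are discarded
    first.  If nothing survives, the result is flagged unclassified rather
    than raising.

    Ties in the argmax are broken toward the deeper prefix, then
    lexicographically.
    """
    if genome_id is None:
        genome_id = hits[0].genome_id if hits else ""
    if score_cutoffs is not None:
        hits = [
            h
            for h in hits
            if h.marker_id is None
            or h.marker_id not in score_cutoffs
            or h.score >= score_cutoffs[h.marker_id]
        ]
    if len(hits) == 0:
        return ConsensusAssignment(
            genome_id=genome_id,
            lineage_prefix=(),
            level=0,
            score=0.0,
            classified=False,
        )
    table = _prefix_scores(hits, leniency)
    # deepest wins on score ties, then lexicographic
    best = max(table.items(), key=lambda kv: (kv[1], len(kv[0]), _neg_lex(kv[0])))
    return ConsensusAssignment(
        genome_id=genome_id,
        lineage_prefix=best[0],
        level=len(best[0]),
        score=best[1],
        score_table=table,
    )


class _neg_lex:
    """Order-reversing wrapper so lexicographically-first wins under max()."""

    __slots__ = ("value",)

    def __init__(self, value: tuple[str, ...]) -> None:
        self.value = value

    def __lt__(self, other: "_neg_lex") -> bool:
        return self.value > other.value

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_lex) and self.value == other.value


def consensus_cluster_classification(
    genome_hits: Mapping[str, Sequence[ProteinTaxonHit]],
    cluster_assignments: Mapping[str, str],
    leniency: float = 1.0,
    score_cutoffs: Optional[Mapping[str, float]] = None,
    mode: str = "pool",
) -> dict[str, ConsensusAssignment]:
    """Consensus lineage per genome cluster.

    ``mode='pool'`` (default) pools the protein hits of all member genomes
    and classifies the pooled table.  ``mode='vote'`` classifies each member
    genome first and lets the member assignments vote with unit score.
    """
    if mode not in ("pool", "vote"):
        raise ValueError(f"unknown mode {mode!r}")
    clusters: dict[str, list[str]] = {}
    for genome_id, cluster_id in cluster_assignments.items():
        clusters.setdefault(cluster_id, []).append(genome_id)
    results: dict[str, ConsensusAssignment] = {}
    for cluster_id, members in sorted(clusters.items()):
        if not members:
            raise ValueError(f"empty cluster {cluster_id!r}")
        if mode == "pool":
            pooled = [h for g in members for h in genome_hits.get(g, ())]
            results[cluster_id] = consensus_genome_classification(
                pooled, leniency=leniency, score_cutoffs=score_cutoffs,
                genome_id=cluster_id,
            )
        else:
            ballots = []
            for g in members:
                a = consensus_genome_classification(
                    genome_hits.get(g, ()), leniency=leniency,
                    score_cutoffs=score_cutoffs, genome_id=g,
                )
                if a.classified:
                    ballots.append(
                        ProteinTaxonHit(
                            protein_id=g, genome_id=cluster_id,
                            lineage=a.lineage_prefix, score=1.0,
                        )
                    )
            results[cluster_id] = consensus_genome_classification(
                ballots, leniency=leniency, genome_id=cluster_id
            )
    return results


def consensus_habitat(
    member_habitats: Sequence[Optional[str]],
) -> tuple[Optional[str], float, bool]:
    """Plurality habitat vote over cluster members.

    Returns ``(label, support, tie)`` with support = count / non-missing
    total.  Missing labels (``None``) are excluded from the vote; ties go to
    the lexicographically first label with the tie flag set.  If every label
    is missing the result is ``(None, 0.0, False)``.
    """
    votes = [h for h in member_habitats if h is not None]
    if len(member_habitats) == 0:
        raise ValueError("empty habitat list")
    if not votes:
        return (None, 0.0, False)
    counts: dict[str, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    winners = sorted(label for label, c in counts.items() if c == top)
    return (winners[0], top / len(votes), len(winners) > 1)
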