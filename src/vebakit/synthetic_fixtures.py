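"""Seeded synthetic-fixture generators for every input the toolkit consumes.

Each generator is a pure function of its :class:`FixtureSpec` (seed
included), so fixtures are reproducible and the whole pipeline is testable
without downloads.  The statistical conventions — log-normal contig lengths
and abundances, Dirichlet domain-probability vectors, latent-factor
correlated feature pairs — emulate the shapes of real metagenomic inputs,
not their full complexity; they make planted structure recoverable, which is
what the consuming tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ContigRecord
from .genome_clustering import ANIEdge
from .taxonomy_consensus import ProteinTaxonHit

__all__ = [
    "FixtureSpec",
    "make_contig_set",
    "make_ani_fixture",
    "make_counts_fixture",
    "make_annotation_fixture",
]

DOMAIN_CATEGORIES = ("archaea", "bacteria", "eukarya", "organelle", "unknown")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted structure shared by the generators.

    The defaults describe a small but non-trivial community: a handful of
    genomes per species cluster with within-cluster ANI well above and
    between-cluster ANI well below the species threshold, contig lengths
    log-normal around a few kb, strongly concentrated domain probabilities,
    and, for counts, 40 samples per condition at a fixed sequencing depth.
    """

    seed: int = 0
    n_samples: int = 40
    n_genomes: int = 12
    n_contigs_per_genome: int = 10
    n_features: int = 20
    n_clusters: int = 3
    # contig lengths ~ lognormal(mean log bp, sigma)
    length_log_mean: float = 8.0
    length_log_sigma: float = 0.7
    # domain mixture: weight per category in DOMAIN_CATEGORIES order
    domain_weights: tuple[float, ...] = (0.0, 0.7, 0.3, 0.0, 0.0)
    dirichlet_concentration: float = 50.0
    # ANI ranges (percent): within-cluster strictly above between-cluster
    within_ani: tuple[float, float] = (96.0, 99.0)
    between_ani: tuple[float, float] = (80.0, 90.0)
    between_edge_fraction: float = 0.5
    # counts fixture
    sequencing_depth: int = 100_000
    latent_correlation: float = 0.9
    baseline_correlation: float = 0.0  # planted-pair correlation in condition B
    n_planted_pairs: int = 1
    abundance_log_sigma: float = 1.0
    # annotation fixture
    lineage_depth: int = 5
    n_hits: int = 50
    contamination_fraction: float = 0.1
    contamination_level: int = 4

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genomes", "n_contigs_per_genome",
                     "n_features", "n_clusters", "n_hits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.domain_weights) - 1.0) > 1e-9:
            raise ValueError("domain_weights must sum to 1")
        for name in ("latent_correlation", "baseline_correlation"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [-1,1]")
        if self.lineage_depth < 2:
            raise ValueError("lineage_depth must be >= 2")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction outside [0,1]")


def make_contig_set(
    spec: FixtureSpec,
    sample_id: str = "S1",
) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Contigs with planted domains plus their domain-probability table.

    Lengths are log-normal; each contig's planted domain is drawn from
    ``spec.domain_weights`` and its probability vector from a Dirichlet
    concentrated on that domain (one-hot in the infinite-concentration
    limit).  The probability table carries a ``planted_domain`` column for
    oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genomes * spec.n_contigs_per_genome
    lengths = np.maximum(
        rng.lognormal(spec.length_log_mean, spec.length_log_sigma, size=n), 1.0
    ).astype(int)
    planted = rng.choice(len(DOMAIN_CATEGORIES), size=n, p=spec.domain_weights)
    contigs = []
    rows = []
    for i in range(n):
        contig_id = f"{sample_id}_contig{i}"
        contigs.append(
            ContigRecord(contig_id=contig_id, sample_id=sample_id, length=int(lengths[i]))
        )
        alpha = np.ones(len(DOMAIN_CATEGORIES))
        alpha[planted[i]] += spec.dirichlet_concentration
        probs = rng.dirichlet(alpha)
        rows.append(
            {"contig_id": contig_id,
             **dict(zip(DOMAIN_CATEGORIES, probs)),
             "planted_domain": DOMAIN_CATEGORIES[planted[i]]}
        )
    return contigs, pd.DataFrame(rows).set_index("contig_id")


def make_ani_fixture(
    spec: FixtureSpec,
) -> tuple[list[str], list[ANIEdge], dict[str, int]]:
    """Genomes and an ANI edge list with planted species clusters.

    Within-cluster pairs get ANI in ``spec.within_ani``, a random subset of
    between-cluster pairs ANI in ``spec.between_ani``; the ranges must not
    overlap, so the planted partition is recoverable exactly at any
    threshold separating them.  Returns ``(genomes, edges, planted labels)``.
    """
    lo_w, hi_w = spec.within_ani
    lo_b, hi_b = spec.between_ani
    if lo_w <= hi_b:
        raise ValueError("within-cluster ANI range must lie strictly above between-cluster")
    rng = np.random.default_rng(spec.seed)
    genomes: list[str] = []
    planted: dict[str, int] = {}
    per_cluster = max(1, spec.n_genomes // spec.n_clusters)
    g = 0
    for k in range(spec.n_clusters):
        size = per_cluster if k < spec.n_clusters - 1 else spec.n_genomes - g
        for _ in range(size):
            name = f"G{g:03d}"
            genomes.append(name)
            planted[name] = k
            g += 1
    edges: list[ANIEdge] = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            a, b = genomes[i], genomes[j]
            if planted[a] == planted[b]:
                edges.append(ANIEdge(a, b, float(rng.uniform(lo_w, hi_w))))
            elif rng.random() < spec.between_edge_fraction:
                edges.append(ANIEdge(a, b, float(rng.uniform(lo_b, hi_b))))
    return genomes, edges, planted


def make_counts_fixture(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Two condition counts matrices with planted proportional feature pairs.

    Per-feature log abundances are Gaussian; each planted pair shares a
    latent factor with correlation ``spec.latent_correlation`` in condition A
    and ``spec.baseline_correlation`` (default 0: independent) in condition
    B.  Compositions are closed to ``spec.sequencing_depth`` reads per sample
    via multinomial sampling.  Returns ``(counts_a, counts_b, planted pairs)``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_features
    if 2 * spec.n_planted_pairs > m:
        raise ValueError("too many planted pairs for the feature count")
    features = [f"F{i:03d}" for i in range(m)]
    pairs = [(features[2 * k], features[2 * k + 1]) for k in range(spec.n_planted_pairs)]
    base_log_mean = rng.normal(0.0, 1.0, size=m)

    def _condition(r: float) -> pd.DataFrame:
        z = rng.normal(0.0, 1.0, size=(spec.n_samples, m))
        if r != 0.0:
            for (fa, fb) in pairs:
                ia, ib = features.index(fa), features.index(fb)
                shared = z[:, ia]
                z[:, ib] = r * shared + float(np.sqrt(max(0.0, 1 - r * r))) * rng.normal(
                    0.0, 1.0, size=spec.n_samples
                )
        log_abund = base_log_mean[None, :] + spec.abundance_log_sigma * z
        props = np.exp(log_abund)
        props /= props.sum(axis=1, keepdims=True)
        counts = np.vstack(
            [rng.multinomial(spec.sequencing_depth, p) for p in props]
        )
        return pd.DataFrame(
            counts,
            index=[f"sample{i:02d}" for i in range(spec.n_samples)],
            columns=features,
        )

    return _condition(spec.latent_correlation), _condition(spec.baseline_correlation), pairs


def make_annotation_fixture(
    spec: FixtureSpec,
    genome_id: str = "genomeA",
) -> tuple[list[ProteinTaxonHit], tuple[str, ...]]:
    """Protein lineage hits with a planted consensus lineage.

    The majority of hits (by score mass) follow the planted lineage to full
    depth; a ``contamination_fraction`` of hits diverge at
    ``contamination_level`` (1-based, coarse to fine).  The planted lineage
    is recoverable at leniency 1.  Returns ``(hits, planted lineage)``.
    """
    rng = np.random.default_rng(spec.seed)
    depth = spec.lineage_depth
    planted = tuple(f"rank{i}_taxonA" for i in range(1, depth + 1))
    div_level = min(max(spec.contamination_level, 2), depth)
    contaminant = planted[: div_level - 1] + tuple(
        f"rank{i}_taxonB" for i in range(div_level, depth + 1)
    )
    hits: list[ProteinTaxonHit] = []
    for i in range(spec.n_hits):
        is_contaminant = rng.random() < spec.contamination_fraction
        lineage = contaminant if is_contaminant else planted
        score = float(rng.uniform(50.0, 150.0))
        hits.append(
            ProteinTaxonHit(
                protein_id=f"{genome_id}_p{i:03d}",
                genome_id=genome_id,
                lineage=lineage,
                score=score,
            )
        )
    return hits, planted
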