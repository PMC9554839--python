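"""Genome- and contig-level quality gates.

Prokaryotic MAGs pass on completeness/contamination estimates (with a CPR
re-assessment hook so basal bacteria whose single-copy marker sets understate
completeness are not discarded prematurely), eukaryotic bins on total genome
size, viral contigs on a four-criterion scheme following CheckV-style author
recommendations, and contigs on a plain length filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "QualityAssessment",
    "ViralAssessment",
    "FilterResult",
    "PRESETS",
    "filter_prokaryotic",
    "cpr_adjust",
    "filter_viral",
    "filter_eukaryotic_bins",
    "filter_contigs_by_length",
]

_VALID_TIERS = frozenset({"complete", "high", "medium", "low", "not-determined"})
_PASSING_TIERS = frozenset({"complete", "high", "medium"})


@dataclass(frozen=True)
class QualityAssessment:
    """Completeness/contamination estimate for one genome, in percent."""

    genome_id: str
    completeness: float
    contamination: float
    marker_set: str = "default"

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"completeness {self.completeness} outside [0,100] for {self.genome_id!r}"
            )
        if self.contamination < 0:
            raise ValueError(f"negative contamination for {self.genome_id!r}")


@dataclass(frozen=True)
class ViralAssessment:
    contig_id: str
    n_viral_genes: int
    n_host_genes: int
    completeness: float
    quality_tier: str
    miuvig_tier: str
    is_provirus: bool = False
    candidate_p: float = 0.0

    def __post_init__(self) -> None:
        if self.n_viral_genes < 0 or self.n_host_genes < 0:
            raise ValueError(f"negative gene count for {self.contig_id!r}")
        for tier in (self.quality_tier, self.miuvig_tier):
            if tier not in _VALID_TIERS:
                raise ValueError(f"unknown quality tier {tier!r} for {self.contig_id!r}")


@dataclass(frozen=True)
class FilterResult:
    passed: tuple[str, ...]
    failed: tuple[str, ...]


# Default gate removes completeness <= 50 or contamination > 10; the
# high-quality preset keeps completeness >= 70 and contamination < 2.
PRESETS: dict[str, dict] = {
    "default": dict(
        min_completeness=50.0,
        max_contamination=10.0,
        completeness_inclusive=False,
        contamination_inclusive=True,
    ),
    "high_quality": dict(
        min_completeness=70.0,
        max_contamination=2.0,
        completeness_inclusive=True,
        contamination_inclusive=False,
    ),
}


def filter_prokaryotic(
    assessments: Sequence[QualityAssessment],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    completeness_inclusive: bool = False,
    contamination_inclusive: bool = True,
) -> FilterResult:
    """Partition genomes into pass/fail on completeness and contamination.

    With the defaults a genome passes iff completeness > 50 and
    contamination <= 10 (i.e. removal when completeness <= 50 and/or
    contamination > 10).  Boundary strictness is configurable because the
    two boundary conventions both appear in the field; the ``high_quality``
    preset in :data:`PRESETS` gives completeness >= 70 and contamination < 2.
    """
    if not 0.0 <= min_completeness <= 100.0:
        raise ValueError(f"min_completeness {min_completeness} outside [0,100]")
    if max_contamination < 0:
        raise ValueError(f"negative max_contamination {max_contamination}")
    passed, failed = [], []
    for qa in assessments:
        comp_ok = (
            qa.completeness >= min_completeness
            if completeness_inclusive
            else qa.completeness > min_completeness
        )
        cont_ok = (
            qa.contamination <= max_contamination
            if contamination_inclusive
            else qa.contamination < max_contamination
        )
        (passed if comp_ok and cont_ok else failed).append(qa.genome_id)
    return FilterResult(tuple(passed), tuple(failed))


def cpr_adjust(
    assessments: Sequence[QualityAssessment],
    classifications: Mapping[str, str],
    cpr_lineages: Iterable[str] = ("Patescibacteria",),
    cpr_provider: Optional[Callable[[str], QualityAssessment]] = None,
    **filter_kwargs,
) -> tuple[list[QualityAssessment], FilterResult, dict[str, str]]:
    """Re-assess CPR genomes with the appropriate marker set, then refilter.

    Genomes whose lineage string contains any of ``cpr_lineages`` get
    replacement completeness/contamination scores from ``cpr_provider`` (an
    adapter keyed by genome id, standing in for a CPR-specific assessment
    workflow); the standard prokaryotic filter is then re-applied to the full
    set.  Non-CPR genomes are untouched.

    Returns ``(updated assessments, refiltered partition, per-genome errors)``;
    an adapter failure is recorded per genome while the rest proceed.
    """
    tokens = tuple(cpr_lineages)
    updated: list[QualityAssessment] = []
    errors: dict[str, str] = {}
    for qa in assessments:
        lineage = classifications.get(qa.genome_id, "")
        if any(tok in lineage for tok in tokens):
            if cpr_provider is None:
                errors[qa.genome_id] = "no CPR provider configured"
                updated.append(qa)
                continue
            try:
                adjusted = cpr_provider(qa.genome_id)
            except Exception as exc:  # adapter contract: record, keep going
                errors[qa.genome_id] = str(exc)
                updated.append(qa)
                continue
            updated.append(
                replace(
                    qa,
                    completeness=adjusted.completeness,
                    contamination=adjusted.contamination,
                    marker_set="CPR",
                )
            )
        else:
            updated.append(qa)
    return updated, filter_prokaryotic(updated, **filter_kwargs), errors


def filter_viral(
    assessments: Sequence[ViralAssessment],
    candidate_alpha: float = 0.05,
    include_proviruses: bool = False,
) -> FilterResult:
    """Four-criterion viral contig filter plus the candidate p-value gate.

    A contig passes iff candidate_p < candidate_alpha, viral genes >= 5x host
    genes, completeness >= 50%, and both the assessment quality tier and the
    MIUViG tier are medium/high/complete; proviruses are excluded unless
    ``include_proviruses`` is set.
    """
    passed, failed = [], []
    for va in assessments:
        ok = (
            va.candidate_p < candidate_alpha
            and va.n_viral_genes >= 5 * va.n_host_genes
            and va.completeness >= 50.0
            and va.quality_tier in _PASSING_TIERS
            and va.miuvig_tier in _PASSING_TIERS
            and (not va.is_provirus or include_proviruses)
        )
        (passed if ok else failed).append(va.contig_id)
    return FilterResult(tuple(passed), tuple(failed))


def filter_eukaryotic_bins(
    bin_sizes: Mapping[str, int], min_genome_size: int = 2_000_000
) -> FilterResult:
    """Keep bins whose total size reaches ``min_genome_size`` bp (inclusive)."""
    passed, failed = [], []
    for bin_id, size in bin_sizes.items():
        if size < 0:
            raise ValueError(f"negative size for bin {bin_id!r}")
        (passed if size >= min_genome_size else failed).append(bin_id)
    return FilterResult(tuple(passed), tuple(failed))


def filter_contigs_by_length(contigs, min_length: int = 1500):
    """Retain contigs with length >= ``min_length`` bp (inclusive boundary).

    Accepts :class:`~vebakit.core_io.ContigRecord` objects or anything with a
    ``length`` attribute; returns the retained items in input order.
    """
    return [c for c in contigs if c.length >= min_length]
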