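"""Identifier schemes, naming conventions, file plumbing and assembly statistics.

This module holds the conventions every other part of the toolkit relies on:
the canonical genome (MAG) naming scheme per domain, simplified eukaryotic
gene identifiers, a harmonized GFF3 dialect usable for feature counting, the
contig–MAG–SLC / ORF–SSO identifier-map bookkeeping, and standard assembly
statistics (N50, GC fraction, coding density).

Genome names follow one scheme per domain tag:

* prokaryotic:  ``[SampleID]_[Algorithm]_P.[Iteration]_[Name]``
* eukaryotic:   ``[SampleID]_[Algorithm]_E.[Iteration]_[Name]``
* viral:        ``[SampleID]_[Algorithm]_[Name]``

Sample id and algorithm may not contain the ``_`` separator so that names
always parse back losslessly; the local name may (e.g. ``bin.1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ContigRecord",
    "GenomeName",
    "IdentifierMap",
    "render_genome_name",
    "parse_genome_name",
    "GeneIdSimplifier",
    "simplify_eukaryotic_gene_id",
    "harmonize_gene_models",
    "assembly_stats",
    "n50",
    "gc_fraction",
]

_DOMAIN_TAGS = ("P", "E", "V")
_ITER_TAG_RE = re.compile(r"^([PE])\.(\d+)$")


@dataclass(frozen=True)
class ContigRecord:
    """A contig flowing through the binning procedure.

    ``length`` is in bp; if ``sequence`` is present its length must equal
    ``length``.
    """

    contig_id: str
    sample_id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative contig length: {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != length field {self.length} "
                f"for contig {self.contig_id!r}"
            )


@dataclass(frozen=True)
class GenomeName:
    """Structured form of a MAG name; round-trips through render/parse."""

    sample_id: str
    algorithm: str
    domain_tag: str
    iteration: Optional[int]
    local_name: str


def _check_component(value: str, what: str, allow_sep: bool = False) -> None:
    if not value:
        raise ValueError(f"empty {what} in genome name")
    if not allow_sep and "_" in value:
        raise ValueError(f"{what} {value!r} contains reserved separator '_'")


def render_genome_name(name: GenomeName) -> str:
    """Render the canonical string for a :class:`GenomeName`.

    Examples
    --------
    >>> render_genome_name(GenomeName("SRR17458623", "METABAT2", "P", 1, "bin.1"))
    'SRR17458623_METABAT2_P.1_bin.1'
    >>> render_genome_name(GenomeName("SRR9668957", "VIRFINDER", "V", None, "Virus.1"))
    'SRR9668957_VIRFINDER_Virus.1'
    """
    if name.domain_tag not in _DOMAIN_TAGS:
        raise ValueError(f"unknown domain tag {name.domain_tag!r}")
    _check_component(name.sample_id, "sample_id")
    _check_component(name.algorithm, "algorithm")
    _check_component(name.local_name, "local_name", allow_sep=True)
    if name.domain_tag in ("P", "E"):
        if name.iteration is None:
            raise ValueError(f"iteration required for domain tag {name.domain_tag}")
        if name.iteration < 1:
            raise ValueError(f"iteration must be positive, got {name.iteration}")
        return (
            f"{name.sample_id}_{name.algorithm}_"
            f"{name.domain_tag}.{name.iteration}_{name.local_name}"
        )
    # viral: no iteration tag
    if name.iteration is not None:
        raise ValueError("viral genome names carry no iteration")
    if _ITER_TAG_RE.match(name.local_name.split("_", 1)[0]):
        # would be indistinguishable from a P/E name on parse
        raise ValueError(
            f"viral local name {name.local_name!r} mimics an iteration tag"
        )
    return f"{name.sample_id}_{name.algorithm}_{name.local_name}"


def parse_genome_name(rendered: str) -> GenomeName:
    """Invert :func:`render_genome_name`; raises ``ValueError`` on malformed input."""
    parts = rendered.split("_")
    if len(parts) < 3:
        raise ValueError(f"not a genome name: {rendered!r}")
    sample_id, algorithm = parts[0], parts[1]
    _check_component(sample_id, "sample_id")
    _check_component(algorithm, "algorithm")
    m = _ITER_TAG_RE.match(parts[2])
    if m:
        if len(parts) < 4:
            raise ValueError(f"missing local name in {rendered!r}")
        return GenomeName(
            sample_id=sample_id,
            algorithm=algorithm,
            domain_tag=m.group(1),
            iteration=int(m.group(2)),
            local_name="_".join(parts[3:]),
        )
    return GenomeName(
        sample_id=sample_id,
        algorithm=algorithm,
        domain_tag="V",
        iteration=None,
        local_name="_".join(parts[2:]),
    )


class GeneIdSimplifier:
    """Emit simplified eukaryotic gene identifiers, guaranteed duplicate-free.

    The template is ``[ContigID]_[GeneStart]:[GeneEnd]([strand])``; a second
    emission of the exact same coordinates gets a ``.k`` suffix with k the
    1-based duplicate ordinal.
    """

    def __init__(self) -> None:
        self._counts: dict[str, int] = {}

    def simplify(self, contig_id: str, start: int, end: int, strand: str) -> str:
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand {strand!r}")
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        base = f"{contig_id}_{start}:{end}({strand})"
        seen = self._counts.get(base, 0)
        self._counts[base] = seen + 1
        if seen == 0:
            return base
        candidate = f"{base}.{seen}"
        # suffixed form could itself collide with an explicitly emitted id
        while candidate in self._counts:
            seen += 1
            self._counts[base] = seen + 1
            candidate = f"{base}.{seen}"
        self._counts[candidate] = 1
        return candidate


def simplify_eukaryotic_gene_id(
    contig_id: str,
    start: int,
    end: int,
    strand: str,
    simplifier: Optional[GeneIdSimplifier] = None,
) -> str:
    """One-shot wrapper around :class:`GeneIdSimplifier`.

    Pass a shared ``simplifier`` to get duplicate disambiguation across calls;
    without one each call is independent (no duplicates possible).
    """
    if simplifier is None:
        simplifier = GeneIdSimplifier()
    return simplifier.simplify(contig_id, start, end, strand)


_GENE_COLUMNS = ("gene_id", "contig_id", "start", "end", "strand")

#: Attribute key shared by all harmonized records, chosen to match the
#: default grouping key of common feature-counting tools.
GFF_ATTRIBUTE_KEY = "gene_id"


def harmonize_gene_models(
    euk_genes: pd.DataFrame,
    prok_genes: pd.DataFrame,
    contig_lengths: Optional[Mapping[str, int]] = None,
    feature_type: str = "CDS",
) -> str:
    """Merge eukaryotic and prokaryotic gene tables into one GFF3 document.

    Both tables must carry columns ``gene_id, contig_id, start, end, strand``
    with 1-based inclusive coordinates (the GFF3 convention).  Every record
    carries its gene id under the shared ``gene_id`` attribute key plus a
    ``contig_id`` attribute, so a single downstream counting invocation covers
    both domains.

    Returns the GFF3 document as a string (ending in a newline when non-empty).
    """
    frames = [(df, src) for df, src in ((euk_genes, "eukaryotic"), (prok_genes, "prokaryotic"))]
    lines = ["##gff-version 3"]
    seen_ids: set[str] = set()
    for df, source in frames:
        if df is None or len(df) == 0:
            continue
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{source} gene table missing columns {missing}")
        for row in df.itertuples(index=False):
            start, end = int(row.start), int(row.end)
            if start > end:
                raise ValueError(f"gene {row.gene_id!r}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"gene {row.gene_id!r}: GFF3 coordinates are 1-based")
            if contig_lengths is not None and row.contig_id in contig_lengths:
                if end > contig_lengths[row.contig_id]:
                    raise ValueError(
                        f"gene {row.gene_id!r} end {end} exceeds contig "
                        f"{row.contig_id!r} length {contig_lengths[row.contig_id]}"
                    )
            if row.strand not in ("+", "-"):
                raise ValueError(f"gene {row.gene_id!r}: unknown strand {row.strand!r}")
            if row.gene_id in seen_ids:
                raise ValueError(f"duplicate gene id {row.gene_id!r}")
            seen_ids.add(row.gene_id)
            attrs = (
                f"ID={row.gene_id};{GFF_ATTRIBUTE_KEY}={row.gene_id};"
                f"contig_id={row.contig_id}"
            )
            lines.append(
                "\t".join(
                    (
                        str(row.contig_id),
                        source,
                        feature_type,
                        str(start),
                        str(end),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    )
                )
            )
    return "\n".join(lines) + "\n"


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that contigs of length >= L cover half the assembly."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def gc_fraction(sequences: Iterable[str]) -> float:
    """(G+C)/(A+C+G+T) over all sequences; ambiguity codes are ignored."""
    gc = at = 0
    for seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("no unambiguous nucleotides")
    return gc / total


def _union_span_length(spans: Iterable[tuple[int, int]]) -> int:
    # spans are 1-based inclusive; merge overlaps before summing
    merged_len = 0
    cur_start = cur_end = None
    for start, end in sorted(spans):
        if start > end:
            raise ValueError(f"span start {start} > end {end}")
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            merged_len += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        merged_len += cur_end - cur_start + 1
    return merged_len


def assembly_stats(
    lengths: Sequence[int],
    sequences: Optional[Sequence[str]] = None,
    coding_spans: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> dict:
    """Standard assembly quality-control statistics.

    Parameters
    ----------
    lengths:
        Contig lengths in bp (non-empty, all positive).
    sequences:
        Optional nucleotide sequences; enables ``gc_fraction``.
    coding_spans:
        Optional mapping contig id -> list of 1-based inclusive (start, end)
        coding spans; enables ``coding_density`` = union of coding bp / total bp.
    """
    result = {
        "n50": n50(lengths),
        "n_contigs": len(lengths),
        "total_bp": int(sum(lengths)),
        "gc_fraction": None,
        "coding_density": None,
    }
    if sequences is not None:
        result["gc_fraction"] = gc_fraction(sequences)
    if coding_spans is not None:
        coding_bp = sum(_union_span_length(spans) for spans in coding_spans.values())
        result["coding_density"] = coding_bp / result["total_bp"]
    return result


@dataclass
class IdentifierMap:
    """Bidirectional feature↔parent bookkeeping along a feature hierarchy.

    Tiers are ordered coarse-ward, e.g. ``contig→MAG`` then ``MAG→SLC``.
    Every child maps to at most one parent per tier and chains are acyclic,
    so any feature can be traced up the full hierarchy.
    """

    tiers: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def add_tier(self, name: str, mapping: Mapping[str, str]) -> "IdentifierMap":
        child_to_parent = dict(mapping)
        for child, parent in child_to_parent.items():
            if child == parent:
                raise ValueError(f"self-mapping {child!r} in tier {name!r}")
        self.tiers.append((name, child_to_parent))
        self._check_acyclic()
        return self

    def _check_acyclic(self) -> None:
        for start in self.tiers[0][1] if self.tiers else ():
            seen = {start}
            node = start
            for _, mapping in self.tiers:
                if node not in mapping:
                    break
                node = mapping[node]
                if node in seen:
                    raise ValueError(f"cycle through {node!r}")
                seen.add(node)

    def parent(self, feature_id: str, tier: str) -> Optional[str]:
        for name, mapping in self.tiers:
            if name == tier:
                return mapping.get(feature_id)
        raise KeyError(f"unknown tier {tier!r}")

    def children(self, parent_id: str, tier: str) -> list[str]:
        for name, mapping in self.tiers:
            if name == tier:
                return sorted(c for c, p in mapping.items() if p == parent_id)
        raise KeyError(f"unknown tier {tier!r}")

    def lineage(self, feature_id: str) -> list[str]:
        """Trace a feature up through successive tiers, starting from itself."""
        chain = [feature_id]
        node = feature_id
        for _, mapping in self.tiers:
            if node not in mapping:
                break
            node = mapping[node]
            chain.append(node)
        return chain

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature_id": child, "parent_id": parent, "tier": name}
            for name, mapping in self.tiers
            for child, parent in sorted(mapping.items())
        ]
        return pd.DataFrame(rows, columns=["feature_id", "parent_id", "tier"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IdentifierMap":
        imap = cls()
        for tier in frame["tier"].unique():
            sub = frame[frame["tier"] == tier]
            imap.add_tier(tier, dict(zip(sub["feature_id"], sub["parent_id"])))
        return imap
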