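"""Iterative consensus-binning orchestration.

The state machine: run every binning algorithm on the remaining contig pool,
dereplicate the candidate bins into one consensus set, apply the quality
gate, name and accept the survivors with an iteration tag (``P.1``,
``P.2``, ...), remove their contigs from the pool, and feed the unbinned
remainder back in under a fresh random seed.  Contigs of bins that fail the
quality gate are recycled too — a genome that is hard to bin on the first
pass is often easy once its neighbours are out of the way.

Binners, the dereplicator and the QC gate are all pluggable adapters so the
orchestration is testable with synthetic stand-ins and usable with real
external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

from .core_io import ContigRecord, GenomeName, render_genome_name
from .quality_filters import filter_contigs_by_length

__all__ = [
    "BinnerAdapter",
    "IterationRecord",
    "seed_policy",
    "dereplicate_candidate_bins",
    "run_iterative_binning",
    "build_pseudo_coassembly",
    "split_pseudo_contig_id",
]

# Bin assignments are partial maps contig_id -> local bin label.
BinAssignment = Mapping[str, str]


@dataclass(frozen=True)
class BinnerAdapter:
    """A pluggable binning algorithm.

    ``bin_fn(contigs, coverage, seed)`` returns a partial assignment
    contig_id -> bin label over the input contigs; unassigned contigs are
    simply omitted.  Adapters must be deterministic given (inputs, seed).
    """

    name: str
    bin_fn: Callable[[Sequence[ContigRecord], object, int], BinAssignment]

    def bin(self, contigs, coverage, seed: int) -> BinAssignment:
        assignment = self.bin_fn(contigs, coverage, seed)
        pool = {c.contig_id for c in contigs}
        stray = set(assignment) - pool
        if stray:
            raise ValueError(
                f"binner {self.name!r} assigned contigs outside the pool: {sorted(stray)[:5]}"
            )
        return assignment


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    seed: int
    bins_accepted: tuple[str, ...]
    contigs_binned: int
    contigs_remaining: int


_SEED_PRIME = 1_000_003  # large prime offset keeps per-iteration seeds distinct


def seed_policy(base_seed: int, iteration: int) -> int:
    """Deterministic, distinct seed per iteration (kept below 2^31)."""
    if iteration < 1:
        raise ValueError(f"iteration must be >= 1, got {iteration}")
    return (base_seed + iteration * _SEED_PRIME) % (2**31)


def dereplicate_candidate_bins(
    candidates: Mapping[str, BinAssignment],
    scores: Mapping[tuple[str, str], float],
) -> dict[str, tuple[str, str]]:
    """Greedy score-ranked consensus over candidate bins from several binners.

    ``candidates`` maps binner name -> partial contig assignment;
    ``scores`` maps (binner, bin label) -> quality score.  Bins are accepted
    in descending score (ties broken by binner then label for determinism)
    and a bin is accepted only if none of its contigs are already claimed.

    Returns contig_id -> (binner, bin label) for all accepted bins.  This is
    a deliberately naive stand-in for external consensus-dereplication tools,
    which plug in through the same adapter surface.
    """
    bins: dict[tuple[str, str], set[str]] = {}
    for binner, assignment in candidates.items():
        for contig, label in assignment.items():
            bins.setdefault((binner, label), set()).add(contig)
    for key in bins:
        if key not in scores:
            raise ValueError(f"no score for candidate bin {key}")
    claimed: set[str] = set()
    consensus: dict[str, tuple[str, str]] = {}
    for key in sorted(bins, key=lambda k: (-scores[k], k[0], k[1])):
        members = bins[key]
        if members & claimed:
            continue
        claimed |= members
        for contig in members:
            consensus[contig] = key
    return consensus


def run_iterative_binning(
    contigs: Sequence[ContigRecord],
    coverage: object,
    binners: Sequence[BinnerAdapter],
    dereplicator: Callable[[Mapping[str, BinAssignment], Mapping], dict],
    qc: Callable[[str, frozenset], bool],
    n_iter: int = 1,
    base_seed: int = 0,
    sample_id: Optional[str] = None,
    domain_tag: str = "P",
    bin_scorer: Optional[Callable[[str, str, frozenset], float]] = None,
    force_all_iterations: bool = False,
) -> tuple[dict[str, tuple[str, ...]], list[ContigRecord], list[IterationRecord]]:
    """Run the iterative consensus-binning loop.

    Parameters
    ----------
    contigs, coverage:
        The contig pool and an opaque coverage object handed to each binner.
    binners:
        Non-empty list of :class:`BinnerAdapter`.
    dereplicator:
        ``(candidates, scores) -> contig_id -> (binner, label)`` consensus;
        :func:`dereplicate_candidate_bins` is the built-in.
    qc:
        ``(bin_name, frozenset of contig ids) -> bool`` quality gate, applied
        after dereplication and before contig removal so rejected bins'
        contigs recycle into the next iteration.
    bin_scorer:
        Optional ``(binner, label, members) -> score`` for the dereplicator;
        defaults to member count (bigger candidate bins rank first).
    n_iter, base_seed:
        Iteration budget and the base of :func:`seed_policy`.  The loop stops
        early once an iteration accepts zero bins unless
        ``force_all_iterations`` is set.

    Returns
    -------
    (accepted, unbinned, records):
        ``accepted`` maps genome name -> tuple of member contig ids (pairwise
        disjoint); ``unbinned`` is the final remaining pool; ``records`` is
        one :class:`IterationRecord` per executed iteration.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if not binners:
        raise ValueError("at least one binner is required")
    if sample_id is None:
        samples = {c.sample_id for c in contigs}
        if len(samples) == 1:
            sample_id = next(iter(samples))
        else:
            sample_id = "MULTISAMPLE"
    if bin_scorer is None:
        bin_scorer = lambda binner, label, members: float(len(members))

    pool: dict[str, ContigRecord] = {c.contig_id: c for c in contigs}
    if len(pool) != len(contigs):
        raise ValueError("duplicate contig ids in input pool")
    accepted: dict[str, tuple[str, ...]] = {}
    records: list[IterationRecord] = []

    for t in range(1, n_iter + 1):
        seed = seed_policy(base_seed, t)
        remaining = [pool[k] for k in sorted(pool)]
        entering = len(remaining)
        candidates: dict[str, BinAssignment] = {}
        for binner in binners:
            try:
                candidates[binner.name] = binner.bin(remaining, coverage, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"binner {binner.name!r} failed at iteration {t}: {exc}"
                ) from exc
        members_by_bin: dict[tuple[str, str], set[str]] = {}
        for binner_name, assignment in candidates.items():
            for contig, label in assignment.items():
                members_by_bin.setdefault((binner_name, label), set()).add(contig)
        scores = {
            key: bin_scorer(key[0], key[1], frozenset(members))
            for key, members in members_by_bin.items()
        }
        consensus = dereplicator(candidates, scores)

        consensus_bins: dict[tuple[str, str], set[str]] = {}
        for contig, key in consensus.items():
            consensus_bins.setdefault(tuple(key), set()).add(contig)

        accepted_this_iter: list[str] = []
        binned_count = 0
        for (binner_name, label) in sorted(consensus_bins):
            members = frozenset(consensus_bins[(binner_name, label)])
            name = render_genome_name(
                GenomeName(
                    sample_id=sample_id,
                    algorithm=binner_name.upper(),
                    domain_tag=domain_tag,
                    iteration=t,
                    local_name=label,
                )
            )
            if qc(name, members):
                accepted[name] = tuple(sorted(members))
                accepted_this_iter.append(name)
                binned_count += len(members)
                for contig in members:
                    del pool[contig]
        records.append(
            IterationRecord(
                iteration=t,
                seed=seed,
                bins_accepted=tuple(accepted_this_iter),
                contigs_binned=binned_count,
                contigs_remaining=entering - binned_count,
            )
        )
        if not pool:
            break
        if not accepted_this_iter and not force_all_iterations:
            break

    unbinned = [pool[k] for k in sorted(pool)]
    return accepted, unbinned, records


_PSEUDO_SEP = "__"


def build_pseudo_coassembly(
    unbinned_per_sample: Mapping[str, Sequence[ContigRecord]],
    min_length: int = 1500,
) -> list[ContigRecord]:
    """Union of per-sample unbinned contigs forming a pseudo-coassembly.

    Each contig id gets a ``sample__`` prefix so it parses back to its source
    sample (:func:`split_pseudo_contig_id`); contigs below ``min_length`` bp
    are dropped.
    """
    out: list[ContigRecord] = []
    seen: set[str] = set()
    for sample_id in sorted(unbinned_per_sample):
        for contig in filter_contigs_by_length(
            unbinned_per_sample[sample_id], min_length=min_length
        ):
            new_id = f"{sample_id}{_PSEUDO_SEP}{contig.contig_id}"
            if new_id in seen:
                raise ValueError(f"pseudo-coassembly id collision: {new_id!r}")
            seen.add(new_id)
            out.append(
                ContigRecord(
                    contig_id=new_id,
                    sample_id=sample_id,
                    length=contig.length,
                    sequence=contig.sequence,
                )
            )
    return out


def split_pseudo_contig_id(pseudo_id: str) -> tuple[str, str]:
    """Recover ``(sample_id, original contig id)`` from a pseudo-coassembly id."""
    sample_id, sep, original = pseudo_id.partition(_PSEUDO_SEP)
    if not sep:
        raise ValueError(f"not a pseudo-coassembly id: {pseudo_id!r}")
    return sample_id, original
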