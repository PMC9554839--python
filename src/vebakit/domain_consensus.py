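"""Bin-level taxonomic-domain consensus from per-contig predictions.

Eukaryotic binning works best when domain prediction happens at the bin
level rather than per contig: organelles and the odd misclassified contig
get captured by the genome they travel with.  Per-contig prediction
probability vectors (one probability per domain category, e.g. archaea /
bacteria / eukarya / organelle / unknown) are aggregated into bin-level
logits — the (optionally length-weighted) sum of log probabilities — and a
softmax turns the logits back into bin-level probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import softmax as _softmax

__all__ = [
    "ContigDomainPrediction",
    "BinDomainPrediction",
    "aggregate_bin_domain",
    "classify_bins_by_domain",
]

#: Floor applied inside the log so a single zero probability cannot veto a bin.
EPSILON_FLOOR = 1e-10


@dataclass(frozen=True)
class ContigDomainPrediction:
    """Per-contig probability vector over domain categories (sums to 1)."""

    contig_id: str
    probabilities: Mapping[str, float]
    length: Optional[int] = None

    def __post_init__(self) -> None:
        probs = np.asarray(list(self.probabilities.values()), dtype=float)
        if not np.all(np.isfinite(probs)):
            raise ValueError(f"non-finite probability for contig {self.contig_id!r}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"probability outside [0,1] for contig {self.contig_id!r}")
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"probabilities for contig {self.contig_id!r} sum to {probs.sum():.8f}"
            )


@dataclass(frozen=True)
class BinDomainPrediction:
    bin_id: str
    logits: Mapping[str, float]
    probabilities: Mapping[str, float]
    call: str = field(default="")


def aggregate_bin_domain(
    contigs: Sequence[ContigDomainPrediction],
    bin_id: str = "",
    weighting: str = "uniform",
) -> BinDomainPrediction:
    """Aggregate contig probability vectors into a bin-level domain call.

    logit_d = Σ_c w_c · ln(max(p_{c,d}, ε)), then probabilities = softmax(logits)
    and the call is the argmax (ties broken by the category order of the first
    contig's probability mapping).

    ``weighting='length'`` scales each contig's log term by its length divided
    by the mean length, so long contigs dominate; the default is uniform.
    """
    if len(contigs) == 0:
        raise ValueError("empty bin")
    categories = list(contigs[0].probabilities.keys())
    catset = set(categories)
    for c in contigs:
        if set(c.probabilities.keys()) != catset:
            raise ValueError(
                f"category-set mismatch for contig {c.contig_id!r}: "
                f"{sorted(c.probabilities)} vs {sorted(categories)}"
            )
    if weighting == "uniform":
        weights = np.ones(len(contigs))
    elif weighting == "length":
        lengths = np.array([c.length for c in contigs], dtype=float)
        if np.any(np.isnan(lengths)):
            raise ValueError("length weighting requires a length on every contig")
        weights = lengths / lengths.mean()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    prob_matrix = np.array(
        [[c.probabilities[cat] for cat in categories] for c in contigs], dtype=float
    )
    log_probs = np.log(np.maximum(prob_matrix, EPSILON_FLOOR))
    logits = weights @ log_probs
    probs = _softmax(logits)
    call = categories[int(np.argmax(probs))]  # argmax takes first on ties
    return BinDomainPrediction(
        bin_id=bin_id,
        logits=dict(zip(categories, logits.tolist())),
        probabilities=dict(zip(categories, probs.tolist())),
        call=call,
    )


def classify_bins_by_domain(
    bins: Sequence[BinDomainPrediction],
    eukaryote_categories: set[str],
    min_probability: float = 0.5,
) -> dict[str, list[str]]:
    """Partition bins into eukaryotic / prokaryotic / undetermined.

    A bin is eukaryotic when the summed probability over
    ``eukaryote_categories`` (typically eukarya plus organelle, so organelles
    are captured with their host genome) reaches ``min_probability``;
    prokaryotic when the complementary mass does; otherwise undetermined.
    """
    if not eukaryote_categories:
        raise ValueError("empty eukaryote category set")
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError(f"min_probability {min_probability} outside [0,1]")
    partition: dict[str, list[str]] = {
        "eukaryotic": [],
        "prokaryotic": [],
        "undetermined": [],
    }
    for b in bins:
        euk_mass = sum(
            p for cat, p in b.probabilities.items() if cat in eukaryote_categories
        )
        if euk_mass >= min_probability:
            partition["eukaryotic"].append(b.bin_id)
        elif (1.0 - euk_mass) >= min_probability:
            partition["prokaryotic"].append(b.bin_id)
        else:
            partition["undetermined"].append(b.bin_id)
    return partition
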