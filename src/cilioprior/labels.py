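"""Training-label curation.

Positive and negative training partitions are built by cross-filtering
user-supplied source lists against an evidence table of per-gene study
counts (``noe_any`` -- any species; ``noe_human`` -- human studies only).
A candidate benchmark list is held out of training entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["LabelSet", "CurationError", "curate_labels", "partition_sizes"]


class CurationError(ValueError):
    """Raised when curation produces an empty training partition."""


@dataclass(frozen=True)
class LabelSet:
    """Disjoint gene partitions with per-gene provenance tags.

    The four partitions are pairwise disjoint: every labelled gene sits in
    exactly one of ``positives``, ``negatives``, ``held_out_candidates`` or
    ``unknown``.
    """

    positives: frozenset[str]
    negatives: frozenset[str]
    held_out_candidates: frozenset[str] = frozenset()
    unknown: frozenset[str] = frozenset()
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = [
            self.positives,
            self.negatives,
            self.held_out_candidates,
            self.unknown,
        ]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                overlap = parts[i] & parts[j]
                if overlap:
                    raise ValueError(
                        f"label partitions overlap on {sorted(overlap)[:5]}"
                    )
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        object.__setattr__(
            self, "held_out_candidates", frozenset(self.held_out_candidates)
        )
        object.__setattr__(self, "unknown", frozenset(self.unknown))

    @property
    def universe(self) -> frozenset[str]:
        return (
            self.positives
            | self.negatives
            | self.held_out_candidates
            | self.unknown
        )


def _noe_lookup(evidence: pd.DataFrame, column: str) -> Mapping[str, int]:
    if "gene" in evidence.columns:
        ser = evidence.set_index("gene")[column]
    else:
        ser = evidence[column]
    if (ser < 0).any():
        raise ValueError(f"negative counts in evidence column {column!r}")
    return ser.to_dict()


def curate_labels(
    gold_standard: Iterable[str],
    metabolome: Iterable[str],
    housekeeping: Iterable[str],
    candidates: Iterable[str],
    evidence: pd.DataFrame,
    *,
    evidence_column: str = "noe_any",
) -> LabelSet:
    """Cross-filter source lists against evidence counts.

    Rules:

    * genes appearing in both a positive and a negative source list carry
      conflicting annotation and are dropped from both partitions;
    * positive-source genes stay positive only with evidence count >= 1;
    * negative-source genes stay negative only with evidence count == 0
      (absence from the evidence table counts as zero);
    * ``candidates`` are excluded from training and kept as a held-out
      benchmark partition.

    Parameters
    ----------
    evidence:
        Table with a ``gene`` column (or gene index) and the count column
        named by ``evidence_column``.
    evidence_column:
        Which evidence count to use; ``"noe_any"`` (default) or
        ``"noe_human"``.
    """
    gold = set(gold_standard)
    neg_source = set(metabolome) | set(housekeeping)
    cand = set(candidates)
    noe = _noe_lookup(evidence, evidence_column)

    conflicted = gold & neg_source
    positives = {
        g for g in gold - conflicted - cand if noe.get(g, 0) >= 1
    }
    negatives = {
        g for g in neg_source - conflicted - cand if noe.get(g, 0) == 0
    }
    if not positives:
        raise CurationError("curation left an empty positive set")
    if not negatives:
        raise CurationError("curation left an empty negative set")

    metab = set(metabolome)
    provenance: dict[str, str] = {}
    for g in positives:
        provenance[g] = "gold-standard"
    for g in negatives:
        provenance[g] = "metabolome" if g in metab else "housekeeping"
    held_out = cand - positives - negatives
    for g in held_out:
        provenance[g] = "candidate"

    return LabelSet(
        positives=frozenset(positives),
        negatives=frozenset(negatives),
        held_out_candidates=frozenset(held_out),
        provenance=provenance,
    )


def partition_sizes(labelset: LabelSet) -> dict[str, int]:
    """Per-partition counts; values sum to the labelled universe size."""
    counts = {
        "positives": len(labelset.positives),
        "negatives": len(labelset.negatives),
        "held_out_candidates": len(labelset.held_out_candidates),
        "unknown": len(labelset.unknown),
    }
    counts["total"] = len(labelset.universe)
    return counts
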