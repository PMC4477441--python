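"""Validation statistics for ranked gene scores.

ROC / precision-recall summaries, one-tailed rank-sum tests against
evidence bins, the Jonckheere-Terpstra ordinal trend test, the held-out
benchmark flagging fraction, and hypergeometric gene-set enrichment with
Benjamini-Hochberg control.

Both rank tests carry an exact-enumeration path for small samples and a
tie-corrected normal approximation otherwise; the switchover sizes are
arguments so either path can be exercised directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "BinnedScores",
    "EnrichmentResult",
    "roc_auc",
    "precision_recall_curve",
    "wilcoxon_one_tailed",
    "jonckheere_terpstra",
    "bin_by_evidence",
    "benchmark_flagged_fraction",
    "hypergeom_enrichment",
]


# ---------------------------------------------------------------------------
# ROC / PR


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve with ties counted one half.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(scores, method="average")
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def precision_recall_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> pd.DataFrame:
    """Precision and recall at every distinct score threshold.

    A gene is selected when its score is >= the threshold; thresholds are
    the distinct observed scores in descending order, so recall is
    non-decreasing down the table.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)[::-1]
    rows = []
    for t in thresholds:
        selected = scores >= t
        tp = int((labels[selected] == 1).sum())
        rows.append(
            {
                "threshold": float(t),
                "precision": tp / int(selected.sum()),
                "recall": tp / n_pos,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-sum test


def _rank_sum_exact_p(ranks_x: float, n_x: int, n: int) -> float:
    # tie-free: ranks are 1..n; enumerate all placements of the x sample
    total = 0
    hits = 0
    for combo in itertools.combinations(range(1, n + 1), n_x):
        total += 1
        if sum(combo) >= ranks_x - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_one_tailed(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alternative: str = "greater",
    exact_max_n: int = 12,
) -> float:
    """One-tailed Wilcoxon rank-sum p-value for ``x`` vs ``y``.

    ``alternative="greater"`` tests whether ``x`` is stochastically larger
    than ``y``. Exact enumeration over all rank assignments is used when
    ``len(x) + len(y) <= exact_max_n`` and there are no ties; otherwise a
    normal approximation with tie-corrected variance and continuity
    correction.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative == "less":
        return wilcoxon_one_tailed(y, x, alternative="greater",
                                   exact_max_n=exact_max_n)
    pooled = np.concatenate([x, y])
    n, n_x = pooled.size, x.size
    ranks = scipy.stats.rankdata(pooled, method="average")
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(pooled).size < n
    if n <= exact_max_n and not has_ties:
        return _rank_sum_exact_p(w, n_x, n)
    mean = n_x * (n + 1) / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_x * (n - n_x) / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0 if w <= mean else 0.5
    z = (w - mean - 0.5) / math.sqrt(var)
    return float(scipy.stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test


@dataclass(frozen=True)
class BinnedScores:
    """Score lists per ordered ordinal bin (no gene in two bins)."""

    labels: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must align")

    def nonempty(self) -> "BinnedScores":
        keep = [i for i, v in enumerate(self.values) if len(v) > 0]
        return BinnedScores(
            labels=tuple(self.labels[i] for i in keep),
            values=tuple(tuple(self.values[i]) for i in keep),
        )

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.values)


def _mann_whitney_count(a: np.ndarray, b: np.ndarray) -> float:
    # pairs (i, j) with a_i < b_j, ties half
    less = (a[:, None] < b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    stat = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            stat += _mann_whitney_count(groups[i], groups[j])
    return stat


def _jt_exact_p(pooled: np.ndarray, sizes: Sequence[int], observed: float) -> float:
    indices = tuple(range(pooled.size))

    def assignments(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in assignments(rest, sizes_left[1:]):
                yield (chosen,) + tail

    total = 0
    hits = 0
    for assignment in assignments(indices, list(sizes)):
        groups = [pooled[list(idx)] for idx in assignment]
        total += 1
        if _jt_statistic(groups) >= observed - 1e-9:
            hits += 1
    return hits / total


def jonckheere_terpstra(
    binned: BinnedScores,
    *,
    alternative: str = "increasing",
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Jonckheere-Terpstra test for a monotone trend across ordered bins.

    The statistic sums the Mann-Whitney counts (ties one half) over all
    ordered bin pairs. The p-value is one-sided for an increasing trend;
    ``alternative="decreasing"`` reverses the bin order first. Exact by
    enumeration of all group assignments when the pooled size is at most
    ``exact_max_n``, else a normal approximation with tie-corrected
    variance and continuity correction.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    binned = binned.nonempty()
    groups = [np.asarray(v, dtype=float) for v in binned.values]
    if alternative == "decreasing":
        groups = groups[::-1]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty bins")
    stat = _jt_statistic(groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    sizes = np.array([g.size for g in groups])
    if n <= exact_max_n:
        return stat, _jt_exact_p(pooled, sizes, stat)
    mean = (n**2 - (sizes**2).sum()) / 4
    _, ties = np.unique(pooled, return_counts=True)
    t1 = (
        n * (n - 1) * (2 * n + 5)
        - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
        - (ties * (ties - 1) * (2 * ties + 5)).sum()
    ) / 72
    t2 = (
        (sizes * (sizes - 1) * (sizes - 2)).sum()
        * (ties * (ties - 1) * (ties - 2)).sum()
    ) / (36 * n * (n - 1) * (n - 2))
    t3 = ((sizes * (sizes - 1)).sum() * (ties * (ties - 1)).sum()) / (
        8 * n * (n - 1)
    )
    var = t1 + t2 + t3
    if var <= 0:
        return stat, 1.0 if stat <= mean else 0.5
    z = (stat - mean - 0.5) / math.sqrt(var)
    return stat, float(scipy.stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Evidence binning


def bin_by_evidence(
    score_table: pd.DataFrame,
    evidence: pd.DataFrame,
    *,
    exact_counts: Sequence[int] = (0, 1, 2, 3, 4, 5, 6, 7),
    terminal_min: int = 8,
    human_only: bool = False,
    exclude_genes: Iterable[str] = (),
) -> BinnedScores:
    """Assign gene scores to ordinal evidence-count bins.

    ``exact_counts`` lists the counts given their own bin; every count >=
    ``terminal_min`` falls in the terminal open bin (labelled ``">=k"``).
    ``human_only`` selects the human-only evidence column. Genes in
    ``exclude_genes`` (typically the training set) are dropped before
    binning.
    """
    exact_counts = list(exact_counts)
    if sorted(set(exact_counts)) != exact_counts:
        raise ValueError("exact_counts must be strictly increasing and unique")
    if terminal_min <= max(exact_counts):
        raise ValueError("terminal_min overlaps an exact-count bin")
    column = "noe_human" if human_only else "noe_any"
    ev = evidence.set_index("gene") if "gene" in evidence.columns else evidence
    scores = (
        score_table.set_index("gene")["score"]
        if "gene" in score_table.columns
        else score_table["score"]
    )
    excluded = set(exclude_genes)

    labels = [str(c) for c in exact_counts] + [f">={terminal_min}"]
    buckets: list[list[float]] = [[] for _ in labels]
    exact_index = {c: i for i, c in enumerate(exact_counts)}
    for gene, score in scores.items():
        if gene in excluded:
            continue
        count = int(ev[column].get(gene, 0)) if gene in ev.index else 0
        if count >= terminal_min:
            buckets[-1].append(float(score))
        elif count in exact_index:
            buckets[exact_index[count]].append(float(score))
        else:
            raise ValueError(
                f"evidence count {count} for {gene!r} falls in no bin"
            )
    return BinnedScores(
        labels=tuple(labels), values=tuple(tuple(b) for b in buckets)
    )


def benchmark_flagged_fraction(
    score_table: pd.DataFrame,
    held_out_candidates: Iterable[str],
    selection: Iterable[str],
) -> float:
    """Fraction of held-out benchmark genes inside the selected list."""
    held_out = set(held_out_candidates)
    if not held_out:
        raise ValueError("held-out candidate set is empty")
    selected = set(selection)
    return len(held_out & selected) / len(held_out)


# ---------------------------------------------------------------------------
# Gene-set enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    fdr: float


def hypergeom_enrichment(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    background: Iterable[str],
    *,
    min_set: int = 5,
    max_set: int = 400,
    min_overlap: int = 3,
    fdr_max: float = 0.1,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment with Benjamini-Hochberg control.

    Collections are intersected with the background before size filtering;
    sets outside ``[min_set, max_set]`` or overlapping the query by fewer
    than ``min_overlap`` genes are not tested. BH adjustment runs across
    all tested sets; only results with FDR < ``fdr_max`` are returned,
    sorted by p-value.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    m = len(background)
    q = len(query)

    tested: list[tuple[str, int, int, float]] = []
    for name, members in collections.items():
        members = set(members) & background
        if not (min_set <= len(members) <= max_set):
            continue
        overlap = len(members & query)
        if overlap < min_overlap:
            continue
        p = float(scipy.stats.hypergeom.sf(overlap - 1, m, len(members), q))
        tested.append((name, overlap, len(members), p))
    if not tested:
        return []
    pvals = np.array([t[3] for t in tested])
    fdrs = scipy.stats.false_discovery_control(pvals, method="bh")
    results = [
        EnrichmentResult(
            set_name=name,
            overlap=overlap,
            set_size=size,
            query_size=q,
            background_size=m,
            p_value=p,
            fdr=float(fdr),
        )
        for (name, overlap, size, p), fdr in zip(tested, fdrs)
        if fdr < fdr_max
    ]
    return sorted(results, key=lambda r: r.p_value)
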