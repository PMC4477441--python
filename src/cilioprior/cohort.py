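"""Allele-count statistics for replication cohorts.

Frequencies, the 2x2 Fisher exact test on allele counts, the allele-level
odds ratio, and pooled multi-database frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

import scipy.stats

__all__ = [
    "AlleleCountTable",
    "allele_frequency",
    "percentage",
    "fisher_exact_2x2",
    "odds_ratio",
    "pooled_frequency",
]


def _round_half_even(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class AlleleCountTable:
    """Case and control arms as (alt allele count, total allele count)."""

    case_alt: int
    case_total: int
    control_alt: int
    control_total: int

    def __post_init__(self) -> None:
        for alt, total, arm in (
            (self.case_alt, self.case_total, "case"),
            (self.control_alt, self.control_total, "control"),
        ):
            if total <= 0:
                raise ValueError(f"{arm} total must be positive")
            if not 0 <= alt <= total:
                raise ValueError(f"{arm} alt count outside [0, total]")

    def as_2x2(self) -> list[list[int]]:
        """Rows: case/control; columns: alt alleles / non-alt alleles."""
        return [
            [self.case_alt, self.case_total - self.case_alt],
            [self.control_alt, self.control_total - self.control_alt],
        ]


def allele_frequency(alt: int, total: int, *, percent_decimals: int = 2) -> tuple[float, float]:
    """Return ``(proportion, percent)`` for ``alt`` of ``total`` alleles.

    The percentage is rounded half-even to ``percent_decimals`` places.
    """
    if total <= 0:
        raise ValueError("total allele count must be positive")
    if not 0 <= alt <= total:
        raise ValueError("alt count outside [0, total]")
    prop = alt / total
    return prop, _round_half_even(100.0 * prop, percent_decimals)


def percentage(part: float, whole: float, *, decimals: int = 1) -> float:
    """``100 * part / whole`` rounded half-even to ``decimals`` places."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return _round_half_even(100.0 * part / whole, decimals)


def fisher_exact_2x2(table: AlleleCountTable) -> float:
    """Two-sided Fisher exact p-value on the allele-count table.

    Two-sided by the probability-mass convention: the sum of probabilities
    of all tables (under fixed margins) no more probable than the observed
    one. Degenerate margins (an all-zero row or column) give p = 1.
    """
    t = table.as_2x2()
    row_sums = [sum(r) for r in t]
    col_sums = [t[0][0] + t[1][0], t[0][1] + t[1][1]]
    if 0 in row_sums or 0 in col_sums:
        return 1.0
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def odds_ratio(table: AlleleCountTable) -> float:
    """Cross-product odds ratio ``(a*d)/(b*c)`` on allele counts.

    Haldane's 0.5 correction is added to every cell only when any cell is
    zero, so the result is always finite.
    """
    (a, b), (c, d) = table.as_2x2()
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def pooled_frequency(count_pairs: Sequence[tuple[int, int]]) -> float:
    """Pooled proportion ``sum(alt) / sum(total)`` across databases."""
    if not count_pairs:
        raise ValueError("no count pairs supplied")
    alt_sum = 0
    total_sum = 0
    for alt, total in count_pairs:
        if total <= 0:
            raise ValueError("each total must be positive")
        if not 0 <= alt <= total:
            raise ValueError("alt count outside [0, total]")
        alt_sum += alt
        total_sum += total
    return alt_sum / total_sum
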