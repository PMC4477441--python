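"""Family exome variant filtering and gene-list intersection.

The cascade: per-record annotation filters (autosomal, population allele
frequency, CADD for non-frameshifts, GERP for frameshifts), a trio
segregation check for homozygous calls, compound-heterozygote pairing with
phase-by-descent, control-database subtraction, intersection with a
prioritized gene list, and a per-gene recurrence tally across families.

Every dropped record carries exactly one machine-readable reason, so
retained plus per-reason drops always account for the input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort import _round_half_even

__all__ = [
    "VariantRecord",
    "CompHetPair",
    "records_from_frame",
    "filter_variants",
    "segregation_filter",
    "find_compound_hets",
    "control_db_filter",
    "intersect_gene_set",
    "tally_recurrence",
    "reduction_percentage",
    "run_variant_pipeline",
]

#: consequence classes counted as coding or canonical splice
QUALIFYING_CONSEQUENCES = frozenset(
    {"frameshift", "other-coding", "canonical-splice"}
)

_CARRIER = {"het", "hom"}


@dataclass(frozen=True)
class VariantRecord:
    family: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    zygosity: str
    gt_father: Optional[str] = None
    gt_mother: Optional[str] = None
    af: Optional[float] = None
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    autosomal: bool = True

    def __post_init__(self) -> None:
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        for gt in (self.gt_father, self.gt_mother):
            if gt is not None and gt not in ("ref", "het", "hom"):
                raise ValueError(f"unknown parental genotype {gt!r}")
        if self.af is not None and not 0 <= self.af <= 1:
            raise ValueError("population_af must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CompHetPair:
    """Two het variants of one gene in one family, with phase."""

    first: VariantRecord
    second: VariantRecord
    phase: str  # trans / cis / unknown

    def __post_init__(self) -> None:
        if self.first.family != self.second.family:
            raise ValueError("pair spans two families")
        if self.first.gene != self.second.gene:
            raise ValueError("pair spans two genes")
        if self.first.key == self.second.key:
            raise ValueError("pair members must be distinct variants")
        if self.phase not in ("trans", "cis", "unknown"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def gene(self) -> str:
        return self.first.gene

    @property
    def family(self) -> str:
        return self.first.family


def records_from_frame(frame: pd.DataFrame) -> list[VariantRecord]:
    """Build records from the documented VCF-like table."""
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()

        def _opt(name):
            v = d.get(name)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) else v

        records.append(
            VariantRecord(
                family=str(d["family"]),
                gene=str(d["gene"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                consequence=str(d["consequence"]),
                zygosity=str(d["zygosity"]),
                gt_father=_opt("gt_father"),
                gt_mother=_opt("gt_mother"),
                af=_opt("af"),
                cadd_phred=_opt("cadd_phred"),
                gerp=_opt("gerp"),
                autosomal=bool(d.get("autosomal", True)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Record-level filters


def filter_variants(
    records: Iterable[VariantRecord],
    *,
    af_max: float = 0.01,
    cadd_min: float = 10.0,
    gerp_min: float = 4.0,
    keep_unannotated: bool = False,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Annotation filter cascade.

    Retains autosomal records with population AF < ``af_max`` whose
    deleteriousness passes the consequence-specific rule: frameshifts need
    GERP >= ``gerp_min``; everything else CADD-phred >= ``cadd_min``.
    Records lacking the needed annotation are dropped with reason
    ``"unannotated"`` unless ``keep_unannotated``.

    Returns ``(retained, [(record, drop_reason), ...])``.
    """
    retained: list[VariantRecord] = []
    drops: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if not rec.autosomal:
            drops.append((rec, "non-autosomal"))
            continue
        needed = rec.gerp if rec.consequence == "frameshift" else rec.cadd_phred
        if rec.af is None or needed is None:
            if keep_unannotated:
                retained.append(rec)
            else:
                drops.append((rec, "unannotated"))
            continue
        if rec.af >= af_max:
            drops.append((rec, "af"))
            continue
        if rec.consequence == "frameshift":
            if rec.gerp < gerp_min:
                drops.append((rec, "gerp"))
                continue
        elif rec.cadd_phred < cadd_min:
            drops.append((rec, "cadd"))
            continue
        retained.append(rec)
    return retained, drops


def segregation_filter(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]], list[VariantRecord]]:
    """Trio segregation check for homozygous calls.

    A hom call requires every genotyped parent to be a het-or-hom carrier;
    a genotyped non-carrier parent is a Mendelian violation and drops the
    record. Het calls pass unchanged; records without parental data pass
    and are collected in an ``unphased`` list.

    Returns ``(retained, [(record, reason)], unphased)``.
    """
    retained: list[VariantRecord] = []
    drops: list[tuple[VariantRecord, str]] = []
    unphased: list[VariantRecord] = []
    for rec in records:
        if rec.gt_father is None and rec.gt_mother is None:
            retained.append(rec)
            unphased.append(rec)
            continue
        if rec.zygosity == "hom":
            violated = any(
                gt is not None and gt not in _CARRIER
                for gt in (rec.gt_father, rec.gt_mother)
            )
            if violated:
                drops.append((rec, "mendelian-violation"))
                continue
        retained.append(rec)
    return retained, drops, unphased


# ---------------------------------------------------------------------------
# Compound heterozygotes


def _parental_origin(rec: VariantRecord) -> Optional[str]:
    """Which parent transmitted a het variant, when unambiguous."""
    if rec.gt_father is None or rec.gt_mother is None:
        return None
    father = rec.gt_father in _CARRIER
    mother = rec.gt_mother in _CARRIER
    if father and not mother:
        return "father"
    if mother and not father:
        return "mother"
    return None


def find_compound_hets(
    records: Iterable[VariantRecord],
) -> list[CompHetPair]:
    """All unordered pairs of distinct het variants per (family, gene).

    Phase is ``trans`` when the two parental origins are unambiguous and
    differ, ``cis`` when unambiguous and equal, ``unknown`` otherwise.
    """
    hets = [r for r in records if r.zygosity == "het"]
    pairs: list[CompHetPair] = []
    keyfunc = lambda r: (r.family, r.gene)
    for _, group in itertools.groupby(sorted(hets, key=keyfunc), key=keyfunc):
        group = list(group)
        for a, b in itertools.combinations(group, 2):
            if a.key == b.key:
                continue
            origin_a, origin_b = _parental_origin(a), _parental_origin(b)
            if origin_a is None or origin_b is None:
                phase = "unknown"
            elif origin_a == origin_b:
                phase = "cis"
            else:
                phase = "trans"
            pairs.append(CompHetPair(first=a, second=b, phase=phase))
    return pairs


def potential_pairs(pairs: Iterable[CompHetPair]) -> list[CompHetPair]:
    """Pairs counted downstream: trans plus unknown phase; cis excluded."""
    return [p for p in pairs if p.phase != "cis"]


# ---------------------------------------------------------------------------
# Control database


def _control_maps(control_db: pd.DataFrame):
    hom_carriers: dict[tuple, set[str]] = {}
    any_carriers: dict[tuple, set[str]] = {}
    for row in control_db.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        any_carriers.setdefault(key, set()).add(str(row.individual))
        if str(row.zygosity) == "hom":
            hom_carriers.setdefault(key, set()).add(str(row.individual))
    return hom_carriers, any_carriers


def control_db_filter(
    hom_records: Sequence[VariantRecord],
    pairs: Sequence[CompHetPair],
    control_db: pd.DataFrame,
    *,
    same_individual: bool = True,
) -> tuple[list[VariantRecord], list[CompHetPair]]:
    """Remove calls explained by unaffected control individuals.

    A hom record is removed when any control carries it in hom state (het
    control carriers do not disqualify a recessive allele). A pair is
    removed when both members occur in one control individual — a true
    biallelic control; ``same_individual=False`` switches to the looser
    rule removing pairs whose members are each seen in any control.
    """
    hom_carriers, any_carriers = _control_maps(control_db)
    kept_homs = [r for r in hom_records if not hom_carriers.get(r.key)]
    kept_pairs = []
    for pair in pairs:
        c1 = any_carriers.get(pair.first.key, set())
        c2 = any_carriers.get(pair.second.key, set())
        removed = bool(c1 & c2) if same_individual else bool(c1 and c2)
        if not removed:
            kept_pairs.append(pair)
    return kept_homs, kept_pairs


# ---------------------------------------------------------------------------
# Gene-list intersection and recurrence


def intersect_gene_set(
    hom_records: Sequence[VariantRecord],
    pairs: Sequence[CompHetPair],
    gene_list: Iterable[str],
) -> tuple[list[VariantRecord], list[CompHetPair], dict]:
    """Restrict to coding / canonical-splice calls in the listed genes.

    Returns the prioritized homs and pairs plus before/after tallies.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene list must be non-empty")

    def qualifies(rec: VariantRecord) -> bool:
        return rec.gene in genes and rec.consequence in QUALIFYING_CONSEQUENCES

    kept_homs = [r for r in hom_records if qualifies(r)]
    kept_pairs = [
        p for p in pairs if qualifies(p.first) and qualifies(p.second)
    ]
    tallies = {
        "before": {"hom": len(hom_records), "pairs": len(pairs)},
        "after": {"hom": len(kept_homs), "pairs": len(kept_pairs)},
    }
    return kept_homs, kept_pairs, tallies


def tally_recurrence(
    hom_records: Sequence[VariantRecord],
    pairs: Sequence[CompHetPair],
    *,
    flag_min_families: int = 3,
) -> tuple[dict[str, int], list[str]]:
    """Per-gene family counts and recurrently hit genes.

    A family counts once per gene regardless of how many qualifying calls
    it carries. Genes hit in at least ``flag_min_families`` families are
    flagged.
    """
    families: dict[str, set[str]] = {}
    for rec in hom_records:
        families.setdefault(rec.gene, set()).add(rec.family)
    for pair in pairs:
        families.setdefault(pair.gene, set()).add(pair.family)
    counts = {g: len(f) for g, f in sorted(families.items())}
    flagged = [g for g, c in counts.items() if c >= flag_min_families]
    return counts, flagged


def reduction_percentage(n_before: int, n_after: int) -> float:
    """Percent reduction ``100 * (1 - after/before)`` to one decimal."""
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    if n_after > n_before:
        raise ValueError("n_after cannot exceed n_before")
    return _round_half_even(100.0 * (1.0 - n_after / n_before), 1)


# ---------------------------------------------------------------------------
# End-to-end convenience


def run_variant_pipeline(
    variant_frame: pd.DataFrame,
    control_db: pd.DataFrame,
    gene_list: Iterable[str],
    *,
    af_max: float = 0.01,
    cadd_min: float = 10.0,
    gerp_min: float = 4.0,
    flag_min_families: int = 3,
) -> dict:
    """Run the whole cascade on a variant table; return a summary report."""
    records = records_from_frame(variant_frame)
    filtered, ann_drops = filter_variants(
        records, af_max=af_max, cadd_min=cadd_min, gerp_min=gerp_min
    )
    segregating, seg_drops, unphased = segregation_filter(filtered)
    homs = [r for r in segregating if r.zygosity == "hom"]
    pairs = potential_pairs(find_compound_hets(segregating))
    homs, pairs = control_db_filter(homs, pairs, control_db)
    kept_homs, kept_pairs, tallies = intersect_gene_set(homs, pairs, gene_list)
    counts, flagged = tally_recurrence(
        kept_homs, kept_pairs, flag_min_families=flag_min_families
    )

    n_before = tallies["before"]["hom"] + tallies["before"]["pairs"]
    n_after = tallies["after"]["hom"] + tallies["after"]["pairs"]
    drop_reasons: dict[str, int] = {}
    for _, reason in ann_drops + seg_drops:
        drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
    return {
        "input_records": len(records),
        "drop_reasons": drop_reasons,
        "unphased_records": len(unphased),
        "tallies_units": tallies,
        "tallies_variants": {
            "before": {
                "hom": tallies["before"]["hom"],
                "pair_variants": 2 * tallies["before"]["pairs"],
            },
            "after": {
                "hom": tallies["after"]["hom"],
                "pair_variants": 2 * tallies["after"]["pairs"],
            },
        },
        "reduction_pct_units": (
            reduction_percentage(n_before, n_after) if n_before else None
        ),
        "family_counts": counts,
        "flagged_genes": flagged,
    }
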