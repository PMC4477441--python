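"""Seeded synthetic inputs for every pipeline stage.

Each generator draws from its own pseudo-random stream, seeded from
``config.seed`` plus a stable per-operation offset, so adding a call to
one generator never perturbs the outputs of another. Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import LabelSet

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "simulate_screen",
    "simulate_evidence",
    "simulate_expression",
    "simulate_cohort_variants",
]

# per-operation seed-stream offsets (stable; never reorder)
_STREAM_SCREEN = 1
_STREAM_EVIDENCE = 2
_STREAM_EXPRESSION = 3
_STREAM_VARIANTS = 4


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_params: int = 31
    n_replicates: int = 2
    frac_positive: float = 0.1
    effect_size: float = 2.5
    n_informative: int = 10
    batch_shift: float = 0.5
    noe_lambda_pos: float = 4.0
    noe_lambda_neg: float = 0.2
    n_tissues: int = 5
    samples_per_tissue: int = 8
    low_quality_frac: float = 0.1
    quality_min: float = 6.0
    n_families: int = 20
    n_comphet_families: int = 4
    n_hom_families: int = 2
    causal_gene: str = "G0001"
    common_allele_af: float = 0.0036
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_params": self.n_params,
            "n_replicates": self.n_replicates,
            "n_tissues": self.n_tissues,
            "samples_per_tissue": self.samples_per_tissue,
            "n_families": self.n_families,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if not 0 < self.frac_positive < 1:
            raise ConfigurationError("frac_positive must lie in (0, 1)")
        if self.n_informative > self.n_params:
            raise ConfigurationError("n_informative must be <= n_params")
        if not 0 <= self.noe_lambda_neg <= self.noe_lambda_pos:
            raise ConfigurationError(
                "need noe_lambda_pos >= noe_lambda_neg >= 0"
            )
        if not 0 < self.common_allele_af < 1:
            raise ConfigurationError("common_allele_af must lie in (0, 1)")

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# Screen


def simulate_screen(
    config: SimulationConfig,
) -> tuple[list[pd.DataFrame], LabelSet]:
    """Two-replicate screen feature matrices plus the ground-truth labels.

    Features are standard normal per gene; true positives carry an
    additive ``effect_size`` shift on the first ``n_informative`` columns,
    and replicate ``r`` (0-based) receives a uniform ``batch_shift * r``
    offset emulating a batch effect.
    """
    rng = _rng(config, _STREAM_SCREEN)
    genes = config.gene_names()
    n_pos = int(round(config.frac_positive * config.n_genes))
    n_pos = min(max(n_pos, 1), config.n_genes - 1)
    pos_idx = rng.choice(config.n_genes, size=n_pos, replace=False)
    is_pos = np.zeros(config.n_genes, dtype=bool)
    is_pos[pos_idx] = True

    columns = [f"param{j:02d}" for j in range(1, config.n_params + 1)]
    replicates = []
    for r in range(config.n_replicates):
        values = rng.standard_normal((config.n_genes, config.n_params))
        values[is_pos, : config.n_informative] += config.effect_size
        values += config.batch_shift * r
        replicates.append(
            pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=columns)
        )
    positives = frozenset(np.array(genes)[is_pos])
    negatives = frozenset(np.array(genes)[~is_pos])
    truth = LabelSet(
        positives=positives,
        negatives=negatives,
        provenance={g: "truth" for g in genes},
    )
    return replicates, truth


# ---------------------------------------------------------------------------
# Evidence


def simulate_evidence(
    truth: LabelSet,
    noe_lambda_pos: float,
    noe_lambda_neg: float,
    seed: int,
) -> pd.DataFrame:
    """Poisson evidence counts correlated with the true class.

    ``noe_any`` is Poisson(lambda_pos) for true positives and
    Poisson(lambda_neg) otherwise; ``noe_human`` is a binomial thinning of
    ``noe_any``, so ``noe_human <= noe_any`` holds by construction.
    """
    if not 0 <= noe_lambda_neg <= noe_lambda_pos:
        raise ConfigurationError("need noe_lambda_pos >= noe_lambda_neg >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_EVIDENCE]))
    genes = sorted(truth.universe)
    is_pos = np.array([g in truth.positives for g in genes])
    lam = np.where(is_pos, noe_lambda_pos, noe_lambda_neg)
    noe_any = rng.poisson(lam)
    noe_human = rng.binomial(noe_any, 0.5)
    return pd.DataFrame(
        {"gene": genes, "noe_any": noe_any, "noe_human": noe_human}
    )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-structured non-negative expression plus sample metadata.

    Values are log-normal around gene baselines with a per-(tissue, gene)
    offset, so tissue mean profiles differ. A ``low_quality_frac``
    fraction of samples (in expectation) receives a quality score below
    ``quality_min``.
    """
    if config.samples_per_tissue < 2:
        raise ConfigurationError(
            "samples_per_tissue must be >= 2 (principal components undefined)"
        )
    rng = _rng(config, _STREAM_EXPRESSION)
    genes = config.gene_names()
    base = rng.normal(1.0, 1.0, size=config.n_genes)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for t in range(config.n_tissues):
        tissue = f"tissue{t + 1:02d}"
        tissue_shift = rng.normal(0.0, 1.0, size=config.n_genes)
        for s in range(config.samples_per_tissue):
            sample = f"{tissue}_s{s + 1:02d}"
            noise = rng.normal(0.0, 0.3, size=config.n_genes)
            columns[sample] = np.exp(base + tissue_shift + noise)
            low = rng.random() < config.low_quality_frac
            if low:
                quality = rng.uniform(1.0, config.quality_min - 0.5)
            else:
                quality = rng.uniform(config.quality_min + 0.5, 10.0)
            meta_rows.append(
                {"sample": sample, "tissue": tissue, "quality": round(quality, 2)}
            )
    expr = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows)
    return expr, meta


# ---------------------------------------------------------------------------
# Cohort variants


_VARIANT_COLUMNS = [
    "family", "gene", "chrom", "pos", "ref", "alt", "consequence",
    "zygosity", "gt_father", "gt_mother", "af", "cadd_phred", "gerp",
    "autosomal",
]


def _record(family, gene, chrom, pos, ref, alt, consequence, zygosity,
            gt_father, gt_mother, af, cadd, gerp, autosomal=True) -> dict:
    return dict(zip(_VARIANT_COLUMNS, [
        family, gene, chrom, pos, ref, alt, consequence, zygosity,
        gt_father, gt_mother, round(float(af), 6), round(float(cadd), 2),
        round(float(gerp), 2), autosomal,
    ]))


def simulate_cohort_variants(
    config: SimulationConfig,
    gene_universe: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Family variant tables with one planted recurrent causal gene.

    The causal gene receives biallelic hits in
    ``n_comphet_families + n_hom_families`` families: compound-het
    families share one common frameshift allele (population frequency
    ``common_allele_af``) in trans with a family-private rare second hit;
    homozygous families carry a private rare homozygous variant with
    carrier parents. Background families receive variants that either
    fail a filter (common, or weakly conserved/deleterious) or pass but do
    not recur across more than two families. The control database holds
    common variants only.

    Returns ``(variant table, control database, truth report)``.
    """
    gene_universe = list(gene_universe)
    if config.causal_gene not in gene_universe:
        raise ConfigurationError(
            f"causal gene {config.causal_gene!r} absent from gene universe"
        )
    n_causal = config.n_comphet_families + config.n_hom_families
    if n_causal > config.n_families:
        raise ConfigurationError("more causal families than families")

    rng = _rng(config, _STREAM_VARIANTS)
    families = [f"F{i:03d}" for i in range(1, config.n_families + 1)]
    causal_families = families[:n_causal]
    background_families = families[n_causal:]
    background_genes = [g for g in gene_universe if g != config.causal_gene]
    if not background_genes:
        raise ConfigurationError("gene universe must contain non-causal genes")

    records: list[dict] = []
    shared = dict(chrom="14", pos=100428, ref="CA", alt="C")

    # compound-het families: shared frameshift (paternal) + private rare hit
    for i in range(config.n_comphet_families):
        fam = causal_families[i]
        records.append(_record(
            fam, config.causal_gene, shared["chrom"], shared["pos"],
            shared["ref"], shared["alt"], "frameshift", "het",
            "het", "ref", config.common_allele_af, 22.0,
            rng.uniform(4.2, 5.5),
        ))
        records.append(_record(
            fam, config.causal_gene, "14", 100428 + 50 * (i + 1), "G", "T",
            "other-coding", "het", "ref", "het",
            rng.uniform(1e-5, 5e-4), rng.uniform(25.0, 35.0),
            rng.uniform(2.0, 5.0),
        ))

    # homozygous families: private rare hom variant, both parents carriers
    for i in range(config.n_hom_families):
        fam = causal_families[config.n_comphet_families + i]
        records.append(_record(
            fam, config.causal_gene, "14", 100900 + 10 * (i + 1), "C", "T",
            "other-coding", "hom", "het", "het",
            rng.uniform(1e-5, 5e-4), rng.uniform(25.0, 35.0),
            rng.uniform(2.0, 5.0),
        ))

    # background families: failing variants plus non-recurrent passing hits
    pool = background_genes.copy()
    for i, fam in enumerate(background_families):
        common_gene = background_genes[
            int(rng.integers(len(background_genes)))
        ]
        records.append(_record(
            fam, common_gene, "2", 5000 + i, "A", "G", "other-coding",
            "het", None, None, rng.uniform(0.02, 0.3),
            rng.uniform(15.0, 30.0), rng.uniform(2.0, 5.0),
        ))
        weak_gene = background_genes[int(rng.integers(len(background_genes)))]
        records.append(_record(
            fam, weak_gene, "3", 7000 + i, "T", "C", "other-coding",
            "het", None, None, rng.uniform(1e-4, 5e-3),
            rng.uniform(0.5, 9.5), rng.uniform(-2.0, 3.0),
        ))
        # a passing hom in a gene reused by at most two background families
        hom_gene = pool[(i // 2) % len(pool)] if len(pool) * 2 >= len(
            background_families
        ) else pool[i % len(pool)]
        records.append(_record(
            fam, hom_gene, "5", 9000 + 3 * i, "G", "A", "other-coding",
            "hom", "het", "het", rng.uniform(1e-5, 5e-4),
            rng.uniform(20.0, 35.0), rng.uniform(2.0, 5.0),
        ))

    variants = pd.DataFrame(records, columns=_VARIANT_COLUMNS)

    # controls: common variants only; the shared frameshift appears het
    control_rows = []
    for j in range(8):
        control_rows.append({
            "chrom": "2", "pos": 5000 + j, "ref": "A", "alt": "G",
            "individual": f"C{j:04d}", "zygosity": "hom",
        })
    for j in range(3):
        control_rows.append({
            "chrom": shared["chrom"], "pos": shared["pos"],
            "ref": shared["ref"], "alt": shared["alt"],
            "individual": f"C{100 + j:04d}", "zygosity": "het",
        })
    control_db = pd.DataFrame(control_rows)

    truth = {
        "causal_gene": config.causal_gene,
        "causal_families": causal_families,
        "n_comphet_families": config.n_comphet_families,
        "n_hom_families": config.n_hom_families,
        "shared_allele": {**shared, "af": config.common_allele_af},
    }
    return variants, control_db, truth
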