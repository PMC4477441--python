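"""Feature fusion: build the per-gene feature matrix from three sources.

* batch quantile normalization of the screen replicate matrices,
* consistency-weighted median aggregation of per-reagent scores into one
  gene-level value,
* per-tissue expression signature features (median expression plus the
  gene loadings of the leading principal components).

Assembly is an inner join on gene identifiers; genes missing from any
source are dropped and the losses recorded in a join report. No value is
ever imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "FeatureMatrix",
    "ExpressionBlock",
    "quantile_normalize",
    "weighted_median",
    "aggregate_reagents",
    "expression_signature_features",
    "assemble_features",
]


@dataclass
class FeatureMatrix:
    """Genes x named numeric features with a source tag per column."""

    data: pd.DataFrame
    sources: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.data.isna().any().any():
            raise ValueError("assembled feature matrix must have no missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


def quantile_normalize(
    matrix: pd.DataFrame,
    batches: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Quantile-normalize columns within each batch.

    Within a batch, every column's sorted values are replaced by the
    across-column means of the order statistics; tied entries receive the
    mean of the rank-mean values over their tied positions, so ties stay
    tied. With ``batches=None`` all columns form a single batch.
    """
    if matrix.empty:
        raise ValueError("matrix must be non-empty")
    if batches is None:
        batches = {c: "all" for c in matrix.columns}
    missing = set(matrix.columns) - set(batches)
    if missing:
        raise ValueError(f"columns without a batch label: {sorted(missing)}")

    out = matrix.copy().astype(float)
    for batch in dict.fromkeys(batches.values()):
        cols = [c for c in matrix.columns if batches[c] == batch]
        if not cols:
            raise ValueError(f"batch {batch!r} has no columns")
        block = matrix[cols].to_numpy(dtype=float)
        rank_means = np.sort(block, axis=0).mean(axis=1)
        for j, c in enumerate(cols):
            col = block[:, j]
            order = np.argsort(col, kind="stable")
            assigned = np.empty_like(col)
            assigned[order] = rank_means
            # average over tied positions so ties stay tied
            ser = pd.Series(assigned)
            out[c] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def weighted_median(
    scores: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Smallest score whose cumulative weight reaches half the total.

    With equal weights this is the ordinary median for odd counts and the
    lower median for even counts.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if weights is None:
        weights = np.ones_like(scores)
    else:
        weights = np.asarray(weights, dtype=float)
    if weights.shape != scores.shape:
        raise ValueError("weights must match scores in length")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = np.argsort(scores, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, total / 2.0 - 1e-12))
    return float(scores[order][idx])


def _consistency_weights(scores: np.ndarray) -> np.ndarray:
    # down-weight reagents deviating from the leave-one-out median
    iqr = float(
        np.percentile(scores, 75) - np.percentile(scores, 25)
    )
    eps = max(0.05 * iqr, 64 * np.finfo(float).eps)
    weights = np.empty_like(scores)
    for i in range(scores.size):
        rest = np.delete(scores, i)
        weights[i] = 1.0 / (eps + abs(scores[i] - float(np.median(rest))))
    return weights


def aggregate_reagents(reagent_table: pd.DataFrame) -> pd.Series:
    """Collapse per-reagent scores to one gene-level value.

    Each gene's reagent scores are combined with :func:`weighted_median`
    under inverse-deviation consistency weights
    ``w_i = 1 / (eps + |x_i - median(x_without_i)|)`` with
    ``eps = 0.05 * IQR`` of the gene's scores (floored at machine-epsilon
    scale), so discordant reagents are down-weighted. Expects columns
    ``gene`` and ``score``.
    """
    if not {"gene", "score"} <= set(reagent_table.columns):
        raise ValueError("reagent table needs 'gene' and 'score' columns")
    out = {}
    for gene, grp in reagent_table.groupby("gene", sort=True):
        scores = grp["score"].to_numpy(dtype=float)
        if scores.size == 1:
            out[gene] = float(scores[0])
            continue
        out[gene] = weighted_median(scores, _consistency_weights(scores))
    return pd.Series(out, name="centriole").rename_axis("gene")


@dataclass
class ExpressionBlock:
    """Per-gene expression signature features.

    ``features`` holds, per tissue, the per-gene median expression column
    and one gene-loading column per retained principal component.
    ``components`` maps tissue name to the retained component count.
    """

    features: pd.DataFrame
    components: Mapping[str, int]
    tissues: tuple[str, ...]


def _tissue_pca(block: np.ndarray, variance_target: float) -> list[np.ndarray]:
    """Gene-loading vectors of the leading PCs covering the variance target."""
    centered = block - block.mean(axis=0, keepdims=True)
    if not np.any(np.abs(centered) > 1e-12):
        return []
    # samples are observations, genes are variables
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    var = svals**2
    ratios = var / var.sum()
    k = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12)) + 1
    k = min(k, int((var > 1e-20 * var.max()).sum()))
    loadings = []
    for comp in vt[:k]:
        if comp[np.argmax(np.abs(comp))] < 0:
            comp = -comp
        loadings.append(comp)
    return loadings


def expression_signature_features(
    expression: pd.DataFrame,
    sample_meta: pd.DataFrame,
    *,
    quality_min: float = 6.0,
    variance_target: float = 0.95,
) -> ExpressionBlock:
    """Derive per-tissue signature features from an expression matrix.

    Samples with a quality score below ``quality_min`` are excluded, the
    surviving matrix is quantile-normalized across all samples, then per
    tissue the per-gene median and the gene loadings of the smallest
    number of leading principal components reaching ``variance_target``
    cumulative variance are emitted. Loading vectors are unit-norm and
    sign-fixed so each component's largest-magnitude entry is positive.

    ``expression`` is genes x samples; ``sample_meta`` needs columns
    ``sample``, ``tissue`` and ``quality``.
    """
    meta = sample_meta.set_index("sample") if "sample" in sample_meta.columns else sample_meta
    keep = meta.index[meta["quality"] >= quality_min]
    kept = expression[keep]
    for tissue, grp in meta.loc[keep].groupby("tissue"):
        if len(grp) < 2:
            raise ValueError(
                f"tissue {tissue!r} has fewer than 2 samples after quality exclusion"
            )
    normalized = quantile_normalize(kept)

    feature_cols: dict[str, np.ndarray] = {}
    components: dict[str, int] = {}
    tissues = sorted(meta.loc[keep, "tissue"].unique())
    for tissue in tissues:
        samples = meta.index[(meta["quality"] >= quality_min) & (meta["tissue"] == tissue)]
        block = normalized[samples].to_numpy(dtype=float)
        feature_cols[f"{tissue}_median"] = np.median(block, axis=1)
        loadings = _tissue_pca(block.T, variance_target)
        components[tissue] = len(loadings)
        for k, vec in enumerate(loadings, start=1):
            feature_cols[f"{tissue}_pc{k}"] = vec
    features = pd.DataFrame(feature_cols, index=expression.index)
    return ExpressionBlock(
        features=features, components=components, tissues=tuple(tissues)
    )


def assemble_features(
    screen_reps: Sequence[pd.DataFrame],
    centriole: pd.Series,
    expression: pd.DataFrame,
) -> tuple[FeatureMatrix, dict]:
    """Inner-join the three feature sources on gene identifier.

    Genes missing from any source are dropped; the join report records,
    for each source, how many genes present in every other source that
    source lost, plus the assembled gene count.
    """
    blocks: dict[str, pd.DataFrame] = {}
    sources: dict[str, str] = {}
    for i, rep in enumerate(screen_reps, start=1):
        renamed = rep.add_prefix(f"rep{i}_")
        blocks[f"screen-rep{i}"] = renamed
        sources.update({c: f"screen-rep{i}" for c in renamed.columns})
    blocks["centriole"] = centriole.to_frame("centriole")
    sources["centriole"] = "centriole"
    blocks["expression"] = expression
    sources.update({c: "expression" for c in expression.columns})

    gene_sets = {name: set(b.index) for name, b in blocks.items()}
    common = set.intersection(*gene_sets.values())
    if not common:
        raise ValueError("no gene is present in all feature sources")

    losses = {}
    for name in blocks:
        others = set.intersection(
            *(g for n, g in gene_sets.items() if n != name)
        )
        losses[name] = len(others - gene_sets[name])
    report = {
        "assembled_genes": len(common),
        "genes_per_source": {n: len(g) for n, g in gene_sets.items()},
        "lost_to_source": losses,
    }

    first = next(iter(blocks.values()))
    gene_order = [g for g in first.index if g in common]
    joined = pd.concat(
        [b.loc[gene_order] for b in blocks.values()], axis=1
    )
    return FeatureMatrix(data=joined, sources=sources), report
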