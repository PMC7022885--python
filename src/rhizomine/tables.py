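"""Feature x sample count tables: filtering, aggregation, normalization
and a differential-abundance test.

Raw per-taxon (or per-COG) read counts flow through a fixed sequence:
contaminant lineages are removed, low-abundance features are dropped
(a feature is retained iff it has at least ``min_count`` raw reads in at
least ``min_samples`` libraries), species-level counts are aggregated to
a target rank (family by default), and samples are brought onto a common
scale with median-of-ratios size factors before any between-sample
statistic is computed.

The differential-abundance test is a negative-binomial Wald contract:
per-feature method-of-moments dispersion, no shrinkage, Benjamini-
Hochberg adjustment.  It is deliberately an approximation seam — an
external NB-GLM implementation can be substituted behind the same
row schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

UNRANKED = "unranked"


@dataclass
class CountTable:
    """Non-negative integer feature x sample matrix plus sample metadata.

    ``counts`` is features-as-rows; ``sample_meta`` is indexed by sample
    id with (at least) ``genotype`` and ``soil`` columns when the design
    factors are used downstream.
    """

    counts: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta is not None:
            missing = set(self.counts.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def features(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, features: Sequence) -> "CountTable":
        return CountTable(self.counts.loc[list(features)], self.sample_meta)


def remove_contaminant_lineages(
    table: CountTable,
    tree: TaxonomyTree,
    exclude_roots: Iterable[int],
) -> CountTable:
    """Drop features whose lineage passes through any excluded root.

    Features are taxids; ids not present in the taxonomy are dropped
    with a warning (stale taxids are a fact of life for reference
    databases).  An empty exclusion set is the identity on features
    known to the tree.
    """
    exclude = set(exclude_roots)
    kept = []
    unknown = 0
    for feature in table.features:
        try:
            taxid = int(feature)
        except (TypeError, ValueError):
            unknown += 1
            continue
        if taxid not in tree:
            unknown += 1
            continue
        lineage = set(tree.lineage(taxid))
        if lineage & exclude:
            continue
        kept.append(feature)
    if unknown:
        logger.warning("dropped %d features with taxids unknown to the taxonomy", unknown)
    if not kept:
        logger.warning("contaminant filter removed every feature")
    return CountTable(table.counts.loc[kept], table.sample_meta)


def low_abundance_filter(
    table: CountTable, min_count: int = 5, min_samples: int = 3
) -> CountTable:
    """Retain features with >= ``min_count`` raw reads in >= ``min_samples``
    libraries; everything else is removed.

    Operates on raw (unnormalized) counts by design: the threshold is in
    reads, not in scaled units.
    """
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {table.n_samples} samples present"
        )
    mask = (table.counts >= min_count).sum(axis=1) >= min_samples
    return CountTable(table.counts.loc[mask], table.sample_meta)


def aggregate_at_rank(
    table: CountTable, tree: TaxonomyTree, rank: str = "family"
) -> CountTable:
    """Sum taxid-keyed counts into their ancestor at ``rank``.

    Features whose lineage lacks the rank fall into a single
    ``unranked`` bucket rather than being promoted to a nearby rank,
    so column totals are conserved exactly.
    """
    if table.n_features == 0:
        return CountTable(table.counts.copy(), table.sample_meta)
    buckets: dict = {}
    for feature in table.features:
        taxid = int(feature)
        ancestor = tree.ancestor_at_rank(taxid, rank)
        key = UNRANKED if ancestor is None else ancestor
        buckets.setdefault(key, []).append(feature)
    rows = {}
    for key, members in buckets.items():
        rows[key] = table.counts.loc[members].sum(axis=0)
    aggregated = pd.DataFrame(rows).T
    aggregated.columns = table.counts.columns
    aggregated = aggregated.astype(table.counts.dtypes.iloc[0] if table.n_features else int)
    return CountTable(aggregated, table.sample_meta)


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each feature with strictly positive counts in every sample, the
    ratio of each sample's count to the feature's geometric mean across
    samples is formed; a sample's factor is the median of its ratios.
    Geometric means accumulate in log space to avoid under/overflow.
    """
    counts = table.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; add a pseudocount "
            "or filter samples before computing size factors"
        )
    ref = counts[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


def normalize(table: CountTable, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = set(table.samples) - set(factors.index)
    if missing:
        raise ValueError(f"no size factor for samples: {sorted(missing)}")
    if (factors.loc[table.samples] <= 0).any():
        raise ValueError("size factors must be positive")
    return table.counts.div(factors.loc[table.samples], axis=1)


@dataclass(frozen=True)
class DiffAbundanceRow:
    """Per-feature differential-abundance result."""

    feature: object
    base_mean: float
    log2_fold_change: float
    p_value: float
    fdr: float
    significant: bool


def diff_abundance(
    table: CountTable,
    contrast: tuple[str, str, str],
    alpha: float = 0.05,
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test between two metadata levels.

    ``contrast = (factor, levelA, levelB)``; a positive log2 fold change
    means enrichment in ``levelA``.  Counts are normalized by
    median-of-ratios size factors (computed here unless supplied);
    per-feature dispersion is a pooled method-of-moments estimate with
    no shrinkage, and the Wald statistic is referred to a t distribution
    with ``nA + nB - 2`` degrees of freedom — a small-sample guard that
    a normal reference would not provide.  P-values are BH-adjusted.
    """
    if table.sample_meta is None:
        raise ValueError("diff_abundance requires sample metadata")
    factor_name, level_a, level_b = contrast
    if factor_name not in table.sample_meta.columns:
        raise ValueError(f"metadata has no factor {factor_name!r}")
    labels = table.sample_meta.loc[table.samples, factor_name]
    for level in (level_a, level_b):
        if level not in set(labels):
            raise ValueError(f"level {level!r} absent from factor {factor_name!r}")
    samples_a = [s for s in table.samples if labels[s] == level_a]
    samples_b = [s for s in table.samples if labels[s] == level_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrast level needs at least 2 samples")

    sub = CountTable(table.counts[samples_a + samples_b], table.sample_meta)
    if factors is None:
        factors = size_factors(sub)
    norm = normalize(sub, factors)
    a = norm[samples_a].to_numpy(dtype=float)
    b = norm[samples_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]

    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # Pooled method-of-moments NB dispersion: var = mu + alpha*mu^2.
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    pooled_mu = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(
            pooled_mu > 0, (pooled_var - pooled_mu) / pooled_mu**2, 0.0
        )
    dispersion = np.clip(dispersion, 0.0, None)

    # Wald on log means via the delta method; half-count offset keeps
    # zero-mean groups finite without dominating expressed features.
    eps = 0.5
    lfc = np.log2(mu_a + eps) - np.log2(mu_b + eps)
    var_log_a = (mu_a + dispersion * mu_a**2) / (n_a * (mu_a + eps) ** 2)
    var_log_b = (mu_b + dispersion * mu_b**2) / (n_b * (mu_b + eps) ** 2)
    se = np.sqrt(var_log_a + var_log_b)
    ln_fc = np.log(mu_a + eps) - np.log(mu_b + eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, ln_fc / se, 0.0)
    df = n_a + n_b - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df=df)
    p = np.where(se > 0, p, 1.0)
    p = np.clip(p, 0.0, 1.0)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    result = pd.DataFrame(
        {
            "feature": list(sub.features),
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": p,
            "fdr": fdr,
            "significant": fdr < alpha,
        }
    )
    return result.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
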