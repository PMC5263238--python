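"""Per-region differential expression across age groups and regional-breadth
classification.

The analysis asks, for every gene and every brain region separately, whether
log2 expression differs among three fixed age groups (young 16-44, middle
45-74, old >= 75 years) by one-way fixed-effects ANOVA, controls the false
discovery rate per region with Benjamini-Hochberg, and then classifies each
aging-altered gene by the number of regions in which it is significant
(regional breadth): region-specific (1), region-selective (2-7),
multi-regional (>= 8) and cross-regional (all 10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AGE_GROUPS = ("young", "middle", "old")

#: Age-group bounds in integer years: young 16-44, middle 45-74, old >= 75.
AGE_GROUP_BOUNDS = {"young": (16, 44), "middle": (45, 74), "old": (75, math.inf)}

#: Breadth category labels, from narrowest to broadest.
BREADTH_CATEGORIES = (
    "region_specific",
    "region_selective",
    "multi_regional",
    "cross_regional",
)

DEFAULT_FDR_THRESHOLD = 1e-3


def assign_age_group(age: float) -> str:
    """Map an age in years onto the young/middle/old partition.

    Ages below 16 are outside the studied range and raise ``ValueError``.
    """
    if age < 16:
        raise ValueError(f"age {age} is below the study minimum of 16 years")
    if age <= 44:
        return "young"
    if age <= 74:
        return "middle"
    return "old"


def assign_age_groups(ages: Iterable[float]) -> np.ndarray:
    """Vectorised :func:`assign_age_group`."""
    ages = np.asarray(list(ages), dtype=float)
    if (ages < 16).any():
        bad = ages[ages < 16].min()
        raise ValueError(f"age {bad} is below the study minimum of 16 years")
    out = np.where(ages <= 44, "young", np.where(ages <= 74, "middle", "old"))
    return out.astype(object)


@dataclass
class ProbeGroup:
    """Probe sets interrogating one transcript.

    ``signals`` is a probe-set x sample table of log2 signals.
    """

    transcript_id: str
    signals: pd.DataFrame

    def __post_init__(self) -> None:
        if self.signals.shape[0] < 1:
            # Empty groups are tolerated here; summarize_gene_level skips them
            # with a logged warning rather than failing the whole run.
            pass


def summarize_gene_level(probe_groups: Sequence[ProbeGroup]) -> pd.DataFrame:
    """Collapse probe-set signals to one row per transcript by the median.

    The gene-level signal of a transcript in a sample is the median across the
    probe sets interrogating it. Probe groups without any probe set are
    skipped with a warning.
    """
    rows = {}
    for group in probe_groups:
        if group.signals.shape[0] == 0:
            logger.warning(
                "probe group %s has no probe sets; skipped", group.transcript_id
            )
            continue
        rows[group.transcript_id] = group.signals.median(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out


def anova_aging(
    matrix: pd.DataFrame,
    group_labels: Sequence[str],
    min_group_size: int = 2,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of log2 signal on age group, per gene.

    Parameters
    ----------
    matrix
        Gene x sample log2 expression for a single brain region.
    group_labels
        Age-group label per column of ``matrix``.
    min_group_size
        Groups with fewer samples are dropped from the test. If fewer than
        two usable groups remain, every gene is untestable and F and p are
        returned as NaN.

    Returns a DataFrame indexed by gene with columns ``F`` and ``p``.

    Degenerate cases follow the fixed-effects definitions: zero
    between-group and zero within-group variance gives F = 0, p = 1; perfect
    separation (within-group variance zero, group means unequal) gives
    F = inf and p = 0.
    """
    labels = np.asarray(list(group_labels), dtype=object)
    if len(labels) != matrix.shape[1]:
        raise ValueError("group_labels length must match number of samples")

    blocks = []
    for g in AGE_GROUPS:
        cols = np.flatnonzero(labels == g)
        if len(cols) >= min_group_size:
            blocks.append(matrix.to_numpy()[:, cols])
        elif len(cols) > 0:
            logger.warning("age group %r has < %d samples; dropped", g, min_group_size)

    out = pd.DataFrame(index=matrix.index.copy(), columns=["F", "p"], dtype=float)
    out.index.name = "gene_id"
    if len(blocks) < 2:
        logger.warning("fewer than 2 usable age groups; all genes untestable")
        return out

    k = len(blocks)
    sizes = np.array([b.shape[1] for b in blocks])
    n = sizes.sum()
    means = np.column_stack([b.mean(axis=1) for b in blocks])
    grand = np.column_stack([b.sum(axis=1) for b in blocks]).sum(axis=1) / n
    ss_between = (sizes[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.zeros(matrix.shape[0])
    for b, m in zip(blocks, means.T):
        ss_within += ((b - m[:, None]) ** 2).sum(axis=1)

    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    # ss_within == 0: perfect separation when group means differ, no signal
    # at all when they coincide.
    degenerate = ss_within <= 0
    F = np.where(degenerate & (ss_between > 0), np.inf, F)
    F = np.where(degenerate & (ss_between <= 0), 0.0, F)
    p = stats.f.sf(F, df1, df2)
    p = np.where(np.isinf(F), 0.0, p)
    out["F"] = F
    out["p"] = p
    return out


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    NaN p-values propagate as NaN q-values and do not count toward the family
    size.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return q
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def fold_change(matrix: pd.DataFrame, group_labels: Sequence[str]) -> pd.DataFrame:
    """Old-minus-young mean log2 difference per gene, with direction.

    ``delta_log2 = mean(old) - mean(young)``; ``direction`` is ``up`` when
    positive, ``down`` when negative and ``none`` on an exact tie.
    """
    labels = np.asarray(list(group_labels), dtype=object)
    young = matrix.to_numpy()[:, labels == "young"]
    old = matrix.to_numpy()[:, labels == "old"]
    if young.shape[1] == 0 or old.shape[1] == 0:
        raise ValueError("both young and old groups must be non-empty")
    delta = old.mean(axis=1) - young.mean(axis=1)
    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
    return pd.DataFrame(
        {"delta_log2": delta, "direction": direction}, index=matrix.index.copy()
    )


def run_de(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-region aging differential expression over all brain regions.

    ``expression`` is gene x sample (log2); ``metadata`` must be indexed or
    keyed by ``sample_id`` with columns ``region`` and ``age``. Within each
    region the three age groups are compared by one-way ANOVA, BH-adjusted
    across genes (untestable genes are excluded from the BH family for that
    region), and old-vs-young fold change is attached.

    Returns a tidy table with one row per (gene, region):
    gene_id, region, F, p, q, delta_log2, direction, significant.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[expression.columns]
    groups = assign_age_groups(meta["age"])

    records = []
    for region in pd.unique(meta["region"]):
        cols = meta.index[meta["region"].to_numpy() == region]
        sub = expression[cols]
        labels = groups[np.asarray(meta["region"] == region)]
        res = anova_aging(sub, labels)
        res["q"] = fdr_adjust(res["p"])
        try:
            fc = fold_change(sub, labels)
        except ValueError:
            fc = pd.DataFrame(
                {"delta_log2": np.nan, "direction": "none"}, index=sub.index
            )
        res = res.join(fc)
        res["region"] = region
        res["gene_id"] = res.index
        records.append(res.reset_index(drop=True))
    table = pd.concat(records, ignore_index=True)
    table["significant"] = table["q"] < fdr_threshold
    return table[
        ["gene_id", "region", "F", "p", "q", "delta_log2", "direction", "significant"]
    ]


@dataclass(frozen=True)
class BreadthThresholds:
    """Region-count cut-points of the breadth taxonomy.

    Defaults encode the 10-region taxonomy: specific = 1 region, selective =
    2-7, multi-regional >= 8, cross-regional = all regions.
    """

    selective_min: int = 2
    multi_regional_min: int = 8
    n_regions_total: int = 10


def classify_regional_breadth(
    n_significant: Mapping[str, int] | pd.Series,
    n_regions_total: int = 10,
    thresholds: BreadthThresholds | None = None,
) -> pd.Series:
    """Classify genes by the number of regions where they are aging-altered.

    A gene significant in exactly 1 region is ``region_specific``, in 2-7
    ``region_selective``, in >= 8 ``multi_regional`` and in all 10
    ``cross_regional``; genes significant nowhere are ``unclassified``.
    The cut-points are defined for the 10-region design; other region counts
    require explicit ``thresholds``.
    """
    if thresholds is None:
        if n_regions_total != 10:
            raise ValueError(
                "breadth cut-points are defined for 10 regions; pass explicit "
                "BreadthThresholds to rescale"
            )
        thresholds = BreadthThresholds()
    n = pd.Series(dict(n_significant) if not isinstance(n_significant, pd.Series) else n_significant)
    total = thresholds.n_regions_total
    if (n > total).any():
        raise ValueError("a gene cannot be significant in more regions than exist")

    def categorize(count: int) -> str:
        if count == 0:
            return "unclassified"
        if count == total:
            return "cross_regional"
        if count >= thresholds.multi_regional_min:
            return "multi_regional"
        if count >= thresholds.selective_min:
            return "region_selective"
        return "region_specific"

    out = n.map(categorize)
    out.name = "breadth"
    return out


def breadth_table(
    de_table: pd.DataFrame,
    n_regions_total: int = 10,
    thresholds: BreadthThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene breadth summary from a tidy :func:`run_de` table."""
    n_sig = (
        de_table.groupby("gene_id")["significant"].sum().astype(int)
    )
    cats = classify_regional_breadth(n_sig, n_regions_total, thresholds)
    return pd.DataFrame({"n_regions": n_sig, "breadth": cats}).rename_axis("gene_id")


def select_top_genes(de_table: pd.DataFrame, region: str, k: int) -> list[str]:
    """The k most significant genes in a region.

    Ordered by ascending q, then p, then gene id. If the region holds fewer
    than k rows the full ordered list is returned with a logged count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = de_table[de_table["region"] == region]
    sub = sub.sort_values(["q", "p", "gene_id"], kind="mergesort")
    genes = sub["gene_id"].tolist()
    if len(genes) < k:
        logger.info("region %s holds only %d genes (< k=%d)", region, len(genes), k)
        return genes
    return genes[:k]


def overrepresentation_test(
    gene_set: Iterable[str],
    category_genes: Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-sided hypergeometric over-representation p-value.

    Probability, under random draws from ``universe``, of an overlap between
    ``gene_set`` and ``category_genes`` at least as large as observed.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    gene_set = set(gene_set)
    category = set(category_genes)
    if not gene_set <= universe or not category <= universe:
        raise ValueError("gene_set and category_genes must be subsets of universe")
    overlap = len(gene_set & category)
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(category), len(gene_set))
    )
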