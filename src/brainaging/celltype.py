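"""Cell-type-specific gene lists and their enrichment across breadth classes.

A reference panel gives the mean (linear-scale) expression of every gene in
seven CNS cell types (neurons, astrocytes, OPCs, newly formed and myelinating
oligodendrocytes, microglia, endothelial cells). A gene's specificity score
for a type is its expression there relative to its maximum over the other
types; genes exceeding a score threshold form the per-type marker lists,
which are then intersected with independent lists and tested for
over-representation within regional-breadth categories of aging-altered
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diffexpr import overrepresentation_test

#: The seven reference CNS cell types.
CELL_TYPES = (
    "neuron",
    "astrocyte",
    "OPC",
    "newly_formed_OLG",
    "myelinating_OLG",
    "microglia",
    "endothelial",
)

DEFAULT_EPS = 1.0
DEFAULT_THRESHOLD = 5.0


@dataclass
class CellTypeReference:
    """Gene x cell-type mean expression panel on the linear scale.

    ``marker_truth`` (optional) records which genes were planted as markers of
    which type when the panel is synthetic.
    """

    profiles: pd.DataFrame
    marker_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("reference means must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)


def specificity_scores(
    reference: CellTypeReference | pd.DataFrame, eps: float = DEFAULT_EPS
) -> pd.DataFrame:
    """Specificity score of every gene for every cell type.

    score(g, t) = (mean expression of g in t + eps) /
                  (max mean expression of g over the other types + eps)

    The pseudocount ``eps`` (linear scale) keeps the ratio finite for genes
    silent outside their home type. Scores are dimensionless; a flat gene
    scores 1 everywhere, and at most one type can score above 1.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    prof = reference.profiles if isinstance(reference, CellTypeReference) else reference
    x = prof.to_numpy(dtype=float)
    n_types = x.shape[1]
    scores = np.empty_like(x)
    for j in range(n_types):
        others = np.delete(x, j, axis=1)
        scores[:, j] = (x[:, j] + eps) / (others.max(axis=1) + eps)
    return pd.DataFrame(scores, index=prof.index.copy(), columns=prof.columns.copy())


def specificity_score(
    reference: CellTypeReference | pd.DataFrame,
    gene: str,
    cell_type: str,
    eps: float = DEFAULT_EPS,
) -> float:
    """Specificity score of a single (gene, cell type) pair."""
    prof = reference.profiles if isinstance(reference, CellTypeReference) else reference
    if gene not in prof.index:
        raise KeyError(f"unknown gene {gene!r}")
    if cell_type not in prof.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    return float(specificity_scores(reference, eps=eps).loc[gene, cell_type])


def derive_marker_lists(
    reference: CellTypeReference | pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> dict[str, list[str]]:
    """Assign genes to cell types by thresholding the specificity score.

    A gene is a marker of type t iff score(g, t) >= threshold. With
    threshold > 1 at most one type can qualify per gene, so the lists are
    disjoint by construction.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1 so marker lists are disjoint")
    scores = specificity_scores(reference, eps=eps)
    return {
        t: scores.index[scores[t] >= threshold].tolist() for t in scores.columns
    }


def marker_table(
    reference: CellTypeReference | pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Tidy (gene, cell_type, score) table of derived markers."""
    scores = specificity_scores(reference, eps=eps)
    lists = derive_marker_lists(reference, threshold=threshold, eps=eps)
    rows = [
        {"gene_id": g, "cell_type": t, "score": scores.loc[g, t]}
        for t, genes in lists.items()
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "score"])


def consensus_lists(
    list_a: Mapping[str, Iterable[str]], list_b: Mapping[str, Iterable[str]]
) -> dict[str, list[str]]:
    """Per-type intersection of two marker-list collections.

    Only cell types present in both collections are retained; disjoint type
    keys are an error.
    """
    shared = set(list_a) & set(list_b)
    if not shared:
        raise ValueError("the two marker collections share no cell-type labels")
    return {
        t: sorted(set(list_a[t]) & set(list_b[t])) for t in sorted(shared)
    }


def _odds_ratio(overlap: int, set_size: int, cat_size: int, n_universe: int) -> float:
    """Sample odds ratio of the 2x2 membership table."""
    a = overlap
    b = set_size - overlap
    c = cat_size - overlap
    d = n_universe - set_size - cat_size + overlap
    if b * c == 0:
        return float("inf") if a * d > 0 else 0.0
    return (a * d) / (b * c)


def celltype_breadth_enrichment(
    marker_lists: Mapping[str, Iterable[str]],
    breadth: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of each marker list within each breadth category.

    ``breadth`` is the per-gene table with a ``breadth`` column (see
    ``diffexpr.breadth_table``). Marker lists are restricted to the universe
    of tested genes before testing. Empty categories or empty marker lists
    yield p = 1 with ``degenerate`` flagged.

    Returns a tidy table (cell_type, category, overlap, n_markers,
    n_category, p, odds_ratio, degenerate).
    """
    universe = set(universe)
    rows = []
    categories = breadth["breadth"].unique()
    for t in marker_lists:
        markers = set(marker_lists[t]) & universe
        for cat in categories:
            cat_genes = set(breadth.index[breadth["breadth"] == cat]) & universe
            degenerate = not markers or not cat_genes
            if degenerate:
                p, orat, overlap = 1.0, 0.0, 0
            else:
                overlap = len(markers & cat_genes)
                p = overrepresentation_test(markers, cat_genes, universe)
                orat = _odds_ratio(overlap, len(markers), len(cat_genes), len(universe))
            rows.append(
                {
                    "cell_type": t,
                    "category": cat,
                    "overlap": overlap,
                    "n_markers": len(markers),
                    "n_category": len(cat_genes),
                    "p": p,
                    "odds_ratio": orat,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
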