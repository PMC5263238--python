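"""Sample similarity, clustering, embedding and age-group discrimination.

Given a gene subset (e.g. the cross-regional aging-altered genes), samples
are compared by Spearman correlation, grouped by agglomerative clustering on
Euclidean distance, embedded in two dimensions by t-SNE, and scored for how
well a 3-way cut of the sample dendrogram recovers the true age groups. The
discrimination score operationalizes "successfully discriminated": clusters
are mapped onto age groups by the assignment maximizing sample-level
agreement (exhaustive over the 3! mappings), and an individual counts as
correct when the majority of its samples land in the cluster mapped to its
true group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE

from .diffexpr import AGE_GROUPS

DEFAULT_LINKAGE = "complete"


def sample_correlation(
    matrix: pd.DataFrame, gene_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Spearman correlation between samples over a gene subset.

    Constant sample vectors have undefined rank correlation; their
    off-diagonal entries are NaN (the diagonal stays 1).
    """
    sub = matrix.loc[list(gene_subset)] if gene_subset is not None else matrix
    if sub.shape[0] == 0:
        raise ValueError("gene subset must be non-empty")
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    rho = sub.corr(method="spearman")
    np.fill_diagonal(rho.to_numpy(), 1.0)
    return rho


@dataclass
class ClusterResult:
    """Agglomerative clustering of one axis of an expression matrix."""

    linkage: np.ndarray
    labels: list[str]
    method: str

    def cut(self, k: int) -> pd.Series:
        """Flat cluster ids (1..k) from cutting the dendrogram."""
        if k > len(self.labels):
            raise ValueError(f"k={k} exceeds the {len(self.labels)} clustered items")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram in Newick format (branch lengths from merge heights)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def hierarchical_cluster(
    matrix: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    axis: str = "samples",
    method: str = DEFAULT_LINKAGE,
) -> ClusterResult:
    """Agglomerative clustering on Euclidean distance.

    ``axis`` selects whether samples (columns) or genes (rows) are
    clustered. Complete linkage is the default; any scipy linkage method is
    accepted.
    """
    sub = matrix.loc[list(gene_subset)] if gene_subset is not None else matrix
    data = sub.T if axis == "samples" else sub
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(data.to_numpy(), metric="euclidean"), method=method)
    return ClusterResult(Z, list(data.index), method)


@dataclass
class EmbeddingResult:
    """2-D t-SNE coordinates for each sample."""

    coordinates: pd.DataFrame
    method: str
    seed: int
    perplexity: float


def embed(
    matrix: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> EmbeddingResult:
    """t-SNE embedding of samples on a gene subset.

    Requires n_samples > 3 * perplexity, the usual stability condition for
    the perplexity-calibrated Gaussian kernel.
    """
    sub = matrix.loc[list(gene_subset)] if gene_subset is not None else matrix
    n = sub.shape[1]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples (need n > 3*perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(sub.T.to_numpy())
    frame = pd.DataFrame(coords, index=sub.columns, columns=["dim1", "dim2"])
    return EmbeddingResult(frame, "tsne", seed, perplexity)


@dataclass
class DiscriminationReport:
    """Age-group discrimination of individuals from a 3-cluster sample cut."""

    n_correct: int
    n_total: int
    per_individual: pd.DataFrame
    per_region: pd.DataFrame | None
    cluster_to_group: dict[int, str]

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def _best_mapping(
    clusters: np.ndarray, true_groups: np.ndarray
) -> dict[int, str]:
    """Cluster -> age-group assignment maximizing sample-level agreement."""
    cluster_ids = sorted(pd.unique(clusters))
    groups = [g for g in AGE_GROUPS if g in set(true_groups)] or list(AGE_GROUPS)
    best, best_score = None, -1
    for perm in itertools.permutations(groups, min(len(cluster_ids), len(groups))):
        mapping = dict(zip(cluster_ids, perm))
        score = sum(mapping.get(c) == g for c, g in zip(clusters, true_groups))
        if score > best_score:
            best, best_score = mapping, score
    # Clusters beyond the number of groups (degenerate cuts) map to the group
    # with which they agree most.
    for c in cluster_ids:
        if c not in best:
            sub = true_groups[clusters == c]
            best[c] = pd.Series(sub).mode().iloc[0]
    return best


def score_age_discrimination(
    cluster_labels: pd.Series | Sequence[int],
    true_age_groups: Sequence[str],
    individuals: Sequence[str] | None = None,
    regions: Sequence[str] | None = None,
) -> DiscriminationReport:
    """Score how well sample clusters recover the true age groups.

    An individual's predicted group is the modal mapped group of its samples
    (ties broken by sample count, then by young < middle < old); the
    individual is correct when this matches its true group. The report is
    invariant to any relabeling of the cluster ids because the mapping is
    re-optimized over all assignments.
    """
    clusters = np.asarray(cluster_labels)
    truth = np.asarray(true_age_groups, dtype=object)
    if len(clusters) != len(truth):
        raise ValueError("cluster labels and true groups must align")
    if individuals is None:
        individuals = [f"s{i}" for i in range(len(clusters))]
    individuals = np.asarray(individuals, dtype=object)

    mapping = _best_mapping(clusters, truth)
    mapped = np.array([mapping[c] for c in clusters], dtype=object)

    rank = {g: i for i, g in enumerate(AGE_GROUPS)}
    rows = []
    for ind in pd.unique(individuals):
        sel = individuals == ind
        votes = pd.Series(mapped[sel]).value_counts()
        top = votes[votes == votes.max()].index
        predicted = sorted(top, key=lambda g: rank.get(g, 99))[0]
        true_group = pd.Series(truth[sel]).mode().iloc[0]
        rows.append(
            {
                "individual_id": ind,
                "predicted_group": predicted,
                "true_group": true_group,
                "n_samples": int(sel.sum()),
                "correct": predicted == true_group,
            }
        )
    per_individual = pd.DataFrame(rows)

    per_region = None
    if regions is not None:
        regions = np.asarray(regions, dtype=object)
        reg_rows = []
        for r in pd.unique(regions):
            sel = regions == r
            reg_rows.append(
                {
                    "region": r,
                    "n_samples": int(sel.sum()),
                    "n_correct": int((mapped[sel] == truth[sel]).sum()),
                }
            )
        per_region = pd.DataFrame(reg_rows)

    return DiscriminationReport(
        n_correct=int(per_individual["correct"].sum()),
        n_total=len(per_individual),
        per_individual=per_individual,
        per_region=per_region,
        cluster_to_group=mapping,
    )


def discriminate_age_groups(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    method: str = DEFAULT_LINKAGE,
) -> DiscriminationReport:
    """End-to-end: cluster samples on a gene subset, cut to 3, score groups."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[matrix.columns]
    clusters = hierarchical_cluster(matrix, gene_subset, axis="samples", method=method).cut(3)
    return score_age_discrimination(
        clusters.to_numpy(),
        meta["age_group"].to_numpy(),
        individuals=meta["individual_id"].to_numpy(),
        regions=meta["region"].to_numpy() if "region" in meta else None,
    )


def standardize_for_heatmap(values: pd.DataFrame, clip: float = 3.0) -> pd.DataFrame:
    """Per-row z-scores (population SD), clipped to [-clip, clip].

    Zero-variance rows standardize to all zeros.
    """
    if clip <= 0:
        raise ValueError("clip must be > 0")
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population convention (ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(
        np.clip(z, -clip, clip), index=values.index.copy(), columns=values.columns.copy()
    )
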