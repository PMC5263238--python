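"""Shuffled-label permutation tests on per-tile cell counts.

The observed statistic is a pooled-variance two-sample t comparing young
versus old tile counts (positive t = higher counts in young). The null
distribution comes from recomputing t under random label shuffles, optionally
over several resampling rounds that each draw a per-group tile subsample
first; p-values use the add-one convention so they can never be exactly
zero. Tiles, not cases, are the exchangeable units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Pooled-variance two-sample t statistic, sign convention x - y.

    Degenerate inputs: zero pooled variance gives t = 0 for equal means and
    +/- inf (flagged by the caller) for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    n1, n2 = len(x), len(y)
    diff = x.mean() - y.mean()
    pooled = (
        ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    ) / (n1 + n2 - 2)
    if pooled <= 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled * (1 / n1 + 1 / n2)))


def _t_from_partition(values: np.ndarray, x_idx: np.ndarray) -> np.ndarray:
    """Vectorised pooled t for many partitions.

    ``x_idx`` is (P, n1): the indices assigned to the first group in each of
    P partitions of ``values``; the rest form the second group.
    """
    n = len(values)
    n1 = x_idx.shape[1]
    n2 = n - n1
    total = values.sum()
    total_sq = (values**2).sum()
    sx = values[x_idx].sum(axis=1)
    sxx = (values[x_idx] ** 2).sum(axis=1)
    sy = total - sx
    syy = total_sq - sxx
    mx, my = sx / n1, sy / n2
    ssw = (sxx - n1 * mx**2) + (syy - n2 * my**2)
    pooled = ssw / (n1 + n2 - 2)
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1 / n1 + 1 / n2))
    degenerate_t = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t = np.where(pooled <= 0, degenerate_t, t)
    return t


@dataclass(frozen=True)
class PermutationScheme:
    """How the null is built: rounds, shuffles per round, tail, subsampling.

    ``n_iterations`` resampling rounds each draw ``subsample_size`` tiles per
    group (without replacement; None uses every tile) and shuffle labels
    ``n_permutations`` times; nulls pool across rounds, so the null holds
    n_iterations x n_permutations values.
    """

    n_iterations: int = 1
    n_permutations: int = 10_000
    tail: str = "right"
    subsample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_permutations < 1:
            raise ValueError("n_iterations and n_permutations must be >= 1")
        if self.tail not in ("right", "left", "two"):
            raise ValueError("tail must be 'right', 'left' or 'two'")
        if self.subsample_size is not None and self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2 per group")


@dataclass
class PermutationResult:
    """Observed (mean true-label) t, pooled null, p-value and null SD."""

    observed_t: float
    null: np.ndarray
    p_value: float
    null_sd: float
    scheme: PermutationScheme


def _tail_p(observed: float, null: np.ndarray, tail: str) -> float:
    """Add-one permutation p-value; never 0, minimum 1/(N_null+1)."""
    n = len(null)
    if n == 0:
        raise ValueError("null distribution is empty")
    right = (1 + np.count_nonzero(null >= observed)) / (1 + n)
    left = (1 + np.count_nonzero(null <= observed)) / (1 + n)
    if tail == "right":
        return right
    if tail == "left":
        return left
    return min(1.0, 2 * min(right, left))


def permutation_test(
    counts: Sequence[float],
    group_labels: Sequence[str],
    scheme: PermutationScheme | None = None,
    group_order: tuple[str, str] = ("young", "old"),
) -> PermutationResult:
    """Shuffled-label permutation test of a young-vs-old count difference.

    ``group_order`` fixes the sign convention: t > 0 means higher counts in
    the first-named group. The reported observed t is the mean of the
    true-label t across rounds.
    """
    scheme = scheme or PermutationScheme()
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(list(group_labels), dtype=object)
    g1, g2 = group_order
    idx1 = np.flatnonzero(labels == g1)
    idx2 = np.flatnonzero(labels == g2)
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("both groups need at least 2 tiles")

    rng = np.random.default_rng(scheme.seed)
    nulls = []
    observed = []
    for _ in range(scheme.n_iterations):
        if scheme.subsample_size is not None:
            s = scheme.subsample_size
            if s > len(idx1) or s > len(idx2):
                raise ValueError("subsample_size exceeds a group's tile count")
            take1 = rng.choice(idx1, size=s, replace=False)
            take2 = rng.choice(idx2, size=s, replace=False)
        else:
            take1, take2 = idx1, idx2
        values = counts[np.concatenate([take1, take2])]
        n1 = len(take1)
        observed.append(two_sample_t(values[:n1], values[n1:]))
        perm = np.argsort(
            rng.random((scheme.n_permutations, len(values))), axis=1
        )[:, :n1]
        nulls.append(_t_from_partition(values, perm))
    null = np.concatenate(nulls)
    obs = float(np.mean(observed))
    return PermutationResult(
        observed_t=obs,
        null=null,
        p_value=_tail_p(obs, null, scheme.tail),
        null_sd=float(null.std(ddof=0)),
        scheme=scheme,
    )


def exact_permutation_p(
    counts: Sequence[float],
    group_labels: Sequence[str],
    tail: str = "right",
    group_order: tuple[str, str] = ("young", "old"),
) -> float:
    """Exhaustive-enumeration permutation p-value (small designs only).

    Enumerates every partition of the tiles into the two group sizes;
    intended as the exact reference for Monte-Carlo results at <= ~12 tiles.
    The identity partition is part of the enumeration, so the add-one and
    plain conventions coincide.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(list(group_labels), dtype=object)
    g1, _ = group_order
    n1 = int((labels == g1).sum())
    observed = two_sample_t(counts[labels == g1], counts[labels != g1])
    parts = np.array(list(combinations(range(len(counts)), n1)))
    null = _t_from_partition(counts, parts)
    right = np.count_nonzero(null >= observed) / len(null)
    left = np.count_nonzero(null <= observed) / len(null)
    if tail == "right":
        return float(right)
    if tail == "left":
        return float(left)
    return float(min(1.0, 2 * min(right, left)))


def run_count_comparisons(
    tile_table: pd.DataFrame,
    measures: Sequence[str],
    scheme: PermutationScheme | None = None,
    group_order: tuple[str, str] = ("young", "old"),
) -> pd.DataFrame:
    """Permutation-test each count measure, young vs old, tiles as units.

    ``tile_table`` is the tidy per-tile table from ``ihc.summarize_case``
    (columns case_id, age_group, tile_id, measure, value). Unknown measures
    are skipped with a warning. Successive measures use decorrelated
    sub-seeds derived from the scheme seed.
    """
    scheme = scheme or PermutationScheme()
    rows = []
    available = set(tile_table["measure"])
    seed_seq = np.random.SeedSequence(scheme.seed)
    children = seed_seq.spawn(len(measures))
    for measure, child in zip(measures, children):
        if measure not in available:
            import warnings

            warnings.warn(f"measure {measure!r} absent from table; skipped", stacklevel=2)
            continue
        sub = tile_table[tile_table["measure"] == measure]
        sub_scheme = replace(scheme, seed=int(child.generate_state(1)[0] % (2**31)))
        res = permutation_test(
            sub["value"].to_numpy(),
            sub["age_group"].to_numpy(),
            sub_scheme,
            group_order=group_order,
        )
        rows.append(
            {
                "measure": measure,
                "observed_t": res.observed_t,
                "p_value": res.p_value,
                "null_sd": res.null_sd,
                "n_" + group_order[0]: int((sub["age_group"] == group_order[0]).sum()),
                "n_" + group_order[1]: int((sub["age_group"] == group_order[1]).sum()),
                "tail": scheme.tail,
                "n_iterations": scheme.n_iterations,
                "n_permutations": scheme.n_permutations,
            }
        )
    return pd.DataFrame(rows)
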