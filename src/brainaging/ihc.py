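"""Immunohistochemistry tile quantification.

Tiles are RGB crops of scanned slides in which cells of interest carry a
brown DAB stain (OLIG2 or NeuN) and all other nuclei a blue hematoxylin
counterstain. Each tile passes an information QC (Shannon entropy of the
grayscale histogram, tiles <= 5 bits excluded), then a channel-based
segmentation: Otsu foreground thresholding against the pale background,
per-pixel brown/blue classification from the red-blue channel difference,
morphological opening, 8-connected components, and a minimum-area filter.
Objects are binned by cell-body area (small 500-3,000 px, medium
3,000-6,000, large 6,000-9,000, very large > 9,000), tiles are classed by
nucleus density (pooled terciles proxying white vs gray matter) and the most
extreme tiles per case are selected for statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage import measure, morphology
from skimage.color import rgb2hed
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: Cell-body area bins in pixels. Lower bounds inclusive; ``large`` includes
#: its 9,000 upper bound so that ``very_large`` is strictly > 9,000.
SIZE_BINS = (
    ("small", 500, 3000),
    ("medium", 3000, 6000),
    ("large", 6000, 9001),  # upper bound exclusive => includes area 9000
    ("very_large", 9001, np.inf),
)
MIN_BINNED_AREA = 500

DEFAULT_ENTROPY_MIN = 5.0


@dataclass
class SegmentationParams:
    """Tunable parameters of the channel-based segmentation.

    ``delta`` is the red-minus-blue margin (intensity units) above which a
    foreground pixel is called brown/stained. ``mode`` 'channel' uses the raw
    RGB difference; 'hed' classifies by H-DAB color deconvolution instead.
    """

    delta: float = 20.0
    opening_radius: int = 2
    min_area: int = 50
    mode: str = "channel"

    def __post_init__(self) -> None:
        if self.mode not in ("channel", "hed"):
            raise ValueError("mode must be 'channel' or 'hed'")
        if self.min_area < 1 or self.opening_radius < 0:
            raise ValueError("min_area must be >= 1 and opening_radius >= 0")


@dataclass
class DetectedObject:
    """One segmented cell: centroid (pixels, origin top-left), area, class."""

    x: float
    y: float
    area: int
    stain_class: str  # "stained" | "other"
    mean_rgb: tuple[float, float, float]


def _luma(tile: np.ndarray) -> np.ndarray:
    """8-bit grayscale via the Rec. 601 luma weights."""
    tile = np.asarray(tile, dtype=float)
    gray = 0.299 * tile[..., 0] + 0.587 * tile[..., 1] + 0.114 * tile[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def compute_tile_entropy(tile: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin grayscale histogram.

    Ranges from 0 (constant tile) to 8 bits (all levels equally frequent).
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("tile is empty")
    counts = np.bincount(_luma(tile).ravel(), minlength=256)
    return float(_stats.entropy(counts, base=2))


def filter_tiles_by_entropy(
    entropies: Sequence[float], min_entropy: float = DEFAULT_ENTROPY_MIN
) -> np.ndarray:
    """Boolean retain mask: keep tiles with entropy strictly above the cutoff."""
    return np.asarray(entropies, dtype=float) > min_entropy


def segment_cells(
    tile: np.ndarray, params: SegmentationParams | None = None
) -> list[DetectedObject]:
    """Detect and classify stained/counterstained cells in one RGB tile.

    Pipeline: grayscale Otsu foreground (cells are darker than the pale
    background), per-pixel stain class (brown where R - B > delta, blue
    otherwise; or by H-DAB deconvolution in 'hed' mode), morphological
    opening, 8-connected components, minimum-area filter; each object takes
    the majority pixel class.
    """
    params = params or SegmentationParams()
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("tile must be an RGB array (H, W, 3)")
    rgb = tile.astype(float)
    gray = _luma(tile)
    if gray.min() == gray.max():
        return []
    fg = gray < threshold_otsu(gray)
    if params.opening_radius > 0:
        fg = morphology.opening(fg, morphology.disk(params.opening_radius))
    if not fg.any():
        return []

    if params.mode == "channel":
        stained_px = (rgb[..., 0] - rgb[..., 2]) > params.delta
    else:
        hed = rgb2hed(tile)
        stained_px = hed[..., 2] > hed[..., 0]

    labels = measure.label(fg, connectivity=2)
    objects: list[DetectedObject] = []
    for region in measure.regionprops(labels, intensity_image=rgb):
        if region.area < params.min_area:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        n_stained = int(stained_px[rr, cc].sum())
        cls = "stained" if n_stained * 2 > region.area else "other"
        cy, cx = region.centroid
        mean_rgb = tuple(float(v) for v in region.intensity_mean)
        objects.append(
            DetectedObject(
                x=float(cx), y=float(cy), area=int(region.area),
                stain_class=cls, mean_rgb=mean_rgb,
            )
        )
    return objects


def objects_frame(objects: Iterable[DetectedObject]) -> pd.DataFrame:
    """Tidy per-object table (x, y, area, stain_class, mean channel means)."""
    rows = [
        {
            "x": o.x, "y": o.y, "area": o.area, "stain_class": o.stain_class,
            "mean_r": o.mean_rgb[0], "mean_g": o.mean_rgb[1], "mean_b": o.mean_rgb[2],
        }
        for o in objects
    ]
    return pd.DataFrame(rows, columns=["x", "y", "area", "stain_class", "mean_r", "mean_g", "mean_b"])


def bin_label(area: float) -> str | None:
    """Size-bin label for one area; None when area < 500 px (unbinned)."""
    if area < MIN_BINNED_AREA:
        return None
    for label, lo, hi in SIZE_BINS:
        if lo <= area < hi:
            return label
    raise AssertionError("size bins must cover [500, inf)")


def bin_by_area(objects: Iterable[DetectedObject] | Sequence[float]) -> dict[str, int]:
    """Counts per size bin; objects under 500 px stay out of every bin."""
    areas = [
        o.area if isinstance(o, DetectedObject) else float(o) for o in objects
    ]
    counts = {label: 0 for label, _, _ in SIZE_BINS}
    for a in areas:
        label = bin_label(a)
        if label is not None:
            counts[label] += 1
    return counts


@dataclass
class TileStats:
    """Per-tile counts, QC entropy, and (optionally) a density class."""

    tile_id: str
    case_id: str
    age_group: str
    n_total: int
    n_stained: int
    n_other: int
    bins: dict[str, int]
    entropy: float
    density_class: str | None = None

    def __post_init__(self) -> None:
        if self.n_stained + self.n_other != self.n_total:
            raise ValueError("stained + other must equal total")


def tile_stats(
    tile: np.ndarray,
    tile_id: str,
    case_id: str,
    age_group: str,
    params: SegmentationParams | None = None,
) -> tuple[list[DetectedObject], TileStats]:
    """Segment one tile and summarize it."""
    objects = segment_cells(tile, params)
    n_stained = sum(o.stain_class == "stained" for o in objects)
    stats = TileStats(
        tile_id=tile_id,
        case_id=case_id,
        age_group=age_group,
        n_total=len(objects),
        n_stained=n_stained,
        n_other=len(objects) - n_stained,
        bins=bin_by_area(objects),
        entropy=compute_tile_entropy(tile),
    )
    return objects, stats


def stats_frame(tiles: Iterable[TileStats]) -> pd.DataFrame:
    """One row per tile with counts, bins and entropy."""
    rows = []
    for t in tiles:
        row = {
            "tile_id": t.tile_id, "case_id": t.case_id, "age_group": t.age_group,
            "total": t.n_total, "stained": t.n_stained, "other": t.n_other,
            "entropy": t.entropy, "density_class": t.density_class,
        }
        row.update({f"bin_{k}": v for k, v in t.bins.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def classify_density(
    tiles: pd.DataFrame,
    k: int = 50,
    low_fraction: float = 1 / 3,
    high_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Assign pooled-tercile density classes and select extreme tiles per case.

    Tiles are ranked by total nucleus count (stable ties by tile id) over the
    pooled distribution: the bottom ``low_fraction`` are ``low`` density, the
    top ``high_fraction`` are ``high``, the rest ``mid``. Within the low
    class the k lowest-count tiles per case are selected, within the high
    class the k highest; a shortfall selects all and logs it.

    Returns a copy of ``tiles`` with ``density_class`` and ``selected``
    columns.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = tiles.copy()
    order = out.sort_values(["total", "tile_id"], kind="mergesort").index
    n = len(out)
    n_low = int(n * low_fraction)
    n_high = int(n * high_fraction)
    cls = pd.Series("mid", index=out.index)
    cls.loc[order[:n_low]] = "low"
    if n_high > 0:
        cls.loc[order[n - n_high:]] = "high"
    out["density_class"] = cls

    selected = pd.Series(False, index=out.index)
    for case_id, case_tiles in out.groupby("case_id"):
        for dclass, ascending in (("low", True), ("high", False)):
            pool = case_tiles[case_tiles["density_class"] == dclass]
            if len(pool) < k:
                logger.info(
                    "case %s has only %d %s-density tiles (< k=%d); selecting all",
                    case_id, len(pool), dclass, k,
                )
            chosen = pool.sort_values(
                ["total", "tile_id"], ascending=[ascending, True], kind="mergesort"
            ).index[:k]
            selected.loc[chosen] = True
    out["selected"] = selected
    return out


def rank_tiles_by_density(tiles: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k tiles with the highest nucleus counts across all cases.

    Ties are broken stably by tile id; k beyond the table returns everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = tiles.sort_values(
        ["total", "tile_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k).copy()


MEASURES = ("total", "stained", "other") + tuple(f"bin_{b}" for b, _, _ in SIZE_BINS)


def summarize_case(tiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-tile measures and per-case totals.

    Returns (tile-level tidy table keyed case/age_group/tile/measure,
    case-level totals keyed case/age_group/measure).
    """
    if len(tiles) == 0:
        raise ValueError("need at least one retained tile")
    measures = [m for m in MEASURES if m in tiles.columns]
    tidy = tiles.melt(
        id_vars=["case_id", "age_group", "tile_id"],
        value_vars=measures,
        var_name="measure",
        value_name="value",
    )
    case_totals = (
        tidy.groupby(["case_id", "age_group", "measure"], sort=False)["value"]
        .sum()
        .reset_index()
    )
    return tidy, case_totals
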