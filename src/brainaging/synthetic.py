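"""Synthetic cohorts, cell-type reference panels and stained image tiles.

Every generator carries its ground truth alongside the data so downstream
recovery can be measured: the expression generator plants aging effects with
known per-region direction and magnitude, the reference generator records
which genes are true markers of which type, and the tile generator returns
the centroid, radius and stain class of every rendered disk.

The emulated design mirrors a multi-region post-mortem cohort: each
individual contributes samples from up to ten brain regions, ages span
16-102 years and fall into three groups (young 16-44, middle 45-74, old
>= 75), and planted aging effects shift the old-group mean by a chosen log2
amount with the middle group halfway in between. Image tiles emulate
DAB-stained (brown) and hematoxylin-counterstained (blue) somata as flat
colored disks on a pale background plus Gaussian RGB noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk_pixels

from .celltype import CELL_TYPES, CellTypeReference
from .diffexpr import assign_age_groups

#: The ten sampled brain regions.
REGIONS = (
    "FCTX", "TCTX", "OCTX", "WHMT", "CRBL",
    "SNIG", "PUTM", "THAL", "HIPP", "MEDU",
)

_BANKS = ("MRC_sudden_death", "sun_health")
_BANK_PROBS = (99 / 134, 35 / 134)  # cohort-shaped source proportions
_CAUSES = ("cardiac", "respiratory", "accident", "other")
_SEXES = ("M", "F")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when disjoint disks cannot be placed within the attempt budget."""


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth aging effect on one gene.

    ``effect_size`` is the old-minus-young group-mean difference in log2
    units within each affected region; the middle group sits at the
    midpoint. ``direction`` 'down' flips the sign.
    """

    gene_id: str
    affected_regions: tuple[str, ...]
    direction: str = "up"
    effect_size: float = 2.0
    celltype_label: str | None = None

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not self.affected_regions:
            raise ConfigurationError("affected_regions must be non-empty")
        if self.direction not in ("up", "down"):
            raise ConfigurationError("direction must be 'up' or 'down'")

    @property
    def signed_size(self) -> float:
        return self.effect_size if self.direction == "up" else -self.effect_size


@dataclass
class ExpressionStudyConfig:
    """Configuration of a synthetic multi-region expression cohort.

    Ages are drawn uniformly over ``age_range`` (integer years), so group
    sizes are unequal, as in a real cohort. ``missing_region_rate`` drops an
    individual's sample for a region completely at random; the 0.08 default
    reproduces the shape of a cohort in which 134 individuals contribute
    1,231 of a possible 1,340 region samples. ``region_offsets`` optionally
    gives each region a per-gene-block log2 shift (regional identity);
    offsets are drawn N(0, region_offset_sd) per (region, block) when not
    given explicitly.
    """

    n_individuals: int = 30
    regions: tuple[str, ...] = REGIONS
    age_range: tuple[int, int] = (16, 102)
    n_genes: int = 2000
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    region_offsets: dict[str, Sequence[float]] | None = None
    region_offset_sd: float = 0.25
    n_gene_blocks: int = 20
    missing_region_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 6:
            raise ConfigurationError("n_individuals must be >= 6")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigurationError("regions must be unique")
        if len(self.regions) > 10:
            raise ConfigurationError("at most 10 regions are supported")
        lo, hi = self.age_range
        if not (16 <= lo <= hi <= 106):
            raise ConfigurationError("age_range must lie within [16, 106]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 <= self.missing_region_rate < 1:
            raise ConfigurationError("missing_region_rate must be in [0, 1)")
        if self.n_genes < 1 or self.n_gene_blocks < 1:
            raise ConfigurationError("n_genes and n_gene_blocks must be >= 1")
        for eff in self.planted_effects:
            unknown = set(eff.affected_regions) - set(self.regions)
            if unknown:
                raise ConfigurationError(
                    f"planted effect {eff.gene_id} names unknown regions {sorted(unknown)}"
                )

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


@dataclass
class ExpressionStudy:
    """A synthetic cohort: expression, sample metadata, planted-effect truth.

    ``expression`` is gene x sample (log2); ``metadata`` has one row per
    sample with columns sample_id, individual_id, region, age, age_group,
    sex, bank, cause_of_death; ``truth`` lists the planted effects.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    config: ExpressionStudyConfig | None = None


def _effect_multiplier(age_group: np.ndarray) -> np.ndarray:
    """Old samples get the full planted shift, middle the midpoint, young none."""
    return np.where(age_group == "old", 1.0, np.where(age_group == "middle", 0.5, 0.0))


def generate_expression_study(config: ExpressionStudyConfig) -> ExpressionStudy:
    """Draw one cohort from the configured generative model."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, config.n_individuals)
    sexes = rng.choice(_SEXES, config.n_individuals)
    banks = rng.choice(_BANKS, config.n_individuals, p=_BANK_PROBS)
    causes = rng.choice(_CAUSES, config.n_individuals)

    present = rng.random((config.n_individuals, len(config.regions))) >= config.missing_region_rate

    meta_rows = []
    for i in range(config.n_individuals):
        ind = f"ind{i:03d}"
        for j, region in enumerate(config.regions):
            if not present[i, j]:
                continue
            meta_rows.append(
                {
                    "sample_id": f"{ind}_{region}",
                    "individual_id": ind,
                    "region": region,
                    "age": int(ages[i]),
                    "sex": sexes[i],
                    "bank": banks[i],
                    "cause_of_death": causes[i],
                }
            )
    metadata = pd.DataFrame(meta_rows)
    metadata["age_group"] = assign_age_groups(metadata["age"])
    n_samples = len(metadata)

    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(config.n_genes)

    # Regional identity: per-(region, block) log2 offsets.
    blocks = np.minimum(
        np.arange(config.n_genes) * config.n_gene_blocks // config.n_genes,
        config.n_gene_blocks - 1,
    )
    if config.region_offsets is not None:
        offsets = {
            r: np.asarray(v, dtype=float) for r, v in config.region_offsets.items()
        }
        for r, v in offsets.items():
            if len(v) != config.n_gene_blocks:
                raise ConfigurationError(
                    f"region_offsets[{r!r}] must have n_gene_blocks={config.n_gene_blocks} entries"
                )
    else:
        offsets = {
            r: config.region_offset_sd * rng.standard_normal(config.n_gene_blocks)
            for r in config.regions
        }

    signal = np.tile(baseline[:, None], (1, n_samples))
    region_arr = metadata["region"].to_numpy()
    for r in config.regions:
        cols = region_arr == r
        if r in offsets and cols.any():
            signal[:, cols] += offsets[r][blocks][:, None]

    mult = _effect_multiplier(metadata["age_group"].to_numpy())
    for eff in config.planted_effects:
        if eff.gene_id not in gene_index:
            raise ConfigurationError(f"planted effect names unknown gene {eff.gene_id!r}")
        row = gene_index[eff.gene_id]
        affected = np.isin(region_arr, eff.affected_regions)
        signal[row, affected] += eff.signed_size * mult[affected]

    signal += config.noise_sd * rng.standard_normal(signal.shape)

    expression = pd.DataFrame(signal, index=pd.Index(genes, name="gene_id"),
                              columns=pd.Index(metadata["sample_id"].to_numpy()))
    truth = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "affected_regions": ",".join(e.affected_regions),
                "direction": e.direction,
                "effect_size": e.effect_size,
                "celltype_label": e.celltype_label or "",
            }
            for e in config.planted_effects
        ],
        columns=["gene_id", "affected_regions", "direction", "effect_size", "celltype_label"],
    )
    return ExpressionStudy(expression, metadata, truth, config)


# ---------------------------------------------------------------------------
# Cell-type reference panels
# ---------------------------------------------------------------------------

@dataclass
class CellTypeReferenceConfig:
    """Configuration of a synthetic cell-type reference panel.

    Each planted marker's home-type mean is exactly ``marker_fold`` times its
    maximum over the other six types before noise; multiplicative log-normal
    noise (sigma ``noise_sd`` on the natural-log scale) is applied afterwards.
    Non-marker genes vary across types only within a bounded jitter so they
    never mimic a marker.
    """

    cell_types: tuple[str, ...] = CELL_TYPES
    n_genes: int = 2000
    markers_per_type: int = 50
    marker_fold: float = 20.0
    noise_sd: float = 0.05
    base_range: tuple[float, float] = (20.0, 200.0)
    jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) != len(set(self.cell_types)):
            raise ConfigurationError("cell type labels must be unique")
        if self.marker_fold <= 1:
            raise ConfigurationError("marker_fold must be > 1")
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ConfigurationError(
                "markers_per_type x number of cell types exceeds n_genes"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.jitter < 1:
            raise ConfigurationError("jitter must be in [0, 1)")


def generate_celltype_reference(config: CellTypeReferenceConfig) -> CellTypeReference:
    """Draw one reference panel with recorded marker ground truth."""
    rng = np.random.default_rng(config.seed)
    n_types = len(config.cell_types)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    base = rng.uniform(*config.base_range, config.n_genes)
    values = base[:, None] * rng.uniform(
        1 - config.jitter, 1 + config.jitter, (config.n_genes, n_types)
    )

    truth_rows = []
    for j, t in enumerate(config.cell_types):
        rows = range(j * config.markers_per_type, (j + 1) * config.markers_per_type)
        for i in rows:
            others = np.delete(values[i], j)
            values[i, j] = config.marker_fold * others.max()
            truth_rows.append({"gene_id": genes[i], "cell_type": t})

    if config.noise_sd > 0:
        values = values * np.exp(
            config.noise_sd * rng.standard_normal(values.shape)
        )

    profiles = pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"), columns=list(config.cell_types)
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "cell_type"])
    return CellTypeReference(profiles, marker_truth=truth)


# ---------------------------------------------------------------------------
# Stained image tiles
# ---------------------------------------------------------------------------

@dataclass
class TileConfig:
    """Configuration of one synthetic stained tile.

    Disks of the stained class render in a DAB-like brown, counterstained
    disks in a hematoxylin-like blue, on a pale background; iid Gaussian
    noise (``noise_sd`` intensity units) is added per channel.
    """

    width: int = 1600
    height: int = 1200
    n_stained: int = 25
    n_counterstained: int = 25
    radius_range: tuple[int, int] = (8, 20)
    stained_color: tuple[int, int, int] = (150, 100, 60)
    counterstained_color: tuple[int, int, int] = (70, 85, 150)
    background_color: tuple[int, int, int] = (235, 230, 225)
    overlap_allowed: bool = False
    noise_sd: float = 3.0
    min_separation: float = 2.0
    max_attempts_per_disk: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width * self.height <= 0:
            raise ConfigurationError("tile must have positive area")
        for color in (self.stained_color, self.counterstained_color, self.background_color):
            if any(not 0 <= c <= 255 for c in color):
                raise ConfigurationError("RGB components must lie in [0, 255]")
        if self.radius_range[0] < 2 or self.radius_range[1] < self.radius_range[0]:
            raise ConfigurationError("radius_range minimum must be >= 2")
        if self.n_stained < 0 or self.n_counterstained < 0:
            raise ConfigurationError("disk counts must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.min_separation < 0:
            raise ConfigurationError("min_separation must be >= 0")


@dataclass
class TileGroundTruth:
    """Every rendered disk: centroid (x, y), radius and stain class.

    Coordinates are pixels, origin top-left, x rightward, y downward.
    """

    objects: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        if len(self.objects) == 0:
            return {"stained": 0, "counterstained": 0}
        c = self.objects["stain_class"].value_counts().to_dict()
        return {"stained": c.get("stained", 0), "counterstained": c.get("counterstained", 0)}

    def to_json(self) -> str:
        return json.dumps(
            {"objects": self.objects.to_dict(orient="records"), "counts": self.counts}
        )


def generate_tile(config: TileConfig) -> tuple[np.ndarray, TileGroundTruth]:
    """Render one tile and its ground truth.

    Disks lie fully inside the tile. With ``overlap_allowed`` False,
    placement uses rejection sampling with ``max_attempts_per_disk`` tries
    per disk; exhausting the budget raises :class:`PlacementError` naming
    the achieved count.
    """
    rng = np.random.default_rng(config.seed)
    classes = ["stained"] * config.n_stained + ["counterstained"] * config.n_counterstained

    placed: list[tuple[float, float, int, str]] = []  # (x, y, r, class)
    for idx, cls in enumerate(classes):
        r = int(rng.integers(config.radius_range[0], config.radius_range[1] + 1))
        for _ in range(config.max_attempts_per_disk):
            x = float(rng.uniform(r, config.width - r))
            y = float(rng.uniform(r, config.height - r))
            # the separation margin keeps rasterized boundaries from becoming
            # 8-adjacent, so rendered disks stay disjoint as components
            gap = r + config.min_separation
            if config.overlap_allowed or all(
                (x - px) ** 2 + (y - py) ** 2 > (gap + pr) ** 2 for px, py, pr, _ in placed
            ):
                placed.append((x, y, r, cls))
                break
        else:
            raise PlacementError(
                f"placed only {len(placed)} of {len(classes)} disjoint disks "
                f"within {config.max_attempts_per_disk} attempts per disk"
            )

    image = np.empty((config.height, config.width, 3), dtype=float)
    image[:] = config.background_color
    color = {"stained": config.stained_color, "counterstained": config.counterstained_color}
    for x, y, r, cls in placed:
        rr, cc = _disk_pixels((y, x), r, shape=(config.height, config.width))
        image[rr, cc] = color[cls]

    if config.noise_sd > 0:
        image += config.noise_sd * rng.standard_normal(image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    truth = TileGroundTruth(
        pd.DataFrame(placed, columns=["x", "y", "radius", "stain_class"])
    )
    return image, truth
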