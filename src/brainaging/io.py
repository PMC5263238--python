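"""Plain-text I/O: TSV matrices and metadata, GMT gene sets, PNG tiles."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import ExpressionStudy, TileGroundTruth


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    """Genes as rows (gene_id column), samples as columns."""
    expression.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(study: ExpressionStudy, outdir: str | Path) -> dict[str, Path]:
    """Write expression.tsv, metadata.tsv and truth.tsv into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(study.expression, paths["expression"])
    write_metadata(study.metadata, paths["metadata"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_study(indir: str | Path) -> ExpressionStudy:
    indir = Path(indir)
    return ExpressionStudy(
        expression=read_expression(indir / "expression.tsv"),
        metadata=read_metadata(indir / "metadata.tsv"),
        truth=pd.read_csv(indir / "truth.tsv", sep="\t"),
    )


def write_reference(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.rename_axis("gene_id").to_csv(path, sep="\t")


def read_reference(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: one set per line, name TAB description TAB genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_tile(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), image)


def read_tile(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_ground_truth(truth: TileGroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path: str | Path) -> TileGroundTruth:
    payload = json.loads(Path(path).read_text())
    frame = pd.DataFrame(
        payload["objects"], columns=["x", "y", "radius", "stain_class"]
    )
    return TileGroundTruth(frame)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Tile manifest: columns path, case_id, age_group (and optional dialect)."""
    manifest = pd.read_csv(path, sep="\t")
    required = {"path", "case_id", "age_group"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest
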