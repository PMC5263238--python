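import numpy as np
import pandas as pd
import pytest

from brainaging import synthetic


@pytest.fixture(scope="session")
def small_study():
    """A small 4-region cohort with two planted effects and known truth."""
    regions = ("FCTX", "CRBL", "HIPP", "SNIG")
    effects = (
        synthetic.PlantedEffect("g00000", regions, "up", 2.0),
        synthetic.PlantedEffect("g00001", ("FCTX",), "down", 2.0),
    )
    config = synthetic.ExpressionStudyConfig(
        n_individuals=30,
        regions=regions,
        n_genes=120,
        planted_effects=effects,
        noise_sd=0.5,
        missing_region_rate=0.0,
        seed=11,
    )
    return synthetic.generate_expression_study(config)


@pytest.fixture(scope="session")
def small_reference():
    config = synthetic.CellTypeReferenceConfig(
        n_genes=400, markers_per_type=20, marker_fold=20.0, seed=7
    )
    return synthetic.generate_celltype_reference(config)


@pytest.fixture(scope="session")
def small_tile():
    config = synthetic.TileConfig(
        width=600, height=400, n_stained=6, n_counterstained=8,
        radius_range=(8, 14), seed=3,
    )
    return synthetic.generate_tile(config)
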