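"""Shared fixtures: small ground-truthed synthetic panels."""

import numpy as np
import pandas as pd
import pytest

from phenomap import PanelConfig, simulate_panel
from phenomap.containers import StrainAnnotation, TraitMatrix


@pytest.fixture(scope="session")
def null_panel():
    """An exchangeable 5-population panel with no planted effects."""
    cfg = PanelConfig(n_environments=50, seed=11)
    return simulate_panel(cfg)


@pytest.fixture()
def tiny_matrix():
    """A fully explicit 4-strain x 6-trait matrix for hand-checked tests."""
    values = pd.DataFrame(
        {
            "E001|lag": [0.0, 1.0, -1.0, 0.5],
            "E001|rate": [0.0, 2.0, -0.5, 0.25],
            "E001|efficiency": [0.0, 0.5, -2.0, 1.0],
            "E002|lag": [0.1, 1.1, -0.9, np.nan],
            "E002|rate": [0.2, 1.8, -0.3, 0.3],
            "E002|efficiency": [-0.1, 0.6, -1.5, 0.9],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return TraitMatrix(values)


@pytest.fixture()
def annotation_table():
    return StrainAnnotation(
        pd.DataFrame(
            {
                "strain_id": ["s1", "s2", "s3", "s4"],
                "species": ["A", "A", "A", "A"],
                "population": ["P1", "P1", "P2", "P2"],
                "source": ["wild", "lab", "wild", "clinical"],
                "mosaic": [False, False, False, False],
                "auxotroph": [False, False, False, True],
                "clean_lineage": [True, True, True, True],
            }
        )
    )
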