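import numpy as np
import pandas as pd
import pytest

import immunopanel as ip


@pytest.fixture(scope="session")
def small_panel():
    """A 50-gene panel with 7 housekeeping, full control set, 3 sets, 2 cell types."""
    return ip.simulate_panel(
        n_endogenous=50, n_housekeeping=7, n_positive=6, n_negative=8,
        n_sets=3, n_cell_types=2, seed=11,
    )


@pytest.fixture(scope="session")
def two_group_design():
    return ip.build_design(
        [("VEH", "single", "day1", "lung", 8), ("cSiO2", "single", "day1", "lung", 8)]
    )


@pytest.fixture(scope="session")
def planted_experiment(small_panel, two_group_design):
    """Counts with one +2 log2 planted gene and uniform responders."""
    panel, sets, markers = small_panel
    config = ip.SimulationConfig(effects={"Gene0001": 2.0}, responder_fraction=1.0)
    matrix, truth = ip.simulate_counts(panel, two_group_design, config, seed=5)
    return matrix, truth


@pytest.fixture(scope="session")
def normalized_experiment(small_panel, planted_experiment):
    panel, sets, markers = small_panel
    matrix, truth = planted_experiment
    normalizer = ip.PanelNormalizer()
    normalized = normalizer.fit_transform(matrix, panel)
    return normalized, normalizer


@pytest.fixture
def two_group_contrast(two_group_design):
    meta = two_group_design
    case = tuple(meta.index[meta["treatment"] == "cSiO2"])
    ref = tuple(meta.index[meta["treatment"] == "VEH"])
    return ip.Contrast("Acute.1x", case, ref)


def make_count_matrix(counts: dict[str, list], probes: list[str]) -> ip.CountMatrix:
    """Helper: build a CountMatrix with dummy lung metadata."""
    frame = pd.DataFrame(counts, index=probes)
    meta = pd.DataFrame(
        {
            "treatment": "VEH",
            "regimen": "single",
            "time_point": "day1",
            "tissue": "lung",
            "replicate": np.arange(1, len(frame.columns) + 1),
        },
        index=frame.columns,
    )
    return ip.CountMatrix(frame, meta, stage="raw")
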