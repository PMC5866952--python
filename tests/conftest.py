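"""Shared fixtures: small deterministic tables and a scaled-down design."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drymarker import FeatureMatrix, SimulationDesign


@pytest.fixture
def small_yields() -> pd.DataFrame:
    """Two trials x three cultivars with exact hand-checkable means."""
    rows = []
    cells = {
        # trial -> cultivar -> (control_mean, drought_mean)
        "T1": {"A": (80, 40), "B": (100, 60), "C": (50, 45)},
        "T2": {"A": (90, 45), "B": (110, 77), "C": (60, 30)},
    }
    for trial, cultivars in cells.items():
        for cultivar, (c, d) in cultivars.items():
            for r, (cv, dv) in enumerate(zip((c - 2, c + 2), (d - 2, d + 2))):
                rows.append((cultivar, trial, "control", f"r{r}", cv))
                rows.append((cultivar, trial, "drought", f"r{r}", dv))
    df = pd.DataFrame(
        rows, columns=["cultivar", "trial", "treatment", "replicate", "starch_yield"]
    )
    return df.astype({"starch_yield": float})


@pytest.fixture
def tiny_design() -> SimulationDesign:
    """Reduced problem size for fast end-to-end runs."""
    return SimulationDesign(
        n_cultivars=12,
        n_experimental_trials=3,
        n_agronomic_trials=4,
        metabolite_experimental_trials=3,
        metabolite_agronomic_trials=4,
        transcript_experimental_trials=2,
        transcript_agronomic_trials=2,
        metabolite_replicates=2,
        n_metabolites=40,
        n_transcripts=20,
        n_informative_metabolites=6,
        n_informative_transcripts=5,
    )


def feature_matrix(values: np.ndarray, meta: dict | None = None) -> FeatureMatrix:
    """Build a FeatureMatrix from a raw array with generated ids."""
    values = np.asarray(values, dtype=float)
    idx = [f"s{i}" for i in range(values.shape[0])]
    cols = [f"f{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=idx, columns=cols)
    mdf = pd.DataFrame(meta or {}, index=idx)
    return FeatureMatrix(vdf, mdf)
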