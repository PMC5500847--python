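"""Shared fixtures: hand-built cell ensembles and short acquisitions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from impedcyto.core import AcquisitionConfig
from impedcyto.sim.cells import GM, LYMPHOCYTE, CellEnsemble


def make_ensemble(diameters, classes, arrival_times, cd64=None) -> CellEnsemble:
    """Build a CellEnsemble from explicit per-cell values."""
    diameters = np.asarray(diameters, dtype=float)
    n = diameters.size
    cd64 = np.zeros(n) if cd64 is None else np.asarray(cd64, dtype=float)
    frame = pd.DataFrame(
        {
            "cell_class": list(classes),
            "diameter_um": diameters,
            "cd64_expression": cd64,
            "arrival_time_s": np.asarray(arrival_times, dtype=float),
        }
    )
    n_lymph = int((frame["cell_class"] == LYMPHOCYTE).sum())
    return CellEnsemble(
        frame,
        ground_truth={"n_lymphocytes": n_lymph, "n_gm": n - n_lymph},
    )


def spaced_mixture_ensemble(
    n_cells: int, spacing_s: float = 5e-3, lymph_fraction: float = 0.35, seed: int = 0
) -> CellEnsemble:
    """A two-class ensemble with regular (non-coincident) arrivals."""
    rng = np.random.default_rng(seed)
    n_lymph = int(round(lymph_fraction * n_cells))
    classes = np.array(
        [LYMPHOCYTE] * n_lymph + [GM] * (n_cells - n_lymph), dtype=object
    )
    rng.shuffle(classes)
    diameters = np.where(
        classes == LYMPHOCYTE,
        np.clip(rng.normal(8.5, 0.6, n_cells), 6.0, 10.0),
        np.clip(rng.normal(13.0, 0.6, n_cells), 11.0, 15.0),
    )
    arrivals = (np.arange(n_cells) + 0.5) * spacing_s + rng.uniform(
        -1e-4, 1e-4, n_cells
    )
    return make_ensemble(diameters, classes, arrivals)


@pytest.fixture
def short_acquisition() -> AcquisitionConfig:
    """A 2-second acquisition at the reference 250 kHz sampling rate."""
    return AcquisitionConfig(duration_s=2.0)
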