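"""Synthetic leukocyte ensembles.

Leukocytes reaching the counters after erythrocyte lysis fall into two
size classes: lymphocytes (6–10 µm diameter) and the merged
granulocyte+monocyte population (11–15 µm).  The Coulter counters cannot
separate granulocytes from monocytes, so the simulator uses the same
two-class model the device resolves.  Each cell carries a CD64 expression
index drawn log-normally around the sample's nCD64 value, and a Poisson
arrival time set by the cell concentration and the blood pump rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..core import AcquisitionConfig, ConfigurationError

__all__ = ["PopulationConfig", "CellEnsemble", "simulate_cell_population"]

LYMPHOCYTE = "lymphocyte"
GM = "granulocyte_monocyte"

#: Diameter support (µm) for the two size classes.
LYMPH_DIAMETER_RANGE = (6.0, 10.0)
GM_DIAMETER_RANGE = (11.0, 15.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth description of one blood sample's leukocytes.

    Either ``n_cells`` is given directly, or it is drawn Poisson with mean
    ``concentration_per_ul × blood_flow_ul_min / 60 × duration_s``.

    ``ncd64`` is the sample-level neutrophil CD64 index; per-cell CD64
    expression is log-normal with median ``ncd64`` (granulocytes+monocytes)
    or ``lymph_cd64`` (lymphocytes, essentially CD64-negative).
    """

    n_cells: int | None = None
    concentration_per_ul: float | None = 5000.0
    lymphocyte_fraction: float = 0.35
    lymph_diameter_mean_um: float = 8.5
    lymph_diameter_sd_um: float = 0.6
    gm_diameter_mean_um: float = 13.0
    gm_diameter_sd_um: float = 0.6
    ncd64: float = 2.0
    cd64_sigma: float = 0.35
    lymph_cd64: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cells is not None and self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.n_cells is None:
            if self.concentration_per_ul is None or self.concentration_per_ul < 0:
                raise ConfigurationError("concentration_per_ul must be >= 0")
        if not 0.0 <= self.lymphocyte_fraction <= 1.0:
            raise ConfigurationError("lymphocyte_fraction must be in [0, 1]")
        if self.ncd64 < 0 or self.lymph_cd64 < 0:
            raise ConfigurationError("CD64 indices must be >= 0")


@dataclass
class CellEnsemble:
    """Per-cell records: class, diameter (µm), CD64 index, arrival time (s)."""

    cells: pd.DataFrame  # columns: cell_class, diameter_um, cd64_expression, arrival_time_s
    ground_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_lymphocytes(self) -> int:
        return int((self.cells["cell_class"] == LYMPHOCYTE).sum())

    @property
    def n_gm(self) -> int:
        return int((self.cells["cell_class"] == GM).sum())

    def subset(self, mask: np.ndarray) -> "CellEnsemble":
        return CellEnsemble(
            self.cells.loc[mask].reset_index(drop=True), dict(self.ground_truth)
        )


def _truncnorm_diameters(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cell_population(
    config: PopulationConfig,
    acquisition: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> CellEnsemble:
    """Draw a leukocyte ensemble with Poisson arrivals and truncated-normal sizes.

    The expected number of arrivals over the acquisition window is
    ``concentration × blood flow rate × duration`` — cells ride the blood
    stream, so buffer flows do not add cells, they only dilute.
    """
    acquisition = acquisition or AcquisitionConfig()
    rng = np.random.default_rng(seed)

    if config.n_cells is not None:
        n = int(config.n_cells)
    else:
        expected = (
            config.concentration_per_ul
            * acquisition.blood_flow_ul_min
            / 60.0
            * acquisition.duration_s
        )
        n = int(rng.poisson(expected))

    n_lymph = int(rng.binomial(n, config.lymphocyte_fraction)) if n else 0
    n_gm = n - n_lymph

    d_lymph = _truncnorm_diameters(
        rng, n_lymph, config.lymph_diameter_mean_um, config.lymph_diameter_sd_um,
        *LYMPH_DIAMETER_RANGE,
    )
    d_gm = _truncnorm_diameters(
        rng, n_gm, config.gm_diameter_mean_um, config.gm_diameter_sd_um,
        *GM_DIAMETER_RANGE,
    )

    # log-normal CD64 with median equal to the configured index
    cd64_lymph = config.lymph_cd64 * np.exp(
        config.cd64_sigma * rng.standard_normal(n_lymph)
    )
    cd64_gm = config.ncd64 * np.exp(config.cd64_sigma * rng.standard_normal(n_gm))

    arrivals = np.sort(rng.uniform(0.0, acquisition.duration_s, size=n))

    cells = pd.DataFrame(
        {
            "cell_class": np.concatenate(
                [np.repeat(LYMPHOCYTE, n_lymph), np.repeat(GM, n_gm)]
            )
            if n
            else pd.Series(dtype=object),
            "diameter_um": np.concatenate([d_lymph, d_gm]) if n else np.empty(0),
            "cd64_expression": np.concatenate([cd64_lymph, cd64_gm])
            if n
            else np.empty(0),
        }
    )
    if n:
        cells = cells.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
            drop=True
        )
        cells["arrival_time_s"] = arrivals
    else:
        cells["arrival_time_s"] = np.empty(0)

    return CellEnsemble(
        cells,
        ground_truth={
            "n_lymphocytes": n_lymph,
            "n_gm": n_gm,
            "ncd64": config.ncd64,
            "concentration_per_ul": config.concentration_per_ul,
        },
    )
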