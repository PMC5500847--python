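"""Generator contracts: cell ensembles, capture, traces, flow events, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from impedcyto.core import AcquisitionConfig, ConfigurationError
from impedcyto.sim import (
    CaptureModelParams,
    CohortConfig,
    FlowConfig,
    NoiseConfig,
    PopulationConfig,
    TIME_WINDOWS,
    default_flow_gates,
    simulate_capture,
    simulate_cell_population,
    simulate_cohort,
    simulate_flow_events,
    synthesize_trace,
)
from impedcyto.sim.capture import capture_probability
from impedcyto.sim.cells import GM, LYMPHOCYTE
from impedcyto.clinstats import coefficient_of_variation, flow_summary

from conftest import make_ensemble


class TestCellPopulation:
    def test_zero_cells_gives_empty_ensemble(self):
        ens = simulate_cell_population(PopulationConfig(n_cells=0), seed=1)
        assert len(ens) == 0

    def test_class_fractions_within_binomial_ci(self):
        """10,000 cells at 35% lymphocytes: realized fraction inside the 99% CI."""
        config = PopulationConfig(n_cells=10_000, lymphocyte_fraction=0.35)
        ens = simulate_cell_population(config, seed=42)
        n, p = 10_000, 0.35
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= ens.n_lymphocytes <= hi

    def test_diameter_bounds_per_class(self):
        ens = simulate_cell_population(PopulationConfig(n_cells=5000), seed=3)
        cells = ens.cells
        lymph = cells.loc[cells.cell_class == LYMPHOCYTE, "diameter_um"]
        gm = cells.loc[cells.cell_class == GM, "diameter_um"]
        assert lymph.between(6.0, 10.0).all()
        assert gm.between(11.0, 15.0).all()

    def test_poisson_arrival_count(self):
        """5,000 cells/µl at 0.518 µl/min blood flow for 60 s ≈ 2,590 arrivals."""
        acq = AcquisitionConfig(duration_s=60.0)
        config = PopulationConfig(concentration_per_ul=5000.0)
        ens = simulate_cell_population(config, acq, seed=7)
        expected = 5000.0 * 0.518 / 60.0 * 60.0
        lo, hi = stats.poisson.ppf([0.005, 0.995], expected)
        assert lo <= len(ens) <= hi
        assert np.all(np.diff(np.sort(ens.cells.arrival_time_s)) >= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_cells=-1)
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_cells=None, concentration_per_ul=-5.0)

    def test_bit_reproducible(self):
        a = simulate_cell_population(PopulationConfig(n_cells=500), seed=9)
        b = simulate_cell_population(PopulationConfig(n_cells=500), seed=9)
        pd.testing.assert_frame_equal(a.cells, b.cells)


class TestCapture:
    def _gm_ensemble(self, n, expression):
        return make_ensemble(
            np.full(n, 13.0),
            [GM] * n,
            np.arange(n) * 1e-3,
            cd64=np.full(n, expression),
        )

    def test_kappa_zero_captures_nothing(self):
        ens = self._gm_ensemble(1000, 5.0)
        _, exit_ens = simulate_capture(
            ens, CaptureModelParams(efficiency=0.0, lymphocyte_inflation=1.0), seed=1
        )
        assert exit_ens.n_gm == 1000

    def test_saturation_limit(self):
        assert capture_probability(0.5, np.array([1e9]))[0] == pytest.approx(1.0)

    def test_captured_fraction_within_binomial_ci(self):
        """κ chosen for mean P = 0.5: captured count inside the binomial 99% CI."""
        expression = 2.0
        kappa = np.log(2.0) / expression
        ens = self._gm_ensemble(10_000, expression)
        _, exit_ens = simulate_capture(
            ens, CaptureModelParams(efficiency=kappa, lymphocyte_inflation=1.0), seed=2
        )
        captured = 10_000 - exit_ens.n_gm
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.5)
        assert lo <= captured <= hi

    def test_capture_monotone_in_expression(self):
        """Expected captured fraction strictly increases with mean CD64."""
        fractions = []
        for mean in [0.5, 1.0, 2.0, 4.0, 8.0]:
            ens = self._gm_ensemble(10_000, mean)
            _, exit_ens = simulate_capture(
                ens,
                CaptureModelParams(efficiency=0.285, lymphocyte_inflation=1.0),
                seed=5,
            )
            fractions.append(1.0 - exit_ens.n_gm / 10_000)
        assert all(b > a for a, b in zip(fractions, fractions[1:]))

    def test_lymphocyte_inflation(self):
        ens = make_ensemble(
            np.full(1000, 8.5), [LYMPHOCYTE] * 1000, np.arange(1000) * 1e-3
        )
        _, exit_ens = simulate_capture(
            ens, CaptureModelParams(efficiency=0.3, lymphocyte_inflation=1.27), seed=3
        )
        assert exit_ens.n_lymphocytes == round(1.27 * 1000)
        assert np.all(np.diff(exit_ens.cells.arrival_time_s) >= 0)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ConfigurationError):
            CaptureModelParams(efficiency=-0.1)


class TestTraceSynthesis:
    def test_empty_ensemble_pure_noise(self, short_acquisition):
        ens = make_ensemble([], [], [])
        trace = synthesize_trace(ens, NoiseConfig.off(), short_acquisition, seed=1)
        assert np.all(trace.samples == 0.0)

    def test_cubic_amplitude_law(self, short_acquisition):
        """8 vs 13 µm cells: noiseless peak ratio = (13/8)³ within 1%."""
        ens = make_ensemble([8.0, 13.0], [LYMPHOCYTE, GM], [0.5, 1.5])
        trace = synthesize_trace(ens, NoiseConfig.off(), short_acquisition, seed=1)
        fs = short_acquisition.sampling_rate_hz
        peak_small = trace.samples[: int(fs)].max()
        peak_large = trace.samples[int(fs) :].max()
        assert peak_large / peak_small == pytest.approx((13 / 8) ** 3, rel=0.01)

    def test_arrival_beyond_duration_reports_cells(self, short_acquisition):
        ens = make_ensemble([13.0, 13.0], [GM, GM], [0.5, 5.0])
        with pytest.raises(ConfigurationError, match=r"\[1\]"):
            synthesize_trace(ens, NoiseConfig.off(), short_acquisition, seed=1)

    def test_drift_frequency_must_be_below_hpf(self):
        with pytest.raises(ConfigurationError):
            NoiseConfig(drift_frequency_hz=25.0)

    def test_bit_reproducible(self, short_acquisition):
        ens = make_ensemble([13.0], [GM], [1.0])
        a = synthesize_trace(ens, NoiseConfig(), short_acquisition, seed=4)
        b = synthesize_trace(ens, NoiseConfig(), short_acquisition, seed=4)
        assert np.array_equal(a.samples, b.samples)


class TestFlowEvents:
    def test_normalization_identity(self):
        """Neutrophil mean FITC equal to bead mean → nCD64 ≈ 1."""
        events = simulate_flow_events(FlowConfig(ncd64=1.0, n_events=20_000), seed=1)
        summary = flow_summary(events, default_flow_gates())
        assert summary.ncd64 == pytest.approx(1.0, rel=0.05)

    def test_configured_ncd64_recovered(self):
        """Configured nCD64 = 2.43 recovered within 5% on 10,000 events."""
        events = simulate_flow_events(FlowConfig(ncd64=2.43), seed=2)
        summary = flow_summary(events, default_flow_gates())
        assert summary.ncd64 == pytest.approx(2.43, rel=0.05)

    def test_zero_beads_rejected(self):
        with pytest.raises(ConfigurationError, match="bead"):
            FlowConfig(
                fractions={
                    "neutrophil": 0.5,
                    "lymphocyte": 0.3,
                    "monocyte": 0.1,
                    "bead": 0.0,
                    "debris": 0.1,
                }
            )

    def test_no_debris_all_events_gated(self):
        config = FlowConfig(
            fractions={
                "neutrophil": 0.4,
                "lymphocyte": 0.3,
                "monocyte": 0.15,
                "bead": 0.15,
                "debris": 0.0,
            },
            n_events=2000,
        )
        events = simulate_flow_events(config, seed=3)
        assert set(events.population) == {"neutrophil", "lymphocyte", "monocyte", "bead"}


class TestCohort:
    def test_wbc_group_cvs_match_configuration(self):
        """Realized WBC CVs within 10% relative of 62.88% / 68.81% at n = 500."""
        cohort = simulate_cohort(CohortConfig(n_patients=500), seed=5)
        septic = cohort.loc[cohort.septic == 1, "wbc_per_ul"]
        nonseptic = cohort.loc[cohort.septic == 0, "wbc_per_ul"]
        assert coefficient_of_variation(septic) == pytest.approx(62.88, rel=0.10)
        assert coefficient_of_variation(nonseptic) == pytest.approx(68.81, rel=0.10)

    def test_leukocyte_range_respected(self):
        cohort = simulate_cohort(CohortConfig(n_patients=300), seed=6)
        assert cohort.wbc_per_ul.between(530.0, 38_570.0).all()

    def test_recovered_trajectory_rises_then_falls(self):
        """Recovered patients: median nCD64 at TW6 below TW2, peak in between."""
        cohort = simulate_cohort(CohortConfig(n_patients=100), seed=7)
        rec = cohort[cohort.outcome == "recovered"]
        medians = rec.groupby("time_window")["ncd64"].median()[TIME_WINDOWS]
        assert medians["TW6"] < medians["TW2"]
        assert medians.idxmax() in {"TW2", "TW3"}

    def test_nonrecovered_rise_tw5_to_tw6(self):
        config = CohortConfig(
            n_patients=100, septic_fraction=1.0, deceased_fraction_septic=0.5
        )
        cohort = simulate_cohort(config, seed=8)
        dec = cohort[cohort.outcome == "deceased"]
        medians = dec.groupby("time_window")["ncd64"].median()
        assert medians["TW6"] > medians["TW5"]

    def test_invalid_septic_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(septic_fraction=1.5)

    def test_bit_reproducible(self):
        a = simulate_cohort(CohortConfig(n_patients=50), seed=9)
        b = simulate_cohort(CohortConfig(n_patients=50), seed=9)
        pd.testing.assert_frame_equal(a, b)
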