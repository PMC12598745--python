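"""Mass-balance rate inference from enrichment time series."""

import numpy as np
import pandas as pd
import pytest

from matsip import bulk_rates as br
from matsip import simulate as sim
from matsip.errors import (
    ConfigError,
    InsufficientDataError,
    InvalidValueError,
    MissingBaselineError,
    SchemaError,
)
from matsip.isotope import atom_fraction_to_ratio, natural_atom_fraction

X_NAT_N = natural_atom_fraction("N")
X_NAT_C = natural_atom_fraction("C")


def series_from_atom_fractions(times, fractions, element="N",
                               treatment="labeled"):
    return pd.DataFrame({
        "time_h": times,
        "ratio": [atom_fraction_to_ratio(x) for x in fractions],
        "element": element,
        "treatment": treatment,
    })


class TestExcessAtomFraction:
    def test_series_equal_to_baseline_gives_zeros(self):
        base = series_from_atom_fractions([0, 2], [X_NAT_N, X_NAT_N])
        excess = br.excess_atom_fraction(base, baseline=base)
        assert np.allclose(excess, 0.0)

    def test_enriched_vs_control_ratio_pair(self):
        # mat biomass at the observed enrichment maximum vs the control mean
        series = pd.DataFrame({"time_h": [48.0], "ratio": [0.011294],
                               "element": "C"})
        baseline = pd.DataFrame({"time_h": [0.0], "ratio": [0.010924],
                                 "element": "C"})
        excess = br.excess_atom_fraction(series, baseline)
        assert excess.iloc[0] == pytest.approx(3.62e-4, abs=1e-6)

    def test_negative_excess_passes_through(self):
        series = series_from_atom_fractions([0], [X_NAT_N - 1e-4])
        baseline = series_from_atom_fractions([0], [X_NAT_N])
        assert br.excess_atom_fraction(series, baseline).iloc[0] < 0

    def test_mixed_elements_rejected(self):
        series = series_from_atom_fractions([0], [X_NAT_N], element="N")
        baseline = series_from_atom_fractions([0], [X_NAT_C], element="C")
        with pytest.raises(SchemaError):
            br.excess_atom_fraction(series, baseline)

    def test_missing_baseline_rejected(self):
        series = series_from_atom_fractions([0], [X_NAT_N])
        with pytest.raises(MissingBaselineError):
            br.excess_atom_fraction(series, baseline=series.iloc[:0])


class TestNitrogenAssimilation:
    composition = br.BiomassComposition(n_wt_pct=7.0)
    pool = br.SubstratePool.n_label("ammonium", 0.98)

    def test_zero_enrichment_zero_rate(self):
        series = series_from_atom_fractions([0, 2, 4, 8], [X_NAT_N] * 4)
        baseline = series_from_atom_fractions([0], [X_NAT_N], treatment="control")
        est = br.n_assimilation_rate(series, self.composition, self.pool,
                                     baseline)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_example(self):
        # Δx = 0.003117 over 8 h against a 0.9763 pool excess and a
        # 4997 μmol N/g pool → ≈2.0 μmol N/g/h
        series = series_from_atom_fractions([0.0, 8.0], [0.0036630, 0.0067800])
        baseline = series_from_atom_fractions([0.0], [0.0036630])
        est = br.n_assimilation_rate(series, self.composition, self.pool,
                                     baseline)
        assert est.value == pytest.approx(2.0, rel=0.01)
        assert est.method == "finite-difference"

    def test_noiseless_forward_simulation_recovered(self):
        config = sim.ExperimentConfig(
            seed=5, true_rates={("ammonium", "day"): 2.0},
            noise=sim.NoiseModel(irms_ratio_sd=0.0))
        table, _ = sim.simulate_labeling_timecourse(config)
        grp = table[table["series_id"] == "ammonium_day"].rename(
            columns={"value": "ratio"})
        est = br.n_assimilation_rate(grp, self.composition, self.pool)
        assert est.value == pytest.approx(2.0, abs=0.02)

    def test_doubling_pool_excess_halves_rate(self):
        series = series_from_atom_fractions([0, 4, 8],
                                            [X_NAT_N, 0.005, 0.0065])
        baseline = series_from_atom_fractions([0], [X_NAT_N])
        lo = br.SubstratePool("ammonium", X_NAT_N + 0.4)
        hi = br.SubstratePool("ammonium", X_NAT_N + 0.8)
        r_lo = br.n_assimilation_rate(series, self.composition, lo, baseline)
        r_hi = br.n_assimilation_rate(series, self.composition, hi, baseline)
        assert r_lo.value == pytest.approx(2 * r_hi.value, rel=1e-12)

    def test_insufficient_data_and_wrong_pool(self):
        series = series_from_atom_fractions([0], [X_NAT_N])
        baseline = series_from_atom_fractions([0], [X_NAT_N])
        with pytest.raises(InsufficientDataError):
            br.n_assimilation_rate(series, self.composition, self.pool, baseline)
        with pytest.raises(InvalidValueError):
            br.n_assimilation_rate(series, self.composition,
                                   br.SubstratePool.dic_spike(), baseline)


class TestCarbonFixation:
    def test_hand_example_hourly_daily_12h(self):
        # Δexcess 4e−4 over 12 h, 2% pool excess, 40% C, 500 g/m²
        times = np.array([0.0, 6.0, 12.0])
        fractions = X_NAT_C + 4e-4 / 12.0 * times
        series = series_from_atom_fractions(times, fractions, element="C")
        baseline = series_from_atom_fractions([0.0], [X_NAT_C], element="C")
        comp = br.BiomassComposition(c_wt_pct=40.0, areal_dry_density=500.0)
        pool = br.SubstratePool.dic_spike(0.02)
        hourly = br.c_fixation_rate(series, comp, pool, baseline)
        assert hourly.value == pytest.approx(6.67e-4, rel=1e-3)
        daily, per12 = br.areal_gross_productivity(series, comp, pool, baseline)
        assert daily.value == pytest.approx(8.0, rel=1e-3)
        assert per12.value == pytest.approx(4.0, rel=1e-3)

    def test_areal_requires_density(self):
        series = series_from_atom_fractions([0, 6], [X_NAT_C, X_NAT_C + 1e-4],
                                            element="C")
        baseline = series_from_atom_fractions([0], [X_NAT_C], element="C")
        comp = br.BiomassComposition(c_wt_pct=40.0)
        with pytest.raises(ConfigError):
            br.areal_gross_productivity(series, comp,
                                        br.SubstratePool.dic_spike(), baseline)

    def test_control_series_rate_within_noise(self):
        config = sim.ExperimentConfig(seed=11)
        table, _ = sim.simulate_labeling_timecourse(config)
        grp = table[(table["series_id"] == "bicarbonate_day")].rename(
            columns={"value": "ratio"})
        controls = grp[grp["treatment"] == "control"].copy()
        controls["treatment"] = "labeled"
        comp = br.BiomassComposition(c_wt_pct=40.0)
        est = br.c_fixation_rate(controls, comp, br.SubstratePool.dic_spike(),
                                 baseline=grp[grp["treatment"] == "control"])
        assert abs(est.value) < 3 * est.stderr


class TestUreaConsumption:
    setup = br.IncubationSetup(volume_ml=100.0, wet_mass_g=5.0,
                               dry_wet_ratio=0.1)

    def test_constant_concentration_zero_rate(self):
        est = br.urea_consumption_rate([0, 1, 2], [0.5, 0.5, 0.5], self.setup)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_printed_formula_hand_example(self):
        # 0.5 → 0.4 mmol/l over 2 h in 100 ml with 0.5 g dry biomass:
        # 10 μmol urea/g/h, doubled to 20 μmol urea-N/g/h
        est = br.urea_consumption_rate([0.0, 2.0], [0.5, 0.4], self.setup)
        assert est.value == pytest.approx(20.0, rel=1e-12)
        assert est.units == "umol urea-N/g dry/h"

    def test_invariant_under_joint_volume_mass_scaling(self):
        scaled = br.IncubationSetup(volume_ml=300.0, wet_mass_g=15.0,
                                    dry_wet_ratio=0.1)
        a = br.urea_consumption_rate([0, 1, 2], [0.5, 0.45, 0.41], self.setup)
        b = br.urea_consumption_rate([0, 1, 2], [0.5, 0.45, 0.41], scaled)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_window_restriction(self):
        with pytest.raises(InsufficientDataError):
            br.urea_consumption_rate([0.0, 4.0, 8.0], [0.5, 0.3, 0.2],
                                     self.setup, window_h=2.0)


class TestDilutionCheck:
    setup = br.IncubationSetup(volume_ml=100.0, wet_mass_g=5.0)

    def test_zero_replacement_no_bias(self):
        report = br.dilution_correction_check(self.setup, [0.0, 0.0])
        assert report.max_relative_bias == 0.0
        assert not report.flagged

    def test_cumulative_dilution_factor(self):
        report = br.dilution_correction_check(self.setup, [1.0] * 5)
        assert report.cumulative_factor == pytest.approx(0.951, abs=1e-3)
        assert report.max_relative_bias == pytest.approx(0.049, abs=1e-3)

    def test_flagged_when_bias_exceeds_depletion_share(self):
        report = br.dilution_correction_check(self.setup, [1.0] * 5,
                                              observed_depletion_frac=0.5)
        assert report.flagged
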