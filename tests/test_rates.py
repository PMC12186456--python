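import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grazefit.rates import (
    UndefinedRateError,
    WellObservation,
    assign_control_mu,
    clearance_and_proportion,
    derive_rates,
    generation_time,
    grazing_rate,
    gross_growth_efficiency,
    gross_growth_efficiency_volume,
    ingestion_rate,
    log_mean_density,
    specific_growth_rate,
)

positive = st.floats(min_value=1e-3, max_value=1e7)


class TestSpecificGrowthRate:
    @pytest.mark.parametrize(
        "n0,nt,t,expected",
        [
            (100, 100, 1.0, 0.0),
            (100, 200, 1.0, math.log(2)),
            (100, 50, 2.0, math.log(0.5) / 2),
        ],
    )
    def test_examples(self, n0, nt, t, expected):
        assert specific_growth_rate(n0, nt, t) == pytest.approx(expected)

    @pytest.mark.parametrize("n0,nt,t", [(0, 100, 1), (100, 0, 1), (100, 100, 0)])
    def test_undefined_cases(self, n0, nt, t):
        with pytest.raises(UndefinedRateError):
            specific_growth_rate(n0, nt, t)


class TestLogMeanDensity:
    @pytest.mark.parametrize(
        "x0,xt,expected",
        [
            (100, 100, 100.0),
            (100, 200, 100.0 / math.log(2)),
            (50_000, 10_000, 40_000.0 / math.log(5)),
        ],
    )
    def test_examples(self, x0, xt, expected):
        assert log_mean_density(x0, xt) == pytest.approx(expected, rel=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(UndefinedRateError):
            log_mean_density(0, 100)

    @given(positive, positive)
    @settings(max_examples=100, deadline=None)
    def test_between_inputs_and_symmetric(self, x0, xt):
        m = log_mean_density(x0, xt)
        assert min(x0, xt) - 1e-9 <= m <= max(x0, xt) + 1e-9
        assert m == pytest.approx(log_mean_density(xt, x0), rel=1e-9)


class TestGrazingRate:
    def test_controls_doubled_prey_flat(self):
        assert grazing_rate(math.log(2), 100, 100, 1.0) == pytest.approx(math.log(2))

    def test_identical_dynamics_no_grazing(self):
        assert grazing_rate(0.0, 500, 500, 1.0) == 0.0

    def test_negative_grazing_preserved(self):
        # controls declining faster than the experimental well
        g = grazing_rate(-0.3, 1000, 1000 * math.exp(-0.1), 1.0)
        assert g == pytest.approx(-0.2)

    @given(positive, positive, positive, positive)
    @settings(max_examples=100, deadline=None)
    def test_single_control_identity(self, c0, ct, p0, pt):
        """g computed via mu equals (ln(Ct/C0) - ln(Pt/P0))/t directly."""
        t = 1.5
        mu = specific_growth_rate(c0, ct, t)
        direct = (math.log(ct / c0) - math.log(pt / p0)) / t
        assert grazing_rate(mu, p0, pt, t) == pytest.approx(direct, rel=1e-9, abs=1e-12)


class TestAssignControlMu:
    controls = pd.DataFrame(
        {
            "well_id": ["c1", "c2", "c3", "c4"],
            "P0": [1e3, 2e3, 2e4, 4e4],
            "mu": [0.1, 0.1, 0.3, 0.3],
        }
    )

    def test_density_bins(self):
        mu, prov = assign_control_mu(
            self.controls, [1.5e3, 3e4], strategy="density_bins", n_bins=2
        )
        np.testing.assert_allclose(mu, [0.1, 0.3])
        assert "c1" in prov[0] and "c3" in prov[1]

    def test_global_mean(self):
        mu, _ = assign_control_mu(self.controls, [1e3, 4e4], strategy="global_mean")
        np.testing.assert_allclose(mu, [0.2, 0.2])

    def test_log_density_interpolation(self):
        controls = pd.DataFrame(
            {"well_id": ["a", "b"], "P0": [1e3, 1e5], "mu": [0.1, 0.5]}
        )
        mu, _ = assign_control_mu(controls, [1e4], strategy="interpolate")
        assert mu[0] == pytest.approx(0.3)

    def test_nearest_control(self):
        mu, prov = assign_control_mu(
            self.controls, [2.1e4], strategy="nearest_control"
        )
        assert mu[0] == 0.3 and prov[0] == "c3"

    def test_no_controls_is_an_error(self):
        with pytest.raises(UndefinedRateError):
            assign_control_mu(self.controls.iloc[:0], [1e3])


class TestIngestionClearance:
    def test_ingestion_direct(self):
        i_cells, i_carbon = ingestion_rate(10_000, 0.1, 25.0, m_pg=27.1)
        assert i_cells == pytest.approx(40.0)
        assert i_carbon == pytest.approx(40.0 * 27.1 / 1000)

    def test_zero_grazing_zero_ingestion(self):
        assert ingestion_rate(10_000, 0.0, 25.0)[0] == 0.0

    def test_rejects_nonpositive_predator(self):
        with pytest.raises(UndefinedRateError):
            ingestion_rate(10_000, 0.1, 0.0)

    def test_clearance_equals_proportion(self):
        """39.1 uL cleared per predator per day = 3.9% of prey ingested."""
        c, prop = clearance_and_proportion(0.0391 * 10_000, 10_000)
        assert c == pytest.approx(0.0391)
        assert round(prop * 100, 1) == 3.9

    def test_clearance_direct(self):
        c, _ = clearance_and_proportion(40.0, 10_000)
        assert c == pytest.approx(0.004)  # 4.0 uL

    def test_zero_ingestion_zero_clearance(self):
        assert clearance_and_proportion(0.0, 5_000)[0] == 0.0


class TestGGE:
    def test_volume_basis(self):
        gge = gross_growth_efficiency_volume(0.32, 63_650, 667, 221)
        assert round(gge, 2) == 0.14

    def test_carbon_basis(self):
        gge = gross_growth_efficiency(0.32, 7.00, 667 * 27.1 / 1000)
        assert round(gge, 2) == 0.12

    def test_zero_growth_zero_gge(self):
        assert gross_growth_efficiency(0.0, 7.0, 18.0) == 0.0

    def test_undefined_for_nonpositive_ingestion(self):
        with pytest.raises(UndefinedRateError):
            gross_growth_efficiency(0.3, 7.0, 0.0)


def test_generation_time():
    assert round(generation_time(0.32), 2) == 2.17
    with pytest.raises(UndefinedRateError):
        generation_time(0.0)


class TestWellObservation:
    def test_control_must_not_carry_predator_fields(self):
        with pytest.raises(ValueError):
            WellObservation(
                well_id="c", role="control", P0=100, Pt=90, t_days=1.0, R0=25.0
            )

    def test_experimental_requires_predators(self):
        with pytest.raises(ValueError):
            WellObservation(well_id="e", role="experimental", P0=100, Pt=90, t_days=1.0)


class TestDeriveRates:
    @staticmethod
    def _wells():
        wells = [
            WellObservation(
                well_id=f"C{i}", role="control", P0=p, Pt=p * math.exp(0.1),
                t_days=1.0, target_prey=p,
            )
            for i, p in enumerate([1e3, 1e4, 5e4])
        ]
        wells += [
            WellObservation(
                well_id=f"E{i}", role="experimental", P0=p, Pt=p * math.exp(-0.1),
                R0=25.0, Rt=30.0, t_days=1.0, target_prey=p,
                counted_prey_0=int(p), counted_prey_t=int(p * 0.9),
                counted_pred_0=75, counted_pred_t=90,
            )
            for i, p in enumerate([1e3, 1e4, 5e4])
        ]
        return wells

    def test_corrected_and_uncorrected_variants(self):
        rates_c, controls = derive_rates(self._wells(), correction="controls")
        rates_u, _ = derive_rates(self._wells(), correction="none")
        # mu = 0.1 in controls, prey declined at -0.1 in wells: g = 0.2 vs 0.1
        np.testing.assert_allclose(rates_c["g"], 0.2, rtol=1e-9)
        np.testing.assert_allclose(rates_u["g"], 0.1, rtol=1e-9)
        assert rates_c.attrs["correction"] == "controls"
        assert rates_u.attrs["correction"] == "none"
        assert len(controls) == 3

    def test_low_count_flag(self):
        wells = self._wells()
        wells[3] = WellObservation(
            well_id="E0", role="experimental", P0=1e3, Pt=900.0, R0=25.0, Rt=30.0,
            t_days=1.0, counted_pred_0=20, counted_pred_t=30,
        )
        rates, _ = derive_rates(wells, correction="none")
        assert "low_count" in rates.set_index("well_id").loc["E0", "flags"]

    def test_negative_grazing_flagged_not_clamped(self):
        wells = [
            WellObservation(well_id="c", role="control", P0=1e4,
                            Pt=1e4 * math.exp(-0.3), t_days=1.0),
            WellObservation(well_id="e", role="experimental", P0=1e4,
                            Pt=1e4 * math.exp(-0.1), R0=25.0, Rt=25.0, t_days=1.0),
        ]
        rates, _ = derive_rates(wells, correction="controls")
        assert rates.loc[0, "g"] == pytest.approx(-0.2)
        assert "negative_grazing" in rates.loc[0, "flags"]

    def test_gge_bases_agree_within_20_percent(self):
        """Carbon- and volume-basis GGE agree to ~20% for the default
        conversion models (a sanity property, not an identity)."""
        rates, _ = derive_rates(self._wells(), correction="controls")
        ok = rates.dropna(subset=["GGE", "GGE_volume"])
        assert len(ok) > 0
        ratio = ok["GGE"] / ok["GGE_volume"]
        assert ((ratio - 1).abs() < 0.2).all()
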