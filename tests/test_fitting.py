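import math

import numpy as np
import pandas as pd
import pytest

from grazefit.fitting import (
    IncomparableFitsError,
    TransformRefusalError,
    aicc,
    covariate_effects,
    discriminate_fr_type,
    fit_fr,
    fit_nr,
    rank_models,
)
from grazefit.models import FRParams, NRParams, clearance_curve, fr_predict, nr_predict


def rates_frame(P, y, column, correction="controls"):
    df = pd.DataFrame({"P0": P, "P_mean": P, column: y})
    df.attrs["correction"] = correction
    return df


class TestAicc:
    def test_direct_evaluation(self):
        # 20*ln(0.05) + 2*3 + 2*3*4/16
        assert aicc(1.0, 20, 3) == pytest.approx(-52.4146, abs=1e-3)

    def test_approaches_aic_for_large_n(self):
        n = 10_000
        plain_aic = n * math.log(1.0 / n) + 2 * 3
        assert aicc(1.0, n, 3) == pytest.approx(plain_aic, abs=0.01)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            aicc(0.0, 20, 3)
        with pytest.raises(ValueError):
            aicc(1.0, 4, 3)


class TestFitNR:
    truth = NRParams(rmax=0.32, p_prime=1349.0, k2=5000.0)

    def test_noiseless_recovery(self, density_grid):
        r = nr_predict(density_grid, self.truth)
        fit = fit_nr(rates_frame(density_grid, r, "r"), density_axis="mean")
        assert fit.params["rmax"] == pytest.approx(0.32, rel=1e-6)
        assert fit.params["p_prime"] == pytest.approx(1349.0, rel=1e-6)
        assert fit.params["k2"] == pytest.approx(5000.0, rel=1e-6)

    def test_monte_carlo_rmax_within_10_percent(self, density_grid):
        """Median rmax over noisy replicates stays within 10% of truth."""
        rng = np.random.default_rng(5)
        est = []
        for _ in range(60):
            r = nr_predict(density_grid, self.truth) + rng.normal(0, 0.03, 20)
            est.append(
                fit_nr(rates_frame(density_grid, r, "r"), density_axis="mean",
                       n_starts=4).params["rmax"]
            )
        assert abs(np.median(est) / 0.32 - 1) < 0.10

    def test_axis_choice_hardly_matters_on_same_data(self, density_grid):
        rng = np.random.default_rng(7)
        r = nr_predict(density_grid, self.truth) + rng.normal(0, 0.03, 20)
        df = rates_frame(density_grid, r, "r")
        # identical x-columns here: the comparison degenerates exactly
        fi = fit_nr(df, density_axis="initial")
        fm = fit_nr(df, density_axis="mean")
        assert abs(fi.aicc - fm.aicc) < 2.0

    def test_too_few_wells(self, density_grid):
        df = rates_frame(density_grid[:4], np.ones(4) * 0.1, "r")
        with pytest.raises(ValueError):
            fit_nr(df)


class TestFitFR:
    def test_noiseless_recovery_theta3(self, density_grid):
        truth = FRParams.from_imax_k(667.0, 20_000.0, theta=3.0)
        I = fr_predict(density_grid, truth)
        fit = fit_fr(rates_frame(density_grid, I, "I_cells"), model="FR3-theta=3")
        assert fit.params["a"] == pytest.approx(truth.a, rel=1e-6)
        assert fit.params["h"] == pytest.approx(truth.h, rel=1e-6)
        assert fit.derived["imax"][0] == pytest.approx(667.0, rel=1e-6)

    def test_noiseless_recovery_free_theta(self, density_grid):
        truth = FRParams.from_imax_k(667.0, 20_000.0, theta=2.0)
        I = fr_predict(density_grid, truth)
        fit = fit_fr(rates_frame(density_grid, I, "I_cells"), model="FR-free-theta")
        assert fit.params["theta"] == pytest.approx(2.0, rel=1e-4)
        assert fit.params["h"] == pytest.approx(truth.h, rel=1e-4)

    def test_reparameterization_invariance(self, density_grid):
        """FR2 and the Michaelis-Menten form give the same curve and AICc."""
        rng = np.random.default_rng(3)
        truth = FRParams.from_imax_k(667.0, 20_000.0, theta=1.0)
        I = fr_predict(density_grid, truth) * rng.lognormal(0, 0.1, 20)
        df = rates_frame(density_grid, I, "I_cells")
        f2 = fit_fr(df, model="FR2")
        fmm = fit_fr(df, model="FRmm")
        np.testing.assert_allclose(
            f2.predict(density_grid), fmm.predict(density_grid), rtol=1e-6
        )
        assert f2.aicc == pytest.approx(fmm.aicc, abs=1e-6)

    def test_log_transform_refused_on_negative_ingestion(self, density_grid):
        I = fr_predict(density_grid, FRParams(a=0.01, h=0.0015)).copy()
        I[0] = -5.0
        df = rates_frame(density_grid, I, "I_cells")
        with pytest.raises(TransformRefusalError):
            fit_fr(df, model="FR2", transform="log")

    def test_unknown_model_id(self, density_grid):
        df = rates_frame(density_grid, np.ones(20), "I_cells")
        with pytest.raises(ValueError):
            fit_fr(df, model="FR9")


class TestRankModels:
    @staticmethod
    def _fits(density_grid, seed=0):
        rng = np.random.default_rng(seed)
        truth = FRParams.from_imax_k(667.0, 20_000.0, theta=3.0)
        I = fr_predict(density_grid, truth) * rng.lognormal(0, 0.2, len(density_grid))
        df = rates_frame(density_grid, I, "I_cells")
        return [fit_fr(df, model=m) for m in ("FR2", "FR3", "FR3-theta=3")]

    def test_order_invariance(self, density_grid):
        fits = self._fits(density_grid)
        t1 = rank_models(fits)
        t2 = rank_models(fits[::-1])
        pd.testing.assert_frame_equal(t1, t2)

    def test_delta_and_support(self, density_grid):
        table = rank_models(self._fits(density_grid))
        assert table["delta_aicc"].iloc[0] == 0.0
        assert (table["delta_aicc"].diff().dropna() >= 0).all()
        assert (table.loc[table["delta_aicc"] < 2, "support"] == "substantial").all()

    def test_single_fit_trivial(self, density_grid):
        table = rank_models(self._fits(density_grid)[:1])
        assert len(table) == 1 and table["delta_aicc"].iloc[0] == 0.0

    def test_mixed_transforms_refused(self, density_grid):
        truth = FRParams.from_imax_k(667.0, 20_000.0, theta=1.0)
        I = fr_predict(density_grid, truth)
        df = rates_frame(density_grid, I, "I_cells")
        f1 = fit_fr(df, model="FR2", transform="none")
        f2 = fit_fr(df, model="FR3", transform="log")
        with pytest.raises(IncomparableFitsError):
            rank_models([f1, f2])


class TestDiscriminateFRType:
    def _simulated(self, theta, rng, noise=0.15):
        P = np.geomspace(1_000, 70_000, 20)
        fr = FRParams.from_imax_k(667.0, 20_000.0, theta=theta)
        C = clearance_curve(P, fr) * rng.lognormal(0, noise, len(P))
        return P, C

    def test_type_two_detected(self):
        P, C = self._simulated(1.0, np.random.default_rng(1))
        assert discriminate_fr_type(P, C).verdict == "typeII"

    def test_type_three_detected(self):
        P, C = self._simulated(3.0, np.random.default_rng(2))
        v = discriminate_fr_type(P, C)
        assert v.verdict == "typeIII"
        assert v.linear_coef > 0 and v.quadratic_coef < 0

    def test_constant_proportion_inconclusive(self):
        P = np.geomspace(1_000, 70_000, 20)
        rng = np.random.default_rng(3)
        C = 0.02 * rng.lognormal(0, 0.05, len(P))
        assert discriminate_fr_type(P, C).verdict == "inconclusive"

    def test_preconditions(self):
        with pytest.raises(ValueError):
            discriminate_fr_type([1e3] * 8, [0.1] * 8)  # no density span
        with pytest.raises(ValueError):
            discriminate_fr_type([1e3, 1e4, 1e5], [0.1, 0.2, 0.1])  # too few


class TestCovariateEffects:
    def test_known_flw_slope_recovered(self):
        rng = np.random.default_rng(11)
        n = 10
        flw = np.linspace(0.45, 0.9, n)
        mu = 0.1 - 0.5 * flw + rng.normal(0, 0.02, n)
        rates = pd.DataFrame(
            {
                "mu_prey_net": mu,
                "flw_fraction": flw,
                "I_cells": np.full(n, 100.0),
                "Rm": np.full(n, 25.0),
            }
        )
        out = covariate_effects(rates)
        row = out[(out.response == "mu") & (out.term == "flw_fraction")].iloc[0]
        assert row["coef"] < 0 and row["p"] < 0.05

    def test_null_slope_not_significant(self):
        rng = np.random.default_rng(13)
        n = 12
        rates = pd.DataFrame(
            {
                "mu_prey_net": rng.normal(0.1, 0.05, n),
                "flw_fraction": np.linspace(0.4, 0.9, n),
                "I_cells": rng.normal(100, 10, n),
                "Rm": rng.normal(25, 2, n),
            }
        )
        out = covariate_effects(rates)
        row = out[(out.response == "mu") & (out.term == "flw_fraction")].iloc[0]
        assert abs(row["coef"]) < 0.5 and row["p"] > 0.05

    def test_predator_interference_detected(self):
        rng = np.random.default_rng(17)
        n = 20
        rm = rng.uniform(15, 40, n)
        flw = np.linspace(0.45, 0.9, n)
        I = 300.0 * (rm / 25.0) ** -0.5 * rng.lognormal(0, 0.05, n)
        rates = pd.DataFrame(
            {"mu_prey_net": np.zeros(n), "flw_fraction": flw, "I_cells": I, "Rm": rm}
        )
        out = covariate_effects(rates)
        row = out[(out.response == "I") & (out.term == "Rm")].iloc[0]
        assert row["coef"] < 0 and row["p"] < 0.05

    def test_constant_covariate_skipped_with_notice(self):
        rates = pd.DataFrame(
            {
                "mu_prey_net": [0.1, 0.2, 0.15, 0.12],
                "flw_fraction": [0.5] * 4,
                "I_cells": [10.0, 20.0, 30.0, 40.0],
                "Rm": [25.0] * 4,
            }
        )
        out = covariate_effects(rates)
        assert (out["note"] == "constant_covariate").any()
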