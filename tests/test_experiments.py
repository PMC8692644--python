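import numpy as np
import pytest
from hypothesis import given, strategies as st

from polarfoodweb.errors import DomainError, ParameterError
from polarfoodweb.experiments import (
    ConversionConstants,
    MSYMetrics,
    YieldCurve,
    areal_n_to_kilotonnes,
    kilotonnes_to_areal_n,
    msy_metrics,
    percent_change,
    redfield_n_to_c,
    scenario_delta_report,
)


class TestRedfield:
    @pytest.mark.parametrize("npp, gc", [(844.5, 67.1), (912.3, 72.5)])
    def test_reported_production_conversions(self, npp, gc):
        assert redfield_n_to_c(npp) == pytest.approx(gc, abs=0.05)

    def test_zero(self):
        assert redfield_n_to_c(0.0) == 0.0

    def test_linear(self):
        assert redfield_n_to_c(200.0) == pytest.approx(2 * redfield_n_to_c(100.0))


class TestKilotonnes:
    def test_zero(self):
        assert areal_n_to_kilotonnes(0.0, 1.34) == 0.0

    def test_demersal_catch_conversion(self):
        assert areal_n_to_kilotonnes(0.341, 1.340) == pytest.approx(409.4,
                                                                    abs=0.1)

    def test_planktivorous_msy_conversion(self):
        assert areal_n_to_kilotonnes(0.182, 2.038) == pytest.approx(143.7,
                                                                    abs=0.1)

    def test_nonpositive_content_rejected(self):
        with pytest.raises(ParameterError):
            areal_n_to_kilotonnes(1.0, 0.0)

    @given(st.floats(0, 10), st.floats(0.5, 5))
    def test_inverse_identity(self, x, content):
        kt = areal_n_to_kilotonnes(x, content)
        assert kilotonnes_to_areal_n(kt, content) == pytest.approx(
            x, rel=1e-12, abs=1e-12)


class TestPercentChange:
    def test_reported_npp_change(self):
        assert round(percent_change(844.5, 912.3)) == 8

    def test_identity_and_halving(self):
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(100.0, 50.0) == -50.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 1.0)


def toy_curve(f_ext=2.0, b0=10.0, grid=None, guild="plank"):
    m = np.asarray(grid if grid is not None
                   else np.arange(0.0, 2.01, 0.1))
    biomass = b0 * np.maximum(1 - m / f_ext, 0.0)
    catch = m * biomass
    return YieldCurve(guild=guild, multipliers=m, catch=catch,
                      biomass=biomass, megafauna={},
                      converged=np.ones(m.size, bool))


class TestMSYMetrics:
    def test_symmetric_dome_peak(self):
        # catch = F(2-F): maximum 1.0 at F = 1.0
        m = np.round(np.arange(0.0, 2.01, 0.1), 10)
        c = YieldCurve(guild="plank", multipliers=m, catch=m * (2 - m),
                       biomass=2 - m, megafauna={},
                       converged=np.ones(m.size, bool))
        out = msy_metrics(c)
        assert out.f_msy == pytest.approx(1.0, abs=1e-9)
        assert out.msy == pytest.approx(1.0, abs=1e-9)

    def test_toy_biomass_model_peak_at_half_extinction_rate(self):
        # B(F) = B0(1 - F/F_ext), catch = F*B: analytic peak at F_ext/2,
        # off-grid, recovered by quadratic refinement
        f_ext = 1.7
        curve = toy_curve(f_ext=f_ext, grid=np.arange(0.0, 1.51, 0.25))
        out = msy_metrics(curve)
        assert out.f_msy == pytest.approx(f_ext / 2, rel=1e-6)
        assert out.msy == pytest.approx(10.0 * f_ext / 4, rel=1e-6)

    def test_ratios_against_baseline_point(self):
        curve = toy_curve(f_ext=4.0, grid=np.arange(0.0, 3.01, 0.5))
        out = msy_metrics(curve)
        i1 = list(curve.multipliers).index(1.0)
        assert out.catch_at_baseline == pytest.approx(curve.catch[i1])
        assert out.b_over_b_msy == pytest.approx(
            curve.biomass[i1] / out.b_msy)

    def test_edge_maximum_warns(self):
        m = np.arange(0.0, 1.01, 0.2)
        c = YieldCurve(guild="dem", multipliers=m, catch=m.copy(),
                       biomass=10 - m, megafauna={},
                       converged=np.ones(m.size, bool))
        with pytest.warns(UserWarning, match="edge"):
            out = msy_metrics(c)
        assert out.edge_maximum

    def test_too_few_points_rejected(self):
        m = np.array([0.0, 0.5, 1.0])
        c = YieldCurve(guild="dem", multipliers=m, catch=m, biomass=m,
                       megafauna={}, converged=np.ones(3, bool))
        with pytest.raises(ParameterError):
            msy_metrics(c)


class TestYieldCurveInvariants:
    def test_grid_must_include_zero_and_one(self):
        with pytest.raises(ParameterError):
            YieldCurve(guild="plank", multipliers=np.array([0.5, 1.0, 1.5]),
                       catch=np.zeros(3), biomass=np.zeros(3), megafauna={},
                       converged=np.ones(3, bool))

    def test_grid_strictly_increasing(self):
        with pytest.raises(ParameterError):
            YieldCurve(guild="plank",
                       multipliers=np.array([0.0, 1.0, 1.0]),
                       catch=np.zeros(3), biomass=np.zeros(3), megafauna={},
                       converged=np.ones(3, bool))


class TestScenarioDelta:
    def test_identical_runs_give_all_zero_changes(self, baseline_run):
        df = scenario_delta_report(baseline_run, baseline_run)
        changes = df["percent_change"].dropna()
        assert np.allclose(changes, 0.0)

    def test_row_count_is_pools_plus_npp(self, baseline_run, future_run):
        df = scenario_delta_report(baseline_run, future_run)
        assert len(df) == baseline_run.web.idx.n + 1

    def test_npp_row_reports_production_increase(self, baseline_run,
                                                 future_run):
        df = scenario_delta_report(baseline_run, future_run)
        row = df[df["quantity"] == "net_primary_production"].iloc[0]
        assert row["percent_change"] > 0
        assert row["direction"] == "increase"
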