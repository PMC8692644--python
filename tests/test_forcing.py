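import numpy as np
import pytest
from hypothesis import given, strategies as st

import polarfoodweb as pw
from polarfoodweb.errors import DomainError, FormatError, ParameterError
from polarfoodweb.forcing import (
    BASELINE_DIN_INFLUX,
    FUTURE_DIN_INFLUX,
    MonthlyCycle,
    ScenarioSpec,
    daily_value,
    forcing_roundtrip,
    generate_forcing,
    read_forcing,
    write_forcing,
)
from polarfoodweb.geometry import DomainGeometry


def cycle(values, variable="temperature", zone="offshore", layer="surface"):
    return MonthlyCycle(variable, zone, layer, np.asarray(values, float))


class TestDailyValue:
    def test_constant_cycle_everywhere(self):
        c = cycle([3.2] * 12)
        for day in (1, 100, 200, 365):
            assert daily_value(c, day) == pytest.approx(3.2)

    def test_linear_interpolation_between_midpoints(self):
        # Jan midpoint day 16, Feb midpoint day 45.5; Jan=0, Feb=10
        c = cycle([0, 10] + [0] * 10)
        expected = 10 * (31 - 16) / (45.5 - 16)
        assert daily_value(c, 31) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.0847, abs=1e-3)

    def test_month_midpoint_returns_monthly_value(self):
        vals = np.arange(12, dtype=float)
        c = cycle(vals)
        march_mid = 31 + 28 + 16  # day 75
        assert daily_value(c, march_mid) == pytest.approx(vals[2])

    def test_day_out_of_range(self):
        c = cycle([1.0] * 12)
        with pytest.raises(DomainError):
            daily_value(c, 0)
        with pytest.raises(DomainError):
            daily_value(c, 366)

    @given(st.lists(st.floats(-10, 40), min_size=12, max_size=12),
           st.integers(1, 365))
    def test_piecewise_linear_bounds(self, vals, day):
        c = cycle(vals)
        v = daily_value(c, day)
        assert min(vals) - 1e-9 <= v <= max(vals) + 1e-9


class TestGenerateForcing:
    def test_baseline_influx_matches_reported_annual_value(self, baseline_forcing):
        influx = pw.annual_boundary_influx(baseline_forcing, "DIN")
        assert influx == pytest.approx(BASELINE_DIN_INFLUX, rel=1e-9)

    def test_future_influx_matches_reported_annual_value(self, future_forcing):
        influx = pw.annual_boundary_influx(future_forcing, "DIN")
        assert influx == pytest.approx(FUTURE_DIN_INFLUX, rel=1e-9)

    def test_zero_ice_scale_zeroes_ice_cycles(self):
        f = generate_forcing(ScenarioSpec(label="custom", ice_scale=0.0))
        for zone in ("inshore", "offshore"):
            assert np.all(f.cycle("ice_cover", zone, "ice").values == 0)
            assert np.all(f.cycle("ice_thickness", zone, "ice").values == 0)

    def test_deterministic_without_seed(self):
        a = generate_forcing(ScenarioSpec.baseline())
        b = generate_forcing(ScenarioSpec.baseline())
        assert a.equals(b)

    def test_jitter_changes_values_but_is_reproducible(self):
        a = generate_forcing(ScenarioSpec.baseline(seed=5))
        b = generate_forcing(ScenarioSpec.baseline(seed=5))
        c = generate_forcing(ScenarioSpec.baseline())
        assert a.equals(b)
        assert not a.equals(c)

    def test_future_contrasts_with_baseline(self, baseline_forcing,
                                            future_forcing):
        def mean_of(f, var, zone, layer):
            return f.cycle(var, zone, layer).values.mean()

        assert (mean_of(future_forcing, "ice_cover", "offshore", "ice")
                < mean_of(baseline_forcing, "ice_cover", "offshore", "ice"))
        assert (pw.annual_boundary_influx(future_forcing, "DIN")
                < pw.annual_boundary_influx(baseline_forcing, "DIN"))
        assert (mean_of(future_forcing, "temperature", "offshore", "surface")
                > mean_of(baseline_forcing, "temperature", "offshore",
                          "surface"))

    def test_negative_scale_rejected(self):
        with pytest.raises(ParameterError):
            ScenarioSpec(ice_scale=-0.1)


class TestAnnualBoundaryInflux:
    def test_closed_form_constant_cycles(self, baseline_forcing):
        f = generate_forcing(ScenarioSpec.baseline())
        i, c = 0.01, 3.0
        f.cycle("ocean_inflow", "offshore", "n/a").values[:] = i
        f.cycle("boundary_detritus", "offshore", "n/a").values[:] = c
        geom = DomainGeometry()
        expected = 365 * i * c * geom.mean_depth_m
        assert pw.annual_boundary_influx(f, "detritus") == pytest.approx(
            expected, rel=1e-12)

    def test_zero_inflow_gives_zero(self):
        f = generate_forcing(ScenarioSpec.baseline())
        f.cycle("ocean_inflow", "offshore", "n/a").values[:] = 0.0
        assert pw.annual_boundary_influx(f, "DIN") == 0.0

    def test_linear_in_concentration(self, baseline_forcing):
        f = generate_forcing(ScenarioSpec.baseline())
        base = pw.annual_boundary_influx(f, "phytoplankton")
        f.cycle("boundary_phytoplankton", "offshore", "n/a").values[:] *= 2
        assert pw.annual_boundary_influx(f, "phytoplankton") == pytest.approx(
            2 * base, rel=1e-12)

    def test_unknown_tracer_rejected(self, baseline_forcing):
        with pytest.raises(DomainError):
            pw.annual_boundary_influx(baseline_forcing, "silicate")


class TestForcingIO:
    def test_roundtrip_identity(self, baseline_forcing, tmp_path):
        back = forcing_roundtrip(baseline_forcing, tmp_path / "f.csv")
        assert back.equals(baseline_forcing)

    def test_missing_variable_named_in_error(self, baseline_forcing, tmp_path):
        path = tmp_path / "f.csv"
        write_forcing(baseline_forcing, path)
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("ice_thickness,")]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="ice_thickness"):
            read_forcing(path)

    def test_hand_edited_cycle_reads_back_exactly(self, baseline_forcing,
                                                  tmp_path):
        path = tmp_path / "f.csv"
        write_forcing(baseline_forcing, path)
        known = [float(m) for m in range(1, 13)]
        out = []
        for line in path.read_text().splitlines():
            if line.startswith("wave_height,"):
                parts = line.split(",")
                parts[4] = repr(known[int(parts[3]) - 1])
                line = ",".join(parts)
            out.append(line)
        path.write_text("\n".join(out) + "\n")
        f = read_forcing(path)
        assert np.array_equal(
            f.cycle("wave_height", "inshore", "n/a").values, known)


def test_monthly_cycle_invariants():
    with pytest.raises(ParameterError):
        MonthlyCycle("ice_cover", "inshore", "ice", np.full(12, 1.2))
    with pytest.raises(ParameterError):
        MonthlyCycle("irradiance", "inshore", "surface", np.full(12, -1.0))
    with pytest.raises(ParameterError):
        MonthlyCycle("irradiance", "inshore", "surface", np.ones(11))
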