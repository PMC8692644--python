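import numpy as np
import pytest
from hypothesis import given, strategies as st

import polarfoodweb as pw
from polarfoodweb.errors import DomainError
from polarfoodweb.foodweb import (
    assemble_derivative,
    compile_web,
    holling_flux,
    ice_feeding_modifier,
    migration_presence,
    primary_production_rate,
    q10_factor,
)
from polarfoodweb.params import (
    ModifierParams,
    PhytoParams,
    PresenceSchedule,
    default_parameters,
)
from polarfoodweb.runner import default_initial_state


class TestQ10:
    def test_identity_at_reference(self):
        assert q10_factor(5.0, 5.0, 2.0) == 1.0

    def test_doubling_over_ten_degrees(self):
        assert q10_factor(15.0, 5.0, 2.0) == pytest.approx(2.0)

    def test_half_interval_closed_form(self):
        assert q10_factor(10.0, 5.0, 2.0) == pytest.approx(np.sqrt(2.0),
                                                           rel=1e-9)


class TestHolling:
    def test_no_food_no_flux(self):
        total, per = holling_flux(1.0, [0.0, 0.0], 1.0, 1.0)
        assert total == 0.0 and np.all(per == 0.0)

    def test_half_saturation_definition(self):
        total, _ = holling_flux(2.0, [3.0], 1.5, 3.0)
        assert total == pytest.approx(2.0 * 1.5 / 2.0)

    def test_hand_example_split(self):
        total, per = holling_flux(1.0, [2.0, 2.0], 1.0, 1.0)
        assert total == pytest.approx(4.0 / 5.0)
        assert per.tolist() == pytest.approx([2.0 / 5.0, 2.0 / 5.0])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=5),
           st.floats(0.01, 10), st.floats(0.1, 10))
    def test_total_bounded_and_apportioned(self, avail, umax, h):
        total, per = holling_flux(1.0, avail, umax, h)
        assert 0 <= total <= umax
        assert per.sum() == pytest.approx(total, rel=1e-9, abs=1e-12)


class TestPrimaryProduction:
    def test_zero_light(self):
        u = primary_production_rate(1.0, 0.0, 5.0, 1.0, PhytoParams())
        assert u == (0.0, 0.0)

    def test_zero_nutrients(self):
        u = primary_production_rate(1.0, 50.0, 0.0, 0.0, PhytoParams())
        assert u == (0.0, 0.0)

    def test_saturating_limit_is_umax_times_biomass(self):
        p = PhytoParams()
        no3, nh4 = primary_production_rate(3.0, 1e9, 1e9, 1e9, p)
        assert no3 + nh4 == pytest.approx(p.u_max * 3.0, rel=1e-6)

    def test_ammonia_preferred(self):
        no3, nh4 = primary_production_rate(1.0, 50.0, 2.0, 2.0, PhytoParams())
        assert nh4 > no3


class TestMigrationPresence:
    def test_resident_guild_always_one(self):
        sched = PresenceSchedule(fractions={})
        assert migration_presence(sched, "fish_d", 180) == 1.0

    def test_constant_schedule(self):
        sched = PresenceSchedule(fractions={"cet": [0.5] * 12})
        for d in (1, 100, 365):
            assert migration_presence(sched, "cet", d) == pytest.approx(0.5)

    def test_node_value_at_month_midpoint(self):
        vals = [0, 0.1, 0.3, 0.5, 0.8, 1.0, 1.0, 0.9, 0.6, 0.4, 0.2, 0.1]
        sched = PresenceSchedule(fractions={"bird": vals})
        assert migration_presence(sched, "bird", 16) == pytest.approx(0.0)
        july_mid = 31 + 28 + 31 + 30 + 31 + 30 + 16
        assert migration_presence(sched, "bird", july_mid) == pytest.approx(1.0)


class TestIceFeedingModifier:
    def test_bird_unconstrained_without_ice(self):
        assert ice_feeding_modifier("bird", 0.0, 0.0) == pytest.approx(1.0)

    def test_bird_floor_at_full_cover(self):
        p = ModifierParams(bird_floor=0.1)
        assert ice_feeding_modifier("bird", 1.0, 0.0, p) == pytest.approx(0.1)

    def test_pinniped_edge_optimum_and_consolidated_ice_penalty(self):
        p = ModifierParams()
        at_opt = ice_feeding_modifier("pinn", p.pinn_cover_opt, 0.0, p)
        assert at_opt == pytest.approx(1.0)
        assert ice_feeding_modifier("pinn", 0.0, 0.0, p) == pytest.approx(1.0)
        assert ice_feeding_modifier("pinn", 1.0, 0.0, p) < at_opt

    def test_bear_ramp_midpoint_splits_evenly(self):
        p = ModifierParams(bear_thickness_lo=0.2, bear_thickness_hi=0.8)
        hunt, scav = ice_feeding_modifier("bear", 0.8, 0.5, p)
        assert hunt == pytest.approx(0.5)
        assert scav == pytest.approx(0.5)

    def test_resident_guild_unmodified(self):
        assert ice_feeding_modifier("benth_s", 0.7, 1.0) == 1.0


class TestAssembleDerivative:
    def test_budget_identity_is_exact(self, baseline_forcing, fleet):
        web = compile_web(baseline_forcing, fleet=fleet)
        s = default_initial_state(web)
        der = assemble_derivative(s, web, 120)
        lhs = der.dstate.sum()
        rhs = der.inputs.sum() - der.exports.sum()
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)

    def test_all_biology_zero_leaves_chemistry_only(self, baseline_forcing):
        web = compile_web(baseline_forcing)
        idx = web.idx
        s = idx.zeros()
        s[idx["det_so"]] = 10.0
        der = assemble_derivative(s, web, 200)
        # mineralization moves detritus to ammonia; no biological pool gains
        assert der.F[idx["det_so"], idx["nh4_so"]] > 0
        assert der.F[:, idx["fish_p"]].sum() == 0.0
        assert der.F[:, idx["omniv"]].sum() == 0.0

    def test_nan_state_rejected_with_pool_name(self, baseline_forcing):
        web = compile_web(baseline_forcing)
        s = default_initial_state(web)
        s[web.idx["omniv"]] = np.nan
        with pytest.raises(DomainError, match="omniv"):
            assemble_derivative(s, web, 0)

    def test_absent_guild_is_frozen(self, baseline_forcing, fleet):
        # migratory fish fully outside the domain in January: no fluxes in
        # or out of its pool, so its state is held
        presence = PresenceSchedule(fractions={
            "fish_m": [0.0] * 12})
        web = compile_web(baseline_forcing, presence=presence, fleet=fleet)
        s = default_initial_state(web)
        der = assemble_derivative(s, web, 15)
        i = web.idx["fish_m"]
        assert der.F[i, :].sum() == 0.0
        assert der.F[:, i].sum() == 0.0
        assert der.exports[i].sum() == 0.0

    def test_zero_ice_forcing_is_temperate_configuration(self):
        f = pw.generate_forcing(pw.ScenarioSpec(label="custom", ice_scale=0.0))
        web = compile_web(f)
        assert np.all(web.mod_cons == 1.0)
        s = default_initial_state(web)
        from polarfoodweb.runner import step_day
        for d in range(0, 365, 30):
            s, _ = step_day(s, web, d)
        idx = web.idx
        for arr in (idx.ice_no3, idx.ice_nh4, idx.ice_algae, idx.ice_det,
                    idx.snow_no3, idx.snow_nh4):
            assert np.all(s[arr] == 0.0)


class TestChemostatReduction:
    def test_steady_state_matches_closed_form(self):
        # One-pool chemostat: phytoplankton + a single nutrient under
        # constant dilution D and saturating light.  At steady state the
        # residual nutrient concentration is h*D/(u_max - D).
        p = PhytoParams(u_max=0.8, n_half_sat=1.2, nh4_inhibition=0.0,
                        light_half_sat=1.0)
        D, n_in = 0.2, 8.0
        N, P = n_in, 0.05
        dt = 0.05
        for _ in range(40000):
            no3, nh4 = primary_production_rate(P, 1e12, N, 0.0, p)
            uptake = no3 + nh4
            N += dt * (D * (n_in - N) - uptake)
            P += dt * (uptake - D * P)
        expected = p.n_half_sat * D / (p.u_max - D)
        assert N == pytest.approx(expected, rel=1e-3)
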