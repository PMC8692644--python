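"""Nitrogen-currency food-web flux network and daily derivative assembly.

Design: the instantaneous derivative is represented as a pool-to-pool flux
matrix ``F`` (``F[i, j]`` = flux from pool *i* to pool *j*, mMN m⁻² d⁻¹)
plus an input matrix (columns: boundary, river, atmosphere) and an export
matrix (columns: outflow, denitrification, burial, landings).  The state
derivative is then column-sums minus row-sums of ``F`` plus inputs minus
exports, so the domain nitrogen budget closes exactly by construction:
sum(dState/dt) = sum(inputs) − sum(exports).

Everything that depends only on the repeating annual forcing — daily
interpolations, light fields under snow and ice, Q10 factors, melt/freeze
rates, migration presence, fishing rate schedules — is precompiled into
365-day coefficient arrays by :func:`compile_web`, leaving only the
state-dependent nonlinear terms (Holling feeding, nutrient-saturating
primary production, quadratic mortality) for the per-step loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polarfoodweb.errors import DomainError, ParameterError
from polarfoodweb.fleet import FleetConfig, HarvestMultipliers
from polarfoodweb.forcing import DAYS_IN_YEAR, MONTH_LENGTHS, ForcingSet, daily_series
from polarfoodweb.geometry import DomainGeometry
from polarfoodweb.ice import (
    ice_algae_fluxes,
    interior_ice_irradiance,
    sub_ice_irradiance,
)
from polarfoodweb.params import (
    BEAR_HUNT_PREY,
    BEAR_SCAV_PREY,
    ModifierParams,
    ParameterSet,
    PresenceSchedule,
    default_parameters,
    default_presence,
)
from polarfoodweb.state import MIGRATORY_GUILDS, PoolIndex

INPUT_CATS = ("boundary", "river", "atmosphere")
EXPORT_CATS = ("outflow", "denitrification", "burial", "landings")
_I_BOUND, _I_RIVER, _I_ATMOS = 0, 1, 2
_E_OUT, _E_DENIT, _E_BURY, _E_LAND = 0, 1, 2, 3

_TINY = 1e-300


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def q10_factor(temperature, t_ref, q10):
    """Q10 temperature multiplier: q10 ** ((T − T_ref) / 10)."""
    if np.any(np.asarray(q10) <= 0):
        raise ParameterError("Q10 must be positive")
    return np.asarray(q10) ** ((np.asarray(temperature, float) - t_ref) / 10.0)


def holling_flux(consumer_mass, availabilities, u_max, half_sat):
    """Preference-weighted Holling type-II uptake.

    ``availabilities`` are the already-weighted prey availabilities
    π_i·P_i.  Total uptake is B_c·u_max·A/(A+h) with A = Σπ_i·P_i,
    apportioned across prey in proportion to π_i·P_i.  Returns
    ``(total, per_prey)``.
    """
    if half_sat <= 0:
        raise ParameterError("half-saturation must be positive")
    a = np.asarray(availabilities, dtype=float)
    total_avail = a.sum()
    total = consumer_mass * u_max * total_avail / (total_avail + half_sat)
    if total_avail <= 0:
        return 0.0, np.zeros_like(a)
    return float(total), total * a / total_avail


def nutrient_saturation(no3_conc, nh4_conc, half_sat, nh4_inhibition):
    """Saturation factor and NO3/NH4 uptake weights with ammonia preference."""
    w_nh4 = np.asarray(nh4_conc, float)
    w_no3 = np.asarray(no3_conc, float) * np.exp(-nh4_inhibition * w_nh4)
    eff = w_no3 + w_nh4
    sat = eff / (eff + half_sat)
    return sat, w_no3, w_nh4


def primary_production_rate(phyto_mass, irradiance, no3_conc, nh4_conc,
                            params) -> tuple:
    """Nitrate and ammonia uptake by phytoplankton (mMN d⁻¹ in the mass units
    of ``phyto_mass``), ammonia drawn preferentially.

    Multiplicative light saturation × nutrient saturation × maximum rate ×
    biomass; apply any Q10 factor to ``params.u_max`` upstream or scale the
    result.
    """
    lf = irradiance / (irradiance + params.light_half_sat)
    sat, w_no3, w_nh4 = nutrient_saturation(no3_conc, nh4_conc,
                                            params.n_half_sat,
                                            params.nh4_inhibition)
    total = phyto_mass * params.u_max * lf * sat
    eff = w_no3 + w_nh4
    if np.ndim(eff) == 0:
        if eff <= 0:
            return 0.0, 0.0
        return float(total * w_no3 / eff), float(total * w_nh4 / eff)
    share = np.where(eff > 0, w_no3 / np.where(eff > 0, eff, 1.0), 0.0)
    return total * share, total * (1.0 - share)


def migration_presence(schedule: PresenceSchedule, guild: str, day) -> float:
    """Fraction of a guild inside the domain on a given day (resident = 1)."""
    return schedule.daily(guild, day)


def ice_feeding_modifier(guild: str, cover, thickness,
                         params: ModifierParams | None = None):
    """Ice dependence of megafauna foraging.

    Birds and cetaceans risk entrapment under ice: their feeding multiplier
    falls linearly from 1 at zero cover to a floor at full cover.
    Pinnipeds are ice-edge dependent: unimodal in cover around an optimum.
    Maritime mammals (polar bears) need thick ice to hunt pinnipeds: the
    hunting weight ramps 0→1 over a thickness window and the complement is
    returned as the land-based scavenging weight — for ``guild="bear"``
    the return value is the pair ``(hunt_weight, scavenge_weight)``.
    """
    p = params or ModifierParams()
    cover = float(cover)
    if not 0.0 <= cover <= 1.0:
        raise DomainError("ice cover must lie in [0, 1]")
    if guild == "bird":
        return 1.0 - (1.0 - p.bird_floor) * cover
    if guild == "cet":
        return 1.0 - (1.0 - p.cet_floor) * cover
    if guild == "pinn":
        # ice-edge dependence: unconstrained up to the cover optimum (haul-out
        # range), declining towards a floor under consolidated ice
        if cover <= p.pinn_cover_opt:
            return 1.0
        z = (cover - p.pinn_cover_opt) / p.pinn_cover_width
        return p.pinn_floor + (1.0 - p.pinn_floor) * float(np.exp(-z * z))
    if guild == "bear":
        lo, hi = p.bear_thickness_lo, p.bear_thickness_hi
        w = float(np.clip((float(thickness) - lo) / (hi - lo), 0.0, 1.0))
        return w, 1.0 - w
    return 1.0


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

def _day_months() -> np.ndarray:
    months = np.repeat(np.arange(1, 13), MONTH_LENGTHS.astype(int))
    assert months.size == DAYS_IN_YEAR
    return months


@dataclass
class CompiledWeb:
    """Everything the integrator needs, with forcing precompiled to 365 days."""

    idx: PoolIndex
    params: ParameterSet
    geometry: DomainGeometry
    forcing: ForcingSet
    fleet: FleetConfig | None
    multipliers: HarvestMultipliers
    presence: PresenceSchedule

    # consumer arrays
    cons_names: list = field(default_factory=list)
    ci: np.ndarray = None
    u_max: np.ndarray = None
    half_sat: np.ndarray = None
    W: np.ndarray = None
    M: np.ndarray = None
    qf_cons: np.ndarray = None       # (365, n_c)
    mod_cons: np.ndarray = None      # (365, n_c)
    pres_cons: np.ndarray = None     # (365, n_c)
    refuge: np.ndarray = None        # (n,) prey refuge densities
    bear_row_day: np.ndarray = None  # (365, n) or None
    bear_ci: int = -1

    # mortality
    mort_idx: np.ndarray = None
    mort_lin: np.ndarray = None
    mort_dd: np.ndarray = None
    D_mort: np.ndarray = None        # (n_m, n)
    mort_pres: np.ndarray = None     # (365, n_m)

    # linear transfers and exports
    lin_src: np.ndarray = None
    lin_dst: np.ndarray = None
    lin_rate: np.ndarray = None      # (365, m)
    exp_src: np.ndarray = None
    exp_cat: np.ndarray = None
    exp_rate: np.ndarray = None      # (365, k)
    inputs_day: np.ndarray = None    # (365, n, 3)

    # environment summaries used by the nonlinear blocks
    T: np.ndarray = None             # (365, 3) si/so/deep
    E_mean: np.ndarray = None        # (365, 2) si/so layer-mean light
    E_macro: np.ndarray = None       # (365,)
    E_ice: np.ndarray = None         # (365, 2)
    pool_presence: np.ndarray = None  # (365, n)
    qf_phyto: np.ndarray = None      # (365, 2)

    # diagnostics index tuples
    npp_water_ix: tuple = None
    npp_ice_ix: tuple = None

    def zeros_state(self) -> np.ndarray:
        return self.idx.zeros()


def _layer_mean_light(e_under, k, depth):
    kd = k * depth
    return e_under * (1.0 - np.exp(-kd)) / np.maximum(kd, 1e-12)


def compile_web(forcing: ForcingSet,
                params: ParameterSet | None = None,
                geometry: DomainGeometry | None = None,
                presence: PresenceSchedule | None = None,
                fleet: FleetConfig | None = None,
                multipliers: HarvestMultipliers | None = None) -> CompiledWeb:
    """Precompile the model for one scenario (forcing + config)."""
    params = params or default_parameters()
    geometry = geometry or DomainGeometry()
    presence = presence if presence is not None else default_presence()
    multipliers = multipliers or HarvestMultipliers()
    idx = PoolIndex(geometry)
    n = idx.n
    web = CompiledWeb(idx=idx, params=params, geometry=geometry,
                      forcing=forcing, fleet=fleet, multipliers=multipliers,
                      presence=presence)

    g = geometry
    f_in, f_off = g.inshore_area_fraction, g.offshore_area_fraction
    v_si, v_so, v_d = idx.layer_volume
    h_in = g.inshore_depth_m
    h_up = g.offshore_upper_depth_m
    h_dn = g.offshore_total_depth_m - h_up

    # ---------------- daily environment ---------------------------------
    ds = lambda var, zone, layer: daily_series(forcing.cycle(var, zone, layer))
    T = np.column_stack([
        ds("temperature", "inshore", "surface"),
        ds("temperature", "offshore", "surface"),
        ds("temperature", "offshore", "deep"),
    ])
    cover = np.column_stack([ds("ice_cover", "inshore", "ice"),
                             ds("ice_cover", "offshore", "ice")])
    thick = np.column_stack([ds("ice_thickness", "inshore", "ice"),
                             ds("ice_thickness", "offshore", "ice")])
    snow = np.column_stack([ds("snow_thickness", "inshore", "ice"),
                            ds("snow_thickness", "offshore", "ice")])
    irr = np.column_stack([ds("irradiance", "inshore", "surface"),
                           ds("irradiance", "offshore", "surface")])
    spm = np.column_stack([ds("spm", "inshore", "surface"),
                           ds("spm", "offshore", "surface")])
    kz = ds("vertical_diffusivity", "offshore", "n/a")
    q_ocean = ds("ocean_inflow", "offshore", "n/a") * g.mean_depth_m
    q_river = ds("river_inflow", "inshore", "n/a") * g.mean_depth_m
    b_no3 = ds("boundary_din", "offshore", "n/a")
    b_det = ds("boundary_detritus", "offshore", "n/a")
    b_phyt = ds("boundary_phytoplankton", "offshore", "n/a")
    atm = np.column_stack([ds("atmos_deposition", "inshore", "n/a"),
                           ds("atmos_deposition", "offshore", "n/a")])
    riv_conc = ds("river_nutrient", "inshore", "n/a")

    opt = params.optics
    e_under = sub_ice_irradiance(irr, cover, thick, snow, opt)
    k_att = opt.k_water + opt.k_spm * spm
    web.E_mean = np.column_stack([
        _layer_mean_light(e_under[:, 0], k_att[:, 0], h_in),
        _layer_mean_light(e_under[:, 1], k_att[:, 1], h_up),
    ])
    web.E_macro = e_under[:, 0] * np.exp(-k_att[:, 0] * 5.0)
    web.E_ice = interior_ice_irradiance(irr, thick, snow, opt)
    web.T = T

    # melt / freeze rates from prescribed ice and snow volumes
    v_ice = cover * thick
    v_snow = cover * snow
    def _rates(v):
        dv = np.roll(v, -1, axis=0) - v
        with np.errstate(divide="ignore", invalid="ignore"):
            melt = np.where(v > 0, np.clip(-dv / np.maximum(v, _TINY), 0, 1), 0.0)
        melt = np.where((np.roll(v, -1, axis=0) == 0) & (v > 0), 1.0, melt)
        freeze = np.maximum(dv, 0.0)
        return melt, freeze
    melt_ice, freeze_ice = _rates(v_ice)
    melt_snow, _ = _rates(v_snow)

    months = _day_months()

    # presence per migratory guild
    pres = np.ones((DAYS_IN_YEAR, len(MIGRATORY_GUILDS)))
    for j, gname in enumerate(MIGRATORY_GUILDS):
        if gname in presence.fractions:
            pres[:, j] = [presence.daily(gname, d)
                          for d in range(1, DAYS_IN_YEAR + 1)]
    pool_presence = np.ones((DAYS_IN_YEAR, n))
    for j, gname in enumerate(MIGRATORY_GUILDS):
        pool_presence[:, idx[gname]] = pres[:, j]
    web.pool_presence = pool_presence
    pres_of = {gname: pres[:, j] for j, gname in enumerate(MIGRATORY_GUILDS)}

    # megafauna ice modifiers (domain-aggregate ice state)
    mp = params.modifiers
    cbar = f_in * cover[:, 0] + f_off * cover[:, 1]
    num = f_in * cover[:, 0] * thick[:, 0] + f_off * cover[:, 1] * thick[:, 1]
    tbar = np.where(cbar > 0, num / np.maximum(cbar, _TINY), 0.0)
    mod_bird = 1.0 - (1.0 - mp.bird_floor) * cbar
    mod_cet = 1.0 - (1.0 - mp.cet_floor) * cbar
    z = np.maximum(cbar - mp.pinn_cover_opt, 0.0) / mp.pinn_cover_width
    mod_pinn = mp.pinn_floor + (1.0 - mp.pinn_floor) * np.exp(-z * z)
    bear_w = np.clip((tbar - mp.bear_thickness_lo)
                     / (mp.bear_thickness_hi - mp.bear_thickness_lo), 0.0, 1.0)

    # ---------------- consumers -----------------------------------------
    cons = params.consumers
    names = list(cons)
    n_c = len(names)
    web.cons_names = names
    web.ci = np.array([idx[c] for c in names])
    web.u_max = np.array([cons[c].u_max for c in names])
    web.half_sat = np.array([cons[c].half_sat for c in names])

    tsel = {"surface_in": 0, "surface_off": 1, "deep": 2}
    W = np.zeros((n_c, n))
    M = np.zeros((n_c, n))
    det_dest = np.zeros(n)
    det_dest[idx["det_si"]] = f_in
    det_dest[idx["det_so"]] = f_off
    nh4_dest = np.zeros(n)
    nh4_dest[idx["nh4_si"]] = f_in
    nh4_dest[idx["nh4_so"]] = f_off
    # benthic waste goes to the sediment, excluding bare rock
    hab_w = idx.habitat_area.copy()
    hab_w[[0, 4]] = 0.0
    hab_w /= hab_w.sum()
    sed_dest = np.zeros(n)
    sed_dest[idx.sed_lab] = hab_w
    pw_dest = np.zeros(n)
    pw_dest[idx.pw_nh4] = hab_w

    qf_cons = np.ones((DAYS_IN_YEAR, n_c))
    mod_cons = np.ones((DAYS_IN_YEAR, n_c))
    pres_cons = np.ones((DAYS_IN_YEAR, n_c))
    for j, cname in enumerate(names):
        c = cons[cname]
        for prey, w in c.prey.items():
            W[j, idx[prey]] = w
        M[j, idx[cname]] = c.assim
        if c.guild_type == "benthic":
            M[j] += c.defecate * sed_dest + c.excrete * pw_dest
        else:
            M[j] += c.defecate * det_dest + c.excrete * nh4_dest
        qf_cons[:, j] = q10_factor(T[:, tsel[c.temp_layer]], c.t_ref, c.q10)
        if cname == "bird":
            mod_cons[:, j] = mod_bird
        elif cname == "cet":
            mod_cons[:, j] = mod_cet
        elif cname == "pinn":
            mod_cons[:, j] = mod_pinn
        if cname in pres_of:
            pres_cons[:, j] = pres_of[cname]
    web.W, web.M = W, M
    web.qf_cons, web.mod_cons, web.pres_cons = qf_cons, mod_cons, pres_cons
    refuge = np.zeros(n)
    for pool, r in params.refuges.items():
        refuge[idx[pool]] = r
    web.refuge = refuge

    if "bear" in names:
        j = names.index("bear")
        web.bear_ci = j
        hunt = np.zeros(n)
        scav = np.zeros(n)
        for p_name in BEAR_HUNT_PREY:
            hunt[idx[p_name]] = cons["bear"].prey.get(p_name, 0.0)
        for p_name in BEAR_SCAV_PREY:
            scav[idx[p_name]] = cons["bear"].prey.get(p_name, 0.0)
        web.bear_row_day = np.outer(bear_w, hunt) + np.outer(1 - bear_w, scav)

    # mortality (consumers only; phytoplankton mortality is a linear entry)
    web.mort_idx = web.ci.copy()
    web.mort_lin = np.array([cons[c].mort for c in names])
    web.mort_dd = np.array([cons[c].mort_dd for c in names])
    D_mort = np.zeros((n_c, n))
    for j, cname in enumerate(names):
        if cons[cname].mort_dest == "corpse":
            D_mort[j, idx["corpse"]] = 1.0
        else:
            D_mort[j] = det_dest
    web.D_mort = D_mort
    web.mort_pres = pres_cons.copy()

    # ---------------- linear transfer entries ---------------------------
    ch = params.chem
    qf3 = np.column_stack([q10_factor(T[:, k], ch.t_ref, ch.q10)
                           for k in range(3)])
    web.qf_phyto = np.column_stack([
        q10_factor(T[:, 0], params.phyto.t_ref, params.phyto.q10),
        q10_factor(T[:, 1], params.phyto.t_ref, params.phyto.q10),
    ])
    ones = np.ones(DAYS_IN_YEAR)
    lin: list = []      # (src, dst, rate_day)

    def add(src, dst, rate_day):
        lin.append((idx[src] if isinstance(src, str) else src,
                    idx[dst] if isinstance(dst, str) else dst,
                    np.asarray(rate_day, float) * ones))

    hab_w_in = np.asarray(g.inshore_habitat_fractions)[1:]
    hab_w_in = hab_w_in / hab_w_in.sum()
    hab_w_off = np.asarray(g.offshore_habitat_fractions)[1:]
    hab_w_off = hab_w_off / hab_w_off.sum()
    ph = params.phyto
    for cls, w in zip(("fine", "medium", "coarse"), hab_w_in):
        add("phyt_si", f"sed_lab_in_{cls}", ph.sink / h_in * w)
        add("det_si", f"sed_lab_in_{cls}", ch.det_sink / h_in * w)
    add("phyt_so", "phyt_d", ph.sink / h_up)
    add("det_so", "det_d", ch.det_sink / h_up)
    for cls, w in zip(("fine", "medium", "coarse"), hab_w_off):
        add("phyt_d", f"sed_lab_off_{cls}", ph.sink / h_dn * w)
        add("det_d", f"sed_lab_off_{cls}", ch.det_sink / h_dn * w)
    for suffix, k in (("si", 0), ("so", 1), ("d", 2)):
        add(f"phyt_{suffix}", f"det_{suffix}", ph.mort)
        add(f"det_{suffix}", f"nh4_{suffix}", ch.det_min * qf3[:, k])
        add(f"nh4_{suffix}", f"no3_{suffix}", ch.nitrif_water * qf3[:, k])
    for hj in range(8):
        k = 0 if idx.habitat_zone[hj] == 0 else 2
        lab, ref = idx.sed_lab[hj], idx.sed_ref[hj]
        pno3, pnh4 = idx.pw_no3[hj], idx.pw_nh4[hj]
        over_no3 = idx["no3_si"] if k == 0 else idx["no3_d"]
        over_nh4 = idx["nh4_si"] if k == 0 else idx["nh4_d"]
        add(lab, pnh4, ch.sed_lab_min * qf3[:, k])
        add(lab, ref, ch.lab_to_ref)
        add(ref, pnh4, ch.ref_min)
        add(pnh4, pno3, ch.nitrif_sed * qf3[:, k])
        add(pno3, over_no3, ch.pw_release)
        add(pnh4, over_nh4, ch.pw_release)
    # corpses and debris settle into the sediment
    full_hab_w = idx.habitat_area.copy()
    full_hab_w[[0, 4]] = 0.0
    full_hab_w /= full_hab_w.sum()
    for hj in range(8):
        if full_hab_w[hj] > 0:
            add("corpse", int(idx.sed_lab[hj]), ch.corpse_min * full_hab_w[hj])
    add("discard", "corpse", ch.discard_sink)
    for cls, w in zip(("fine", "medium", "coarse"), hab_w_in):
        add("mdebris", f"sed_lab_in_{cls}", ch.mdebris_min * w)
    # macrophyte shedding
    add("mphyt", "mdebris", params.macro.shed_rate)

    # spawning (seasonal) and maturation
    for sp in params.spawning:
        season = np.isin(months, list(sp.season)).astype(float)
        add(sp.adult, sp.larva, sp.spawn_rate * season)
        add(sp.larva, sp.adult, sp.maturation_rate)

    # vertical mixing and inshore-offshore exchange (volume-exchange form)
    dz_mid = 0.5 * h_up + 0.5 * h_dn
    vx = kz / dz_mid * f_off            # m³ m⁻² d⁻¹ of domain
    qh = params.transport.horizontal_exchange
    for tracer in ("no3", "nh4", "det", "phyt"):
        add(f"{tracer}_d", f"{tracer}_so", vx / v_d)
        add(f"{tracer}_so", f"{tracer}_d", vx / v_so)
        add(f"{tracer}_si", f"{tracer}_so", qh / v_si)
        add(f"{tracer}_so", f"{tracer}_si", qh / v_so)

    # melt / freeze exchange between ice and surface water
    ice_route = {"ice_no3": "no3", "ice_nh4": "nh4",
                 "ice_algae": "phyt", "ice_det": "det"}
    snow_route = {"snow_no3": "no3", "snow_nh4": "nh4"}
    for zj, zshort, wsuf in ((0, "in", "si"), (1, "off", "so")):
        for src_f, dst_f in ice_route.items():
            add(f"{src_f}_{zshort}", f"{dst_f}_{wsuf}", melt_ice[:, zj])
        for src_f, dst_f in snow_route.items():
            add(f"{src_f}_{zshort}", f"{dst_f}_{wsuf}", melt_snow[:, zj])
        ent = params.ice_bio.entrain_frac * freeze_ice[:, zj]
        v_layer = v_si if zj == 0 else v_so
        add(f"no3_{wsuf}", f"ice_no3_{zshort}", ent / v_layer)
        add(f"nh4_{wsuf}", f"ice_nh4_{zshort}", ent / v_layer)
        # new ice also freezes in a phytoplankton inoculum for the ice algae
        add(f"phyt_{wsuf}", f"ice_algae_{zshort}", ent / v_layer)

    # ---------------- exports and fleet ---------------------------------
    exp: list = []      # (src, cat, rate_day)

    def add_exp(src, cat, rate_day):
        exp.append((idx[src] if isinstance(src, str) else src, cat,
                    np.asarray(rate_day, float) * ones))

    for hj in range(8):
        k = 0 if idx.habitat_zone[hj] == 0 else 2
        add_exp(int(idx.pw_no3[hj]), _E_DENIT, ch.denitrif * qf3[:, k])
        add_exp(int(idx.sed_ref[hj]), _E_BURY, ch.burial)
    # boundary exchange spans the full offshore water column: the gross
    # in/outflow volume splits between upper and deep layers by volume
    so_share = v_so / (v_so + v_d)
    for tracer in ("no3", "nh4", "det", "phyt"):
        add_exp(f"{tracer}_so", _E_OUT, q_ocean * so_share / v_so)
        add_exp(f"{tracer}_d", _E_OUT, q_ocean * (1 - so_share) / v_d)
        add_exp(f"{tracer}_si", _E_OUT, q_river / v_si)

    if fleet is not None:
        offal_f = fleet.offal_fraction
        for guild in ("fish_p", "fish_m", "fish_d", "benth_s", "benth_c",
                      "pinn", "cet"):
            rate = fleet.aggregate_rate(guild) * multipliers.for_guild(guild)
            if rate == 0:
                continue
            pres_g = pres_of.get(guild, ones)
            dfrac = fleet.discard_fraction(guild)
            add_exp(guild, _E_LAND,
                    rate * (1 - dfrac) * (1 - offal_f) * pres_g)
            add(guild, "discard", rate * dfrac * pres_g)
            add(guild, "corpse", rate * (1 - dfrac) * offal_f * pres_g)
        for guild in ("bird", "pinn", "cet"):
            r = fleet.bycatch_rate(guild)
            if r > 0:
                add(guild, "corpse", r * pres_of.get(guild, ones))
        ab = fleet.abrasion_rate()
        if ab > 0:
            fp = fleet.abrasion_footprint()
            wts = idx.habitat_area * fp[np.tile(np.arange(4), 2)]
            wts = wts / wts.sum() if wts.sum() > 0 else full_hab_w
            for guild in ("benth_s", "benth_c"):
                for hj in range(8):
                    if wts[hj] > 0:
                        add(guild, int(idx.sed_lab[hj]), ab * wts[hj])

    web.lin_src = np.array([e[0] for e in lin])
    web.lin_dst = np.array([e[1] for e in lin])
    web.lin_rate = np.column_stack([e[2] for e in lin]) if lin else \
        np.zeros((DAYS_IN_YEAR, 0))
    web.exp_src = np.array([e[0] for e in exp])
    web.exp_cat = np.array([e[1] for e in exp])
    web.exp_rate = np.column_stack([e[2] for e in exp]) if exp else \
        np.zeros((DAYS_IN_YEAR, 0))

    # ---------------- external inputs -----------------------------------
    inputs = np.zeros((DAYS_IN_YEAR, n, 3))
    so_share = v_so / (v_so + v_d)
    inputs[:, idx["no3_so"], _I_BOUND] = q_ocean * so_share * b_no3
    inputs[:, idx["no3_d"], _I_BOUND] = q_ocean * (1 - so_share) * b_no3
    inputs[:, idx["det_so"], _I_BOUND] = q_ocean * so_share * b_det
    inputs[:, idx["det_d"], _I_BOUND] = q_ocean * (1 - so_share) * b_det
    inputs[:, idx["phyt_so"], _I_BOUND] = q_ocean * so_share * b_phyt
    inputs[:, idx["phyt_d"], _I_BOUND] = q_ocean * (1 - so_share) * b_phyt
    inputs[:, idx["no3_si"], _I_RIVER] = q_river * riv_conc
    for zj, (no3_s, snow_no3) in enumerate(
            zip(("no3_si", "no3_so"), ("snow_no3_in", "snow_no3_off"))):
        f_z = f_in if zj == 0 else f_off
        inputs[:, idx[no3_s], _I_ATMOS] = \
            f_z * atm[:, zj] * (1.0 - cover[:, zj])
        inputs[:, idx[snow_no3], _I_ATMOS] = f_z * atm[:, zj] * cover[:, zj]
    web.inputs_day = inputs

    # NPP diagnostic index blocks
    nut_rows = [idx["no3_si"], idx["no3_so"], idx["nh4_si"], idx["nh4_so"]]
    phyt_cols = [idx["phyt_si"], idx["phyt_so"]]
    web.npp_water_ix = np.ix_(nut_rows, phyt_cols)
    web.npp_ice_ix = np.ix_(list(idx.ice_no3) + list(idx.ice_nh4),
                            list(idx.ice_algae))
    return web


# ---------------------------------------------------------------------------
# derivative assembly
# ---------------------------------------------------------------------------

@dataclass
class Derivative:
    """One day's assembled fluxes."""

    F: np.ndarray            # (n, n) pool-to-pool
    inputs: np.ndarray       # (n, 3)
    exports: np.ndarray      # (n, 4)

    @property
    def dstate(self) -> np.ndarray:
        return (self.F.sum(axis=0) - self.F.sum(axis=1)
                + self.inputs.sum(axis=1) - self.exports.sum(axis=1))


def assemble_derivative(state: np.ndarray, web: CompiledWeb,
                        day_index: int) -> Derivative:
    """Assemble all fluxes for one day (0-based index into the 365-day year).

    Conservation: sum(dstate) equals sum(inputs) − sum(exports) exactly.
    """
    if np.any(~np.isfinite(state)):
        bad = web.idx.names[int(np.argmax(~np.isfinite(state)))]
        raise DomainError(f"non-finite state in pool {bad}")
    if np.any(state < -1e-9):
        bad = web.idx.names[int(np.argmin(state))]
        raise DomainError(f"negative state in pool {bad}")

    idx = web.idx
    n = idx.n
    d = day_index % DAYS_IN_YEAR
    B = np.maximum(state, 0.0)

    # feeding -------------------------------------------------------------
    # G[c, p] is the gross uptake consumer c draws from prey pool p; the
    # routing matrix M (rows sum to 1: assimilated + defecated + excreted)
    # distributes it to the consumer pool, detritus and ammonia, so
    # F[p, dest] = sum_c G[c, p] * M[c, dest] debits prey exactly.
    if web.bear_row_day is not None:
        web.W[web.bear_ci] = web.bear_row_day[d]
    Bp = B * web.pool_presence[d]
    WB = web.W * np.maximum(Bp - web.refuge, 0.0)[None, :]
    A = WB.sum(axis=1)
    U = (Bp[web.ci] * web.u_max * web.qf_cons[d] * web.mod_cons[d]
         * A / (A + web.half_sat))
    scale = np.where(A > 0, U / np.maximum(A, _TINY), 0.0)
    G = scale[:, None] * WB
    F = np.einsum("cp,cd->pd", G, web.M)

    # consumer mortality (linear + quadratic), presence-scaled
    mB = B[web.mort_idx]
    mflux = web.mort_pres[d] * (web.mort_lin + web.mort_dd * mB) * mB
    F[web.mort_idx] += mflux[:, None] * web.D_mort

    # primary production --------------------------------------------------
    p = web.params.phyto
    v = idx.layer_volume
    for zj, (no3_i, nh4_i, ph_i) in enumerate((
            (idx["no3_si"], idx["nh4_si"], idx["phyt_si"]),
            (idx["no3_so"], idx["nh4_so"], idx["phyt_so"]))):
        e = web.E_mean[d, zj]
        if e <= 0 or B[ph_i] <= 0:
            continue
        u_no3, u_nh4 = primary_production_rate(
            B[ph_i], e, B[no3_i] / v[zj], B[nh4_i] / v[zj], p)
        q = web.qf_phyto[d, zj]
        F[no3_i, ph_i] += u_no3 * q
        F[nh4_i, ph_i] += u_nh4 * q

    # macrophytes (inshore, light-limited logistic) -----------------------
    mc = web.params.macro
    m_i = idx["mphyt"]
    if B[m_i] > 0 and web.E_macro[d] > 0:
        lf = web.E_macro[d] / (web.E_macro[d] + mc.light_half_sat)
        sat, w_no3, w_nh4 = nutrient_saturation(
            B[idx["no3_si"]] / v[0], B[idx["nh4_si"]] / v[0],
            mc.n_half_sat, p.nh4_inhibition)
        cap = max(0.0, 1.0 - B[m_i] / mc.carrying_capacity)
        total = mc.u_max * lf * sat * cap * B[m_i]
        eff = w_no3 + w_nh4
        if eff > 0 and total > 0:
            F[idx["no3_si"], m_i] += total * w_no3 / eff
            F[idx["nh4_si"], m_i] += total * w_nh4 / eff

    # sympagic biology ----------------------------------------------------
    up_no3, up_nh4, death = ice_algae_fluxes(
        B[idx.ice_algae], B[idx.ice_no3], B[idx.ice_nh4],
        web.E_ice[d], web.params.ice_bio)
    F[idx.ice_no3, idx.ice_algae] += up_no3
    F[idx.ice_nh4, idx.ice_algae] += up_nh4
    F[idx.ice_algae, idx.ice_det] += death

    # precompiled linear transfers ---------------------------------------
    if web.lin_src.size:
        np.add.at(F, (web.lin_src, web.lin_dst), web.lin_rate[d] * B[web.lin_src])

    exports = np.zeros((n, 4))
    if web.exp_src.size:
        np.add.at(exports, (web.exp_src, web.exp_cat),
                  web.exp_rate[d] * B[web.exp_src])

    return Derivative(F=F, inputs=web.inputs_day[d].copy(), exports=exports)
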