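"""Sea-ice/snow optics and sympagic biogeochemistry.

Ice cover, ice thickness and snow thickness are prescribed by the forcing
(no ice thermodynamics); this module models what lives in and under that
ice: light attenuation through snow and ice, ice-algal growth on ice
nitrate/ammonia (ammonia preferred), linear ice-algal death to ice
detritus, and proportional melt/freeze exchange of every ice-carried pool
with the surface water column.  Within the ice, biology only transfers
nitrogen between ice pools — total ice nitrogen is conserved; melt/freeze
moves mass between ice and water without creating or destroying any.

Masses are areal (mMN per m² of zone surface); zone arrays are ordered
(inshore, offshore).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polarfoodweb.errors import DomainError, ParameterError


@dataclass(frozen=True)
class OpticsParams:
    """Light attenuation constants.

    k_ice, k_snow: exponential attenuation coefficients (m⁻¹) of ice and
    snow; ice_transmission: scalar surface transmission factor through the
    ice surface; k_water and k_spm: water-column attenuation baseline (m⁻¹)
    and increment per unit suspended particulate matter (m⁻¹ per g m⁻³).
    """

    k_ice: float = 1.5
    k_snow: float = 10.0
    ice_transmission: float = 0.9
    k_water: float = 0.10
    k_spm: float = 0.04

    def __post_init__(self):
        vals = (self.k_ice, self.k_snow, self.ice_transmission,
                self.k_water, self.k_spm)
        if any(v < 0 for v in vals):
            raise ParameterError("optics constants must be non-negative")
        if self.ice_transmission > 1:
            raise ParameterError("ice surface transmission cannot exceed 1")


@dataclass(frozen=True)
class IceBioParams:
    """Sympagic biology constants.

    u_max: maximum ice-algal uptake rate (d⁻¹); light_half_sat
    (E m⁻² d⁻¹) and n_half_sat (mMN m⁻²): half-saturation constants;
    ammonia_inhibition: exponential inhibition of nitrate uptake by ammonia
    ((mMN m⁻²)⁻¹); death_rate: linear ice-algal mortality to ice detritus
    (d⁻¹); entrain_frac: fraction of new-ice volume that entrains dissolved
    nutrients from surface water on freezing.
    """

    u_max: float = 0.6
    light_half_sat: float = 2.0
    n_half_sat: float = 1.0
    ammonia_inhibition: float = 1.5
    death_rate: float = 0.05
    entrain_frac: float = 0.5

    def __post_init__(self):
        if any(v < 0 for v in (self.u_max, self.light_half_sat,
                               self.n_half_sat, self.ammonia_inhibition,
                               self.death_rate, self.entrain_frac)):
            raise ParameterError("ice biology constants must be non-negative")


_MASS_FIELDS = ("snow_no3", "snow_nh4", "ice_no3", "ice_nh4",
                "ice_algae", "ice_det")


@dataclass
class IceState:
    """Per-zone ice descriptors and ice-carried nitrogen pools."""

    cover: np.ndarray
    thickness: np.ndarray
    snow: np.ndarray
    snow_no3: np.ndarray
    snow_nh4: np.ndarray
    ice_no3: np.ndarray
    ice_nh4: np.ndarray
    ice_algae: np.ndarray
    ice_det: np.ndarray

    def __post_init__(self):
        for name in ("cover", "thickness", "snow") + _MASS_FIELDS:
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name),
                                                         dtype=float)))
        if np.any(self.cover < 0) or np.any(self.cover > 1):
            raise ParameterError("ice cover must lie in [0, 1]")
        if np.any(self.thickness < 0) or np.any(self.snow < 0):
            raise ParameterError("ice/snow thickness must be non-negative")
        for name in _MASS_FIELDS:
            v = getattr(self, name)
            if np.any(v < 0):
                raise ParameterError(f"{name}: ice-carried masses must be >= 0")
            if np.any((self.cover == 0.0) & (v > 0.0)):
                raise ParameterError(
                    f"{name}: ice-carried mass without ice cover"
                )

    @classmethod
    def zeros(cls, n_zones: int = 2) -> "IceState":
        z = np.zeros(n_zones)
        return cls(*([z.copy() for _ in range(9)]))

    @property
    def ice_volume(self) -> np.ndarray:
        """Ice volume per m² of zone (m): cover × thickness."""
        return self.cover * self.thickness

    @property
    def snow_volume(self) -> np.ndarray:
        return self.cover * self.snow

    def total_nitrogen(self) -> np.ndarray:
        return sum(getattr(self, f) for f in _MASS_FIELDS)

    def copy(self) -> "IceState":
        return IceState(**{f: getattr(self, f).copy()
                           for f in ("cover", "thickness", "snow") + _MASS_FIELDS})


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

def sub_ice_irradiance(surface_irradiance, cover, h_ice, h_snow,
                       optics: OpticsParams | None = None):
    """Irradiance entering the water under partial ice cover, E m⁻² d⁻¹.

    Area-weighted mix of the open-water path (full transmission) and the
    through-ice path τ·exp(−k_ice·h_ice − k_snow·h_snow).
    """
    optics = optics or OpticsParams()
    cover = np.asarray(cover, dtype=float)
    h_ice = np.asarray(h_ice, dtype=float)
    h_snow = np.asarray(h_snow, dtype=float)
    if np.any(h_ice < 0) or np.any(h_snow < 0):
        raise DomainError("ice/snow thickness must be non-negative")
    if np.any(cover < 0) or np.any(cover > 1):
        raise DomainError("ice cover must lie in [0, 1]")
    through_ice = optics.ice_transmission * np.exp(
        -optics.k_ice * h_ice - optics.k_snow * h_snow
    )
    out = np.asarray(surface_irradiance, dtype=float) * (
        (1.0 - cover) + cover * through_ice
    )
    return float(out) if np.ndim(out) == 0 else out


def interior_ice_irradiance(surface_irradiance, h_ice, h_snow,
                            optics: OpticsParams | None = None):
    """Irradiance at mid-ice depth (where the algae sit), through the snow."""
    optics = optics or OpticsParams()
    return (np.asarray(surface_irradiance, dtype=float)
            * optics.ice_transmission
            * np.exp(-optics.k_snow * np.asarray(h_snow, float)
                     - 0.5 * optics.k_ice * np.asarray(h_ice, float)))


# ---------------------------------------------------------------------------
# sympagic biology
# ---------------------------------------------------------------------------

def ice_algae_fluxes(algae, ice_no3, ice_nh4, irradiance,
                     params: IceBioParams | None = None):
    """Instantaneous sympagic transfer rates (mMN m⁻² d⁻¹).

    Returns (uptake_no3, uptake_nh4, death): light- and
    nutrient-saturating ice-algal uptake split between ammonia (preferred)
    and nitrate (inhibited exponentially by ammonia), and linear death to
    ice detritus.
    """
    p = params or IceBioParams()
    algae = np.asarray(algae, float)
    no3 = np.asarray(ice_no3, float)
    nh4 = np.asarray(ice_nh4, float)
    irr = np.asarray(irradiance, float)
    lf = irr / (irr + p.light_half_sat)
    w_nh4 = nh4
    w_no3 = no3 * np.exp(-p.ammonia_inhibition * nh4)
    n_eff = w_nh4 + w_no3
    sf = n_eff / (n_eff + p.n_half_sat)
    total = algae * p.u_max * lf * sf
    with np.errstate(invalid="ignore", divide="ignore"):
        share_nh4 = np.where(n_eff > 0, w_nh4 / np.where(n_eff > 0, n_eff, 1.0), 0.0)
    up_nh4 = total * share_nh4
    up_no3 = total - up_nh4
    death = algae * p.death_rate
    return up_no3, up_nh4, death


def ice_biology_step(ice: IceState, irradiance, dt: float,
                     params: IceBioParams | None = None):
    """One explicit step of the sympagic biology; conserves total ice N.

    Returns ``(new_ice, demand)`` where ``demand`` is the nutrient drawn
    from the ice nitrate and ammonia pools (mMN m⁻²).
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    up_no3, up_nh4, death = ice_algae_fluxes(
        ice.ice_algae, ice.ice_no3, ice.ice_nh4, irradiance, params
    )
    # clamp the step to available donor mass
    u_no3 = np.minimum(up_no3 * dt, ice.ice_no3)
    u_nh4 = np.minimum(up_nh4 * dt, ice.ice_nh4)
    d = np.minimum(death * dt, ice.ice_algae)
    out = ice.copy()
    out.ice_no3 = ice.ice_no3 - u_no3
    out.ice_nh4 = ice.ice_nh4 - u_nh4
    out.ice_algae = ice.ice_algae + u_no3 + u_nh4 - d
    out.ice_det = ice.ice_det + d
    return out, {"no3": u_no3, "nh4": u_nh4}


# ---------------------------------------------------------------------------
# melt / freeze exchange
# ---------------------------------------------------------------------------

#: routing of melting ice pools into surface-water pools
MELT_ROUTING = {
    "ice_no3": "nitrate",
    "ice_nh4": "ammonia",
    "ice_algae": "phytoplankton",
    "ice_det": "detritus",
    "snow_no3": "nitrate",
    "snow_nh4": "ammonia",
}


def melt_exchange_flux(before: IceState, after: IceState,
                       water_no3_conc=0.0, water_nh4_conc=0.0,
                       params: IceBioParams | None = None):
    """Mass exchange implied by a forcing-driven change in ice/snow volume.

    When ice volume shrinks, the same proportion of every ice-carried pool
    is delivered to the surface water (ice algae as phytoplankton, ice
    detritus as suspended detritus, nutrients as their dissolved
    counterparts); snow pools melt with snow volume.  When ice volume
    grows, dissolved nutrients are entrained from surface water in
    proportion to the new ice volume and the configured entrainment
    fraction (water concentrations in mMN m⁻³).

    Returns ``(new_ice, fluxes)`` with ``fluxes`` keyed by water pool name;
    positive values are deliveries to the water (mMN m⁻² d⁻¹ over a one-day
    transition).
    """
    p = params or IceBioParams()
    nz = before.cover.shape[0]
    fluxes = {k: np.zeros(nz) for k in
              ("nitrate", "ammonia", "phytoplankton", "detritus")}
    masses = {f: getattr(before, f).copy() for f in _MASS_FIELDS}

    v_b, v_a = before.ice_volume, after.ice_volume
    sv_b, sv_a = before.snow_volume, after.snow_volume

    with np.errstate(invalid="ignore", divide="ignore"):
        ice_loss = np.where(v_b > 0, np.clip(1.0 - v_a / np.where(v_b > 0, v_b, 1.0),
                                             0.0, 1.0), 0.0)
        snow_loss = np.where(sv_b > 0,
                             np.clip(1.0 - sv_a / np.where(sv_b > 0, sv_b, 1.0),
                                     0.0, 1.0), 0.0)
    ice_loss = np.where(v_a == 0.0, np.where(v_b > 0, 1.0, ice_loss), ice_loss)
    snow_loss = np.where(sv_a == 0.0, np.where(sv_b > 0, 1.0, snow_loss), snow_loss)

    for f in ("ice_no3", "ice_nh4", "ice_algae", "ice_det"):
        transfer = ice_loss * masses[f]
        fluxes[MELT_ROUTING[f]] += transfer
        masses[f] = masses[f] - transfer
    for f in ("snow_no3", "snow_nh4"):
        transfer = snow_loss * masses[f]
        fluxes[MELT_ROUTING[f]] += transfer
        masses[f] = masses[f] - transfer

    # freezing entrains dissolved nutrients from the surface water
    growth = np.maximum(v_a - v_b, 0.0)
    ent_no3 = p.entrain_frac * growth * np.asarray(water_no3_conc, float)
    ent_nh4 = p.entrain_frac * growth * np.asarray(water_nh4_conc, float)
    masses["ice_no3"] = masses["ice_no3"] + ent_no3
    masses["ice_nh4"] = masses["ice_nh4"] + ent_nh4
    fluxes["nitrate"] -= ent_no3
    fluxes["ammonia"] -= ent_nh4

    # a vanished ice sheet carries nothing
    gone = after.cover == 0.0
    for f in _MASS_FIELDS:
        fluxes[MELT_ROUTING[f]] += np.where(gone, masses[f], 0.0)
        masses[f] = np.where(gone, 0.0, masses[f])
    out = IceState(cover=after.cover.copy(), thickness=after.thickness.copy(),
                   snow=after.snow.copy(), **masses)
    return out, fluxes
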