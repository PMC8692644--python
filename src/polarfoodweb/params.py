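"""Biological and chemical process parameters, with shipped defaults.

Rates are daily; half-saturations are in the units of the quantity they
saturate (areal prey availability mMN m⁻², nutrient concentration
mMN m⁻³, irradiance E m⁻² d⁻¹).  Temperature dependence of poikilotherm
rates is a Q10 factor relative to a reference temperature; homeotherms
(seabirds, mammals) carry Q10 = 1.

The shipped defaults constitute the calibrated baseline configuration:
they were fitted (see the calibration module) so the baseline steady state
reproduces the headline annual quantities of the study region — annual net
primary production near 845 mMN m⁻² y⁻¹ and planktivorous/demersal
fish biomasses and catches of the observed magnitude.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from polarfoodweb.errors import ParameterError
from polarfoodweb.forcing import MonthlyCycle, daily_value
from polarfoodweb.ice import IceBioParams, OpticsParams


@dataclass
class ConsumerParams:
    """Holling type-II consumer: saturating preference-weighted feeding."""

    u_max: float
    half_sat: float
    prey: dict
    q10: float = 2.0
    t_ref: float = 5.0
    temp_layer: str = "surface_off"   # surface_in | surface_off | deep
    assim: float = 0.6
    excrete: float = 0.25
    defecate: float = 0.15
    mort: float = 0.01
    mort_dd: float = 0.0
    mort_dest: str = "detritus"       # detritus | corpse
    guild_type: str = "pelagic"       # pelagic | benthic | top

    def __post_init__(self):
        if min(self.u_max, self.half_sat, self.q10, self.mort,
               self.mort_dd) < 0:
            raise ParameterError("consumer rates must be non-negative")
        if any(w < 0 for w in self.prey.values()):
            raise ParameterError("preference weights must be non-negative")
        if self.assim + self.excrete + self.defecate > 1.0 + 1e-9:
            raise ParameterError(
                "assimilated + excreted + defecated fractions must sum <= 1"
            )


@dataclass
class PhytoParams:
    u_max: float = 0.545
    light_half_sat: float = 8.0
    n_half_sat: float = 1.0          # mMN m⁻³
    nh4_inhibition: float = 0.5      # m³ mMN⁻¹
    q10: float = 1.5
    t_ref: float = 5.0
    mort: float = 0.05               # d⁻¹, to suspended detritus
    sink: float = 0.5                # m d⁻¹


@dataclass
class MacrophyteParams:
    u_max: float = 0.12
    light_half_sat: float = 4.0
    n_half_sat: float = 1.0
    carrying_capacity: float = 4.0   # mMN per m² of domain
    shed_rate: float = 0.004         # d⁻¹, to macrophyte debris


@dataclass
class ChemParams:
    """First-order mineralization / nitrogen-cycle rates (d⁻¹)."""

    det_min: float = 0.010
    nitrif_water: float = 0.05
    nitrif_sed: float = 0.10
    sed_lab_min: float = 0.005
    lab_to_ref: float = 0.0005
    ref_min: float = 2.0e-4
    burial: float = 2.0e-5           # refractory loss out of the system
    denitrif: float = 0.005          # porewater nitrate loss
    pw_release: float = 0.01         # porewater -> overlying water
    corpse_min: float = 0.02         # corpses -> labile sediment detritus
    discard_sink: float = 0.05       # discards -> corpses
    mdebris_min: float = 0.02        # macrophyte debris -> labile sediment
    det_sink: float = 1.0            # m d⁻¹
    q10: float = 2.0
    t_ref: float = 5.0


@dataclass
class TransportParams:
    #: inshore-offshore exchange velocity, m³ per m² of domain per day
    horizontal_exchange: float = 0.5


@dataclass
class SpawnParams:
    """Seasonal spawning transfer from an adult guild into a larval pool."""

    adult: str
    larva: str
    spawn_rate: float = 0.001        # d⁻¹ of adult mass, during season
    maturation_rate: float = 0.02    # d⁻¹ of larval mass, year-round
    season: tuple = (3, 4, 5, 6)     # months


@dataclass
class ModifierParams:
    """Ice dependence of megafauna foraging."""

    bird_floor: float = 0.2
    cet_floor: float = 0.3
    pinn_floor: float = 0.2
    pinn_cover_opt: float = 0.5
    pinn_cover_width: float = 0.3
    bear_thickness_lo: float = 0.2   # m, hunting weight 0 below
    bear_thickness_hi: float = 0.8   # m, hunting weight 1 above


@dataclass
class ParameterSet:
    """Everything the derivative needs besides geometry, forcing and fleet."""

    phyto: PhytoParams = field(default_factory=PhytoParams)
    macro: MacrophyteParams = field(default_factory=MacrophyteParams)
    chem: ChemParams = field(default_factory=ChemParams)
    transport: TransportParams = field(default_factory=TransportParams)
    ice_bio: IceBioParams = field(default_factory=IceBioParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    modifiers: ModifierParams = field(default_factory=ModifierParams)
    consumers: dict = field(default_factory=dict)
    spawning: list = field(default_factory=list)
    #: prey refuge densities (mMN m⁻²): the part of a pool inaccessible to
    #: predators (spatial/behavioural refugia); stabilises low-density prey
    refuges: dict = field(default_factory=dict)
    substeps: int = 1

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- dotted-path access used by the calibration machinery ------------
    def get(self, path: str) -> float:
        obj = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
        last = parts[-1]
        return obj[last] if isinstance(obj, dict) else getattr(obj, last)

    def set(self, path: str, value: float) -> None:
        obj = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
        last = parts[-1]
        if isinstance(obj, dict):
            obj[last] = value
        else:
            object.__setattr__(obj, last, value)

    def with_values(self, updates: dict) -> "ParameterSet":
        out = self.copy()
        for k, v in updates.items():
            out.set(k, v)
        return out


@dataclass
class PresenceSchedule:
    """Monthly fractions (0-1) of each migratory guild inside the domain."""

    fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for guild, vals in self.fractions.items():
            v = np.asarray(vals, dtype=float)
            if v.shape != (12,):
                raise ParameterError(f"{guild}: presence needs 12 monthly values")
            if np.any(v < 0) or np.any(v > 1):
                raise ParameterError(f"{guild}: presence fractions in [0, 1]")
            clean[guild] = v
        self.fractions = clean

    def daily(self, guild: str, day: float) -> float:
        """Interpolated presence fraction; guilds without an entry are resident."""
        if guild not in self.fractions:
            return 1.0
        cyc = MonthlyCycle("presence", "offshore", "n/a", self.fractions[guild])
        return daily_value(cyc, day)


# ---------------------------------------------------------------------------
# shipped defaults
# ---------------------------------------------------------------------------

def default_presence() -> PresenceSchedule:
    return PresenceSchedule(fractions={
        "fish_m": [0.0, 0.0, 0.05, 0.3, 0.8, 1.0, 1.0, 1.0, 0.8, 0.3, 0.05, 0.0],
        "bird": [0.3, 0.3, 0.4, 0.7, 1.0, 1.0, 1.0, 1.0, 0.9, 0.6, 0.4, 0.3],
        "cet": [0.2, 0.2, 0.3, 0.6, 0.9, 1.0, 1.0, 1.0, 0.9, 0.6, 0.3, 0.2],
    })


def default_parameters() -> ParameterSet:
    """The calibrated default parameter set."""
    consumers = {
        "omniv": ConsumerParams(
            u_max=0.25, half_sat=20.0,
            prey={"phyt_si": 1.0, "phyt_so": 1.0, "det_si": 0.1, "det_so": 0.1},
            assim=0.6, excrete=0.25, defecate=0.15,
            mort=0.01, mort_dd=0.004, mort_dest="detritus",
            guild_type="pelagic"),
        "carniv": ConsumerParams(
            u_max=0.08, half_sat=4.0,
            prey={"omniv": 1.0, "larv_plank": 0.3, "larv_dem": 0.3,
                  "larv_sb": 0.3, "larv_cb": 0.3},
            assim=0.6, excrete=0.25, defecate=0.15,
            mort=0.005, mort_dd=0.005, mort_dest="detritus",
            guild_type="pelagic"),
        "larv_plank": ConsumerParams(
            u_max=0.08, half_sat=3.0,
            prey={"phyt_si": 0.5, "phyt_so": 0.5, "omniv": 0.5},
            assim=0.6, excrete=0.25, defecate=0.15,
            mort=0.03, mort_dest="detritus", guild_type="pelagic"),
        "larv_dem": ConsumerParams(
            u_max=0.08, half_sat=3.0,
            prey={"phyt_si": 0.5, "phyt_so": 0.5, "omniv": 0.5},
            assim=0.6, excrete=0.25, defecate=0.15,
            mort=0.03, mort_dest="detritus", guild_type="pelagic"),
        "larv_sb": ConsumerParams(
            u_max=0.08, half_sat=3.0,
            prey={"phyt_si": 0.5, "phyt_so": 0.5, "omniv": 0.5},
            assim=0.6, excrete=0.25, defecate=0.15,
            mort=0.03, mort_dest="detritus", guild_type="pelagic"),
        "larv_cb": ConsumerParams(
            u_max=0.08, half_sat=3.0,
            prey={"phyt_si": 0.5, "phyt_so": 0.5, "omniv": 0.5},
            assim=0.6, excrete=0.25, defecate=0.15,
            mort=0.03, mort_dest="detritus", guild_type="pelagic"),
        "benth_s": ConsumerParams(
            u_max=0.025, half_sat=6.0,
            prey={"det_si": 0.5, "det_d": 0.6, "phyt_si": 0.2, "phyt_d": 0.3,
                  "sed_lab_in_fine": 0.5, "sed_lab_in_medium": 0.5,
                  "sed_lab_in_coarse": 0.5, "sed_lab_off_fine": 0.5,
                  "sed_lab_off_medium": 0.5, "sed_lab_off_coarse": 0.5},
            assim=0.5, excrete=0.2, defecate=0.3, temp_layer="deep",
            mort=0.002, mort_dd=4.0e-4, mort_dest="corpse",
            guild_type="benthic"),
        "benth_c": ConsumerParams(
            u_max=0.012, half_sat=4.0,
            prey={"benth_s": 1.0, "corpse": 0.6, "discard": 0.3},
            assim=0.5, excrete=0.25, defecate=0.25, temp_layer="deep",
            mort=0.001, mort_dd=5.0e-4, mort_dest="corpse",
            guild_type="benthic"),
        "fish_p": ConsumerParams(
            u_max=0.0097, half_sat=0.5,
            prey={"omniv": 1.0, "carniv": 0.8, "larv_plank": 0.3,
                  "larv_dem": 0.3, "larv_sb": 0.3, "larv_cb": 0.3},
            assim=0.30, excrete=0.50, defecate=0.20,
            mort=0.0010, mort_dd=6.6e-5, mort_dest="corpse",
            guild_type="top"),
        "fish_m": ConsumerParams(
            u_max=0.010, half_sat=0.5,
            prey={"omniv": 0.4, "carniv": 1.0},
            assim=0.30, excrete=0.50, defecate=0.20,
            mort=0.0014, mort_dd=1.0e-4, mort_dest="corpse",
            guild_type="top"),
        "fish_d": ConsumerParams(
            u_max=0.0070, half_sat=2.0,
            prey={"benth_s": 1.0, "benth_c": 0.5, "fish_p": 0.1,
                  "fish_m": 0.1, "corpse": 0.2, "discard": 0.4},
            assim=0.30, excrete=0.50, defecate=0.20, temp_layer="deep",
            mort=0.0008, mort_dd=7.1e-5, mort_dest="corpse",
            guild_type="top"),
        "bird": ConsumerParams(
            u_max=0.04, half_sat=6.0, q10=1.0,
            prey={"fish_p": 1.0, "fish_m": 1.0, "discard": 0.5},
            assim=0.10, excrete=0.80, defecate=0.10,
            mort=5.0e-4, mort_dd=0.02, mort_dest="corpse",
            guild_type="top"),
        "pinn": ConsumerParams(
            u_max=0.022, half_sat=8.0, q10=1.0,
            prey={"fish_p": 1.0, "fish_m": 1.0, "fish_d": 0.4},
            assim=0.10, excrete=0.80, defecate=0.10,
            mort=3.0e-4, mort_dd=0.01, mort_dest="corpse",
            guild_type="top"),
        "cet": ConsumerParams(
            u_max=0.018, half_sat=8.0, q10=1.0,
            prey={"omniv": 0.3, "carniv": 0.6, "fish_p": 1.0, "fish_m": 1.0},
            assim=0.10, excrete=0.80, defecate=0.10,
            mort=2.0e-4, mort_dd=0.01, mort_dest="corpse",
            guild_type="top"),
        "bear": ConsumerParams(
            u_max=0.03, half_sat=1.0, q10=1.0,
            prey={"pinn": 1.0, "corpse": 1.0, "discard": 0.5, "bird": 0.5},
            assim=0.10, excrete=0.80, defecate=0.10,
            mort=2.0e-4, mort_dd=0.05, mort_dest="corpse",
            guild_type="top"),
    }
    spawning = [
        SpawnParams("fish_p", "larv_plank"),
        SpawnParams("fish_d", "larv_dem"),
        SpawnParams("benth_s", "larv_sb"),
        SpawnParams("benth_c", "larv_cb"),
    ]
    refuges = {
        "phyt_si": 0.1, "phyt_so": 0.3, "phyt_d": 0.1,
        "omniv": 0.2, "carniv": 0.1,
        "larv_plank": 0.01, "larv_dem": 0.01, "larv_sb": 0.01,
        "larv_cb": 0.01,
        "benth_s": 2.0, "benth_c": 0.1,
        "fish_p": 0.1, "fish_m": 0.1, "fish_d": 0.2,
        "bird": 0.002, "pinn": 0.005, "cet": 0.01,
        "corpse": 0.05, "discard": 0.02, "mphyt": 0.2,
    }
    return ParameterSet(consumers=consumers, spawning=spawning,
                        refuges=refuges)


#: prey of the maritime-mammal guild reachable only by hunting on ice
BEAR_HUNT_PREY = ("pinn",)
#: prey of the maritime-mammal guild reachable by land-based scavenging
BEAR_SCAV_PREY = ("corpse", "discard", "bird")
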