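"""Fishing-fleet forcing layer.

A fleet is a set of gears, each with an effort share, per-guild harvest-rate
weights (daily fishing mortality at unit effort), discard fractions,
bycatch rates on birds/pinnipeds/cetaceans and a seabed-abrasion rate with
a sediment-habitat footprint.  The harvest rate of a guild is the
effort-weighted sum over gears; two scenario multipliers scale the
planktivorous and demersal rates only, with everything else held at
baseline.  Landings leave the domain (a ledger export); discards enter the
discard pool, offal the corpse pool; bycatch mass goes to corpses and
abraded benthos mass to labile sediment detritus, so neither changes total
nitrogen.

Effort shares are relative: they are renormalised to sum to one, so scaling
every share by the same factor leaves the fluxes unchanged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from polarfoodweb.errors import ParameterError

#: guilds a gear may harvest
HARVESTABLE = ("fish_p", "fish_m", "fish_d", "benth_s", "benth_c",
               "pinn", "cet")
BYCATCH_GUILDS = ("bird", "pinn", "cet")


@dataclass
class Gear:
    name: str
    effort: float
    #: daily harvest mortality per guild at unit effort (d⁻¹)
    harvest_rates: dict = field(default_factory=dict)
    #: discard fraction of the gross catch, per guild
    discard_fractions: dict = field(default_factory=dict)
    #: daily bycatch mortality for bird/pinn/cet at unit effort (d⁻¹)
    bycatch_rates: dict = field(default_factory=dict)
    #: daily benthos mortality from seabed contact at unit effort (d⁻¹)
    abrasion_rate: float = 0.0
    #: relative footprint over sediment classes (rock, fine, medium, coarse)
    habitat_footprint: tuple = (0.0, 1.0, 1.0, 1.0)
    #: fraction of gear activity in the inshore zone
    inshore_share: float = 0.3

    def __post_init__(self):
        if self.effort < 0 or self.abrasion_rate < 0:
            raise ParameterError(f"{self.name}: rates must be non-negative")
        if any(r < 0 for r in self.harvest_rates.values()):
            raise ParameterError(f"{self.name}: harvest rates must be >= 0")
        if any(not 0 <= fr <= 1 for fr in self.discard_fractions.values()):
            raise ParameterError(f"{self.name}: discard fractions in [0, 1]")
        if any(r < 0 for r in self.bycatch_rates.values()):
            raise ParameterError(f"{self.name}: bycatch rates must be >= 0")


@dataclass
class HarvestMultipliers:
    """Scenario multipliers on the baseline planktivorous/demersal rates."""

    plank: float = 1.0
    dem: float = 1.0

    def __post_init__(self):
        if self.plank < 0 or self.dem < 0:
            raise ParameterError("harvest multipliers must be non-negative")

    def for_guild(self, guild: str) -> float:
        if guild == "fish_p":
            return self.plank
        if guild == "fish_d":
            return self.dem
        return 1.0


@dataclass
class FleetConfig:
    gears: list
    #: offal fraction of the landed weight returned to the corpse pool
    offal_fraction: float = 0.05

    def __post_init__(self):
        total = sum(g.effort for g in self.gears)
        if total <= 0:
            raise ParameterError("total gear effort must be positive")
        for g in self.gears:
            g.effort = g.effort / total
        if not 0 <= self.offal_fraction <= 1:
            raise ParameterError("offal fraction must lie in [0, 1]")

    def copy(self) -> "FleetConfig":
        return copy.deepcopy(self)

    # -- aggregates ------------------------------------------------------
    def aggregate_rate(self, guild: str) -> float:
        """Effort-weighted baseline harvest rate of a guild (d⁻¹)."""
        return sum(g.effort * g.harvest_rates.get(guild, 0.0)
                   for g in self.gears)

    def gear_share(self, guild: str) -> dict:
        """Each gear's share of the guild's gross catch (sums to 1)."""
        contributions = {g.name: g.effort * g.harvest_rates.get(guild, 0.0)
                         for g in self.gears}
        total = sum(contributions.values())
        if total == 0:
            return {name: 0.0 for name in contributions}
        return {name: c / total for name, c in contributions.items()}

    def discard_fraction(self, guild: str) -> float:
        """Catch-weighted mean discard fraction for a guild."""
        shares = self.gear_share(guild)
        return sum(shares[g.name] * g.discard_fractions.get(guild, 0.0)
                   for g in self.gears)

    def bycatch_rate(self, guild: str) -> float:
        return sum(g.effort * g.bycatch_rates.get(guild, 0.0)
                   for g in self.gears)

    def abrasion_rate(self) -> float:
        return sum(g.effort * g.abrasion_rate for g in self.gears)

    def abrasion_footprint(self) -> np.ndarray:
        """Effort-and-abrasion-weighted footprint over sediment classes."""
        w = np.zeros(4)
        for g in self.gears:
            fp = np.asarray(g.habitat_footprint, float)
            if fp.sum() > 0:
                w += g.effort * g.abrasion_rate * fp / fp.sum()
        return w / w.sum() if w.sum() > 0 else np.array([0, 1, 1, 1]) / 3.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def harvest_fluxes(biomass: dict, fleet: FleetConfig,
                   multipliers: HarvestMultipliers | None = None,
                   presence: dict | None = None) -> dict:
    """Gross daily catch flux per guild (mMN m⁻² d⁻¹).

    ``presence`` optionally scales migratory-guild catch by the fraction of
    the population inside the domain.
    """
    multipliers = multipliers or HarvestMultipliers()
    presence = presence or {}
    out = {}
    for guild, b in biomass.items():
        rate = fleet.aggregate_rate(guild) * multipliers.for_guild(guild)
        out[guild] = rate * b * presence.get(guild, 1.0)
    return out


def partition_catch(gross: float, discard_fraction: float,
                    offal_fraction: float) -> dict:
    """Split a gross catch into landings, discards and offal (conserving it).

    Discards return to the discard pool; an offal fraction of the landed
    processed weight returns to the corpse pool; the remainder exits the
    domain as landings.
    """
    if gross < 0:
        raise ParameterError("gross catch must be non-negative")
    discards = discard_fraction * gross
    landed = gross - discards
    offal = offal_fraction * landed
    return {"landings": landed - offal, "discards": discards, "offal": offal}


def apply_bycatch_and_abrasion(biomass: dict, fleet: FleetConfig) -> dict:
    """Daily bycatch and abrasion mortality fluxes (mMN m⁻² d⁻¹).

    Bycatch of birds/pinnipeds/cetaceans is routed to corpses; abraded
    benthos to labile sediment detritus.  Internal transfers only.
    """
    out = {"to_corpse": {}, "to_sediment": {}}
    for guild in BYCATCH_GUILDS:
        r = fleet.bycatch_rate(guild)
        if guild in biomass:
            out["to_corpse"][guild] = r * biomass[guild]
    ab = fleet.abrasion_rate()
    for guild in ("benth_s", "benth_c"):
        if guild in biomass:
            out["to_sediment"][guild] = ab * biomass[guild]
    return out


@dataclass
class CatchAccounts:
    """Annual landings/discards/offal per guild and per gear (mMN m⁻² y⁻¹)."""

    landings: dict = field(default_factory=dict)
    discards: dict = field(default_factory=dict)
    offal: dict = field(default_factory=dict)
    by_gear: dict = field(default_factory=dict)

    @property
    def total_landings(self) -> float:
        return float(sum(self.landings.values()))

    @property
    def total_discards(self) -> float:
        return float(sum(self.discards.values()))

    @classmethod
    def from_annual_gross(cls, gross: dict, fleet: FleetConfig) -> "CatchAccounts":
        """Build accounts from per-guild annual gross catches."""
        acc = cls()
        for guild, g in gross.items():
            parts = partition_catch(g, fleet.discard_fraction(guild),
                                    fleet.offal_fraction)
            acc.landings[guild] = parts["landings"]
            acc.discards[guild] = parts["discards"]
            acc.offal[guild] = parts["offal"]
            shares = fleet.gear_share(guild)
            for gear, s in shares.items():
                acc.by_gear.setdefault(gear, {})[guild] = s * g
        return acc


# ---------------------------------------------------------------------------
# shipped default fleet
# ---------------------------------------------------------------------------

def default_fleet() -> FleetConfig:
    """Baseline fleet: aggregate harvest rates tuned to land catches of the
    observed magnitude at the calibrated baseline biomasses."""
    gears = [
        Gear("pelagic_trawl", effort=0.25,
             harvest_rates={"fish_p": 5.72e-4, "fish_m": 2.0e-4},
             discard_fractions={"fish_p": 0.01, "fish_m": 0.01},
             inshore_share=0.1),
        Gear("demersal_trawl", effort=0.30,
             harvest_rates={"fish_d": 3.50e-4},
             discard_fractions={"fish_d": 0.02},
             abrasion_rate=2.0e-5,
             habitat_footprint=(0.0, 1.0, 1.0, 0.6),
             inshore_share=0.2),
        Gear("longline", effort=0.10,
             harvest_rates={"fish_d": 2.0e-4},
             discard_fractions={"fish_d": 0.02},
             bycatch_rates={"bird": 1.0e-6},
             inshore_share=0.4),
        Gear("gillnet", effort=0.10,
             harvest_rates={"fish_d": 0.6e-4},
             discard_fractions={"fish_d": 0.01},
             bycatch_rates={"bird": 2.0e-6, "pinn": 1.0e-6, "cet": 5.0e-7},
             inshore_share=0.7),
        Gear("shrimp_trawl", effort=0.10,
             harvest_rates={"benth_c": 2.0e-4, "fish_d": 1.0e-5},
             discard_fractions={"fish_d": 0.2, "benth_c": 0.05},
             abrasion_rate=1.0e-5,
             habitat_footprint=(0.0, 1.0, 0.8, 0.2),
             inshore_share=0.3),
        Gear("creel", effort=0.08,
             harvest_rates={"benth_c": 5.0e-5},
             inshore_share=0.8),
        Gear("whaler", effort=0.02,
             harvest_rates={"cet": 1.0e-4},
             inshore_share=0.2),
        Gear("sealer", effort=0.05,
             harvest_rates={"pinn": 2.0e-4},
             inshore_share=0.6),
    ]
    return FleetConfig(gears=gears)
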