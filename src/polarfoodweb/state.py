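"""Flat nitrogen state vector and its pool index.

Every pool of the food web — dissolved nutrients per zone/layer, snow/ice
pools per zone, sediment pools per habitat, and the biological guilds —
lives in one flat numpy vector of areal nitrogen densities
(mMN per m² of total domain surface).  Conservation checks are then exact
vector sums.  :class:`PoolIndex` owns the canonical ordering and the
convenience index arrays used by the derivative assembly.
"""

from __future__ import annotations

import numpy as np

from polarfoodweb.errors import StructuralError
from polarfoodweb.geometry import SEDIMENT_CLASSES, DomainGeometry

_ZONES_SHORT = ("in", "off")

WATER_POOLS = (
    "no3_si", "no3_so", "no3_d",
    "nh4_si", "nh4_so", "nh4_d",
    "det_si", "det_so", "det_d",
    "phyt_si", "phyt_so", "phyt_d",
)

ICE_FIELDS = ("snow_no3", "snow_nh4", "ice_no3", "ice_nh4",
              "ice_algae", "ice_det")

SED_FIELDS = ("sed_lab", "sed_ref", "pw_no3", "pw_nh4")

BIO_POOLS = (
    "mphyt", "mdebris", "corpse", "discard",
    "omniv", "carniv",
    "larv_plank", "larv_dem", "larv_sb", "larv_cb",
    "benth_s", "benth_c",
    "fish_p", "fish_m", "fish_d",
    "bird", "pinn", "cet", "bear",
)

#: guilds whose domain presence follows a monthly migration schedule
MIGRATORY_GUILDS = ("fish_m", "bird", "cet", "pinn")

#: human-readable labels for reports
POOL_LABELS = {
    "no3": "water-column nitrate", "nh4": "water-column ammonia",
    "det": "suspended detritus and bacteria", "phyt": "phytoplankton",
    "snow_no3": "nitrate in snow", "snow_nh4": "ammonia in snow",
    "ice_no3": "nitrate in ice", "ice_nh4": "ammonia in ice",
    "ice_algae": "ice algae", "ice_det": "ice detritus and bacteria",
    "sed_lab": "labile sediment detritus and bacteria",
    "sed_ref": "refractory sediment detritus",
    "pw_no3": "porewater nitrate", "pw_nh4": "porewater ammonia",
    "mphyt": "macrophytes", "mdebris": "macrophyte debris",
    "corpse": "corpses", "discard": "fishery discards",
    "omniv": "omnivorous zooplankton", "carniv": "carnivorous zooplankton",
    "larv_plank": "larvae of planktivorous fish",
    "larv_dem": "larvae of demersal fish",
    "larv_sb": "larvae of suspension/deposit benthos",
    "larv_cb": "larvae of carnivore/scavenge benthos",
    "benth_s": "suspension and deposit feeding benthos",
    "benth_c": "carnivore and scavenge feeding benthos",
    "fish_p": "planktivorous fish", "fish_m": "migratory fish",
    "fish_d": "demersal fish", "bird": "seabirds", "pinn": "pinnipeds",
    "cet": "cetaceans", "bear": "maritime mammals",
}


def _build_names() -> tuple:
    names = list(WATER_POOLS)
    for z in _ZONES_SHORT:
        for f in ICE_FIELDS:
            names.append(f"{f}_{z}")
    for z in _ZONES_SHORT:
        for h in SEDIMENT_CLASSES:
            for f in SED_FIELDS:
                names.append(f"{f}_{z}_{h}")
    names.extend(BIO_POOLS)
    return tuple(names)


class PoolIndex:
    """Canonical pool ordering plus precomputed index arrays."""

    def __init__(self, geometry: DomainGeometry | None = None):
        self.geometry = geometry or DomainGeometry()
        self.names = _build_names()
        self._pos = {n: i for i, n in enumerate(self.names)}
        self.n = len(self.names)

        g = self.geometry
        # ice pools, ordered (inshore, offshore) per field
        for f in ICE_FIELDS:
            setattr(self, f, np.array([self._pos[f + "_in"],
                                       self._pos[f + "_off"]]))
        # sediment pools, ordered inshore rock..coarse then offshore
        for f in SED_FIELDS:
            setattr(self, f, np.array(
                [self._pos[f"{f}_{z}_{h}"]
                 for z in _ZONES_SHORT for h in SEDIMENT_CLASSES]))
        #: zone of each of the 8 habitats (0 inshore, 1 offshore)
        self.habitat_zone = np.array([0] * 4 + [1] * 4)
        #: habitat area as fraction of total domain surface
        self.habitat_area = np.concatenate([
            g.inshore_area_fraction * np.asarray(g.inshore_habitat_fractions),
            g.offshore_area_fraction * np.asarray(g.offshore_habitat_fractions),
        ])

        self.water_surface_no3 = np.array([self._pos["no3_si"],
                                           self._pos["no3_so"]])
        self.water_surface_nh4 = np.array([self._pos["nh4_si"],
                                           self._pos["nh4_so"]])
        self.water_surface_det = np.array([self._pos["det_si"],
                                           self._pos["det_so"]])
        self.water_surface_phyt = np.array([self._pos["phyt_si"],
                                            self._pos["phyt_so"]])
        #: volume (m³ per m² of domain) of the si / so / d layers
        self.layer_volume = np.array([g.v_inshore, g.v_offshore_upper,
                                      g.v_offshore_deep])

    def __getitem__(self, name: str) -> int:
        try:
            return self._pos[name]
        except KeyError as exc:
            raise StructuralError(f"unknown pool {name!r}") from exc

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def zeros(self) -> np.ndarray:
        return np.zeros(self.n)

    def label(self, name: str) -> str:
        """Long label plus zone/layer qualifier for a pool name."""
        for key in sorted(POOL_LABELS, key=len, reverse=True):
            if name == key or name.startswith(key + "_"):
                suffix = name[len(key):].lstrip("_")
                return POOL_LABELS[key] + (f" ({suffix})" if suffix else "")
        return name
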