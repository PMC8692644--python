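"""Domain geometry: two horizontal zones, three water layers, eight seabed habitats.

The domain is a polar shelf sea split into an inshore zone with a single
water layer and an offshore zone with an upper (surface to 60 m, euphotic)
and a lower (disphotic) layer.  The seabed of each zone is divided into four
sediment classes (rock, fine, medium, coarse), giving eight habitats.
All state bookkeeping is per square metre of *total* domain surface, so a
layer's volume is expressed in m³ per m² of domain (i.e. metres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from polarfoodweb.errors import ParameterError

SEDIMENT_CLASSES = ("rock", "fine", "medium", "coarse")
ZONES = ("inshore", "offshore")


@dataclass(frozen=True)
class DomainGeometry:
    """Fixed spatial constants of the model domain.

    Defaults describe a Barents-Sea-scale domain: total surface area
    1.60898e6 km², offshore upper layer 0–60 m.
    """

    total_area_km2: float = 1.60898e6
    inshore_area_fraction: float = 0.25
    inshore_depth_m: float = 50.0
    offshore_upper_depth_m: float = 60.0
    offshore_total_depth_m: float = 200.0
    #: habitat area fractions within each zone, order (rock, fine, medium, coarse)
    inshore_habitat_fractions: tuple = (0.10, 0.30, 0.40, 0.20)
    offshore_habitat_fractions: tuple = (0.05, 0.35, 0.40, 0.20)

    def __post_init__(self):
        if self.total_area_km2 <= 0:
            raise ParameterError("total_area_km2 must be positive")
        if not 0.0 <= self.inshore_area_fraction <= 1.0:
            raise ParameterError("inshore_area_fraction must lie in [0, 1]")
        for d in (self.inshore_depth_m, self.offshore_upper_depth_m,
                  self.offshore_total_depth_m):
            if d <= 0:
                raise ParameterError("depths must be positive")
        if self.offshore_total_depth_m <= self.offshore_upper_depth_m:
            raise ParameterError("offshore total depth must exceed upper-layer depth")
        for fr in (self.inshore_habitat_fractions, self.offshore_habitat_fractions):
            if len(fr) != 4 or any(f < 0 for f in fr):
                raise ParameterError("habitat fractions: four non-negative values")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ParameterError("habitat fractions must sum to 1 within a zone")

    # --- volumes in m³ per m² of total domain surface -------------------
    @property
    def total_area_m2(self) -> float:
        return self.total_area_km2 * 1e6

    @property
    def offshore_area_fraction(self) -> float:
        return 1.0 - self.inshore_area_fraction

    @property
    def v_inshore(self) -> float:
        return self.inshore_area_fraction * self.inshore_depth_m

    @property
    def v_offshore_upper(self) -> float:
        return self.offshore_area_fraction * self.offshore_upper_depth_m

    @property
    def v_offshore_deep(self) -> float:
        return self.offshore_area_fraction * (
            self.offshore_total_depth_m - self.offshore_upper_depth_m
        )

    @property
    def mean_depth_m(self) -> float:
        """Domain-volume per unit domain surface (m)."""
        return self.v_inshore + self.v_offshore_upper + self.v_offshore_deep
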