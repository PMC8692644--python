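"""Scenario comparison, fishing yield curves and MSY reference points.

Unit conventions follow the study region's reporting: model quantities are
areal nitrogen (mMN m⁻² and mMN m⁻² y⁻¹); catches and biomasses convert to
thousands of tonnes live weight through guild nitrogen contents
(2.038 mMN gWW⁻¹ planktivorous, 1.340 mMN gWW⁻¹ demersal) and the domain
surface area; production converts to carbon through Redfield equivalence
(molar C:N = 106:16).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polarfoodweb.errors import DomainError, ParameterError, StructuralError
from polarfoodweb.fleet import FleetConfig, HarvestMultipliers
from polarfoodweb.runner import RunResult, run_scenario

MEGAFAUNA = ("bird", "pinn", "cet", "bear")


@dataclass(frozen=True)
class ConversionConstants:
    plank_n_content: float = 2.038     # mMN per g wet weight
    dem_n_content: float = 1.340
    domain_area_km2: float = 1.60898e6
    redfield_c_to_n: float = 106.0 / 16.0
    carbon_molar_mass: float = 12.0    # g mol⁻¹

    def __post_init__(self):
        if min(self.plank_n_content, self.dem_n_content,
               self.domain_area_km2, self.redfield_c_to_n,
               self.carbon_molar_mass) <= 0:
            raise ParameterError("conversion constants must be positive")

    def n_content(self, guild: str) -> float:
        if guild in ("fish_p", "plank", "planktivorous"):
            return self.plank_n_content
        if guild in ("fish_d", "dem", "demersal"):
            return self.dem_n_content
        raise DomainError(f"no nitrogen content for guild {guild!r}")


def redfield_n_to_c(npp: float,
                    constants: ConversionConstants | None = None) -> float:
    """mMN m⁻² y⁻¹ → gC m⁻² y⁻¹ assuming Redfield equivalence."""
    if npp < 0:
        raise DomainError("production must be non-negative")
    c = constants or ConversionConstants()
    return npp * c.redfield_c_to_n * c.carbon_molar_mass / 1000.0


def areal_n_to_kilotonnes(x: float, n_content: float,
                          area_km2: float = 1.60898e6) -> float:
    """mMN m⁻² (y⁻¹) → 10³ tonnes live weight (y⁻¹)."""
    if n_content <= 0:
        raise ParameterError("nitrogen content must be positive")
    return x * area_km2 * 1e6 / n_content / 1e9


def kilotonnes_to_areal_n(kt: float, n_content: float,
                          area_km2: float = 1.60898e6) -> float:
    """Inverse of :func:`areal_n_to_kilotonnes`."""
    if n_content <= 0:
        raise ParameterError("nitrogen content must be positive")
    return kt * 1e9 * n_content / (area_km2 * 1e6)


def percent_change(baseline: float, scenario: float) -> float:
    """100 × (scenario − baseline) / baseline."""
    if baseline == 0:
        raise DomainError("percent change undefined for zero baseline")
    return 100.0 * (scenario - baseline) / baseline


def scenario_delta_report(baseline: RunResult,
                          future: RunResult) -> pd.DataFrame:
    """Per-pool percent change in annual mean mass, plus an NPP row.

    Pools with a zero annual mean in the baseline report NaN change.
    """
    if tuple(baseline.pool_names) != tuple(future.pool_names):
        raise StructuralError("runs do not share a pool list")
    rows = []
    for i, name in enumerate(baseline.pool_names):
        b = float(baseline.annual_means[i])
        f = float(future.annual_means[i])
        pc = percent_change(b, f) if b != 0 else float("nan")
        rows.append((name, b, f, pc))
    rows.append(("net_primary_production", baseline.npp, future.npp,
                 percent_change(baseline.npp, future.npp)))
    df = pd.DataFrame(rows, columns=["quantity", "baseline", "scenario",
                                     "percent_change"])
    df["direction"] = np.where(df["percent_change"] > 0, "increase",
                               np.where(df["percent_change"] < 0,
                                        "decrease", "no change"))
    return df


# ---------------------------------------------------------------------------
# yield curves
# ---------------------------------------------------------------------------

DEFAULT_MULTIPLIER_GRID = tuple(np.round(np.arange(0.0, 3.51, 0.25), 2))

_GUILD_POOL = {"plank": "fish_p", "dem": "fish_d"}


@dataclass
class YieldCurve:
    """Equilibrium catch and biomass versus fishing-mortality multiplier."""

    guild: str                          # "plank" | "dem"
    multipliers: np.ndarray
    catch: np.ndarray                   # landings, mMN m⁻² y⁻¹
    biomass: np.ndarray                 # annual mean of the varied guild
    megafauna: dict                     # guild -> biomass array
    converged: np.ndarray               # bool per grid point

    def __post_init__(self):
        m = np.asarray(self.multipliers, float)
        if np.any(np.diff(m) <= 0):
            raise ParameterError("multiplier grid must be strictly increasing")
        if 0.0 not in m or 1.0 not in m:
            raise ParameterError("multiplier grid must include 0 and 1")
        self.multipliers = m

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"multiplier": self.multipliers,
                           "catch": self.catch, "biomass": self.biomass,
                           "converged": self.converged})
        for k, v in self.megafauna.items():
            df[f"biomass_{k}"] = v
        return df


@dataclass
class MSYMetrics:
    msy: float                          # mMN m⁻² y⁻¹
    f_msy: float                        # multiplier of the baseline rate
    b_msy: float                        # mMN m⁻²
    f_baseline_over_f_msy: float
    b_over_b_msy: float
    catch_at_baseline: float
    biomass_at_baseline: float
    edge_maximum: bool = False


def yield_curve_scan(forcing, guild: str,
                     multipliers=DEFAULT_MULTIPLIER_GRID,
                     params=None, geometry=None, presence=None,
                     fleet: FleetConfig | None = None,
                     max_years: int = 200, tolerance: float = 1e-4,
                     warm_start: bool = True) -> YieldCurve:
    """Steady-state run per grid point, the other guild's multiplier at 1.

    With ``warm_start`` each point starts from the previous point's final
    state, which shortens spin-up without changing the (initial-condition
    independent) converged cycle.
    """
    if guild not in _GUILD_POOL:
        raise DomainError("guild must be 'plank' or 'dem'")
    pool = _GUILD_POOL[guild]
    mults = np.asarray(multipliers, float)
    catch = np.zeros(mults.size)
    biom = np.zeros(mults.size)
    mega = {g: np.zeros(mults.size) for g in MEGAFAUNA}
    conv = np.zeros(mults.size, bool)
    state = None
    for i, m in enumerate(mults):
        hm = HarvestMultipliers(plank=m if guild == "plank" else 1.0,
                                dem=m if guild == "dem" else 1.0)
        res = run_scenario(forcing, params=params, geometry=geometry,
                           presence=presence, fleet=fleet, multipliers=hm,
                           initial_state=state, max_years=max_years,
                           tolerance=tolerance)
        if warm_start:
            state = res.state_final
        conv[i] = res.converged
        if not res.converged:
            warnings.warn(f"{guild} multiplier {m}: run did not converge; "
                          "point excluded from MSY search", stacklevel=2)
        catch[i] = res.catch.landings.get(pool, 0.0)
        biom[i] = res.annual_mean(pool)
        for g in MEGAFAUNA:
            mega[g][i] = res.annual_mean(g)
    return YieldCurve(guild=guild, multipliers=mults, catch=catch,
                      biomass=biom, megafauna=mega, converged=conv)


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> tuple:
    """Vertex of the parabola through three points (x must be distinct)."""
    c = np.polyfit(x, y, 2)
    if c[0] >= 0:       # not concave; fall back to the grid maximum
        j = int(np.argmax(y))
        return float(x[j]), float(y[j])
    xv = -c[1] / (2.0 * c[0])
    xv = float(np.clip(xv, x.min(), x.max()))
    return xv, float(np.polyval(c, xv))


def msy_metrics(curve: YieldCurve) -> MSYMetrics:
    """MSY reference points from a yield curve.

    The grid maximum is refined by quadratic interpolation through its
    3-point neighbourhood; B_MSY is interpolated at F_MSY; status ratios
    are computed against the multiplier-1 (baseline) grid point.
    """
    ok = np.asarray(curve.converged, bool)
    if ok.sum() < 5:
        raise ParameterError("yield curve needs at least 5 valid points")
    m = curve.multipliers[ok]
    c = np.asarray(curve.catch, float)[ok]
    b = np.asarray(curve.biomass, float)[ok]
    j = int(np.argmax(c))
    edge = j in (0, len(m) - 1)
    if edge:
        warnings.warn("yield-curve maximum at the grid edge: "
                      "dome not resolved", stacklevel=2)
        f_msy, msy = float(m[j]), float(c[j])
    else:
        f_msy, msy = _quadratic_peak(m[j - 1:j + 2], c[j - 1:j + 2])
    b_msy = float(np.interp(f_msy, m, b))
    i1 = int(np.argmin(np.abs(curve.multipliers - 1.0)))
    catch_base = float(curve.catch[i1])
    biom_base = float(curve.biomass[i1])
    return MSYMetrics(
        msy=msy, f_msy=f_msy, b_msy=b_msy,
        f_baseline_over_f_msy=1.0 / f_msy if f_msy > 0 else float("inf"),
        b_over_b_msy=biom_base / b_msy if b_msy > 0 else float("inf"),
        catch_at_baseline=catch_base, biomass_at_baseline=biom_base,
        edge_maximum=edge,
    )
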