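"""Individual-based larval biology for leptocephalus particles.

The larva contributes four things to the transport model: an
ontogenetic specific-gravity schedule (its density relative to seawater
over development, driving Stokes buoyancy), a diel-vertical-migration
clamp that holds settlement-competent larvae in the top 2 m, lethal
temperature bounds (14–32 °C), and onshore-mortality semantics — a
pre-competent particle that contacts a land cell dies, standing in for
habitat-mismatch mortality near shore.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DensitySchedule",
    "StokesParams",
    "BioRules",
    "Fate",
    "density_ratio",
    "stokes_velocity",
    "dvm_clamp",
    "thermal_fate",
    "beaching_fate",
]

SECONDS_PER_DAY = 86_400.0


class Fate:
    """Integer-coded exclusive particle fates (absorbing except ALIVE)."""

    ALIVE = 0
    OUT_OF_DOMAIN = 1
    DEAD_BEACHED = 2
    DEAD_COLD = 3
    DEAD_HOT = 4
    SETTLED = 5

    NAMES = {
        ALIVE: "alive",
        OUT_OF_DOMAIN: "out_of_domain",
        DEAD_BEACHED: "dead_beached",
        DEAD_COLD: "dead_cold",
        DEAD_HOT: "dead_hot",
        SETTLED: "settled",
    }
    CODES = {v: k for k, v in NAMES.items()}


@dataclass(frozen=True)
class BioRules:
    """Biological rule set.

    dvm_top : metres — competent larvae are held at or above this depth.
    competency window — days post spawn in which settlement is possible;
    closed at both ends, and the upper end is the pelagic larval
    duration (simulation end).
    Lethal bounds are strict: a larva survives at exactly 14 or 32 °C.
    """

    dvm_top: float = 2.0
    competency_start: float = 41.0
    competency_end: float = 71.0
    lethal_cold: float = 14.0
    lethal_hot: float = 32.0

    def __post_init__(self) -> None:
        if self.dvm_top <= 0:
            raise ValueError("dvm_top must be positive")
        if not 0 < self.competency_start < self.competency_end:
            raise ValueError("competency window must satisfy 0 < start < end")
        if not self.lethal_cold < self.lethal_hot:
            raise ValueError("lethal_cold must be below lethal_hot")

    @property
    def pld(self) -> float:
        return self.competency_end


@dataclass(frozen=True)
class StokesParams:
    """Inputs to the Stokes settling/rising velocity.

    radius is the equivalent spherical radius of the larva; by default
    half a 2×10⁻⁴ m head diameter.  viscosity is dynamic (Pa·s),
    water_density kg/m³.
    """

    radius: float = 1.0e-4
    viscosity: float = 1.0e-3
    water_density: float = 1024.4
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("radius", "viscosity", "water_density", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class DensitySchedule:
    """Ontogenetic larva:seawater density-ratio table.

    Rows are (age_fraction, density_ratio) with age_fraction = age/PLD
    in [0, 1] strictly increasing, and density_ratio the larval density
    divided by the seawater density at the upper thermocline.  Ratios
    below 1 are positively buoyant.  Lookup is piecewise-linear with
    clamped ends.
    """

    def __init__(self, age_fraction, ratio, provenance: str = ""):
        af = np.asarray(age_fraction, dtype=float)
        r = np.asarray(ratio, dtype=float)
        if af.size == 0:
            raise ValueError("density schedule table is empty")
        if af.size != r.size:
            raise ValueError("age_fraction and ratio must have equal length")
        if np.any(np.diff(af) <= 0):
            raise ValueError("age_fraction must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("density ratios must be finite")
        if np.any((r < 0.9) | (r > 1.1)):
            raise ValueError("density ratios outside the 0.9–1.1 sanity band")
        self.age_fraction = af
        self.ratio = r
        self.provenance = provenance

    @classmethod
    def from_csv(cls, path) -> "DensitySchedule":
        df = pd.read_csv(path, comment="#")
        required = {"age_fraction", "density_ratio"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"density schedule {path} must have columns {sorted(required)}"
            )
        return cls(df["age_fraction"].values, df["density_ratio"].values,
                   provenance=str(path))

    @classmethod
    def default(cls) -> "DensitySchedule":
        """The packaged synthetic ontogenetic schedule."""
        ref = resources.files("leptoflow.data") / "density_schedule_synthetic.csv"
        with resources.as_file(ref) as p:
            return cls.from_csv(p)


def density_ratio(schedule: DensitySchedule, age_days, pld_days: float) -> np.ndarray:
    """Larva:seawater density ratio at the given age.

    Piecewise-linear interpolation of the schedule at age/PLD, clamped
    at both table ends (ages beyond the PLD keep the final ratio).
    """
    frac = np.asarray(age_days, dtype=float) / float(pld_days)
    return np.interp(frac, schedule.age_fraction, schedule.ratio)


def stokes_velocity(ratio, params: StokesParams = StokesParams()) -> np.ndarray:
    """Stokes buoyancy velocity in m/day, positive upward.

    w = (2/9) g r² (ρ_w − ρ_l) / μ with ρ_l = ratio × ρ_w.  A neutrally
    buoyant larva (ratio 1) gets 0; ratios above 1 sink (negative).
    """
    ratio = np.asarray(ratio, dtype=float)
    delta_rho = params.water_density * (1.0 - ratio)
    w_ms = (2.0 / 9.0) * params.g * params.radius**2 * delta_rho / params.viscosity
    return w_ms * SECONDS_PER_DAY


def dvm_clamp(depth, age_days, rules: BioRules = BioRules()) -> np.ndarray:
    """Hold competent larvae in the surface layer.

    During the (closed) competency window the larva's depth is capped at
    ``rules.dvm_top`` regardless of proximity to settlement habitat;
    outside the window depth is unchanged.
    """
    depth = np.asarray(depth, dtype=float)
    age = np.asarray(age_days, dtype=float)
    active = (age >= rules.competency_start) & (age <= rules.competency_end)
    return np.where(active, np.minimum(depth, rules.dvm_top), depth)


def thermal_fate(temp, rules: BioRules = BioRules()) -> np.ndarray:
    """Lethal-temperature fate: strict bounds at 14 and 32 °C."""
    temp = np.asarray(temp, dtype=float)
    fate = np.full(temp.shape, Fate.ALIVE, dtype=np.int16)
    fate[temp < rules.lethal_cold] = Fate.DEAD_COLD
    fate[temp > rules.lethal_hot] = Fate.DEAD_HOT
    return fate


def beaching_fate(on_land, age_days, rules: BioRules = BioRules(),
                  in_zone=None) -> np.ndarray:
    """Onshore-mortality fate for particles in land cells.

    Pre-competent larvae die on any land contact.  Competent larvae on
    land outside a settlement zone also die; those inside a zone are
    left alive for the settlement check.  ``in_zone`` defaults to
    nowhere-in-zone.
    """
    on_land = np.asarray(on_land, dtype=bool)
    age = np.asarray(age_days, dtype=float)
    if in_zone is None:
        in_zone = np.zeros(on_land.shape, dtype=bool)
    competent = age >= rules.competency_start
    dead = on_land & (~competent | ~np.asarray(in_zone, dtype=bool))
    fate = np.full(on_land.shape, Fate.ALIVE, dtype=np.int16)
    fate[dead] = Fate.DEAD_BEACHED
    return fate
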