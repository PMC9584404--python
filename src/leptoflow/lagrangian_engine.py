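"""Lagrangian transport engine for larval particles.

Particles are advected through the gridded ocean state with a
CFL-checked Forward Euler scheme and a stochastic 3-D random walk:
horizontal displacements are uniform-δ steps scaled to the explicit
Lagrangian diffusivity K_h (Okubo's empirical power law of the grid
length), vertical displacements scale with the local vertical
diffusivity and reflect at the surface and bottom.  Biology (buoyancy,
DVM clamp, lethal temperatures, onshore mortality) and settlement are
applied in a fixed, documented order each step, and positions plus
sampled temperature/salinity are recorded on a fixed cadence (3 h by
default) across independent replicate iterations.

Step order: advection → horizontal dispersion → vertical dispersion →
buoyancy → DVM clamp → sample T/S → thermal fate → onshore mortality →
out-of-domain check → settlement check.  All fates are absorbing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .larval_ibm import (
    SECONDS_PER_DAY,
    BioRules,
    DensitySchedule,
    Fate,
    StokesParams,
    beaching_fate,
    density_ratio,
    dvm_clamp,
    stokes_velocity,
    thermal_fate,
)
from .settlement import SettlementRecord, SettlementZone, settle_check, zone_index
from .spawn_release import ReleaseSpec
from .synthetic_ocean import M_PER_DEG_LAT, FIELD_VARS, OceanField

__all__ = [
    "EngineConfig",
    "LarvaEnsemble",
    "FieldSampler",
    "SimulationResult",
    "cfl_max_dt",
    "okubo_kh",
    "advect_euler",
    "horizontal_dispersion_step",
    "vertical_dispersion_step",
    "reflect_depth",
    "step",
    "run_simulation",
]


def cfl_max_dt(dgrid_m: float, umax_ms: float) -> float:
    """Fine-scale CFL timestep bound, dt_max = 0.7 · dGrid / Umax."""
    if dgrid_m <= 0 or umax_ms <= 0:
        raise ValueError("dgrid and umax must be positive")
    return 0.7 * dgrid_m / umax_ms


def okubo_kh(length_scale_m: float) -> float:
    """Okubo's empirical horizontal diffusivity for a length scale.

    K_h = 0.0103 · l^1.15 in cgs units (l in cm, K_h in cm²/s),
    returned in m²/s.  For a 3.1 km grid this gives ≈ 2.13 m²/s.
    """
    if length_scale_m <= 0:
        raise ValueError("length scale must be positive")
    l_cm = length_scale_m * 100.0
    kh_cgs = 0.0103 * l_cm**1.15
    return kh_cgs * 1e-4


@dataclass(frozen=True)
class EngineConfig:
    """Numerical configuration of the transport engine.

    dt must respect the CFL bound 0.7·dgrid/umax and divide the record
    interval.  ``kh`` defaults to the Okubo diffusivity of the grid
    length.  ``buoyancy`` switches the Stokes term between an explicit
    per-step velocity ('velocity') and off.
    """

    dt: float = 10_800.0  # s (3 h)
    dgrid: float = 3_100.0  # m
    umax: float = 0.2  # m/s, order of fastest currents
    kh: float | None = None  # m²/s; None → okubo_kh(dgrid)
    n_iterations: int = 100
    seed: int = 0
    record_interval: float = 10_800.0  # s
    duration_days: float = 71.0
    buoyancy: str = "velocity"  # 'velocity' | 'off'

    def __post_init__(self) -> None:
        bound = cfl_max_dt(self.dgrid, self.umax)
        if self.dt > bound + 1e-9:
            raise ValueError(
                f"dt={self.dt:.0f} s violates the CFL bound "
                f"0.7*dgrid/umax = {bound:.0f} s"
            )
        if self.record_interval % self.dt != 0:
            raise ValueError("dt must divide record_interval")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if self.buoyancy not in ("velocity", "off"):
            raise ValueError("buoyancy must be 'velocity' or 'off'")

    @property
    def kh_eff(self) -> float:
        return okubo_kh(self.dgrid) if self.kh is None else self.kh

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * SECONDS_PER_DAY / self.dt))

    @property
    def record_every(self) -> int:
        return int(round(self.record_interval / self.dt))

    @property
    def n_records(self) -> int:
        """Records per larva including the release instant (71 d at 3 h → 569)."""
        return self.n_steps // self.record_every + 1


@dataclass
class LarvaEnsemble:
    """State arrays for one iteration's particles (vectorized LarvaState)."""

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    age_days: np.ndarray
    fate: np.ndarray  # int16, Fate codes
    temp: np.ndarray
    salt: np.ndarray
    zone: np.ndarray  # settled zone index, −1 if not settled

    @classmethod
    def from_release(cls, release: ReleaseSpec) -> "LarvaEnsemble":
        n = release.n
        return cls(
            lon=release.lon.astype(float).copy(),
            lat=release.lat.astype(float).copy(),
            depth=release.depth.astype(float).copy(),
            age_days=np.zeros(n),
            fate=np.full(n, Fate.ALIVE, dtype=np.int16),
            temp=np.full(n, np.nan),
            salt=np.full(n, np.nan),
            zone=np.full(n, -1, dtype=np.int64),
        )

    @property
    def alive(self) -> np.ndarray:
        return self.fate == Fate.ALIVE


class FieldSampler:
    """Linear-in-time, tri-linear-in-space sampler of an OceanField.

    Land NaNs are filled (velocities/diffusivity with 0, tracers with
    the wet mean of their time/depth slice) so interpolation next to the
    coast stays finite; the landmask itself drives beaching.
    """

    def __init__(self, field: OceanField):
        self.field = field
        self.t0, self.t1 = float(field.time[0]), float(field.time[-1])
        self.bottom = float(field.depth[-1])
        axes = (field.time, field.depth, field.lat, field.lon)
        self._itp: dict[str, RegularGridInterpolator] = {}
        for var in FIELD_VARS:
            arr = np.asarray(field.ds[var].values, dtype=float)
            if np.isnan(arr).any():
                arr = arr.copy()
                if var in ("u", "v", "w", "kz"):
                    arr[np.isnan(arr)] = 0.0
                else:
                    wet_mean = np.nanmean(arr, axis=(2, 3), keepdims=True)
                    wet_mean = np.nan_to_num(wet_mean, nan=0.0)
                    mask = np.isnan(arr)
                    arr[mask] = np.broadcast_to(wet_mean, arr.shape)[mask]
            self._itp[var] = RegularGridInterpolator(
                axes, arr, method="linear", bounds_error=False, fill_value=None
            )

    def sample(self, var: str, t, lon, lat, depth) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0 - 1e-6) or np.any(t > self.t1 + 1e-6):
            raise ValueError(
                f"sample time outside field time span [{self.t0}, {self.t1}] s"
            )
        depth = np.clip(np.asarray(depth, dtype=float), 0.0, self.bottom)
        pts = np.column_stack([
            np.broadcast_to(t, np.shape(lon)).ravel(),
            depth.ravel(),
            np.asarray(lat, dtype=float).ravel(),
            np.asarray(lon, dtype=float).ravel(),
        ])
        return self._itp[var](pts).reshape(np.shape(lon))


def advect_euler(lon, lat, depth, t, sampler: FieldSampler, dt: float):
    """One Forward Euler advection step.

    Displacement is the locally interpolated (u, v, w) times dt, with
    metres→degrees conversion at the particle latitude (spherical
    scaling, 111 320 m/deg latitude and ×cos(lat) for longitude).
    """
    u = sampler.sample("u", t, lon, lat, depth)
    v = sampler.sample("v", t, lon, lat, depth)
    w = sampler.sample("w", t, lon, lat, depth)
    new_lon = lon + u * dt / (M_PER_DEG_LAT * np.cos(np.deg2rad(lat)))
    new_lat = lat + v * dt / M_PER_DEG_LAT
    new_depth = depth + w * dt  # w positive down
    return new_lon, new_lat, new_depth


def horizontal_dispersion_step(kh: float, dt: float, rng: np.random.Generator,
                               n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-δ horizontal random-walk displacement in metres.

    Each component is δ·A with δ ~ U[−1, 1] independently per axis and
    A = √(6·K_h·dt), so the per-component variance is A²/3 = 2·K_h·dt
    and the mean squared planar displacement is 4·K_h·dt.
    """
    if kh < 0:
        raise ValueError("kh must be non-negative")
    amp = np.sqrt(6.0 * kh * dt)
    return (amp * rng.uniform(-1.0, 1.0, size=n),
            amp * rng.uniform(-1.0, 1.0, size=n))


def reflect_depth(depth: np.ndarray, bottom: float) -> np.ndarray:
    """Fold a proposed depth into [0, bottom] by mirror reflection."""
    if bottom <= 0:
        raise ValueError("bottom must be positive")
    d = np.mod(np.asarray(depth, dtype=float), 2.0 * bottom)
    return np.where(d > bottom, 2.0 * bottom - d, d)


def vertical_dispersion_step(depth, kz, dt: float, rng: np.random.Generator,
                             bottom: float) -> np.ndarray:
    """Vertical random-walk increment scaled by the local diffusivity.

    Same uniform-δ construction as the horizontal step (amplitude
    √(6·kz·dt) per particle) with reflecting boundaries at the surface
    and the bottom — the combination that satisfies the well-mixed
    condition for constant kz.
    """
    depth = np.asarray(depth, dtype=float)
    kz = np.maximum(np.asarray(kz, dtype=float), 0.0)
    amp = np.sqrt(6.0 * kz * dt)
    proposed = depth + amp * rng.uniform(-1.0, 1.0, size=depth.shape)
    return reflect_depth(proposed, bottom)


def step(ens: LarvaEnsemble, sampler: FieldSampler, t: float,
         rules: BioRules, config: EngineConfig, rng: np.random.Generator,
         zones: Sequence[SettlementZone] = (),
         schedule: DensitySchedule | None = None,
         stokes: StokesParams = StokesParams()) -> LarvaEnsemble:
    """Advance alive larvae by one timestep (in place) and return the ensemble.

    Applies the documented update order and assigns at most one
    (absorbing) fate transition per larva per step.
    """
    alive = ens.alive
    if not alive.any():
        return ens
    idx = np.flatnonzero(alive)
    lon, lat, depth = ens.lon[idx], ens.lat[idx], ens.depth[idx]
    age = ens.age_days[idx]
    dt = config.dt

    # 1. advection
    lon, lat, depth = advect_euler(lon, lat, depth, t, sampler, dt)
    # 2. horizontal dispersion
    dx, dy = horizontal_dispersion_step(config.kh_eff, dt, rng, idx.size)
    lon = lon + dx / (M_PER_DEG_LAT * np.cos(np.deg2rad(lat)))
    lat = lat + dy / M_PER_DEG_LAT
    # 3. vertical dispersion (reflecting)
    kz = sampler.sample("kz", t, lon, lat, depth)
    depth = vertical_dispersion_step(depth, kz, dt, rng, sampler.bottom)
    # 4. buoyancy (explicit Stokes velocity, off while the DVM clamp holds)
    new_age = age + dt / SECONDS_PER_DAY
    if config.buoyancy == "velocity" and schedule is not None:
        ratio = density_ratio(schedule, new_age, rules.pld)
        w_up = stokes_velocity(ratio, stokes)  # m/day, positive up
        dvm_active = (new_age >= rules.competency_start) & (new_age <= rules.competency_end)
        depth = depth - np.where(dvm_active, 0.0, w_up) * dt / SECONDS_PER_DAY
        depth = reflect_depth(depth, sampler.bottom)
    # 5. DVM clamp
    depth = dvm_clamp(depth, new_age, rules)
    # 6. sample temperature / salinity at the updated position
    t_new = t + dt
    in_dom = sampler.field.in_domain(lon, lat)
    temp = np.where(in_dom, sampler.sample("temp", t_new, lon, lat, depth), np.nan)
    salt = np.where(in_dom, sampler.sample("salt", t_new, lon, lat, depth), np.nan)

    ens.lon[idx], ens.lat[idx], ens.depth[idx] = lon, lat, depth
    ens.age_days[idx] = new_age
    ens.temp[idx] = np.where(np.isnan(temp), ens.temp[idx], temp)
    ens.salt[idx] = np.where(np.isnan(salt), ens.salt[idx], salt)

    # 7. fates, in precedence order; each larva gets at most one transition
    fate = np.full(idx.size, Fate.ALIVE, dtype=np.int16)
    tf = thermal_fate(np.where(np.isnan(temp), 20.0, temp), rules)
    fate = np.where((fate == Fate.ALIVE) & in_dom, tf, fate)
    on_land = sampler.field.is_land(lon, lat) & in_dom
    if on_land.any():
        in_zone = np.zeros(idx.size, dtype=bool)
        if zones:
            land_i = np.flatnonzero(on_land)
            in_zone[land_i] = zone_index(lon[land_i], lat[land_i], zones) >= 0
        bf = beaching_fate(on_land, new_age, rules, in_zone)
        fate = np.where(fate == Fate.ALIVE, bf, fate)
    fate = np.where((fate == Fate.ALIVE) & ~in_dom, Fate.OUT_OF_DOMAIN, fate)
    ens.fate[idx] = fate

    # 8. settlement check on the post-step position
    if zones:
        new_fate, zidx = settle_check(ens.lon, ens.lat, ens.age_days, ens.fate,
                                      zones, rules)
        ens.zone = np.where(new_fate == Fate.SETTLED, zidx, ens.zone)
        ens.fate = new_fate
    return ens


@dataclass
class SimulationResult:
    """Recorded trajectories and settlement records of all iterations.

    Trajectory arrays have shape (iteration, particle, record); records
    are at the engine's fixed cadence and frozen after an absorbing
    fate.
    """

    config: EngineConfig
    rules: BioRules
    release: ReleaseSpec
    zone_islands: list[str]
    time: np.ndarray  # (record,) seconds since origin
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    temp: np.ndarray
    salt: np.ndarray
    fate: np.ndarray  # int16
    settlements: list[SettlementRecord] = dc_field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return self.lon.shape[0]

    @property
    def n_particles(self) -> int:
        return self.lon.shape[1]

    @property
    def n_records(self) -> int:
        return self.lon.shape[2]

    def settlement_table(self) -> pd.DataFrame:
        cols = ["larva_id", "iteration", "island", "time", "dps", "lon", "lat"]
        if not self.settlements:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([dataclasses.asdict(s) for s in self.settlements])[cols]

    def to_netcdf(self, path) -> None:
        legend = ", ".join(f"{k}={v}" for k, v in sorted(Fate.NAMES.items()))
        ds = xr.Dataset(
            {
                "lon": (("iteration", "particle", "record"), self.lon.astype(np.float32)),
                "lat": (("iteration", "particle", "record"), self.lat.astype(np.float32)),
                "depth": (("iteration", "particle", "record"), self.depth.astype(np.float32)),
                "temp": (("iteration", "particle", "record"), self.temp.astype(np.float32)),
                "salt": (("iteration", "particle", "record"), self.salt.astype(np.float32)),
                "fate": (("iteration", "particle", "record"), self.fate.astype(np.int16),
                         {"legend": legend}),
            },
            coords={"record_time": ("record", self.time,
                                    {"units": "s",
                                     "long_name": "seconds since simulation origin"})},
            attrs={"dt": self.config.dt, "seed": self.config.seed,
                   "duration_days": self.config.duration_days},
        )
        ds.to_netcdf(path, engine="scipy")


def iteration_rng(master_seed: int, iteration: int) -> np.random.Generator:
    """Per-iteration generator, a pure function of (master seed, index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration,))
    )


def run_simulation(release: ReleaseSpec, field: OceanField, rules: BioRules,
                   zones: Sequence[SettlementZone], config: EngineConfig,
                   schedule: DensitySchedule | None = None,
                   stokes: StokesParams = StokesParams()) -> SimulationResult:
    """Run ``config.n_iterations`` independent replicate simulations.

    Every iteration releases the same particle stain and draws its
    dispersion noise from a generator derived purely from
    (config.seed, iteration index), so outputs are reproducible and
    iteration-order independent.
    """
    t_release = release.event.release_time if release.event else 0.0
    t_end = t_release + config.duration_days * SECONDS_PER_DAY
    if t_end > field.time[-1] + 1e-6:
        raise ValueError(
            f"field time span ends at {field.time[-1]:.0f} s but the run "
            f"needs {t_end:.0f} s"
        )
    sampler = FieldSampler(field)
    n = release.n
    n_rec = config.n_records
    shape = (config.n_iterations, n, n_rec)
    rec_time = t_release + np.arange(n_rec) * config.record_interval

    out = {k: np.zeros(shape, dtype=np.float32)
           for k in ("lon", "lat", "depth", "temp", "salt")}
    fates = np.zeros(shape, dtype=np.int16)
    settlements: list[SettlementRecord] = []

    for it in range(config.n_iterations):
        rng = iteration_rng(config.seed, it)
        ens = LarvaEnsemble.from_release(release)
        # initial sampled environment
        ens.temp[:] = sampler.sample("temp", t_release, ens.lon, ens.lat, ens.depth)
        ens.salt[:] = sampler.sample("salt", t_release, ens.lon, ens.lat, ens.depth)
        _record(out, fates, ens, it, 0)
        rec_i = 1
        settled_seen = np.zeros(n, dtype=bool)
        for k in range(config.n_steps):
            t = t_release + k * config.dt
            step(ens, sampler, t, rules, config, rng, zones, schedule, stokes)
            newly = (ens.fate == Fate.SETTLED) & ~settled_seen
            if newly.any():
                for pid in np.flatnonzero(newly):
                    zi = int(ens.zone[pid])
                    settlements.append(SettlementRecord(
                        larva_id=int(pid), iteration=it,
                        island=zones[zi].island,
                        time=float(t + config.dt),
                        dps=float(ens.age_days[pid]),
                        lon=float(ens.lon[pid]), lat=float(ens.lat[pid]),
                    ))
                settled_seen |= newly
            if (k + 1) % config.record_every == 0:
                _record(out, fates, ens, it, rec_i)
                rec_i += 1

    return SimulationResult(
        config=config, rules=rules, release=release,
        zone_islands=[z.island for z in zones],
        time=rec_time,
        lon=out["lon"], lat=out["lat"], depth=out["depth"],
        temp=out["temp"], salt=out["salt"], fate=fates,
        settlements=settlements,
    )


def _record(out: dict, fates: np.ndarray, ens: LarvaEnsemble,
            it: int, rec: int) -> None:
    out["lon"][it, :, rec] = ens.lon
    out["lat"][it, :, rec] = ens.lat
    out["depth"][it, :, rec] = ens.depth
    out["temp"][it, :, rec] = ens.temp
    out["salt"][it, :, rec] = ens.salt
    fates[it, :, rec] = ens.fate
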