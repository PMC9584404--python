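"""Analytic 4-D ocean fields for larval-dispersal experiments.

Real larval dispersal models are forced by archived hydrodynamic model
output (velocities, hydrography, diffusivity on a lon/lat/depth/time
grid).  This module builds fields with the same structure from analytic
components — uniform background currents, solid-body or Rankine gyres,
a two-layer stratification with a controllable thermocline, simple
coastlines and vertical-diffusivity profiles — so that transport,
retention, mortality and settlement behaviour can be exercised and
tested against closed forms.

Conventions
-----------
depth is metres, positive down, with ``depth_axis[0] == 0`` at the
surface; vertical velocity ``w`` is positive down; time is seconds from
a configurable origin.  Land cells carry NaN velocities and a true
``landmask``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import xarray as xr

__all__ = [
    "OceanField",
    "FieldScenario",
    "GridSpec",
    "UniformCurrent",
    "Gyre",
    "TwoLayerTemperature",
    "HalfPlaneCoast",
    "CircularIsland",
    "KzProfile",
    "ThermoclineError",
    "render_field",
    "thermocline_depth",
    "gradient_max_below",
    "write_field",
    "read_field",
]

M_PER_DEG_LAT = 111_320.0  # spherical metre/degree scaling

FIELD_VARS = ("u", "v", "w", "temp", "salt", "kz")


class ThermoclineError(ValueError):
    """Raised when a temperature profile has no distinct thermocline."""


# ---------------------------------------------------------------------------
# scenario components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformCurrent:
    """Spatially uniform horizontal current.

    ``bearing_deg`` is the compass direction the current flows toward
    (0 = north, 90 = east).
    """

    speed: float  # m/s
    bearing_deg: float = 90.0

    @property
    def uv(self) -> tuple[float, float]:
        theta = np.deg2rad(self.bearing_deg)
        return self.speed * np.sin(theta), self.speed * np.cos(theta)


@dataclass(frozen=True)
class Gyre:
    """Axisymmetric gyre: rigid rotation inside ``radius_m``.

    ``kind='solid_body'`` has zero flow outside the core; ``'rankine'``
    decays as 1/r outside (a Rankine vortex).  ``sense=+1`` is
    counter-clockwise (cyclonic in the northern hemisphere).  Velocities
    are defined on a local tangent plane anchored at the gyre centre so
    that the rendered field is exactly divergence-free in those metric
    coordinates.
    """

    lon: float
    lat: float
    radius_m: float
    peak_speed: float  # tangential speed at radius_m, m/s
    sense: int = 1
    kind: str = "rankine"

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError(f"gyre radius must be positive, got {self.radius_m}")
        if self.kind not in ("rankine", "solid_body"):
            raise ValueError(f"unknown gyre kind {self.kind!r}")

    def velocity(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) in m/s at the given lon/lat points."""
        coslat0 = np.cos(np.deg2rad(self.lat))
        x = (np.asarray(lon) - self.lon) * M_PER_DEG_LAT * coslat0
        y = (np.asarray(lat) - self.lat) * M_PER_DEG_LAT
        r = np.hypot(x, y)
        omega = self.peak_speed / self.radius_m
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.kind == "solid_body":
                vt = np.where(r <= self.radius_m, omega * r, 0.0)
            else:
                vt = np.where(
                    r <= self.radius_m,
                    omega * r,
                    self.peak_speed * self.radius_m / np.maximum(r, 1e-12),
                )
            # tangential unit vector (-y, x)/r; at the centre velocity is 0
            u = np.where(r > 0, -self.sense * vt * y / np.maximum(r, 1e-12), 0.0)
            v = np.where(r > 0, self.sense * vt * x / np.maximum(r, 1e-12), 0.0)
        return u, v


@dataclass(frozen=True)
class TwoLayerTemperature:
    """Two-layer stratification with a tanh transition.

    T(z) = deep + (surface - deep) * (1 - tanh((z - z_c)/h)) / 2,
    so the maximum |dT/dz| sits at the nominal thermocline ``z_c``.
    """

    surface_temp: float = 26.0  # °C
    deep_temp: float = 20.0
    thermocline_m: float = 50.0
    thickness_m: float = 10.0

    def at(self, depth: np.ndarray) -> np.ndarray:
        z = np.asarray(depth, dtype=float)
        s = (1.0 - np.tanh((z - self.thermocline_m) / self.thickness_m)) / 2.0
        return self.deep_temp + (self.surface_temp - self.deep_temp) * s


@dataclass(frozen=True)
class HalfPlaneCoast:
    """Land occupying one side of a meridian or parallel.

    ``axis='lon'`` with ``side='greater'`` makes every cell east of
    ``position`` land (a straight north-south coastline).
    """

    axis: str  # 'lon' or 'lat'
    position: float  # degrees
    side: str = "greater"  # which side is land

    def mask(self, lon2d: np.ndarray, lat2d: np.ndarray) -> np.ndarray:
        coord = lon2d if self.axis == "lon" else lat2d
        return coord > self.position if self.side == "greater" else coord < self.position


@dataclass(frozen=True)
class CircularIsland:
    lon: float
    lat: float
    radius_m: float

    def mask(self, lon2d: np.ndarray, lat2d: np.ndarray) -> np.ndarray:
        coslat0 = np.cos(np.deg2rad(self.lat))
        x = (lon2d - self.lon) * M_PER_DEG_LAT * coslat0
        y = (lat2d - self.lat) * M_PER_DEG_LAT
        return np.hypot(x, y) <= self.radius_m


@dataclass(frozen=True)
class KzProfile:
    """Vertical diffusivity: constant, or decaying with depth.

    ``kz(z) = background + (surface - background) * exp(-z / efold_m)``.
    With ``surface == background`` this is a constant profile.
    """

    surface: float = 1e-3  # m²/s
    background: float = 1e-3
    efold_m: float = 50.0

    def at(self, depth: np.ndarray) -> np.ndarray:
        z = np.asarray(depth, dtype=float)
        return self.background + (self.surface - self.background) * np.exp(-z / self.efold_m)


@dataclass(frozen=True)
class FieldScenario:
    """Composable description of an analytic ocean state.

    All velocity components superpose; coast components union into the
    landmask.  Rendering is deterministic (no RNG).
    """

    currents: Sequence[UniformCurrent] = ()
    gyres: Sequence[Gyre] = ()
    temperature: TwoLayerTemperature = field(default_factory=TwoLayerTemperature)
    salinity: float = 36.0  # PSU, uniform
    coasts: Sequence[HalfPlaneCoast | CircularIsland] = ()
    kz: KzProfile = field(default_factory=KzProfile)
    w: float = 0.0  # uniform vertical velocity, m/s positive down


@dataclass(frozen=True)
class GridSpec:
    lon: tuple[float, float, int]  # (min, max, n)
    lat: tuple[float, float, int]
    depth: tuple[float, int]  # (max_depth, n); surface level is always 0
    time: tuple[float, int]  # (span_seconds, n); origin is 0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        lon = np.linspace(*self.lon)
        lat = np.linspace(*self.lat)
        depth = np.linspace(0.0, self.depth[0], self.depth[1])
        time = np.linspace(0.0, self.time[0], self.time[1])
        for name, ax in (("lon", lon), ("lat", lat), ("depth", depth), ("time", time)):
            if ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly monotone with ≥2 levels")
        return lon, lat, depth, time


# ---------------------------------------------------------------------------
# OceanField container
# ---------------------------------------------------------------------------

class OceanField:
    """Gridded 4-D hydrography the particles sample.

    Thin wrapper over an :class:`xarray.Dataset` with dims
    ``(time, depth, lat, lon)`` and variables u, v, w (m/s), temp (°C),
    salt (PSU), kz (m²/s) plus a 2-D boolean ``landmask``.
    """

    def __init__(self, ds: xr.Dataset):
        missing = [v for v in (*FIELD_VARS, "landmask") if v not in ds]
        if missing:
            raise ValueError(f"ocean field dataset missing variables: {missing}")
        for ax in ("lon", "lat", "depth", "time"):
            vals = ds[ax].values
            if vals.size < 1 or np.any(np.diff(vals) <= 0):
                raise ValueError(f"axis {ax!r} must be strictly monotone increasing")
        if ds["depth"].values[0] != 0.0:
            raise ValueError("depth axis must start at the surface (0 m)")
        self.ds = ds

    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def depth(self) -> np.ndarray:
        return self.ds["depth"].values

    @property
    def time(self) -> np.ndarray:
        return self.ds["time"].values

    @property
    def landmask(self) -> np.ndarray:
        return self.ds["landmask"].values.astype(bool)

    def is_land(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Landmask of the containing cell (nearest grid node)."""
        i = _nearest_index(self.lat, np.asarray(lat))
        j = _nearest_index(self.lon, np.asarray(lon))
        return self.landmask[i, j]

    def profile(self, var: str = "temp", lon: float | None = None,
                lat: float | None = None, t: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(depth, values) column at the given horizontal point and time."""
        da = self.ds[var]
        sel: dict = {"time": t}
        sel["lon"] = self.lon[self.lon.size // 2] if lon is None else lon
        sel["lat"] = self.lat[self.lat.size // 2] if lat is None else lat
        col = da.sel(sel, method="nearest")
        return self.depth, np.asarray(col.values, dtype=float)

    def in_domain(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )


def _nearest_index(axis: np.ndarray, x: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(axis, x)
    idx = np.clip(idx, 1, axis.size - 1)
    left = axis[idx - 1]
    right = axis[idx]
    idx = np.where(np.abs(x - left) <= np.abs(right - x), idx - 1, idx)
    return np.clip(idx, 0, axis.size - 1)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_field(scenario: FieldScenario, grid: GridSpec) -> OceanField:
    """Render an analytic scenario onto a regular grid.

    Deterministic: the same scenario and grid always produce the same
    field.  Land cells get NaN velocities and tracers.
    """
    lon, lat, depth, time = grid.axes()
    lon2d, lat2d = np.meshgrid(lon, lat)  # (lat, lon)

    u2 = np.zeros_like(lon2d, dtype=float)
    v2 = np.zeros_like(lon2d, dtype=float)
    for cur in scenario.currents:
        cu, cv = cur.uv
        u2 += cu
        v2 += cv
    for gyre in scenario.gyres:
        gu, gv = gyre.velocity(lon2d, lat2d)
        u2 += gu
        v2 += gv

    land = np.zeros_like(lon2d, dtype=bool)
    for coast in scenario.coasts:
        land |= coast.mask(lon2d, lat2d)

    shape = (time.size, depth.size, lat.size, lon.size)
    u = np.broadcast_to(u2, shape).copy()
    v = np.broadcast_to(v2, shape).copy()
    w = np.full(shape, float(scenario.w))
    temp = np.broadcast_to(
        scenario.temperature.at(depth)[None, :, None, None], shape
    ).copy()
    salt = np.full(shape, float(scenario.salinity))
    kz = np.broadcast_to(scenario.kz.at(depth)[None, :, None, None], shape).copy()

    land4 = np.broadcast_to(land[None, None, :, :], shape)
    for arr in (u, v, w, temp, salt, kz):
        arr[land4] = np.nan

    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), u,
                  {"units": "m s-1", "long_name": "eastward velocity"}),
            "v": (("time", "depth", "lat", "lon"), v,
                  {"units": "m s-1", "long_name": "northward velocity"}),
            "w": (("time", "depth", "lat", "lon"), w,
                  {"units": "m s-1", "long_name": "vertical velocity",
                   "positive": "down"}),
            "temp": (("time", "depth", "lat", "lon"), temp,
                     {"units": "degC", "long_name": "potential temperature"}),
            "salt": (("time", "depth", "lat", "lon"), salt,
                     {"units": "1e-3", "long_name": "salinity"}),
            "kz": (("time", "depth", "lat", "lon"), kz,
                   {"units": "m2 s-1", "long_name": "vertical diffusivity"}),
            "landmask": (("lat", "lon"), land.astype(np.int8),
                         {"long_name": "land mask", "flag_values": "0 1",
                          "flag_meanings": "water land"}),
        },
        coords={
            "lon": ("lon", lon, {"units": "degrees_east", "axis": "X"}),
            "lat": ("lat", lat, {"units": "degrees_north", "axis": "Y"}),
            "depth": ("depth", depth,
                      {"units": "m", "positive": "down", "axis": "Z"}),
            "time": ("time", time,
                     {"units": "s", "axis": "T",
                      "long_name": "seconds since simulation origin"}),
        },
        attrs={"Conventions": "CF-1.8", "source": "leptoflow analytic scenario"},
    )
    return OceanField(ds)


# ---------------------------------------------------------------------------
# thermocline diagnostics
# ---------------------------------------------------------------------------

def _temperature_gradient(depth: np.ndarray, temp: np.ndarray) -> np.ndarray:
    """Centred finite-difference dT/dz on the native levels."""
    return np.gradient(np.asarray(temp, float), np.asarray(depth, float))


def thermocline_depth(depth: np.ndarray, temp: np.ndarray,
                      rel_tol: float = 0.05) -> float:
    """Depth of maximum |dT/dz|, with sub-level parabolic refinement.

    The thermocline estimator: centred finite differences on the native
    levels locate the level of strongest stratification; a parabola
    through that level and its neighbours refines the estimate to within
    the level spacing.  Ties break toward the shallower depth.

    Raises
    ------
    ThermoclineError
        for isothermal or constant-gradient (linear) profiles, where no
        distinct gradient maximum exists.  ``rel_tol`` sets how much the
        gradient must vary, relative to its maximum magnitude, before a
        profile counts as distinct.
    """
    depth = np.asarray(depth, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if depth.size < 3:
        raise ValueError("need at least 3 depth levels")
    if not np.all(np.isfinite(temp)):
        raise ValueError("temperature profile contains non-finite values")
    g = np.abs(_temperature_gradient(depth, temp))
    gmax = g.max()
    if gmax <= 0:
        raise ThermoclineError("isothermal profile: no temperature gradient")
    if (gmax - g.min()) < rel_tol * gmax:
        raise ThermoclineError(
            "no distinct thermocline: gradient magnitude nearly constant with depth"
        )
    k = int(np.argmax(g))  # argmax takes the first (shallowest) on ties
    if 0 < k < depth.size - 1:
        # parabolic vertex through (z_{k-1},g_{k-1}), (z_k,g_k), (z_{k+1},g_{k+1})
        z0, z1, z2 = depth[k - 1], depth[k], depth[k + 1]
        g0, g1, g2 = g[k - 1], g[k], g[k + 1]
        denom = (z0 - z1) * (z0 - z2) * (z1 - z2)
        a = (z2 * (g1 - g0) + z1 * (g0 - g2) + z0 * (g2 - g1)) / denom
        b = (z2**2 * (g0 - g1) + z1**2 * (g2 - g0) + z0**2 * (g1 - g2)) / denom
        if a < 0:  # proper maximum
            vertex = -b / (2 * a)
            if z0 <= vertex <= z2:
                return float(vertex)
    return float(depth[k])


def gradient_max_below(depth: np.ndarray, temp: np.ndarray,
                       thermocline: float) -> float:
    """Depth strictly below the thermocline where |dT/dz| is maximal.

    Used to place the bottom extent of the spawning stain.  Ties break
    toward the shallower level, so a constant-gradient deep layer
    returns the first level below the thermocline.
    """
    depth = np.asarray(depth, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if thermocline < depth[0] or thermocline > depth[-1]:
        raise ValueError("thermocline outside the profile depth span")
    below = depth > thermocline
    if not below.any():
        raise ValueError("no depth levels below the thermocline")
    g = np.abs(_temperature_gradient(depth, temp))
    idx = np.flatnonzero(below)
    k = idx[int(np.argmax(g[idx]))]  # first index on ties → shallower
    return float(depth[k])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_field(field: OceanField, path) -> None:
    """Write an OceanField to NetCDF (classic format, CF-style metadata)."""
    field.ds.to_netcdf(path, engine="scipy")


def read_field(path) -> OceanField:
    """Read a NetCDF ocean field; errors name any missing variable."""
    ds = xr.load_dataset(path, engine="scipy")
    missing = [v for v in (*FIELD_VARS, "landmask") if v not in ds]
    if missing:
        raise ValueError(f"field file {path} missing variables: {missing}")
    return OceanField(ds)
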