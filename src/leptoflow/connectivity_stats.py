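"""Dispersal assessment: fate bookkeeping, densities, connectivity and
development-environment statistics.

Everything here consumes the recorded trajectories and settlement table
of a simulation and produces the descriptive and inferential summaries
used to characterize dispersal: per-day fate proportions, gridded
occupancy densities, settlement kernel-density surfaces (max-normalized
to 1), island connectivity matrices and per-iteration settlement
footprints, the coefficient of dispersal (straight-line : along-track
distance, 1 = linear transport, →0 = circuitous/retained), per-settler
development-environment records, and island contrasts via
Kruskal–Wallis, Dunn's post-hoc test with Bonferroni correction, and
Hedges' g effect sizes with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .larval_ibm import SECONDS_PER_DAY, Fate
from .lagrangian_engine import SimulationResult

__all__ = [
    "EARTH_RADIUS_KM",
    "DevEnvRecord",
    "ConnectivityMatrix",
    "EffectSizeResult",
    "IslandContrasts",
    "haversine_km",
    "path_length",
    "coefficient_of_dispersal",
    "fate_proportions",
    "gridded_density",
    "settlement_kde",
    "connectivity_matrix",
    "settlement_footprints",
    "dev_env_summary",
    "hedges_g",
    "magnitude_class",
    "dunn_test",
    "island_contrasts",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# distances and tortuosity
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (haversine, R = 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def path_length(lon, lat) -> float:
    """Along-track great-circle length of a trajectory, km."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 2:
        raise ValueError("a track needs at least 2 records")
    return float(np.sum(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))


def coefficient_of_dispersal(lon, lat) -> float:
    """Straight-line : along-track distance ratio for a settled track.

    The chord runs from the spawning location (first record) to the
    settlement location (last record).  1 means perfectly linear
    transport; values near 0 mean circuitous, retained dispersal.
    Always in (0, 1] by the triangle inequality on the sphere.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    total = path_length(lon, lat)
    if total <= 0:
        raise ValueError("zero path length: track never moved")
    chord = float(haversine_km(lon[0], lat[0], lon[-1], lat[-1]))
    return min(chord / total, 1.0)


# ---------------------------------------------------------------------------
# fate bookkeeping and densities
# ---------------------------------------------------------------------------

def fate_proportions(result: SimulationResult) -> pd.DataFrame:
    """Across-iteration mean proportion of larvae per fate, per day.

    Rows are whole days post spawn (day 0 = release record), columns
    the fate names; each row sums to 1 because fates are exclusive.
    """
    rec_per_day = SECONDS_PER_DAY / result.config.record_interval
    n_days = int(result.config.duration_days)
    day_recs = np.round(np.arange(n_days + 1) * rec_per_day).astype(int)
    day_recs = day_recs[day_recs < result.n_records]
    rows = []
    n = result.n_particles
    for rec in day_recs:
        f = result.fate[:, :, rec]  # (iter, particle)
        props = {
            name: np.mean(np.count_nonzero(f == code, axis=1) / n)
            for code, name in Fate.NAMES.items()
        }
        rows.append(props)
    df = pd.DataFrame(rows, index=pd.Index(day_recs / rec_per_day, name="day"))
    return df


def gridded_density(result: SimulationResult, lon_edges, lat_edges,
                    mode: str = "all-steps") -> np.ndarray:
    """Occupancy counts per grid cell, shape (n_lat_cells, n_lon_cells).

    'all-steps' bins every record of every larva still in the domain
    (out-of-domain records excluded); 'final-step' bins only the final
    record of in-domain larvae.  Display scaling (natural log) is left
    to the caller.  Cross-checked against brute-force per-record
    binning.
    """
    if mode not in ("all-steps", "final-step"):
        raise ValueError("mode must be 'all-steps' or 'final-step'")
    if mode == "final-step":
        lon = result.lon[:, :, -1].ravel()
        lat = result.lat[:, :, -1].ravel()
        keep = result.fate[:, :, -1].ravel() != Fate.OUT_OF_DOMAIN
    else:
        lon = result.lon.ravel()
        lat = result.lat.ravel()
        keep = result.fate.ravel() != Fate.OUT_OF_DOMAIN
    h, _, _ = np.histogram2d(lat[keep], lon[keep], bins=[lat_edges, lon_edges])
    return h


def settlement_kde(lon, lat, grid_lon, grid_lat,
                   bandwidth: tuple[float, float] | None = None,
                   min_bandwidth: float = 1e-3):
    """Gaussian settlement-density surface, max-normalized to 1.

    A separable product-Gaussian kernel with a per-axis
    normal-reference bandwidth h_i = σ_i · n^(−1/6) (configurable via
    ``bandwidth`` in degrees).  Returns (surface, raw) where ``surface``
    is the density divided by its maximum (values in [0, 1], max
    exactly 1) and ``raw`` the unnormalized kernel sum, whose integral
    over the plane is the number of points.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise ValueError("settlement KDE needs at least one point")
    n = lon.size
    if bandwidth is None:
        hx = max(np.std(lon) * n ** (-1.0 / 6.0), min_bandwidth)
        hy = max(np.std(lat) * n ** (-1.0 / 6.0), min_bandwidth)
    else:
        hx, hy = bandwidth
    gx = np.asarray(grid_lon, dtype=float)
    gy = np.asarray(grid_lat, dtype=float)
    kx = np.exp(-0.5 * ((gx[None, :, None] - lon[None, None, :]) / hx) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None, None] - lat[None, None, :]) / hy) ** 2)
    raw = np.sum(kx * ky, axis=2) / (2.0 * np.pi * hx * hy)
    peak = raw.max()
    if peak <= 0:
        raise ValueError("degenerate KDE: zero density everywhere on the grid")
    return raw / peak, raw


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Island-level connectivity summary across iterations."""

    totals: pd.Series  # settled larvae per island, all iterations
    iteration_fraction: pd.Series  # fraction of iterations with ≥1 settler
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "settled_total": self.totals,
            "iteration_fraction": self.iteration_fraction,
        })


def connectivity_matrix(records: pd.DataFrame, n_iterations: int,
                        islands=None) -> ConnectivityMatrix:
    """Totals and per-island fraction of iterations with settlement."""
    if len(records) and records["iteration"].max() >= n_iterations:
        raise ValueError("iteration id outside the declared range")
    names = list(islands) if islands is not None else (
        sorted(records["island"].unique()) if len(records) else [])
    totals = pd.Series(0, index=pd.Index(names, name="island"), dtype=int)
    frac = pd.Series(0.0, index=totals.index)
    if len(records):
        counts = records.groupby("island").size()
        totals.loc[counts.index] = counts
        per_iter = records.groupby("island")["iteration"].nunique()
        frac.loc[per_iter.index] = per_iter / n_iterations
    return ConnectivityMatrix(totals=totals, iteration_fraction=frac,
                              n_iterations=n_iterations)


def settlement_footprints(records: pd.DataFrame,
                          n_iterations: int) -> pd.DataFrame:
    """Relative frequency of island combinations settled per iteration.

    Each iteration contributes one footprint — the set of islands that
    received at least one settler (possibly empty).  Frequencies sum to
    1 over iterations.
    """
    sets = {it: frozenset() for it in range(n_iterations)}
    if len(records):
        for it, grp in records.groupby("iteration"):
            sets[int(it)] = frozenset(grp["island"])
    counts: dict[frozenset, int] = {}
    for fp in sets.values():
        counts[fp] = counts.get(fp, 0) + 1
    rows = [
        {"footprint": tuple(sorted(fp)), "count": c,
         "frequency": c / n_iterations}
        for fp, c in counts.items()
    ]
    return (pd.DataFrame(rows)
            .sort_values("frequency", ascending=False)
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# development environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DevEnvRecord:
    """Development-environment summary for one settled larva."""

    larva_id: int
    iteration: int
    island: str
    coefficient_of_dispersal: float
    settlement_dps: float
    mean_temp: float
    min_temp: float
    max_temp: float
    mean_salt: float
    min_salt: float
    max_salt: float
    release_depth: float
    mean_depth: float


def dev_env_summary(result: SimulationResult) -> pd.DataFrame:
    """Per-settler development environment table.

    Summaries run over the recorded history from release to the
    settlement record inclusive: mean/min/max sampled temperature and
    salinity, release depth, mean dispersal depth, settlement age, and
    the coefficient of dispersal of the recorded track.
    """
    recs = []
    t0 = float(result.time[0])
    dt_rec = float(result.config.record_interval)
    for s in result.settlements:
        it, pid = s.iteration, s.larva_id
        last = min(int(np.ceil((s.time - t0) / dt_rec)), result.n_records - 1)
        sl = slice(0, last + 1)
        temp = result.temp[it, pid, sl].astype(float)
        salt = result.salt[it, pid, sl].astype(float)
        lon = result.lon[it, pid, sl].astype(float)
        lat = result.lat[it, pid, sl].astype(float)
        depth = result.depth[it, pid, sl].astype(float)
        recs.append(DevEnvRecord(
            larva_id=pid, iteration=it, island=s.island,
            coefficient_of_dispersal=coefficient_of_dispersal(lon, lat),
            settlement_dps=s.dps,
            mean_temp=float(np.nanmean(temp)),
            min_temp=float(np.nanmin(temp)),
            max_temp=float(np.nanmax(temp)),
            mean_salt=float(np.nanmean(salt)),
            min_salt=float(np.nanmin(salt)),
            max_salt=float(np.nanmax(salt)),
            release_depth=float(depth[0]),
            mean_depth=float(np.mean(depth)),
        ))
    cols = [f.name for f in DevEnvRecord.__dataclass_fields__.values()]
    if not recs:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.__dict__ for r in recs])[cols]


# ---------------------------------------------------------------------------
# island contrasts
# ---------------------------------------------------------------------------

def hedges_g(x, y) -> float:
    """Hedges' g: Cohen's d with the small-sample correction J.

    g = J · (mean(x) − mean(y)) / s_pooled with
    J = 1 − 3 / (4(n₁+n₂) − 9) and the pooled-variance denominator.
    Returns NaN when both groups have zero variance (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else float("nan")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * diff / np.sqrt(pooled))


def magnitude_class(g: float) -> str:
    """Cohen-style magnitude bands with exclusive lower bounds.

    negligible (< 0.2), small (< 0.5), medium (< 0.8), large (≥ 0.8);
    undefined g maps to 'undefined'.
    """
    if np.isnan(g):
        return "undefined"
    a = abs(g)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def _bootstrap_ci(x, y, n_boot: int, rng: np.random.Generator,
                  level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for Hedges' g."""
    gs = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        gs[b] = hedges_g(xb, yb)
    gs = gs[np.isfinite(gs)]
    if gs.size == 0:
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(gs, alpha)), float(np.quantile(gs, 1.0 - alpha)))


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with tie correction.

    z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − T/(12(N−1)))(1/n_i + 1/n_j)]
    with T = Σ(t³ − t) over tied values; two-sided p with Bonferroni
    adjustment over all pairs.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = {}
    start = 0
    sizes = {}
    for k in names:
        n_k = np.asarray(groups[k]).size
        mean_ranks[k] = ranks[start:start + n_k].mean()
        sizes[k] = n_k
        start += n_k
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p": p, "p_adj": min(1.0, p * m)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSizeResult:
    island_a: str
    island_b: str
    g: float
    ci_low: float
    ci_high: float
    magnitude: str
    dunn_z: float
    dunn_p_adj: float


@dataclass
class IslandContrasts:
    """Omnibus + pairwise island contrasts for one variable."""

    variable: str
    normality: pd.DataFrame  # per island Lilliefors statistic/p
    kruskal_h: float
    kruskal_p: float
    pairwise: list[EffectSizeResult] = dc_field(default_factory=list)

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.pairwise])


def island_contrasts(dev_env: pd.DataFrame, variable: str,
                     n_boot: int = 2000, seed: int = 0,
                     min_group: int = 2) -> IslandContrasts:
    """Island-level contrasts of one development-environment variable.

    Groups the per-settler records by island (dropping islands with
    fewer than ``min_group`` records), screens each group for normality
    with a Lilliefors-corrected Kolmogorov–Smirnov test, runs the
    tie-corrected Kruskal–Wallis omnibus test, then Dunn's pairwise
    test with Bonferroni correction, and Hedges' g with a seeded
    percentile-bootstrap confidence interval and a magnitude class.
    """
    if variable not in dev_env.columns:
        raise ValueError(f"unknown variable {variable!r}")
    groups = {
        str(isl): grp[variable].to_numpy(dtype=float)
        for isl, grp in dev_env.groupby("island")
        if len(grp) >= min_group
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 islands with enough records")

    norm_rows = []
    for isl, vals in groups.items():
        if vals.size >= 4 and np.ptp(vals) > 0:
            stat, p = lilliefors(vals, dist="norm")
        else:
            stat, p = float("nan"), float("nan")
        norm_rows.append({"island": isl, "ks_stat": stat, "ks_p": p,
                          "n": vals.size})
    normality = pd.DataFrame(norm_rows)

    h, p_kw = sps.kruskal(*groups.values())
    dunn = dunn_test(groups)
    rng = np.random.default_rng(seed)
    pairwise = []
    for _, row in dunn.iterrows():
        a, b = row["group_a"], row["group_b"]
        g = hedges_g(groups[a], groups[b])
        lo, hi = _bootstrap_ci(groups[a], groups[b], n_boot, rng)
        pairwise.append(EffectSizeResult(
            island_a=a, island_b=b, g=g, ci_low=lo, ci_high=hi,
            magnitude=magnitude_class(g),
            dunn_z=float(row["z"]), dunn_p_adj=float(row["p_adj"]),
        ))
    return IslandContrasts(variable=variable, normality=normality,
                           kruskal_h=float(h), kruskal_p=float(p_kw),
                           pairwise=pairwise)
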