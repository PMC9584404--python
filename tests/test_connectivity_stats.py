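"""Assessment layer: distances, densities, connectivity, contrasts."""

import numpy as np
import pandas as pd
import pytest

from leptoflow.larval_ibm import BioRules, Fate
from leptoflow.lagrangian_engine import EngineConfig, SimulationResult
from leptoflow.settlement import SettlementRecord
from leptoflow.spawn_release import ReleaseSpec
from leptoflow.connectivity_stats import (
    coefficient_of_dispersal,
    connectivity_matrix,
    dev_env_summary,
    dunn_test,
    fate_proportions,
    gridded_density,
    haversine_km,
    hedges_g,
    island_contrasts,
    magnitude_class,
    path_length,
    settlement_footprints,
    settlement_kde,
)

DT = 10_800.0


def make_result(n_iter=1, n=1, days=2.0, fill_lon=-77.0, fill_lat=24.0,
                settlements=None):
    """Handmade SimulationResult with constant positions."""
    cfg = EngineConfig(n_iterations=n_iter, dt=DT, record_interval=DT,
                       duration_days=days, umax=0.2, kh=0.0)
    n_rec = cfg.n_records
    shape = (n_iter, n, n_rec)
    release = ReleaseSpec(upper_depth=40.0, lower_depth=150.0,
                          lon=np.full(n, fill_lon), lat=np.full(n, fill_lat),
                          depth=np.full(n, 75.0))
    return SimulationResult(
        config=cfg, rules=BioRules(), release=release, zone_islands=[],
        time=np.arange(n_rec) * DT,
        lon=np.full(shape, fill_lon, dtype=np.float32),
        lat=np.full(shape, fill_lat, dtype=np.float32),
        depth=np.full(shape, 75.0, dtype=np.float32),
        temp=np.full(shape, 25.0, dtype=np.float32),
        salt=np.full(shape, 36.0, dtype=np.float32),
        fate=np.zeros(shape, dtype=np.int16),
        settlements=settlements or [],
    )


class TestDistances:
    def test_one_degree_longitude_at_equator(self):
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.19, abs=0.01)

    def test_identical_points_zero_path(self):
        assert path_length([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == 0.0

    def test_path_concatenation_additive(self):
        lon = np.array([0.0, 0.3, 0.8, 1.4])
        lat = np.array([0.0, 0.2, 0.1, 0.5])
        total = path_length(lon, lat)
        partial = path_length(lon[:3], lat[:3]) + path_length(lon[2:], lat[2:])
        assert total == pytest.approx(partial, rel=1e-12)

    def test_straight_track_coefficient_one(self):
        # three collinear points along a meridian: great-circle segments
        # sum exactly to the chord
        assert coefficient_of_dispersal([0.0, 0.0, 0.0],
                                        [0.0, 0.5, 1.0]) == pytest.approx(1.0)

    def test_right_angle_track_five_sevenths(self):
        """3 km east then 4 km north closes with a 5 km chord: ratio 5/7."""
        km = 1.0 / 111.19492664455873  # degrees per km on a meridian/equator
        lon = np.array([0.0, 3.0 * km, 3.0 * km])
        lat = np.array([0.0, 0.0, 4.0 * km])
        assert coefficient_of_dispersal(lon, lat) == pytest.approx(5.0 / 7.0, abs=1e-3)

    def test_loop_back_gives_small_coefficient(self):
        theta = np.linspace(0.0, 2.0 * np.pi * 0.98, 60)
        lon = 0.5 * np.cos(theta)
        lat = 0.5 * np.sin(theta)
        assert coefficient_of_dispersal(lon, lat) < 0.05

    def test_zero_path_is_an_error(self):
        with pytest.raises(ValueError, match="zero path"):
            coefficient_of_dispersal([0.0, 0.0], [0.0, 0.0])


class TestFateProportions:
    def test_all_alive_is_one_every_day(self):
        res = make_result(n_iter=2, n=5, days=3.0)
        fp = fate_proportions(res)
        assert np.allclose(fp["alive"], 1.0)
        assert np.allclose(fp.sum(axis=1), 1.0)

    def test_half_beached_from_day_one(self):
        res = make_result(n_iter=1, n=4, days=3.0)
        rec_per_day = int(86_400 / DT)
        res.fate[0, :2, rec_per_day:] = Fate.DEAD_BEACHED
        fp = fate_proportions(res)
        assert fp["dead_beached"].iloc[0] == 0.0
        assert np.allclose(fp["dead_beached"].iloc[1:], 0.5)
        assert np.allclose(fp.sum(axis=1), 1.0)

    def test_rows_sum_to_one_with_random_fates(self):
        res = make_result(n_iter=3, n=10, days=2.0)
        rng = np.random.default_rng(5)
        res.fate[:] = rng.integers(0, 6, size=res.fate.shape).astype(np.int16)
        fp = fate_proportions(res)
        assert np.allclose(fp.sum(axis=1), 1.0)


class TestGriddedDensity:
    def test_stationary_particle_counts_all_records(self):
        res = make_result(days=2.0)  # 17 records
        lon_edges = np.linspace(-78.0, -76.0, 11)
        lat_edges = np.linspace(23.0, 25.0, 11)
        h = gridded_density(res, lon_edges, lat_edges, mode="all-steps")
        assert h.sum() == res.n_records
        assert h.max() == res.n_records

    def test_final_step_counts_in_domain_particles(self):
        res = make_result(n=4, days=2.0)
        res.fate[0, 0, -1] = Fate.OUT_OF_DOMAIN
        lon_edges = np.linspace(-78.0, -76.0, 11)
        lat_edges = np.linspace(23.0, 25.0, 11)
        h = gridded_density(res, lon_edges, lat_edges, mode="final-step")
        assert h.sum() == 3

    def test_matches_brute_force_binning(self):
        res = make_result(n_iter=2, n=8, days=2.0)
        rng = np.random.default_rng(9)
        res.lon[:] = rng.uniform(-78.0, -76.0, res.lon.shape).astype(np.float32)
        res.lat[:] = rng.uniform(23.0, 25.0, res.lat.shape).astype(np.float32)
        lon_edges = np.linspace(-78.0, -76.0, 9)
        lat_edges = np.linspace(23.0, 25.0, 7)
        h = gridded_density(res, lon_edges, lat_edges, mode="all-steps")
        brute = np.zeros_like(h)
        for it in range(2):
            for p in range(8):
                for r in range(res.n_records):
                    i = np.searchsorted(lat_edges, res.lat[it, p, r]) - 1
                    j = np.searchsorted(lon_edges, res.lon[it, p, r]) - 1
                    if 0 <= i < brute.shape[0] and 0 <= j < brute.shape[1]:
                        brute[i, j] += 1
        assert h.sum() == brute.sum()
        np.testing.assert_array_equal(h, brute)


class TestSettlementKde:
    def test_single_point_peak_of_one(self):
        gx = np.linspace(-1.0, 1.0, 41)
        gy = np.linspace(-1.0, 1.0, 41)
        surf, _ = settlement_kde([0.0], [0.0], gx, gy, bandwidth=(0.1, 0.1))
        assert surf.max() == 1.0
        assert surf[20, 20] == 1.0
        assert np.all((surf >= 0.0) & (surf <= 1.0))

    def test_two_distant_clusters_equal_modes(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 0.02, 200)
        b = rng.normal(3.0, 0.02, 200)
        lon = np.concatenate([a, b])
        lat = np.concatenate([np.zeros(200), np.zeros(200)])
        gx = np.linspace(-1.0, 4.0, 201)
        gy = np.linspace(-0.5, 0.5, 41)
        surf, _ = settlement_kde(lon, lat, gx, gy, bandwidth=(0.05, 0.05))
        left = surf[:, gx < 1.5].max()
        right = surf[:, gx >= 1.5].max()
        assert max(left, right) == 1.0
        assert min(left, right) > 0.9

    def test_kernel_mass_integrates_to_n(self):
        """The unnormalized surface integrates to the point count."""
        rng = np.random.default_rng(4)
        lon = rng.normal(0.0, 0.1, 50)
        lat = rng.normal(0.0, 0.1, 50)
        gx = np.linspace(-2.0, 2.0, 401)
        gy = np.linspace(-2.0, 2.0, 401)
        _, raw = settlement_kde(lon, lat, gx, gy, bandwidth=(0.08, 0.08))
        integral = np.trapezoid(np.trapezoid(raw, gx, axis=1), gy)
        assert integral == pytest.approx(50.0, rel=0.01)

    def test_no_points_is_an_error(self):
        with pytest.raises(ValueError):
            settlement_kde([], [], np.linspace(0, 1, 5), np.linspace(0, 1, 5))


def records_df(rows):
    return pd.DataFrame(rows, columns=["larva_id", "iteration", "island",
                                       "time", "dps", "lon", "lat"])


class TestConnectivity:
    def test_island_settled_in_two_of_three_iterations(self):
        recs = records_df([
            (0, 0, "A", 0.0, 45.0, 0.0, 0.0),
            (1, 1, "A", 0.0, 50.0, 0.0, 0.0),
            (2, 1, "B", 0.0, 55.0, 0.0, 0.0),
        ])
        cm = connectivity_matrix(recs, n_iterations=3)
        assert cm.iteration_fraction["A"] == pytest.approx(2.0 / 3.0)
        assert cm.totals["A"] == 2 and cm.totals["B"] == 1

    def test_empty_records_all_zero(self):
        cm = connectivity_matrix(records_df([]), 5, islands=["A", "B"])
        assert (cm.totals == 0).all() and (cm.iteration_fraction == 0.0).all()

    def test_totals_match_brute_force_group_by(self):
        rng = np.random.default_rng(12)
        rows = [(i, int(rng.integers(0, 10)), rng.choice(list("ABCD")),
                 0.0, 50.0, 0.0, 0.0) for i in range(200)]
        recs = records_df(rows)
        cm = connectivity_matrix(recs, 10)
        for island in "ABCD":
            assert cm.totals[island] == sum(1 for r in rows if r[2] == island)

    def test_iteration_out_of_range_rejected(self):
        recs = records_df([(0, 7, "A", 0.0, 45.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            connectivity_matrix(recs, n_iterations=5)


class TestFootprints:
    def test_single_island_every_iteration(self):
        recs = records_df([(i, it, "A", 0.0, 50.0, 0.0, 0.0)
                           for it in range(4) for i in range(3)])
        fp = settlement_footprints(recs, 4)
        assert len(fp) == 1
        assert fp.loc[0, "footprint"] == ("A",)
        assert fp.loc[0, "frequency"] == 1.0

    def test_no_settlement_empty_footprint(self):
        fp = settlement_footprints(records_df([]), 3)
        assert fp.loc[0, "footprint"] == ()
        assert fp.loc[0, "frequency"] == 1.0

    def test_constructed_ten_iterations_hand_count(self):
        rows = []
        for it in range(10):
            rows.append((0, it, "A", 0.0, 50.0, 0.0, 0.0))
            if it < 4:
                rows.append((1, it, "B", 0.0, 52.0, 0.0, 0.0))
        fp = settlement_footprints(records_df(rows), 10)
        freq = {r.footprint: r.frequency for r in fp.itertuples()}
        assert freq[("A", "B")] == pytest.approx(0.4)
        assert freq[("A",)] == pytest.approx(0.6)
        assert fp["frequency"].sum() == pytest.approx(1.0)


class TestDevEnv:
    def test_constant_history_mean_min_max_equal(self):
        settle = SettlementRecord(larva_id=0, iteration=0, island="A",
                                  time=8 * DT, dps=1.0, lon=-77.0, lat=24.0)
        res = make_result(days=2.0, settlements=[settle])
        res.lon[0, 0, :] = np.linspace(-77.0, -76.9, res.n_records)
        df = dev_env_summary(res)
        assert df.loc[0, "mean_temp"] == 25.0
        assert df.loc[0, "min_temp"] == 25.0
        assert df.loc[0, "max_temp"] == 25.0
        assert df.loc[0, "release_depth"] == 75.0

    def test_two_value_history_mean_and_range(self):
        settle = SettlementRecord(larva_id=0, iteration=0, island="A",
                                  time=DT, dps=0.125, lon=-77.0, lat=24.0)
        res = make_result(days=2.0, settlements=[settle])
        res.temp[0, 0, 0] = 20.0
        res.temp[0, 0, 1] = 30.0
        res.lon[0, 0, 1] = -76.95
        df = dev_env_summary(res)
        assert df.loc[0, "mean_temp"] == pytest.approx(25.0)
        assert df.loc[0, "min_temp"] == 20.0
        assert df.loc[0, "max_temp"] == 30.0

    def test_coefficient_in_unit_interval(self):
        settle = SettlementRecord(larva_id=0, iteration=0, island="A",
                                  time=8 * DT, dps=1.0, lon=-76.5, lat=24.2)
        res = make_result(days=2.0, settlements=[settle])
        rng = np.random.default_rng(2)
        res.lon[0, 0, :] = -77.0 + np.cumsum(rng.uniform(0, 0.05, res.n_records))
        res.lat[0, 0, :] = 24.0 + np.cumsum(rng.uniform(-0.03, 0.03, res.n_records))
        cod = dev_env_summary(res).loc[0, "coefficient_of_dispersal"]
        assert 0.0 < cod <= 1.0


class TestEffectSizes:
    def test_identical_groups_g_zero_negligible(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert hedges_g(x, x) == 0.0
        assert magnitude_class(hedges_g(x, x)) == "negligible"

    def test_small_sample_correction_factor_68_over_71(self):
        """n₁=n₂=10 with raw Cohen's d = 1 gives g = 1 − 3/71 = 68/71."""
        base = np.arange(10, dtype=float)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1
        x = base + 1.0
        y = base.copy()
        assert hedges_g(x, y) == pytest.approx(68.0 / 71.0, rel=1e-12)

    @pytest.mark.parametrize("g,expected", [
        (0.0, "negligible"), (0.19, "negligible"),
        (0.2, "small"), (0.49, "small"),
        (0.5, "medium"), (0.79, "medium"),
        (0.8, "large"), (0.85, "large"), (-0.9, "large"),
    ])
    def test_magnitude_bands_exclusive_lower_bounds(self, g, expected):
        assert magnitude_class(g) == expected

    def test_zero_variance_both_sides_flagged_undefined(self):
        g = hedges_g(np.full(5, 1.0), np.full(5, 2.0))
        assert np.isnan(g)
        assert magnitude_class(g) == "undefined"


class TestDunn:
    def test_two_group_z_squared_matches_kruskal_h(self):
        """Without ties, Dunn's z² for two groups equals the
        Kruskal–Wallis H statistic."""
        from scipy.stats import kruskal
        rng = np.random.default_rng(21)
        x = rng.normal(0.0, 1.0, 15)
        y = rng.normal(0.8, 1.0, 12)
        d = dunn_test({"x": x, "y": y})
        h, _ = kruskal(x, y)
        assert d.loc[0, "z"] ** 2 == pytest.approx(h, rel=1e-10)

    def test_sign_reflects_rank_order(self):
        d = dunn_test({"low": np.arange(10.0), "high": np.arange(10.0) + 20.0})
        assert d.loc[0, "z"] < 0  # low − high

    def test_bonferroni_never_exceeds_one(self):
        rng = np.random.default_rng(22)
        groups = {k: rng.normal(0, 1, 10) for k in "abcd"}
        d = dunn_test(groups)
        assert len(d) == 6
        assert (d["p_adj"] <= 1.0).all()
        assert (d["p_adj"] >= d["p"] - 1e-15).all()


class TestIslandContrasts:
    def dev_frame(self, rng, shift=0.0):
        rows = []
        for isl, mu in (("A", 0.2), ("B", 0.2 + shift), ("C", 0.5)):
            for v in rng.normal(mu, 0.05, 25):
                rows.append({"island": isl, "coefficient_of_dispersal": v})
        return pd.DataFrame(rows)

    def test_full_contrast_pipeline(self):
        rng = np.random.default_rng(30)
        df = self.dev_frame(rng, shift=0.15)
        res = island_contrasts(df, "coefficient_of_dispersal",
                               n_boot=200, seed=1)
        assert res.kruskal_p < 0.01
        pw = res.pairwise_frame()
        assert len(pw) == 3
        for _, row in pw.iterrows():
            if np.isfinite(row["g"]):
                assert row["ci_low"] <= row["g"] <= row["ci_high"]
        ab = pw[(pw.island_a == "A") & (pw.island_b == "C")].iloc[0]
        assert ab["magnitude"] == "large"

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            island_contrasts(pd.DataFrame({"island": ["A", "A", "B", "B"],
                                           "x": [1.0, 2.0, 1.0, 2.0]}), "y")

    def test_needs_two_islands(self):
        df = pd.DataFrame({"island": ["A"] * 5,
                           "coefficient_of_dispersal": np.arange(5.0)})
        with pytest.raises(ValueError, match="2 islands"):
            island_contrasts(df, "coefficient_of_dispersal")
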