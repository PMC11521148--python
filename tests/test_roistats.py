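"""Tissue masking, ROI summaries, radial profiles, statistical battery."""

import numpy as np
import pandas as pd
import pytest

from ringpol import group_tests, mad_mask, radial_profile, roi_summary, spearman_battery
from ringpol.roistats import rank_sum_test


class TestMadMask:
    def test_constant_map_keeps_everything(self):
        m = mad_mask(np.full((20, 20), 3.0))
        assert m.mask.all()

    def test_planted_outliers_recovered_exactly(self, rng):
        # uniform base: no base pixel can exceed 3 scaled MADs, so the
        # exclusions are exactly the planted values
        x = rng.uniform(-1, 1, 10_000)
        idx = rng.choice(10_000, 50, replace=False)
        x[idx] = 10.0
        m = mad_mask(x)
        excluded = np.nonzero(~m.mask)[0]
        assert set(excluded) == set(idx)

    def test_normal_null_exclusion_near_3sigma_tail(self, rng):
        x = rng.normal(size=200_000)
        frac = 1.0 - mad_mask(x).mask.mean()
        assert frac == pytest.approx(0.0027, abs=5e-4)

    def test_within_region_restricts_statistics(self, rng):
        x = np.zeros((40, 40))
        region = np.zeros((40, 40), bool)
        region[10:30, 10:30] = True
        x[region] = rng.uniform(0.99, 1.01, region.sum())
        x[15, 15] = 50.0  # defect inside tissue
        m = mad_mask(x, within=region)
        assert not m.mask[15, 15]
        assert not m.mask[0, 0]          # background never kept
        assert m.mask[region].sum() == region.sum() - 1

    def test_idempotent_when_no_new_outliers(self, rng):
        x = rng.uniform(0, 1, 5000)
        kept = x[mad_mask(x).mask]
        assert mad_mask(kept).mask.all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mad_mask(np.array([1.0, np.nan]))


class TestRoiSummary:
    def test_uniform_map(self):
        maps = {"delta_deg": np.full((8, 8), 5.0)}
        row = roi_summary(maps, mad_mask(maps["delta_deg"]), day=7, group="control")
        assert row["delta_deg_mean"] == 5.0
        assert row["delta_deg_max"] == 5.0
        assert row["n_pixels"] == 64

    def test_defect_excluded_from_mean(self, rng):
        x = rng.normal(5.0, 0.01, (30, 30))
        x[10:12, 10:12] = 40.0
        row = roi_summary({"delta_deg": x}, mad_mask(x))
        assert row["delta_deg_mean"] == pytest.approx(5.0, abs=0.01)

    def test_empty_mask_rejected(self):
        maps = {"p": np.ones((4, 4))}
        m = mad_mask(maps["p"])
        m.mask[:] = False
        with pytest.raises(ValueError):
            roi_summary(maps, m)


class TestRadialProfile:
    def _ring_map(self, fn, n=101, r_in=20.0, width=20.0):
        c = (n - 1) / 2
        rr, cc = np.mgrid[0:n, 0:n]
        r = np.hypot(rr - c, cc - c)
        f = (r - r_in) / width
        x = np.where((f >= 0) & (f <= 1), fn(np.clip(f, 0, 1)), np.nan)
        return x, (c, c)

    def test_flat_map_flat_profile(self):
        x, center = self._ring_map(lambda f: np.full_like(f, 4.0))
        prof = radial_profile(x, center, 20.0, 20.0, n_bins=10)
        assert prof.profile_std == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(prof.values[1:-1], 4.0)

    def test_bump_location_recovered(self):
        bump = lambda f: 2.0 + 5.0 * np.exp(-0.5 * ((f - 0.3) / 0.1) ** 2)
        x, center = self._ring_map(bump)
        prof = radial_profile(x, center, 20.0, 20.0, n_bins=20)
        assert prof.peak_distance_um == pytest.approx(0.3 * 20.0, abs=20.0 / 20)
        assert prof.distance_um[1] > prof.distance_um[0]

    def test_bump_increases_profile_std(self):
        flat, center = self._ring_map(lambda f: np.full_like(f, 2.0))
        bump, _ = self._ring_map(lambda f: 2.0 + 4.0 * np.exp(-0.5 * ((f - 0.3) / 0.1) ** 2))
        p0 = radial_profile(flat, center, 20.0, 20.0)
        p1 = radial_profile(bump, center, 20.0, 20.0)
        assert p1.profile_std > p0.profile_std

    def test_geometry_outside_map_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.full((20, 20), np.nan), (10, 10), 5.0, 5.0)


def _toy_table(rng, trend=1.0, n_per_cell=6):
    rows = []
    for day in (2, 4, 7, 14, 21):
        for group in ("control", "treated"):
            boost = 2.0 if group == "treated" else 0.0
            for i in range(n_per_cell):
                rows.append({
                    "sample_id": len(rows), "day": day, "group": group,
                    "delta_deg_mean": trend * day + boost + rng.normal(0, 0.5),
                    "DeltaC_mean": 0.001 * day + rng.normal(0, 5e-4),
                })
    return pd.DataFrame(rows)


class TestSpearman:
    def test_strict_increase_gives_rho_one(self):
        t = pd.DataFrame({
            "day": [2, 4, 7, 14, 21], "group": ["control"] * 5,
            "delta_deg_mean": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        out = spearman_battery(t)
        assert out["design"].loc["delta_deg_mean", "rho_day"] == pytest.approx(1.0)

    def test_identical_columns_correlate_perfectly(self, rng):
        t = _toy_table(rng)
        t["R_deg_mean"] = t["delta_deg_mean"]  # psi = 0: total == linear
        out = spearman_battery(t)
        assert out["rho"].loc["R_deg_mean", "delta_deg_mean"] == pytest.approx(1.0)

    def test_constant_column_reported_missing(self, rng):
        t = _toy_table(rng)
        t["D_mean"] = 0.0
        out = spearman_battery(t)
        assert np.isnan(out["rho"].loc["D_mean", "delta_deg_mean"])

    def test_rank_invariance_under_monotone_transform(self, rng):
        t = _toy_table(rng)
        a = spearman_battery(t)["design"].loc["delta_deg_mean", "rho_day"]
        t2 = t.copy()
        t2["delta_deg_mean"] = np.exp(t2["delta_deg_mean"] / 5.0)
        b = spearman_battery(t2)["design"].loc["delta_deg_mean", "rho_day"]
        assert a == pytest.approx(b, abs=1e-12)


class TestGroupTests:
    def test_identical_groups_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = rank_sum_test(x, x)
        assert p == pytest.approx(1.0)

    def test_tiny_cells_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [1.0, 2.0])

    def test_report_structure_and_significance(self, rng):
        t = _toy_table(rng)
        rep = group_tests(t, param="delta_deg_mean")
        assert set(rep.kruskal["group"]) == {"control", "treated"}
        assert (rep.kruskal["p"] < 0.01).all()           # strong day trend
        assert len(rep.pairwise_days) == 2 * 10          # all day pairs, both arms
        assert (rep.between_groups["p"] < 0.05).any()    # treated offset detectable
        assert rep.shapiro is not None

    def test_unadjusted_versus_holm(self, rng):
        t = _toy_table(rng)
        plain = group_tests(t).pairwise_days
        holm = group_tests(t, adjust="holm").pairwise_days
        assert "p_holm" not in plain.columns
        assert (holm["p_holm"] >= holm["p"] - 1e-15).all()

    def test_power_at_large_shift(self, rng):
        hits = 0
        reps = 120
        for _ in range(reps):
            x = rng.normal(0, 1, 10)
            y = rng.normal(2.0, 1, 10)  # 2 sd shift: high power
            _, p = rank_sum_test(x, y)
            hits += p < 0.05
        assert hits / reps > 0.8

    def test_null_kruskal_type_I_sane(self, rng):
        from scipy.stats import kruskal

        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = [rng.normal(size=10) for _ in range(5)]
            rejections += kruskal(*groups).pvalue < 0.05
        assert 0.01 <= rejections / reps <= 0.10
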