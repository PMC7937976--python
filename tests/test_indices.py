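"""Index catalog, expression evaluation, rmcorr and the discovery searches."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from phenospectra.indices import (
    Band,
    SEARCH_RANGE_NM,
    IndexDefinition,
    band_value,
    compute_index,
    exhaustive_pair_search,
    get_index,
    greedy_index_builder,
    index_catalog,
    rmcorr,
)


class TestBandValue:
    def test_nearest_band(self):
        wl = np.array([550.0, 650.0])
        spec = np.array([0.1, 0.4])
        assert band_value(wl, spec, Band(651.0)) == 0.4

    def test_range_mean(self):
        wl = np.array([610.0, 650.0, 690.0])
        spec = np.array([0.1, 0.2, 0.3])
        assert band_value(wl, spec, Band(600.0, 700.0)) == pytest.approx(0.2)

    def test_out_of_grid_rejected(self):
        wl = np.linspace(400, 1000, 50)
        with pytest.raises(ValueError, match="outside"):
            band_value(wl, np.ones(50), Band(300.0))

    def test_empty_range_rejected(self):
        wl = np.array([500.0, 900.0])
        with pytest.raises(ValueError, match="no grid bands"):
            band_value(wl, np.ones(2), Band(600.0, 700.0))


class TestCatalog:
    def test_counts(self):
        cat = index_catalog()
        assert sum(d.origin == "published" for d in cat) == 10
        assert sum(d.origin == "novel" for d in cat) == 10

    def test_band_positions_audit(self):
        """Every referenced wavelength sits inside the usable sensor range."""
        for d in index_catalog():
            for b in d.bands():
                lo, hi = b.lo, (b.hi if b.hi is not None else b.lo)
                assert 480.0 <= lo <= hi <= 2470.0, (d.name, b)

    @pytest.mark.parametrize("name,expected", [
        ("RGRI", 1.0), ("WPI2", 1.0), ("MCARI", 0.0), ("PRI", 0.0), ("NDVI", 0.0),
        ("WPI1", 0.0), ("MSI", 1.0), ("WBI", 1.0), ("R_960/699", 1.0),
        ("NDI_1407/1862", 0.0), ("R_1451/1263", 1.0),
    ])
    def test_flat_spectrum_identities(self, name, expected):
        wl = np.linspace(480, 2470, 400)
        flat = np.full(wl.size, 0.37)
        assert compute_index(wl, flat, get_index(name)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_ndvi_hand_arithmetic(self):
        wl = np.array([650.0, 850.0])
        spec = np.array([0.1, 0.5])
        assert compute_index(wl, spec, get_index("NDVI")) == pytest.approx(
            0.4 / 0.6, abs=1e-4
        )

    def test_cri1_hand_arithmetic(self):
        wl = np.array([511.0, 551.0])
        spec = np.array([0.05, 0.10])
        assert compute_index(wl, spec, get_index("CRI1")) == pytest.approx(10.0)

    def test_division_by_zero_is_missing(self):
        # IND_715/655 blows up when rho715 == rho655
        wl = np.array([655.0, 715.0])
        spec = np.array([0.2, 0.2])
        assert np.isnan(compute_index(wl, spec, get_index("IND_715/655")))

    def test_json_round_trip(self):
        for d in index_catalog():
            back = IndexDefinition.from_json(d.to_json())
            wl = np.linspace(480, 2470, 300)
            spec = np.linspace(0.1, 0.5, 300)
            assert compute_index(wl, spec, back) == pytest.approx(
                compute_index(wl, spec, d), nan_ok=True
            )


class TestRmcorr:
    def test_single_subject_equals_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20) * 0.3
        r = rmcorr(np.zeros(20, int), x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_common_slope_lines_give_unit_correlation(self):
        x = np.concatenate([np.arange(5.0), np.arange(5.0)])
        y = np.concatenate([2 * np.arange(5.0) + 1, 2 * np.arange(5.0) + 10])
        ids = np.repeat([0, 1], 5)
        assert rmcorr(ids, x, y) == pytest.approx(1.0)

    def test_simpsons_paradox_sign_flip(self):
        """Within-subject slope +1, between-subject slope negative: rmcorr is
        positive while pooled Pearson is negative."""
        rng = np.random.default_rng(1)
        ids = np.repeat(np.arange(6), 8)
        x = rng.normal(size=48) + ids * 1.0
        y = (x - ids * 1.0) + rng.normal(size=48) * 0.1 - ids * 3.0
        assert rmcorr(ids, x, y) > 0
        assert np.corrcoef(x, y)[0, 1] < 0

    def test_matches_pingouin(self):
        rng = np.random.default_rng(2)
        ids = np.repeat(np.arange(8), 6)
        x = rng.normal(size=48) + ids * 0.5
        y = 0.7 * x + rng.normal(size=48) * 0.5 - ids * 1.0
        mine = rmcorr(ids, x, y)
        ref = pg.rm_corr(
            data=pd.DataFrame({"s": ids, "x": x, "y": y}), x="x", y="y", subject="s"
        )
        assert mine == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            rmcorr(np.arange(5), np.arange(5.0), np.arange(5.0))

    def test_zero_within_variance_rejected(self):
        ids = np.repeat([0, 1], 3)
        x = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="variance"):
            rmcorr(ids, x, y)


def brute_force_pair_search(wl, S, y):
    """Independent double-loop oracle for the exhaustive search."""
    keep = (wl >= SEARCH_RANGE_NM[0]) & (wl <= SEARCH_RANGE_NM[1])
    wl, S = wl[keep], S[:, keep]
    best = (0.0, None)
    n = wl.size

    def corr(v):
        if np.any(~np.isfinite(v)) or np.ptp(v) == 0:
            return np.nan
        return np.corrcoef(v, y)[0, 1]

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                r = corr(np.where(S[:, j] != 0, S[:, i] / S[:, j], np.nan))
            if np.isfinite(r) and abs(r) > abs(best[0]) + 1e-15:
                best = (r, ("ratio", i, j))
    for i in range(n):
        for j in range(i + 1, n):
            den = S[:, i] + S[:, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                r = corr(np.where(den != 0, (S[:, i] - S[:, j]) / den, np.nan))
            if np.isfinite(r) and abs(r) > abs(best[0]) + 1e-15:
                best = (r, ("nd", i, j))
    return best


class TestExhaustiveSearch:
    def test_planted_ratio_recovered(self):
        rng = np.random.default_rng(0)
        wl = np.linspace(500, 2400, 15)
        S = rng.uniform(0.1, 0.6, (50, 15))
        y = S[:, 8] / S[:, 3]
        res = exhaustive_pair_search(wl, S, y)
        assert abs(res.correlation) == pytest.approx(1.0, abs=1e-12)
        bands = sorted(b.lo for b in res.definition.bands())
        assert bands == sorted([wl[8], wl[3]])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        wl = np.linspace(500, 2400, 10)
        S = rng.uniform(0.05, 0.7, (30, 10))
        y = rng.normal(size=30)
        res = exhaustive_pair_search(wl, S, y)
        r_oracle, combo = brute_force_pair_search(wl, S, y)
        assert res.correlation == pytest.approx(r_oracle, abs=1e-12)
        kind, i, j = combo
        got = sorted({b.lo for b in res.definition.bands()})
        assert got == sorted({wl[i], wl[j]})

    def test_normalized_difference_sign_symmetry(self):
        rng = np.random.default_rng(3)
        wl = np.linspace(500, 2400, 12)
        S = rng.uniform(0.1, 0.6, (40, 12))
        y = -(S[:, 5] - S[:, 9]) / (S[:, 5] + S[:, 9])
        res = exhaustive_pair_search(wl, S, y)
        assert res.correlation == pytest.approx(-1.0, abs=1e-12)
        assert "NDI" in res.definition.name

    def test_search_respects_wavelength_window(self):
        rng = np.random.default_rng(4)
        wl = np.concatenate([[400.0, 450.0], np.linspace(500, 2400, 10), [2490.0]])
        S = rng.uniform(0.1, 0.6, (30, wl.size))
        y = S[:, 0] * 2.0  # signal planted on an excluded band
        res = exhaustive_pair_search(wl, S, y)
        for b in res.definition.bands():
            assert SEARCH_RANGE_NM[0] <= b.lo <= SEARCH_RANGE_NM[1]

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            exhaustive_pair_search(
                np.linspace(500, 600, 4), np.random.default_rng(0).random((5, 4)),
                np.ones(5),
            )


class TestGreedyBuilder:
    def test_single_band_trait_stops_at_one_band(self):
        rng = np.random.default_rng(0)
        wl = np.linspace(500, 2400, 20)
        S = rng.uniform(0.1, 0.6, (60, 20))
        y = S[:, 4] + 0.01 * rng.normal(size=60)
        res = greedy_index_builder(wl, S, y)
        assert len({b.lo for b in res.definition.bands()}) == 1
        assert len(res.search_trace) == 1

    def test_reachable_three_band_expression(self):
        """trait = (rho_a + rho_b)/rho_c is reachable in three greedy steps
        when rho_a dominates the signal."""
        rng = np.random.default_rng(5)
        n = 60
        a = rng.uniform(0.2, 0.8, n)
        b = rng.uniform(0.3, 0.5, n)
        c = 0.50 + 0.005 * rng.uniform(size=n)
        S = rng.uniform(0.1, 0.6, (n, 8))
        S[:, 2], S[:, 5], S[:, 6] = a, b, c
        wl = np.linspace(500, 2400, 8)
        y = (a + b) / c
        res = greedy_index_builder(wl, S, y, tol=1e-6)
        assert abs(res.correlation) >= 1.0 - 1e-9
        assert len({bb.lo for bb in res.definition.bands()}) <= 3

    def test_trace_monotone_and_beats_single_band(self):
        rng = np.random.default_rng(6)
        wl = np.linspace(500, 2400, 15)
        S = rng.uniform(0.1, 0.6, (50, 15))
        y = S[:, 2] / S[:, 11] + 0.05 * rng.normal(size=50)
        res = greedy_index_builder(wl, S, y)
        trace = res.search_trace
        assert np.all(np.diff(trace) >= 0)
        best_single = max(
            abs(np.corrcoef(S[:, j], y)[0, 1]) for j in range(15)
        )
        assert abs(res.correlation) >= best_single - 1e-12

    def test_max_four_distinct_bands(self):
        rng = np.random.default_rng(7)
        wl = np.linspace(500, 2400, 25)
        S = rng.uniform(0.1, 0.6, (80, 25))
        y = (S[:, 1] + S[:, 5]) * S[:, 9] / S[:, 13] + 0.01 * rng.normal(size=80)
        res = greedy_index_builder(wl, S, y, tol=1e-6)
        assert len({b.lo for b in res.definition.bands()}) <= 4

    def test_rmcorr_kind_requires_subjects(self):
        rng = np.random.default_rng(8)
        wl = np.linspace(500, 2400, 5)
        S = rng.random((12, 5))
        with pytest.raises(ValueError, match="subject"):
            greedy_index_builder(wl, S, rng.normal(size=12),
                                 correlation_kind="rmcorr")
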