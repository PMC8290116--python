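"""Patterson's D, f_dM, D_XY, RND, the block jackknife and outlier flags."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from cladesv import introgression_stats as ist
from cladesv import synthetic_data as sd

ABBA = (0, 1, 1, 0)
BABA = (1, 0, 1, 0)


class TestPattersonD:
    def test_pure_abba_site(self, site_frame):
        assert ist.patterson_d(site_frame([ABBA])) == 1.0

    def test_equal_ingroup_frequencies_give_zero(self, site_frame):
        sites = site_frame([(0.3, 0.3, 0.8, 0.0), (0.7, 0.7, 0.5, 0.1)])
        assert ist.patterson_d(sites) == pytest.approx(0.0)

    def test_fixed_pattern_arithmetic(self, site_frame):
        sites = site_frame([ABBA, ABBA, ABBA, BABA])
        assert ist.patterson_d(sites) == pytest.approx(0.5)

    def test_empty_site_set_is_undefined(self, site_frame):
        assert ist.patterson_d(site_frame([])) is None
        assert ist.patterson_d(site_frame([(0, 0, 0, 0)])) is None

    def test_matches_brute_force_enumeration_on_toys(self, rng):
        """Windowed D equals direct per-site weight enumeration (<=10 sites)."""
        for _ in range(25):
            n = int(rng.integers(1, 11))
            freqs = rng.random((n, 4))
            sites = pd.DataFrame(freqs, columns=["p1", "p2", "p3", "p4"])
            sites.insert(0, "pos", np.arange(1, n + 1))
            sites.insert(0, "chrom", "c")
            num = den = 0.0
            for p1, p2, p3, p4 in freqs:
                abba = (1 - p1) * p2 * p3 * (1 - p4)
                baba = p1 * (1 - p2) * p3 * (1 - p4)
                num += abba - baba
                den += abba + baba
            assert ist.patterson_d(sites) == pytest.approx(num / den, abs=1e-12)


class TestFdm:
    def test_pure_abba_window(self, site_frame):
        assert ist.f_dm(site_frame([ABBA] * 5)) == pytest.approx(1.0)

    def test_pure_baba_window_is_minus_one(self, site_frame):
        assert ist.f_dm(site_frame([BABA] * 5)) == pytest.approx(-1.0)

    def test_no_shared_derived_alleles_gives_zero(self, site_frame):
        sites = site_frame([(0, 0, 1, 0), (0, 0, 1, 0)])
        assert ist.f_dm(sites) == pytest.approx(0.0)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            freqs = rng.random((40, 4))
            sites = pd.DataFrame(freqs, columns=["p1", "p2", "p3", "p4"])
            val = ist.f_dm(sites)
            d = ist.patterson_d(sites)
            assert -1.0 - 1e-12 <= val <= 1.0 + 1e-12
            assert -1.0 - 1e-12 <= d <= 1.0 + 1e-12

    def test_swapping_ingroups_negates_d_and_fdm(self, rng):
        freqs = rng.random((60, 4))
        sites = pd.DataFrame(freqs, columns=["p1", "p2", "p3", "p4"])
        swapped = sites.rename(columns={"p1": "p2", "p2": "p1"})
        assert ist.patterson_d(swapped) == pytest.approx(-ist.patterson_d(sites), abs=1e-12)
        assert ist.f_dm(swapped) == pytest.approx(-ist.f_dm(sites), abs=1e-12)


class TestDxy:
    def test_fixed_differences(self):
        p_a = [1] * 5 + [0] * 45
        p_b = [0] * 50
        assert ist.dxy(p_a, p_b) == pytest.approx(0.1)

    def test_identical_fixed_populations(self):
        assert ist.dxy([1, 1, 0], [1, 1, 0]) == 0.0

    def test_shared_intermediate_frequency(self):
        assert ist.dxy([0.5], [0.5]) == pytest.approx(0.5)

    def test_no_sites_is_missing(self):
        assert ist.dxy([], []) is None

    def test_bounded_in_unit_interval(self, rng):
        a, b = rng.random(100), rng.random(100)
        assert 0.0 <= ist.dxy(a, b) <= 1.0


class TestRnd:
    def test_ratio(self):
        assert ist.rnd(0.02, 0.04) == pytest.approx(0.5)

    def test_equal_divergences(self):
        assert ist.rnd(0.03, 0.03) == 1.0

    def test_zero_denominator_missing(self):
        assert ist.rnd(0.02, 0.0) is None
        assert ist.rnd(None, 0.04) is None


class TestBlockJackknife:
    def test_matches_hand_evaluated_delete_one(self, site_frame):
        """Weighted delete-one evaluated step by step on 3 blocks."""
        patterns = [ABBA] * 6 + [BABA] * 2 + [ABBA] * 3 + [BABA] * 3 + [ABBA] * 5
        sites = site_frame(patterns, spacing=400_000)  # → blocks of 2-3 sites
        block_size = 1_000_000
        jk = ist.block_jackknife(sites, block_size=block_size)

        # oracle: accumulate per-block numerator/denominator directly
        blocks = {}
        for _, row in sites.iterrows():
            key = (row["pos"] - 1) // block_size
            abba = (1 - row.p1) * row.p2 * row.p3 * (1 - row.p4)
            baba = row.p1 * (1 - row.p2) * row.p3 * (1 - row.p4)
            num, den = blocks.get(key, (0.0, 0.0))
            blocks[key] = (num + abba - baba, den + abba + baba)
        nums = np.array([blocks[k][0] for k in sorted(blocks)])
        dens = np.array([blocks[k][1] for k in sorted(blocks)])
        g = len(nums)
        theta = nums.sum() / dens.sum()
        loo = (nums.sum() - nums) / (dens.sum() - dens)
        h = dens.sum() / dens
        theta_j = g * theta - float(((1 - dens / dens.sum()) * loo).sum())
        pseudo = h * theta - (h - 1) * loo
        var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1)) / g)
        assert jk.n_blocks == g >= 3
        assert jk.D == pytest.approx(theta, abs=1e-12)
        assert jk.se == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_identical_blocks_degenerate(self, site_frame):
        patterns = ([ABBA] * 3 + [BABA]) * 4
        sites = site_frame(patterns, spacing=250_000)
        with pytest.warns(UserWarning, match="degenerate"):
            jk = ist.block_jackknife(sites, block_size=1_000_000)
        assert jk.se == 0.0 and jk.p == 0.0

    def test_single_block_errors(self, site_frame):
        with pytest.raises(ValueError, match="2 nonempty blocks"):
            ist.block_jackknife(site_frame([ABBA] * 5, spacing=10))

    def test_null_calibration_rejection_rate(self):
        """Without introgression, |Z| > 1.96 in ≈5% of replicates and the
        genome-wide D is centred on zero."""
        chroms = {"chr1": 20_000_000, "chr2": 20_000_000}
        hits = 0
        ds, ses = [], []
        for rep in range(60):
            sites, _ = sd.simulate_sites(chroms, sites_per_mb=600, seed=500 + rep)
            jk = ist.block_jackknife(sites)
            ds.append(jk.D)
            ses.append(jk.se)
            hits += abs(jk.z) > 1.96
        # binomial(60, 0.05) central 95% range
        assert 0 <= hits <= 8
        assert abs(np.mean(ds)) < 2 * np.std(ds) / np.sqrt(len(ds))


class TestFlagOutliers:
    def test_constant_series_unflagged(self):
        assert not ist.flag_outliers([3.0] * 10).any()

    def test_four_sd_value_flagged(self, rng):
        base = rng.normal(0, 1.0, size=200)
        values = np.append(base, base.mean() + 4.5 * base.std())
        flags = ist.flag_outliers(values)
        assert flags[-1]

    def test_exactly_three_sd_not_flagged(self):
        base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 10)

        def gap(x):
            arr = np.append(base, x)
            return x - (arr.mean() + 3 * arr.std(ddof=0))

        x0 = brentq(gap, 0.0, 100.0)
        flags = ist.flag_outliers(np.append(base, x0 - 1e-9))
        assert not flags[-1]                       # strictly outside only
        flags_hi = ist.flag_outliers(np.append(base, x0 * 1.01))
        assert flags_hi[-1]

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            ist.flag_outliers([1.0])


class TestWindowStatistics:
    def test_min_informative_sites_boundary(self, site_frame):
        """99 informative sites → window absent; 100 → present."""
        for n, present in [(99, False), (100, True)]:
            patterns = [ABBA] * n
            sites = site_frame(patterns, spacing=1)  # all in the first window
            out = ist.window_statistics(sites, d_window=1_000_000, fdm_window=100_000, min_sites=100)
            assert (len(out["d_windows"]) == 1) is present
            assert (len(out["fdm_windows"]) == 1) is present

    def test_planted_tract_recovery(self):
        """A full-replacement donor-P3→P2 tract yields f_dM-positive,
        RND-reduced outlier windows exactly at the tract."""
        tract = {"chrom": "chr2", "start": 2_000_000, "end": 2_500_000, "gamma": 1.0}
        chroms = {"chr1": 5_000_000, "chr2": 5_000_000}
        sites, _ = sd.simulate_sites(chroms, sites_per_mb=3_000, tracts=[tract], seed=11)
        out = ist.window_statistics(sites, min_sites=50)
        fw = out["fdm_windows"]
        inside = fw[(fw.chrom == "chr2") & (fw.start >= tract["start"]) & (fw.end <= tract["end"])]
        outside = fw.drop(inside.index)
        assert len(inside) == 5
        assert inside["f_dM_outlier"].all()
        assert inside["rnd_outlier"].all()
        assert (inside["rnd_p2"].to_numpy() < outside["rnd_p2"].median()).all()
        assert not outside["f_dM_outlier"].any()

    def test_gamma_zero_keeps_d_windows_centred(self):
        sites, _ = sd.simulate_sites({"chr1": 10_000_000}, sites_per_mb=1_500, seed=21)
        out = ist.window_statistics(sites, min_sites=100)
        d = out["d_windows"]["D"]
        assert len(d) == 10
        assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d))
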