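"""Windowed statistics against brute-force enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divergekit import scanstats as sc
from divergekit import simtruth as st
from divergekit import demography as dm
from divergekit.variants import MISSING

from conftest import make_table


# ---------------------------------------------------------------------------
# Brute-force oracles: explicit enumeration over allele copies / pairs
# ---------------------------------------------------------------------------

def brute_pi_site(k, n):
    """Mean pairwise difference at one site by enumerating allele-copy pairs."""
    copies = [1] * int(k) + [0] * int(n - k)
    pairs = list(itertools.combinations(copies, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_dxy_site(kA, nA, kB, nB):
    """Mean between-population difference by enumerating cross pairs."""
    a = [1] * int(kA) + [0] * int(nA - kA)
    b = [1] * int(kB) + [0] * int(nB - kB)
    return sum(x != y for x in a for y in b) / (len(a) * len(b))


def brute_fst_window(sites):
    """Hudson ratio-of-sums from per-site pair enumeration.

    sites: list of (kA, nA, kB, nB).
    """
    hw = [0.5 * (brute_pi_site(kA, nA) + brute_pi_site(kB, nB))
          for kA, nA, kB, nB in sites]
    hb = [brute_dxy_site(*s) for s in sites]
    return 1.0 - sum(hw) / sum(hb) if sum(hb) > 0 else np.nan


def brute_r2(x, y):
    """Squared Pearson correlation via the textbook sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    return num * num / den if den > 0 else np.nan


def brute_zz(dosages):
    """ZA - ZnS by exhaustive pair enumeration over polymorphic sites."""
    poly = [row for row in dosages if len(set(row)) > 1]
    m = len(poly)
    if m < 3:
        return np.nan
    allp = [brute_r2(poly[i], poly[j]) for i in range(m) for j in range(i + 1, m)]
    adj = [brute_r2(poly[i], poly[i + 1]) for i in range(m - 1)]
    return np.nanmean(adj) - np.nanmean(allp)


def brute_tajima_d(site_counts, n):
    """Tajima's D from an independent implementation of the constants."""
    seg = [k for k in site_counts if 0 < k < n]
    S = len(seg)
    if S == 0:
        return np.nan
    pi = sum(brute_pi_site(k, n) for k in seg)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def windows_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestDiversityAndD:
    def test_single_site_theta_pi(self):
        # one site with 2 derived of n=4 in a 10-bp window:
        # brute force over all 6 haplotype pairs gives 4/6 per site
        table = make_table([[1, 1]], positions=[3])
        w = windows_df([("chr1", 0, 10)])
        out = sc.diversity_and_d(table, w, "pop")
        assert out["theta_pi"].iloc[0] == pytest.approx(brute_pi_site(2, 4) / 10)
        assert out["theta_pi"].iloc[0] == pytest.approx(0.066667, abs=1e-5)

    def test_monomorphic_window(self):
        table = make_table([[0, 0]], positions=[3])
        out = sc.diversity_and_d(table, windows_df([("chr1", 0, 10)]), "pop")
        assert out["theta_pi"].iloc[0] == 0.0
        assert np.isnan(out["tajima_d"].iloc[0])

    def test_singleton_matches_tajima_constants(self):
        table = make_table([[1, 0]], positions=[5])
        out = sc.diversity_and_d(table, windows_df([("chr1", 0, 10)]), "pop")
        assert out["tajima_d"].iloc[0] == pytest.approx(brute_tajima_d([1], 4), abs=1e-12)

    def test_incomplete_sites_excluded(self):
        g = np.array([[1, 0], [1, MISSING]], dtype=np.int8)
        table = make_table(g, positions=[2, 5])
        out = sc.diversity_and_d(table, windows_df([("chr1", 0, 10)]), "pop")
        assert out["n_sites"].iloc[0] == 1


class TestFstDxy:
    def _paired_table(self, rowsA, rowsB):
        g = np.concatenate([np.array(rowsA), np.array(rowsB)], axis=1)
        return make_table(g, populations=["A"] * len(rowsA[0]) + ["B"] * len(rowsB[0]))

    def test_fixed_difference(self):
        table = self._paired_table([[0, 0]], [[2, 2]])
        out = sc.fst_dxy(table, windows_df([("chr1", 0, 10)]), "A", "B")
        assert out["fst"].iloc[0] == pytest.approx(1.0)
        assert out["dxy"].iloc[0] == pytest.approx(1.0 / 10)

    def test_identical_frequencies(self):
        # exactly zero under the plug-in estimator; the unbiased default is
        # negative at identical *sample* frequencies (within-pop diversity
        # corrected upward) but centred on zero under panmixia
        table = self._paired_table([[1, 1]], [[1, 1]])
        w = windows_df([("chr1", 0, 10)])
        out = sc.fst_dxy(table, w, "A", "B", estimator="plugin")
        assert out["fst"].iloc[0] == pytest.approx(0.0)
        assert sc.fst_dxy(table, w, "A", "B")["fst"].iloc[0] < 0.0

    def test_dxy_invariant_fst_sensitive_to_within_pop_arrangement(self):
        # same per-site frequencies, different genotype arrangements:
        # d_XY depends only on frequencies, Hudson F_ST does not change
        # either (it is frequency-based) -- but within-pop heterozygosity
        # changes if the frequency itself changes; construct the contrast
        t1 = self._paired_table([[1, 1]], [[2, 0]])   # freqs 0.5 / 0.5
        t2 = self._paired_table([[2, 0]], [[2, 0]])   # same freqs, rearranged
        w = windows_df([("chr1", 0, 10)])
        d1 = sc.fst_dxy(t1, w, "A", "B")["dxy"].iloc[0]
        d2 = sc.fst_dxy(t2, w, "A", "B")["dxy"].iloc[0]
        assert d1 == pytest.approx(d2)
        t3 = self._paired_table([[1, 1]], [[1, 1]])   # freq 0.5 vs 0.25+...
        t4 = self._paired_table([[2, 2]], [[1, 1]])   # pop A freq 1.0
        f3 = sc.fst_dxy(t3, w, "A", "B")["fst"].iloc[0]
        f4 = sc.fst_dxy(t4, w, "A", "B")["fst"].iloc[0]
        assert f3 != f4


class TestLd:
    def test_identical_dosages_r2_one(self):
        table = make_table([[0, 1, 2, 1], [0, 1, 2, 1]], positions=[2, 5])
        assert sc.geno_r2(table, 0, 1) == pytest.approx(1.0)

    def test_all_equal_pairwise_r2_gives_zero_zz(self):
        # three sites with identical dosage vectors: every r2 = 1, ZA = ZnS
        table = make_table([[0, 1, 2, 1]] * 3, positions=[2, 5, 8])
        assert sc.zz(table, [0, 1, 2]) == pytest.approx(0.0)

    def test_four_site_hand_case_matches_enumeration(self):
        rows = [[0, 1, 2, 1, 0], [2, 1, 0, 1, 2], [0, 0, 1, 2, 2], [1, 2, 0, 0, 1]]
        table = make_table(rows, positions=[2, 5, 8, 11])
        assert sc.zz(table, [0, 1, 2, 3]) == pytest.approx(brute_zz(rows), abs=1e-12)

    def test_fewer_than_three_polymorphic_sites(self):
        table = make_table([[1, 1, 1, 1], [0, 1, 2, 1]], positions=[2, 5])
        assert np.isnan(sc.zz(table, [0, 1]))


class TestOracleEquivalence:
    def test_hundred_random_windows(self):
        # theta-pi, d_XY, F_ST, r2 and ZZ all match exhaustive brute-force
        # enumeration to 1e-12 on random small windows
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n_sites = rng.integers(3, 7)
            nA = nB = 3  # diploids per population
            gA = rng.integers(0, 3, size=(n_sites, nA))
            gB = rng.integers(0, 3, size=(n_sites, nB))
            g = np.concatenate([gA, gB], axis=1)
            table = make_table(
                g, positions=np.arange(1, n_sites + 1) * 3,
                populations=["A"] * nA + ["B"] * nB)
            w = windows_df([("chr1", 0, 30)])

            # theta-pi (population A)
            out = sc.diversity_and_d(table, w, "A")
            kA = gA.sum(axis=1)
            pi = sum(brute_pi_site(k, 2 * nA) for k in kA if 0 < k < 2 * nA)
            assert out["theta_pi"].iloc[0] == pytest.approx(pi / 30, abs=1e-12)
            # Tajima's D
            expected_d = brute_tajima_d(list(kA), 2 * nA)
            got_d = out["tajima_d"].iloc[0]
            if np.isnan(expected_d):
                assert np.isnan(got_d)
            else:
                assert got_d == pytest.approx(expected_d, abs=1e-12)

            # F_ST / d_XY
            fd = sc.fst_dxy(table, w, "A", "B")
            sites = [(gA[i].sum(), 2 * nA, gB[i].sum(), 2 * nB) for i in range(n_sites)]
            dxy = sum(brute_dxy_site(*s) for s in sites) / 30
            assert fd["dxy"].iloc[0] == pytest.approx(dxy, abs=1e-12)
            expected_fst = brute_fst_window(sites)
            if np.isnan(expected_fst):
                assert np.isnan(fd["fst"].iloc[0])
            else:
                assert fd["fst"].iloc[0] == pytest.approx(expected_fst, abs=1e-12)

            # r2 and ZZ
            r2 = sc.geno_r2(table, 0, 1)
            expected_r2 = brute_r2(list(g[0].astype(float)), list(g[1].astype(float)))
            if np.isnan(expected_r2):
                assert np.isnan(r2)
            else:
                assert r2 == pytest.approx(expected_r2, abs=1e-12)
            expected_zz = brute_zz([list(row) for row in g])
            got_zz = sc.zz(table, list(range(n_sites)))
            if np.isnan(expected_zz):
                assert np.isnan(got_zz)
            else:
                assert got_zz == pytest.approx(expected_zz, abs=1e-12)


class TestDaf:
    def _polarized(self, rows):
        recs = []
        for i, (d, c) in enumerate(rows):
            recs.append({"chrom": "chr1", "pos": i + 1, "usable": True,
                         "derived_E": d, "called_E": c})
        return pd.DataFrame(recs)

    def test_uniform_frequency(self):
        pol = self._polarized([(4, 16)] * 3)
        out = sc.mean_daf(windows_df([("chr1", 0, 10)]), pol, "E", min_genotyped=6)
        assert out["daf"].iloc[0] == pytest.approx(0.25)

    def test_fixed_derived_excluded(self):
        pol = self._polarized([(16, 16), (8, 16)])
        out = sc.mean_daf(windows_df([("chr1", 0, 10)]), pol, "E", min_genotyped=6)
        assert out["daf"].iloc[0] == pytest.approx(0.5)

    def test_arithmetic_mean(self):
        pol = self._polarized([(2, 16), (8, 16), (14, 16)])
        out = sc.mean_daf(windows_df([("chr1", 0, 10)]), pol, "E", min_genotyped=6)
        assert out["daf"].iloc[0] == pytest.approx(0.5)

    def test_undergenotyped_sites_excluded(self):
        pol = self._polarized([(2, 10), (8, 16)])  # 5 of 8 individuals < 6
        out = sc.mean_daf(windows_df([("chr1", 0, 10)]), pol, "E", min_genotyped=6)
        assert out["daf"].iloc[0] == pytest.approx(0.5)


class TestRhoThetaQuantiles:
    def test_constant_ratio_and_flat_profile(self):
        wt = windows_df([("chr1", i * 10, (i + 1) * 10) for i in range(10)])
        wt["theta_pi"] = 0.01
        rho = wt[["chrom", "start", "end"]].copy()
        rho["rho"] = 0.5
        merged = sc.rho_over_theta(rho, wt)
        assert (merged["rho_over_theta"] == 50.0).all()
        prof = sc.quantile_profile(np.full(10, 0.25), merged["rho_over_theta"])
        assert np.allclose(prof["mean_stat"], 0.25)

    def test_zero_theta_window_missing(self):
        wt = windows_df([("chr1", 0, 10), ("chr1", 10, 20)])
        wt["theta_pi"] = [0.0, 0.01]
        rho = wt[["chrom", "start", "end"]].copy()
        rho["rho"] = 1.0
        merged = sc.rho_over_theta(rho, wt)
        assert np.isnan(merged["rho_over_theta"].iloc[0])

    def test_hand_set_bins(self):
        cond = np.arange(10, dtype=float)
        stat = np.arange(10, dtype=float) * 2
        prof = sc.quantile_profile(stat, cond, n_quantiles=5)
        assert list(prof["mean_stat"]) == [1.0, 5.0, 9.0, 13.0, 17.0]
        assert list(prof["n_windows"]) == [2] * 5

    def test_fewer_windows_than_quantiles(self):
        with pytest.raises(ValueError):
            sc.quantile_profile([1.0, 2.0], [1.0, 2.0], n_quantiles=5)


class TestIslandsAndCorrelation:
    def test_anticorrelated_statistics_give_twenty_islands(self):
        wt = windows_df([("chr1", i * 10, (i + 1) * 10) for i in range(100)])
        wt["fst"] = np.arange(100, dtype=float)
        wt["dxy"] = -np.arange(100, dtype=float)
        islands = sc.island_windows(wt)
        assert len(islands) == 20
        assert (islands["fst"] >= 80).all()

    def test_spearman_extremes(self):
        x = np.arange(50, dtype=float)
        rho, _ = sc.correlate_windows(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = sc.correlate_windows(x, np.exp(-x))
        assert rho == pytest.approx(-1.0)


class TestWindowsAndMask:
    def test_masked_windows_dropped_entirely(self):
        w = sc.make_windows({"chr1": 100}, 25)
        assert len(w) == 4
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [30], "end": [55]})
        kept = sc.drop_masked_windows(w, mask)
        assert list(kept["start"]) == [0, 75]


class TestNeutralCalibrationAndRho:
    def test_zz_tracks_recombination_heterogeneity(self):
        # windows simulated under heterogeneous rho: ZZ correlates
        # positively with the true window rho
        n_loci = 220
        rng = np.random.default_rng(77)
        rates = 10 ** rng.uniform(-9.2, -6.8, n_loci)
        m = dm.DemographicModel.from_name("SI", {"nu1": 1.0, "nu2": 1.0, "t_iso": 5.0})
        tab, truth = st.simulate_pair_dataset(
            m, 8, 0, n_loci, locus_length=5000, seed=78, recombination_rate=rates)
        lengths = {c: 5000 for c in truth.window_rho["chrom"]}
        windows = sc.make_windows(lengths, 5000)
        zz_table = sc.zz_per_window(tab, windows, population="pop1")
        merged = zz_table.merge(truth.window_rho, on=["chrom", "start", "end"])
        rho_stat, p = sc.correlate_windows(merged["zz"], merged["rho"])
        assert rho_stat > 0.3
        assert p < 0.01
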