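"""Windowed population-genetic statistics and linked-selection contrasts.

Per non-overlapping window: nucleotide diversity (theta-pi per bp), Tajima's
D, Hudson F_ST and d_XY between population pairs, the ZZ linkage statistic
(mean adjacent-pair genotype r^2 minus mean all-pair r^2), mean derived
allele frequency (DAF), and, given a windowed population recombination rate
rho, the diversity-rescaled ratio rho/theta-pi (an approximation to r/mu).

Windows are 0-based half-open; a site at 1-based VCF position p belongs to
the window containing p-1.  Windows overlapping any mask interval are
dropped entirely.  Within-population statistics use sites with complete
genotypes in the focal population; between-population statistics use
per-site called copies with at least two complete haplotype calls per
population.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .variants import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Windows and masking
# ---------------------------------------------------------------------------

def chrom_lengths_from_table(table: GenotypeTable) -> dict:
    """Infer chromosome lengths as the maximum observed position."""
    return table.sites.groupby("chrom", sort=False)["pos"].max().to_dict()


def make_windows(chrom_lengths: dict, size: int) -> pd.DataFrame:
    """Non-overlapping windows of ``size`` bp tiling each chromosome."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(np.ceil(length / size)) * size, size):
            rows.append((chrom, start, start + size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def drop_masked_windows(windows: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Remove windows overlapping any mask interval (both 0-based half-open)."""
    keep = np.ones(len(windows), dtype=bool)
    for chrom, grp in mask.groupby("chrom"):
        sel = windows["chrom"] == chrom
        if not sel.any():
            continue
        w = windows[sel]
        overlap = np.zeros(len(w), dtype=bool)
        for _, m in grp.iterrows():
            overlap |= (w["start"].to_numpy() < m["end"]) & (w["end"].to_numpy() > m["start"])
        keep[np.flatnonzero(sel.to_numpy())[overlap]] = False
    return windows[keep].reset_index(drop=True)


def _window_site_indices(table: GenotypeTable, windows: pd.DataFrame):
    """Yield (window row index, site index array) pairs."""
    pos0 = table.sites["pos"].to_numpy() - 1  # 0-based
    chroms = table.sites["chrom"].to_numpy()
    for wi, row in windows.iterrows():
        sel = np.flatnonzero(
            (chroms == row["chrom"]) & (pos0 >= row["start"]) & (pos0 < row["end"]))
        yield wi, sel


# ---------------------------------------------------------------------------
# Diversity and Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int):
    """a1, a2, b1, b2, c1, c2, e1, e2 for a haploid sample size n."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _complete_pop_dosage(table: GenotypeTable, population: str):
    """Dosage rows of sites fully genotyped in the focal population, plus
    the site-selection mask and haploid n."""
    idx = table.population_indices(population)
    g = table.genotypes[:, idx]
    complete = (g != MISSING).all(axis=1)
    return g, complete, 2 * len(idx)


def diversity_and_d(table: GenotypeTable, windows: pd.DataFrame, population: str) -> pd.DataFrame:
    """theta-pi per bp and Tajima's D per window for one population.

    theta-pi is the mean number of pairwise differences per site,
    ``sum_sites 2 i (n - i) / (n (n - 1))`` over complete segregating
    sites, divided by the window length.  D uses the Tajima (1989)
    normalizing constants; with no segregating site D is undefined (NaN).
    """
    g, complete, n = _complete_pop_dosage(table, population)
    alt = np.where(g == MISSING, 0, g).sum(axis=1)
    a1, e1, e2 = _tajima_constants(n)

    out = windows.copy()
    theta = np.zeros(len(windows))
    taj = np.full(len(windows), np.nan)
    nsites = np.zeros(len(windows), dtype=int)
    for wi, sel in _window_site_indices(table, windows):
        sel = sel[complete[sel]]
        i = alt[sel]
        seg = (i > 0) & (i < n)
        i = i[seg]
        S = len(i)
        nsites[wi] = S
        length = windows["end"].iloc[wi] - windows["start"].iloc[wi]
        pi_sum = np.sum(2.0 * i * (n - i) / (n * (n - 1.0)))
        theta[wi] = pi_sum / length
        if S > 0:
            var = e1 * S + e2 * S * (S - 1)
            taj[wi] = (pi_sum - S / a1) / np.sqrt(var)
    out["theta_pi"] = theta
    out["tajima_d"] = taj
    out["n_sites"] = nsites
    return out


# ---------------------------------------------------------------------------
# Differentiation: Hudson F_ST and d_XY
# ---------------------------------------------------------------------------

def _pop_counts(table: GenotypeTable, population: str):
    idx = table.population_indices(population)
    g = table.genotypes[:, idx]
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=1)
    n = 2 * called.sum(axis=1)
    return alt.astype(float), n.astype(float)


def _site_h_components(kA, nA, kB, nB, estimator="hudson"):
    """Per-site within- and between-population heterozygosity.

    ``estimator="hudson"`` uses the unbiased within-population form
    2k(n-k)/(n(n-1)) (Hudson's F_ST as popularised by Bhatia et al.);
    ``"plugin"`` uses sample-frequency heterozygosity 2p(1-p), which gives
    exactly 0 for identical sample frequencies but is biased upward by
    ~1/n in small samples.  The between-population term is the mean
    cross-population difference in either case.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if estimator == "hudson":
            hwA = 2.0 * kA * (nA - kA) / (nA * (nA - 1.0))
            hwB = 2.0 * kB * (nB - kB) / (nB * (nB - 1.0))
        elif estimator == "plugin":
            hwA = 2.0 * kA * (nA - kA) / (nA * nA)
            hwB = 2.0 * kB * (nB - kB) / (nB * nB)
        else:
            raise ValueError(f"unknown F_ST estimator {estimator!r}")
        hb = (kA * (nB - kB) + kB * (nA - kA)) / (nA * nB)
    hw = 0.5 * (hwA + hwB)
    return hw, hb


def fst_dxy(table: GenotypeTable, windows: pd.DataFrame, popA: str, popB: str,
            estimator: str = "hudson") -> pd.DataFrame:
    """Hudson F_ST (ratio-of-sums 1 - Hw/Hb) and d_XY per bp per window.

    Hw is the average of the two within-population heterozygosities (see
    :func:`_site_h_components` for the estimator choice) and Hb the mean
    between-population difference; both are summed over the window's
    usable sites before taking the ratio.  Windows with a zero
    between-population sum get missing F_ST.
    """
    kA, nA = _pop_counts(table, popA)
    kB, nB = _pop_counts(table, popB)
    usable = (nA >= 2) & (nB >= 2)
    hw, hb = _site_h_components(kA, nA, kB, nB, estimator)

    out = windows.copy()
    fst = np.full(len(windows), np.nan)
    dxy = np.zeros(len(windows))
    for wi, sel in _window_site_indices(table, windows):
        sel = sel[usable[sel]]
        length = windows["end"].iloc[wi] - windows["start"].iloc[wi]
        sw, sb = np.nansum(hw[sel]), np.nansum(hb[sel])
        dxy[wi] = sb / length
        if sb > 0:
            fst[wi] = 1.0 - sw / sb
    out["fst"] = fst
    out["dxy"] = dxy
    return out


# ---------------------------------------------------------------------------
# LD: genotype r^2 and the ZZ statistic
# ---------------------------------------------------------------------------

def geno_r2(table: GenotypeTable, site_i: int, site_j: int, sample_index=None) -> float:
    """Squared Pearson correlation of alt-dosage vectors at two sites
    (genotype-r^2 on unphased data), over samples called at both."""
    gi = table.genotypes[site_i]
    gj = table.genotypes[site_j]
    if sample_index is not None:
        gi, gj = gi[sample_index], gj[sample_index]
    ok = (gi != MISSING) & (gj != MISSING)
    return _dosage_r2(gi[ok].astype(float), gj[ok].astype(float))


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return np.nan
    vx = x - x.mean()
    vy = y - y.mean()
    den = np.sqrt((vx**2).sum() * (vy**2).sum())
    if den == 0:
        return np.nan
    return float(((vx * vy).sum() / den) ** 2)


def zz(table: GenotypeTable, window_sites, population=None) -> float:
    """ZZ = ZA - ZnS over a window's polymorphic sites.

    ZA is the mean genotype-r^2 over adjacent polymorphic pairs (position
    order) and ZnS the mean over all pairs; at least 3 polymorphic sites
    are required (else NaN).  Elevated ZZ indicates intra-window
    recombination: adjacent LD stays high while overall LD decays.
    """
    idx = (table.population_indices(population) if population is not None
           else np.arange(table.n_samples))
    sel = np.asarray(window_sites)
    g = table.genotypes[np.ix_(sel, idx)].astype(float)
    g[g == MISSING] = np.nan
    poly = np.array([len(np.unique(row[~np.isnan(row)])) > 1 for row in g])
    g = g[poly]
    m = len(g)
    if m < 3:
        return np.nan
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(g[i]) & ~np.isnan(g[j])
            r2[i, j] = _dosage_r2(g[i][ok], g[j][ok])
    adj = np.array([r2[i, i + 1] for i in range(m - 1)])
    allp = r2[np.triu_indices(m, 1)]
    za = np.nanmean(adj)
    zns = np.nanmean(allp)
    return float(za - zns)


def zz_per_window(table: GenotypeTable, windows: pd.DataFrame, population=None) -> pd.DataFrame:
    out = windows.copy()
    vals = np.full(len(windows), np.nan)
    for wi, sel in _window_site_indices(table, windows):
        if len(sel):
            vals[wi] = zz(table, sel, population)
    out["zz"] = vals
    return out


# ---------------------------------------------------------------------------
# Derived allele frequencies
# ---------------------------------------------------------------------------

def mean_daf(
    windows: pd.DataFrame,
    polarized_sites: pd.DataFrame,
    population: str,
    min_genotyped: int = 6,
) -> pd.DataFrame:
    """Mean derived allele frequency per window in the focal population.

    Qualifying sites are usable polarized sites, polymorphic within the
    focal population, with at least ``min_genotyped`` individuals
    genotyped there.  Windows without qualifying sites get NaN.
    """
    df = polarized_sites[polarized_sites["usable"]]
    d = df[f"derived_{population}"].to_numpy(dtype=float)
    n = df[f"called_{population}"].to_numpy(dtype=float)
    ok = (n >= 2 * min_genotyped) & (d > 0) & (d < n)
    df = df[ok]
    freq = d[ok] / n[ok]
    pos0 = df["pos"].to_numpy() - 1
    chroms = df["chrom"].to_numpy()

    out = windows.copy()
    vals = np.full(len(windows), np.nan)
    for wi, row in windows.iterrows():
        sel = (chroms == row["chrom"]) & (pos0 >= row["start"]) & (pos0 < row["end"])
        if sel.any():
            vals[wi] = freq[sel].mean()
    out["daf"] = vals
    return out


# ---------------------------------------------------------------------------
# rho / theta, quantile profiles, islands, correlations
# ---------------------------------------------------------------------------

def rho_over_theta(window_rho: pd.DataFrame, window_table: pd.DataFrame) -> pd.DataFrame:
    """Merge a windowed rho table (chrom, start, end, rho) into the window
    table and add rho/theta-pi (missing where theta-pi is 0)."""
    merged = window_table.merge(window_rho, on=["chrom", "start", "end"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["rho_over_theta"] = np.where(
            merged["theta_pi"] > 0, merged["rho"] / merged["theta_pi"], np.nan)
    return merged


def quantile_profile(stat, conditioning_stat, n_quantiles: int = 5) -> pd.DataFrame:
    """Mean of ``stat`` across equal-count quantile bins of the
    conditioning statistic (windows with a missing value in either are
    excluded)."""
    stat = np.asarray(stat, dtype=float)
    cond = np.asarray(conditioning_stat, dtype=float)
    ok = ~np.isnan(stat) & ~np.isnan(cond)
    stat, cond = stat[ok], cond[ok]
    if len(cond) < n_quantiles:
        raise ValueError("fewer windows than quantiles")
    order = np.argsort(cond, kind="stable")
    rows = []
    for b, chunk in enumerate(np.array_split(order, n_quantiles)):
        rows.append({
            "quantile": b + 1,
            "n_windows": len(chunk),
            "mean_conditioning": cond[chunk].mean(),
            "mean_stat": stat[chunk].mean(),
        })
    return pd.DataFrame(rows)


def island_windows(
    window_table: pd.DataFrame,
    fst_col: str = "fst",
    dxy_col: str = "dxy",
    fst_quantile: float = 0.8,
    dxy_quantile: float = 0.2,
) -> pd.DataFrame:
    """Windows in the top F_ST quantile and the bottom d_XY quantile —
    candidates for high relative, low absolute divergence (strong linked
    selection)."""
    df = window_table.dropna(subset=[fst_col, dxy_col])
    fst_thr = np.quantile(df[fst_col], fst_quantile)
    dxy_thr = np.quantile(df[dxy_col], dxy_quantile)
    return df[(df[fst_col] >= fst_thr) & (df[dxy_col] <= dxy_thr)].reset_index(drop=True)


def correlate_windows(stat_a, stat_b):
    """Spearman rank correlation (average ranks for ties), NaNs dropped
    pairwise.  Returns (rho, p)."""
    a = np.asarray(stat_a, dtype=float)
    b = np.asarray(stat_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    res = spearmanr(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def scan(
    table: GenotypeTable,
    window_size: int,
    populations,
    pairs=None,
    mask: pd.DataFrame | None = None,
    window_rho: pd.DataFrame | None = None,
    polarized_sites: pd.DataFrame | None = None,
    daf_population: str | None = None,
    daf_min_genotyped: int = 6,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Full windowed scan: diversity and D per population, F_ST/d_XY per
    pair, ZZ, optional DAF and rho/theta-pi."""
    lengths = chrom_lengths or chrom_lengths_from_table(table)
    windows = make_windows(lengths, window_size)
    if mask is not None and len(mask):
        windows = drop_masked_windows(windows, mask)

    out = windows.copy()
    for pop in populations:
        dd = diversity_and_d(table, windows, pop)
        out[f"theta_pi_{pop}"] = dd["theta_pi"]
        out[f"tajima_d_{pop}"] = dd["tajima_d"]
    for popA, popB in (pairs or []):
        fd = fst_dxy(table, windows, popA, popB)
        out[f"fst_{popA}_{popB}"] = fd["fst"]
        out[f"dxy_{popA}_{popB}"] = fd["dxy"]
    out["zz"] = zz_per_window(table, windows)["zz"]
    if polarized_sites is not None and daf_population is not None:
        out["daf"] = mean_daf(windows, polarized_sites, daf_population,
                              min_genotyped=daf_min_genotyped)["daf"]
    if window_rho is not None:
        first_pop = populations[0]
        tmp = out.rename(columns={f"theta_pi_{first_pop}": "theta_pi"})
        merged = rho_over_theta(window_rho, tmp[["chrom", "start", "end", "theta_pi"]])
        out["rho"] = merged["rho"]
        out["rho_over_theta"] = merged["rho_over_theta"]
    return out


def write_window_table(window_table: pd.DataFrame, path) -> None:
    window_table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_islands_bed(islands: pd.DataFrame, path) -> None:
    islands[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)
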