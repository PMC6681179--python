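"""Effective sex ratios from autosome/X drift contrast on a three-leaf tree.

A hierarchical Bayesian model of SNP-frequency evolution along a rooted
population tree ((a, b), c).  Each branch carries an autosomal drift length
``tau = t / (2 Ne)``; drift over a branch is approximated by a truncated
Gaussian ("surface") kernel with variance ``tau * p * (1 - p)`` and the
excess mass absorbed at the frequency boundaries.  X-linked markers evolve on
the same tree with branch lengths tied by the female fraction ``xi``:

    tau_X = tau_A * (16 - 8 xi) / 9,

so a male-biased gene pool (xi < 0.5) inflates X-linked drift relative to
autosomal drift.  Posteriors over (tau, xi) per branch come from a
component-wise random-walk Metropolis sampler with pilot-run step
adaptation; the per-branch support statistic for a biased sex ratio is

    S = 1 - 2 |p - 0.5|,

with ``p`` the posterior fraction of samples with xi > 0.5 and small S
(below 0.05) read as strong support for a biased sex ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variants as vr

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-6   # floor on p(1-p) so boundary-frequency parents keep a proper kernel
_P_FLOOR = 1e-9     # floor on binomial success probabilities

TAU_PRIOR_MAX = 10.0


def tau_x_factor(xi) -> np.ndarray:
    """tau_X / tau_A = (16 - 8 xi) / 9; equals 4/3 at xi = 0.5."""
    return (16.0 - 8.0 * np.asarray(xi)) / 9.0


def drift_transition(p0: float, tau: float, grid: np.ndarray | None = None):
    """Truncated-Gaussian drift kernel for a descendant frequency.

    Returns ``(atom0, atom1, density)``: point masses absorbed at 0 and 1
    and, if ``grid`` is given, the Gaussian density evaluated on it.  With
    ``tau = 0`` or a boundary ``p0`` the kernel degenerates to a point mass.
    """
    from scipy.stats import norm

    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    var = tau * p0 * (1 - p0)
    if var == 0:
        atom0 = 1.0 if p0 == 0 else 0.0
        atom1 = 1.0 if p0 == 1 else 0.0
        dens = None if grid is None else np.zeros_like(grid, dtype=float)
        if grid is not None and 0 < p0 < 1:
            dens = np.where(np.isclose(grid, p0), np.inf, 0.0)
        return atom0, atom1, dens
    sd = np.sqrt(var)
    atom0 = norm.cdf(0.0, loc=p0, scale=sd)
    atom1 = norm.sf(1.0, loc=p0, scale=sd)
    dens = None if grid is None else norm.pdf(grid, loc=p0, scale=sd)
    return float(atom0), float(atom1), dens


@dataclass
class DriftTree:
    """Rooted three-leaf tree ((a, b), c) with per-branch drift and sex ratio.

    Branches are the three leaves plus the internal branch ``"ab"``; each
    carries an autosomal drift length ``tau_A`` and a female fraction
    ``xi``; the implied X-linked drift is ``tau_A * (16 - 8 xi)/9``.
    """

    leaves: tuple
    tau_a: dict
    xi: dict

    @property
    def branches(self) -> list:
        return [*self.leaves, "ab"]

    def tau_x(self, branch) -> float:
        return self.tau_a[branch] * float(tau_x_factor(self.xi[branch]))

    def validate(self) -> None:
        for br in self.branches:
            if self.tau_a.get(br, 0) <= 0:
                raise ValueError(f"tau_A must be positive on branch {br!r}")
            x = self.xi.get(br)
            if x is None or not 0 < x < 1:
                raise ValueError(f"xi must lie in (0, 1) on branch {br!r}")

    @classmethod
    def from_posterior(cls, posterior: "EsrPosterior") -> "DriftTree":
        """Posterior-median tree."""
        leaves = tuple(posterior.branches[:3])
        return cls(
            leaves=leaves,
            tau_a={br: posterior.median_tau(br) for br in posterior.branches},
            xi={br: posterior.median_xi(br) for br in posterior.branches},
        )


@dataclass
class McmcConfig:
    """Sampler schedule: pilot adaptation runs, main chain, thinning."""

    n_pilot: int = 25
    pilot_iters: int = 1000
    n_iter: int = 100_000
    burn_in: int = 50_000
    thin: int = 25
    target_acceptance: float = 0.35


#: a reduced schedule for quick runs / replicated analyses
FAST_MCMC = McmcConfig(n_pilot=6, pilot_iters=150, n_iter=5000, burn_in=2500, thin=3)


@dataclass
class EsrPosterior:
    """Posterior samples of per-branch drift and effective sex ratio."""

    branches: list
    tau_samples: np.ndarray  # (n_samples, n_branches)
    xi_samples: np.ndarray   # (n_samples, n_branches)
    rhat: dict = field(default_factory=dict)
    flagged: bool = False

    def branch_index(self, branch) -> int:
        return self.branches.index(branch)

    def p_biased(self, branch) -> float:
        """Posterior fraction of samples with xi > 0.5."""
        return float((self.xi_samples[:, self.branch_index(branch)] > 0.5).mean())

    def median_xi(self, branch) -> float:
        return float(np.median(self.xi_samples[:, self.branch_index(branch)]))

    def median_tau(self, branch) -> float:
        return float(np.median(self.tau_samples[:, self.branch_index(branch)]))

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for i, br in enumerate(self.branches):
            cols[f"tau_{br}"] = self.tau_samples[:, i]
            cols[f"xi_{br}"] = self.xi_samples[:, i]
        return pd.DataFrame(cols)


def support_statistic(posterior: EsrPosterior, branch) -> float:
    """S = 1 - 2 |p - 0.5| with p the posterior fraction of xi > 0.5.

    S near 1 means the posterior straddles a balanced sex ratio; S below
    0.05 (p outside [0.025, 0.975]) is strong support for a biased one.
    """
    if posterior.xi_samples.shape[0] < 1:
        raise ValueError("posterior has no retained samples")
    p = posterior.p_biased(branch)
    return 1.0 - 2.0 * abs(p - 0.5)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor from one chain."""
    n = len(x) // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], x[len(x) - n:]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (w * n)))


class _MarkerSet:
    """Latent state for one marker class (autosomal or X-linked)."""

    def __init__(self, counts: dict, leaves, rng):
        a, b, c = leaves
        self.k = {l: np.asarray(counts[l][0], dtype=float) for l in leaves}
        self.n = {l: np.asarray(counts[l][1], dtype=float) for l in leaves}
        self.S = len(self.k[a])
        ktot = sum(self.k.values())
        ntot = sum(self.n.values())
        self.r = np.clip((ktot + 1) / (ntot + 2), 0.01, 0.99)
        self.xab = self.r.copy()
        self.y = {l: (self.k[l] + 1) / (self.n[l] + 2) for l in leaves}
        # per-SNP proposal scales
        self.s_r = np.full(self.S, 0.1)
        self.s_xab = np.full(self.S, 0.1)
        self.s_y = {l: np.full(self.S, 0.1) for l in leaves}


def _clip01(x):
    return np.minimum(1.0, np.maximum(0.0, x))


def _vfloor(c):
    """p(1-p) with a floor, for an already-clipped frequency."""
    return np.maximum(c * (1.0 - c), _VAR_FLOOR)


def _norm_logpdf(x, mean, var):
    return -0.5 * ((x - mean) ** 2 / var + np.log(var))


def _kernel_var(parent, tau_eff):
    return tau_eff * _vfloor(_clip01(parent))


def _binom_loglik(k, n, y):
    p = np.minimum(1 - _P_FLOOR, np.maximum(_P_FLOOR, y))
    return k * np.log(p) + (n - k) * np.log1p(-p)


class _DriftTreeSampler:
    """Component-wise random-walk Metropolis over latent frequencies and
    per-branch (tau, xi); SNPs are conditionally independent so latent
    updates are vectorized across sites."""

    def __init__(self, auto_counts, x_counts, leaves, rng):
        self.leaves = tuple(leaves)
        self.branches = [*self.leaves, "ab"]
        self.rng = rng
        self.A = _MarkerSet(auto_counts, self.leaves, rng)
        self.X = _MarkerSet(x_counts, self.leaves, rng)
        self.tau = {br: 0.05 for br in self.branches}
        self.xi = {br: 0.5 for br in self.branches}
        self.s_tau = {br: 0.3 for br in self.branches}
        self.s_xi = {br: 0.15 for br in self.branches}
        self.acc = {}

    # branch -> effective tau for a marker set
    def _tau_eff(self, br, is_x):
        t = self.tau[br]
        return t * float(tau_x_factor(self.xi[br])) if is_x else t

    def _accept(self, key, delta, size=None):
        if size is None:
            ok = np.log(self.rng.uniform()) < delta
        else:
            ok = np.log(self.rng.uniform(size=size)) < delta
        n_acc = np.count_nonzero(ok) if size is not None else int(ok)
        tot, acc = self.acc.get(key, (0, 0))
        self.acc[key] = (tot + (size or 1), acc + n_acc)
        return ok

    # ---- latent-field updates ------------------------------------------
    def _update_root(self, ms, is_x):
        # r is kept strictly inside (0, 1), so no clipping is needed here
        a, b, c = self.leaves
        t_ab = self._tau_eff("ab", is_x)
        t_c = self._tau_eff(c, is_x)
        prop = ms.r + self.rng.normal(0, ms.s_r)
        inside = (prop > 0) & (prop < 1)
        prop = np.where(inside, prop, ms.r)
        vf_new = _vfloor(prop)
        vf_old = _vfloor(ms.r)
        lratio = np.log(vf_new / vf_old)
        delta = -0.5 * (
            (ms.xab - prop) ** 2 / (t_ab * vf_new)
            - (ms.xab - ms.r) ** 2 / (t_ab * vf_old)
            + (ms.y[c] - prop) ** 2 / (t_c * vf_new)
            - (ms.y[c] - ms.r) ** 2 / (t_c * vf_old)
            + 2.0 * lratio
        )
        delta = np.where(inside, delta, -np.inf)
        ok = self._accept(("r", is_x), delta, size=ms.S)
        ms.r = np.where(ok, prop, ms.r)

    def _update_internal(self, ms, is_x):
        a, b, _c = self.leaves
        t_ab = self._tau_eff("ab", is_x)
        t_a = self._tau_eff(a, is_x)
        t_b = self._tau_eff(b, is_x)
        prop = ms.xab + self.rng.normal(0, ms.s_xab)
        cold = _clip01(ms.xab)
        cnew = _clip01(prop)
        vf_r = t_ab * _vfloor(ms.r)
        vf_new = _vfloor(cnew)
        vf_old = _vfloor(cold)
        delta = -0.5 * (
            ((prop - ms.r) ** 2 - (ms.xab - ms.r) ** 2) / vf_r
            + (ms.y[a] - cnew) ** 2 / (t_a * vf_new)
            - (ms.y[a] - cold) ** 2 / (t_a * vf_old)
            + (ms.y[b] - cnew) ** 2 / (t_b * vf_new)
            - (ms.y[b] - cold) ** 2 / (t_b * vf_old)
            + 2.0 * np.log(vf_new / vf_old)
        )
        ok = self._accept(("xab", is_x), delta, size=ms.S)
        ms.xab = np.where(ok, prop, ms.xab)

    def _update_leaf(self, ms, leaf, is_x):
        t = self._tau_eff(leaf, is_x)
        parent = ms.xab if leaf in self.leaves[:2] else ms.r
        cpar = _clip01(parent) if leaf in self.leaves[:2] else parent
        var = t * _vfloor(cpar)
        y = ms.y[leaf]
        prop = y + self.rng.normal(0, ms.s_y[leaf])
        delta = (
            -0.5 * ((prop - cpar) ** 2 - (y - cpar) ** 2) / var
            + _binom_loglik(ms.k[leaf], ms.n[leaf], prop)
            - _binom_loglik(ms.k[leaf], ms.n[leaf], y)
        )
        ok = self._accept(("y", leaf, is_x), delta, size=ms.S)
        ms.y[leaf] = np.where(ok, prop, y)

    # ---- branch-parameter updates --------------------------------------
    #
    # Given the latent frequencies, each branch's kernel log-likelihood is
    #   -(1/2) * (d2vf / tau + sl + S * log(tau))
    # where d2vf = sum d^2/vf and sl = sum log(vf) do not depend on tau, so
    # one pass over the SNPs per sweep makes every tau/xi update O(1).

    def _branch_stats(self):
        a, b, c = self.leaves
        stats = {}
        for ms, is_x in ((self.A, False), (self.X, True)):
            vf_r = _vfloor(ms.r)
            sl_r = float(np.log(vf_r).sum())
            cab = _clip01(ms.xab)
            vf_ab = _vfloor(cab)
            sl_ab = float(np.log(vf_ab).sum())
            stats[("ab", is_x)] = (float(((ms.xab - ms.r) ** 2 / vf_r).sum()), sl_r, ms.S)
            stats[(a, is_x)] = (float(((ms.y[a] - cab) ** 2 / vf_ab).sum()), sl_ab, ms.S)
            stats[(b, is_x)] = (float(((ms.y[b] - cab) ** 2 / vf_ab).sum()), sl_ab, ms.S)
            stats[(c, is_x)] = (float(((ms.y[c] - ms.r) ** 2 / vf_r).sum()), sl_r, ms.S)
        return stats

    def _branch_loglik_cached(self, stats, br, is_x, tau_eff):
        d2vf, sl, S = stats[(br, is_x)]
        return -0.5 * (d2vf / tau_eff + sl + S * np.log(tau_eff))

    def _update_tau(self, stats, br):
        old = self.tau[br]
        prop = old * np.exp(self.rng.normal(0, self.s_tau[br]))
        if not 0 < prop < TAU_PRIOR_MAX:
            self._accept(("tau", br), -np.inf)
            return
        fac = float(tau_x_factor(self.xi[br]))
        ll = self._branch_loglik_cached
        delta = (
            ll(stats, br, False, prop) - ll(stats, br, False, old)
            + ll(stats, br, True, prop * fac) - ll(stats, br, True, old * fac)
            + np.log(prop) - np.log(old)  # log-scale proposal Jacobian
        )
        if self._accept(("tau", br), delta):
            self.tau[br] = prop

    def _update_xi(self, stats, br):
        old = self.xi[br]
        prop = old + self.rng.normal(0, self.s_xi[br])
        if not 0 < prop < 1:
            self._accept(("xi", br), -np.inf)
            return
        tau = self.tau[br]
        ll = self._branch_loglik_cached
        delta = (
            ll(stats, br, True, tau * float(tau_x_factor(prop)))
            - ll(stats, br, True, tau * float(tau_x_factor(old)))
        )
        if self._accept(("xi", br), delta):
            self.xi[br] = prop

    def _update_rescale(self, stats, br):
        """Ridge move: rescale tau_A while holding tau_X = tau_A*(16-8 xi)/9
        fixed by adjusting xi.  The (tau, xi) -> (s*tau, xi') map has unit
        Jacobian, so acceptance depends on the autosomal likelihood alone;
        this mixes the tau/xi trade-off the X-linked likelihood induces."""
        s = np.exp(self.rng.normal(0, 0.3))
        old = self.tau[br]
        prop = old * s
        fac_new = float(tau_x_factor(self.xi[br])) / s
        xi_new = (16.0 - 9.0 * fac_new) / 8.0
        if not (0 < prop < TAU_PRIOR_MAX and 0 < xi_new < 1):
            self._accept(("rescale", br), -np.inf)
            return
        ll = self._branch_loglik_cached
        delta = ll(stats, br, False, prop) - ll(stats, br, False, old)
        if self._accept(("rescale", br), delta):
            self.tau[br] = prop
            self.xi[br] = xi_new

    # ---- iteration / adaptation ----------------------------------------
    def sweep(self):
        for ms, is_x in ((self.A, False), (self.X, True)):
            self._update_root(ms, is_x)
            self._update_internal(ms, is_x)
            for leaf in self.leaves:
                self._update_leaf(ms, leaf, is_x)
        stats = self._branch_stats()
        for br in self.branches:
            self._update_tau(stats, br)
            self._update_xi(stats, br)
            self._update_rescale(stats, br)

    def adapt(self, target):
        """Rescale proposal widths toward the target acceptance rate and
        reset counters (pilot-phase only)."""
        def factor(tot, acc):
            rate = acc / max(tot, 1)
            return np.exp(np.clip(rate - target, -0.5, 0.5) * 2.0)

        for ms, is_x in ((self.A, False), (self.X, True)):
            # per-SNP acceptance would need per-SNP counters; adapt globally
            for key, scale_attr in ((("r", is_x), "s_r"), (("xab", is_x), "s_xab")):
                tot, acc = self.acc.get(key, (0, 0))
                setattr(ms, scale_attr, np.clip(getattr(ms, scale_attr) * factor(tot, acc),
                                                1e-3, 2.0))
            for leaf in self.leaves:
                tot, acc = self.acc.get(("y", leaf, is_x), (0, 0))
                ms.s_y[leaf] = np.clip(ms.s_y[leaf] * factor(tot, acc), 1e-3, 2.0)
        for br in self.branches:
            tot, acc = self.acc.get(("tau", br), (0, 0))
            self.s_tau[br] = float(np.clip(self.s_tau[br] * factor(tot, acc), 1e-3, 3.0))
            tot, acc = self.acc.get(("xi", br), (0, 0))
            self.s_xi[br] = float(np.clip(self.s_xi[br] * factor(tot, acc), 1e-3, 1.0))
        self.acc = {}


def fit_drift_tree(
    autosomal_counts: dict,
    x_counts: dict,
    leaves=("a", "b", "c"),
    mcmc_config: McmcConfig | None = None,
    seed=None,
) -> EsrPosterior:
    """Sample the posterior over per-branch (tau_A, xi) from allele counts.

    Parameters
    ----------
    autosomal_counts, x_counts : dict
        ``{leaf: (derived_copies, total_copies)}`` arrays over SNPs; X-linked
        totals must already be male-adjusted
        (:func:`divergekit.variants.adjust_x_counts`).
    leaves : sequence of 3
        Leaf order (a, b, c) for the rooted topology ((a, b), c); the fourth
        branch reported is the internal branch ``"ab"``.

    Branch lengths on the X side are tied to the autosomal ones through
    ``tau_X = tau_A (16 - 8 xi)/9`` for every posterior sample.  Results
    carry split-chain R-hat diagnostics and are flagged if any exceeds 1.1.
    """
    cfg = mcmc_config or McmcConfig()
    rng = np.random.default_rng(seed)
    sampler = _DriftTreeSampler(autosomal_counts, x_counts, leaves, rng)

    for _ in range(cfg.n_pilot):
        for _ in range(cfg.pilot_iters):
            sampler.sweep()
        sampler.adapt(cfg.target_acceptance)

    taus, xis = [], []
    for it in range(cfg.n_iter):
        sampler.sweep()
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            taus.append([sampler.tau[br] for br in sampler.branches])
            xis.append([sampler.xi[br] for br in sampler.branches])

    tau_samples = np.array(taus)
    xi_samples = np.array(xis)
    rhat = {}
    for i, br in enumerate(sampler.branches):
        rhat[f"tau_{br}"] = _split_rhat(tau_samples[:, i])
        rhat[f"xi_{br}"] = _split_rhat(xi_samples[:, i])
    flagged = any(np.isfinite(v) and v > 1.1 for v in rhat.values())
    if flagged:
        logger.warning("MCMC convergence flagged: %s", rhat)
    return EsrPosterior(sampler.branches, tau_samples, xi_samples, rhat, flagged)


# ---------------------------------------------------------------------------
# Replicated analysis from a genotype table
# ---------------------------------------------------------------------------

def _complete_counts(adjusted: pd.DataFrame, leaves, x_linked: bool, min_maf: float = 0.0):
    """SNPs complete in all three leaves and segregating in the pooled sample.

    ``min_maf`` additionally requires a pooled minor-allele frequency: the
    truncated-Gaussian drift model describes standing variation, and very
    rare variants are predominantly young mutations that arose on a single
    branch, which it misreads as extra drift on that branch.
    """
    cls = adjusted["chrom_class"].to_numpy()
    sel = cls == (vr.X_LINKED if x_linked else vr.AUTOSOME)
    sub = adjusted[sel]
    full = np.ones(len(sub), dtype=bool)
    for leaf in leaves:
        called = sub[f"called_{leaf}"].to_numpy()
        full &= called == called.max()
    alt = sum(sub[f"alt_{l}"].to_numpy() for l in leaves)
    tot = sum(sub[f"called_{l}"].to_numpy() for l in leaves)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    seg = (alt > 0) & (alt < tot) & (maf >= min_maf)
    sub = sub[full & seg]
    return sub


def replicate_esr(
    table,
    sexes,
    leaves,
    n_replicates: int = 50,
    n_autosomal: int = 5000,
    n_x: int = 5000,
    mcmc_config: McmcConfig | None = None,
    seed=None,
    support_threshold: float = 0.05,
    min_maf: float = 0.1,
):
    """Pseudoreplicated ESR analysis: resample SNP panels and refit.

    Each replicate draws ``n_autosomal`` autosomal and ``n_x`` X-linked
    SNPs with no missing data (without replacement, pooled minor-allele
    frequency at least ``min_maf``; see :func:`_complete_counts`) and runs
    :func:`fit_drift_tree`.  If fewer complete SNPs exist than requested the
    analysis runs at the available count with a logged warning; no usable
    X-linked SNPs is an error.

    Returns ``(posteriors, summary)`` where the summary has one row per
    branch: median xi, mean p, and the fraction of replicates with
    S below ``support_threshold``.
    """
    adjusted = vr.adjust_x_counts(table, sexes)
    auto = _complete_counts(adjusted, leaves, x_linked=False, min_maf=min_maf)
    xsub = _complete_counts(adjusted, leaves, x_linked=True, min_maf=min_maf)
    if len(xsub) == 0:
        raise vr.SexingError("no complete X-linked SNPs after male adjustment")
    if len(auto) == 0:
        raise ValueError("no complete autosomal SNPs")
    n_a = min(n_autosomal, len(auto))
    n_xl = min(n_x, len(xsub))
    if n_a < n_autosomal or n_xl < n_x:
        logger.warning(
            "replicate_esr: running at %d autosomal and %d X SNPs (requested %d/%d)",
            n_a, n_xl, n_autosomal, n_x)

    rng = np.random.default_rng(seed)
    posteriors = []
    for _ in range(n_replicates):
        ia = rng.choice(len(auto), size=n_a, replace=False)
        ix = rng.choice(len(xsub), size=n_xl, replace=False)
        ac = {l: (auto[f"alt_{l}"].to_numpy()[ia], auto[f"called_{l}"].to_numpy()[ia])
              for l in leaves}
        xc = {l: (xsub[f"alt_{l}"].to_numpy()[ix], xsub[f"called_{l}"].to_numpy()[ix])
              for l in leaves}
        post = fit_drift_tree(ac, xc, leaves, mcmc_config=mcmc_config,
                              seed=int(rng.integers(1, 2**31)))
        posteriors.append(post)

    rows = []
    for br in posteriors[0].branches:
        s_vals = [support_statistic(p, br) for p in posteriors]
        rows.append({
            "branch": br,
            "median_xi": float(np.median([p.median_xi(br) for p in posteriors])),
            "mean_p": float(np.mean([p.p_biased(br) for p in posteriors])),
            "fraction_supported": float(np.mean([s < support_threshold for s in s_vals])),
        })
    return posteriors, pd.DataFrame(rows)


def write_posterior_tsv(posterior: EsrPosterior, path) -> None:
    posterior.to_frame().to_csv(path, sep="\t", index=False)


def summary_json(posteriors, path=None) -> dict:
    """Per-branch summary across replicates (pie-chart-ready)."""
    import json

    out = {}
    for br in posteriors[0].branches:
        s = [support_statistic(p, br) for p in posteriors]
        out[br] = {
            "median_xi": float(np.median([p.median_xi(br) for p in posteriors])),
            "p": float(np.mean([p.p_biased(br) for p in posteriors])),
            "S": float(np.median(s)),
            "fraction_supporting_bias": float(np.mean([v < 0.05 for v in s])),
        }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)
    return out
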