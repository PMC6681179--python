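# divergekit

Population-genomic inference for species with structured, partially
connected populations: **which divergence history produced the data, how
much did each sex contribute to it, and where has linked selection shaped
the genome?**

divergekit bundles three analyses that are usually run together on
whole-genome resequencing data from two or three populations, plus the
plumbing and a ground-truth simulator to validate them:

* **Divergence-model comparison on the joint SFS** (`divergekit.demography`).
  A 34-scenario family built from six categories — strict isolation (SI),
  isolation with migration (IM), ancient migration with one or two contact
  episodes (AM, PAM), and secondary contact with one or two episodes
  (SC, PSC) — optionally combined with exponential growth (`ex`), a
  background-selection locus-class mixture (`2N`: a fraction *nr* of loci
  with all effective sizes scaled by *bf* < 1), a migration-heterogeneity
  mixture (`2M2P`: fractions *P1*, *P2* of loci closed to gene flow into
  each population), and an ancestral-misidentification parameter *O*.
  Expected unfolded joint spectra come from an exact two-population
  coalescent engine (or a Monte-Carlo engine for larger samples); fitting
  maximizes the Poisson composite likelihood
  `lnL = Σ D·ln(α̂M) − α̂M − ln Γ(D+1)` with the scale α profiled as
  `α̂ = ΣD/ΣM`; scenarios are compared by `AIC = 2k − 2 lnL` and
  uncertainties come from refitting multinomial bootstrap spectra.

* **Effective sex ratios from autosome/X drift contrast**
  (`divergekit.sexdrift`).  A hierarchical Bayesian model of SNP-frequency
  drift on a rooted three-leaf population tree, with per-branch drift
  `τ = t/2Nₑ` (truncated-Gaussian kernel, variance τ·p(1−p)) and the
  X-linked branch lengths tied to the autosomal ones by the female fraction
  ξ through `τ_X = τ_A (16 − 8ξ)/9`.  Per branch, support for a biased sex
  ratio is `S = 1 − 2|p − 0.5|` with *p* the posterior fraction of samples
  with ξ > 0.5; `S < 0.05` is strong support.  Individuals are sexed from
  the X/autosome depth ratio and X counts use one haplotype per male, two
  per female.

* **Windowed linked-selection statistics** (`divergekit.scanstats`).
  θπ, Tajima's D, Hudson F_ST (`1 − H_w/H_b`, ratio of window sums), d_XY,
  genotype-r² and the ZZ statistic (adjacent-pair minus all-pair mean r²),
  mean derived allele frequency, ρ/θπ, equal-count quantile profiles,
  divergence-island calls (top-quintile F_ST ∩ bottom-quintile d_XY) and
  Spearman correlations.

`divergekit.variants` handles VCF loading, hard filtering, thinning,
depth-ratio sexing and outgroup polarization; `divergekit.spectra` builds,
folds, bootstraps and serializes joint spectra; `divergekit.simtruth` is a
seeded msprime-based generator that emits genotype tables together with a
machine-readable truth record (scenario parameters, locus classes, sexes,
ξ, τ, per-window ρ) for every dataset.

See `docs/methods.md` for model details, priors, numerical choices and
known limitations.

## Worked example

Simulate a secondary-contact dataset with known truth, build the joint SFS,
and ask whether the data prefer secondary contact over strict isolation:

```python
import numpy as np
from divergekit import demography as dm, simtruth as st, spectra as sp

# 1. simulate a secondary-contact dataset with known truth
truth = {"nu1": 1.5, "nu2": 0.8, "M12": 3.0, "M21": 1.5, "t_iso": 1.0, "t_sc": 0.3}
model = dm.DemographicModel.from_name("SC", truth)
table, record = st.simulate_pair_dataset(model, n1=2, n2=2, n_loci=5000, seed=7)

# 2. build the observed joint SFS (4+4 haploid copies)
obs = sp.joint_sfs_from_table(table, "pop1", "pop2")
print(f"segregating sites: {obs.total():.0f}")

# 3. fit the true scenario and a strict-isolation alternative
bounds = {"nu1": (0.05, 20), "nu2": (0.05, 20), "M12": (0.01, 20),
          "M21": (0.01, 20), "t_iso": (0.01, 4), "t_sc": (0.01, 4)}
fit_sc = dm.fit_model(obs, "SC", n_starts=4, seed=1, fixed={"O": 1.0},
                      bounds=bounds, optimizer_options={"maxfev": 600})
fit_si = dm.fit_model(obs, "SI", n_starts=4, seed=1, fixed={"O": 1.0})
print(dm.rank_models([fit_sc, fit_si]).to_string(index=False))

# 4. report the winning fit in demographic units (Nref used by the simulator)
units = dm.to_demographic_units(fit_sc, Nref=10_000, generation_time_years=1.0)
for key in ("N1", "N2", "m12", "m21", "Tiso_years", "Tsc_years"):
    print(f"{key:>11}: {units[key]:,.3g}")
```

Output:

```
segregating sites: 35511
model  k      loglik        aic  delta_aic
   SC  6 -133.073190 278.146381   0.000000
   SI  3 -467.396086 940.792173 662.645792
         N1: 1.71e+04
         N2: 8.31e+03
        m12: 0.000136
        m21: 6.65e-05
 Tiso_years: 2.52e+04
  Tsc_years: 6.87e+03
```

The ΔAIC of ~663 decisively rejects strict isolation.  The fitted sizes
(17,100 and 8,310 diploids against true values 15,000 and 8,000), migration
rates (1.4×10⁻⁴ and 6.7×10⁻⁵ per generation against 1.5×10⁻⁴ and 7.5×10⁻⁵)
and epoch lengths (25,200 years of isolation then 6,870 years of contact
against 20,000 and 6,000, at one generation per year) recover the truth to
within the sampling noise of 5,000 loci.

The same pattern applies to the other analyses: `sexdrift.replicate_esr`
takes a genotype table plus sexes and returns per-branch posteriors and the
fraction of pseudoreplicates supporting a biased sex ratio;
`scanstats.scan` takes a table plus window size and returns the per-window
statistics table.  A thin CLI (`divergekit filter|thin|sexing|polarize|fit|
rank|bootstrap|scan`) wraps the file-based workflows.

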