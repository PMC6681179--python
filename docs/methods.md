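# Methods

This note documents the models, estimators and numerical choices behind
divergekit, and what its synthetic-data validation does and does not show.

## Scope and data model

The package analyses multi-sample diploid SNP data from two or three
populations of one species, as produced by standard short-read variant
calling.  Genotypes are held as alt-allele dosage (0/1/2, missing) with
per-genotype depth and quality; chromosomes are classed as autosomal or
X-linked.  All interval logic is 0-based half-open; VCF positions stay
1-based in the site table.

## Site-level procedures (`variants`)

Hard filters follow common resequencing practice: genotype-level masking
first (minimum depth 6x, minimum genotype quality 20), then site-level
removal (mean depth over genotyped samples at most 15x, at most 40% missing,
site quality at least 20).  Masking before site filtering matches VCFtools
semantics and makes the operation idempotent.  Thinning is a greedy
left-to-right scan per chromosome keeping sites at least a minimum distance
apart.

Sexing uses the X/autosome depth ratio: an XY individual carries one X, so
its X-linked coverage is expected at half its autosomal coverage.  The
decision thresholds are 0.625 (below: XY) and 0.875 (above: XX) — midpoints
around the 0.5 and 1.0 expectations with a +/-0.125 guard band; samples in
the band stay unassigned rather than risk a wrong karyotype.

Polarization uses two outgroup individuals: the ancestral allele is the one
at frequency >= 0.75 among the at most four outgroup copies, or the allele
fixed in one outgroup when the other is entirely missing; anything else is
unusable.  On X-linked sites allele counts are male-adjusted (one copy per
XY, two per XX); a heterozygous X call in an XY individual is biologically
impossible and is treated as sequencing noise (set missing, counted in the
log) rather than as an error.

## Joint SFS (`spectra`)

The unfolded joint SFS is an (n1+1) x (n2+1) count array over derived-copy
numbers, built from complete sites only by default (no projection; a
hypergeometric projection is available but off, because downstream fitting
was designed around complete sites).  The fixed corners (0,0) and (n1,n2)
are always masked in totals and likelihoods.  Bootstrap replicates redraw
the S observed sites multinomially with cell probabilities counts/S, so each
replicate conserves S exactly.

## Divergence scenarios (`demography`)

Six divergence categories (SI, IM, AM, PAM, SC, PSC) describe when gene flow
operates after a split; three optional features add exponential growth
(`ex`), a background-selection locus-class mixture (`2N`: fraction `nr` of
loci with all effective sizes — current, post-split and ancestral —
multiplied by `bf`), and migration heterogeneity (`2M2P`: fractions `P1`,
`P2` of loci receive no migration into population 1, 2).  Excluding the
combinations SI cannot express, the catalogue has 34 scenarios.  Parameters
are scaled by a reference size Nref (sizes nu = N/Nref, times in 2*Nref
generations, migration M = 2*Nref*m, with M12 the rate into population 1);
`O` is the probability a site is correctly polarized and acts by mixing the
expected spectrum with its axis-reversed image, applied after the class
mixture.

### Expected-SFS engines

The exact engine integrates the two-population coalescent as a Markov chain
over lineage configurations: each ancestral lineage is labelled by the
number of descendants it subtends in each sample and by its current
population; coalescence (rate 1/nu per pair) and migration (rate M per
lineage, backward in time) act on the multiset of labels.  The expected SFS
entry (i, j) is the expected total branch time carried by (i, j)-lineages.
Occupancies are accumulated by uniformization (Poisson-weighted powers of
the uniformized transition matrix, which also yields the time integral in
closed form with non-negative terms, hence unconditional stability), stepping
in chunks whose rate tracks the fastest outflow among currently occupied
states; because lineage counts only decrease, the chain restricted to states
at or below the occupied maximum is closed, and the active set shrinks as
coalescences fire.  The final, constant-size ancestral phase is an
absorbing-chain linear solve.  Growth epochs are discretized into 20
piecewise-constant steps (the Monte-Carlo engine and the simulator treat
growth exactly).  The configuration space grows quickly (1,431 states at
4+4 samples; ~30,000 at 6+6), so the exact engine is limited to n1+n2 <= 12
haploid copies; beyond that a Monte-Carlo engine averages branch-mode joint
frequency spectra over independent msprime replicates.  The two engines
agree within Monte-Carlo error on random scenarios, and the exact engine
reproduces the 1/i law for a constant-size population to machine precision.

### Fitting, comparison, uncertainty

The fit maximizes a Poisson composite likelihood over unmasked SFS entries
with the overall scale (the mutational theta) profiled analytically
(alpha-hat = sum(D)/sum(M)), so expectations are only ever needed up to a
constant.  Optimization is derivative-free: parameters move on log10 (sizes,
times, migration) or linear (fractions) scales through a logistic box map;
starts are drawn log-uniformly within bounds (defaults nu in [1e-3, 1e2],
M in [1e-3, 40], t in [1e-3, 20], O in (0.51, 1]); each start runs a short
Nelder-Mead pass and the leading candidates are polished by restarted
Nelder-Mead until the gain drops below 0.01 log-units (a fresh simplex
escapes the premature shrinkage NM is prone to in six and more dimensions —
without restarts we observed stalls tens of log-units short of the optimum).
Models are ranked by AIC = 2k - 2 lnL with k the catalogue's free-parameter
count.  Uncertainty comes from refitting bootstrap spectra from the best
fit (a local polish per replicate), summarized as per-parameter SDs with
band codes (below 20% of the estimate: none; 20-50%: `*`; 50-150%: `**`).
A composite likelihood treats linked sites as independent, so these SDs are
calibrated only to the extent the input SNPs were thinned to approximate
independence; the same caveat applies to AIC differences, which is why the
pipeline thins to ~1 SNP per 100 kb before building the SFS.

## Effective sex ratio (`sexdrift`)

A hierarchical Bayesian model on a rooted three-leaf tree ((a,b),c): each
SNP has a root frequency (uniform prior), latent frequencies drift along
branches, and leaf counts are binomial.  Drift over a branch of length
tau = t/(2Ne) uses the Nicholson truncated-Gaussian surface kernel: a
Gaussian with variance tau*p*(1-p) whose out-of-range mass is absorbed at
the boundaries; latent values live on the real line and are clipped where
they act as frequencies.  The kernel variance uses a floor of 1e-6 on
p*(1-p) so boundary parents retain a proper density.  X-linked markers share
the tree with branch lengths tied by the female fraction xi:
tau_X = tau_A*(16-8xi)/9 (the standard three-X-per-four-autosome argument;
equal to 3/4 scaling at xi = 0.5), with male-adjusted haplotype counts.

Sampling is component-wise random-walk Metropolis, vectorized across SNPs
(they are conditionally independent), with pilot runs (default 25 x 1,000
iterations) adapting proposal scales toward ~35% acceptance before the
recorded phase (default 100,000 iterations, burn-in 50,000, thinning 25).
Because the X likelihood constrains only the product tau_A*f(xi), a
reparameterizing move rescales tau_A while holding tau_X fixed (the map has
unit Jacobian, so acceptance depends on the autosomal likelihood alone);
this mixes the tau/xi ridge and brings split-chain R-hat to ~1.0.  Results
are flagged when any R-hat exceeds 1.1.  Support for a biased sex ratio on
branch i is S_i = 1 - 2|p_i - 0.5| with p_i the posterior fraction of
samples with xi > 0.5; S_i < 0.05 is read as strong support.  Replicated
analyses resample SNP panels (default 50 replicates of 5,000 autosomal +
5,000 X-linked complete SNPs) and report the fraction of replicates
supporting bias per branch.

Two practical limits of the Gaussian surrogate, found during validation and
reflected in the defaults:

* It describes *standing* variation.  Young mutations private to one branch
  read as extra drift there, so `replicate_esr` requires a pooled minor
  allele frequency (default 0.1) when ascertaining SNPs.
* Its thin tails understate fixation probabilities, so at strong drift
  (tau around 0.2 and above) branch lengths — and through them xi — become
  biased on fast-drifting branches.  The method is intended for recently
  diverged populations (tau up to roughly 0.15); an exact time-dependent
  diffusion kernel can be plugged in behind the same interface.
* The posterior assumes independent SNPs; panels drawn from few long loci
  share genealogies and make it overconfident.  Panels should be spread
  genome-wide (the synthetic validation uses ~1 SNP per locus).

## Windowed statistics (`scanstats`)

Per non-overlapping window: theta-pi per bp and Tajima's D (complete sites
in the focal population, Tajima's 1989 constants; D undefined without
segregating sites); Hudson F_ST as a ratio of window sums 1 - Hw/Hb, with
the unbiased within-population heterozygosity 2k(n-k)/(n(n-1)) by default
(a plug-in variant 2p(1-p) is available: it returns exactly 0 at identical
sample frequencies but carries an upward ~1/n bias, visible as inflated
F_ST between small samples of one population); d_XY as the mean
between-population difference per bp; genotype-r^2 (squared Pearson
correlation of dosage vectors over pairwise-complete samples, the unphased
convention) and ZZ = ZA - ZnS (mean adjacent-pair minus mean all-pair r^2,
at least 3 polymorphic sites); mean derived allele frequency over usable
polarized sites polymorphic in the focal population with at least 6
individuals genotyped (the default mirrors an 8-individual panel); and,
given a windowed population recombination rate rho, the ratio rho/theta-pi
(approximately r/mu, removing the shared Ne factor).  Windows overlapping
any mask interval are dropped entirely.  Quantile profiles use equal-count
bins of the conditioning statistic; divergence islands are windows jointly
in the top 20% of F_ST and bottom 20% of d_XY; correlations are Spearman
with average ranks.

## Synthetic data (`simtruth`)

The generator simulates independent loci with msprime under any catalogue
scenario, de-scaled by a reference size (default Nref = 10,000 diploids, a
computationally convenient size; mutation rate default 2.1e-8 per bp per
generation so that per-locus theta is realistic at that Nref).  Locus
classes for 2N/2M2P mixtures are drawn per locus with the model's weights
and simulated under the correspondingly modified history; an optional
distant outgroup population (two diploids) enables polarization tests, and
an optional per-locus recombination rate emits a true-rho table for
linked-selection tests.  Three-population autosome/X datasets scale each
branch's X-linked effective size by 9/(16-8xi), sample one X haplotype per
XY and two per XX individual (hemizygous alt calls are written as dosage 2,
the way callers emit haploid calls), and draw per-site depths around
per-sample means (X mean halved for XY) with a configurable coefficient of
variation (default 0.2 — only the X/A ratio matters for sexing).  Every
dataset carries a truth record (scenario, parameters in demographic units,
locus classes, sexes, xi, per-branch tau, seed); identical seeds give
identical outputs.

What the synthetic validation shows — and does not.  Loci are unlinked and
neutral, genotypes error-free apart from the modelled depth noise, and
ancestral states known by construction.  Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions
(plus coalescent noise), not robustness to genotyping error, reference
bias, segmental duplication, or selection at the analysed sites themselves.

## Validation scales

The checked-in tests run at reduced but statistically meaningful scales,
chosen so the full suite completes comfortably on one CPU: SFS laws at
50,000 loci; secondary-contact recovery and SI-vs-SC selection at 20,000
loci and 4+4 haploid samples over 10 seeded replicates; sex-ratio recovery
at 2,000+2,000 SNP panels with 10 pseudoreplicates and a shortened MCMC
schedule (8 x 150 pilot, 6,000 iterations); windowed-statistic oracles on
100 random windows.  The drift-tree validation tree mirrors a recent
range-expansion setting: two small derived populations (tau ~ 0.12) and
one large stable population (tau ~ 0.03).
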