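"""Seeded coalescent synthetic-data generator with ground truth.

Produces genotype tables that emulate the study designs the rest of the
package analyses: two-population divergence histories with epochs of
isolation/contact, exponential growth, per-locus migration and
background-selection classes, and three-population autosome/X datasets with
sex-ratio-scaled X-linked effective sizes, XX/XY depth profiles and outgroup
individuals for polarization.  Every dataset comes with a machine-readable
:class:`SimulationTruth` so tests can compare estimates against known truth.

Loci are simulated independently (no intra-locus recombination unless a
recombination rate is supplied); identical seeds give identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demography as dm
from .demography import BASE_CLASS, NOMIG_POP1, NOMIG_POP2, REDUCED_NE  # noqa: F401
from .variants import AUTOSOME, X_LINKED, GenotypeTable

logger = logging.getLogger(__name__)


def x_autosome_ratio(xi: float) -> float:
    """Ne_X / Ne_A = 9 / (16 - 8*xi) for female fraction xi.

    With xi = 0.5 this is the classic 3/4; a male-biased pool (xi < 0.5)
    depresses the X-linked effective size further.
    """
    if not 0 < xi < 1:
        raise ValueError("xi must lie in (0, 1)")
    return 9.0 / (16.0 - 8.0 * xi)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    scenario_name: str
    parameter_values: dict
    locus_class_assignments: list = field(default_factory=list)
    sex_assignments: dict = field(default_factory=dict)
    xi: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    window_rho: pd.DataFrame | None = None
    seed: int = 0

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        if self.window_rho is not None:
            payload["window_rho"] = self.window_rho.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _rounded_depth(rng, mean, cv, shape):
    """Per-site depths around a mean with a given coefficient of variation."""
    if cv <= 0:
        return np.full(shape, int(round(mean)), dtype=np.int32)
    d = rng.normal(mean, cv * mean, size=shape)
    return np.maximum(np.rint(d), 0).astype(np.int32)


def _extract_biallelic(mts, sample_index_groups):
    """Collect biallelic variants: positions and per-individual dosage rows.

    ``sample_index_groups`` must be consecutive, ordered haplotype ranges
    (one per individual); dosages are summed per group.
    """
    starts = np.array([g[0] for g in sample_index_groups])
    positions, rows = [], []
    for var in mts.variants():
        if len(var.alleles) != 2:
            continue
        positions.append(int(var.site.position) + 1)  # VCF 1-based
        rows.append(np.add.reduceat(var.genotypes, starts))
    return positions, rows


# ---------------------------------------------------------------------------
# Two-population datasets
# ---------------------------------------------------------------------------

def simulate_pair_dataset(
    model: dm.DemographicModel,
    n1: int,
    n2: int,
    n_loci: int,
    locus_length: int = 2000,
    mu: float = 2.1e-8,
    seed: int = 1,
    Nref: float = 10_000.0,
    n_outgroup: int = 0,
    t_outgroup: float | None = None,
    recombination_rate=0.0,
    depth_mean: float = 12.0,
    depth_cv: float = 0.2,
    gq_mean: float = 60.0,
):
    """Simulate independent loci under a two-population divergence scenario.

    Parameters
    ----------
    model : DemographicModel
        Scaled scenario; 2N/2M2P flags draw per-locus classes with the
        model's mixture weights and simulate each class under its modified
        history.
    n1, n2 : int
        Diploid sample counts per population (``n2=0`` gives a
        single-population dataset).
    mu : float
        Per-bp per-generation mutation rate.
    Nref : float
        Reference (ancestral) diploid size used to de-scale the model.
    n_outgroup : int
        Diploid outgroup individuals (population ``out``) splitting from
        the ancestral population ``t_outgroup`` scaled time units before
        the two-population split; outgroups enable polarization tests.
    recombination_rate : float or array
        Per-bp per-generation recombination rate (scalar or per-locus);
        when non-zero, the truth record carries a per-locus table of the
        population-scaled rate rho = 4*N1*r.

    Returns
    -------
    (GenotypeTable, SimulationTruth)
    """
    import msprime

    if n1 <= 0 or n2 < 0 or n_loci <= 0:
        raise ValueError("sample and locus counts must be positive")
    model.validate()
    rng = np.random.default_rng(seed)

    mixture = dm.locus_class_mixture(model)
    weights = np.array([w for w, _, _ in mixture], dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise dm.ModelError("locus-class weights must be non-negative and sum to 1")
    assignment = rng.choice(len(mixture), size=n_loci, p=weights)
    class_labels = [mixture[a][1] for a in assignment]

    rec = np.broadcast_to(np.asarray(recombination_rate, dtype=float), (n_loci,))

    sample_names = (
        [f"pop1_{i:03d}" for i in range(n1)]
        + [f"pop2_{i:03d}" for i in range(n2)]
        + [f"out_{i:03d}" for i in range(n_outgroup)]
    )
    populations = ["pop1"] * n1 + ["pop2"] * n2 + ["out"] * n_outgroup
    n_ind = len(sample_names)
    diploid_groups = [np.array([2 * i, 2 * i + 1]) for i in range(n_ind)]

    chrom_names = [f"L{i:05d}" for i in range(n_loci)]
    per_locus = {}  # locus index -> (positions, dosage matrix)
    for k, (_w, _label, sub) in enumerate(mixture):
        loci = np.flatnonzero(assignment == k)
        if loci.size == 0:
            continue
        dem = dm.to_msprime_demography(dm.build_epochs(sub), Nref=Nref, ploidy=2)
        if n_outgroup:
            if t_outgroup is None:
                raise ValueError("t_outgroup required when n_outgroup > 0")
            t_split = dm.build_epochs(sub).total_time
            if t_outgroup <= t_split:
                raise ValueError("t_outgroup must predate the population split")
            dem.add_population(name="out", initial_size=Nref)
            dem.add_population(name="root", initial_size=Nref)
            dem.add_population_split(
                time=t_outgroup * 2 * Nref, derived=["anc", "out"], ancestral="root")
            dem.sort_events()
        samples = {"pop1": n1, "pop2": n2}
        if n_outgroup:
            samples["out"] = n_outgroup
        anc_seed = int(rng.integers(1, 2**31))
        reps = msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=2,
            sequence_length=locus_length,
            recombination_rate=None,  # set per locus below if needed
            num_replicates=loci.size, random_seed=anc_seed,
        ) if np.all(rec[loci] == 0) else None
        if reps is None:
            reps = (
                msprime.sim_ancestry(
                    samples=samples, demography=dem, ploidy=2,
                    sequence_length=locus_length, recombination_rate=rec[li],
                    random_seed=int(rng.integers(1, 2**31)),
                )
                for li in loci
            )
        for li, ts in zip(loci, reps):
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=int(rng.integers(1, 2**31)),
                model=msprime.BinaryMutationModel(),
            )
            pos, rows = _extract_biallelic(mts, diploid_groups)
            dosage = np.array(rows, np.int8) if rows else np.zeros((0, n_ind), np.int8)
            per_locus[li] = (pos, dosage)

    frames, dosages = [], []
    for li in range(n_loci):
        pos, dosage = per_locus[li]
        if not pos:
            continue
        # collapse duplicate positions (recurrent hits on the discrete genome)
        pos = np.asarray(pos)
        uniq, first = np.unique(pos, return_index=True)
        frames.append(pd.DataFrame({"chrom": chrom_names[li], "pos": uniq}))
        dosages.append(dosage[first])
    if frames:
        sites = pd.concat(frames, ignore_index=True)
        genotypes = np.concatenate(dosages, axis=0)
    else:
        sites = pd.DataFrame({"chrom": [], "pos": []})
        genotypes = np.zeros((0, n_ind), np.int8)
    sites["ref"] = "A"
    sites["alt"] = "T"
    sites["qual"] = 100.0

    n_sites = len(sites)
    depth = _rounded_depth(rng, depth_mean, depth_cv, (n_sites, n_ind))
    gq = np.maximum(rng.normal(gq_mean, 5.0, size=(n_sites, n_ind)), 0).astype(np.float32)

    table = GenotypeTable(
        sites=sites,
        genotypes=genotypes,
        depth=depth,
        gq=gq,
        samples=pd.DataFrame({"sample": sample_names, "population": populations}),
        chrom_class={c: AUTOSOME for c in chrom_names},
    )
    table.validate()

    units = dm.to_demographic_units(dict(model.params), Nref=Nref)
    truth = SimulationTruth(
        scenario_name=model.name,
        parameter_values={**units, "scaled": dict(model.params), "Nref": Nref, "mu": mu},
        locus_class_assignments=class_labels,
        seed=seed,
    )
    if np.any(rec > 0):
        nu1 = model.params.get("nu1", 1.0)
        truth.window_rho = pd.DataFrame(
            {"chrom": chrom_names, "start": 0, "end": locus_length,
             "rho": 4.0 * nu1 * Nref * rec}
        )
    return table, truth


# ---------------------------------------------------------------------------
# Three-population autosome/X datasets
# ---------------------------------------------------------------------------

@dataclass
class ThreeLeafTree:
    """Rooted three-leaf population tree ((a, b), c) in demographic units.

    ``t_ab`` is the a/b split and ``t_root`` the (ab, c) split, both in
    generations before present.  ``N`` maps branches (leaf names, ``"ab"``,
    ``"root"``) to diploid effective sizes; ``xi`` maps branches to female
    fractions in (0, 1).
    """

    leaves: tuple = ("a", "b", "c")
    t_ab: float = 1000.0
    t_root: float = 3000.0
    N: dict = field(default_factory=dict)
    xi: dict = field(default_factory=dict)

    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "ThreeLeafTree":
        """Build from a 3-leaf Newick string like ``((CA,GA),EF);``."""
        import re

        m = re.match(r"\s*\(\s*\(\s*([\w.-]+)\s*,\s*([\w.-]+)\s*\)\s*,\s*([\w.-]+)\s*\)\s*;?\s*$",
                     newick)
        if not m:
            raise ValueError(f"expected a 3-leaf newick '((a,b),c);', got {newick!r}")
        return cls(leaves=(m.group(1), m.group(2), m.group(3)), **kwargs)

    @property
    def branches(self) -> list:
        a, b, _c = self.leaves
        return [a, b, self.leaves[2], "ab"]

    def branch_durations(self) -> dict:
        a, b, c = self.leaves
        return {a: self.t_ab, b: self.t_ab, c: self.t_root, "ab": self.t_root - self.t_ab}

    def tau(self) -> dict:
        """True per-branch autosomal drift tau = t / (2 Ne)."""
        dur = self.branch_durations()
        return {br: dur[br] / (2.0 * self.N[br]) for br in self.branches}

    def validate(self) -> None:
        if not 0 < self.t_ab < self.t_root:
            raise ValueError("require 0 < t_ab < t_root")
        for br in self.branches + ["root"]:
            if self.N.get(br, 0) <= 0:
                raise ValueError(f"missing or non-positive size for branch {br!r}")
        for br in self.branches:
            x = self.xi.get(br)
            if x is None or not 0 < x < 1:
                raise ValueError(f"xi for branch {br!r} must lie in (0, 1)")


def _three_pop_demography(tree: ThreeLeafTree, scale: dict):
    """msprime demography for the tree with per-branch size scaling factors."""
    import msprime

    a, b, c = tree.leaves
    dem = msprime.Demography()
    dem.add_population(name=a, initial_size=tree.N[a] * scale[a])
    dem.add_population(name=b, initial_size=tree.N[b] * scale[b])
    dem.add_population(name=c, initial_size=tree.N[c] * scale[c])
    dem.add_population(name="ab", initial_size=tree.N["ab"] * scale["ab"])
    dem.add_population(name="root", initial_size=tree.N["root"] * scale.get("root", 1.0))
    dem.add_population_split(time=tree.t_ab, derived=[a, b], ancestral="ab")
    dem.add_population_split(time=tree.t_root, derived=["ab", c], ancestral="root")
    dem.sort_events()
    return dem


def simulate_sex_linked_dataset(
    tree: ThreeLeafTree,
    samples_per_leaf: int = 8,
    n_autosomal_loci: int = 200,
    n_x_loci: int = 200,
    locus_length: int = 2000,
    mu: float = 2.1e-8,
    seed: int = 1,
    female_fraction_of_samples: float = 0.5,
    depth_mean: float = 12.0,
    depth_cv: float = 0.2,
    gq_mean: float = 60.0,
):
    """Simulate autosomal and X-linked loci on a three-leaf population tree.

    X-linked loci use per-branch effective sizes scaled by
    ``9/(16 - 8*xi)`` relative to the autosomal sizes.  XX individuals carry
    two X haplotypes, XY individuals one (hemizygous alt calls are coded as
    dosage 2, the way variant callers emit haploid calls).  Per-sample
    depths follow the coverage expectation used for sexing: X-linked mean
    depth is half the autosomal mean for XY samples and equal for XX.

    Returns ``(GenotypeTable, depth_summary, SimulationTruth)`` where the
    depth summary holds per-sample mean autosomal and X-linked depths.
    """
    import msprime

    tree.validate()
    rng = np.random.default_rng(seed)
    a, b, c = tree.leaves

    n_f = int(round(female_fraction_of_samples * samples_per_leaf))
    sexes_per_leaf = ["XX"] * n_f + ["XY"] * (samples_per_leaf - n_f)
    sample_names, populations, sexes = [], [], {}
    for leaf in (a, b, c):
        for i, sx in enumerate(sexes_per_leaf):
            name = f"{leaf}_{i:03d}"
            sample_names.append(name)
            populations.append(leaf)
            sexes[name] = sx
    n_ind = len(sample_names)
    is_xy = np.array([sexes[s] == "XY" for s in sample_names])

    # ---- autosomes: everyone diploid
    dem_a = _three_pop_demography(tree, {br: 1.0 for br in tree.branches + ["root"]})
    auto_chroms = [f"A{i:05d}" for i in range(n_autosomal_loci)]
    diploid_groups = [np.array([2 * i, 2 * i + 1]) for i in range(n_ind)]
    frames, dosages = [], []
    reps = msprime.sim_ancestry(
        samples={a: samples_per_leaf, b: samples_per_leaf, c: samples_per_leaf},
        demography=dem_a, ploidy=2, sequence_length=locus_length,
        num_replicates=n_autosomal_loci, random_seed=int(rng.integers(1, 2**31)),
    )
    for li, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(rng.integers(1, 2**31)),
            model=msprime.BinaryMutationModel())
        pos, rows = _extract_biallelic(mts, diploid_groups)
        if not pos:
            continue
        pos = np.asarray(pos)
        uniq, first = np.unique(pos, return_index=True)
        frames.append(pd.DataFrame({"chrom": auto_chroms[li], "pos": uniq}))
        dosages.append(np.array(rows, np.int8)[first])

    # ---- X: one haplotype per XY sample, two per XX, sizes scaled by 9/(16-8xi)
    scale = {br: x_autosome_ratio(tree.xi[br]) for br in tree.branches}
    scale["root"] = x_autosome_ratio(tree.xi.get("root", 0.5))
    dem_x = _three_pop_demography(tree, scale)
    x_chroms = [f"X{i:05d}" for i in range(n_x_loci)]
    # haploid X sample layout, leaf by leaf, mirroring sample order
    x_groups, sample_sets = [], []
    offset = 0
    for leaf in (a, b, c):
        n_hap = 0
        for i, sx in enumerate(sexes_per_leaf):
            k = 2 if sx == "XX" else 1
            x_groups.append(np.arange(offset + n_hap, offset + n_hap + k))
            n_hap += k
        sample_sets.append(msprime.SampleSet(n_hap, population=leaf, ploidy=1))
        offset += n_hap
    reps = msprime.sim_ancestry(
        samples=sample_sets, demography=dem_x, ploidy=2, sequence_length=locus_length,
        num_replicates=n_x_loci, random_seed=int(rng.integers(1, 2**31)),
    )
    for li, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(rng.integers(1, 2**31)),
            model=msprime.BinaryMutationModel())
        pos, rows = _extract_biallelic(mts, x_groups)
        if not pos:
            continue
        pos = np.asarray(pos)
        uniq, first = np.unique(pos, return_index=True)
        frames.append(pd.DataFrame({"chrom": x_chroms[li], "pos": uniq}))
        dos = np.array(rows, np.int8)[first]
        # hemizygous alt in XY -> dosage 2 (haploid call convention)
        dos[:, is_xy] *= 2
        dosages.append(dos)

    sites = pd.concat(frames, ignore_index=True)
    genotypes = np.concatenate(dosages, axis=0)
    sites["ref"] = "A"
    sites["alt"] = "T"
    sites["qual"] = 100.0

    on_x = sites["chrom"].str.startswith("X").to_numpy()
    depth = np.empty((len(sites), n_ind), np.int32)
    for j in range(n_ind):
        mean_auto = depth_mean
        mean_x = depth_mean * (0.5 if is_xy[j] else 1.0)
        depth[~on_x, j] = _rounded_depth(rng, mean_auto, depth_cv, ((~on_x).sum(),))
        depth[on_x, j] = _rounded_depth(rng, mean_x, depth_cv, (on_x.sum(),))
    gq = np.maximum(rng.normal(gq_mean, 5.0, size=(len(sites), n_ind)), 0).astype(np.float32)

    table = GenotypeTable(
        sites=sites, genotypes=genotypes, depth=depth, gq=gq,
        samples=pd.DataFrame({"sample": sample_names, "population": populations}),
        chrom_class={**{ch: AUTOSOME for ch in auto_chroms}, **{ch: X_LINKED for ch in x_chroms}},
    )
    table.validate()

    cls = table.site_class()
    summary = pd.DataFrame(
        {"sample": sample_names,
         "autosomal_depth": depth[cls == AUTOSOME].mean(axis=0),
         "x_depth": depth[cls == X_LINKED].mean(axis=0),
         "true_sex": [sexes[s] for s in sample_names]}
    )
    truth = SimulationTruth(
        scenario_name="three-leaf-sex-linked",
        parameter_values={"t_ab": tree.t_ab, "t_root": tree.t_root, "N": dict(tree.N),
                          "mu": mu, "x_autosome_ratio": {br: scale[br] for br in tree.branches}},
        sex_assignments=sexes,
        xi=dict(tree.xi),
        tau=tree.tau(),
        seed=seed,
    )
    return table, summary, truth


# ---------------------------------------------------------------------------
# Text outputs
# ---------------------------------------------------------------------------

def write_sample_tsv(table: GenotypeTable, truth: SimulationTruth, path) -> None:
    df = table.samples.copy()
    if truth.sex_assignments:
        df["true_sex"] = df["sample"].map(truth.sex_assignments)
    df.to_csv(path, sep="\t", index=False)


def write_chromosome_class_tsv(table: GenotypeTable, path) -> None:
    pd.DataFrame(
        {"chrom": list(table.chrom_class), "class": list(table.chrom_class.values())}
    ).to_csv(path, sep="\t", index=False)


def write_rho_tsv(truth: SimulationTruth, path) -> None:
    if truth.window_rho is None:
        raise ValueError("truth has no recombination table")
    truth.window_rho.to_csv(path, sep="\t", index=False)


def write_mask_bed(intervals, path) -> None:
    """Write (chrom, start, end) intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")
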