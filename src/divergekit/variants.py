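"""VCF ingestion and site-level procedures.

Implements the SNP-table layer shared by all downstream analyses: loading a
multi-sample diploid VCF into a dense genotype table, hard filtering on depth
and quality, distance-based thinning, depth-ratio sex inference, outgroup
polarization, and the male/female haplotype-count adjustment for X-linked
sites.

Conventions: VCF positions are 1-based and kept as such in the site table;
all interval logic elsewhere (windows, masks) is 0-based half-open.  Genotypes
are stored as alt-allele dosage in {0, 1, 2} with -1 for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

AUTOSOME = "autosome"
X_LINKED = "X"

#: depth-ratio decision band for sexing: ratios around the 0.5 expectation for
#: XY and 1.0 for XX, with a +/-0.125 guard band on either side.
XY_MAX_RATIO = 0.625
XX_MIN_RATIO = 0.875


class VcfFormatError(ValueError):
    """Raised when the input VCF cannot be interpreted."""


class MetadataError(ValueError):
    """Raised when sample or chromosome metadata is inconsistent."""


@dataclass
class GenotypeTable:
    """Dense biallelic-SNP genotype table.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``, ``qual``;
        positions strictly increasing within a chromosome.
    genotypes : ndarray of int8, shape (n_sites, n_samples)
        Alt-allele dosage 0/1/2, -1 missing.
    depth : ndarray of int32, shape (n_sites, n_samples)
        Per-genotype read depth (DP).
    gq : ndarray of float32, shape (n_sites, n_samples)
        Per-genotype quality (GQ).
    samples : pandas.DataFrame
        Columns ``sample``, ``population``.
    chrom_class : dict
        Chromosome id -> ``"autosome"`` or ``"X"``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    samples: pd.DataFrame
    chrom_class: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_names(self) -> list:
        return list(self.samples["sample"])

    def sample_indices(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples["sample"])}
        try:
            return np.array([pos[n] for n in names], dtype=int)
        except KeyError as e:
            raise MetadataError(f"unknown sample {e.args[0]!r}") from None

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise MetadataError(f"no samples in population {population!r}")
        return idx

    def site_class(self) -> np.ndarray:
        """Per-site chromosome class ('autosome'/'X') from ``chrom_class``."""
        return self.sites["chrom"].map(lambda c: self.chrom_class.get(c, AUTOSOME)).to_numpy()

    def take_sites(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        return replace(
            self,
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            depth=self.depth[index],
            gq=self.gq[index],
        )

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_sites, self.n_samples):
            raise MetadataError("genotype matrix shape does not match sites x samples")
        g = self.genotypes
        if g.size and not np.isin(g, [MISSING, 0, 1, 2]).all():
            raise MetadataError("dosage values must be in {0,1,2,missing}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise MetadataError(f"positions not strictly increasing on {chrom}")


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample->population TSV with columns ``sample`` and ``population``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "population"} <= set(df.columns):
        raise MetadataError("sample table needs 'sample' and 'population' columns")
    return df[["sample", "population"]]


def read_chromosome_classes(path) -> dict:
    """Read a chromosome-class TSV with columns ``chrom`` and ``class``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"chrom", "class"} <= set(df.columns):
        raise MetadataError("chromosome-class table needs 'chrom' and 'class' columns")
    bad = set(df["class"]) - {AUTOSOME, X_LINKED}
    if bad:
        raise MetadataError(f"unknown chromosome classes: {sorted(bad)}")
    return dict(zip(df["chrom"], df["class"]))


def read_mask_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file of masked intervals (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": int, "end": int})


def load_vcf(path, sample_table=None, chromosome_class_table=None) -> GenotypeTable:
    """Load a VCF v4.x into a :class:`GenotypeTable`.

    Multi-allelic records and non-SNP records (indels, MNPs, symbolic
    alleles) are dropped, with the dropped count logged.  Samples are the
    intersection of the VCF header with the sample table; a sample-table
    entry absent from the VCF raises :class:`MetadataError`.

    Parameters
    ----------
    sample_table : DataFrame or path, optional
        ``sample``/``population`` mapping; defaults to all VCF samples in a
        single population ``"pop"``.
    chromosome_class_table : dict or path, optional
        Chromosome -> class mapping; chromosomes not listed are autosomal.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as e:  # cyvcf2 raises bare exceptions on bad files
        raise VcfFormatError(f"cannot read VCF {path}: {e}") from e

    vcf_samples = list(vcf.samples)
    if sample_table is None:
        samples = pd.DataFrame({"sample": vcf_samples, "population": "pop"})
    else:
        if not isinstance(sample_table, pd.DataFrame):
            sample_table = read_sample_table(sample_table)
        missing = set(sample_table["sample"]) - set(vcf_samples)
        if missing:
            raise MetadataError(f"samples not in VCF: {sorted(missing)}")
        samples = sample_table.reset_index(drop=True)

    if chromosome_class_table is None:
        chrom_class = {}
    elif isinstance(chromosome_class_table, dict):
        chrom_class = dict(chromosome_class_table)
    else:
        chrom_class = read_chromosome_classes(chromosome_class_table)

    col = np.array([vcf_samples.index(s) for s in samples["sample"]], dtype=int)

    chroms, poss, refs, alts, quals = [], [], [], [], []
    gts, dps, gqs = [], [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        gt = np.asarray(v.gt_types)[col].astype(np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 == unknown
        gts.append(gt)
        dp = v.format("DP")
        dps.append(
            np.zeros(len(col), np.int32)
            if dp is None
            else np.nan_to_num(dp[:, 0].astype(float)[col], nan=0).astype(np.int32)
        )
        gq = v.format("GQ")
        gqs.append(
            np.zeros(len(col), np.float32)
            if gq is None
            else np.nan_to_num(gq[:, 0].astype(float)[col], nan=0).astype(np.float32)
        )
    if n_dropped:
        logger.info("load_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)

    n = len(chroms)
    table = GenotypeTable(
        sites=pd.DataFrame(
            {"chrom": chroms, "pos": np.array(poss, dtype=int), "ref": refs, "alt": alts,
             "qual": np.array(quals, dtype=float)}
        ),
        genotypes=np.array(gts, np.int8).reshape(n, len(col)),
        depth=np.array(dps, np.int32).reshape(n, len(col)),
        gq=np.array(gqs, np.float32).reshape(n, len(col)),
        samples=samples,
        chrom_class=chrom_class,
    )
    table.validate()
    return table


def write_vcf(table: GenotypeTable, path) -> None:
    """Write the table as a minimal VCF v4.2 text file (GT:DP:GQ)."""
    cls = table.site_class()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom in table.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.sample_names) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(table.n_sites):
            row = table.sites.iloc[i]
            qual = "." if np.isnan(row["qual"]) else f"{row['qual']:.1f}"
            fields = [row["chrom"], str(int(row["pos"])), ".", row["ref"], row["alt"],
                      qual, "PASS", ".", "GT:DP:GQ"]
            for j in range(table.n_samples):
                g = gt_str[int(table.genotypes[i, j])]
                fields.append(f"{g}:{int(table.depth[i, j])}:{int(table.gq[i, j])}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def filter_sites(
    table: GenotypeTable,
    min_gt_depth: int = 6,
    max_mean_depth: float = 15,
    max_missing_fraction: float = 0.4,
    min_site_quality: float = 20,
    min_gt_quality: float = 20,
) -> GenotypeTable:
    """Apply hard genotype- and site-level filters.

    Genotype-level masking comes first (VCFtools semantics): genotypes with
    depth below ``min_gt_depth`` or GQ below ``min_gt_quality`` are set to
    missing.  Sites are then removed if the mean depth over still-genotyped
    samples exceeds ``max_mean_depth``, the missing fraction exceeds
    ``max_missing_fraction``, or site quality falls below
    ``min_site_quality``.  Site order is preserved; the operation is
    idempotent.
    """
    g = table.genotypes.copy()
    bad = (table.depth < min_gt_depth) | (table.gq < min_gt_quality)
    g[bad] = MISSING

    called = g != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            n_called > 0, (table.depth * called).sum(axis=1) / np.maximum(n_called, 1), 0.0
        )
    miss_frac = 1.0 - n_called / table.n_samples
    qual = table.sites["qual"].to_numpy()
    keep = (
        (mean_depth <= max_mean_depth)
        & (miss_frac <= max_missing_fraction)
        & (np.nan_to_num(qual, nan=np.inf) >= min_site_quality)
    )
    logger.info(
        "filter_sites: masked %d genotypes, kept %d/%d sites",
        int(bad.sum()), int(keep.sum()), table.n_sites,
    )
    out = replace(table, genotypes=g)
    return out.take_sites(np.flatnonzero(keep))


def thin_sites(table: GenotypeTable, min_distance_bp: int) -> GenotypeTable:
    """Greedy left-to-right thinning within each chromosome.

    The first site on a chromosome is always kept; a later site is kept iff
    its position is at least ``min_distance_bp`` beyond the last kept one.
    """
    keep = np.zeros(table.n_sites, dtype=bool)
    pos = table.sites["pos"].to_numpy()
    for _, grp in table.sites.groupby("chrom", sort=False):
        last = None
        for i in grp.index:
            if last is None or pos[i] - last >= min_distance_bp:
                keep[i] = True
                last = pos[i]
    return table.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Sexing and X-linked adjustments
# ---------------------------------------------------------------------------

class SexingError(ValueError):
    """Raised when depth-based sexing is impossible (e.g. no X-linked sites)."""


def infer_sex_from_depth(table: GenotypeTable) -> pd.DataFrame:
    """Classify samples as XY/XX from the X/autosome depth ratio.

    XY individuals carry one X, so their X-linked coverage is expected to be
    half the autosomal coverage; XX individuals have equal coverage.  A
    sample is XY if (mean X depth)/(mean autosomal depth) < 0.625, XX if
    > 0.875, else unassigned.

    Returns a DataFrame with columns ``sample``, ``autosomal_depth``,
    ``x_depth``, ``ratio``, ``sex``.
    """
    cls = table.site_class()
    on_x = cls == X_LINKED
    if not on_x.any():
        raise SexingError("no X-linked sites in table")
    if on_x.all():
        raise SexingError("no autosomal sites in table")
    a_depth = table.depth[~on_x].mean(axis=0)
    x_depth = table.depth[on_x].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a_depth > 0, x_depth / np.maximum(a_depth, 1e-12), np.nan)
    sex = np.where(ratio < XY_MAX_RATIO, "XY", np.where(ratio > XX_MIN_RATIO, "XX", "unassigned"))
    sex[np.isnan(ratio)] = "unassigned"
    return pd.DataFrame(
        {"sample": table.sample_names, "autosomal_depth": a_depth, "x_depth": x_depth,
         "ratio": ratio, "sex": sex}
    )


def adjust_x_counts(table: GenotypeTable, sexes) -> pd.DataFrame:
    """Per-site allele counts with one X haplotype per XY male, two per XX female.

    ``sexes`` maps sample name -> 'XY'/'XX' (or a DataFrame from
    :func:`infer_sex_from_depth`).  On X-linked sites an XY sample
    contributes a single allele copy; a heterozygous X call in an XY sample
    is biologically impossible and is treated as missing (count logged).
    Autosomal sites are unchanged (two copies per genotyped diploid).

    Returns a DataFrame with, per population ``P``, columns ``alt_P`` (alt
    allele copies) and ``called_P`` (total called copies), plus ``chrom``,
    ``pos`` and ``chrom_class``.
    """
    if isinstance(sexes, pd.DataFrame):
        sexes = dict(zip(sexes["sample"], sexes["sex"]))
    roster = table.sample_names
    missing_sex = [s for s in roster if sexes.get(s) not in ("XY", "XX")]
    if missing_sex:
        raise SexingError(f"samples without assigned sex: {missing_sex}")

    cls = table.site_class()
    on_x = cls == X_LINKED
    is_xy = np.array([sexes[s] == "XY" for s in roster])

    g = table.genotypes.astype(np.int16).copy()
    het_xy = on_x[:, None] & is_xy[None, :] & (g == 1)
    n_het = int(het_xy.sum())
    if n_het:
        logger.info("adjust_x_counts: %d heterozygous X calls in XY samples set to missing", n_het)
    g[het_xy] = MISSING
    called = g != MISSING

    # per-copy weights: 2 per diploid genotype, 1 for XY on X
    copies = np.where(on_x[:, None] & is_xy[None, :], 1, 2)
    # alt copies: dosage, but XY-on-X dosage 2 (hemizygous alt) contributes 1 copy
    alt = np.where(on_x[:, None] & is_xy[None, :] & (g == 2), 1, np.maximum(g, 0))

    out = {"chrom": table.sites["chrom"], "pos": table.sites["pos"], "chrom_class": cls}
    for pop in table.samples["population"].unique():
        idx = table.population_indices(pop)
        out[f"alt_{pop}"] = (alt[:, idx] * called[:, idx]).sum(axis=1)
        out[f"called_{pop}"] = (copies[:, idx] * called[:, idx]).sum(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Outgroup polarization
# ---------------------------------------------------------------------------

def polarize_sites(table: GenotypeTable, outgroup_samples) -> pd.DataFrame:
    """Assign ancestral alleles from two outgroup individuals.

    The ancestral allele is the one at frequency >= 0.75 among the (at most
    four) outgroup allele copies.  If one outgroup individual is entirely
    missing, the allele fixed in the other is taken; otherwise the site is
    flagged unusable.

    Returns a DataFrame with columns ``site_idx``, ``chrom``, ``pos``,
    ``ancestral`` ('ref'/'alt'), ``usable``, and per ingroup population
    ``P`` the derived-copy count ``derived_P`` and called-copy count
    ``called_P``.
    """
    outgroup_samples = list(outgroup_samples)
    if len(outgroup_samples) != 2:
        raise MetadataError("exactly 2 outgroup samples are required")
    out_idx = table.sample_indices(outgroup_samples)

    g = table.genotypes
    og = g[:, out_idx]  # (n_sites, 2)
    og_called = og != MISSING
    alt_copies = np.where(og_called, og, 0).sum(axis=1)
    tot_copies = 2 * og_called.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(tot_copies > 0, alt_copies / np.maximum(tot_copies, 1), np.nan)

    one_missing = og_called.sum(axis=1) == 1
    usable = np.zeros(table.n_sites, dtype=bool)
    anc_is_alt = np.zeros(table.n_sites, dtype=bool)

    both = og_called.all(axis=1)
    usable |= both & ((alt_freq >= 0.75) | (alt_freq <= 0.25))
    anc_is_alt |= both & (alt_freq >= 0.75)

    # one outgroup fully missing: need the other fixed
    single = one_missing & np.isin(alt_copies, [0, 2]) & (tot_copies == 2)
    usable |= single
    anc_is_alt |= single & (alt_copies == 2)

    ingroup_mask = np.ones(table.n_samples, dtype=bool)
    ingroup_mask[out_idx] = False

    res = {
        "site_idx": np.arange(table.n_sites),
        "chrom": table.sites["chrom"].to_numpy(),
        "pos": table.sites["pos"].to_numpy(),
        "ancestral": np.where(anc_is_alt, "alt", "ref"),
        "usable": usable,
    }
    for pop in table.samples["population"].unique():
        idx = np.flatnonzero((table.samples["population"] == pop).to_numpy() & ingroup_mask)
        if idx.size == 0:
            continue
        sub = g[:, idx]
        called = sub != MISSING
        alt_cnt = np.where(called, sub, 0).sum(axis=1)
        n_called = 2 * called.sum(axis=1)
        derived = np.where(anc_is_alt, n_called - alt_cnt, alt_cnt)
        res[f"derived_{pop}"] = derived
        res[f"called_{pop}"] = n_called
    return pd.DataFrame(res)


def write_polarization_tsv(polarized: pd.DataFrame, path) -> None:
    polarized.to_csv(path, sep="\t", index=False)


def write_sex_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.4f")
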