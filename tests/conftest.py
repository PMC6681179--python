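"""Shared fixtures: small hand-built genotype tables and VCF writers."""

import numpy as np
import pandas as pd
import pytest

from divergekit.variants import GenotypeTable


def make_table(
    genotypes,
    chroms=None,
    positions=None,
    populations=None,
    depth=None,
    gq=None,
    qual=None,
    chrom_class=None,
):
    """Build a GenotypeTable from a dosage matrix and optional metadata."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    chroms = list(chroms) if chroms is not None else ["chr1"] * n_sites
    positions = (
        np.asarray(positions) if positions is not None else np.arange(1, n_sites + 1) * 10
    )
    populations = list(populations) if populations is not None else ["pop"] * n_samples
    depth = (
        np.asarray(depth, dtype=np.int32)
        if depth is not None
        else np.full((n_sites, n_samples), 10, dtype=np.int32)
    )
    gq = (
        np.asarray(gq, dtype=np.float32)
        if gq is not None
        else np.full((n_sites, n_samples), 60.0, dtype=np.float32)
    )
    qual = np.asarray(qual, dtype=float) if qual is not None else np.full(n_sites, 100.0)
    table = GenotypeTable(
        sites=pd.DataFrame(
            {"chrom": chroms, "pos": positions, "ref": "A", "alt": "T", "qual": qual}
        ),
        genotypes=g,
        depth=depth,
        gq=gq,
        samples=pd.DataFrame(
            {"sample": [f"s{i}" for i in range(n_samples)], "population": populations}
        ),
        chrom_class=chrom_class or {},
    )
    table.validate()
    return table


@pytest.fixture
def tiny_vcf(tmp_path):
    """A small VCF with 3 biallelic SNPs, 1 indel and 1 triallelic site."""
    path = tmp_path / "tiny.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Quality">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB\n"
        "chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP:GQ\t0/1:12:60\t0/0:9:55\n"
        "chr1\t200\t.\tC\tCTT\t50\tPASS\t.\tGT:DP:GQ\t0/1:12:60\t0/0:9:55\n"
        "chr1\t300\t.\tG\tA\t50\tPASS\t.\tGT:DP:GQ\t1/1:14:70\t./.:0:0\n"
        "chr1\t400\t.\tT\tC,G\t50\tPASS\t.\tGT:DP:GQ\t0/1:12:60\t0/2:9:55\n"
        "chr1\t500\t.\tG\tC\t50\tPASS\t.\tGT:DP:GQ\t0/0:11:80\t0/1:13:66\n"
    )
    return path
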