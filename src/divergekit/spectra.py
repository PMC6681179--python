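"""Joint site-frequency spectra: construction, folding, bootstrap, serialization.

The joint SFS over two populations is an (n1+1) x (n2+1) array of site counts
indexed by derived-copy number in each population.  The fixed corners (0,0)
and (n1,n2) carry no information about segregating variation and are masked by
default; masked entries are excluded from totals, bootstrap resampling and
likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.stats import hypergeom


class SfsError(ValueError):
    pass


def default_mask(n1: int, n2: int) -> np.ndarray:
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = True
    mask[n1, n2] = True
    return mask


@dataclass
class JointSFS:
    """Joint SFS counts with corner masking.

    ``mask`` entries that are True are excluded from all sums and
    likelihoods.  ``polarized`` records whether entries are indexed by
    derived (True) or minor/folded (False) allele counts.
    """

    counts: np.ndarray
    n1: int
    n2: int
    polarized: bool = True
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise SfsError(f"counts shape {self.counts.shape} != ({self.n1+1}, {self.n2+1})")
        if (self.counts < 0).any():
            raise SfsError("negative SFS entries")
        if self.mask is None:
            self.mask = default_mask(self.n1, self.n2)
        self.mask = np.asarray(self.mask, dtype=bool)

    def total(self) -> float:
        """Total segregating count: sum over unmasked entries."""
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.counts.copy(), self.n1, self.n2, self.polarized, self.mask.copy())


def _project_counts(k: np.ndarray, n_from: np.ndarray, n_to: int) -> np.ndarray:
    """Hypergeometric projection weights of derived count k from n_from to n_to copies.

    Returns an array of shape (len(k), n_to+1): row i gives the probability
    that a subsample of size ``n_to`` contains j derived copies.
    """
    j = np.arange(n_to + 1)
    return hypergeom.pmf(j[None, :], n_from[:, None], k[:, None], n_to)


def build_joint_sfs(
    polarized_sites: pd.DataFrame,
    pop1: str,
    pop2: str,
    n1: int,
    n2: int,
    require_complete: bool = True,
    project: bool = False,
) -> JointSFS:
    """Tally usable polarized sites into an unfolded joint SFS.

    Parameters
    ----------
    polarized_sites : DataFrame
        Output of :func:`divergekit.variants.polarize_sites` (columns
        ``usable``, ``derived_<pop>``, ``called_<pop>``).
    n1, n2 : int
        Haploid sample sizes (allele copies) for pop1 and pop2.
    require_complete : bool
        If True (default), only sites with every individual genotyped in
        both populations enter the SFS.  If False and ``project`` is True,
        sites with at least (n1, n2) called copies are projected down
        hypergeometrically.
    """
    df = polarized_sites[polarized_sites["usable"]]
    d1 = df[f"derived_{pop1}"].to_numpy(dtype=float)
    d2 = df[f"derived_{pop2}"].to_numpy(dtype=float)
    c1 = df[f"called_{pop1}"].to_numpy(dtype=int)
    c2 = df[f"called_{pop2}"].to_numpy(dtype=int)

    counts = np.zeros((n1 + 1, n2 + 1))
    if require_complete or not project:
        sel = (c1 == n1) & (c2 == n2)
        d1s, d2s = d1[sel], d2[sel]
        if ((d1s > n1) | (d2s > n2)).any():
            raise SfsError("derived count exceeds haploid sample size")
        np.add.at(counts, (d1s.astype(int), d2s.astype(int)), 1.0)
    else:
        sel = (c1 >= n1) & (c2 >= n2)
        if sel.any():
            w1 = _project_counts(d1[sel], c1[sel], n1)
            w2 = _project_counts(d2[sel], c2[sel], n2)
            counts = np.einsum("si,sj->ij", w1, w2)
    return JointSFS(counts, n1, n2, polarized=True)


def joint_sfs_from_table(table, pop1: str, pop2: str) -> JointSFS:
    """Joint SFS directly from a genotype table whose REF allele is ancestral.

    Intended for simulated data (the generator encodes the ancestral state
    as REF); only sites fully genotyped in both populations are tallied.
    """
    from .variants import MISSING

    i1 = table.population_indices(pop1)
    i2 = table.population_indices(pop2)
    g1 = table.genotypes[:, i1]
    g2 = table.genotypes[:, i2]
    complete = (g1 != MISSING).all(axis=1) & (g2 != MISSING).all(axis=1)
    n1, n2 = 2 * len(i1), 2 * len(i2)
    counts = np.zeros((n1 + 1, n2 + 1))
    d1 = g1[complete].sum(axis=1).astype(int)
    d2 = g2[complete].sum(axis=1).astype(int)
    np.add.at(counts, (d1, d2), 1.0)
    return JointSFS(counts, n1, n2, polarized=True)


def fold(sfs: JointSFS) -> JointSFS:
    """Fold an unfolded joint SFS: merge entry (i, j) with (n1-i, n2-j).

    Each pair of reflected cells is merged into its lexicographically
    smaller member; self-conjugate cells are left in place.  The unmasked
    total is preserved.  Folding a folded spectrum raises :class:`SfsError`.
    """
    if not sfs.polarized:
        raise SfsError("SFS is already folded")
    n1, n2 = sfs.n1, sfs.n2
    counts = np.zeros_like(sfs.counts)
    mask = np.ones_like(sfs.mask)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            ri, rj = n1 - i, n2 - j
            if (i, j) <= (ri, rj):
                counts[i, j] = sfs.counts[i, j]
                if (i, j) != (ri, rj):
                    counts[i, j] += sfs.counts[ri, rj]
                mask[i, j] = sfs.mask[i, j] and sfs.mask[ri, rj]
    return JointSFS(counts, n1, n2, polarized=False, mask=mask)


def bootstrap_sfs(sfs: JointSFS, n_replicates: int = 100, seed: int | None = None) -> list:
    """Multinomial bootstrap over unmasked SFS entries.

    Each replicate redraws the S observed sites with replacement, i.e. a
    multinomial of size S with cell probabilities counts/S; replicate totals
    equal the original total exactly.
    """
    S = sfs.total()
    if S <= 0:
        raise SfsError("cannot bootstrap an empty SFS")
    rng = np.random.default_rng(seed)
    free = ~sfs.mask
    probs = sfs.counts[free] / S
    reps = []
    for _ in range(n_replicates):
        draw = rng.multinomial(int(round(S)), probs)
        counts = np.zeros_like(sfs.counts)
        counts[free] = draw
        reps.append(JointSFS(counts, sfs.n1, sfs.n2, sfs.polarized, sfs.mask.copy()))
    return reps


# ---------------------------------------------------------------------------
# Serialization: TSV matrix with a 2-line header
# ---------------------------------------------------------------------------

def write_sfs(sfs: JointSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n1={sfs.n1}\tn2={sfs.n2}\tpolarized={int(sfs.polarized)}\n")
        masked = ";".join(f"{i},{j}" for i, j in zip(*np.nonzero(sfs.mask)))
        fh.write(f"# mask={masked}\n")
        for row in sfs.counts:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        head1 = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in head1)
        head2 = fh.readline().strip().lstrip("# ")
        n1, n2 = int(meta["n1"]), int(meta["n2"])
        mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
        mask_spec = head2.split("=", 1)[1]
        if mask_spec:
            for cell in mask_spec.split(";"):
                i, j = cell.split(",")
                mask[int(i), int(j)] = True
        counts = np.loadtxt(fh, ndmin=2)
    return JointSFS(counts, n1, n2, polarized=bool(int(meta["polarized"])), mask=mask)
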