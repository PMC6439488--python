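"""Folded site-frequency spectra.

The folded SFS is the currency of single-population demographic
inference here: a vector of site counts indexed by minor-allele copy
number 1..n_chrom//2, plus a separate count of monomorphic sites (class
0 is never stored in ``counts``).  Folding uses minor-allele counts
because ancestral states are unknown for de-novo-assembled RAD loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["FoldedSFS", "compute_folded_sfs", "read_sfs", "write_sfs", "write_fastsimcoal_maf"]


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum with an explicit monomorphic class.

    Attributes
    ----------
    n_chrom : int
        Number of sampled chromosomes (2 × individuals).
    counts : ndarray of length n_chrom // 2
        Site counts per minor-allele copy number class 1..n_chrom//2.
    n_monomorphic : int
        Sites fixed in the sample (minor-allele count 0).
    """

    n_chrom: int
    counts: np.ndarray
    n_monomorphic: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n_chrom < 2:
            raise ValueError("n_chrom must be >= 2")
        if len(self.counts) != self.n_chrom // 2:
            raise ValueError(
                f"counts must have length n_chrom//2 = {self.n_chrom // 2}, "
                f"got {len(self.counts)}"
            )
        if (self.counts < 0).any() or self.n_monomorphic < 0:
            raise ValueError("negative site counts")

    @property
    def total_sites(self) -> int:
        return int(self.n_monomorphic + self.counts.sum())

    @property
    def n_polymorphic(self) -> int:
        return int(self.counts.sum())


def compute_folded_sfs(
    g: GenotypeMatrix,
    snp_policy: str = "all_sites",
    n_monomorphic: int = 0,
    locus_group_key=None,
) -> FoldedSFS:
    """Fold a complete biallelic genotype matrix into an SFS.

    Each retained site contributes one count to the class min(c, n−c)
    where c is the number of copies of allele 1 among the n=2S sampled
    chromosomes; sites with c = 0 or c = n are added to the monomorphic
    class.  ``n_monomorphic`` seeds the monomorphic count with sites not
    present in the matrix (e.g. the invariant portion of the genotyped
    sequence), which demographic fitting needs for absolute scaling.

    ``snp_policy`` is ``"all_sites"`` or ``"first_snp_per_locus"``; under
    the latter, loci are grouped by ``locus_group_key`` (a callable on
    the locus id; default: the id up to the last ``_``) and only the
    first site per group, in input order, is retained — the standard
    guard against intra-locus linkage when RAD loci carry several SNPs.
    """
    if g.missing_mask().any():
        raise ValueError("matrix has missing calls; apply the complete-data filter first")
    if snp_policy not in {"all_sites", "first_snp_per_locus"}:
        raise ValueError(f"unknown snp_policy {snp_policy!r}")
    if n_monomorphic < 0:
        raise ValueError("n_monomorphic must be >= 0")
    n_chrom = 2 * g.n_samples
    loci = range(g.n_loci)
    if snp_policy == "first_snp_per_locus":
        if locus_group_key is None:
            locus_group_key = lambda lid: lid.rsplit("_", 1)[0]
        seen: set = set()
        chosen = []
        for j in loci:
            key = locus_group_key(g.locus_ids[j])
            if key not in seen:
                seen.add(key)
                chosen.append(j)
        loci = chosen
    counts = np.zeros(n_chrom // 2, dtype=np.int64)
    mono = int(n_monomorphic)
    for j in loci:
        site = g.calls[:, j]
        alleles = np.unique(site)
        if alleles.max() > 1 or len(alleles) > 2:
            raise ValueError(
                f"locus {g.locus_ids[j]!r} is not coded biallelic (0/1); "
                "filter to biallelic loci first"
            )
        c = int((site == 1).sum())
        folded = min(c, n_chrom - c)
        if folded == 0:
            mono += 1
        else:
            counts[folded - 1] += 1
    return FoldedSFS(n_chrom, counts, mono)


def write_sfs(sfs: FoldedSFS, path) -> None:
    """Write the two-line SFS text format."""
    with open(path, "w") as fh:
        fh.write(f"n_chrom={sfs.n_chrom} n_monomorphic={sfs.n_monomorphic}\n")
        fh.write(" ".join(str(int(c)) for c in sfs.counts) + "\n")


def read_sfs(path) -> FoldedSFS:
    with open(path) as fh:
        header = fh.readline().split()
        kv = dict(item.split("=") for item in header)
        counts = np.array(fh.readline().split(), dtype=np.int64)
    return FoldedSFS(int(kv["n_chrom"]), counts, int(kv["n_monomorphic"]))


def write_fastsimcoal_maf(sfs: FoldedSFS, path, name: str = "pop") -> None:
    """Write a fastsimcoal-style folded ("MAF") observation file.

    One observation line of n_chrom//2 + 1 entries: the monomorphic
    class followed by minor-allele classes 1..n_chrom//2.
    """
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t".join(f"d0_{i}" for i in range(sfs.n_chrom // 2 + 1)) + "\n")
        row = [str(sfs.n_monomorphic)] + [str(int(c)) for c in sfs.counts]
        fh.write("\t".join(row) + "\n")
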