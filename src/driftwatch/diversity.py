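"""Within-population diversity summaries.

Summaries follow the conventions of classical population-genetics
packages: observed heterozygosity Ho, unbiased expected heterozygosity
He (the 1 − Σp² gene diversity with the n/(n−1) small-sample
correction), the fixation index Fis = 1 − Ho/He, and allelic richness
by hypergeometric rarefaction to a standard sample size.  All summaries
assume the matrix has already been restricted to one population's
complete, within-population-polymorphic loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["PopSummary", "summarize_population", "individual_heterozygosity"]


@dataclass
class PopSummary:
    """Diversity summary for one population."""

    n: int
    n_loci_complete: int
    Ho: float
    He: float
    Fis: float
    AR: float

    def summary(self) -> str:
        return (
            f"n={self.n}  loci={self.n_loci_complete}  "
            f"Ho={self.Ho:.4f}  He={self.He:.4f}  Fis={self.Fis:.4f}  AR={self.AR:.3f}"
        )


def _locus_allele_counts(calls_locus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = calls_locus.ravel()
    a = a[a != MISSING]
    return np.unique(a, return_counts=True)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` chromosomes.

    For allele with ``k`` of ``n`` total copies, the inclusion probability
    is 1 − C(n−k, g)/C(n, g), the hypergeometric zero-draw complement.
    """
    n = int(counts.sum())
    # hypergeom.pmf(0, n, k, g) = C(n-k, g)/C(n, g)
    p_absent = hypergeom.pmf(0, n, counts, g)
    return float(np.sum(1.0 - p_absent))


def summarize_population(g: GenotypeMatrix, rarefaction_size: int | None = None) -> PopSummary:
    """Ho, unbiased He, Fis and rarefied allelic richness for one population.

    Parameters
    ----------
    g : GenotypeMatrix
        One population's complete polymorphic matrix (no missing calls).
    rarefaction_size : int, optional
        Number of *individuals* the richness is rarefied to (the
        subsample is 2×rarefaction_size chromosomes).  Defaults to the
        full sample size, at which AR equals the mean observed allele
        count.
    """
    n = g.n_samples
    if rarefaction_size is None:
        rarefaction_size = n
    if rarefaction_size > n:
        raise ValueError("rarefaction_size exceeds the number of individuals")
    if g.n_loci == 0:
        raise ValueError("no loci to summarize")
    n_chrom = 2 * n
    ho_per_locus = np.empty(g.n_loci)
    he_per_locus = np.empty(g.n_loci)
    ar_per_locus = np.empty(g.n_loci)
    for j in range(g.n_loci):
        calls = g.calls[:, j]
        ho_per_locus[j] = np.mean(calls[:, 0] != calls[:, 1])
        _, counts = _locus_allele_counts(calls)
        p = counts / n_chrom
        he_per_locus[j] = (n_chrom / (n_chrom - 1)) * (1.0 - np.sum(p**2))
        ar_per_locus[j] = _rarefied_richness(counts, 2 * rarefaction_size)
    ho = float(ho_per_locus.mean())
    he = float(he_per_locus.mean())
    fis = 1.0 - ho / he
    return PopSummary(n, g.n_loci, ho, he, fis, float(ar_per_locus.mean()))


def individual_heterozygosity(g: GenotypeMatrix) -> dict[str, float]:
    """Per-sample fraction of heterozygous loci.

    Average genome-wide multilocus heterozygosity, the individual-level
    quantity used in heterozygosity-fitness correlations.  The matrix
    must be the individual's population's complete polymorphic matrix.
    """
    if g.n_loci == 0:
        raise ValueError("no loci")
    het = (g.calls[:, :, 0] != g.calls[:, :, 1]).mean(axis=1)
    return dict(zip(g.sample_ids, het.astype(float).tolist()))
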