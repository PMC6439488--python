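"""Weir & Cockerham (1984) F-statistics and Fst-based utilities.

Fst is estimated from the classical variance components: for each locus
and allele, ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals) are computed from sample
sizes, allele frequencies and heterozygote frequencies, and the
multi-locus estimate is the ratio of sums Σa / Σ(a+b+c).  The estimator
is unbiased but not range-restricted: values slightly below zero are
expected when true differentiation is nil.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "PairwiseFstMatrix",
    "weir_cockerham_fst",
    "per_locus_fst",
    "fst_matrix_correlation",
    "remove_top_fst_loci",
]


@dataclass
class PairwiseFstMatrix:
    """Symmetric matrix of pairwise Weir-Cockerham Fst plus the joint estimate."""

    populations: list[str]
    matrix: np.ndarray
    overall_fst: float

    def value(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.matrix[i, j])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.populations), k=1)
        return self.matrix[iu]

    def summary(self) -> str:
        lines = ["pairwise Weir-Cockerham Fst"]
        width = max(len(p) for p in self.populations)
        header = " " * (width + 1) + "  ".join(f"{p:>7s}" for p in self.populations)
        lines.append(header)
        for i, p in enumerate(self.populations):
            cells = []
            for j in range(len(self.populations)):
                cells.append("      -" if i == j else f"{self.matrix[i, j]:7.4f}")
            lines.append(f"{p:<{width}s} " + "  ".join(cells))
        lines.append(f"overall Fst = {self.overall_fst:.4f}")
        return "\n".join(lines)


def _locus_components(pop_calls: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed WC84 variance components (a, b, c) over alleles at one locus.

    ``pop_calls`` holds one (n_i, 2) array of called genotypes per
    population (missing already removed).
    """
    pops = [c for c in pop_calls if len(c) > 0]
    r = len(pops)
    if r < 2:
        return (0.0, 0.0, 0.0)
    n = np.array([len(c) for c in pops], dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        return (0.0, 0.0, 0.0)
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return (0.0, 0.0, 0.0)
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    a_sum = b_sum = c_sum = 0.0
    for u in alleles:
        p_i = np.array([np.mean(c == u) for c in pops])
        h_i = np.array([np.mean((c == u).sum(axis=1) == 1) for c in pops])
        pbar = np.sum(n * p_i) / (r * nbar)
        s2 = np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n * h_i) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return (a_sum, b_sum, c_sum)


def _population_calls(
    g: GenotypeMatrix, pop: PopulationMap, codes: list[str]
) -> dict[str, np.ndarray]:
    out = {}
    for code in codes:
        samples = pop.samples_in(code)
        out[code] = g.subset(samples).calls
    return out


def _usable_codes(g: GenotypeMatrix, pop: PopulationMap, codes: list[str]) -> list[str]:
    usable = []
    for code in codes:
        n = len(pop.samples_in(code))
        if n < 2:
            warnings.warn(f"population {code!r} has {n} individual(s); excluded from Fst")
        else:
            usable.append(code)
    return usable


def _multi_locus_fst(calls_by_pop: list[np.ndarray]) -> float:
    a_tot = d_tot = 0.0
    n_loci = calls_by_pop[0].shape[1]
    for j in range(n_loci):
        per_pop = []
        for calls in calls_by_pop:
            c = calls[:, j]
            ok = ~(c == MISSING).any(axis=1)
            per_pop.append(c[ok])
        a, b, cc = _locus_components(per_pop)
        a_tot += a
        d_tot += a + b + cc
    return a_tot / d_tot if d_tot != 0 else math.nan


def weir_cockerham_fst(g: GenotypeMatrix, pop: PopulationMap) -> PairwiseFstMatrix:
    """Pairwise and overall multi-locus Weir-Cockerham Fst.

    Populations with fewer than two individuals are excluded with a
    warning; at least two usable populations are required.  Loci may be
    multiallelic (components are summed over alleles).
    """
    pop.validate_against(g)
    codes = _usable_codes(g, pop, pop.populations)
    if len(codes) < 2:
        raise ValueError("need at least two populations with >=2 individuals")
    calls = _population_calls(g, pop, codes)
    k = len(codes)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f = _multi_locus_fst([calls[codes[i]], calls[codes[j]]])
            mat[i, j] = mat[j, i] = f
    overall = _multi_locus_fst([calls[c] for c in codes])
    return PairwiseFstMatrix(codes, mat, overall)


def per_locus_fst(
    g: GenotypeMatrix, pop: PopulationMap, pair: tuple[str, str]
) -> np.ndarray:
    """Per-locus WC84 Fst for one population pair (NaN where undefined)."""
    a_code, b_code = pair
    calls_a = g.subset(pop.samples_in(a_code)).calls
    calls_b = g.subset(pop.samples_in(b_code)).calls
    out = np.full(g.n_loci, np.nan)
    for j in range(g.n_loci):
        per_pop = []
        for calls in (calls_a, calls_b):
            c = calls[:, j]
            ok = ~(c == MISSING).any(axis=1)
            per_pop.append(c[ok])
        a, b, cc = _locus_components(per_pop)
        denom = a + b + cc
        if denom != 0:
            out[j] = a / denom
    return out


def fst_matrix_correlation(
    a: PairwiseFstMatrix, b: PairwiseFstMatrix
) -> tuple[float, float, float, float]:
    """Pearson correlation between two pairwise-Fst matrices.

    Returns ``(r, p, cv_a, cv_b)`` where the correlation and two-sided
    p-value are computed on the vectorized upper triangles restricted to
    the shared population codes, and each CV is 100·sd/mean of the
    corresponding triangle.  This is the plain pairwise-value
    correlation (no Mantel permutation), matching how cross-marker Fst
    agreement is usually reported for these data.
    """
    shared = [p for p in a.populations if p in b.populations]
    dropped = (set(a.populations) | set(b.populations)) - set(shared)
    if dropped:
        warnings.warn(f"populations missing from one matrix dropped: {sorted(dropped)}")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared populations (3 pairs) for correlation")
    ia = [a.populations.index(p) for p in shared]
    ib = [b.populations.index(p) for p in shared]
    sub_a = a.matrix[np.ix_(ia, ia)]
    sub_b = b.matrix[np.ix_(ib, ib)]
    iu = np.triu_indices(len(shared), k=1)
    va, vb = sub_a[iu], sub_b[iu]
    if len(va) < 3:
        raise ValueError("fewer than 3 shared pairs")
    r, p = pearsonr(va, vb)
    cv_a = 100.0 * np.std(va, ddof=1) / np.mean(va)
    cv_b = 100.0 * np.std(vb, ddof=1) / np.mean(vb)
    return (float(r), float(p), float(cv_a), float(cv_b))


def remove_top_fst_loci(
    g: GenotypeMatrix,
    pop: PopulationMap,
    pair: tuple[str, str],
    fraction: float = 0.05,
) -> GenotypeMatrix:
    """Drop the most divergent loci for a population pair.

    Computes per-locus pairwise Fst and removes the ``ceil(fraction ×
    n_loci)`` highest-Fst loci from the full matrix (all samples).  Ties
    at the cutoff are broken by input order, first-listed removed first.
    Used as a sensitivity analysis: if downstream Ne and demographic
    estimates are unchanged, loci under divergent selection are unlikely
    to be driving them.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if pair[0] == pair[1]:
        raise ValueError("population pair must name two distinct populations")
    fst = per_locus_fst(g, pop, pair)
    n_remove = math.ceil(fraction * g.n_loci)
    keyed = sorted(
        range(g.n_loci),
        key=lambda j: (-(fst[j] if np.isfinite(fst[j]) else -np.inf), j),
    )
    removed = set(keyed[:n_remove])
    keep = [j for j in range(g.n_loci) if j not in removed]
    return g.take_loci(np.array(keep, dtype=int))
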