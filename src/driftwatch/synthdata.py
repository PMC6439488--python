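"""Seeded synthetic-data generators with known ground truth.

Every pipeline input can be generated here so that each analysis stage
is testable against a known truth without any external deposit:

* multi-population biallelic genotypes with a target Fst
  (Balding-Nichols island model) or a known divergence time (discrete
  Wright-Fisher drift of allele frequencies);
* individual-based Wright-Fisher populations of known true Ne, whose
  accumulated drift LD validates the LD-based Ne estimator;
* folded SFS datasets drawn from the expected spectrum of a known
  constant or bottleneck demography;
* body-condition records with a tunable heterozygosity-fitness effect.

All generators are deterministic given their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .condition import BodyRecord
from .demography import expected_sfs_mc
from .genotypes import GenotypeMatrix, PopulationMap
from .sfs import FoldedSFS

__all__ = [
    "GeneratorSpec",
    "generate",
    "gen_structured_genotypes",
    "gen_wf_population",
    "gen_sfs_dataset",
    "gen_body_condition",
    "write_genotype_bundle",
]


@dataclass
class GeneratorSpec:
    """Scenario name, scenario-specific parameters and a seed."""

    scenario: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    dispatch = {
        "island_fst": gen_structured_genotypes,
        "divergence_pair": gen_structured_genotypes,
        "wf_known_ne": gen_wf_population,
        "sfs_truth": gen_sfs_dataset,
        "body_condition": gen_body_condition,
    }
    if spec.scenario not in dispatch:
        raise ValueError(f"unknown scenario {spec.scenario!r}")
    if spec.scenario in {"island_fst", "divergence_pair"}:
        return gen_structured_genotypes(scenario=spec.scenario, seed=spec.seed, **spec.parameters)
    return dispatch[spec.scenario](seed=spec.seed, **spec.parameters)


def _hw_genotypes(freqs: np.ndarray, n_ind: int, rng) -> np.ndarray:
    """(n_ind, n_loci, 2) Hardy-Weinberg calls from per-locus frequencies."""
    a = (rng.random((n_ind, len(freqs))) < freqs).astype(np.int16)
    b = (rng.random((n_ind, len(freqs))) < freqs).astype(np.int16)
    return np.stack([a, b], axis=2)


def gen_structured_genotypes(
    scenario: str = "island_fst",
    n_pops: int = 2,
    n_per_pop: int = 25,
    n_loci: int = 500,
    target_fst: float = 0.25,
    divergence_time: int = 100,
    pop_size: int = 100,
    ancestral_beta: float = 0.8,
    seed: int = 0,
):
    """Structured multi-population genotypes with known divergence truth.

    ``island_fst``: ancestral frequencies from a symmetric
    Beta(ancestral_beta, ancestral_beta); population frequencies from
    the Balding-Nichols beta-drift parameterization at the target Fst.
    ``divergence_pair``: population frequencies evolved independently by
    discrete Wright-Fisher binomial drift in populations of
    ``pop_size`` diploids for ``divergence_time`` generations.
    Genotypes are Hardy-Weinberg within populations.

    Returns ``(GenotypeMatrix, PopulationMap, truth)`` where ``truth``
    records the generating parameters.
    """
    rng = np.random.default_rng(seed)
    if scenario not in {"island_fst", "divergence_pair"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "island_fst" and not (0 <= target_fst < 1):
        raise ValueError("target_fst must be in [0, 1)")
    anc = rng.beta(ancestral_beta, ancestral_beta, n_loci)
    anc = np.clip(anc, 0.01, 0.99)  # keep loci segregating in the ancestor
    pop_freqs = []
    for _ in range(n_pops):
        if scenario == "island_fst":
            if target_fst == 0:
                pop_freqs.append(anc.copy())
            else:
                F = target_fst
                pop_freqs.append(rng.beta(anc * (1 - F) / F, (1 - anc) * (1 - F) / F))
        else:
            p = anc.copy()
            for _ in range(divergence_time):
                p = rng.binomial(2 * pop_size, p) / (2.0 * pop_size)
            pop_freqs.append(p)
    codes = [f"POP{i + 1}" for i in range(n_pops)]
    calls = []
    sample_ids = []
    assignments = {}
    for code, freqs in zip(codes, pop_freqs):
        calls.append(_hw_genotypes(freqs, n_per_pop, rng))
        for i in range(n_per_pop):
            sid = f"{code}_{i + 1:03d}"
            sample_ids.append(sid)
            assignments[sid] = code
    g = GenotypeMatrix(
        sample_ids, [f"locus_{j + 1}" for j in range(n_loci)], np.concatenate(calls)
    )
    truth = {
        "scenario": scenario,
        "target_fst": target_fst if scenario == "island_fst" else None,
        "divergence_time": divergence_time if scenario == "divergence_pair" else None,
        "pop_size": pop_size if scenario == "divergence_pair" else None,
        "ancestral_freqs": anc,
    }
    return g, PopulationMap(assignments), truth


def _gene_drop(
    pedigree: list[tuple[np.ndarray, np.ndarray]], N: int, n_loci: int, rng
) -> np.ndarray:
    """Drop unlinked biallelic alleles (founder frequency 0.5) through a
    fixed pedigree; returns final-generation (N, n_loci) allele counts."""
    geno = rng.binomial(2, 0.5, size=(N, n_loci)).astype(np.int8)
    for p1, p2 in pedigree:
        child = (rng.random(geno.shape) < geno[p1] / 2.0).astype(np.int8)
        child += (rng.random(geno.shape) < geno[p2] / 2.0).astype(np.int8)
        geno = child
    return geno


def gen_wf_population(
    true_ne: int,
    n_loci: int = 500,
    sample_size: int = 50,
    burn_in: int | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Individual-based Wright-Fisher population of known effective size.

    ``true_ne`` diploids carry unlinked biallelic loci initialized at
    frequency 0.5 and evolve for ``burn_in`` generations (default
    min(4·true_ne, 200)) so that drift LD accumulates; a random sample
    of ``sample_size`` individuals without replacement is returned.
    A single random-mating pedigree is simulated and alleles are
    gene-dropped through it; loci that fix are re-dropped through the
    *same* pedigree, so every locus pair shares the common ancestry that
    generates drift LD while the output stays fully polymorphic.
    """
    if sample_size > true_ne:
        raise ValueError("sample_size cannot exceed true_ne")
    if burn_in is None:
        burn_in = min(4 * true_ne, 200)
    rng = np.random.default_rng(seed)
    pedigree = []
    for _ in range(burn_in):
        p1 = rng.integers(0, true_ne, true_ne)
        p2 = rng.integers(0, true_ne - 1, true_ne)
        p2 = p2 + (p2 >= p1)
        pedigree.append((p1, p2))
    geno = _gene_drop(pedigree, true_ne, n_loci, rng)
    for _ in range(200):
        freq = geno.mean(axis=0) / 2.0
        fixed = np.flatnonzero((freq == 0) | (freq == 1))
        if len(fixed) == 0:
            break
        geno[:, fixed] = _gene_drop(pedigree, true_ne, len(fixed), rng)
    sample = rng.choice(true_ne, sample_size, replace=False)
    counts = geno[sample]
    calls = np.zeros((sample_size, n_loci, 2), dtype=np.int16)
    calls[:, :, 0] = counts >= 1
    calls[:, :, 1] = counts == 2
    return GenotypeMatrix(
        [f"ind_{i + 1:03d}" for i in range(sample_size)],
        [f"locus_{j + 1}" for j in range(n_loci)],
        calls,
    )


def gen_sfs_dataset(
    model,
    n_chrom: int,
    n_sites: int,
    mu: float = 2.5e-8,
    seed: int = 0,
    n_genealogies: int = 100_000,
) -> FoldedSFS:
    """Folded SFS of ``n_sites`` sites drawn from a known demography.

    Sites are multinomial draws from the Monte-Carlo expected folded
    class probabilities of ``model`` (a :class:`ConstantModel` or
    :class:`BottleneckModel`).
    """
    if n_sites < 1000:
        raise ValueError("n_sites must be >= 1000")
    ss = np.random.SeedSequence([seed, 0x5F5])
    exp_seed, draw_seed = (int(s % 2**31) for s in ss.generate_state(2))
    exp = expected_sfs_mc(model, n_chrom, mu, n_genealogies, exp_seed)
    probs = np.concatenate([[exp.p_monomorphic], exp.probs])
    rng = np.random.default_rng(draw_seed)
    draw = rng.multinomial(n_sites, probs / probs.sum())
    return FoldedSFS(n_chrom, draw[1:], int(draw[0]))


def gen_body_condition(
    n: int = 91,
    true_slope_allometry: float = 3.0,
    hfc_effect: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    mean_ln_svl: float = np.log(500.0),
    sd_ln_svl: float = 0.12,
) -> tuple[list[BodyRecord], dict[str, float]]:
    """Body-size records plus heterozygosity with a known HFC effect.

    SVL is log-normal; ln(mass) follows the allometry
    ``true_slope_allometry``·ln(SVL) plus a residual of total standard
    deviation ``noise_sd`` whose correlation with individual
    heterozygosity is ``hfc_effect`` (0 gives an exact null).
    Heterozygosity is Beta-distributed with mean ≈ 0.3, the level seen
    at polymorphic RAD loci in small snake populations.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    if not (0 <= abs(hfc_effect) <= 1):
        raise ValueError("hfc_effect must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    ln_svl = rng.normal(mean_ln_svl, sd_ln_svl, n)
    het = rng.beta(6.0, 14.0, n)
    z_het = (het - het.mean()) / het.std() if het.std() > 0 else np.zeros(n)
    z_noise = rng.normal(size=n)
    resid = noise_sd * (
        hfc_effect * z_het + np.sqrt(max(0.0, 1.0 - hfc_effect**2)) * z_noise
    )
    # intercept puts a 500 mm individual at ~150 g
    intercept = np.log(150.0) - true_slope_allometry * np.log(500.0)
    ln_mass = intercept + true_slope_allometry * ln_svl + resid
    records = [
        BodyRecord(f"ind_{i + 1:03d}", float(np.exp(ln_svl[i])), float(np.exp(ln_mass[i])))
        for i in range(n)
    ]
    hets = {rec.sample_id: float(h) for rec, h in zip(records, het)}
    return records, hets


def write_genotype_bundle(
    g: GenotypeMatrix, pop: PopulationMap, prefix
) -> dict[str, str]:
    """Write a genotype TSV, VCF and population map under a path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_tsv": f"{prefix}.genotypes.tsv",
        "genotypes_vcf": f"{prefix}.genotypes.vcf",
        "popmap": f"{prefix}.popmap.tsv",
    }
    g.to_tsv(paths["genotypes_tsv"])
    g.to_vcf(paths["genotypes_vcf"])
    pop.to_tsv(paths["popmap"])
    return paths
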