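"""Diploid genotype matrices, population maps, and their file formats.

The universal input to every analysis in this package is a rectangular
matrix of diploid genotype calls: one row per sample, one column per
locus, two small non-negative integer allele codes per cell (``-1``
marks a missing allele).  Two on-disk representations are supported:

* a simple genotype TSV — header ``sample<TAB>locus_1<TAB>...``, cells
  ``a/b`` with integer allele codes and ``./.`` for missing;
* VCF v4.2 (GT field only), read via :mod:`cyvcf2`.  Multiallelic VCF
  records are skipped with a warning; internal coordinates are 0-based
  and VCF positions are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "load_genotypes",
    "load_population_map",
    "filter_complete_polymorphic",
]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Rectangular diploid genotype matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (row labels).
    locus_ids : list of str
        Unique locus identifiers (column labels).
    calls : ndarray of shape (n_samples, n_loci, 2), integer
        Allele codes; ``-1`` denotes a missing allele.  Biallelic loci
        use codes {0, 1}; multiallelic input (e.g. microsatellite-like
        tables) may use larger codes.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    ploidy: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_samples, n_loci, 2)")
        if self.calls.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match calls")
        if self.calls.shape[1] != len(self.locus_ids):
            raise ValueError("locus_ids length does not match calls")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) mask, True where a call is missing."""
        return (self.calls == MISSING).any(axis=2)

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.locus_ids), self.calls[idx]
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids), [self.locus_ids[j] for j in idx], self.calls[:, idx]
        )

    def subset(self, sample_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None
        return self.take_samples(idx)

    def allele_counts(self, locus: int) -> dict[int, int]:
        """Observed copies of each allele at ``locus`` (missing excluded)."""
        a = self.calls[:, locus].ravel()
        a = a[a != MISSING]
        vals, counts = np.unique(a, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_tsv(self, path) -> None:
        """Write the genotype TSV dialect."""
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.locus_ids) + "\n")
            for i, s in enumerate(self.sample_ids):
                cells = []
                for j in range(self.n_loci):
                    a, b = self.calls[i, j]
                    cells.append("./." if a == MISSING or b == MISSING else f"{a}/{b}")
                fh.write(s + "\t" + "\t".join(cells) + "\n")

    def to_vcf(self, path, contig: str = "1") -> None:
        """Write biallelic loci as a minimal VCF v4.2 (GT only).

        Loci are placed on a single synthetic contig at 1-based
        positions following input order.  Only valid for matrices whose
        allele codes are within {0, 1, -1}.
        """
        if self.calls.max() > 1:
            raise ValueError("to_vcf supports biallelic (codes 0/1) matrices only")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            for j, lid in enumerate(self.locus_ids):
                gts = []
                for i in range(self.n_samples):
                    a, b = self.calls[i, j]
                    if a == MISSING or b == MISSING:
                        gts.append("./.")
                    else:
                        gts.append(f"{a}/{b}")
                fh.write(
                    f"{contig}\t{j + 1}\t{lid}\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


@dataclass
class PopulationMap:
    """Assignment of samples to population codes."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def validate_against(self, g: GenotypeMatrix) -> None:
        known = set(g.sample_ids)
        missing = [s for s in self.assignments if s not in known]
        if missing:
            raise ValueError(f"samples in population map absent from matrix: {missing}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")


def _parse_cell(cell: str, path: str, lineno: int) -> tuple[int, int]:
    if cell == "./.":
        return (MISSING, MISSING)
    try:
        a, b = cell.split("/")
        return (int(a), int(b))
    except ValueError:
        raise GenotypeFormatError(
            f"{path}:{lineno}: cannot parse genotype cell {cell!r}"
        ) from None


def _load_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or cols[0] != "sample":
            raise GenotypeFormatError(f"{path}:1: expected header 'sample<TAB>locus...'")
        locus_ids = cols[1:]
        sample_ids: list[str] = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            if parts[0] in sample_ids:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {parts[0]!r}")
            sample_ids.append(parts[0])
            rows.append([_parse_cell(c, str(path), lineno) for c in parts[1:]])
    calls = np.array(rows, dtype=np.int16)
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample id in VCF header")
    locus_ids: list[str] = []
    rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        gt = np.asarray(var.genotypes)[:, :2]
        gt = np.where(gt < 0, MISSING, gt)
        locus_ids.append(lid)
        rows.append(gt)
    vcf.close()
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multiallelic record(s)")
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic records found")
    calls = np.stack(rows, axis=1).astype(np.int16)
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def load_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from TSV or VCF.

    ``format`` is ``"tsv"`` or ``"vcf"``; when None it is inferred from
    the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "tsv":
        return _load_tsv(path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def load_population_map(path) -> PopulationMap:
    """Read a ``sample<TAB>population`` TSV."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected 'sample<TAB>population'"
                )
            if parts[0] in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {parts[0]!r}")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)


def filter_complete_polymorphic(
    g: GenotypeMatrix, pop: PopulationMap, population: str
) -> GenotypeMatrix:
    """Per-population complete-data polymorphism filter.

    Returns the sub-matrix of ``population``'s samples restricted to
    loci that are (a) scored in every sample of that population and
    (b) polymorphic within it (≥2 alleles observed).  This is the
    standard preprocessing step before diversity summaries, LD-based Ne
    estimation and SFS construction.
    """
    samples = pop.samples_in(population)
    if not samples:
        raise ValueError(f"population {population!r} has no samples")
    pop.validate_against(g)
    sub = g.subset(samples)
    complete = ~sub.missing_mask().any(axis=0)
    keep = []
    for j in np.nonzero(complete)[0]:
        alleles = np.unique(sub.calls[:, j])
        if len(alleles) >= 2:
            keep.append(j)
    return sub.take_loci(np.array(keep, dtype=int))
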