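"""Body condition (Scaled Mass Index) and heterozygosity-fitness correlation.

The Scaled Mass Index standardizes each individual's body mass to the
mean body length of the sample via an allometric exponent estimated by
model-II regression of ln(mass) on ln(length):

    SMI_i = M_i · (L0 / L_i) ** b

where L0 is the arithmetic mean snout-vent length and b the
standardized-major-axis (or major-axis) slope.  The HFC test then asks
whether SMI covaries with individual multilocus heterozygosity; the
p-value comes from a two-sided permutation test on |r|, which makes no
distributional assumption at the small sample sizes typical of
endangered-species datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BodyRecord",
    "SmaFit",
    "HfcResult",
    "sma_slope",
    "scaled_mass_index",
    "hfc_regression",
    "HFCRegression",
]


@dataclass
class BodyRecord:
    """One individual's body-size measurements (SVL in mm, mass in g)."""

    sample_id: str
    svl: float
    mass: float

    def __post_init__(self) -> None:
        if self.svl <= 0 or self.mass <= 0:
            raise ValueError("svl and mass must be positive")


@dataclass
class SmaFit:
    """Model-II allometric slope of ln(mass) on ln(SVL)."""

    b_sma: float
    svl0: float
    r: float
    method: str

    def summary(self) -> str:
        return (
            f"model-II ({self.method}) allometry: slope={self.b_sma:.4f}, "
            f"r={self.r:.4f}, reference SVL={self.svl0:.2f}"
        )


@dataclass
class HfcResult:
    """Association between SMI and individual heterozygosity."""

    r2: float
    p: float
    n: int
    slope: float

    def summary(self) -> str:
        return (
            f"HFC regression (n={self.n}): slope={self.slope:.4g}, "
            f"r^2={self.r2:.4f}, permutation p={self.p:.4f}"
        )


def _ma_slope(sxx: float, syy: float, sxy: float) -> float:
    """Major-axis slope: orientation of the leading eigenvector of the
    2x2 covariance matrix."""
    if sxy == 0:
        raise ValueError("major-axis slope undefined for zero covariance")
    return (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


def sma_slope(records: list[BodyRecord], method: str = "sma") -> SmaFit:
    """Model-II slope of the ln-ln mass/length allometry.

    ``method="sma"`` (standardized major axis): b = sign(r)·sd(y)/sd(x);
    ``method="ma"`` (major axis): slope of the leading principal axis of
    the ln-ln covariance matrix.  The reference length ``svl0`` is the
    arithmetic mean of raw SVL.
    """
    if method not in {"sma", "ma"}:
        raise ValueError("method must be 'sma' or 'ma'")
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.log([rec.svl for rec in records])
    y = np.log([rec.mass for rec in records])
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in ln-transformed data")
    r = float(np.corrcoef(x, y)[0, 1])
    if method == "sma":
        if r == 0:
            raise ValueError("sma slope sign undefined at r = 0")
        b = math.copysign(sy / sx, r)
    else:
        b = _ma_slope(sx**2, sy**2, float(np.cov(x, y, ddof=1)[0, 1]))
    svl0 = float(np.mean([rec.svl for rec in records]))
    return SmaFit(float(b), svl0, r, method)


def scaled_mass_index(rec: BodyRecord, fit: SmaFit) -> float:
    """SMI = mass·(svl0/svl)^b — mass standardized to the reference length."""
    return rec.mass * (fit.svl0 / rec.svl) ** fit.b_sma


def _perm_pvalue(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    """Two-sided permutation p-value on |r|, plus the observed r."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    r_obs = float((xc * yc).sum() / denom)
    perms = np.array([rng.permutation(len(x)) for _ in range(n_perm)])
    r_perm = (xc[perms] * yc).sum(axis=1) / denom
    n_ge = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-15))
    return (n_ge + 1) / (n_perm + 1), r_obs


def hfc_regression(
    smi: dict[str, float],
    het: dict[str, float],
    method: str = "ma",
    n_permutations: int = 9999,
    seed: int = 0,
) -> HfcResult:
    """Test for a heterozygosity-fitness correlation.

    ``smi`` and ``het`` are per-sample dictionaries paired by sample id.
    The slope is the chosen model-II slope of SMI on heterozygosity
    (default major axis); r² is the squared Pearson correlation and the
    p-value comes from a seeded two-sided permutation test on |r|.
    """
    unmatched = sorted(set(smi) ^ set(het))
    if unmatched:
        raise ValueError(f"unmatched sample ids between SMI and heterozygosity: {unmatched}")
    ids = sorted(smi)
    if len(ids) < 5:
        raise ValueError("need at least 5 paired samples")
    x = np.array([het[s] for s in ids], dtype=float)
    y = np.array([smi[s] for s in ids], dtype=float)
    if x.std() == 0:
        raise ValueError("zero variance in heterozygosity")
    if y.std() == 0:
        raise ValueError("zero variance in SMI")
    rng = np.random.default_rng(seed)
    p, r = _perm_pvalue(x, y, n_permutations, rng)
    sxx, syy = x.var(ddof=1), y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if method == "ma":
        slope = _ma_slope(sxx, syy, sxy) if sxy != 0 else 0.0
    elif method == "sma":
        slope = math.copysign(math.sqrt(syy / sxx), r)
    elif method == "ols":
        slope = sxy / sxx
    else:
        raise ValueError("method must be 'ma', 'sma' or 'ols'")
    return HfcResult(r**2, p, len(ids), float(slope))


class HFCRegression:
    """Model-style wrapper pairing body records with heterozygosity.

    Computes the pooled allometric exponent, per-individual SMI, and the
    permutation HFC test in one ``fit()`` call.
    """

    def __init__(
        self,
        records: list[BodyRecord],
        het: dict[str, float],
        sma_method: str = "sma",
        hfc_method: str = "ma",
        n_permutations: int = 9999,
        seed: int = 0,
    ):
        self.records = records
        self.het = het
        self.sma_method = sma_method
        self.hfc_method = hfc_method
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self) -> tuple[SmaFit, dict[str, float], HfcResult]:
        fit = sma_slope(self.records, self.sma_method)
        smi = {rec.sample_id: scaled_mass_index(rec, fit) for rec in self.records}
        het = {s: self.het[s] for s in smi}
        result = hfc_regression(
            smi, het, self.hfc_method, self.n_permutations, self.seed
        )
        return fit, smi, result
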