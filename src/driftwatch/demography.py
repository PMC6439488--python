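"""Single-population demographic inference from the folded SFS.

Two competing demographies are fitted to a folded site-frequency
spectrum by maximum composite likelihood:

* a constant-size model with one parameter, the current diploid
  effective size ``NCURR``;
* an instantaneous-size-change ("bottleneck") model with three
  parameters — ``NCURR``, the ancestral size ``NANCES``, and the time
  ``TBOT`` (generations before present) at which the size switched.
  The direction of change is unconstrained, so growth is admissible.

Sites are treated as independent draws from the expected per-site class
probabilities (multinomial composite likelihood including the
monomorphic class), with the expected SFS obtained either from the
closed-form constant-size coalescent expectation E[L_b] = 4N/b or from
Monte-Carlo coalescent genealogies under the piecewise-constant model.
Model choice is by AIC over the best of many independent multi-start
optimizations; parameter uncertainty is assessed by site bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .sfs import FoldedSFS

__all__ = [
    "ConstantModel",
    "BottleneckModel",
    "FitConfig",
    "ExpectedSFS",
    "FitResult",
    "BootstrapResult",
    "CoalescentSampler",
    "expected_sfs_constant",
    "expected_sfs_mc",
    "sfs_log_likelihood",
    "fit_model",
    "compare_models",
    "bootstrap_fit",
    "generations_to_years",
    "SFSDemography",
]


@dataclass
class ConstantModel:
    """Constant-size demography (the null model)."""

    NCURR: float

    def __post_init__(self) -> None:
        if self.NCURR <= 0:
            raise ValueError("NCURR must be positive")


@dataclass
class BottleneckModel:
    """One instantaneous size change at ``TBOT`` generations before present.

    Backward in time the population has size ``NCURR`` for t < TBOT and
    ``NANCES`` for t >= TBOT.  ``NANCES`` may be smaller than ``NCURR``
    (growth) — no ordering is imposed.
    """

    NCURR: float
    NANCES: float
    TBOT: float

    def __post_init__(self) -> None:
        if min(self.NCURR, self.NANCES, self.TBOT) <= 0:
            raise ValueError("all bottleneck parameters must be positive")


@dataclass
class FitConfig:
    """Constants governing SFS model fitting.

    ``mu`` is the per-site per-generation mutation rate (default the
    "high" vertebrate nuclear rate 2.5e-8; 2.1e-9 is the usual "low"
    alternative).  ``n_runs`` independent optimizations are started from
    log-uniform draws within ``prior_ranges`` (the upper bounds only
    bound the starting box, not the search).  ``n_genealogies`` controls
    the Monte-Carlo precision of each expected-SFS evaluation.
    ``generation_time_years`` converts fitted times to calendar years.
    """

    mu: float = 2.5e-8
    n_runs: int = 100
    n_genealogies: int = 100_000
    prior_ranges: dict = field(
        default_factory=lambda: {
            "NCURR": (10.0, 50_000.0),
            "NANCES": (10.0, 50_000.0),
            "TBOT": (1.0, 10_000.0),
        }
    )
    seed: int = 0
    generation_time_years: float = 2.03
    n_batches: int = 10
    nm_maxiter: int = 200

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for k, (lo, hi) in self.prior_ranges.items():
            if lo <= 0 or hi <= lo:
                raise ValueError(f"invalid prior range for {k}")


@dataclass
class ExpectedSFS:
    """Expected per-site probabilities of each folded class.

    ``probs[b-1]`` is the probability that a site is polymorphic with
    minor-allele count b; ``p_monomorphic`` completes the simplex.
    ``mc_se`` holds Monte-Carlo standard errors (zeros for the analytic
    engine).
    """

    n_chrom: int
    probs: np.ndarray
    p_monomorphic: float
    mc_se: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.mc_se = np.asarray(self.mc_se, dtype=float)
        total = self.p_monomorphic + self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")


@dataclass
class FitResult:
    """Best run of a multi-start composite-likelihood fit."""

    model: str
    params: dict
    max_lnL: float
    AIC: float
    n_runs_completed: int
    best_run_seed: int

    def summary(self) -> str:
        pstr = "  ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return (
            f"{self.model} model fit ({self.n_runs_completed} runs)\n"
            f"  params : {pstr}\n"
            f"  lnL    : {self.max_lnL:.3f}\n"
            f"  AIC    : {self.AIC:.3f}"
        )


@dataclass
class BootstrapResult:
    """Site-bootstrap replicates of a model fit."""

    replicates: list[FitResult]
    tbot_distribution: np.ndarray
    concordant: bool | None

    def central_interval(self, level: float = 0.90) -> tuple[float, float]:
        lo = 100 * (1 - level) / 2
        return (
            float(np.percentile(self.tbot_distribution, lo)),
            float(np.percentile(self.tbot_distribution, 100 - lo)),
        )


def _folded_index(n_chrom: int) -> int:
    return n_chrom // 2


def _fold(unfolded: np.ndarray, n_chrom: int) -> np.ndarray:
    """Fold unfolded classes 1..n-1 (index 0..n-2) to minor-allele classes."""
    half = n_chrom // 2
    folded = np.zeros(unfolded.shape[:-1] + (half,))
    for b in range(1, half + 1):
        if b == n_chrom - b:
            folded[..., b - 1] = unfolded[..., b - 1]
        else:
            folded[..., b - 1] = unfolded[..., b - 1] + unfolded[..., n_chrom - b - 1]
    return folded


def expected_sfs_constant(N: float, n_chrom: int, mu: float) -> ExpectedSFS:
    """Closed-form expected folded SFS under constant size.

    Uses the standard coalescent expectation E[L_b] = 4N/b generations
    for the branch length subtending b of the n samples, and the linear
    per-site polymorphism probability p_b = mu * E[L_b].
    """
    if n_chrom < 4 or n_chrom % 2:
        raise ValueError("n_chrom must be even and >= 4")
    b = np.arange(1, n_chrom)
    unfolded = mu * 4.0 * N / b
    if unfolded.sum() >= 1.0:
        raise ValueError(
            "mu*4N*sum(1/b) >= 1: per-site probability model invalid for these inputs"
        )
    probs = _fold(unfolded, n_chrom)
    return ExpectedSFS(n_chrom, probs, 1.0 - probs.sum(), np.zeros_like(probs))


class CoalescentSampler:
    """Reusable Monte-Carlo engine for expected folded SFS.

    Simulates ``n_genealogies`` single-population coalescent genealogies
    for a sample of ``n_chrom`` chromosomes.  The genealogy topology and
    the unit-rate exponential waiting variables are drawn once at
    construction; expected SFS evaluation for any piecewise-constant
    demography then only rescales the waiting times (pairwise
    coalescence rate k(k-1)/(4N(t)) per generation).  Because topology
    and times are independent under the single-population coalescent,
    class expectations are accumulated as batchwise products of mean
    level durations and mean lineage-size counts; the batch spread gives
    the Monte-Carlo standard error.  Reusing one sampler inside an
    optimization run makes the objective deterministic (common random
    numbers).
    """

    def __init__(self, n_chrom: int, n_genealogies: int, seed: int, n_batches: int = 10):
        if n_genealogies < 1000:
            raise ValueError("n_genealogies must be >= 1000")
        if n_chrom < 4 or n_chrom % 2:
            raise ValueError("n_chrom must be even and >= 4")
        self.n_chrom = n_chrom
        self.n_batches = n_batches
        # round G down to a multiple of n_batches
        self.G = (n_genealogies // n_batches) * n_batches
        rng = np.random.default_rng(seed)
        n = n_chrom
        G = self.G
        self.E = rng.exponential(size=(G, n - 1))  # column k-2 is level k
        batch = np.arange(G) // (G // n_batches)
        sizes = np.ones((G, n), dtype=np.int32)
        rows = np.arange(G)
        # mean count of lineages of size b while k lineages persist, per batch
        C = np.zeros((n_batches, n - 1, n))
        for k in range(n, 1, -1):
            seg = sizes[:, :k]
            idx = (batch[:, None] * (n + 1) + seg).ravel()
            bc = np.bincount(idx, minlength=n_batches * (n + 1)).reshape(
                n_batches, n + 1
            )
            C[:, k - 2, :] = bc[:, :n]
            i = rng.integers(0, k, size=G)
            j = rng.integers(0, k - 1, size=G)
            j = j + (j >= i)
            sizes[rows, i] += sizes[rows, j]
            sizes[rows, j] = sizes[rows, k - 1]
        self.C = C / (G // n_batches)

    def _level_times(self, model) -> np.ndarray:
        """Generations spent at each lineage level, per genealogy."""
        n = self.n_chrom
        k = np.arange(2, n + 1)  # level values for columns 0..n-2
        rate_scale = 4.0 / (k * (k - 1.0))
        v = self.E * rate_scale  # required integral of dt/N(t)
        T = np.empty_like(v)
        if isinstance(model, ConstantModel):
            for col in range(n - 2, -1, -1):
                T[:, col] = v[:, col] * model.NCURR
            return T
        t = np.zeros(self.G)
        for col in range(n - 2, -1, -1):  # level n first (col n-2), down to level 2
            vk = v[:, col]
            rem = np.maximum(model.TBOT - t, 0.0)
            cap = rem / model.NCURR
            Tk = np.where(vk <= cap, vk * model.NCURR, rem + (vk - cap) * model.NANCES)
            T[:, col] = Tk
            t = t + Tk
        return T

    def expected_sfs(self, model, mu: float) -> ExpectedSFS:
        n = self.n_chrom
        B = self.n_batches
        T = self._level_times(model)
        Tb = T.reshape(B, self.G // B, n - 1).mean(axis=1)
        # expected branch length per unfolded class, per batch
        Lb = np.einsum("bk,bks->bs", Tb, self.C[:, :, 1:n])
        unfolded = mu * Lb
        folded = _fold(unfolded, n)
        probs = folded.mean(axis=0)
        se = folded.std(axis=0, ddof=1) / math.sqrt(B)
        p_mono = 1.0 - probs.sum()
        return ExpectedSFS(n, probs, p_mono, se)


def expected_sfs_mc(
    model,
    n_chrom: int,
    mu: float,
    n_genealogies: int = 100_000,
    seed: int = 0,
    n_batches: int = 10,
) -> ExpectedSFS:
    """Monte-Carlo expected folded SFS for a constant or bottleneck model.

    ``n_batches`` controls the granularity of the Monte-Carlo standard
    error estimate (the SE itself has n_batches − 1 degrees of freedom,
    so agreement checks against other engines should use enough batches
    for the SE to be reliable).
    """
    return CoalescentSampler(n_chrom, n_genealogies, seed, n_batches).expected_sfs(model, mu)


def sfs_log_likelihood(obs: FoldedSFS, exp: ExpectedSFS) -> float:
    """Multinomial composite log-likelihood of an observed folded SFS.

    lnL = n_monomorphic·ln(p_mono) + Σ_b counts[b]·ln(probs[b]); classes
    with zero expected probability but nonzero observations are floored
    at 1e-12 with a warning.
    """
    if obs.n_chrom != exp.n_chrom:
        raise ValueError("observed and expected SFS have different n_chrom")
    probs = np.asarray(exp.probs, dtype=float)
    p_mono = exp.p_monomorphic
    if p_mono <= 0:
        return -math.inf
    bad = (probs <= 0) & (obs.counts > 0)
    if bad.any():
        warnings.warn("zero expected probability for observed class; floored at 1e-12")
    probs = np.maximum(probs, 1e-12)
    lnL = obs.n_monomorphic * math.log(p_mono)
    lnL += float(np.sum(obs.counts * np.log(probs)))
    return lnL


def _make_model(model_kind: str, params: np.ndarray):
    if model_kind == "constant":
        return ConstantModel(params[0])
    return BottleneckModel(params[0], params[1], params[2])


def _param_names(model_kind: str) -> list[str]:
    return ["NCURR"] if model_kind == "constant" else ["NCURR", "NANCES", "TBOT"]


def fit_model(obs: FoldedSFS, model_kind: str, cfg: FitConfig | None = None) -> FitResult:
    """Multi-start composite-likelihood fit of one demographic model.

    Each of ``cfg.n_runs`` runs draws a starting point log-uniformly
    within the prior ranges and performs a Nelder-Mead search over
    log-parameters; the Monte-Carlo expected SFS uses a fixed
    per-run genealogy sample (common random numbers) so the objective is
    deterministic within a run.  The best run's parameters, composite
    log-likelihood and AIC (k = 1 or 3) are returned.
    """
    if model_kind not in {"constant", "bottleneck"}:
        raise ValueError("model_kind must be 'constant' or 'bottleneck'")
    cfg = cfg or FitConfig()
    if obs.total_sites <= 0:
        raise ValueError("observed SFS has no sites")
    names = _param_names(model_kind)
    k_params = len(names)
    ss = np.random.SeedSequence(cfg.seed)
    run_seeds = ss.generate_state(2 * cfg.n_runs)
    best = None
    best_seed = 0
    best_start_lnL = -math.inf
    best_start = None
    for run in range(cfg.n_runs):
        topo_seed = int(run_seeds[2 * run] % (2**31))
        start_rng = np.random.default_rng(int(run_seeds[2 * run + 1] % (2**31)))
        sampler = CoalescentSampler(
            obs.n_chrom, cfg.n_genealogies, topo_seed, cfg.n_batches
        )
        x0 = np.array(
            [
                start_rng.uniform(math.log(cfg.prior_ranges[n][0]), math.log(cfg.prior_ranges[n][1]))
                for n in names
            ]
        )

        def neg_lnL(x):
            if np.any(np.abs(x) > 50):
                return math.inf
            model = _make_model(model_kind, np.exp(x))
            try:
                exp = sampler.expected_sfs(model, cfg.mu)
            except ValueError:
                return math.inf
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lnL = sfs_log_likelihood(obs, exp)
            return -lnL if math.isfinite(lnL) else math.inf

        f0 = neg_lnL(x0)
        if -f0 > best_start_lnL:
            best_start_lnL = -f0
            best_start = (x0, topo_seed)
        res = minimize(
            neg_lnL,
            x0,
            method="Nelder-Mead",
            options={"maxiter": cfg.nm_maxiter, "xatol": 1e-3, "fatol": 1e-4},
        )
        lnL = -res.fun
        if best is None or lnL > best[1]:
            best = (np.exp(res.x), lnL)
            best_seed = topo_seed
    params_arr, max_lnL = best
    if not math.isfinite(max_lnL) or max_lnL < best_start_lnL:
        warnings.warn("no optimization run improved on its start; returning best start")
        x0, best_seed = best_start
        params_arr, max_lnL = np.exp(x0), best_start_lnL
    # Re-evaluate the winning parameters with an evaluation sampler whose
    # seed depends only on cfg.seed: fits of competing models under the
    # same config then share genealogy noise, so AIC differences are not
    # driven by per-run Monte-Carlo error.
    eval_seed = int(np.random.SeedSequence([cfg.seed, 0xE7A1]).generate_state(1)[0] % 2**31)
    eval_sampler = CoalescentSampler(obs.n_chrom, cfg.n_genealogies, eval_seed, cfg.n_batches)
    model_best = _make_model(model_kind, params_arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lnL_eval = sfs_log_likelihood(obs, eval_sampler.expected_sfs(model_best, cfg.mu))
    if math.isfinite(lnL_eval):
        max_lnL = lnL_eval
    params = dict(zip(names, params_arr.tolist()))
    aic = 2 * k_params - 2 * max_lnL
    return FitResult(model_kind, params, max_lnL, aic, cfg.n_runs, best_seed)


def compare_models(fit_null: FitResult, fit_bot: FitResult):
    """AIC comparison of the constant and bottleneck fits.

    Returns ``(delta_aic, akaike_weights, chosen)``; delta and weights
    are keyed by model name.  Ties (ΔAIC < 1e-9) resolve to the
    1-parameter model by parsimony.
    """
    aics = {fit_null.model: fit_null.AIC, fit_bot.model: fit_bot.AIC}
    amin = min(aics.values())
    delta = {m: a - amin for m, a in aics.items()}
    raw = {m: math.exp(-d / 2.0) for m, d in delta.items()}
    tot = sum(raw.values())
    weights = {m: v / tot for m, v in raw.items()}
    if abs(fit_null.AIC - fit_bot.AIC) < 1e-9 or fit_null.AIC < fit_bot.AIC:
        chosen = fit_null
    else:
        chosen = fit_bot
    return delta, weights, chosen


def bootstrap_fit(
    obs: FoldedSFS,
    model_kind: str,
    cfg: FitConfig | None = None,
    n_boot: int = 50,
    point_fit: FitResult | None = None,
) -> BootstrapResult:
    """Site-bootstrap uncertainty for a fitted model.

    Each replicate resamples round(0.9 × total_sites) sites
    multinomially from the observed per-class proportions (monomorphic
    class included) and refits; the spread of the replicate ``TBOT``
    values is the uncertainty statement.  ``concordant`` records whether
    the full-data point estimate of TBOT lies inside the central 90% of
    the replicate distribution — when it does not, the timing of the
    size change cannot be inferred with confidence.
    """
    cfg = cfg or FitConfig()
    if obs.total_sites < 10:
        raise ValueError("too few sites to bootstrap")
    if point_fit is None:
        point_fit = fit_model(obs, model_kind, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB007]).generate_state(1)[0])
    props = np.concatenate([[obs.n_monomorphic], obs.counts]).astype(float)
    props /= props.sum()
    n_rep_sites = round(0.9 * obs.total_sites)
    replicates = []
    for rep in range(n_boot):
        draw = rng.multinomial(n_rep_sites, props)
        rep_sfs = FoldedSFS(obs.n_chrom, draw[1:], int(draw[0]))
        rep_cfg = FitConfig(
            mu=cfg.mu,
            n_runs=cfg.n_runs,
            n_genealogies=cfg.n_genealogies,
            prior_ranges=cfg.prior_ranges,
            seed=int(np.random.SeedSequence([cfg.seed, rep + 1]).generate_state(1)[0] % (2**31)),
            generation_time_years=cfg.generation_time_years,
            n_batches=cfg.n_batches,
            nm_maxiter=cfg.nm_maxiter,
        )
        replicates.append(fit_model(rep_sfs, model_kind, rep_cfg))
    if model_kind == "bottleneck":
        tbot = np.array([r.params["TBOT"] for r in replicates])
        lo, hi = np.percentile(tbot, [5, 95])
        concordant = bool(lo <= point_fit.params["TBOT"] <= hi)
    else:
        tbot = np.array([])
        concordant = None
    return BootstrapResult(replicates, tbot, concordant)


def generations_to_years(t: float, cfg: FitConfig | None = None) -> float:
    """Convert a time in generations to calendar years."""
    if t < 0:
        raise ValueError("t must be >= 0")
    cfg = cfg or FitConfig()
    return t * cfg.generation_time_years


class SFSDemography:
    """Model-comparison front end for one population's folded SFS.

    ``fit(model_kind)`` fits one model; ``fit_compare()`` fits both and
    returns ``(fit_constant, fit_bottleneck, delta, weights, chosen)``;
    ``bootstrap`` delegates to :func:`bootstrap_fit`.
    """

    def __init__(self, obs: FoldedSFS, config: FitConfig | None = None):
        self.obs = obs
        self.config = config or FitConfig()

    def fit(self, model_kind: str) -> FitResult:
        return fit_model(self.obs, model_kind, self.config)

    def fit_compare(self):
        fit_c = self.fit("constant")
        fit_b = self.fit("bottleneck")
        delta, weights, chosen = compare_models(fit_c, fit_b)
        return fit_c, fit_b, delta, weights, chosen

    def bootstrap(self, model_kind: str, n_boot: int = 50, point_fit=None) -> BootstrapResult:
        return bootstrap_fit(self.obs, model_kind, self.config, n_boot, point_fit)
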