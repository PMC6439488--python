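"""End-to-end analysis pipeline.

Given genotypes, a population map and optional body-size data, runs the
full per-population workflow: complete-data filtering → diversity
summaries → pairwise/overall Fst (plus cross-marker Fst correlation
when a second marker set is supplied) → LD-based contemporary Ne →
folded SFS → demographic model comparison with AIC and site bootstrap
(with the inferred size-change time classified against the ≤100
generation "anthropogenic window") → a sensitivity rerun with the top
high-Fst loci removed → heterozygosity-fitness correlation → forward
projections at the estimated effective sizes with the analytic decay
overlay.  Output is a machine-readable JSON report plus TSV tables;
every stage is seeded from the master seed, so a run is reproducible
bit for bit.  Stage failures are recorded and independent stages still
run.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import condition, demography, diversity, fst, genotypes, ldne, projection, sfs

logger = logging.getLogger(__name__)

ANTHROPOGENIC_GENERATIONS = 100  # TBOT at or below this is a "recent" decline

__all__ = ["RunConfig", "run_all", "ANTHROPOGENIC_GENERATIONS"]


@dataclass
class RunConfig:
    """Paths, per-stage parameters and toggles for a full run."""

    genotypes_path: str
    popmap_path: str
    out_dir: str
    genotype_format: str | None = None
    second_genotypes_path: str | None = None
    body_path: str | None = None
    n_monomorphic: int = 0
    seed: int = 0
    ldne_config: ldne.LdNeConfig = field(default_factory=ldne.LdNeConfig)
    fit_config: demography.FitConfig = field(default_factory=demography.FitConfig)
    life_history: projection.LifeHistory = field(default_factory=projection.LifeHistory)
    n_boot: int = 50
    sensitivity_fraction: float = 0.05
    projection_years: int = 100
    projection_iterations: int = 10
    projection_loci: int = 1000
    projection_p_init: float = 0.81
    run_demography: bool = True
    run_bootstrap: bool = True
    run_sensitivity: bool = True
    run_hfc: bool = True
    run_projection: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (
            ("ldne_config", ldne.LdNeConfig),
            ("fit_config", demography.FitConfig),
            ("life_history", projection.LifeHistory),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)


def _load_body(path) -> list[condition.BodyRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("sample\t"):
                continue
            sid, svl, mass = line.split("\t")
            records.append(condition.BodyRecord(sid, float(svl), float(mass)))
    return records


def _stage_seed(master: int, label: str) -> int:
    h = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float):
        return "inf" if math.isinf(x) else x
    return x


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": 1, "seed": cfg.seed, "populations": {}, "errors": {}}

    g = genotypes.load_genotypes(cfg.genotypes_path, cfg.genotype_format)
    popmap = genotypes.load_population_map(cfg.popmap_path)
    popmap.validate_against(g)

    # range-wide structure
    try:
        fst_matrix = fst.weir_cockerham_fst(g, popmap)
        report["fst"] = {
            "populations": fst_matrix.populations,
            "matrix": _jsonable(fst_matrix.matrix),
            "overall": fst_matrix.overall_fst,
        }
    except Exception as e:  # noqa: BLE001 - stage isolation
        logger.exception("Fst stage failed")
        report["errors"]["fst"] = str(e)
        fst_matrix = None

    if cfg.second_genotypes_path and fst_matrix is not None:
        try:
            g2 = genotypes.load_genotypes(cfg.second_genotypes_path)
            fst2 = fst.weir_cockerham_fst(g2, popmap)
            r, p, cv_a, cv_b = fst.fst_matrix_correlation(fst_matrix, fst2)
            report["fst_marker_correlation"] = {"r": r, "p": p, "cv_a": cv_a, "cv_b": cv_b}
        except Exception as e:  # noqa: BLE001
            logger.exception("cross-marker Fst stage failed")
            report["errors"]["fst_marker_correlation"] = str(e)

    het_all: dict[str, float] = {}
    ne_estimates: dict[str, float] = {}
    for code in popmap.populations:
        pop_report: dict = {"stage_seeds": {}}
        report["populations"][code] = pop_report
        try:
            sub = genotypes.filter_complete_polymorphic(g, popmap, code)
        except Exception as e:  # noqa: BLE001
            report["errors"][f"{code}/filter"] = str(e)
            continue
        pop_report["n_individuals"] = sub.n_samples
        pop_report["n_loci_complete"] = sub.n_loci
        if sub.n_loci == 0:
            report["errors"][f"{code}/filter"] = "no complete polymorphic loci"
            continue

        summary = diversity.summarize_population(sub)
        pop_report["diversity"] = _jsonable(vars(summary))
        het_all.update(diversity.individual_heterozygosity(sub))

        try:
            ld = ldne.LDNe(sub, cfg.ldne_config).fit()
            pop_report["ldne"] = _jsonable(vars(ld))
            ne_estimates[code] = ld.ne_hat
        except Exception as e:  # noqa: BLE001
            report["errors"][f"{code}/ldne"] = str(e)

        if cfg.run_demography:
            try:
                # genotype-matrix columns are one SNP per locus already, so no
                # first-SNP-per-locus thinning is needed here
                spectrum = sfs.compute_folded_sfs(sub, "all_sites", cfg.n_monomorphic)
                sfs.write_sfs(spectrum, out / f"{code}.sfs")
                fit_cfg = demography.FitConfig(
                    mu=cfg.fit_config.mu,
                    n_runs=cfg.fit_config.n_runs,
                    n_genealogies=cfg.fit_config.n_genealogies,
                    prior_ranges=cfg.fit_config.prior_ranges,
                    seed=_stage_seed(cfg.seed, f"{code}/demography"),
                    generation_time_years=cfg.fit_config.generation_time_years,
                    n_batches=cfg.fit_config.n_batches,
                    nm_maxiter=cfg.fit_config.nm_maxiter,
                )
                pop_report["stage_seeds"]["demography"] = fit_cfg.seed
                model = demography.SFSDemography(spectrum, fit_cfg)
                fit_c, fit_b, delta, weights, chosen = model.fit_compare()
                tbot = fit_b.params["TBOT"]
                pop_report["demography"] = {
                    "constant": _jsonable(vars(fit_c)),
                    "bottleneck": _jsonable(vars(fit_b)),
                    "delta_aic": _jsonable(delta),
                    "akaike_weights": _jsonable(weights),
                    "chosen": chosen.model,
                    "tbot_generations": tbot,
                    "tbot_years": demography.generations_to_years(tbot, fit_cfg),
                    "anthropogenic_window": bool(tbot <= ANTHROPOGENIC_GENERATIONS),
                }
                if cfg.run_bootstrap and chosen.model == "bottleneck":
                    boot = model.bootstrap("bottleneck", cfg.n_boot, point_fit=fit_b)
                    with open(out / f"{code}.bootstrap.tsv", "w") as fh:
                        fh.write("rep\tNCURR\tNANCES\tTBOT\tlnL\n")
                        for i, rep in enumerate(boot.replicates):
                            fh.write(
                                f"{i}\t{rep.params['NCURR']:.1f}\t{rep.params['NANCES']:.1f}"
                                f"\t{rep.params['TBOT']:.1f}\t{rep.max_lnL:.3f}\n"
                            )
                    pop_report["demography"]["bootstrap"] = {
                        "n_replicates": len(boot.replicates),
                        "tbot_central90": _jsonable(boot.central_interval(0.90)),
                        "concordant": boot.concordant,
                    }
            except Exception as e:  # noqa: BLE001
                logger.exception("demography stage failed for %s", code)
                report["errors"][f"{code}/demography"] = str(e)

    # sensitivity: drop top high-Fst loci for the first population pair, rerun LDNe
    if cfg.run_sensitivity and fst_matrix is not None and len(fst_matrix.populations) >= 2:
        try:
            pair = (fst_matrix.populations[0], fst_matrix.populations[1])
            pruned = fst.remove_top_fst_loci(g, popmap, pair, cfg.sensitivity_fraction)
            sens: dict = {"pair": list(pair), "n_loci_removed": g.n_loci - pruned.n_loci}
            for code in pair:
                sub_full = genotypes.filter_complete_polymorphic(g, popmap, code)
                sub_pruned = genotypes.filter_complete_polymorphic(pruned, popmap, code)
                full_ld = ldne.LDNe(sub_full, cfg.ldne_config).fit()
                pruned_ld = ldne.LDNe(sub_pruned, cfg.ldne_config).fit()
                delta_ne = (
                    pruned_ld.ne_hat - full_ld.ne_hat
                    if math.isfinite(pruned_ld.ne_hat) and math.isfinite(full_ld.ne_hat)
                    else math.nan
                )
                sens[code] = {
                    "ne_full": _jsonable(full_ld.ne_hat),
                    "ne_pruned": _jsonable(pruned_ld.ne_hat),
                    "delta_ne": _jsonable(delta_ne),
                    "pruned_within_full_ci": bool(
                        full_ld.ci[0] <= pruned_ld.ne_hat <= full_ld.ci[1]
                    ),
                }
            report["sensitivity"] = sens
        except Exception as e:  # noqa: BLE001
            logger.exception("sensitivity stage failed")
            report["errors"]["sensitivity"] = str(e)

    if cfg.run_hfc and cfg.body_path:
        try:
            records = _load_body(cfg.body_path)
            usable = [r for r in records if r.sample_id in het_all]
            het = {r.sample_id: het_all[r.sample_id] for r in usable}
            model = condition.HFCRegression(
                usable, het, seed=_stage_seed(cfg.seed, "hfc")
            )
            sma_fit, smi, hfc_res = model.fit()
            report["hfc"] = {
                "sma": _jsonable(vars(sma_fit)),
                "result": _jsonable(vars(hfc_res)),
                "stage_seed": _stage_seed(cfg.seed, "hfc"),
            }
        except Exception as e:  # noqa: BLE001
            logger.exception("HFC stage failed")
            report["errors"]["hfc"] = str(e)

    if cfg.run_projection:
        finite = sorted({int(round(v)) for v in ne_estimates.values() if math.isfinite(v) and v >= 2})
        sizes = finite if finite else [50, 30, 10]
        report["projection"] = {}
        for N in sizes:
            seed = _stage_seed(cfg.seed, f"projection/{N}")
            traj = projection.simulate_overlapping(
                cfg.life_history,
                projection.SimConfig(
                    pop_size=N,
                    n_loci=cfg.projection_loci,
                    p_init=cfg.projection_p_init,
                    n_years=cfg.projection_years,
                    n_iterations=cfg.projection_iterations,
                    seed=seed,
                ),
            )
            with open(out / f"projection_N{N}.tsv", "w") as fh:
                fh.write("year\tmean_het\tci_low\tci_high\n")
                for y in range(len(traj.years)):
                    fh.write(
                        f"{traj.years[y]}\t{traj.mean_het[y]:.6f}"
                        f"\t{traj.ci_low[y]:.6f}\t{traj.ci_high[y]:.6f}\n"
                    )
            century = projection.century_projection(traj, N)
            analytic = projection.analytic_decay(
                projection.ProjectionParams(traj.mean_het[0], N, cfg.projection_years)
            )
            report["projection"][str(N)] = {
                "stage_seed": seed,
                "loss_century": century.loss,
                "horizon_step": century.horizon_step,
                "horizon_years": century.horizon_years,
                "time_to_half_years": century.time_to_half_years,
                "half_loss_reached": century.half_loss_reached,
                "analytic_loss_100_generations": 1.0 - analytic / traj.mean_het[0]
                if traj.mean_het[0] > 0
                else 0.0,
            }

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
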