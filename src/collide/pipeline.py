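"""Orchestration: tallies -> disparity -> phylogenetic regressions ->
light models, with table/figure-style CSV outputs, structured logging and
full seed auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import read_records, validate_dataset
from .disparity import MODES, disparity_from_tallies
from .light_models import analyze_light
from .phylo import correlation_matrix, majority_rule_consensus, parse_newick_list
from .regression import (
    LOGISTIC_FORMULAS,
    build_design,
    compare_models,
    fit_phylo_logistic,
    fit_phylo_poisson,
)
from .tallies import DEFAULT_WINDOWS, SeasonWindows, filter_nocturnal_passerines, tally

__all__ = ["RunConfig", "RunResult", "run_analysis", "report_tables"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, analysis switches and seeds for one pipeline run."""

    collisions: str
    checklists: str
    traits: str
    trees: str
    nights: str | None = None
    seasons: tuple[str, ...] = ("spring", "autumn")
    modes: tuple[str, ...] = ("count", "days")
    residual_threshold: float = 3.0
    formulas: tuple[str, ...] = LOGISTIC_FORMULAS
    n_boot: int = 100
    seed: int = 0
    min_species_for_regression: int = 10
    fit_poisson: bool = True
    consensus_branch_lengths: str = "mean"
    windows: SeasonWindows = field(default_factory=SeasonWindows)

    def __post_init__(self) -> None:
        if not self.residual_threshold > 0:
            raise ValueError("residual_threshold must be positive")
        if not self.formulas:
            raise ValueError("need at least one model formula")
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("seasons", "modes", "formulas"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "windows" in raw and isinstance(raw["windows"], dict):
            raw["windows"] = SeasonWindows(
                **{k: tuple(v) for k, v in raw["windows"].items()}
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seasons"], d["modes"], d["formulas"] = (
            list(self.seasons),
            list(self.modes),
            list(self.formulas),
        )
        d["windows"] = dataclasses.asdict(self.windows)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.to_dict().items()}, sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    disparity: pd.DataFrame
    fits: pd.DataFrame
    comparisons: dict
    light: pd.DataFrame | None
    consensus_newick: str
    warnings: list[str]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _float_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_analysis(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute both analysis branches and write the result bundle.

    On any stage failure, partial outputs are removed and a stage-labelled
    error is raised.  Reruns with identical config and inputs are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    warnings: list[str] = []
    stage = "load"
    try:
        collisions = read_records(config.collisions, "collision").records
        checklists = read_records(config.checklists, "checklist").records
        traits = read_records(config.traits, "traits").records
        trees = parse_newick_list(Path(config.trees).read_text(encoding="utf-8"))
        report = validate_dataset(collisions + checklists, traits, config.windows)
        if report.missing_species:
            raise ValueError(f"species missing from trait table: {report.missing_species}")
        if report.duplicate_trait_species:
            raise ValueError(f"duplicate trait rows: {report.duplicate_trait_species}")

        stage = "filter"
        filtered = filter_nocturnal_passerines(collisions, traits)
        filtered_chk = filter_nocturnal_passerines(checklists, traits)
        for cls, n in sorted(filtered.excluded_by_class.items()):
            warnings.append(f"excluded {n} collision records of class {cls}")
        focal = [t for t in traits if t.migratory_class == "nocturnal_passerine"]
        focal_ids = [t.species_id for t in focal]

        stage = "tallies"
        table = tally(
            filtered.records, filtered_chk.records, focal_ids, windows=config.windows
        )
        table.to_csv(outdir / "tallies.csv")

        stage = "phylo"
        consensus = majority_rule_consensus(
            trees, branch_lengths=config.consensus_branch_lengths
        )
        newick = consensus.to_newick()
        (outdir / "consensus.nwk").write_text(newick + "\n", encoding="utf-8")

        stage = "disparity"
        disp_rows = []
        disparity_results = {}
        for season in config.seasons:
            for mode in config.modes:
                res = disparity_from_tallies(
                    table, season, mode, config.residual_threshold
                )
                disparity_results[(season, mode)] = res
                for w in res.dropped_zero_expected:
                    warnings.append(
                        f"{season}/{mode}: dropped zero-checklist species {w}"
                    )
                frame = res.to_frame()
                frame.insert(1, "season", season)
                frame.insert(2, "mode", mode)
                disp_rows.append(frame)
        disparity_frame = pd.concat(disp_rows, ignore_index=True)
        _float_csv(disparity_frame, outdir / "disparity.csv")

        stage = "regression"
        fit_rows = []
        comparisons = {}
        ebird = {}
        for season in config.seasons:
            rows = table.rows(season)
            ebird[season] = {
                "count": rows["n_checklists"].to_dict(),
                "days": rows["n_checklist_days"].to_dict(),
            }
        for (season, mode), res in sorted(disparity_results.items()):
            outcome = res.binary_outcome()
            if len(outcome) < config.min_species_for_regression:
                warnings.append(
                    f"{season}/{mode}: only {len(outcome)} classifiable species; "
                    "regression skipped (disparity branch only)"
                )
                continue
            if outcome.nunique() < 2:
                warnings.append(
                    f"{season}/{mode}: outcome is constant; regression skipped"
                )
                continue
            species = list(outcome.index)
            C = correlation_matrix(consensus, species)
            fits = []
            branch_id = zlib.crc32(f"{season}/{mode}".encode())
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, branch_id])
            )
            for formula in config.formulas:
                X, names, _ = build_design(focal, formula, species=species)
                fit = fit_phylo_logistic(
                    outcome.to_numpy(float),
                    X,
                    C,
                    terms=names,
                    n_boot=config.n_boot,
                    rng=rng,
                    formula=formula,
                )
                fits.append(fit)
            if len(fits) > 1:
                comp = compare_models(fits)
            else:
                from .regression import ModelComparison

                comp = ModelComparison(fits, 0, [0.0])
            comparisons[(season, mode)] = comp
            for fit, dAIC in zip(comp.fits, comp.delta_aic):
                row = {
                    "season": season,
                    "mode": mode,
                    "model": "logistic",
                    "formula": fit.formula,
                    "aic": fit.aic,
                    "delta_aic": dAIC,
                    "loglik": fit.loglik,
                    "signal": fit.signal,
                    "is_best": fit is comp.best_fit,
                    "separation": fit.separation,
                }
                for term, b in fit.coef.items():
                    row[f"coef[{term}]"] = b
                fit_rows.append(row)
            if config.fit_poisson:
                obs_col = "n_collisions" if mode == "count" else "n_collision_days"
                rows_all = table.rows(season)
                usable = rows_all[
                    rows_all[["n_checklists", "n_checklist_days"]].min(axis=1) > 0
                ]
                counts = usable[obs_col].to_numpy(float)
                sp_all = list(usable.index)
                C_all = correlation_matrix(consensus, sp_all)
                X, names, _ = build_design(
                    focal,
                    "ebird_tally + flight_call",
                    species=sp_all,
                    ebird_tallies=ebird[season][mode],
                )
                pfit = fit_phylo_poisson(
                    counts, X, C_all, terms=names, formula="ebird_tally + flight_call"
                )
                row = {
                    "season": season,
                    "mode": mode,
                    "model": "poisson",
                    "formula": pfit.formula,
                    "aic": pfit.aic,
                    "delta_aic": 0.0,
                    "loglik": pfit.loglik,
                    "signal": pfit.signal,
                    "is_best": False,
                    "separation": False,
                }
                for term, b in pfit.coef.items():
                    row[f"coef[{term}]"] = b
                fit_rows.append(row)
        fits_frame = pd.DataFrame(fit_rows)
        _float_csv(fits_frame, outdir / "fits.csv")
        sidecar = _fits_sidecar(comparisons)
        (outdir / "fits.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

        stage = "light"
        light_frame = None
        if config.nights:
            nights = read_records(config.nights, "nights").records
            light = analyze_light(nights, focal, "flight_call")
            light_frame = light.to_frame()
            _float_csv(light_frame, outdir / "light_fits.csv")
            _float_csv(light.score_means, outdir / "light_score_means.csv")

        stage = "report"
        # run log carries no timestamps so reruns stay byte-identical
        run_log = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "warnings": warnings,
        }
        log.info(
            "pipeline finished in %.1fs with %d warnings",
            time.time() - t0,
            len(warnings),
        )
        (outdir / "run_log.json").write_text(
            json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    except Exception as exc:
        if not isinstance(exc, StageError):
            exc = StageError(stage, exc)
        for item in outdir.iterdir():
            if item.is_file():
                item.unlink()
            else:
                shutil.rmtree(item)
        raise exc
    return RunResult(
        config=config,
        disparity=disparity_frame,
        fits=fits_frame,
        comparisons=comparisons,
        light=light_frame,
        consensus_newick=newick,
        warnings=warnings,
    )


def _fits_sidecar(comparisons: dict) -> dict:
    out = {}
    for (season, mode), comp in sorted(comparisons.items()):
        entry = []
        for fit, dAIC in zip(comp.fits, comp.delta_aic):
            entry.append(
                {
                    "formula": fit.formula,
                    "coef": fit.coef,
                    "signal": fit.signal,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "delta_aic": dAIC,
                    "n_boot": fit.n_boot,
                    "bootstrap_ci": fit.bootstrap_ci,
                    "converged": fit.converged,
                    "separation": fit.separation,
                }
            )
        out[f"{season}/{mode}"] = {
            "models": entry,
            "best_formula": comp.best_fit.formula,
        }
    return out


_TABLE_TERMS = [
    ("flight call (yes)", "flight_call[yes]"),
    ("habitat (forest)", "habitat[forest]"),
    ("habitat (open)", "habitat[open]"),
    ("canopy stratum (upper)", "stratum[upper]"),
    ("regional population size", "log_pop_size"),
]


def report_tables(comparisons: dict) -> pd.DataFrame:
    """Headline-table layout: one row per season x (full|best) x mode, one
    column per model term, "--" for covariates absent from the model, and
    significance codes from the bootstrap percentile intervals."""
    rows = []
    for (season, mode), comp in sorted(comparisons.items()):
        full = max(comp.fits, key=lambda f: f.n_params)
        for label, fit in (("full model", full), ("best model", comp.best_fit)):
            row = {"season": f"{season} ({label})"}
            for col, term in _TABLE_TERMS:
                if term in fit.coef:
                    code = ""
                    if fit.bootstrap_ci is not None and term in fit.bootstrap_ci:
                        samples = getattr(fit, "boot_samples", None)
                        if samples is not None:
                            code = fit.significance_code(
                                term, samples[:, fit.terms.index(term)]
                            )
                        else:
                            code = fit.significance_code(term)
                    row[col] = f"{fit.coef[term]:.2f}{code}"
                else:
                    row[col] = "--"
            row["data type"] = mode
            rows.append(row)
    cols = ["season"] + [c for c, _ in _TABLE_TERMS] + ["data type"]
    return pd.DataFrame(rows, columns=cols)
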