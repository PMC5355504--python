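"""End-to-end orchestration: census + genotypes in, fitted model out.

Stages run in dependency order — membership, offspring filtering, paternity,
classification, covariates, home-range overlap, model — with every dropped
row logged with a machine-readable reason, and a run manifest recording the
constants, seed and versions, so a run is auditable and row counts are
conserved at every stage.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ConceptionParams, EXTRA_GROUP, assign_cohort,
                       classify_all, conception_window, tabulate_egp)
from .demography import (Individual, MembershipIndex, MembershipRules,
                         SeasonCalendar, breeding_group_composition,
                         build_membership_intervals, filter_offspring_cohort,
                         sex_ratio)
from .homerange import seasonal_overlap_table
from .metrics import female_synchrony, group_instability
from .model import (ModelSpec, build_model_table, dispersion_parameter,
                    drop1_lrts, fit_poisson_glmm, lrt_full_vs_null,
                    stability_check, vif_check)
from .paternity import GenotypeTable, PaternityParams, assign_all


@dataclass
class PipelineConfig:
    """File paths, stage constants and model flags for one run."""

    census: Optional[str] = None
    sightings: Optional[str] = None
    seasons: Optional[str] = None
    genotypes: Optional[str] = None
    births: Optional[str] = None
    locations: Optional[str] = None
    out_dir: Optional[str] = None

    membership_rules: MembershipRules = field(default_factory=MembershipRules)
    conception_params: ConceptionParams = field(default_factory=ConceptionParams)
    paternity_params: PaternityParams = field(default_factory=PaternityParams)
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    grid_cell_size: float = 25.0
    overlap_zero_floor: Optional[float] = None
    sex_ratio_method: str = "daily"
    run_stability: bool = True
    seed: Optional[int] = None


class StageError(RuntimeError):
    """An error naming the pipeline stage that failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: PipelineConfig):
    from . import io

    missing = [n for n in ("census", "sightings", "seasons", "genotypes",
                           "births", "locations")
               if getattr(config, n) is None or not Path(getattr(config, n)).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    return dict(
        individuals=io.read_census(config.census),
        sightings=io.read_sightings(config.sightings),
        seasons=io.read_seasons(config.seasons),
        genotypes_long=io.read_genotypes(config.genotypes),
        births=io.read_births(config.births),
        locations=io.read_locations(config.locations),
    )


def run_all(config: PipelineConfig,
            inputs: Optional[dict] = None,
            truth=None) -> Dict[str, object]:
    """Execute every stage; returns a results dict and optionally writes CSVs.

    ``inputs`` may carry in-memory tables (same keys as the file readers
    produce) to skip file I/O; ``truth`` is an optional
    :class:`egpkit.simulate.TruthLog` for the truth-vs-pipeline audit.
    Any stage error aborts with the failing stage named.
    """
    results: Dict[str, object] = {}
    exclusions: List[pd.DataFrame] = []

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(name, e) from e

    if inputs is None:
        inputs = stage("load", lambda: _load_inputs(config))
    individuals: List[Individual] = inputs["individuals"]
    seasons: List[SeasonCalendar] = inputs["seasons"]
    births: pd.DataFrame = inputs["births"]

    # -- membership ----------------------------------------------------
    def _membership():
        intervals = build_membership_intervals(
            inputs["sightings"], config.membership_rules, individuals)
        return intervals, MembershipIndex(individuals, intervals)
    intervals, index = stage("membership", _membership)
    results["intervals"] = intervals

    # -- offspring filter ----------------------------------------------
    def _filter():
        genotyped = set(inputs["genotypes_long"]["id"].unique())
        persistent = {s.group for s in seasons}
        return filter_offspring_cohort(births, individuals, genotyped,
                                       persistent)
    retained, excluded = stage("offspring_filter", _filter)
    exclusions.append(excluded.assign(stage="offspring_filter"))
    results["retained_births"] = retained

    # -- paternity ------------------------------------------------------
    def _paternity():
        gt = GenotypeTable.from_long(inputs["genotypes_long"])
        return assign_all(retained, individuals, gt, config.paternity_params)
    assignments = stage("paternity", _paternity)
    results["assignments"] = assignments

    # -- classification -------------------------------------------------
    def _classify():
        cls, dropped = classify_all(retained, assignments, index,
                                    config.conception_params)
        cls = cls.merge(retained[["offspring", "natal_group", "birth_date"]],
                        on="offspring")
        cls["group"] = cls["natal_group"]
        cls["cohort"] = [
            assign_cohort(b, g, seasons, config.conception_params)
            for b, g in zip(cls["birth_date"], cls["group"])]
        return cls.drop(columns=["natal_group", "birth_date"]), dropped
    classifications, dropped = stage("classification", _classify)
    exclusions.append(dropped.assign(stage="classification"))
    results["classifications"] = classifications
    results["egp_table"] = tabulate_egp(classifications)

    # -- group-season covariates ----------------------------------------
    def _covariates():
        rows, dropped_rows = [], []
        birth_cohorts = {
            r.offspring: assign_cohort(r.birth_date, r.natal_group, seasons,
                                       config.conception_params)
            for r in births.itertuples(index=False)}
        cls_by_cell = classifications.groupby(["group", "cohort"])
        counts = {k: (len(v), int((v["status"] == EXTRA_GROUP).sum()))
                  for k, v in cls_by_cell}
        male_counts = {}
        for s in seasons:
            n_f, n_m = breeding_group_composition(
                s.group, s, individuals, index,
                config.membership_rules.maturity_age_days)
            male_counts[(s.group, s.cohort_year)] = n_m
            ratio = sex_ratio(s.group, s, individuals, index,
                              config.sex_ratio_method,
                              config.membership_rules.maturity_age_days)
            windows = [
                conception_window(r.birth_date, config.conception_params,
                                  r.offspring)
                for r in births.itertuples(index=False)
                if r.natal_group == s.group
                and birth_cohorts[r.offspring] == s.cohort_year]
            if not windows:
                dropped_rows.append((s.group, s.cohort_year,
                                     "no_live_births"))
                continue
            syn = female_synchrony(windows, s.group, s.cohort_year)
            inst = group_instability(s.group, s, index,
                                     config.membership_rules.maturity_age_days)
            n_off, n_egp = counts.get((s.group, s.cohort_year), (0, 0))
            rows.append((s.group, s.cohort_year, n_egp, n_off, n_f + n_m,
                         ratio, syn.synchrony, inst.instability))
        cov = pd.DataFrame(rows, columns=[
            "group", "cohort", "egp_count", "n_offspring", "size",
            "sex_ratio", "synchrony", "instability"])
        dropped_df = pd.DataFrame(
            dropped_rows, columns=["group", "cohort", "reason"])
        return cov, dropped_df, male_counts
    covariates, dropped_cells, male_counts = stage("covariates", _covariates)
    results["dropped_group_seasons"] = dropped_cells

    # -- home-range overlap ---------------------------------------------
    def _overlap():
        return seasonal_overlap_table(
            inputs["locations"], seasons, male_counts,
            cell_size=config.grid_cell_size,
            zero_floor=config.overlap_zero_floor)
    overlap = stage("homerange", _overlap)
    covariates = covariates.merge(
        overlap[["group", "cohort", "overlap"]], on=["group", "cohort"])
    results["covariates"] = covariates

    # -- model -----------------------------------------------------------
    def _model():
        empty = covariates["n_offspring"] <= 0
        dropped = covariates.loc[empty, ["group", "cohort"]].assign(
            reason="no_classified_offspring")
        table = build_model_table(covariates.loc[~empty])
        spec = config.model_spec
        fit = fit_poisson_glmm(table, spec)
        out = {
            "model_table": table,
            "fit": fit,
            "lrt_full_vs_null": lrt_full_vs_null(table, spec, full=fit),
            "drop1": drop1_lrts(table, spec, full=fit),
            "dispersion": dispersion_parameter(fit),
            "vif": vif_check(table),
            "dropped_cells": dropped,
        }
        if config.run_stability:
            out["stability"] = stability_check(table, spec)
        return out
    results.update(stage("model", _model))
    cell_drop = results.pop("dropped_cells")
    if len(cell_drop):
        exclusions.append(
            cell_drop.rename(columns={"group": "offspring"})
            .assign(stage="model"))

    # -- audit ------------------------------------------------------------
    results["exclusion_log"] = pd.concat(exclusions, ignore_index=True)
    audit = {
        "n_births_in": int(len(births)),
        "n_retained": int(len(retained)),
        "n_excluded_filter": int(len(exclusions[0])),
        "n_classified": int(len(classifications)),
        "n_unclassifiable": int(len(dropped)),
    }
    assert audit["n_births_in"] == audit["n_retained"] + audit["n_excluded_filter"]
    assert audit["n_retained"] == audit["n_classified"] + audit["n_unclassifiable"]
    results["audit"] = audit

    if truth is not None:
        results["truth_comparison"] = compare_with_truth(
            classifications, assignments, truth)

    if config.out_dir is not None:
        _write_outputs(config, results)
    return results


def compare_with_truth(classifications: pd.DataFrame,
                       assignments: pd.DataFrame, truth) -> Dict[str, object]:
    """Truth-vs-pipeline confusion matrix and sire accuracy for simulated runs."""
    t = truth.parentage.set_index("offspring")
    merged = classifications.join(
        t[["sire", "egp"]].rename(columns={"sire": "true_sire",
                                           "egp": "true_egp"}),
        on="offspring", how="inner")
    merged["pipeline_egp"] = merged["status"] == EXTRA_GROUP
    cm = pd.crosstab(merged["true_egp"], merged["pipeline_egp"],
                     rownames=["truth"], colnames=["pipeline"], dropna=False)
    a = assignments[assignments["sire"].notna()].set_index("offspring")
    sire_ok = (a["sire"] == t["sire"].reindex(a.index)).mean()
    return {
        "confusion_matrix": cm,
        "egp_flag_accuracy": float(
            (merged["true_egp"] == merged["pipeline_egp"]).mean()),
        "sire_accuracy": float(sire_ok),
        "n_compared": int(len(merged)),
    }


def _write_outputs(config: PipelineConfig, results: Dict[str, object]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["assignments"].to_csv(out / "assignments.csv", index=False)
    results["classifications"].to_csv(out / "classifications.csv", index=False)
    results["egp_table"].to_csv(out / "egp_by_group_season.csv", index=False)
    results["covariates"].to_csv(out / "covariates.csv", index=False)
    results["exclusion_log"].to_csv(out / "exclusions.csv", index=False)
    fit = results["fit"]
    summary = fit.summary().reset_index(names="term")
    lrt = results["lrt_full_vs_null"]
    summary.to_csv(out / "model_summary.csv", index=False)
    results["drop1"].to_csv(out / "model_drop1.csv", index=False)
    if "stability" in results:
        results["stability"].to_csv(out / "model_stability.csv", index=False)
    if "truth_comparison" in results:
        tc = results["truth_comparison"]
        tc["confusion_matrix"].to_csv(out / "truth_confusion_matrix.csv")
    manifest = {
        "egpkit_version": __version__,
        "seed": config.seed,
        "membership_rules": dataclasses.asdict(config.membership_rules),
        "conception_params": dataclasses.asdict(config.conception_params),
        "paternity_params": dataclasses.asdict(config.paternity_params),
        "model_spec": dataclasses.asdict(config.model_spec),
        "grid_cell_size": config.grid_cell_size,
        "sex_ratio_method": config.sex_ratio_method,
        "conception_window_discretization":
            "offsets [ceil(mean-sd), ceil(mean-sd)+floor(2 sd)] days before birth",
        "python": sys.version.split()[0],
        "audit": results["audit"],
        "model": {
            "loglik": fit.loglik,
            "converged": fit.converged,
            "dispersion": results["dispersion"],
            "lrt_full_vs_null": dataclasses.asdict(lrt),
            "variance_components": fit.variance_components.to_dict(),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
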