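"""Shared fixtures: one default synthetic world, its pipeline run, and the
model-level simulation harnesses reused by several tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from egpkit.model import (ModelSpec, fit_poisson_glmm, lrt_full_vs_null,
                          simulate_model_table)
from egpkit.pipeline import PipelineConfig, run_all
from egpkit.simulate import SimConfig, simulate_all

NULL_BETA = {"intercept": float(np.log(0.16))}
EFFECT_BETA = {"intercept": float(np.log(0.16)), "sex_ratio": 0.3,
               "group_size": -0.3, "synchrony": -0.4, "instability": -0.25,
               "sex_ratio:group_size": 0.2}
RE_INTERCEPTS = {"group:intercept": 0.2, "cohort:intercept": 0.15}
NO_SLOPES = ModelSpec(include_random_slopes=False)
# replication design for the simulation harnesses: 4x the 54-point study
REP_GROUPS, REP_COHORTS = 12, 18


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic world (the generator's stated conditions)."""
    return simulate_all(SimConfig(seed=20240901))


@pytest.fixture(scope="session")
def sim_inputs(default_sim):
    return dict(
        individuals=default_sim.individuals(),
        sightings=default_sim.sightings,
        seasons=default_sim.season_calendar(),
        genotypes_long=default_sim.genotypes,
        births=default_sim.births,
        locations=default_sim.locations,
    )


@pytest.fixture(scope="session")
def pipeline_results(default_sim, sim_inputs):
    """Full pipeline run on the default world with the truth audit."""
    return run_all(PipelineConfig(run_stability=False), inputs=sim_inputs,
                   truth=default_sim.truth)


@pytest.fixture(scope="session")
def calibration_summaries():
    """Per-seed summaries of the default generator over 20 root seeds."""
    out = []
    for seed in range(20):
        sim = simulate_all(SimConfig(seed=seed))
        cov = sim.truth.covariates
        out.append({
            "mean_size": float(cov["size"].mean()),
            "mean_sex_ratio": float(cov["sex_ratio"].mean()),
            "mean_synchrony": float(cov["synchrony"].mean()),
            "mean_instability": float(cov["instability"].mean()),
            "n_births": int(len(sim.truth.parentage)),
            "n_egp": int(sim.truth.parentage["egp"].sum()),
        })
    return out


@pytest.fixture(scope="session")
def null_model_sims():
    """200 replicate fits under the null (all slopes zero): full + null
    model at the 4x replication design, random intercepts only."""
    rows = []
    for rep in range(200):
        rng = np.random.default_rng(50_000 + rep)
        t = simulate_model_table(NULL_BETA, RE_INTERCEPTS, rng,
                                 n_groups=REP_GROUPS, n_cohorts=REP_COHORTS)
        full = fit_poisson_glmm(t, NO_SLOPES)
        lrt = lrt_full_vs_null(t, NO_SLOPES, full=full)
        rec = {"p": lrt.p, "chi2": lrt.chi2, "converged": full.converged,
               "table": t if rep < 30 else None}
        for term in full.estimates.index:
            rec[f"est:{term}"] = full.estimates[term]
            rec[f"se:{term}"] = full.std_errors[term]
        rows.append(rec)
    return rows


@pytest.fixture(scope="session")
def effect_model_sims():
    """100 replicate fits with the stated effect sizes; random intercepts
    in both the generating process and the fitted model (the desk-scale
    recovery harness; the random-slope configuration is exercised by the
    end-to-end pipeline tests)."""
    rows = []
    for rep in range(100):
        rng = np.random.default_rng(90_000 + rep)
        t = simulate_model_table(EFFECT_BETA, RE_INTERCEPTS, rng,
                                 n_groups=REP_GROUPS, n_cohorts=REP_COHORTS)
        fit = fit_poisson_glmm(t, NO_SLOPES)
        rec = {"converged": fit.converged}
        for term in fit.estimates.index:
            rec[f"est:{term}"] = fit.estimates[term]
            rec[f"se:{term}"] = fit.std_errors[term]
        rows.append(rec)
    return rows


@pytest.fixture(scope="session")
def coverage_sims():
    """500 replicates (250 null + 250 with effects) for Wald-interval
    coverage, intercept-only random effects fitted as simulated."""
    rows = []
    for rep in range(500):
        rng = np.random.default_rng(70_000 + rep)
        beta = NULL_BETA if rep < 250 else EFFECT_BETA
        t = simulate_model_table(beta, RE_INTERCEPTS, rng,
                                 n_groups=REP_GROUPS, n_cohorts=REP_COHORTS)
        fit = fit_poisson_glmm(t, NO_SLOPES)
        truth = {term: beta.get(term, 0.0) for term in fit.estimates.index}
        covered = {
            term: abs(fit.estimates[term] - truth[term])
            <= 1.96 * fit.std_errors[term]
            for term in fit.estimates.index if term != "intercept"}
        rows.append({"covered": covered, "converged": fit.converged})
    return rows
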