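"""The group-season Poisson mixed model: table building, fitting, inference."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from egpkit.glmm import GLMMDesign, GLMMResult
from egpkit.model import (ModelSpec, build_model_table, dispersion_parameter,
                          drop1_lrts, fit_poisson_glmm, lrt_full_vs_null,
                          simulate_model_table, stability_check, vif_check)

NO_SLOPES = ModelSpec(include_random_slopes=False)


def example_table(seed=42, **kw):
    rng = np.random.default_rng(seed)
    beta = {"intercept": float(np.log(0.16)), "sex_ratio": 0.3,
            "group_size": -0.3, "synchrony": -0.4, "instability": -0.25,
            "sex_ratio:group_size": 0.2}
    re_sd = {"group:intercept": 0.2, "cohort:intercept": 0.15}
    return simulate_model_table(beta, re_sd, rng, **kw)


def raw_covariates(seed=0, n=54):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "group": np.repeat([f"G{i}" for i in range(6)], n // 6),
        "cohort": np.tile(np.arange(2004, 2004 + n // 6), 6),
        "egp_count": rng.integers(0, 10, n),
        "n_offspring": rng.integers(20, 60, n),
        "size": rng.normal(82, 40, n),
        "sex_ratio": rng.normal(1.6, 0.3, n),
        "synchrony": rng.uniform(0.1, 0.2, n),
        "instability": rng.uniform(0, 1e-3, n),
        "overlap": rng.uniform(1, 10, n),
    })


class TestModelTable:
    def test_z_scores_and_offsets(self):
        t = build_model_table(raw_covariates())
        assert len(t) == 54
        for p in ("sex_ratio", "group_size", "synchrony", "instability"):
            col = t[f"z_{p}"]
            assert col.mean() == pytest.approx(0.0, abs=1e-10)
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(t["log_offspring"], np.log(t["n_offspring"]))
        assert np.allclose(t["log_overlap"], np.log(t["overlap"]))

    def test_bad_rows_named(self):
        cov = raw_covariates()
        cov.loc[3, "overlap"] = 0.0
        with pytest.raises(ValueError, match="non-positive overlap"):
            build_model_table(cov)
        cov = raw_covariates()
        cov.loc[5, "n_offspring"] = 0
        with pytest.raises(ValueError, match="no offspring"):
            build_model_table(cov)

    def test_constant_predictor_rejected(self):
        cov = raw_covariates()
        cov["synchrony"] = 0.15
        with pytest.raises(ValueError, match="constant"):
            build_model_table(cov)

    def test_egp_count_cannot_exceed_offspring(self):
        cov = raw_covariates()
        cov.loc[0, "egp_count"] = cov.loc[0, "n_offspring"] + 1
        with pytest.raises(ValueError, match="exceeds"):
            build_model_table(cov)


class TestOffsets:
    def test_scaling_offspring_shifts_intercept_by_minus_log_k(self):
        """Multiplying the exposure by k must move only the intercept, by
        exactly -log k (offset coefficient fixed at 1)."""
        t = example_table()
        k = 3.0
        t2 = t.copy()
        t2["n_offspring"] *= k
        t2["log_offspring"] = np.log(t2["n_offspring"])
        f1 = fit_poisson_glmm(t, NO_SLOPES)
        f2 = fit_poisson_glmm(t2, NO_SLOPES)
        shift = f2.estimates["intercept"] - f1.estimates["intercept"]
        assert shift == pytest.approx(-np.log(k), abs=2e-3)
        for term in ("sex_ratio", "synchrony"):
            assert f2.estimates[term] == pytest.approx(
                f1.estimates[term], abs=2e-3)


class TestVIF:
    def _table_with_predictors(self, X):
        n = len(X)
        df = raw_covariates(n=n)
        t = build_model_table(df)
        for j, p in enumerate(("sex_ratio", "group_size", "synchrony",
                               "instability")):
            t[f"z_{p}"] = X[:, j]
        return t

    def _orthonormal(self, n=54, k=4, seed=1):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(n, k))
        M = M - M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        Q = Q - Q.mean(axis=0)
        return Q / Q.std(axis=0, ddof=1)

    def test_orthogonal_predictors_have_unit_vif(self):
        t = self._table_with_predictors(self._orthonormal())
        assert np.allclose(vif_check(t).to_numpy(), 1.0, atol=1e-8)

    def test_correlated_pair_closed_form(self):
        """r = 0.8 between two predictors -> VIF = 1/(1-0.64) ~ 2.78."""
        Q = self._orthonormal()
        X = Q.copy()
        X[:, 1] = 0.8 * Q[:, 0] + 0.6 * Q[:, 1]
        t = self._table_with_predictors(X)
        v = vif_check(t)
        assert v["sex_ratio"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)
        assert v["group_size"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)
        assert v["synchrony"] == pytest.approx(1.0, abs=1e-8)

    def test_perfect_collinearity_reported(self):
        Q = self._orthonormal()
        X = Q.copy()
        X[:, 1] = Q[:, 0]
        t = self._table_with_predictors(X)
        with pytest.raises(ValueError, match="collinear"):
            vif_check(t)


class TestDispersion:
    def test_zero_when_fit_is_exact(self):
        y = np.array([3.0, 7.0, 2.0, 9.0, 4.0])
        design = GLMMDesign(y=y, X=np.ones((5, 1)), Z=np.zeros((5, 0)),
                            offset=np.log(y), theta_map=np.zeros(0, int),
                            fixed_names=["intercept"], theta_names=[])
        res = GLMMResult(beta=np.zeros(1), se=np.zeros(1),
                         theta=np.zeros(0), u=np.zeros(0), loglik=0.0,
                         converged=True, singular=False, n_iter=0,
                         design=design)
        fit = type("F", (), {"result": res})()
        assert dispersion_parameter(fit) == pytest.approx(0.0, abs=1e-20)

    def test_overdispersed_counts_detected(self):
        """Negative-binomial responses (variance > mean) push the Pearson
        dispersion above 1."""
        t = example_table(seed=9)
        rng = np.random.default_rng(10)
        mu = t["egp_count"].to_numpy() + 1.0
        t["egp_count"] = rng.negative_binomial(2, 2 / (2 + mu))
        t["n_offspring"] = np.maximum(t["n_offspring"],
                                      t["egp_count"] + 1)
        fit = fit_poisson_glmm(t, NO_SLOPES)
        assert dispersion_parameter(fit) > 1.0

    def test_near_one_for_well_specified_model(self, null_model_sims):
        disp = []
        for rec in null_model_sims[:30]:
            fit = fit_poisson_glmm(rec["table"], NO_SLOPES)
            disp.append(dispersion_parameter(fit))
        assert 0.85 <= float(np.mean(disp)) <= 1.15


class TestInference:
    def test_lrt_nonnegative_with_df5(self):
        t = example_table(seed=4)
        r = lrt_full_vs_null(t, NO_SLOPES)
        assert r.chi2 >= 0.0
        assert r.df == 5
        assert 0.0 <= r.p <= 1.0

    def test_drop1_layout(self):
        """Interaction, synchrony, instability tested in the full model;
        the interaction components in the reduced model; all single-df."""
        t = example_table(seed=4)
        d = drop1_lrts(t, NO_SLOPES)
        assert set(d["term"]) == {"sex_ratio:group_size", "synchrony",
                                  "instability", "sex_ratio", "group_size"}
        assert (d["df"] == 1).all()
        assert (d["chi2"] >= 0).all()
        assert set(d.loc[d["model"] == "reduced", "term"]) == {
            "sex_ratio", "group_size"}

    def test_drop1_rarely_rejects_a_null_term(self, null_model_sims):
        """A predictor simulated with zero effect should be dropped without
        a significant LRT about 95% of the time."""
        ps = []
        for rec in null_model_sims[:30]:
            d = drop1_lrts(rec["table"], NO_SLOPES)
            ps.append(float(d.loc[d["term"] == "synchrony", "p"].iloc[0]))
        assert sum(p < 0.05 for p in ps) <= 5

    def test_null_fits_keep_estimates_within_two_se(self, null_model_sims):
        """With every slope simulated at zero, |estimate| < 2 SE should hold
        for ~95% of replicates, per coefficient."""
        for term in ("sex_ratio", "group_size", "synchrony", "instability",
                     "sex_ratio:group_size"):
            est = np.array([r[f"est:{term}"] for r in null_model_sims])
            se = np.array([r[f"se:{term}"] for r in null_model_sims])
            assert (np.abs(est) < 2 * se).mean() >= 0.90


class TestStability:
    def test_leave_one_out_structure_and_agreement(self):
        """6 + 9 refits; each leave-one-group-out subset loses 9 rows; on
        homogeneous data every refit stays within 2 SE of the full fit."""
        t = example_table(seed=12)
        full = fit_poisson_glmm(t, NO_SLOPES)
        out = stability_check(t, NO_SLOPES)
        assert len(out) == 15
        assert (out["excluded_factor"] == "group").sum() == 6
        sub = t[t["group"] != "G0"]
        assert len(t) - len(sub) == 9
        for term in full.estimates.index:
            dev = (out[term] - full.estimates[term]).abs()
            assert (dev <= 2 * full.std_errors[term] + 1e-8).all()


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available")
def test_fixed_effects_match_lme4_reference(tmp_path):
    """Laplace ML estimates agree with glmer on the same crossed-random-
    intercept Poisson model within 1e-3 on every fixed effect."""
    t = example_table(seed=7, n_groups=6, n_cohorts=9)
    csv = tmp_path / "table.csv"
    t.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$off <- d$log_offspring + d$log_overlap
        m <- glmer(egp_count ~ z_sex_ratio + z_group_size + z_synchrony +
                   z_instability + z_sex_ratio:z_group_size + offset(off) +
                   (1|group) + (1|cohort), data=d, family=poisson)
        cat(fixef(m), sep=",")
        cat("\\n")
        cat(as.numeric(logLik(m)), "\\n")
    """))
    res = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    lines = [l for l in res.stdout.strip().splitlines() if l.strip()]
    r_fixef = np.array([float(v) for v in lines[0].split(",")])
    r_loglik = float(lines[1])
    fit = fit_poisson_glmm(t, NO_SLOPES)
    order = ["intercept", "sex_ratio", "group_size", "synchrony",
             "instability", "sex_ratio:group_size"]
    ours = fit.estimates[order].to_numpy()
    np.testing.assert_allclose(ours, r_fixef, atol=1e-3)
    assert fit.loglik == pytest.approx(r_loglik, abs=5e-3)
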