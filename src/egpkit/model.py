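"""The group-season Poisson mixed model of extra-group paternity counts.

One row per group-season: the response is the number of extra-group
offspring, with log total offspring and log home-range overlap as offsets.
Fixed effects are the z-scored group covariates (sex ratio, group size,
their interaction, female synchrony, group instability); group and cohort
enter as crossed random intercepts with (optionally) uncorrelated random
slopes for each main effect.  Inference is by likelihood-ratio tests: the
full model against a null retaining only random effects and offsets, and
single-term deletions in which the two interaction components are tested in
a reduced, interaction-free model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMDesign, GLMMResult, fit_laplace

PREDICTORS = ("sex_ratio", "group_size", "synchrony", "instability")
INTERACTION = "sex_ratio:group_size"


@dataclass(frozen=True)
class ModelSpec:
    """Configuration flags for the group-season model."""

    include_interaction: bool = True
    include_random_slopes: bool = True
    null_model: bool = False  # fixed part reduced to the intercept
    convergence_tol: float = 1e-8

    @property
    def fixed_terms(self) -> Tuple[str, ...]:
        if self.null_model:
            return ("intercept",)
        terms = ("intercept",) + PREDICTORS
        if self.include_interaction:
            terms = terms + (INTERACTION,)
        return terms


@dataclass
class ModelFit:
    """A fitted group-season model with glmer-style components."""

    spec: ModelSpec
    result: GLMMResult
    table: pd.DataFrame

    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(self.result.beta, index=self.result.design.fixed_names)

    @property
    def std_errors(self) -> pd.Series:
        return pd.Series(self.result.se, index=self.result.design.fixed_names)

    @property
    def variance_components(self) -> pd.Series:
        """Random-effect standard deviations."""
        return pd.Series(self.result.theta,
                         index=self.result.design.theta_names)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.estimates,
            "std_error": self.std_errors,
        })


def build_model_table(covariates: pd.DataFrame,
                      validate: bool = True) -> pd.DataFrame:
    """Z-score the predictors and attach the two log offsets.

    ``covariates`` needs columns ``group, cohort, egp_count, n_offspring,
    size, sex_ratio, synchrony, instability, overlap``.  Returns a copy with
    ``z_*`` predictor columns (mean 0, SD 1) and ``log_offspring`` /
    ``log_overlap`` offsets.  A full six-group, nine-cohort design yields 54
    rows.
    """
    required = {"group", "cohort", "egp_count", "n_offspring", "size",
                "sex_ratio", "synchrony", "instability", "overlap"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns {sorted(missing)}")
    df = covariates.copy().reset_index(drop=True)
    bad = df["n_offspring"] <= 0
    if bad.any():
        r = df.loc[bad].iloc[0]
        raise ValueError(f"no offspring in row {r['group']}/{r['cohort']}")
    bad = df["overlap"] <= 0
    if bad.any():
        r = df.loc[bad].iloc[0]
        raise ValueError(
            f"non-positive overlap in row {r['group']}/{r['cohort']}; the log "
            "offset is undefined")
    if validate and (df["egp_count"] > df["n_offspring"]).any():
        raise ValueError("egp_count exceeds n_offspring in some row")
    source = {"sex_ratio": "sex_ratio", "group_size": "size",
              "synchrony": "synchrony", "instability": "instability"}
    for name, col in source.items():
        x = df[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, float(np.abs(x).max())):
            raise ValueError(f"predictor {col!r} is constant; cannot z-score")
        df[f"z_{name}"] = (x - x.mean()) / sd
    df["log_offspring"] = np.log(df["n_offspring"].to_numpy(dtype=float))
    df["log_overlap"] = np.log(df["overlap"].to_numpy(dtype=float))
    return df


def _design(table: pd.DataFrame, spec: ModelSpec) -> GLMMDesign:
    n = len(table)
    y = table["egp_count"].to_numpy(dtype=float)
    offset = (table["log_offspring"] + table["log_overlap"]).to_numpy(dtype=float)

    cols = {"intercept": np.ones(n)}
    for p in PREDICTORS:
        cols[p] = table[f"z_{p}"].to_numpy(dtype=float)
    cols[INTERACTION] = cols["sex_ratio"] * cols["group_size"]
    fixed_names = list(spec.fixed_terms)
    X = np.column_stack([cols[t] for t in fixed_names])

    # crossed random effects: intercept (+ uncorrelated main-effect slopes)
    re_terms = ["intercept"]
    if spec.include_random_slopes:
        re_terms += list(PREDICTORS)
    z_blocks, theta_map, theta_names = [], [], []
    for factor in ("group", "cohort"):
        codes, levels = pd.factorize(table[factor], sort=True)
        ind = np.zeros((n, len(levels)))
        ind[np.arange(n), codes] = 1.0
        for term in re_terms:
            z_blocks.append(ind * cols[term][:, None])
            theta_map.extend([len(theta_names)] * len(levels))
            theta_names.append(f"{factor}:{term}")
    Z = np.hstack(z_blocks) if z_blocks else np.zeros((n, 0))
    return GLMMDesign(y=y, X=X, Z=Z, offset=offset,
                      theta_map=np.asarray(theta_map, dtype=np.intp),
                      fixed_names=fixed_names, theta_names=theta_names)


def fit_poisson_glmm(table: pd.DataFrame,
                     spec: ModelSpec = ModelSpec()) -> ModelFit:
    """Fit the Poisson mixed model for a prepared group-season table."""
    for factor in ("group", "cohort"):
        if table[factor].nunique() < 2:
            raise ValueError(f"grouping factor {factor!r} needs >= 2 levels")
    design = _design(table, spec)
    result = fit_laplace(design, tol=spec.convergence_tol)
    return ModelFit(spec=spec, result=result, table=table)


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt_full_vs_null(table: pd.DataFrame, spec: ModelSpec = ModelSpec(),
                     full: Optional[ModelFit] = None) -> LRTResult:
    """Likelihood-ratio test of all fixed effects against the null model
    that keeps only the random effects (and slopes) plus the offsets."""
    if full is None:
        full = fit_poisson_glmm(table, spec)
    null = fit_poisson_glmm(table, replace(spec, null_model=True))
    df = len(full.result.design.fixed_names) - 1
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    return LRTResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def _drop_term_fit(table: pd.DataFrame, spec: ModelSpec, term: str) -> float:
    """Log-likelihood of the model with one fixed term removed (random
    slopes untouched)."""
    design = _design(table, spec)
    keep = [i for i, t in enumerate(design.fixed_names) if t != term]
    if len(keep) == len(design.fixed_names):
        raise ValueError(f"term {term!r} not in the model")
    design = GLMMDesign(
        y=design.y, X=design.X[:, keep], Z=design.Z, offset=design.offset,
        theta_map=design.theta_map,
        fixed_names=[design.fixed_names[i] for i in keep],
        theta_names=design.theta_names)
    return fit_laplace(design, tol=spec.convergence_tol).loglik


def drop1_lrts(table: pd.DataFrame, spec: ModelSpec = ModelSpec(),
               full: Optional[ModelFit] = None) -> pd.DataFrame:
    """Single-term likelihood-ratio tests.

    The interaction, synchrony and instability are tested against the full
    model; sex ratio and group size (the interaction components) are tested
    within the reduced, interaction-free model, whose estimates are the
    interpretable ones for those terms.  Returns one row per term with the
    model it was tested in.
    """
    if full is None:
        full = fit_poisson_glmm(table, spec)
    rows = []
    full_terms = [t for t in full.result.design.fixed_names
                  if t != "intercept"]
    in_interaction = {"sex_ratio", "group_size"} if spec.include_interaction \
        else set()
    for term in full_terms:
        if term in in_interaction:
            continue
        ll = _drop_term_fit(table, spec, term)
        chi2 = max(0.0, 2.0 * (full.loglik - ll))
        rows.append((term, "full", chi2, 1, float(stats.chi2.sf(chi2, 1))))
    if in_interaction:
        red_spec = replace(spec, include_interaction=False)
        reduced = fit_poisson_glmm(table, red_spec)
        for term in sorted(in_interaction):
            ll = _drop_term_fit(table, red_spec, term)
            chi2 = max(0.0, 2.0 * (reduced.loglik - ll))
            rows.append((term, "reduced", chi2, 1,
                         float(stats.chi2.sf(chi2, 1))))
    return pd.DataFrame(rows, columns=["term", "model", "chi2", "df", "p"])


def dispersion_parameter(fit: ModelFit) -> float:
    """Sum of squared Pearson residuals over residual degrees of freedom.

    Residual df = n - (fixed effects + variance parameters), the model's
    estimated-parameter count; > 1 signals overdispersion.
    """
    y = fit.result.design.y
    mu = fit.result.fitted
    pearson = (y - mu) / np.sqrt(np.maximum(mu, 1e-12))
    n_par = len(fit.result.beta) + fit.result.design.n_theta
    rdf = len(y) - n_par
    if rdf <= 0:
        raise ValueError("no residual degrees of freedom")
    return float((pearson ** 2).sum() / rdf)


def vif_check(table: pd.DataFrame) -> pd.Series:
    """Variance-inflation factors from a fixed-effects-only model without
    the interaction: each predictor regressed on the other three."""
    Xall = {p: table[f"z_{p}"].to_numpy(dtype=float) for p in PREDICTORS}
    out = {}
    for p in PREDICTORS:
        yv = Xall[p]
        others = np.column_stack([np.ones(len(yv))]
                                 + [Xall[o] for o in PREDICTORS if o != p])
        coef, *_ = np.linalg.lstsq(others, yv, rcond=None)
        resid = yv - others @ coef
        ss_tot = ((yv - yv.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot
        if r2 > 1.0 - 1e-10:
            raise ValueError(f"predictor {p!r} is perfectly collinear; VIF "
                             "diverges")
        out[p] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def stability_check(table: pd.DataFrame, spec: ModelSpec = ModelSpec()
                    ) -> pd.DataFrame:
    """Leave-one-group-out and leave-one-cohort-out refits.

    Returns one row per excluded level with the fixed-effect estimates,
    for comparison with the full-data fit.
    """
    rows = []
    for factor in ("group", "cohort"):
        for level in sorted(table[factor].unique()):
            sub = table[table[factor] != level]
            fit = fit_poisson_glmm(sub, spec)
            rec = {"excluded_factor": factor, "excluded_level": level,
                   "converged": fit.converged}
            rec.update(fit.estimates.to_dict())
            rows.append(rec)
    return pd.DataFrame(rows)


def simulate_model_table(beta: Dict[str, float],
                         re_sd: Dict[str, float],
                         rng: np.random.Generator,
                         n_groups: int = 6, n_cohorts: int = 9,
                         mean_offspring: float = 45.0,
                         overlap_log_sd: float = 0.3) -> pd.DataFrame:
    """Simulate a group-season table directly from the model.

    Used by the parameter-recovery and calibration harnesses: predictors
    are drawn standard normal (then z-scored exactly), random effects from
    the named SD entries (keys like ``group:intercept``,
    ``cohort:sex_ratio``), and the response from the Poisson model with
    both offsets.  ``beta`` keys follow the fixed-term names.
    """
    n = n_groups * n_cohorts
    groups = np.repeat([f"G{i}" for i in range(n_groups)], n_cohorts)
    cohorts = np.tile(np.arange(2004, 2004 + n_cohorts), n_groups)
    df = pd.DataFrame({"group": groups, "cohort": cohorts})
    raw = {}
    for p in PREDICTORS:
        x = rng.standard_normal(n)
        raw[p] = (x - x.mean()) / x.std(ddof=1)
    n_off = np.maximum(
        5, rng.poisson(mean_offspring, n)).astype(float)
    overlap = np.exp(rng.normal(0.0, overlap_log_sd, n))
    eta = np.log(n_off) + np.log(overlap)
    cols = {"intercept": np.ones(n), **raw,
            INTERACTION: raw["sex_ratio"] * raw["group_size"]}
    for term, b in beta.items():
        eta = eta + b * cols[term]
    for factor, codes in (("group", pd.factorize(groups)[0]),
                          ("cohort", pd.factorize(cohorts)[0])):
        n_lev = codes.max() + 1
        for term in ("intercept",) + PREDICTORS:
            sd = re_sd.get(f"{factor}:{term}", 0.0)
            if sd > 0:
                b = rng.normal(0.0, sd, n_lev)
                eta = eta + b[codes] * cols[term]
    y = rng.poisson(np.exp(eta))
    out = pd.DataFrame({
        "group": groups, "cohort": cohorts, "egp_count": y,
        "n_offspring": n_off, "size": raw["group_size"],
        "sex_ratio": raw["sex_ratio"], "synchrony": raw["synchrony"],
        "instability": raw["instability"], "overlap": overlap,
    })
    return build_model_table(out, validate=False)
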