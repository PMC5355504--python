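# Methods

`egpkit` implements a complete analysis of extra-group paternity (EGP) in a
seasonally breeding, group-living primate population: which offspring were
sired by males from outside their mother's group, and which group-level
conditions predict how often that happens.  This note documents the models
and procedures, the constants and their defaults, what the synthetic
generator does and does not emulate, and the numerical choices.

## Male group membership

Males disperse between groups; females are philopatric and counted as
members of their natal group for life (while alive).  Male residence is
derived from near-daily census sightings:

- a candidate transfer to a new group is confirmed once the sighted group
  has remained constant for **30 days** (`routine_confirm_days`);
- if any sighting within those first 30 days is non-routine (prospecting,
  bachelor group, solitary), confirmation requires **60 days**
  (`prospecting_confirm_days`);
- the immigration date is the first day the male was seen in the new group;
  the previous interval ends the day before; death closes an open interval;
- one group per male per day (validated invariant).

"Constant" tolerates census gaps up to `max_gap_days` (default 7); the rule
presumes a near-daily census, which the generator respects.  If the data end
while a transfer is pending, the confirmed interval is closed on the day
before the male was first seen away, and no interval is opened for the
unconfirmed group.

Tenure is an inclusive day count (start day = tenure 1), so a male lost on
the day he joined still contributes weight to the instability numerator.
All dates are ISO-8601 calendar dates; intervals are closed on both ends.

## Paternity by locus exclusion

Candidates for an infant's paternity are genotyped males older than
**1250 days** at presence check and alive **200 days** before the infant's
birth (a conservative bound on the conception date given gestation
166.5 ± 7.4 days).  At each locus jointly typed in offspring, mother and
candidate, the candidate is *excluded* if no assignment lets one offspring
allele come from the mother and the other from the candidate.  Loci where
mother and offspring share no allele are attributed to maternity (maternity
is confirmed first; `maternity_max_mismatch` defaults to 0) and skipped.

Assignment rules: **strict** (sire 0 mismatches, all others excluded at ≥2
loci), **relaxed** (sire 0, runner-up excluded at exactly 1 locus),
**one-mismatch** (sire exactly 1, all others ≥2).  Ties are never broken;
at least 13 jointly typed loci (`min_joint_loci`, half the mean 27.6-locus
panel) are required to attempt assignment.  Likelihood-based confidence
(Cervus-style) is deliberately not reimplemented.

## Conception windows and EGP classification

The conception window subtracts gestation mean ± SD from the birth date and
discretizes to whole days: offsets `ceil(mean − sd)` through
`ceil(mean − sd) + floor(2·sd)` before birth.  For 166.5 ± 7.4 this is
[160, 174] — 15 consecutive dates, the only whole-day discretization with
the correct span (the naive bracket `[ceil(159.1), floor(173.9)]` has 14
days).  The EGP evaluation window pads the conception window by
`egp_buffer_days = 30` on each side (75 days), so a sire who merely
migrated around conception is not mistaken for an extra-group male: an
offspring is **within-group** iff its sire was a member of the offspring's
group on ≥1 of those 75 days, else **extra-group**.  Offspring without an
assigned sire are excluded and logged.  Under a Normal(166.5, 7.4)
gestation the window covers the true conception date for ≈68% of births
(±1 SD); this is a property of the window's construction, not an error.

## Group-season covariates

One row per group × birth cohort (6 × 9 = 54 in the full design):

- **Breeding group size** — members older than 1250 days (strictly) at
  mating-season onset.
- **Sex ratio** — mean daily count of mature females over mean daily count
  of mature males across the season (configurable to a single onset
  census; the averaging window is not fixed by the field convention).
- **Female synchrony** — 15 / U, where U is the number of unique dates on
  which at least one live-birth mother's conception window was open.  1 if
  all windows coincide; 15/(15 n) when n windows are disjoint.  Live births
  only (miscarriages unobserved).
- **Group instability** — daily membership loss (sum of leavers'
  previous-day tenures over all males' previous-day tenures) and daily
  gain (new males over current mature group size), each averaged over the
  season with weights 1/(t+1), t days after onset (the +1 avoids division
  by zero at onset; "inverse time lag" leaves lag zero undefined), then
  summed.  The loss/gain denominator asymmetry (tenures vs head count)
  follows the index's definition.
- **Home-range overlap** — each group-season range is the minimum convex
  polygon of its daily location records; a grid (default **25 m** cells —
  the 15.2 ha island then spans a usable ~16 × 16 grid — anchored at a
  fixed origin) is laid over it; a cell belongs to the range if its center
  is inside or on the hull (boundary counts); male density = breeding
  males / cells; the overlap index sums other groups' densities over the
  focal cells.  Coordinates are planar; no geodesy at island scale.  The
  index is intentionally asymmetric between group pairs.

## The count model

For group *g*, cohort *c*:

    EGP_count_gc ~ Poisson(mu_gc)
    log mu_gc = log N_gc + log O_gc            (offsets, coefficients = 1)
              + b0 + b1 z(sex ratio) + b2 z(size) + b3 z(synchrony)
              + b4 z(instability) + b5 z(sex ratio)·z(size)
              + random effects

with N the classified offspring count, O the overlap index, predictors
z-scored across rows, and crossed random intercepts for group and cohort
plus (by default) uncorrelated random slopes for each main effect within
each factor.  Fitting is maximum likelihood via the Laplace approximation:
an inner penalized-IRLS solve profiles the spherical random effects, and
L-BFGS-B optimizes (β, θ) jointly with θ ≥ 0 — the same objective `glmer`
optimizes, verified against it in the tests.  ML (not REML-like) estimation
keeps fixed-effect likelihood-ratio tests valid.

Inference mirrors the standard workflow: a full-vs-null LRT (null retains
random effects, slopes and offsets; df = 5), single-term LRTs in which the
two interaction components are tested in a reduced interaction-free model,
a Pearson dispersion parameter (squared Pearson residuals at conditional
means over n − p residual df, p counting fixed effects and variance
parameters), VIFs from a fixed-effects-only, interaction-free regression,
and leave-one-group/cohort-out stability refits.  The no-random-slope and
no-interaction variants are configuration flags on the same table.

The published parameter count ("15 in total") cannot be reconciled exactly
with any single random-effects structure (6 fixed + 10 uncorrelated
variance terms = 16 here); the structure used is recorded in the run
manifest rather than assumed to match.

Numerical choices: η clipped at ±30 before exponentiation; inner Newton
with step halving to a 1e-14 relative tolerance, so the outer
finite-difference gradients (step 1e-6) sit far above the inner-solve noise
floor — with a looser inner solve the optimizer stalls on the flat variance
ridge; outer relative-loglik tolerance 1e-8 (non-convergence is flagged on
the fit, never raised);
variance components within 1e-4 of the zero boundary set a `singular`
flag; Wald SEs from the Schur complement of the joint (β, u) Hessian
conditional on θ̂, as `glmer` reports them.

## The synthetic population

The generator emits every input the pipeline reads — census, sightings,
seasons, genotypes, births, locations — plus a truth log (true sires,
conception dates, EGP flags, residence histories), so the whole pipeline is
testable without any download.  Its defaults state the emulated world:

- 6 groups × 9 cohorts; founding mature sizes ~ Normal(82.2, 43.7), sex
  ratios ~ Normal(1.615, 0.318); 86% of mature females conceive per season;
  gestation ~ Normal(166.5, 7.4) days, rounded to whole days.
- Mating season length **100 days**, derived from the reported mean
  synchrony 0.140: with near-complete coverage by conception windows,
  U ≈ season + window tails ≈ 15/0.140 ≈ 107 unique estrous days.
- Males disperse from the natal group at ~4 years and thereafter migrate
  between ring-adjacent groups with probability **0.04 per year**, timed
  around the season; this rate is derived from the reported mean
  instability 3.7e-4 via the expected per-event contribution (a gain event
  contributes ≈ 1/(group size · season days); a loss event ≈ the mover's
  tenure share of the group's summed tenure).  Males die at 0.02/yr;
  occasional prospecting excursions and prospecting-led arrivals exercise
  the 60-day rule without changing residence.
- Genotypes: 28 loci, 8 alleles each, frequencies ~ Dirichlet(1); founders
  drawn from the frequencies, descendants Mendelian; optional per-allele
  error (default 0); typed-panel sizes ~ Normal(27.6, 1.6) capped at 28.
- Each conception is extra-group with probability
  expit(γ0 + γᵀ z(covariates)) computed on the generator's own truth;
  default γ = (logit(0.16), 0, 0, 0, 0, 0) reproduces the 16% overall rate.
  Extra-group sires come from adjacent groups and are screened against
  residence in the mother's group within ±45 days of conception so the
  truth flag and the 75-day rule agree except at discretization edges.
- Infant fates: 14% die in the first year, ~2% are removed with their
  mother, 0.5% remain ungenotyped; **all surviving study-born infants are
  culled before maturity** (age 400–1000 days), emulating the island's
  population-control removals and keeping the breeding pool stationary —
  without this, maturing infants inflate the breeding size far above the
  stated mean.  Consequence: study-born animals never join the breeding or
  candidate-sire pools, so recruitment-driven covariate trends are *not*
  emulated.
- Locations: daily Gaussian scatter (SD 60 m) around group centers on a
  130 m ring, giving every group a positive overlap index.

A single root seed is fanned out per sub-generator (population, matings,
genotypes, locations); identical seeds give byte-identical CSVs.

What a green test establishes — and what it does not: the generator has no
genotyping error by default, no female dispersal or group fission, no rank
or hormone structure, and its EGP model is exactly the log-linear form the
fitted model assumes (up to the logit/log link difference at small rates).
Recovery results therefore validate the pipeline's correctness, not the
biological model's fit to real data.

## Simulation harnesses in the test suite

Null/coverage/sign-recovery harnesses simulate the model table directly at
the 4× replication design (12 groups × 18 cohorts = 216 rows) with random
intercepts (SD 0.2 group, 0.15 cohort) and fit the matching configuration;
effect sizes are β = (0.3, −0.3, −0.4, −0.25) with interaction 0.2 on the
z scale.  The full random-slope configuration is exercised on the 54-row
design by the pipeline fit, the `glmer` cross-check and six end-to-end
replicates with a planted synchrony effect (γ3 = −0.4).  Runtime budgets
are kept by these scales; none of the thresholds were adjusted after
measurement.

## Known limitations

- The exclusion rules stand alone; no likelihood-based confirmation step.
- The membership algorithm trusts the census cadence; with gaps larger
  than `max_gap_days` inside a confirmation span the candidate period
  restarts, which can delay (never falsify) an immigration date.
- Wald intervals condition on the estimated variance components; their
  slight undercoverage at small n is visible in the coverage harness.
- The dispersion parameter uses conditional (random-effects-at-mode)
  fitted values; other conventions (marginal means) give different values
  for the same fit.
- Group-seasons without live births are dropped with a log entry; the
  default world never produces one.
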