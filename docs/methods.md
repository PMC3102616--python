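# Methods

## Scope and modelling goal

`emaxdr` characterizes the dose response of a once-daily inhaled
bronchodilator in COPD on the trough-FEV1 endpoint, at two levels of data
aggregation, and turns the fitted curves into dose-selection decisions
against a 120 mL minimal clinically important difference (MCID, the
midpoint of the accepted 100–140 mL range for trough FEV1 vs placebo).
FEV1 has a notoriously low signal-to-noise ratio — population FEV1 spans
roughly 0.5–3 L while the maximal drug effect is under 200 mL — which is
why both analyses pool information through an explicit Emax model rather
than relying on per-dose pairwise contrasts.

## Study-level model

The observation unit is the least-squares-mean contrast to placebo
`y_ij` (mL) of one treatment arm at one steady-state visit (Week 2 to
Month 6; earlier visits are rejected at validation because the drug reaches
pharmacodynamic steady state by Week 2), together with its reported
standard error. The mean structure is

    y = FOR·μ_F + SAL·(μ_S + γ_S) + TIO·μ_T + IND·(Emax + δ_i + γ_ij)·d/(ED50 + d)

with treatment indicators; δ_i is a between-study and γ_ij a within-study,
between-visit random effect on Emax, both Gaussian. Salmeterol is the only
comparator with a visit-level effect; formoterol and tiotropium carry fixed
means. Random effects enter Emax additively, so they perturb an arm mean in
proportion to its fraction of maximum d/(ED50+d) and leave ED50 untouched.
The reported SE is taken as a known observation SD; no extra residual
variance is estimated, since γ_ij already absorbs visit-level excess
variation. The placebo response is structurally zero because the data are
contrasts.

Assumptions worth keeping in mind: normality at every level, SEs treated as
known, exchangeability of studies given δ, and a common ED50 across
studies and visits.

### Priors

Weakly informative defaults, all overridable per parameter:
Emax and comparator means ~ Normal(0, 500²) mL; log ED50 ~ Normal(log 100,
2²) (a diffuse lognormal spanning ~1–10 000 μg); all variability SDs ~
Half-Normal(100 mL). A `point` prior family fixes a parameter exactly and
removes it from sampling, which is also how degenerate "posteriors" for
testing are produced. Prior sensitivity is assessed by refitting with a
modified prior mapping.

### Computation

Given (Emax, ED50, ω_study, ω_visit), the model is linear and Gaussian in
the random effects, so they are marginalised analytically: an indacaterol
study block is multivariate normal with covariance
`ω²_study f fᵀ + diag(ω²_visit f² + se²)` (f the per-row fractions of
maximum), evaluated with the rank-one Sherman–Morrison and
matrix-determinant-lemma identities in O(rows). A configuration switch
(`gamma_shared_within_visit`) instead shares γ across arms observed at the
same study-visit, adding within-visit rank-one terms (dense per-study
evaluation); the default is one γ per arm-visit row.

MCMC then runs on the eight structural parameters only (positive
parameters log-transformed, with the Jacobian included). The sampler is
adaptive random-walk Metropolis (proposal covariance tracking the warmup
history, scaled 2.38²/d; step size tuned to ~0.3 acceptance) mixed 20/80
with an independence kernel proposing from a multivariate Student-t (df 6)
fitted to the second half of warmup. Chains start at the posterior mode
(Nelder–Mead then L-BFGS) with the Laplace covariance as the initial
proposal; all adaptation freezes at the end of warmup, so the retained
chain has a fixed kernel. Split-R̂ and bulk ESS are computed with arviz;
R̂ ≥ 1.01 raises a warning, never an error. Defaults (4 chains × 1500
warmup + 1500 draws) reach R̂ ≈ 1.01 and bulk ESS ≥ ~600 on the default
synthetic design in a few seconds.

Derived quantities (percent of maximum per dose, ED90 = 9 × ED50,
exceedance probabilities, treatment ranking) are computed per draw and then
summarised. Note the hyperbolic algebra: ED90 is 9 × ED50 and ED80 is
4 × ED50 — the two are easy to conflate when reading summary tables. The
95% prediction band for a new study-visit LSM adds, per draw, fresh δ and γ
(scaled by fraction of maximum) and observation noise with SD equal to the
median reported SE of the input data (overridable).

## Patient-level model

One patient contributes trough FEV1 on study days 14 and/or 15 at one
assigned dose (0 = placebo). The structural model is

    f = (E0_i + η0_i) + (Emax_i + ηm_i) · d/(ED50_i + d)

with per-patient random effects (η0, ηm) — independent by default, with a
switch to estimate their correlation — and covariate links on the fixed
effects. Continuous covariates enter linearly after centering at the
population median (baseline FEV1 centered at 1300 mL); links on ED50 act
multiplicatively through an exponential to preserve positivity; `power`
links (x/ref)^β are available; binary categorical covariates are coded 0/1
with the coding frozen at model build. Observation and prediction are both
log-transformed (transform both sides) with additive residual ε ~ N(0, σ²)
on the log scale, so the residual is approximately proportional on the
natural scale. Back-transformed predictions are median-consistent (no
lognormal bias correction), which we document rather than "fix": predicted
curves are typical-patient medians.

### Estimation

The classical first-order (FO) method: linearise log f in the random
effects at zero, giving per-patient multivariate normal blocks with mean
log f(θ, 0, x) and covariance G Ω Gᵀ + σ² I, G = ∂ log f/∂η |₀ = [1/f,
fr/f]. Blocks of size 1 and 2 (the only sizes the generators produce) use
closed forms vectorised across patients; the 2×2 determinant uses the
cancellation-free expansion `max(v_a v_b − v_ab², 0) + σ²(v_a+v_b) + σ⁴`,
whose first term is a PSD Gram determinant, so the likelihood stays finite
even when the optimizer explores extreme variance values. A genuinely
singular block (σ = 0 with degenerate G) raises an error naming the
patient. Parameters giving any nonpositive prediction get −∞ (the log is
undefined there).

The deviance is minimised by L-BFGS-B on transformed parameters (log for
ED50, SDs and σ; atanh for the correlation) in a scaled space — effects are
divided by 100 and a slope's scale is the effect scale divided by its
covariate's spread — because the raw parameters span seven orders of
magnitude and unscaled quasi-Newton stalls. Three jittered starts (fixed
jitter seed) guard against local optima; fits are deterministic given data
and settings. Standard errors come from the numerically differentiated
curvature (central differences) of the negative log-likelihood at the
optimum; Wald 95% CIs are formed on the transformed scale and
back-transformed, so CIs for positive parameters are asymmetric and
positive.

FO is known to be biased when random effects are large relative to the
curvature of log f; the test suite quantifies the linearisation error
against a Gauss–Hermite quadrature oracle on small instances and verifies
it vanishes quadratically as Ω is halved.

### Covariate selection

Forward entry by likelihood-ratio test: every remaining candidate link is
added and refitted; the smallest p-value below α (χ², df = 1) enters;
selection stops when none qualifies. α defaults to 0.01 — deliberately
conservative because several candidates are screened repeatedly. A
candidate whose fit fails is skipped and logged in the trace, which records
every tested model's −2LL and is reproducible bit for bit.

## Dose-selection rules

Over a tested grid (default {18.75, 37.5, 75, 150, 300, 600} μg):

- **MED**: lowest dose with median predicted improvement ≥ MCID (the ≥ can
  be made strict by flag);
- **optimal**: lowest MED-qualifying dose whose median also exceeds every
  comparator median (point comparison; a probabilistic variant
  P(dose beats comparator) > cutoff is available behind a flag, since a
  credibility-based superiority definition is equally defensible);
- **maximum**: lowest dose whose 95% interval brackets the Emax median.

Decisions are invariant to grid ordering; raising the MCID never lowers the
MED; when all three are defined they satisfy med ≤ optimal ≤ maximum, and
the decision object enforces that ordering.

## Synthetic data: what it does and does not emulate

**Study level.** The design table reproduces an 11-study programme
(2-week crossovers to a 52-week parallel-group study; indacaterol arm
totals per dose 92/91/546/1358/1369/551 for 18.75–600 μg; comparator arm
totals 558/563/420) with one to four steady-state visits per study by
duration. Truth defaults: Emax 177 mL, ED50 28 μg, ω_study 25 mL, ω_visit
15 mL, ω_sal,visit 15 mL; comparator means 110/100/130 mL
(formoterol/salmeterol/tiotropium, plausible mid-range bronchodilator
effects); arm SE = 250·√(2/n) mL from a 250 mL per-patient SD. This
calibration yields a ±60 mL 95% prediction band for typical parallel-group
arms (SE ≤ 25 mL) and a visit-to-visit LSM spread of tens of mL; the two
small crossover studies (SE ≈ 44 mL) fall outside ±60 mL more often, so
the all-arm within-band fraction sits near 0.89 rather than 0.95.

**Patient level.** Baseline FEV1 ~ lognormal, median 1300 mL, log-SD 0.389
(≈25% of patients below 1 L), truncated by rejection to the observed
500–3200 mL span; GOLD-style severity is derived from the 1 L threshold;
reversibility ~ N(12%, 8%) clipped to [−10, 60]; other binary covariates
independent. Structural truth at the reference patient: E0 1300 mL, Emax
185 mL, ED50 19 μg, with links baseline→E0 (+0.95 mL/mL), baseline→Emax
(+0.12 mL/mL), baseline→ED50 (−5·10⁻⁴ /mL through the exponential, i.e.
lower baseline ⇒ higher ED50) and reversibility→Emax (+1.5 mL/%).
Variability: ω_E0 120 mL, ω_Emax 50 mL, σ_log 0.12. 1835 patients are
allocated round-robin over the seven arms {0, 18.75, …, 600} μg, two
records each (days 14/15).

Not emulated: onset kinetics before Week 2, dropout, missingness, adverse
events, correlation among demographic covariates, inter-occasion
variability, and any exposure (PK) dimension. Passing tests therefore
demonstrate statistical correctness of the machinery under the assumed
variance structure, not robustness to the messiness of real trial data.

## Simulation problem sizes used by the test suite

Chosen as the package's own benchmark conditions: study-level recovery and
coverage use 100 replicates of the 11-study design with 3 chains × 1000
warmup + 1000 draws per fit (enough for stable 95% CI quantiles — shorter
chains visibly deflate CI coverage); patient-level recovery uses 50
replicates at the full 1835-patient design; forward-selection calibration
uses 200 null replicates (240 patients, one day) at α = 0.05 and 50 powered
replicates (600 patients, baseline→Emax slope 0.25 mL/mL, ~5 SEs).

## Known limitations

- **ED50 is weakly identified at realistic noise.** With arm SEs of
  17–44 mL (study level) or σ_log 0.12 (patient level) and most patients at
  doses ≥ 75 μg — well above ED50 — the sampling SD of the ED50 estimate is
  25–35% of its value at either level. The recovery simulations show Emax
  medians within 10–15% of truth in ~90% of replicates, but ED50 within
  those bands in only ~25%, while 95% intervals for both parameters cover
  truth at their nominal rate. Per-dose effects and all dose decisions are
  far better determined than ED50 itself (they depend on it only through
  the flat d/(ED50+d) at high doses).
- FO estimation, not FOCE/Laplace/adaptive quadrature; adequate here
  (random effects are modest relative to f) but a known source of bias in
  general.
- The comparator model is intentionally minimal (fixed means, one
  salmeterol visit-level SD): it supports ranking and superiority checks,
  not a network meta-analysis across comparator doses.
- Decision rules use posterior medians and interval endpoints; no
  multiplicity adjustment is applied across the three rules.
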