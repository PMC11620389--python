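# Methods

## Model

Speakers are split into users (fraction *U*) and non-users of a given
lexical item, mixing homogeneously.  Non-users adopt at rate β per
user contact structure, users abandon at rate γ, and population
turnover happens at the mortality rate μ (one generation = 1/μ years).
The user fraction obeys

    dU/dt = β U (1 − U) − (γ + μ) U

— an SIS-type model whose basic reproductive ratio is
R₀ = β/(γ + μ).  For R₀ > 1 the solution is the logistic curve

    U(t) = U* / (1 + (U*/U₀ − 1) e^{−rt}),   r = β − γ − μ,

with carrying capacity U\* = 1 − 1/R₀; for R₀ ≤ 1 the item dies out.
The herd-immunity / stability threshold H = 1 − 1/R₀ equals the
equilibrium prevalence.  Assumptions worth keeping in mind: constant
rates, constant population, homogeneous mixing, rectangular age
distribution, no forgetting of established words (γ = 0 is the package
default; γ is a free parameter everywhere).

Time is measured in **years** throughout; decade-gridded inputs keep
their calendar-year time stamps and are never rescaled.

## Estimators and their validity regimes

* **Acquisition** (R₀ = LE/AoA) and **prevalence** (R₀ = 1/(1 − p_U))
  are equilibrium identities: they are unbiased only for items whose
  dynamics rest at the endemic equilibrium.  The stability coefficient
  S = 1 − |ρ| (|Spearman ρ| of value against time over a recent window,
  default 1950–2000 inclusive) quantifies how well that assumption
  holds per item and is carried into the comparison models.  An
  undefined ρ (constant series) maps to ρ = 0, S = 1: a flat series is
  maximally stable by construction.
* **Growth** (R₀ = 1 + r·L) targets items still spreading.  The
  prolific period is approximated L = LE − AoA (the years during which
  an individual knows and can transmit the item).  Items with
  1 + r·L < 0 are reported missing ("negative_r0") since R₀ is
  nonnegative by definition; non-converged fits propagate as
  "fit_failed".  Note L = LE − AoA differs from the compartmental
  infectious period 1/(γ + μ); the growth estimator is therefore an
  approximation with its own small-sample logic, not an exact model
  identity.

Estimates that cannot be computed are never dropped silently: every
item leaves the pipeline with a machine-readable status and reason
(core_lexicon, no_trajectory, no_significant_increase, fit_failed,
negative_r0, core_prevalence_one, ...), and the report reconciles
included + excluded = input counts on every run.

## Trajectory reconstruction and filters

Corpus frequency trajectories f(t) are max-normalized
(f̃ = f/max f) and scaled by present-day survey prevalence:
U(t) = p_U · f̃(t).  This treats the frequency trajectory as a mirror
of the prevalence trajectory and pins its peak at the survey value.
Filters are applied in order: p_U < 0.95 (strict; the core lexicon is
out of scope), trajectory present, U(t) ≤ 1 everywhere, significant
increase (two-sided Spearman test at α = 0.05 with the extra
requirement ρ > 0), logistic fit convergence.  Sidedness of the trend
test and the treatment of undefined ρ are package choices; both are
configurable.

## Logistic fit numerics

The fitted form is Û(t) = a/(1 + b·e^{−r(t − t₀)}) with a ∈ (0, 1],
b > 0 and r unconstrained in sign, t₀ = first observation year
(conditioning).  Goodness of fit is R² = 1 − SSE/SST with no floor —
negative values are legitimate and simply demote an item's weight in
the comparison models.  The inflection point is t₀ + ln(b)/r.

Initialization is data-driven: a₀ = min(1, 1.05·max U); a logit
regression of ln(U/(a₀ − U)) on time over interior points gives the
rate guess (slope) and the shape guess b₀ = e^{−intercept}.  Deriving
b₀ from the regression intercept rather than from the first
observation matters: early observations of an innovation are often
exactly zero, and a first-value-based b₀ then lands the optimizer in a
flat, inescapable region of parameter space.  On failure the rate
guess is multi-started over ×{0.5, 1, 2}.  Optimization is
trust-region least squares (`scipy.optimize.curve_fit` with analytic
Jacobian), tolerances 1e-10 by default; bootstrap refits use 1e-8
because replicate sampling noise dwarfs optimizer error.  Noiseless
logistic data is recovered to ~1e-9 relative.

One caveat is intrinsic rather than numerical: trajectories still in
their near-exponential phase at the last observation leave (a, b, r)
only weakly identified — a long flat residual valley trades the
carrying capacity against the rate.  Such items produce wide bootstrap
margins, which is the honest answer.

## Margins of error

All margins are halves of 95% confidence intervals.  Inputs:
ΔAoA = 1.96·sd/√N_AoA, Δp = 1.96·√(p(1−p)/N_p), ΔLE from demographic
data (default 1 year at LE = 75).  First-order (delta-method)
propagation gives

    ΔR₀(aoa)    = sqrt((ΔLE/AoA)² + (LE·ΔAoA/AoA²)²)
    ΔR₀(prev)   = Δp/(1−p)²                      (diverges as p → 1)
    ΔR₀(growth) = sqrt(((LE−AoA)·Δr)² + r²(ΔLE² + ΔAoA²))

each validated against Monte-Carlo propagation in the tests.  The
growth-rate margin Δr has no closed form: for each of n_boot (default
300) replicates, counts are drawn independently per time point from
Binomial(N_p, U(t)), the proportion trajectory is refitted, and Δr is
half the width of the percentile [2.5%, 97.5%] interval of the
replicate rates.  Failed replicate fits are dropped and counted; more
than 50% failures flags the margin unreliable (NaN).  Corpus
frequencies are treated as error-free — corpora are large enough that
their sampling error is negligible next to survey error — and binomial
draws are independent across time points (temporal autocorrelation of
survey error is ignored).  Randomness is reproducible: one master
seed, with per-item substreams derived from (seed, CRC32(item id)) so
results do not depend on iteration order.

## Cross-estimator comparison

Paired Wilcoxon signed-rank tests report the standardized effect size
Z/√N (N = nonzero pairs); the literal Z/N normalization is available
behind a flag but Z/√N is the standard definition of the cited effect
size and is the default.  Pearson correlations are computed per method
pair on items where both estimates exist.  The interaction models

    outcome = b₀ + b_x·x + b_xS·x·S + ε

deliberately omit a main effect of S: stability only modulates the
slope between two estimators.  Models with a growth-based variable are
weighted by trajectory R² (floored at 0); the acquisition~prevalence
model is unweighted, as neither side has a trajectory-quality weight.

## Synthetic lexicon generator

The generator emulates the statistical structure the estimators
assume, making end-to-end recovery a test of the implementation rather
than of the theory.  Per item a true ratio R₀\* is drawn (log-normal,
median 6, log-sd 0.5 — centred on the regime reported for spreading
periphery words, with occasional draws above the core-lexicon cap so
the periphery filter is exercised naturally).  The equilibrium
identities then fix the survey-side truth: p = 1 − 1/R₀\*,
AoA = LE/R₀\*.  Stable items sit at U\* throughout; growing items
follow a logistic curve whose midpoint is uniform over 1880–1980.

The trajectory rate of growing items is set to
r = (R₀\* − 1)/(LE − AoA) — the rate the growth estimator inverts
exactly — rather than the compartmental β − γ − μ (recorded alongside
as `r_model`).  The two differ because L = LE − AoA is an
approximation of the infectious period; tying the trajectories to the
estimator's own structure means a correct implementation must recover
R₀\* to machine precision when noise is off, which is the property the
tests lean on.  The midpoint placement takes precedence over the
initial user fraction (the two jointly over-determine the curve); the
implied U(1820) falls in the small-seed regime for all but the latest
midpoints.

Noise channels (each independently switchable): survey prevalence
Binomial(N_p, U(t_final))/N_p; AoA as the mean of N_AoA ratings
~ Normal(AoA, sd) truncated to (0, LE), with per-item rating sd
uniform over 1.5–3.5 years (typical of published norm sets); corpus
frequency c·U(t) with per-item scale c log-uniform over [1e-6, 1e-3]
(exercising normalization invariance) times multiplicative log-normal
noise (sd 0.05).  Defaults N_p = 300 and N_AoA = 30 reflect an
English-sized survey regime; setting N_p ≈ 23 reproduces the
small-survey regime where prevalence margins blow up.  A flag derives
prevalence as the fraction of raters responding instead of a separate
survey, matching how non-English norm sets conflate the two.

What the generator does **not** emulate: corpus token sampling and
genre composition, time-varying life expectancy and acquisition ages,
age- or network-structured transmission, semantic competition between
items.  Passing recovery tests therefore shows the pipeline inverts
data with the assumed structure; it does not validate the model
against real corpora.

## Reference study sizes

The standing simulation studies use a 500-item lexicon (default noise,
half growing) for estimator recovery and 200 growing items at
N_p = 300 with n_boot = 100 for bootstrap coverage — sizes at which
the medians and the coverage proportion are stable to a few percent
while a full run stays in the minutes range.  Measured coverage sits
around 92–95% against the nominal 95%: percentile intervals undercover
slightly for the weakly identified late-midpoint items, a known
property of the percentile bootstrap rather than a bug.

## Known limitations

* Single scalar LE per dataset; real life expectancy drifted upward
  over the observation window.
* The prevalence estimator is biased low for items still far from
  saturation — visible in the recovery study as a ~4–5% shortfall of
  the prevalence median when half the lexicon is still growing.  This
  is a property of applying an equilibrium identity to non-equilibrium
  items, which is exactly what the stability coefficient is meant to
  flag.
* γ is not identifiable from the supported data; it defaults to 0 on
  the argument that established words are rarely forgotten.
* The Spearman increase filter at α = 0.05 admits ~2.5% of flat items
  under noise; they enter the growth method with near-zero rates.
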