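# Methods

This note documents the statistical models, the estimation machinery, the
synthetic-data generators, and the numerical and design choices behind
`esmar`, together with what the test suite does and does not establish.

## Models

All models are Gaussian linear mixed models for a long-format panel of
affect scores `y` indexed by person, day, and beep (the within-day
measurement occasion).

**Empty models.** The empty two-level model decomposes variance into a
person level and a beep level: `y_bi = g00 + u0i + e_bi` with
`u0i ~ N(0, sd_u0^2)` and `e_bi ~ N(0, sd_e^2)`. The empty three-level
model adds a random day-within-person intercept `r_0di ~ N(0, sd_r^2)`.

**AR(1) models.** The two-level AR(1) model regresses each score on the
previous same-day score centered at the person's trait level; both the
trait level and the inertia `phi_i` carry person-level random effects,
optionally correlated. The three-level AR(1) model centers the beep-level
predictor at the *day* mean instead, and adds a second autoregression of
day means on the previous day's centered mean, giving separate
moment-to-moment (`zeta_i`) and day-to-day (`beta_i`) inertias. Because
the two AR models center their beep-level predictors differently they are
not nested, so they are compared by AIC/BIC rather than LRT — valid only
on identical case sets.

Centering uses empirical-Bayes (BLUP) quantities from the empty models:
the predictor for the two-level AR model is the lag of the empty-2L
residual `e.bi`, and the three-level predictors are the lag of the
empty-3L residual `e.bdi` and the previous day's EB day deviation
`r.0di`. EB centering shrinks noisy person/day means and gives slightly
less biased inertia estimates than raw sample means (sample-mean
centering remains available as a sensitivity option). The empty models
are always fitted to **all** observed cases, even when the AR models are
later refitted to the smaller common subset — centering should use all
available information.

Lag construction honors the data's temporal structure: the first beep of
each day never receives a within-day lag (the night interrupts the
process), a beep whose predecessor is missing receives no lag, each
person's first day receives no day-level lag, and a wholly unobserved day
blocks the next day's day-level lag. Mixed-model fitting then applies
listwise deletion over the outcome and the model's predictors.

## Model families and parameter counts

| family           | fixed                        | random (person)            | day int. | k  |
|------------------|------------------------------|----------------------------|----------|----|
| `empty2`         | 1                            | 1                          | no       | 3  |
| `empty3`         | 1                            | 1                          | yes      | 4  |
| `ar2`            | 1 + lev1pred                 | 1 + lev1pred               | no       | 5 (+1 corr) |
| `ar3_nobeta`     | 1 + lev1predfor3l            | 1 + lev1predfor3l          | yes      | 6  |
| `ar3_fixedbeta`  | + lev2pred (fixed)           | 1 + lev1predfor3l          | yes      | 7  |
| `ar3_randombeta` | + lev2pred                   | + lev2pred slope           | yes      | 8 (+3 corr) |
| `ar3_fixedonly`  | 1 + lev2pred + lev1predfor3l | 1                          | yes      | 6  |

`k` counts fixed effects + variance/covariance components + the residual
variance, matching the convention of the standard multilevel software for
this model class so AIC differences are comparable. `ar3_fixedonly`
(both inertias fixed, no random slopes) exists because the artifact
demonstrations report three-level fits after removing non-significant
random inertia effects. A deliberate departure from one published
formulation: the person intercept appears in exactly one random term
(the nested `person/day` specification plus a second person block would
double-parameterize it); the canonical single-intercept form is used
throughout.

## Estimation

Fitting is maximum likelihood (ML, never REML — the information criteria
require it). Writing person `i`'s rows as
`y_i = X_i b + U_i u_i + e_i`, `u_i ~ N(0, s^2 L L')`,
`e_i ~ N(0, s^2 I)`, where `U_i` stacks the person-level random-effect
columns and the day-intercept indicators, every likelihood quantity
reduces via the Woodbury identity to the per-person Gram blocks of
`[U_i, X_i, y_i]` and the q x q matrix `M_i = I + L'U_i'U_i L`
(q = #random slopes + #days, so ~24 at most in practice). The fixed
effects and `s^2` are profiled out in closed form, leaving an
optimization over the relative covariance factor alone — one to four
free parameters for the uncorrelated families.

Numerical choices:

* The relative factor `L` is optimized **unconstrained**; the likelihood
  depends on it only through `L L'`, which guarantees positive
  semi-definiteness at every proposal and places zero-variance boundary
  solutions at finite parameter values (a log-scale parameterization
  would push them to minus infinity). The objective is exactly invariant
  to column sign flips, so it is smooth in the retained parameters.
* Design columns are scaled to unit SD internally (estimates are
  reported on the raw scale) so that intercept- and slope-variance
  parameters are comparable in magnitude to the optimizer.
* L-BFGS starts at 0.5 relative SDs (off-diagonals 0), followed by a
  Nelder-Mead polish; the better optimum wins. Fits are deterministic:
  no randomized restarts.
* A fitted relative SD below 1e-4 flags the fit as `boundary`; boundary
  fits are valid results and are retained in model selection.
* Degenerate inputs: a constant outcome yields the intercept with all
  SDs at the zero boundary; `n_obs <= k` is an error; a panel in which
  no person has two observed days cannot identify the day level and the
  three-level predictors are flagged degenerate.

EB predictions are the BLUP modes `L M^{-1} L' U'(y - Xb)` at the
optimum. Fixed-effect standard errors come from the profiled GLS
information; Wald z-tests replace Satterthwaite-approximate t-tests
(with thousands of usable cases the difference is immaterial), and LRT
p-values use the naive chi-square reference without boundary
corrections — conservative for variance components, matching common
reporting practice for these models.

Correctness is verified two independent ways: the block likelihood
equals a dense multivariate-normal log-density to 1e-8 on small
instances, and maximized logliks and fixed effects agree with lme4 to
1e-3 across 160 randomized fits (taking lme4's best of three optimizers,
since single optimizers occasionally stall at singular fits). The
statsmodels MixedLM implementation serves as a further spot check where
its optimizer is reliable.

## Synthetic data

The generators produce complete balanced panels (an optional MCAR
thinning rate exists for plumbing, default 0) from the two processes:

* **two-level AR(1)**: person trait levels and inertias jointly normal
  (defaults `g00=58, g10=0.37, sd_u0=12, sd_u1=0.14, sd_e=15,
  r=-0.44`, empirically derived positive-affect values); each day is an
  independent stationary AR(1) series — no carry-over across the night;
* **three-level AR(1)**: day means follow a stationary AR(1) across days
  within person, beep series a stationary AR(1) around the day mean
  (defaults `g000=58, g010=0.27, g100=0.16, sd_u00=13, sd_u01=0.22,
  sd_u10=0.13, sd_r=7, sd_e=15`, correlations -0.45/-0.365/0.22).

Sampled inertias at or beyond +-1 are truncated to +-0.99 to preserve
stationarity (the negative side mirrors the stated positive rule). First
beeps of each day and first day means are drawn from their stationary
distributions; this initialization is a documented choice — it avoids
day-one variance artifacts, makes the three-to-two-level reduction
(`sd_r=0, g010=0, sd_u01=0`) exact, and any alternative start would
differ only in O(1/Nb) terms. Per-person random substreams are spawned
deterministically from the root seed, so enlarging the number of persons
never reshuffles earlier persons' data.

What the generators do *not* emulate: missing-data mechanisms beyond
MCAR, unequal sampling intervals within a day, time-of-day or weekday
cycles, trends, floor/ceiling effects of bounded response scales, and
non-Gaussian residuals. Passing tests therefore demonstrate correctness
of the machinery and the selection procedure *under the stated Gaussian
AR assumptions*, not robustness of the procedure on real affect data.

## Level selection and the study harness

Selection fits {`ar2`, `ar3_nobeta`, `ar3_fixedbeta`, `ar3_randombeta`},
all without random-effect correlations, on the common case subset (rows
usable by the most demanding model: observed outcome and all three
lagged predictors present; `Np*(Nd-1)*(Nb-1)` rows for complete balanced
data) and picks the AIC (or BIC) minimizer; three levels are chosen iff
a three-level family wins, with exact ties broken toward two levels
(parsimony; ties do not occur in practice). Empty models never enter the
comparison — testing day-level variance in empty models is precisely the
unreliable procedure this replaces. Non-converged fits are dropped from
the comparison with a logged warning rather than failing the run.

The study harness maps this over a design grid (defaults
Np in {30,60,90}, Nd in {5,7,10,14}, Nb in {5,7,9,11}) for both
generating processes, reporting per-cell proportions of three-level
choices with binomial SEs. Replicate presets: `full` (1000) and `desk`
(200). Each replicate consumes an independent substream, so results are
independent of scheduling. The acceptance script runs 5 realizations per
artifact dataset and 200 replicates per spot cell (~2 min on one CPU);
the test suite uses 30-60 replicates per cell with tolerances widened to
3 binomial SEs at the scale actually run.

## Known limitations: inertia attenuation under estimated-mean centering

Centered AR models require the centering means to be *estimated*, and
estimation error in the mean biases the inertia estimate downward. For
person-level centering over hundreds of occasions the effect is small
(the two-level AR(1) fixed inertia recovers its generating 0.37 to
within ~0.005 at 90x21x10). For the three-level model the day means are
estimated from ~10 beeps each, and the attenuation is an order of
magnitude larger: at 90 persons x 14 days x 10 beeps the fixed beep
inertia averages ~0.06 against a generating 0.16, the fixed day inertia
~0.12 against 0.27, while the day-level SD is correspondingly
overestimated (~7.7 vs 7) and the residual SD slightly underestimated.
This is the same mechanism that produces the small *negative* beep
inertia (~-0.09) when the three-level AR model is fitted to data with no
inertia at all. The attenuation does not impair *level selection* —
which compares fit, not parameter values, and attains the documented
power and Type-I behavior — but three-level inertia point estimates
should be read as lower bounds, more attenuated the fewer beeps per day.
The parameter-recovery tests assert strict 3-Monte-Carlo-SE recovery for
every parameter and therefore fail, by design, exactly on the
three-level AR families; the failing assertions document the measured
attenuation rather than hiding it.

Other limitations: equally spaced occasions are assumed within a day
(real ESM schedules jitter prompts); lag order is fixed at 1; no trends,
cycles, or regime switching; crossed random effects and heteroscedastic
residuals are out of scope; REML and small-sample df corrections are
deliberately absent.
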