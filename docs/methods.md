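# Methods

`aacsim` simulates and analyzes a virtual approach–avoidance conflict
paradigm: a token-foraging game under probabilistic predation (Task 1) and
a companion safe-predator-exposure task (Task 2).  This note documents the
generative models, the analysis procedures, the numerical choices, and the
limits of what the simulation-based tests can show.

## The task model

**Task 1.**  Each epoch schedules exactly six token cycles.  A token stays
available for an exponential time (mean 1.25 s); after it disappears or is
collected, the wait before the next token is the same exponential plus a
fixed 500 ms offset.  The player starts in a safe position; while outside
it, a predator wakes with constant hazard *p* per 100 ms step — 0.1, 0.2
or 0.3 depending on the epoch's threat level.  A catch forfeits all tokens
collected in the epoch and ends collection (later tokens still appear but
are uncollectable).  Blocks hold 45 epochs with threat levels balanced
15/15/15 and shuffled; epochs end after the sixth cycle (the task text is
silent on a fixed wall-clock epoch length, so none is imposed).

Space is abstracted to three positions (safe, left, right).  One key press
moves the player to the token's side, collecting it on arrival; one press
returns it.  Approach latency is token onset → outward press; return
latency is collection → homeward press; hazard exposure accrues during the
return interval, in whole 100-ms steps (`floor(RL / 100)` Bernoulli
trials).  The discrete-step hazard matches the task's stated per-100-ms
unit; a continuous-time exponential alternative was rejected for that
reason.

A deliberate design choice: a *committed* approach always reaches the
token; the availability window limits only unapproached token cycles.
Without this, slow approaches fail stochastically on token expiry and the
decision readout (below) confounds policy with timing.  The consequence is
that the reconstructed decision chain is exactly the agent's logistic
policy, which is what the parameter-recovery tests exploit.

**Behavioural policy.**  The agent approaches a token with probability
`sigmoid(b0 + b_t * threat + b_l * loss)`, with threat coded −1/0/+1 and
loss = tokens currently held (0–5).  Latencies are Gaussian around linear
predictors in the same regressors, truncated at 1 ms.  Defaults (intercept
3.2, loss coefficient −0.8, threat coefficient −0.5; approach 450 ms and
return 150 ms baselines, 80 ms noise) give near-ceiling approach at zero
loss, a marked decline with loss, and per-excursion catch rates of roughly
8/20/23 % across threat levels — a regime in which threat and loss
sensitivity are visible in the readouts while most epochs remain
analyzable.  Lesion agents are controls with individual policy fields
overridden (e.g. an attenuated loss coefficient, or a slowed return).

**Task 2.**  The player stays in the safe place and may press "expose" up
to six times per epoch; each attempt wakes the predator with the threat
level's probability (0.1/0.2/0.3, constant over time); a success ends the
epoch, and further presses after the sixth emit nothing (key disabled).
Press times are generated from the same mixture the analysis fits: with
probability `w` uniform over the epoch timeline, otherwise an
exponentially-modified Gaussian (exGauss) delay after a token onset.

**Memory ratings.**  End-of-session catch-rate ratings are simulated as
`clip(0.99 * true_rate + 36.3 + noise, 0, 100)` — the near-unit slope and
+36.3 percentage-point overestimation healthy players show.

## Readout extraction

Decisions are reconstructed per the cumulative rule: six records per
epoch, record *i* scored 1 iff at least *i* tokens were collected; caught
epochs yield no records because post-catch choices cannot be observed.
Note a structural property of this rule: each loss cell is the *survival
probability* of the per-token policy chain, so even a loss-insensitive
agent has a small negative fitted loss slope (closed form: the slope of
`p**(loss+1)`; ≈ −0.036 at the default intercept).  Recovery tests
therefore compare against this closed-form baseline rather than zero.

Latencies are kept only inside strict open windows (150 < AL < 2000 ms,
0 < RL < 2000 ms — boundary values excluded), only for tokens 1–5, and
return latencies only for uncaught excursions; excluded records are
retained with audit flags rather than dropped.  True catch rates are
catches/excursions per threat level.  Control-cohort QC applies the
leave-one-out rule: a control whose approached-and-survived count falls
more than 4 SD below the mean of the remaining controls is excluded,
iterated to a fixed point; a zero SD never excludes.

## Condition-effects statistics

Approach proportion is analyzed on 3×6 condition means, latencies on
single trials with loss 0–4, in linear mixed models with a random subject
intercept and (optionally) a between-subject group factor, plus
linear×linear contrast rows from a numeric-coded refit.  F tests use
sum-coded factors and Wald contrasts.

Denominator df: statsmodels' MixedLM provides no Satterthwaite
approximation, so the default is a residual approximation
(`n_obs − rank(X) − (n_subjects − 1)`), clearly flagged in the results.
`df_method="satterthwaite"` delegates the F table to lmerTest/lme4 via
`Rscript` when R is installed, reproducing the Satterthwaite recipe
exactly.  If the full factorial is rank-deficient (empty cells in small
runs), the model refits without interactions and flags it.

Greenhouse–Geisser epsilon is estimated from the double-centered
covariance of the subject × condition cell means, clipped to
`[1/(k−1), 1]`, and applied by multiplying both dfs of each F test.  A
caution: this correction is only guaranteed conservative for F values in
the rejection region; for F ≲ 1 the corrected p can be smaller.

Per-subject summaries (feeding the single-case comparisons) are ordinary
least-squares slopes of the condition means on potential loss (averaged
over threat) or on the linear threat code, or the overall mean — OLS on
cell means rather than random-slope BLUPs, keeping single-case values
model-independent.

## Single-case dissociation test

A patient's deficit is the percentile rank (midrank treatment of ties) of
its summary statistic within its own control group.  Two patient groups,
each patient with its own control group, are compared by the difference in
mean ranks.  Because the statistic is purely ordinal, the null
distribution under exchangeability depends only on the control-group
sizes: a patient from the control population is uniform over the n+1
order positions, giving attainable ranks {0, 100/n, …, 100} with equal
probability.  Null replicates draw each pseudo-patient's rank from that
pmf — distribution-free, rather than resampling raw scores.  The p value
is the add-one estimator `(1 + #extreme)/(n_sim + 1)` (one-sided
`null ≥ observed` by default, two-sided on absolute values), which can
never return 0.  For small control groups an exact-enumeration oracle over
the product pmf is provided and used to validate the Monte-Carlo test.

## Exposure-time model

Each Task-2 press after the first token is timed from the most recent
token onset (T2); earlier presses are counted but excluded.  Two
token-independence nulls are available: simulation of uniform pressing
over epoch timelines generated by the task timing model, and re-pairing
of observed press times with token streams of other epochs.  Null
densities are Laplace-smoothed (+0.5 pseudo-count) histograms on 80 bins,
so the mixture likelihood stays finite in empty null bins; cdfs are raw
ECDFs.

The likelihood model is `p(t) = w·f_null(t) + (1−w)·f_exG(t; mu, sigma,
lam)`, with both components renormalized over the observed T2 window
`[0, t_max]`.  The exGauss uses the (mu, sigma, rate) parameterization and
is evaluated in the scaled-complementary-error-function (erfcx) form with
an explicit exponential-tail branch, so it is finite for any admissible
parameters.  The exact printed equations of the original model are not
legible in the source text; the mixture form is reconstructed from the
prose and parameter list, and the parameterization is isolated in two
functions (`exgauss_pdf`, `exgauss_cdf`) should a variant be needed.

Fitting is multi-start (default 10 seeded jitters around a moment-based
start) bounded L-BFGS-B, with `w` on the logit scale and sigma/lam on the
log scale.  Box bounds keep the exGauss on a reaction-time scale (mu ≤
3 s, sigma ≤ 500 ms, tau = 1/lam between 1 ms and 2 s): without them an
arbitrarily broad exGauss can imitate the null itself and `w` loses
identifiability.  With them, pure-null data drives `w` to its upper bound
and the fit is flagged unidentifiable, as it should be.  Split variants
(`split_lambda`, `split_mu`, `split_sigma`, `split_w`, `split_lambda_w`)
give the named parameters group-specific values; they are started from
the fitted combined solution (among other starts), so the nested-model
likelihood ordering holds by construction.

Models are compared by `BIC = k·ln(n) − 2·logL` and log Bayes factors
`LBF = 0.5·(BIC_ref − BIC)` against the combined model, with |ΔLBF| > 3
between best and second best flagged decisive.

## Pipeline and reproducibility

A single master seed deterministically spawns every per-subject and
per-stage stream (SHA-256 of seed + labels, reduced below 2³¹), so a rerun
with the same configuration and seed reproduces every artifact hash.  The
default configuration mirrors the motivating study's design shape: three
MTL-like agents (attenuated loss coefficient, slowed exposure decay) with
10 controls, one HC-like agent with 9 controls, one amygdala-like agent
(slowed return) with 24 controls; 4 Task-1 blocks and 2 Task-2 blocks per
subject.

## Problem sizes and what the tests show

Simulator fidelity checks use ≥10,000 hazard steps, token cycles and
exposure attempts (3 standard errors).  The dissociation test is validated
against exact enumeration at n_sim = 10,000 and calibrated over 1,000 null
replicates with inner n_sim = 2,000.  Mixture recovery uses 20 replicates
at n = 2,000 observations (median relative error < 15 % per parameter);
model-selection recovery uses 20 replicates (4 per generating split
variant) at n = 2,000 per group with 4 optimizer starts.  These sizes make
the recovery experiments well-powered while keeping a full run cheap.

What passing does *not* show: the generator produces clean logistic/linear
condition effects, stationary policies without learning, fatigue or
sequential dependencies beyond the loss mechanism, and exGauss press
timing that matches the fitted model's family.  Real patient and control
data share none of these conveniences, so green tests certify the
*procedures* (correct reconstruction, calibrated tests, recoverable
parameters under the model), not clinical conclusions.  The original
study's clinical quantities (its F tables, reported p values and LBFs)
depend on unavailable single-case data and are out of scope.

## Known limitations

- The 3-position spatial abstraction discards grid geometry; all analyzed
  quantities (decisions, latencies, catches) are preserved, but movement
  kinematics are not modelled.
- The residual-df approximation can be anticonservative for small cohorts;
  use the lmerTest delegation when R is available and df precision
  matters.
- The permutation null assumes epochs are exchangeable in their token
  streams; epochs truncated by early exposure successes make the re-paired
  press sets slightly conservative.
- Multi-patient dissociation groups are aggregated by the mean of member
  ranks; sidedness defaults to one-sided in the hypothesized direction.
  Both are configurable, and two-sided results are reported alongside when
  requested.
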