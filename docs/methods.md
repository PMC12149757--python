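# Methods

`advisdt` analyses how people rely on fallible AI advice in a two-session
binary classification experiment. This note documents the models, the
synthetic-data generator, the numerical choices, and the limits of what the
test suite can show about real data.

## The experimental design being modelled

Participants classify the same 216 stimuli (half "signal", half "noise")
twice: once unaided (Session 1), and once with a scripted, Wizard-of-Oz "AI"
recommendation on every trial (Session 2). The advised session has 9 blocks
of 24 trials. Advice correctness is Bernoulli per trial with block
probabilities 0.9, 0.9, 0.9 (pre-error phase), 0.75, 0.6, 0.45 (error
phase), and 0.9, 0.9, 0.9 (post-error phase). Participants are split between
two instruction conditions, *distrust* (told to stay skeptical and check
each recommendation) and *information-only* (neutral instructions). Trust,
distrust, and advice-use self-reports on a 1–7 Likert scale are queried five
times, after blocks 2, 4, 6, 8 and 9.

## Hierarchical Bayesian SDT model (`advisdt.sdt`)

Each participant × analysis-cell unit *i* has an equal-variance Gaussian SDT
sensitivity `D_i` and criterion `C_i`, reparametrised into hit and
false-alarm probabilities

    h_i = Φ(D_i/2 − C_i),    f_i = Φ(−D_i/2 − C_i).

Units are grouped into cells — by condition, condition × phase, or
condition × advice correctness — with partial pooling:

    D_i ~ Normal(D_μ[cell], precision λ_D)
    C_i ~ Normal(C_μ[cell], precision λ_C)
    D_μ ~ Normal(0, sd 1.9),  C_μ ~ Normal(0, sd 0.95)
    λ_D, λ_C ~ Gamma(0.001, 0.001)

The group-mean prior scales are fixed by the design: with at most 108 hits
and 108 false alarms and the log-linear correction (add 0.5 to each
frequency, 1 to each total), the attainable point estimates are
|d′| ≤ 5.21 and |c| ≤ 2.61, which lie within 3 prior SDs (3 × 1.9 = 5.7,
3 × 0.95 = 2.85). λ_D and λ_C are modelled as two *independent* shared
precisions across the participant-level Gaussians; `SDTPosterior` exposes
both the precisions and the implied SDs.

**Observation model.** The corrected frequencies (hits + 0.5 out of
n_signal + 1; false alarms + 0.5 out of n_noise + 1) enter binomial kernels
with the probabilities above. Counts, not rates, are the observables; the
+0.5 correction keeps perfect or empty cells estimable and bounds the
implied estimates as stated.

**Sampler.** Metropolis-within-Gibbs, vectorised across chains and units:
the cell means and the two precisions have conjugate Gaussian and Gamma
full conditionals; each unit's `(D_i, C_i)` is updated by two scalar
random-walk Metropolis steps whose proposal SDs adapt toward 44% acceptance
during the tuning phase (default 4 chains × 10,000 iterations, first 2,000
tuning, adaptation window 50). Chains are initialised at the jittered
closed-form point estimates `sdt_invert(loglinear_rates(counts))`.
Convergence is flagged when split-R̂ > 1.01 or bulk ESS < 400 (arviz) on any
group-level parameter; the posterior is still returned with a warning. The
sampler is validated by oracle equivalence (a single unit under diffuse
group priors reproduces the closed-form point estimates to < 0.05 at 8,000
retained draws) and by parameter recovery on data simulated from the model.

**d′ differences.** Appropriate reliance is quantified per participant as
the draw-wise difference between advised and unadvised sensitivity,
`d′_S2 − d′_S1`, computed overall and separately for the advice-correct and
advice-incorrect strata of Session 2 (the *detailed* difference). General
reliance predicts a positive difference under correct advice and a negative
one under incorrect advice; appropriate reliance predicts a positive
difference under correct advice and ≈0 under incorrect advice. The two
session fits are independent; draws are pooled across chains and paired at
equal index, so only marginal summaries (mean, 95% HDI) of the difference
are meaningful — the pairing carries no cross-session posterior dependence.
Session-1 participants are grouped by their eventual condition so the
differencing is condition-aligned. Strata that lack one trial type entirely
(possible for short designs in the incorrect-advice split) are dropped from
the fit with a logged warning rather than imputed.

**Highest-density intervals** are computed by the exact sliding-window rule
on sorted draws (narrowest interval containing 95% of them); a test
cross-checks it against a brute-force grid search.

## Reliance metrics (`advisdt.reliance`)

*Acceptance rate*: share of advised trials whose final decision equals the
advice. *Switch percentage*: among advised trials where the participant's
Session-1 decision on the *same stimulus* differed from the advice, the
share that followed the advice. Pairing is by participant × stimulus
identity, which the simulator guarantees and real data must supply.
Contingency tables carry explicit counts with margins emitted as extra
rows, so margin = sum-of-cells is auditable; empty denominators yield an
explicit NaN rate instead of a dropped row. Rates are stored at full
precision; `rate_percent` rounds to 2 decimals for display. Pearson
correlations between per-participant self-report means and behavioral
measures use `scipy.stats.pearsonr`.

`advisdt.reference_tables` stores the original study's published pooled
contingency counts; the acceptance script recomputes the published
acceptance rates and switch percentages from them. The original report's
pooled switch columns label the switched counts under "No"; this package
follows the verbal definition (yes = switched to the advice), which matches
the per-cell table, and the total switch percentage 6952/11420 = 60.88 is
reproduced within one unit of the last printed decimal (the source row
shows 60.87).

## Self-report mixed regression (`advisdt.selfreport`)

Ratings are modelled metrically (Gaussian likelihood on the 1–7 scale —
coefficient magnitudes stay on the rating scale; an ordinal model is out of
scope):

    rating ~ Condition * queryCount + (1 | participant)

The five time points enter through planned contrasts with weight rows
(−1, 1, 0, 0, 0), (−1, −1, 2, 0, 0), (0, 0, 2, −1, −1), (0, 0, 0, 1, −1):
contrast 2 localises a change at the third query relative to the first two;
contrast 3 compares the third query against the last two (recovery). The
rows are deliberately not mutually orthogonal (rows 2 and 3 share time
point 3; their dot product is 4). The weight matrix is mapped to design
columns by the generalized-inverse convention: the hypothesis matrix
(grand-mean row stacked on the weights) is inverted, so each fitted
coefficient estimates exactly its weighted comparison of time-point means.
A plain treatment-coded (categorical) time-point coding is available via
`timepoint_coding="categorical"`; which coding a given report used for its
Condition row may be ambiguous, so both are exposed. Condition is coded
information-only = 1 / distrust = 0 by default (a positive Condition
coefficient means higher ratings under information-only); a centered ±0.5
coding is available and is the one under which label swaps exactly negate
the Condition and interaction coefficients.

Priors: Normal(0, 5) on fixed effects, half-Normal(0, 5) on the
random-intercept and residual SDs — weakly informative relative to a 1–7
response range. The sampler is a collapsed Gibbs scheme: the random
intercepts are integrated out analytically (per-participant compound-
symmetric covariance), fixed effects get a conjugate GLS update, and the two
log-SDs get adaptive random-walk Metropolis steps against the marginal
posterior. Collapsing removes both the σ_u → 0 funnel and the
intercept/random-effect random walk that plague the naive Gibbs scheme; all
parameters reach bulk ESS in the thousands at 4 × 1,500 retained draws. A
floor of 1e-3 on both SDs keeps degenerate (zero-residual) inputs finite.
Summaries report posterior mean, posterior SD, and equal-tailed 95% CI per
coefficient, in the fixed order Intercept, Condition, contrasts 1–4,
interactions 1–4, then the two SDs. A coefficient is read as supported when
its 95% CI excludes 0.

## Synthetic-data generator (`advisdt.simulate`)

The generator is first-class, tested code; it provides ground truth for all
recovery tests.

*Responses.* Each participant is an equal-variance Gaussian SDT observer
(evidence ~ Normal(±d′/2, 1) against criterion c — exactly the inverse of
the model's reparametrisation), followed by probabilistic advice adoption:
when shown advice that conflicts with the own judgment, it is adopted with
probability `adoption_weight`; agreeing advice never changes the response.
This is the minimal mechanism consistent with the SDT analysis when advice
is ignored, and it produces distinct acceptance/switch signatures for the
full-reliance and ignore-advice extremes.

*Population defaults* (`ProfileDistribution`): d′ ~ Normal(0.95, 0.8) —
matching the unadvised mean and spread reported for the original cohort —
c ~ Normal(0, 0.3), adoption weight ~ Beta with mean 0.5 and concentration
10, practice gain 0 (Session-2 unaided skill equals Session 1 by default;
the parameter exists because real cohorts improve). Trust baseline
Normal(4.5, 0.8), distrust baseline Normal(3.0, 0.8), error-induced shift
Normal(0.8, 0.3), Likert noise SD 0.6.

*Stimuli.* A fixed pool of 216 stimulus identities with an exact 50/50
truth split is shared by both sessions (presentation order reshuffled),
giving the stimulus-level pairing the switch percentage requires. Session-2
order is dealt so each block is truth-balanced, stabilising small-cell
counts; Session 1 (27-trial blocks) is balanced at the session level, since
odd block lengths cannot split evenly and no in-scope analysis stratifies
Session 1 by block.

*Self-reports.* Latent trajectory: baseline at time points 1–2, a
persistent step of ±shift from time point 3 on (down for trust, up for
distrust — the asymmetry by which trust lost during the error phase does
not recover), plus Gaussian noise, rounded and clamped to 1..7. The "use"
control item dips at time point 3 only and recovers. Round-and-clamp was
chosen over an ordered-threshold model as the simplest discretisation; the
identical latent distributions at time points 1–2 and 3–5 mean rounding
cannot bias the null contrasts.

*What the generator does not emulate:* correctness-sensitive advice
adoption (a single adoption weight cannot jointly reproduce the original
cohort's ~45% acceptance of incorrect and ~86% acceptance of correct
advice — real participants discount advice they can see is wrong), learning
or fatigue within a session, stimulus-difficulty heterogeneity, reaction
times, certainty ratings, and the lab/online and material sub-study
structure (a scenario label can be carried as an extra column). Passing
recovery tests therefore show the estimators are correct *under the stated
generative assumptions*, not that those assumptions describe any particular
real cohort.

## Pipeline and reproducibility (`advisdt.pipeline`, `advisdt.cli`)

`run_pipeline` executes simulate → SDT fits (Session 1; Session 2 overall,
by phase, by advice correctness) → d′ differences → reliance tables →
trust/distrust regressions → a plain-text report, and writes a JSON
manifest with the config snapshot, per-stage seeds, SHA-256 content hashes
of every output, stage timings, and convergence flags. Stage seeds derive
from the master seed via `SeedSequence(master, spawn_key=(stage_index,))`,
so stages can be re-run in isolation; a fixed config + seed reproduces
every output byte-for-byte (draws are stored as per-parameter `.npy` files
for this reason). Two named profiles exist: `full` (4 chains × 10,000
draws, 2,000 tuning — the reporting configuration) and `reduced`
(4 × 2,000, 500 tuning) for quick runs; the profile is recorded in the
manifest, never silent. The test suite and the acceptance script use the
reduced sizes, with recovery studies at 20 replications and cohorts of
40 participants per condition (SDT) or 131 total (regression) — the scale
at which the checked properties are already well-resolved.

## Known limitations

- The two session posteriors are independent fits; the d′-difference
  distribution is a convolution of independent marginals, not a joint
  posterior over sessions.
- The Gaussian treatment of Likert ratings ignores discreteness and
  boundary effects; with baselines near 1 or 7 the step shift is attenuated
  by clamping.
- Gamma(0.001, 0.001) precision priors are conventional but not
  uninformative near λ → 0; with very few participants per cell the shared
  precisions are weakly identified (the single-participant oracle test
  sidesteps this by diffuse group priors).
- `correlate` returns NaN (undefined) for zero-variance inputs rather than
  raising, so downstream tables can report it explicitly.
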