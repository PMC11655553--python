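# Methods

`iblt` implements the computational analysis of a probabilistic
reward/punishment learning task in which the volatility of win and loss
contingencies is manipulated independently — a design used to measure how
much people up-regulate learning from an outcome stream when that stream is
informative. This note documents the model, the synthetic-data generator,
the estimator, the statistical machinery, and the numerical and design
choices a user should know about.

## Task and generative model

A session is six 80-trial blocks of choosing between two shapes (A/B). Each
trial independently assigns a win (+10p) and a loss (−10p) to one of the two
shapes; the chosen shape collects what landed on it (win only → +10p, loss
only → −10p, both or neither → 0p). Per block one of three volatility
conditions holds: `both-volatile` (win and loss each follow a reversing
80/20 contingency), `wins-volatile` (wins 80/20, losses flat 50/50), or
`losses-volatile` (the mirror). A session runs both-volatile, then four
alternating single-volatile blocks (counterbalanced order), then
both-volatile again. Stimulation condition labels (real/sham; during- vs
before-task timing) are pass-through metadata on sessions and blocks 2–3.

The behavioural model tracks two probability estimates per block, `rwin` and
`rloss` (probability that the win/loss is on shape A), updated every trial by
a delta rule with valence-specific learning rates α_win, α_loss:

    rwin[i+1]  = rwin[i]  + α_win  (winout[i]  − rwin[i])
    rloss[i+1] = rloss[i] + α_loss (lossout[i] − rloss[i])

and maps them to a choice probability with a two-temperature softmax:

    P(A) = 1 / (1 + exp(−(β_win (rwin − 0.5) − β_loss (rloss − 0.5))))

Updating is full-feedback — both outcomes are displayed every trial, so the
estimates are updated regardless of the choice and the state trajectory
depends only on the outcome sequence and α. The state resets to (0.5, 0.5)
at each block start: blocks are treated as distinct environments, and the
(r − 0.5) centring of the softmax makes that the neutral point.

**Model family.** Learning rates are block-wise in every variant; the
winning variant has dual (win/loss) learning rates and dual temperatures
shared across all six blocks (14 free parameters per session). The
comparator family is the crossing {single vs dual learning rate} × {single
vs dual temperature} under constant temperatures, plus the dual/dual
block-wise-temperature variant (24 parameters). This family is a documented
surrogate spanning the constant- vs block-wise-temperature contrast; it is
not a reconstruction of any particular published model set.

## Schedules: exact-count realisation

"80%" contingencies hold *exactly*: each volatile stream is divided into
`n_reversals + 1` segments (default 3 reversals), each at least 14 trials
long with an integral favoured-shape count (for p = 0.8, segment lengths are
multiples of 5), and within each segment exactly p × length trials put the
outcome on the favoured shape, in uniformly shuffled positions. Flat 50/50
streams are exactly balanced over the block. Segment boundaries are drawn
uniformly among feasible compositions. Infeasible requests (counts not
integral, segments too short) are rejected with an explicit message rather
than silently approximated. This makes the printed proportions testable
deterministically in every single block.

## Synthetic cohorts

The generator emulates the study structure: two-session low-mood groups
(stimulation during vs before the task; real/sham counterbalanced within
subject, block order counterbalanced across subjects) plus a two-session
healthy baseline sample. Subject-level parameters are drawn on the
transformed scale:

| quantity | default | meaning |
|---|---|---|
| logit α, volatile stream | −0.62 (α ≈ 0.35) | condition mean when the stream reverses |
| logit α, stable stream | −1.74 (α ≈ 0.15) | condition mean for flat 50/50 streams |
| SD of subject effect | 0.5 logit | shifts both condition means together |
| SD of adjustment effect | 0.4 logit | widens/narrows the volatile−stable gap per valence |
| log β | 2.08 (β ≈ 8) | softmax sensitivity, constant across blocks |
| SD of log β | 0.5 | — |

Random effects are truncated at ±2 SD: bounded heterogeneity keeps agents in
the psychologically plausible range and guarantees that additive effect
injections cannot push a rate out of (0, 1) (any injection that would is
rejected). The adjustment-level random effect matters: without it all
subjects share essentially the same volatile−stable gap, between-subject
variance in the adjustment measures collapses, and group-level inference on
them would be degenerate — individual differences in volatility adaptation
are precisely the phenomenon of interest.

**Effect injections** are additive natural-scale shifts on the
volatile-condition learning rate of one valence, so they move the
corresponding learning-rate *adjustment* by exactly the stated amount. Sample
shifts apply to every session of low-mood groups; stimulation shifts apply
only in blocks 2–3 of real sessions of the during-task group — before-task
stimulation is generated with no effect, which is the ground truth the
pipeline is meant to recover. The default scenario injects win +0.10 /
loss −0.10 (sample) and the exact opposite in stimulated blocks, i.e. a true
sham adjustment bias of −0.20 restored to 0 by real during-task stimulation.
These magnitudes were chosen so that the *measured* effects, after the known
attenuation of point estimates (below), land near the effect sizes typical of
this literature (paired dz ≈ 0.6 for the stimulation contrast).

What the generator does **not** emulate: reaction times, attention lapses or
missed trials, screen-side effects, session-order (practice) effects,
questionnaire–behaviour coupling beyond group membership, and any true
within-subject drift of β across blocks. Passing tests therefore show that
the pipeline recovers what this generative family produces — not that the
model family is correct for human data.

## Estimation

Per subject-session maximum a posteriori on the unconstrained scale (logit
rates, log temperatures), with independent normal priors: sd 2 on every
parameter, rate priors centred at logit −1 (α ≈ 0.27), temperature priors at
log β = 0. The rate prior is centred in the empirically typical
learning-rate range rather than at α = 0.5 because a zero-centred logit
prior systematically inflates weakly identified stable-stream rates toward
0.5, which leaks a positive offset into the adjustment measures; recentring
cuts that bias to under 0.03 on the natural scale without noticeably moving
well-identified parameters.

The optimiser is L-BFGS-B with analytic gradients (state trajectories are
first-order linear filters of the outcome stream, so ∂r/∂α is itself a
linear filter; one likelihood-plus-gradient evaluation costs four `lfilter`
passes per block), multi-start with deterministic seeded restarts (default
10; the large simulation harnesses use 3, which on this likelihood changes
selected optima only at the 1e−6 level), gradient tolerance 1e−6. BIC is
computed from the *unpenalised* nll at the MAP point, k ln(n_obs) + 2 nll
with n_obs the number of modelled choices (480 for a full session), keeping
the criterion's textbook definition. Non-converged fits are flagged and
excluded from model comparison listwise.

Two estimator facts to keep in mind when interpreting absolute numbers:

* **Attenuation.** MAP point estimates of block-wise rates regress toward
  the prior; volatile−stable gaps measured from fits are ~0.6 of their true
  size. Within-subject and between-group contrasts are unaffected (the
  attenuation is common to both sides), but absolute adjustment values
  underestimate the generative truth.
* **α–β trade-off.** Trajectories produced by different learning rates
  differ mostly in amplitude, which the temperature can rescale. This limits
  how much likelihood is gained by splitting a learning rate by valence, and
  is the reason BIC model recovery of the dual-rate structure fails in this
  family: the single-rate/dual-temperature variant (8 parameters) emulates
  dual-rate data well enough that its 6-parameter head start is decisive at
  480 trials/session — across every generating regime tried, from modest to
  extreme win/loss separation. The `model_recovery` harness reports this
  honestly; selecting among these variants by BIC at this sample size is not
  a reliable procedure, and measure computation therefore keys on the
  winning variant directly rather than on a data-driven selection step.

## Derived measures

From block-wise fitted rates: win adjustment = win LR(wins-volatile) − win
LR(losses-volatile); loss adjustment = loss LR(losses-volatile) − loss
LR(wins-volatile); adjustment bias = loss − win adjustment. Stimulation
analyses use blocks 2–3 only (the stimulated pair contains exactly one block
of each single-volatile condition, whichever the counterbalancing assigned);
the group-contrast analysis computes measures per session half (blocks 1–3
vs 4–6, each containing one block of every condition) so Time enters the
ANOVA as a two-level factor, with both-volatile rates supplied by blocks 1
and 6.

## Statistics

* **Mixed-design ANOVA** (`iblt.anova.rm_anova`): univariate approach —
  subject × within-cell means are projected onto orthonormal within-subject
  contrasts (Kronecker products per effect), and each contrast set is
  analysed by OLS over the between factors with Type III sums of squares
  under sum-to-zero coding; Greenhouse-Geisser ε is computed from the
  residual covariance of the contrast scores and corrected p-values are
  reported for within effects with more than 1 df. Incomplete subjects are
  dropped listwise and logged; replicates per cell are averaged; a stratum
  in which the dv is constant returns F = 0 by convention. The engine is
  cross-checked against an independent repeated-measures implementation on
  the designs that implementation supports; with unbalanced groups the
  within main effects test unweighted (Type III) marginal means, which can
  differ from pooled-SS implementations.
* **Outlier rule**: Tukey fences at 1.5 × IQR beyond the quartiles (linear
  interpolation between order statistics), computed separately per factor
  level; stimulation analyses apply the rule to real-minus-sham differences.
  Headline contrasts are reported both with and without removal, plus a
  Wilcoxon signed-rank robustness check on all data points (V = sum of
  positive-difference ranks, exact p for n ≤ 25, continuity-corrected normal
  approximation above).
* **Effect sizes**: Cohen's dz (mean/SD of differences) for paired designs,
  Cohen's d with pooled SD for group contrasts, rank-biserial r for the
  Wilcoxon.
* **Power**: noncentral-t power for the paired design; the planning routine
  returns the smallest n meeting a target power.
* **Calibration harness**: the headline paired contrast is exercised on
  per-subject difference scores drawn from N(dz, 1); 1000-replicate runs
  verify the 5% null rejection rate and ~80% power at the planning effect
  size dz = 0.472 (n = 38). This is run at measure level by design — it
  verifies the inference machinery at the planned sample size, while the
  end-to-end pipeline test covers the simulate → fit → measure path once at
  full scale.

## Model-free validation

Per block, each choice is regressed (logistic) on the win and loss outcome
codes of the previous three trials, coded ±0.5 relative to shape A; lags do
not cross block boundaries, so the first three trials of each block are
dropped (77 design rows per 80-trial block). Blocks sharing a condition are
pooled by default (configurable). Perfect separation triggers an
L2-stabilised refit with a warning. Because a recent loss pushes choice away
from its shape, the raw lag-1 loss coefficient is negative; its negation is
the influence magnitude analogous to the loss learning rate, and the
weight-adjustment measures are built from these influences in parallel with
the learning-rate adjustments. On default cohorts the two measure families
correlate at r ≈ 0.55–0.75 across subjects.

## Problem sizes

The shipped test-suite and acceptance-script runs use: 40-subject cohorts for
parameter recovery; 50 replicate 20-subject cohorts for model recovery (15 in
the acceptance script); 1000 replicates for calibration; and a 38 + 38 + 38
subject three-group study (two sessions each for the stimulation groups) for
the end-to-end analyses, fitted with 3 restarts. These sizes were chosen to
match the study's own scale where it has one (n = 38 per group is the
planning sample size; 41/44/40 are the library defaults) and to keep
simulation harnesses at desk scale elsewhere.

## Known limitations

* Per-subject MAP, no hierarchical pooling: shrinkage is toward a fixed
  prior, not a learned group distribution; absolute adjustment levels are
  attenuated (see above).
* BIC model selection within this family is unreliable at 480
  trials/session (α–β trade-off); the package reports it rather than
  relying on it.
* The ANOVA engine requires crossed factorial designs with complete within
  cells after listwise dropping; no missing-data modelling.
* Exact-count realisation makes outcome sequences slightly sub-Bernoulli in
  variance; agents and fits are unaffected, but analyses that assume i.i.d.
  outcome draws would see mildly deflated sequence variance.
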