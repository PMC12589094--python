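# Methods

## The model

`lifecourse` models a person's health history as a time-ordered stream
of discrete tokens — first-occurrence ICD-style diagnoses, a terminal
death token, input-only sex and lifestyle markers, and stochastic
"no event" padding — each recorded at a continuous age measured in
days from birth.  A decoder-only transformer reads the stream and
emits, at every position, one logit per vocabulary token.  Logits of
predictable tokens (diseases, death, no-event) are interpreted as
natural logs of event rates per day.

Three departures from a text GPT make this work on a continuous time
axis:

1. **Age encoding.**  The learned positional table is replaced by a
   fixed sinusoidal basis evaluated on age, mixed by one trainable
   linear map.  Basis pairs (sin, cos) sit at geometrically spaced
   periods from 100 years down to 2 days, covering lifetime trends and
   sub-year structure; because no parameter attaches to a sequence
   position, inputs of any length are accepted.  The trainable mixing
   makes results insensitive to the exact ladder, which is a design
   choice here (frequency conventions for such ladders are ambiguous
   in the literature this follows).
2. **Same-time attention masking.**  Causal attention is narrowed so a
   query attends only keys with *strictly smaller* age, plus itself.
   Co-occurring events (equal age) carry no ordering information and
   must not predict one another; self-attention is retained so no row
   of the attention matrix is empty.  Leakage through the self edge is
   harmless because prediction sources are chosen by the pairing rule
   below.  Non-informative block padding is masked as a key everywhere.
3. **Competing-exponentials likelihood.**  Each predictable token
   carries an exponential waiting time with rate `λ_i = exp(logit_i)`.
   The next event's identity is then multinomial with probabilities
   `λ_j / Σλ_i` — the softmax — and the waiting time to it is
   exponential with rate `λ* = Σλ_i`.  Both terms are read off the
   same logits vector:

       loss = −log softmax(logits)[j] − (logsumexp(logits) − Σexp(logits)·T*)

   averaged over prediction pairs, in nats per event.  Sex, lifestyle
   and padding tokens are excluded from both terms by a −∞ logit
   (−10⁹ inside softmax paths; exact exclusion in rate sums).

**Target pairing.**  Every predictable token whose age exceeds the
first event's age is predicted from the last position of strictly
smaller age; co-occurring targets share that source.  Waiting times
are therefore strictly positive by construction, which the likelihood
requires.  Tokens with no strictly earlier source contribute no loss.

**Padding as a rate anchor.**  No-event tokens are inserted at a
constant average rate of 1 per 5 years (20 uniform draws over the
0–100-year range intersected with the observation window).  They keep
inter-event gaps short — the piecewise-constant-rate assumption behind
the likelihood is only reasonable over short horizons — and double as
inference probes: appending a no-event token at any age reads off the
predicted rates at that moment.

**Architecture bookkeeping.**  Pre-norm transformer blocks, bias-free
linear maps, gain-only layer norms, weight tying between the input
embedding and the output projection, tanh-form GELU.  At the published
scale (embedding 120, 12 layers, 12 heads, 1,270 tokens, 120-component
age basis) the trainable parameter count is exactly 2,243,400 — 2.2 M
at one-decimal rounding — which is what pins the bias-free/tied
choices.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, no weight decay), float32, linear warmup
then cosine decay.  The paper-scale profile keeps the published
schedule (batch 128, 200,000 iterations, 6·10⁻⁴ → 6·10⁻⁵).  The desk
profile used throughout the tests is

    embedding 32, 4 layers, 4 heads, block 64, batch 48, dropout 0.1,
    6,000 iterations, lr 6·10⁻³ → 6·10⁻⁴, warmup 200, grad clip 1.0

sized so a full parameter-recovery experiment (cohort simulation,
preparation, fit, evaluation) runs on one CPU in minutes.  The desk
learning rate is 10× the published one: at a few thousand iterations
the optimizer must first descend the global rate scale (several nats
of logit shift) before any conditioning can be learned, and the
published rate does not get there.

**Gradient clipping matters more than usual.**  While rates are
miscalibrated — always true at initialization, where logits ≈ 0 imply
one event per token per day — the waiting-time term produces gradients
three to four orders of magnitude above their converged scale.
Unclipped, those transients inflate Adam's second-moment estimates and
suppress all small (conditioning) gradients for thousands of
iterations afterwards: the model plateaus at marginal token
frequencies with near-constant logits.  A global gradient-norm ceiling
of 1.0 (the default) removes the pathology; training batches longer
than the block are cropped to a window ending at a random event, and
batch width adapts to the longest sampled trajectory for speed.

Trajectories longer than the block are cropped to a contiguous window
ending at a random event (ages kept intact).  A cropped-off same-age
prefix cannot corrupt the pairing: a target never pairs with an
equal-age source, so boundary targets are simply omitted.

## The synthetic cohort generator

Registry-grade training data are access-restricted, so every claim the
package tests is made against cohorts drawn from a known hazard model:

    log rate_i(t) = a_i + b_i · age_years + s_i · [male]
                    + Σ_m β_mi · 2^(−lag_m / h_mi)

with first-occurrence diseases, terminal death, sex assigned at birth,
lifestyle tokens at a recruitment age (default 45 y), and pairwise
interaction effects that decay with half-life `h` (∞ = permanent).
Sampling uses piecewise-constant competing exponentials refreshed at
every event and at yearly age knots; the approximation error is
bounded by the hazard change across one knot (< 9 % at the steepest
preset slope, 0.085/year).

The `recovery` preset (20 diseases, n = 5,000) spreads baseline annual
incidences log-uniformly over 3·10⁻⁴–3·10⁻², mixes age slopes of 0,
0.03 and 0.06 per year, sex effects of ±0.6, Gompertz-like mortality
(2·10⁻⁴/year at birth, slope 0.085/year), and plants five
interactions, among them a permanent ×3 comorbidity, a ×4 excess
mortality decaying with a 5-year half-life, and a lifestyle→disease
effect — one of each qualitative kind the attribution machinery must
recover.  The `null` preset removes all interactions; `tiny` is a
5-disease smoke configuration.

What the generator deliberately does not emulate: calendar-time
structure, recording artefacts and source-specific missingness,
diagnosis-code hierarchies, demographic confounders beyond sex.
Passing tests therefore demonstrate that the machinery recovers known
generating mechanisms of this form, not that it handles registry
messiness.

## Evaluation stack

* **Annual risk** from a log-rate: `P(T < 1y) = 1 − exp(−rate·365.25)`.
* **Observed incidence** in yearly age bins with an at-risk denominator
  shrinking by cumulative deaths.
* **Stratified AUC**: per sex and 5-year age bracket (50–80), brackets
  with more than two cases averaged unweighted; bracket variance by
  DeLong's placement method, combined as `σ² = (1/n²) Σ σ_i²`.  Ties
  use the midpoint convention.  A token with no qualifying bracket is
  flagged, never reported as 0.5.
* **Subgroup bias**: precision-weighted pooled AUC, standardized
  residuals `r_s = (μ_s − μ)/σ_s`, disease-level `χ² = Σ r_s²` with
  n−1 degrees of freedom, Bonferroni-corrected thresholds (two-sided
  for residuals, one-sided for diseases); brackets with fewer than six
  cases are dropped before the test.
* **Calibration** in geometric risk bins (factor 5 from 10⁻⁶ to 1).
  The case/control construction follows the stated design: cases per
  5-year age band, one random control datapoint per other proband in
  the band, predictions taken at the preceding token within one year.
* **Incidence cross-entropy** `H(p,q) = −p log q − (1−p) log(1−q)`
  summed over age/sex/token cells; conflicting boundary values surface
  as ∞ rather than being clipped.
* **Nelson–Aalen** cumulative hazards (via lifelines) anchor the
  nonparametric baseline and the hazard-ratio cross-check.
* **Longitudinal harness**: histories truncated at a cutoff age, a
  1-year data gap, outcomes scored in the following 1-year window,
  tokens with fewer than 25 cases dropped.  First-occurrence semantics
  exclude anyone already carrying the token (including death during
  the gap) from that token's at-risk set — without this exclusion even
  ground-truth rates score near 0.5, because a positive prediction is
  paired with an impossible outcome.

## Attribution

The coalition game masks tokens to the no-event placeholder (sex swaps
to the opposite sex); the value of a coalition is the target token's
log-rate at the trajectory's last position, so `exp` of an attribution
is a rate fold-change.  Exact Shapley values are computed by subset
enumeration up to 8 maskable tokens.  Beyond that, the hierarchical
approximation computes Owen values on a binary tree built by recursive
chronological halving, enumerating every on/off configuration of the
sibling groups along each leaf's path (≈ n² evaluations, batched
through one forward pass).  Owen values are exactly efficient and
coincide with Shapley values whenever the game is additive across the
partition — true in particular for the log-linear hazard oracle, which
is what the equivalence tests exploit; for transformer games the
approximation is checked for efficiency and sign agreement instead.
No-event and block-padding tokens are excluded from the maskable set
(masking them is the identity).

The nonparametric hazard-ratio cross-check follows the crude design:
five age- and sex-matched controls per case, Nelson–Aalen curves from
the source occurrence onward, Gaussian-kernel-smoothed derivatives,
and their ratio.  Controls are not censored when they acquire the
source later, so the estimate attenuates toward 1 for common sources —
the planted-effect tests use a rare source where this bias is small.

## Numerical choices and degenerate inputs

* −∞ logits are −10⁹ inside softmax paths (exact zero after exp
  underflow) and exact exclusions in rate sums, avoiding NaNs.
* Waiting times of exactly zero cannot arise from the pairing rule and
  are rejected rather than epsilon-fudged.
* Empty pairings raise instead of contributing zero loss, keeping
  cross-batch averages honest.
* Ages are stored as real days; the TSV format writes two decimals.
  Windows are half-open `[start, end)`; "after death" means strictly
  greater age, so an event co-occurring with death is retained.
* Per-person RNG substreams derive from (seed, CRC32 of person id), so
  cohort-level transforms are independent of cohort order.
* The float64 mode of the tensor engine exists for finite-difference
  gradient checks; training is float32 throughout.

## Known limitations

* Desk-scale fits recover rate *ordering* and calibration well before
  they saturate interaction fine structure; embedding-space geometry
  (nearest-neighbour lists) is meaningful but noisy at this scale.
* The sampler holds rates constant between consecutive events; fast
  hazard changes inside a long gap are only captured through the
  padding-token refresh.
* Repeat diagnoses during sampling are resampled (up to 100 draws,
  then replaced by no-event keeping the drawn waiting time); whether
  the published sampler suppresses repeats is unstated, so this is a
  repository decision.
* The learned-positions ablation flag exists for comparison runs but
  caps sequence length at the block size, unlike the age encoding.
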