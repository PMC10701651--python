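# Methods

This note documents the model, the data-generating assumptions, the
numerical choices, and what the tests do and do not establish.

## Data model

A cohort is five tables: a **roster** (participant, class, sex, age), a
**message log** (one row per one-to-one message: sender, receiver, class),
**nominations** (ego, alter, class, question 1–4), **steps** (participant ×
wave 1–7 × day 1–7, with a per-day completeness flag standing in for the
"less than 24 h of wear" criterion of raw accelerometry), and **FAS answers**
(four items, 0–3 each). Only within-class, non-self events are admitted;
cross-class messages are counted and dropped.

## Network construction

**Web network.** For every ordered pair with at least one message, a directed
edge sender→receiver with weight `m_ij / max_c(m)`; the heaviest pair in each
class has weight exactly 1, so weights are invariant to uniformly rescaling
all counts. **Nomination network.** A directed edge ego→alter exists iff the
ego named the alter in question 1 (the "hang out or have contact with"
question, the one closest in meaning to messaging); the weight is the number
of the four questions naming that alter, divided by 4. Both networks keep the
full class roster as nodes; isolates are permitted.

The stored edge direction is the data direction. The mapping to *who
influences whom* is made once, in the influence matrix: under the default
`received` orientation, the peers salient to an ego influence the ego — a
message **sender** influences the receiver, and a **nominated alter**
influences the nominating ego. The opposite reading is available as
`influence_orientation="sent"`. The two readings differ because the source
descriptions of the weight semantics are not mutually consistent; keeping the
switch in `ModelParams` isolates the choice.

## Attribute preprocessing

Per wave, days 1 and 7 are dropped (never full measurement days), as are
incomplete days and days under 1,000 steps. With ≥3 valid days, PAL = mean
valid steps / 10,000. Participants with fewer valid days are imputed with the
mean PAL of same-sex classmates (cohort mean as fallback) — a deliberately
simple, documented rule standing where the original analysis used multilevel
predictive-mean-matching; it affects only initialization and observed means,
not the dynamics. FAS is the 0–12 item sum.

## Diffusion model

Daily synchronous update, as in the README: social term `S` (row-normalized
influence matrix times PAL), environment target `E_i = PAL̄₀ · FAS_i / FAS̄₀`
clipped to the PAL bounds, combined influence `C = (1−λ)S + λE`, threshold
`T_PAL`, multiplicative step `I_PAL`. Design choices made where the design
was genuinely open:

* **λ (environment mixing) = 0.2, fixed.** Exactly two parameters are
  calibrated, so the environment coupling must be a fixed constant; 0.2 keeps
  the network the dominant channel while making affluence matter. Exposed in
  `ModelParams`.
* **Environment target is a proportional map** from FAS to the PAL scale
  anchored at the wave-1 cohort means (`PAL̄₀`, `FAS̄₀`). Anchors are fixed at
  the wave-1 cohort values rather than per-run sample means so calibration
  and intervention runs share one environment and runs are deterministic
  given their parameters and initial PALs.
* **Isolates** (no influencers) follow environment-only dynamics, `C = E`.
* **Strict inequality at the threshold**, padded by 1e-12 so float roundoff
  in the weighted mean can never move a homogeneous cohort (an exact fixed
  point for all parameter values when λ = 0).
* **No per-step noise.** Run-to-run variation comes from parameter
  uncertainty (the retained ensemble) and initial resampling only.
* **PAL bounds [0.1, 2.0]**, bracketing the plausible empirical range
  (~0.12–1.87); every update is clipped, so boundedness holds for any
  parameters.

## Calibration

Grid `T_PAL ∈ [0, 0.30]` step 0.01 × `I_PAL ∈ [0, 0.05]` step 0.001 (1,581
points, configurable). Each point is simulated to steady state — every class
mean changing < 1e-4 for 10 consecutive days, capped at 500 days with capped
points flagged — from initial PALs resampled with replacement from the wave-1
distribution, and scored by the sum of squared errors between steady-state
class means and observed per-class means at three year points (waves 2–3,
wave 4, waves 5–7). Scores average 3 initializations per point; the same
initial draws are shared across all grid points (common random numbers), so
the SSE surface is not jittered point-to-point. The 100 best points form the
ensemble; all intervention runs use one run per retained combination.

**Initialization is stratified by class and sex.** The model is calibrated
against per-class observations, and class membership carries most of the
persistent between-class PAL differences. Pooling the wave-1 distribution
across classes erases exactly the structure being fit, and the grid search
then degenerates: near-zero thresholds win because compressing every class
toward the cohort mean is the lowest-variance predictor, after which an
intervention boost fully reverts and no persistent impact is possible.
Class+sex strata keep the fit meaningful; sex-only pooling remains available
(`by_class=False`). Empty strata fall back to the sex stratum, then to the
pooled distribution, with warnings.

## Interventions

The per-class quota is round-half-up(0.15 · class size), clamped to ≥2
(giving 2–4 influencers for classes of 15–29). Ranking is centrality
descending, ties by higher PAL, residual ties by a seeded draw; every
tie-break is logged. Centralities are computed on the unweighted directed
structure (normalized in-degree; betweenness normalized by (n−1)(n−2);
incoming-distance closeness with the Wasserman–Faust reachable-component
correction, 0 for unreached nodes).

A scenario applies the boost once, at the calibrated steady state, to the
selected agents (multiplicative, clipped), then runs 200 further days. The
relative impact is measured against the **pre-boost** baseline, so it
includes the boost to the influencers themselves plus its diffusion; a day-60
snapshot is also exported. Each scenario runs once per retained parameter
combination from a freshly resampled, per-combination steady state; the
median and [25th, 75th] percentiles (linear interpolation) summarize the
ensemble; the steps/day equivalent is `median% × baseline mean PAL × 10,000 /
100`. Impact distributions are compared with the two-sided Mann–Whitney U
test; two all-tied samples are reported as p = 1 with a degenerate-variance
flag.

## Synthetic cohort

Each class draws a latent symmetric friendship graph (density 0.45, every
pupil at least one friend). Messages: a class total drawn log-uniformly
inside [143, 5301], split over the latent directed ties that survive
zero-inflation (12%) by a Dirichlet-multinomial with concentration
1/`message_dispersion` (default 8, giving strongly right-skewed pair counts);
every surviving tie carries at least one message. Nominations: question 1
samples each latent tie with a probability solved by bisection so the
*expected* web-vs-nomination edge Jaccard hits `network_overlap_target`
(default 0.69), plus a 1% off-tie rate; questions 2–4 re-nominate question-1
alters with probability 0.25 (placing the mean nomination weight near the
observed ~0.43); minimum one nomination per question is enforced, capped at
10. Steps: per-pupil baseline Normal(9,200 ± sex offset 400, SD 2,600)
clipped to [1,200, 18,700], daily noise SD 1,800, and 12% invalid days (half
flagged incomplete, half drawn under 1,000 steps). FAS items are
Binomial(3, 9.1/12), so sums average 9.1 on 0–12.

What the generator does **not** emulate: message content and timing,
wave-to-wave attrition, any real longitudinal trend in activity (baselines are
stationary, so calibration targets carry class structure but no drift),
age effects, and degree–attribute correlations beyond what the latent graph
induces. Passing tests therefore show that the pipeline's machinery behaves
as specified under the stated statistical structure — not that the study's
empirical medians would be reproduced on the original cohort, which is not
publicly deposited. The printed headline medians serve only as plausibility
context.

## Problem sizes and determinism

The default analysis uses the full synthetic scale (21 classes, ~440 agents,
1,581-point grid, 100-run ensembles); calibration takes about half a minute
on one CPU and a full scenario sweep a few seconds per scenario, so the whole
study re-runs in minutes. All randomness flows through explicit
`numpy.random.Generator` seeds; identical seeds yield byte-identical cohorts,
calibrations and impact tables. The parameter-recovery check runs the grid
search against observations simulated at a known parameter pair from the
same seeded initialization the search uses (matched initial conditions),
making the generating point the unique SSE minimum; with independent noise
the SSE surface is ridged (several threshold/step-size combinations yield
nearly identical steady states) and recovery is only approximate.

## Known limitations

* The functional forms of the original model's supplementary description are
  reconstructed; each reconstructed choice (λ, environment map, orientation,
  threshold tie handling) is isolated behind a constant or switch.
* Networks are static over the simulated horizon.
* The simplified imputation rule understates between-pupil variance for
  heavily missing step data.
* Steady state is declared on class means, not agent states; low-amplitude
  agent-level oscillation inside the threshold band can persist.
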