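# Methods

## Task environment

The Heaton-style WCST is modelled deterministically. Four canonical
stimulus cards — red triangle ×1, green star ×2, yellow cross ×3, blue
circle ×4 — are pairwise distinct on every dimension, so any target card
matches exactly one stimulus card per feature. Targets are drawn uniformly
from the 60 feature combinations that are not identical to a stimulus card
(`uniform-60`, the default): a target identical to a stimulus card would
match it on all three dimensions, making the feedback uninformative about
the rule. A `uniform-64` policy and an explicit `fixed-list` ordering are
available for sensitivity checks. The hidden rule starts at color and
cycles color → shape → number, advancing after every run of 10 consecutive
correct responses. Simulated cohort studies run to 128 trials with no
category cap; the clinical application protocol (used when fitting
observed data) stops at min(128 trials, 6 categories). Trials are 1-based;
features are indexed 1 = color, 2 = shape, 3 = number.

## Agent

State: a predictive distribution over the three rules (initially uniform)
and an activation vector ω (initially (0.5, 0.5, 0.5)). Per trial, in
order: sample a feature from the predictive distribution and choose the
stimulus card matching the target on it; receive feedback; apply the Bayes
step with the indicator likelihood; gate the match vector by feedback into
the matching signal m_t; update ω elementwise as

    ω_t = f · ω_{t−1}^δ ⊙ m_t + λ · [(1−f) · ω_{t−1}^δ ⊙ (1−m_t)] ⊙ ω_{t−1};

build the stability matrix Γ (diag ω, off-diagonals (1−ω_i)/2, rows
summing to 1) and propagate the posterior through it (predictive_k =
Σ_i Γ_ik · posterior_i).

Design choices at points the recursion leaves open:

- **p(a|s=i)** is the 0/1 indicator of a feature match between the chosen
  card and the target, which makes the likelihood denominator the count of
  matching (or non-matching) features.
- **Matching-signal gating.** By default m_t is the match vector on
  positive feedback and the zero vector on negative feedback (the literal
  reading of its definition); `gate_signal_on_feedback=False` passes the
  match vector regardless of feedback. Both readings were evaluated; see
  *Known discrepancies*.
- **Activation floor** 10⁻⁶: a literal zero is absorbing under the power
  damping (0^δ = 0), so activations are clamped below. Configurable;
  cohort statistics are insensitive to the value over 10⁻⁹…10⁻³.
- **Predictive floor** 10⁻¹²: at parameter extremes (δ = 0, λ ∈ {0, 1})
  the dynamics produce exactly degenerate predictive distributions, after
  which a single disconfirming observation would have probability zero.
  Every state is kept at ≥ 10⁻¹² predictive mass (renormalised), applied
  identically in the simulator, the conditional replay, and the vectorised
  likelihood, so the three paths remain exactly equivalent.
- **Lapse ξ** (uniform-response mixture weight): 0 for simulation; 0.01 by
  default when fitting observed human data, so responses matching the
  target on no feature retain positive likelihood.

## Information measures

All measures are in nats (the natural-log convention keeps the entropy
ceiling at ln 3 ≈ 1.0986). Bayesian surprise is computed between
successive predictive distributions, KL[p(s_{t+1}|x_{0:t}) ‖
p(s_t|x_{0:t−1})]; Shannon surprise is −log of the observation marginal
produced by the Bayes normalisation; predictive entropy is the entropy of
the distribution the action was sampled from. Reconstruction from an
observed session replays the same deterministic recursion, so applying it
to a simulated session with the generating parameters reproduces the
simulation-time logs exactly.

## Clinical scoring

- **Perseverative error (PE):** an error whose response matches the target
  on the *perseverated-to principle* — the rule in force before the most
  recent rule change — with that match unambiguous (exactly one matching
  dimension). Errors before the first change, and ambiguous matches, count
  as non-perseverative (E). Full clinical perseveration criteria include
  further clauses (e.g. the "sandwich" rule, provided as an off-by-default
  option) that cannot be applied unambiguously to this simulation setting;
  the operationalisation here is the stable core of those criteria.
- **Trials to first category (TFC):** index of the trial completing the
  first run of 10 consecutive correct responses; censored at session
  length (flag, not sentinel) when never completed.
- **Failures to maintain set (FMS):** errors directly following ≥ 5
  consecutive correct responses under the same, still-current rule; the
  streak resets at category completion so post-change errors are not FMS.

## Estimation

Conditioned on observed actions and feedback the belief recursion is
deterministic, so the action sequence has an exact likelihood: per trial,
log q(a_t) with q(a) = (1−ξ)·Σ_i predictive_i·1[card_for_feature(target,
i) = a] + ξ/4. Feedback is deterministic given actions and protocol and
contributes nothing. The joint posterior over θ = (λ, δ) under the uniform
prior on [0,1]² is evaluated on a 101 × 101 grid with log-sum-exp
normalisation; doubling the resolution moves posterior means by well under
0.005. The grid evaluation is vectorised across nodes ((G, 3) arrays per
trial), so one 128-trial session fits in ≈ 0.2 s on one CPU.

Summaries use marginal means, medians and central credible intervals. The
weighted quantile underlying the intervals uses a midpoint
(continuity-corrected) CDF — node mass counts half below and half above
its position — because naive cumulative interpolation systematically
widens intervals (measured as +0.02…+0.06 over-coverage at every level).

Validation (`recovery_study`): θ* drawn from the prior, one 128-trial
session each, exact grid posterior per session. Reported: per-parameter
RMSE and R² (1 − SS_res/SS_tot) of posterior means; calibration error
(mean |nominal − empirical| coverage of central credible intervals over
α ∈ {0.05, …, 0.95}); SBC ranks (position of θ* among 100 posterior draws
sampled from the grid mass). With 1000 validation sets the empirical
coverage matches nominal within 0.05 at every level and SBC ranks pass a
20-bin chi-square test at α = 0.01; the probability integral transform of
the truths is statistically uniform, as it must be for an exact posterior.
Problem sizes used by the shipped studies — 150 agents per factorial cell,
300 recovery sets (1000 for the calibration check) — balance Monte Carlo
error against desk-scale runtimes (the full suite runs in ≈ 5 minutes).

Fitting observed logs: the hidden rule sequence is reconstructed from the
feedback stream and the deterministic protocol schedule, validating every
trial's feedback against the reconstructed rule (an inconsistency aborts
with a diagnostic naming the trial). Trajectories for an individual are
reconstructed at the posterior mean.

## Synthetic-data generators

`run_factorial` reproduces the clinical-scoring study design: flexibility
λ ∈ {0.3, 0.5, 0.7, 0.9} crossed with information loss δ ∈ {0.4, 0.7,
0.9}, 150 agents per cell, 128-trial protocol. `run_info_dynamics` sweeps
the 3 × 3 grid λ, δ ∈ {0.1, 0.5, 0.9} with full per-trial information
series. `synthetic_cohort` draws per-individual parameters from group
specs (used for the two-cluster flexibility-separation check). One master
seed spawns per-agent substreams (`numpy` SeedSequence), so every study
replays bit-identically and parallelises trivially.

These generators emulate idealised task administration: deterministic
feedback, no omissions or reaction times, stationary parameters within a
session, and (by default) no response lapses. Passing tests therefore
demonstrate internal consistency of simulator, scorer and estimator under
the model's own assumptions — not that the model captures every feature of
human WCST data.

## Known discrepancies with previously reported results

Reference values reported in the literature for this model family (cohort
means of E/PE/TFC/FMS on the same factorial design, and recovery RMSE/R²
obtained with an amortised neural estimator) are **not** reproduced by
this implementation, and the acceptance checks that compare against them
fail by design rather than being weakened:

- Under the literal activation recursion, cohort means differ widely from
  the reference table (e.g. non-perseverative errors ≈ 45 vs ≈ 9 at
  λ = 0.3, δ = 0.4; trials-to-first-category ≈ 124 vs ≈ 17 at λ = 0.3,
  δ = 0.9), and the reference orderings (PE decreasing in λ at every δ;
  FMS and TFC increasing in δ) do not all hold.
- A systematic search over ≈ 600 readings of the ambiguous parts of the
  recursion (signal gating; what happens to components receiving no update
  term; both orientations of the stability matrix, including a
  renormalised destination-indexed variant; floor levels; one-shot vs
  repeated λ-damping; consecutive vs cumulative category counting; several
  success-branch update forms) found no variant matching the reference
  table's joint pattern. Structural analysis indicates the reference
  values require a δ-graded steady-state slip rate and an old-rule-biased
  post-change choice asymmetry that the printed recursion cannot produce:
  its success branch has fixed point ω = 1 (no slip plateau) and its
  hard-zero likelihood removes the superseded rule from the posterior in
  one trial (no asymmetry).
- Consistently, parameter recovery here is better for δ (RMSE ≈ 0.07,
  R² ≈ 0.93) and worse for λ (RMSE ≈ 0.20, R² ≈ 0.53) than the reference
  values (0.094/0.895 for λ, 0.155/0.708 for δ), because in the literal
  dynamics δ dominates observable behaviour. The reference caveat that δ
  recovers worst in its low range is likewise inverted here.

The package therefore documents its dynamics precisely, implements the
recursion literally (with the alternative gating behind a switch), and
reports its own measured validation numbers.

## Limitations

- Only the three-dimensional, four-level card space and deterministic
  feedback of the classical task; no probabilistic-feedback variants.
- The exact likelihood assumes the fitted protocol (rule order, run
  length) matches the administered one; mismatches surface as feedback
  inconsistencies during rule reconstruction.
- Stationary (λ, δ) within a session; no learning-to-learn across
  categories.
- Grid estimation is exact only up to the 0.01 node spacing; posteriors
  sharper than a node or two (δ near 0) are summarised conservatively.
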