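# cardsort

Bayesian cognitive-agent modelling of the **Wisconsin Card Sorting Test
(WCST)** — a generative simulator of trial-by-trial belief updating over
hidden sorting rules, information-theoretic reconstruction of cognitive
dynamics, Heaton-style clinical scoring, and exact-likelihood Bayesian
estimation of the agent's two cognitive parameters.

It is aimed at computational cognitive scientists and neuropsychologists
who want to go beyond summary scores (perseverative errors, trials to first
category, …) and recover *latent* quantities — belief updating, surprise,
uncertainty — from card-sorting behaviour, either simulated or observed.

## The model

In the WCST a target card must be matched to one of four stimulus cards by
a hidden rule s_t ∈ {color, shape, number} that changes silently after 10
consecutive correct responses. The agent maintains a distribution over
rules and updates it each trial from its observation x_t = (a_t, f_t)
(chosen card, binary feedback):

- **Bayes step** — p(s_t | x_{0:t}) ∝ p(x_t | s_t) · p(s_t | x_{0:t−1}),
  with a likelihood built from the feature-match indicators of the chosen
  card (positive feedback spreads mass over matching features, negative
  over non-matching ones).
- **Activation dynamics** — a matching signal m_t (the match vector gated
  by feedback) drives state activations
  ω_t = f·ω_{t−1}^δ⊙m_t + λ·[(1−f)·ω_{t−1}^δ⊙(1−m_t)]⊙ω_{t−1},
  clamped below at 10⁻⁶. **λ ∈ [0,1]** (*flexibility*) sets how
  efficiently attention disengages after negative feedback; **δ ∈ [0,1]**
  (*information loss*) damps the evidence carried by the matching signal.
- **Prediction** — a row-stochastic stability matrix Γ(t) with diag Γ = ω_t
  and off-diagonals (1−ω_i)/2 propagates the posterior through the
  Chapman–Kolmogorov equation to the next trial's predictive distribution,
  from which the next response is sampled.

Each trial yields three information-theoretic measures (nats): **Bayesian
surprise** B_t = KL[p(s_{t+1}|x_{0:t}) ‖ p(s_t|x_{0:t−1})], **Shannon
surprise** I_t = −log p(x_t|x_{0:t−1}), and **predictive entropy** H_t.

Because the belief recursion conditioned on observed (a_t, f_t) is
deterministic, the model has an *exact* trial-wise action likelihood; the
joint posterior over θ = (λ, δ) under a uniform prior on [0,1]² is
evaluated on a dense grid — no simulation-based approximation needed.

## Worked example

```bash
cardsort simulate --lambda 0.9 --delta 0.4 --trials 128 --seed 1 --out session.csv
cardsort score session.csv
```

```json
{
  "total_errors": 57,
  "perseverative_errors": 18,
  "nonperseverative_errors": 39,
  "trials_to_first_category": 11,
  "tfc_censored": false,
  "failures_to_maintain_set": 0,
  "categories_completed": 4
}
```

This flexible but moderately lossy agent (λ=0.9, δ=0.4) finds the first
rule in 11 trials (10 is the minimum) and completes 4 categories; its 57
errors split into 18 perseverative (clinging to a superseded rule) and 39
other errors. Fitting the parameters back from the log and reconstructing
the latent dynamics:

```python
from cardsort import fit_observed

posterior, trajectory = fit_observed("session.csv")
print(posterior.summary())
```

```
lam:   mean 0.806, 95% CI [0.513, 0.965]
delta: mean 0.374, 95% CI [0.292, 0.430]
```

The posterior mean (0.81, 0.37) recovers the generating values (0.9, 0.4)
within the credible intervals; `trajectory.to_frame()` holds the per-trial
surprise and entropy series (e.g. H_1 = ln 3 ≈ 1.0986 before any evidence,
collapsing as the agent locks onto a rule). `cardsort fit`, `recover`,
`table2` and `dynamics` expose the same machinery from the shell.

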