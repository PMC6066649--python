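# aglkit

A reusable analysis pipeline for visual artificial-grammar-learning (AGL)
experiments with two-alternative forced-choice (same/different) responses.
It bundles:

- **Grammars** (`aglkit.grammars`) — executable recognizers and generators
  over a two-category (A/B) tile alphabet at three formal-language levels:
  the regular `ABnA` grammar, the context-free `Mirror` grammar (nested
  dependencies, W·Wᴿ), and the mildly context-sensitive `Copy` grammar
  (crossed dependencies, W·W), plus heuristic candidate strategies
  (`AEdgeStar`, `AEdgePlus`, `BFirst`) in an open registry.
- **Stimulus batteries** (`aglkit.battery`) — 30-item exposure sets and the
  87-item per-grammar test battery (correct items at trained lengths,
  N = 4 / N = 6 generalization items, missing-element foils and
  mismatched-element foils), with tile identities sampled without
  replacement and presentation-timing metadata (166 ms onsets, 20×20 px
  elements, 16×20 px center markers).
- **Consistency coding** (`aglkit.consistency`) — per-trial consistency of
  responses with each candidate grammar, and exact-binomial individual
  success criteria (e.g. 12 of 15 correct, one-sided tail p ≈ 0.02).
- **Synthetic cohorts** (`aglkit.simulate`) — participants with logit-normal
  latent propensities, optionally correlated across the three grammar
  sessions, plus lapses and per-participant strategy overrides.
- **Bayesian multilevel models** (`aglkit.glmm`, `aglkit.multiresponse`) —
  Bernoulli GLMMs with participant random intercepts, residual variance
  fixed at 1 and a custom vectorized Metropolis-within-Gibbs sampler
  (interweaved translation moves, slice-sampled variance, conjugate
  inverse-Wishart covariance update in the multi-response model). Chains
  auto-extend until every intercept term reaches an effective-sample-size
  floor (default 1000, no thinning).
- **Posterior summaries** (`aglkit.posterior`) — rescaling to the
  zero-residual-variance scale (c = 16√3/(15π)), HPD intervals, posterior
  mean success probabilities, p_MCMC, log odds ratios vs alternative
  grammars (group and per-participant), latent-logistic ICC, and
  cross-grammar correlations.
- **Classical endpoints** (`aglkit.classical`) — rank-based
  grammatical-vs-foil comparisons with Cohen's d, Kruskal–Wallis session
  order and string-length effects with Bonferroni-corrected post-hocs.

## CLI

```sh
agl generate-battery --grammar Copy --seed 1 --out-dir batteries
agl simulate --battery-dir batteries --seed 2 --out trials.csv
agl code --trials trials.csv --battery-dir batteries --out consistency.csv
agl fit --consistency consistency.csv --session Copy --candidate Copy --seed 3
agl compare --consistency consistency.csv --session Copy
agl report --trials trials.csv --battery-dir batteries
agl run-all --config config.yaml --out-dir run1
```

`run-all` executes battery construction → simulation (or ingest) → coding →
per-candidate GLMM fits → model-selection tables → classical report, writes
the resolved YAML config plus its hash next to the outputs, and is
byte-reproducible under identical config + seed.

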