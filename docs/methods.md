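# Methods

## Model

The package treats discourse comprehension as online temporal-to-spatial
integration. Word meanings are points in a d-dimensional embedding space
(d = 100 by default). As a discourse unfolds, its words are integrated into
a single context vector, and the predicted N400 amplitude for a target word
is `1 − cos(context, target)`. The value is reported raw — no clamping,
z-scoring or rescaling — so 0 means a perfect semantic fit, 1 orthogonality,
and 2 opposition.

Two interchangeable aggregators produce the context vector:

* **Average aggregator.** The arithmetic mean of all embeddings fed so far.
  Order-blind and exact; serves as the baseline and as the training target
  for the reservoir.
* **Discourse Reservoir.** A leaky echo-state network with fixed random
  input weights `W_in`, fixed random recurrent weights `W_rec` rescaled to a
  chosen spectral radius, unit biases `b`, and state update

  ```
  x' = (1 − a)·x + a·tanh(W_in·u + W_rec·x + b)
  ```

  with leak rate `a`. Only a linear readout `W_out` is learned, by ridge
  regression of reservoir states onto the running average of the input
  sequence: for the k-th token of a document the target is
  `avg(w_1 … w_k)`, current token included. Both the reservoir state and
  the running-average target are reset at every document boundary, because
  a running average across unrelated documents is not a meaningful
  discourse representation. After training, the readout of the current
  state is an online discourse embedding that is updated by a single
  network step per word — no retrieval or replay — which is what makes the
  model an account of semantic immediacy.

Leaky integration is applied *after* the nonlinearity, the standard
echo-state convention.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_units` | 100 | reservoir size; matches the embedding dimensionality |
| `leak_rate` | 0.2 | fraction of the distance to the instantaneous activation covered per word; smaller = longer memory |
| `ridge_penalty` | 1e−2 | L2 penalty of the readout regression |
| `spectral_radius` | 0.95 | largest \|eigenvalue\| of `W_rec` after rescaling; < 1 keeps dynamics contractive |
| `input_scaling` | 1.0 | multiplier on uniform(−1, 1) input weights |
| `bias_scaling` | 0.1 | multiplier on uniform(−1, 1) unit biases; small, so the zero state maps near zero |
| `recurrent_density` | 1.0 | fraction of nonzero recurrent weights |
| `washout` | 0 | initial per-document tokens excluded from training; 0 because early positions (1–10) are exactly the region of interest |
| `feedback` | False | no output-to-reservoir feedback; fixed |

The readout regresses from the reservoir state alone (`state_dim =
n_units`); concatenating the raw input to the state was considered and left
out as the minimal design. Input embeddings are fed raw (not length
normalized); cosine is scale-free, and the synthetic space is unit-norm by
construction anyway. The training solver is the closed-form ridge solution
`(SᵀS + λI)⁻¹SᵀT` (with an `lstsq` fallback for λ = 0 on rank-deficient
designs); any regularized least-squares solver would do, and the unit tests
pin the result to the closed form at 1e−8 relative error.

## Synthetic semantic space and streams

Because pretrained embedding dumps and the original stimulus corpora are
not distributable with the package, a synthetic generator stands in for
them:

* **Space.** `n_clusters` unit-norm cluster centers drawn isotropically;
  each word is `normalize(center + ε)`, where ε has expected norm
  `within_cluster_noise` (per-component std `noise/√d`). With the default
  noise 0.3, mean within-cluster cosine is ≈ 1/(1 + 0.3²) ≈ 0.92 while
  between-cluster cosine is ≈ 0 in 100 dimensions. Words are named
  `c<cluster>_w<index>` so fixtures can select related/unrelated pairs by
  name.
* **Streams.** Each document picks a primary cluster and draws each token
  from it with probability `concentration/(concentration+1)` (default 0.9),
  otherwise from the whole vocabulary — a minimal model of the topical
  coherence of encyclopedia articles. The tracking study trains on 400
  documents of 80–200 tokens (≈ 5.5·10⁴ tokens) and evaluates on 60
  held-out documents of 20–60 tokens; these sizes keep a full study in a
  few seconds while exceeding the scale at which the tracking curve
  saturates.

What the generator does *not* emulate: Zipfian word frequencies, syntax and
word order, polysemy, graded (non-cluster) similarity structure, stop-word
distributions. Passing tests on synthetic data therefore demonstrate that
the machinery — reservoir tracking, linking hypothesis, experiment
harnesses, statistics — behaves correctly when the semantic geometry is as
constructed; they do not certify effect sizes on natural text, which
require a corpus-trained embedding model supplied by the user.

## Experiments

* **Priming.** Context = the prime word itself; one N400 per pair. The
  synthetic stimulus set draws 40 same-cluster and 40 cross-cluster pairs
  (construction gap in the means ≈ 0.9, comfortably above the 0.3 the tests
  require). Matched 1:1 lists are compared by paired t across pair index,
  unmatched lists by two-sample t.
* **Discourse overrule.** The fixture builds a discourse
  `[noun, body…, noun]` whose body comes from a different cluster than the
  opening/closing critical noun. The *opposed* target shares the noun's
  cluster (locally plausible), the *aligned* target the body's cluster
  (contextually appropriate). "Beginning" is the predicted N400 at the
  first content token (after the neutral prime if one is configured),
  "End" at the last token. Across a 50-seed reservoir pool the harness
  reports per-subject reversal (aligned > opposed at Beginning AND aligned
  < opposed at End) and a 2×2 within-subject ANOVA.
* **Scenario rescue.** Each synthetic scenario takes context sentences from
  an *event* cluster, the final-sentence stem from a different cluster, an
  unexpected-related completion from the event cluster, an
  unexpected-unrelated completion from a third cluster, and an *expected*
  completion injected into the table near the mean of the full discourse
  (perturbed by `expected_noise = 0.15` before renormalization) so that it
  is the best completion with or without context. Sentence mode aggregates
  the stem only; discourse mode aggregates context sentences + stem in one
  pass with no resets between sentences. The rescue statistic is
  (unexpected_unrelated − unexpected_related) per unit and mode, compared
  across modes by paired t.

Subject seeds parameterize only reservoir initialization; the space, the
training stream and the stimuli carry their own independent seeds, so pool
variability isolates the network's random wiring, as in a between-subject
wiring analogy.

Text preprocessing lowercases, strips punctuation, removes a frozen
packaged stop-word list (function words; the SHA-1 of the list is recorded
in every run manifest), drops out-of-vocabulary tokens with a logged count,
optionally truncates at the last occurrence of a designated word, and
optionally prepends a neutral prime word. The default prime, when enabled,
is "thing" — concrete, semantically bland, and in ordinary vocabularies;
results at the earliest discourse positions are somewhat sensitive to this
choice, which is why it is off by default and configurable.

## Statistics

`paired_t` is the standard two-sided paired t (df = n − 1); numerically
zero difference vectors are flagged degenerate (t = 0, p = 1) instead of
raising, so constructed noise-free fixtures pass through cleanly.

`rm_anova` implements the fully-within-subject two-factor partition

```
SS_total = SS_subject + SS_A + SS_A×S + SS_B + SS_B×S + SS_AB + SS_AB×S
```

with each effect tested against its own effect-by-subject interaction and
no sphericity correction. For a 2×2 design with n subjects every effect has
df (1, n−1); for 2×3 the three-level factor and the interaction have
(2, 2(n−1)). A zero error mean square yields F = ∞ (or 0 when the effect is
also zero) with a degenerate flag. Post-hoc contrasts are unadjusted paired
t tests with a Bonferroni column provided alongside. The implementation is
cross-checked in the test suite against statsmodels' `AnovaRM`, an explicit
nested-loop sums-of-squares oracle, and one hand-worked 3-subject example
whose F values are exact rationals (289, 9, 3/7).

When an experiment is run with a deterministic aggregator (the average, or
a single reservoir), there is no subject sample; the scenario harness then
uses the stimulus items as the error-carrying random factor instead of
seeds.

## Numerical choices and edge cases

* Embedding tables refuse zero vectors (cosine undefined) and enforce one
  dimensionality; lookups are lowercase-normalized.
* `cosine` raises on zero vectors and mismatched lengths rather than
  returning NaN.
* Spectral-radius rescaling divides by the computed largest |eigenvalue|;
  a zero radius (possible only for degenerate density settings) is an
  error.
* Tracking curves omit positions supported by fewer than 5 held-out
  documents, so tail positions never rest on one or two documents.
* All generators are `numpy.random.default_rng(seed)`-driven and
  bit-reproducible; model weights are a pure function of (config, dims),
  which is also how serialized models are reloaded (the archive stores the
  config and the trained readout, and regenerates the fixed weights).

## Known limitations

* The reservoir readout approximates, never equals, the running average:
  the equal weighting 1/k of all past tokens is not exactly representable
  by a fading-memory linear readout. Tracking cosines of ≈ 0.94 at position
  1 and ≈ 0.99 at position 10 on clustered synthetic streams are typical.
* The synthetic space's cluster geometry makes condition contrasts larger
  than those obtainable with corpus-trained embeddings; statistics on
  synthetic fixtures demonstrate machinery, not natural-language effect
  sizes.
* Echo-state hyperparameters beyond units/leak/ridge (spectral radius,
  input scaling, bias, density, washout) are package defaults chosen for
  reproducibility and recorded in every manifest; alternative choices are
  exposed in `ReservoirConfig`.
* Multi-word targets are represented by their head content word; there is
  no sentence segmentation, lemmatization or parsing.
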