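# discourse-n400

Reservoir-computing simulations of discourse-modulated N400 amplitudes.

## The problem

The N400 is a scalp-recorded ERP component that grows when an incoming word
fits its semantic context poorly. Two classic phenomena constrain any model
of it:

* **Semantic priming** — a word preceded by a related word ("vein … blood")
  elicits a smaller N400 than one preceded by an unrelated word.
* **Discourse overrule** — prior discourse can reverse the pattern expected
  from local lexical semantics: after a story in which a peanut sings and
  dances, "the peanut was *salted*" elicits the N400 and "the peanut was
  *in love*" does not. Likewise, an unexpected sentence completion is
  *rescued* (reduced N400) when it is related to the event described by the
  preceding discourse, and only then.

Both effects are *immediate*: discourse information influences the very next
word with no retrieval delay. This package models that immediacy as
temporal-to-spatial integration. Word meaning lives in a distributed
embedding space; the ongoing discourse is integrated word by word into a
single context vector; and the predicted N400 for a target word *t* given
context vector *c* is the linking hypothesis

```
N400(c, t) = 1 − cos(c, t)        ∈ [0, 2]
```

The discourse context is computed two ways:

* **Bag-of-words average** — the arithmetic mean of the embeddings seen so
  far (order-blind baseline).
* **Discourse Reservoir** — a leaky echo-state network (100 units, leak rate
  a = 0.2, spectral radius 0.95, fixed random recurrent weights) whose
  state update is `x' = (1 − a)·x + a·tanh(W_in·u + W_rec·x + b)` and whose
  ridge-regression readout (penalty 1e−2) is trained to emit the running
  average avg(w₁…w_k) of its input sequence. The fading-memory state makes
  the accumulated discourse available instantaneously at every word — a
  neurophysiologically motivated implementation of the same aggregation.

A pool of reservoirs with different initialization seeds plays the role of
an experimental subject sample; within-subject statistics (paired *t*,
two-factor repeated-measures ANOVA with effect-by-subject error terms) are
computed over the pool.

Everything runs on either a pretrained embedding file in word2vec text
format or on a built-in synthetic clustered semantic space, so all
experiments and tests execute with no downloads.

## Worked example

Train the reservoir on a synthetic stream, check how well it tracks the
running average on held-out documents, then run the discourse-overrule
simulation with a 50-reservoir subject pool:

```python
from discourse_n400 import (
    SyntheticSpaceSpec, generate_synthetic_space, generate_training_stream,
    ReservoirConfig, train_discourse_reservoir, SubjectPool,
    make_overrule_fixture, run_peanut,
)

space = generate_synthetic_space(SyntheticSpaceSpec(seed=11))   # 10 clusters x 50 words, dim 100
stream = generate_training_stream(space, n_docs=200, doc_len_range=(50, 150), seed=12)

model = train_discourse_reservoir(space, stream, ReservoirConfig(seed=0))
held = generate_training_stream(space, n_docs=50, doc_len_range=(20, 60), seed=13)
for pos, cos in model.tracking_curve(held, space, max_position=10):
    if pos in (1, 5, 10):
        print(f"position {pos:2d}: mean cosine {cos:.3f}")

pool = SubjectPool(seeds=tuple(range(50)))
subjects = pool.train(space, stream)
fix = make_overrule_fixture(space, seed=7)
res = run_peanut(space, list(fix.tokens),
                 targets=(fix.opposed_target, fix.aligned_target), subjects=subjects)
for cond, mean in sorted(res.condition_means.items()):
    print(f"{cond}: {mean:.3f}")
print(f"reversal: {res.stats['n_reversed']}/{res.stats['n_subjects']} subjects")
print(res.stats["anova"].summary())
```

prints

```
position  1: mean cosine 0.941
position  5: mean cosine 0.980
position 10: mean cosine 0.991
beginning:aligned: 0.928
beginning:opposed: 0.075
end:aligned: 0.055
end:opposed: 0.723
reversal: 50/50 subjects
Repeated-measures ANOVA (50 subjects)
------------------------------------------------
discourse_position F(1, 49) =   624.5183   p = 1.53e-29
target         F(1, 49) =   415.5322   p = 1.4e-25
discourse_position:target F(1, 49) = 46811.0362   p = 1.07e-74
```

Reading the output: the trained readout reproduces the running-average
discourse vector increasingly well as a document unfolds (cosine 0.98 by
word 5). In the overrule design the discourse opens and closes with a
critical noun whose cluster matches the *opposed* target; at the beginning
the discourse-*aligned* target therefore has the large predicted N400
(0.928 vs 0.075), and by the end of the contradicting discourse body the
pattern has reversed (0.055 vs 0.723) for every one of the 50 simulated
subjects — the position × target interaction carries the effect.

The same experiments are scriptable from the shell (`discourse-n400
make-space | make-stream | train-reservoir | eval-tracking | priming |
peanut | scenarios | make-fixtures`); every run writes TSV results plus a
YAML manifest from which it can be reproduced byte-identically.

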