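"""End-to-end simulation experiments.

Three classic N400 paradigms are reproduced over any embedding table:

* **priming** — word pairs, related vs unrelated: the one-word context of
  the prime predicts a smaller N400 for related targets.
* **discourse overrule** (the "peanut in love" design) — a discourse whose
  body contradicts the local semantics of its first/last critical noun:
  the predicted N400 for the discourse-aligned vs locally-plausible target
  reverses between the beginning and the end of the discourse.
* **event-knowledge rescue** — three-completion scenarios run with and
  without their context sentences: an unexpected-but-event-related target
  is rescued (lower N400) only when the discourse context is present.

A pool of independently initialized reservoirs plays the role of the
subject sample; within-subject statistics are computed over the pool.
Synthetic fixture generators stand in for stimulus corpora that are not
distributable, with construction margins chosen to mirror the real effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .discourse import (
    Aggregator,
    AverageAggregator,
    PreprocessSpec,
    ReservoirAggregator,
    preprocess,
)
from .n400 import discourse_target_n400, pairwise_priming_n400, predict_n400
from .reservoir import DiscourseReservoirResults, ReservoirConfig, train_discourse_reservoir
from .semantic_space import EmbeddingTable, TokenStream, cluster_of
from .stats import paired_t, posthoc_pairwise, rm_anova, two_sample_t

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "SubjectPool",
    "ExperimentResult",
    "OverruleFixture",
    "run_priming",
    "run_peanut",
    "run_scenarios",
    "generate_synthetic_scenarios",
    "generate_synthetic_pairs",
    "make_overrule_fixture",
    "run_tracking_study",
]


def run_tracking_study(
    seed: int = 0,
    dim: int = 100,
    n_clusters: int = 10,
    words_per_cluster: int = 500,
    within_cluster_noise: float = 0.3,
    n_train_docs: int = 400,
    train_doc_len: tuple[int, int] = (80, 200),
    n_heldout_docs: int = 60,
    heldout_doc_len: tuple[int, int] = (20, 60),
    topic_concentration: float = 9.0,
    config: ReservoirConfig | None = None,
    max_position: int = 12,
) -> dict:
    """Running-average tracking benchmark at full model scale.

    Builds a clustered 100-dimensional space, trains the 100-unit reservoir
    (leak 0.2, ridge 1e-2) on a topically coherent stream of >= 5e4 tokens
    with per-document running-average targets, and evaluates the mean cosine
    between readout and true running average per token position on held-out
    documents.  Sub-seeds for space, streams and reservoir are derived from
    ``seed`` so the whole study is reproducible from one integer.
    """
    from .semantic_space import SyntheticSpaceSpec, generate_synthetic_space, generate_training_stream

    space = generate_synthetic_space(
        SyntheticSpaceSpec(
            dim=dim,
            n_clusters=n_clusters,
            words_per_cluster=words_per_cluster,
            within_cluster_noise=within_cluster_noise,
            seed=seed,
        )
    )
    train = generate_training_stream(
        space, n_train_docs, train_doc_len, topic_concentration=topic_concentration, seed=seed + 1
    )
    heldout = generate_training_stream(
        space, n_heldout_docs, heldout_doc_len, topic_concentration=topic_concentration, seed=seed + 2
    )
    cfg = config or ReservoirConfig(seed=seed + 3)
    results = train_discourse_reservoir(space, train, cfg)
    curve = results.tracking_curve(heldout, space, max_position=max_position)
    return {
        "space": space,
        "train_stream": train,
        "heldout_stream": heldout,
        "results": results,
        "curve": dict(curve),
        "n_train_tokens": train.n_tokens,
        "n_heldout_docs": heldout.n_documents,
    }


@dataclass(frozen=True)
class Scenario:
    """A three-completion discourse item.

    ``context_sentences`` are the scene-setting sentences; the
    ``final_sentence_stem`` runs up to (excluding) the target position; the
    three completions are a locally expected word, an unexpected word related
    to the described event, and an unexpected unrelated word.
    """

    item_id: str
    context_sentences: tuple[str, ...]
    final_sentence_stem: str
    expected: str
    unexpected_related: str
    unexpected_unrelated: str

    def __post_init__(self):
        targets = {self.expected, self.unexpected_related, self.unexpected_unrelated}
        if len(targets) != 3:
            raise ValueError(f"scenario {self.item_id}: the three targets must be distinct")
        stem_words = set(self.final_sentence_stem.lower().split())
        if targets & stem_words:
            raise ValueError(f"scenario {self.item_id}: a target word appears in the stem")

    @property
    def targets(self) -> dict[str, str]:
        return {
            "expected": self.expected,
            "unexpected_related": self.unexpected_related,
            "unexpected_unrelated": self.unexpected_unrelated,
        }


@dataclass
class SubjectPool:
    """Independently initialized reservoirs acting as experimental subjects.

    Every seed builds and trains its own reservoir on the shared training
    stream; seeds must be distinct so subject variability reflects reservoir
    initialization alone.
    """

    seeds: tuple[int, ...] = tuple(range(50))
    base_config: ReservoirConfig = field(default_factory=ReservoirConfig)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("subject seeds must be distinct")

    def train(self, table: EmbeddingTable, stream: TokenStream) -> list[DiscourseReservoirResults]:
        out = []
        for s in self.seeds:
            cfg = replace(self.base_config, seed=int(s))
            out.append(train_discourse_reservoir(table, stream, cfg))
        return out


@dataclass
class ExperimentResult:
    """Long-format N400 records plus the derived summaries and tests."""

    n400_table: pd.DataFrame
    condition_means: dict
    stats: dict
    extras: dict = field(default_factory=dict)

    def recompute_condition_means(self, by: str = "condition") -> dict:
        return self.n400_table.groupby(by, observed=True)["value"].mean().to_dict()


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(values.min()),
        "max": float(values.max()),
    }


# ---------------------------------------------------------------------------
# Experiment 1: semantic priming over word pairs


def run_priming(table: EmbeddingTable, pairs, paired: bool | None = None) -> ExperimentResult:
    """Predicted-N400 priming contrast over (prime, target, condition) pairs.

    With equally many related and unrelated pairs the contrast is a paired t
    across pair index (matching the list design); otherwise a two-sample t.
    """
    df = pairwise_priming_n400(table, pairs)
    counts = df["condition"].value_counts()
    if len(counts) != 2:
        raise ValueError(f"priming needs exactly two conditions, got {list(counts.index)}")
    if (counts < 2).any():
        raise ValueError("need at least 2 retained pairs per condition")
    cond_a, cond_b = sorted(counts.index)
    xa = df.loc[df["condition"] == cond_a, "value"].to_numpy()
    xb = df.loc[df["condition"] == cond_b, "value"].to_numpy()
    if paired is None:
        paired = bool(counts[cond_a] == counts[cond_b])
    if paired:
        if counts[cond_a] != counts[cond_b]:
            raise ValueError("paired test requested but the conditions are not matched 1:1")
        test = paired_t(xa, xb)
    else:
        test = two_sample_t(xa, xb)
    means = {cond_a: float(xa.mean()), cond_b: float(xb.mean())}
    return ExperimentResult(
        n400_table=df,
        condition_means=means,
        stats={"t_test": test, "paired": paired},
        extras={"box_stats": {cond_a: _box_stats(xa), cond_b: _box_stats(xb)}},
    )


def generate_synthetic_pairs(
    table: EmbeddingTable, n_per_condition: int = 40, seed: int = 0
) -> list[tuple[str, str, str]]:
    """Related (same-cluster) and unrelated (cross-cluster) word pairs.

    Words are drawn without replacement from a cluster-labeled synthetic
    space, so the related/unrelated cosine gap is the space's own
    within/between gap.
    """
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for w in table.words():
        try:
            by_cluster.setdefault(cluster_of(w), []).append(w)
        except ValueError:
            continue
    clusters = sorted(by_cluster)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for unrelated pairs")
    pairs: list[tuple[str, str, str]] = []
    used: set[str] = set()

    def draw(cluster: int) -> str:
        candidates = [w for w in by_cluster[cluster] if w not in used]
        if not candidates:
            raise ValueError(f"cluster {cluster} exhausted; use a larger space")
        w = candidates[rng.integers(len(candidates))]
        used.add(w)
        return w

    for _ in range(n_per_condition):
        c = clusters[rng.integers(len(clusters))]
        pairs.append((draw(c), draw(c), "related"))
    for _ in range(n_per_condition):
        c1, c2 = rng.choice(clusters, size=2, replace=False)
        pairs.append((draw(int(c1)), draw(int(c2)), "unrelated"))
    return pairs


# ---------------------------------------------------------------------------
# Experiment 2: discourse overrule ("peanut in love" design)


@dataclass(frozen=True)
class OverruleFixture:
    """Synthetic analog of the peanut discourse.

    The critical noun opens and closes the discourse; the body comes from a
    different cluster, so the context drifts away from the noun's local
    semantics.  The ``opposed`` target shares the noun's cluster (locally
    plausible, like "salted"); the ``aligned`` target shares the body's
    cluster (contextually appropriate, like "love").
    """

    tokens: tuple[str, ...]
    critical_noun: str
    aligned_target: str
    opposed_target: str


def make_overrule_fixture(
    table: EmbeddingTable, seed: int = 0, body_length: int = 20
) -> OverruleFixture:
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for w in table.words():
        try:
            by_cluster.setdefault(cluster_of(w), []).append(w)
        except ValueError:
            continue
    clusters = sorted(by_cluster)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    c_noun, c_body = rng.choice(clusters, size=2, replace=False)
    noun_words = by_cluster[int(c_noun)]
    body_words = by_cluster[int(c_body)]
    if len(noun_words) < 2 or len(body_words) < body_length + 1:
        raise ValueError("clusters too small for the requested fixture")
    noun, opposed = (str(w) for w in rng.choice(noun_words, size=2, replace=False))
    chosen = [str(w) for w in rng.choice(body_words, size=body_length + 1, replace=False)]
    aligned, body = chosen[0], chosen[1:]
    tokens = (noun, *body, noun)
    return OverruleFixture(
        tokens=tokens, critical_noun=noun, aligned_target=aligned, opposed_target=opposed
    )


def _resolve_tokens(discourse, spec: PreprocessSpec, table: EmbeddingTable):
    """Accept either a raw text (preprocessed) or an explicit token list."""
    if isinstance(discourse, str):
        report = preprocess(discourse, spec, table)
        primed = spec.neutral_prime_word is not None
        return report.tokens, primed
    return list(discourse), False


def run_peanut(
    table: EmbeddingTable,
    discourse,
    targets: tuple[str, str],
    subjects: list[DiscourseReservoirResults] | None = None,
    aggregator: str = "reservoir",
    preprocess_spec: PreprocessSpec | None = None,
    target_labels: tuple[str, str] = ("opposed", "aligned"),
) -> ExperimentResult:
    """Word-by-word N400 trajectories for two targets over one discourse.

    ``targets`` is (locally-plausible word, discourse-aligned word) — the
    "salted"/"love" roles.  Beginning is the N400 at the discourse's first
    content token (after the neutral prime, if any), End at its last token.
    With a reservoir subject pool a 2x2 within-subject ANOVA
    (discourse_position x target) and the per-subject reversal indicator
    (aligned > opposed at Beginning AND aligned < opposed at End) are
    computed.
    """
    spec = preprocess_spec or PreprocessSpec()
    tokens, primed = _resolve_tokens(discourse, spec, table)
    for t in targets:
        if t not in table:
            raise ValueError(f"target {t!r} is not in the embedding table")
    opposed_word, aligned_word = targets
    label_of = {opposed_word: target_labels[0], aligned_word: target_labels[1]}
    begin_pos = 2 if primed else 1
    end_pos = len(tokens)
    if aggregator == "average":
        subject_aggs = [("avg", AverageAggregator(table.dim))]
    elif aggregator == "reservoir":
        if not subjects:
            raise ValueError("reservoir aggregation requires a trained subject pool")
        subject_aggs = [(f"seed{r.config.seed}", ReservoirAggregator(r)) for r in subjects]
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")

    traj_frames = []
    records = []
    n_reversed = 0
    for sid, agg in subject_aggs:
        traj = discourse_target_n400(agg, tokens, list(targets), table)
        traj.insert(0, "subject_id", sid)
        traj_frames.append(traj)
        by_target = {
            t: traj[traj["target"] == t].set_index("position")["value"] for t in targets
        }
        for t in targets:
            for pos_label, pos in (("beginning", begin_pos), ("end", end_pos)):
                records.append(
                    {
                        "subject_id": sid,
                        "item_id": "discourse",
                        "discourse_position": pos_label,
                        "target": label_of[t],
                        "target_word": t,
                        "value": float(by_target[t].loc[pos]),
                    }
                )
        reversed_ = (
            by_target[aligned_word].loc[begin_pos] > by_target[opposed_word].loc[begin_pos]
            and by_target[aligned_word].loc[end_pos] < by_target[opposed_word].loc[end_pos]
        )
        n_reversed += bool(reversed_)

    cell_table = pd.DataFrame.from_records(records)
    means = (
        cell_table.groupby(["discourse_position", "target"], observed=True)["value"]
        .mean()
        .to_dict()
    )
    stats: dict = {"n_subjects": len(subject_aggs), "n_reversed": n_reversed}
    if len(subject_aggs) >= 2:
        stats["anova"] = rm_anova(
            cell_table, value="value", subject="subject_id", a="discourse_position", b="target"
        )
    return ExperimentResult(
        n400_table=cell_table,
        condition_means={f"{k[0]}:{k[1]}": v for k, v in means.items()},
        stats=stats,
        extras={
            "trajectories": pd.concat(traj_frames, ignore_index=True),
            "tokens": tokens,
            "begin_position": begin_pos,
            "end_position": end_pos,
        },
    )


# ---------------------------------------------------------------------------
# Experiment 3: event-knowledge rescue over three-completion scenarios

CONDITIONS = ("expected", "unexpected_related", "unexpected_unrelated")


def _scenario_context_vector(agg: Aggregator, scenario: Scenario, mode: str,
                             spec: PreprocessSpec, table: EmbeddingTable) -> np.ndarray:
    """Aggregate over the stem alone (sentence mode) or the whole discourse
    (context sentences + stem, one pass, no reset between sentences)."""
    if mode == "sentence":
        text = scenario.final_sentence_stem
    elif mode == "discourse":
        text = " ".join((*scenario.context_sentences, scenario.final_sentence_stem))
    else:
        raise ValueError(f"unknown context mode {mode!r}")
    report = preprocess(text, spec, table)
    agg.reset()
    for tok in report.tokens:
        agg.feed(table[tok])
    return np.asarray(agg.current(), dtype=float)


def run_scenarios(
    table: EmbeddingTable,
    scenarios: list[Scenario],
    subjects: list[DiscourseReservoirResults] | None = None,
    aggregator: str = "reservoir",
    context_modes: tuple[str, ...] = ("sentence", "discourse"),
    preprocess_spec: PreprocessSpec | None = None,
) -> ExperimentResult:
    """N400 for the three completions with and without discourse context.

    For every scenario x subject x context mode, the aggregate at the end of
    the final-sentence stem is compared with each completion.  When both
    context modes are run, a 2x3 within-subject ANOVA (context x relatedness)
    is computed over per-unit cell means, together with all pairwise
    post-hoc contrasts and the rescue difference
    (unexpected_unrelated - unexpected_related) compared across modes by
    paired t.  The error-carrying unit is the reservoir seed when a pool of
    >= 2 subjects is supplied, and the scenario item otherwise.
    """
    spec = preprocess_spec or PreprocessSpec()
    if aggregator == "average":
        subject_aggs = [("avg", AverageAggregator(table.dim))]
    elif aggregator == "reservoir":
        if not subjects:
            raise ValueError("reservoir aggregation requires a trained subject pool")
        subject_aggs = [(f"seed{r.config.seed}", ReservoirAggregator(r)) for r in subjects]
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")

    records = []
    kept, dropped = [], []
    for sc in scenarios:
        if any(t not in table for t in sc.targets.values()):
            dropped.append(sc.item_id)
            continue
        kept.append(sc)
    if dropped:
        logger.warning("dropped %d scenarios with out-of-vocabulary targets: %s", len(dropped), dropped)
    if not kept:
        raise ValueError("no scenario has all three targets in the table")

    for sid, agg in subject_aggs:
        for sc in kept:
            for mode in context_modes:
                ctx = _scenario_context_vector(agg, sc, mode, spec, table)
                for cond, word in sc.targets.items():
                    records.append(
                        {
                            "subject_id": sid,
                            "item_id": sc.item_id,
                            "context": mode,
                            "condition": cond,
                            "target": word,
                            "value": predict_n400(ctx, table[word]),
                        }
                    )
    long = pd.DataFrame.from_records(records)
    means = long.groupby(["context", "condition"], observed=True)["value"].mean()
    result_stats: dict = {"n_scenarios": len(kept)}
    extras: dict = {}
    # error-carrying unit: seeds if a real pool, else scenario items
    unit = "subject_id" if len(subject_aggs) >= 2 else "item_id"
    cells = (
        long.groupby([unit, "context", "condition"], observed=True)["value"].mean().reset_index()
    )
    if len(context_modes) == 2 and cells[unit].nunique() >= 2:
        result_stats["anova"] = rm_anova(
            cells, value="value", subject=unit, a="context", b="condition"
        )
        result_stats["posthoc"] = posthoc_pairwise(
            cells, within="condition", value="value", subject=unit, conditioning="context"
        )
        wide = cells.pivot_table(index=unit, columns=["context", "condition"], values="value")
        rescue = {
            mode: (
                wide[(mode, "unexpected_unrelated")] - wide[(mode, "unexpected_related")]
            ).to_numpy()
            for mode in context_modes
        }
        result_stats["rescue_t"] = paired_t(rescue["discourse"], rescue["sentence"])
        extras["rescue_difference_means"] = {m: float(v.mean()) for m, v in rescue.items()}
    return ExperimentResult(
        n400_table=long,
        condition_means={f"{k[0]}:{k[1]}": float(v) for k, v in means.items()},
        stats=result_stats,
        extras={**extras, "unit": unit, "cell_means_by_unit": cells},
    )


def generate_synthetic_scenarios(
    table: EmbeddingTable,
    n_items: int,
    seed: int = 0,
    context_sentence_len: int = 8,
    n_context_sentences: int = 2,
    stem_len: int = 6,
    expected_noise: float = 0.15,
) -> list[Scenario]:
    """Build three-completion scenarios from a cluster-labeled space.

    Per item an *event* cluster supplies the context sentences, a different
    *stem* cluster supplies the final-sentence stem, and a third cluster the
    unrelated completion.  The expected completion is a new word injected
    into the table whose vector sits near the mean of the full discourse
    (context + stem, perturbed by ``expected_noise`` before renormalization),
    so it is the best fit with or without context; the unexpected-related
    completion is an unused event-cluster word, which only the discourse
    context can rescue.  Adds the injected expected words to ``table``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for w in table.words():
        try:
            by_cluster.setdefault(cluster_of(w), []).append(w)
        except ValueError:
            continue
    clusters = sorted(by_cluster)
    if len(clusters) < 3:
        raise ValueError("need at least three clusters (event, stem, unrelated)")
    # context/stem tokens may recur across items (ordinary vocabulary), but
    # target words are globally unique so every item contributes 3 distinct
    # completions
    used_targets: set[str] = set()

    def draw_tokens(cluster: int, k: int) -> list[str]:
        pool = by_cluster[cluster]
        if len(pool) < k:
            raise ValueError(f"cluster {cluster} has fewer than {k} words")
        return [str(w) for w in rng.choice(pool, size=k, replace=False)]

    def draw_target(cluster: int, exclude: set[str]) -> str:
        candidates = [w for w in by_cluster[cluster] if w not in used_targets and w not in exclude]
        if not candidates:
            raise ValueError(f"cluster {cluster} exhausted; use a larger space or fewer items")
        w = str(candidates[rng.integers(len(candidates))])
        used_targets.add(w)
        return w

    scenarios = []
    for i in range(n_items):
        c_event, c_stem, c_far = rng.choice(clusters, size=3, replace=False)
        ctx_tokens = [
            draw_tokens(int(c_event), context_sentence_len) for _ in range(n_context_sentences)
        ]
        stem_tokens = draw_tokens(int(c_stem), stem_len)
        item_words = {t for sent in ctx_tokens for t in sent} | set(stem_tokens)
        related = draw_target(int(c_event), exclude=item_words)
        unrelated = draw_target(int(c_far), exclude=item_words)
        all_tokens = [t for sent in ctx_tokens for t in sent] + stem_tokens
        mix = table.vectors(all_tokens).mean(axis=0)
        mix = mix / np.linalg.norm(mix)
        noise = expected_noise / np.sqrt(table.dim) * rng.standard_normal(table.dim)
        expected_vec = mix + noise
        expected_vec /= np.linalg.norm(expected_vec)
        expected = f"item{i}_expected"
        table.add(expected, expected_vec)
        scenarios.append(
            Scenario(
                item_id=f"item{i}",
                context_sentences=tuple(" ".join(s) for s in ctx_tokens),
                final_sentence_stem=" ".join(stem_tokens),
                expected=expected,
                unexpected_related=related,
                unexpected_unrelated=unrelated,
            )
        )
    return scenarios
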