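"""Discourse preprocessing and the two context-aggregation strategies.

A discourse context vector can be formed either as the plain arithmetic mean
of the word embeddings seen so far (order-blind bag of words) or as the
readout of a trained Discourse Reservoir fed the same words one at a time
(order-sensitive, neurophysiologically motivated).  Both hide behind the same
stateful feed/current interface so experiments can swap them freely.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .reservoir import DiscourseReservoirResults
from .semantic_space import EmbeddingTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_STOPWORDS",
    "PreprocessSpec",
    "PreprocessReport",
    "PreprocessingError",
    "preprocess",
    "stopword_list_hash",
    "Aggregator",
    "AverageAggregator",
    "ReservoirAggregator",
    "trajectory",
]

# Frozen English function-word list: articles, auxiliaries and copulas,
# pronouns and possessives, prepositions, conjunctions, light adverbs.
DEFAULT_STOPWORDS = frozenset(
    """
    a an the
    am is are was were be been being
    do does did done doing have has had having
    will would shall should can could may might must
    i me my mine you your yours he him his she her hers it its
    we us our ours they them their theirs this that these those
    who whom whose which what
    in on at by for from to of with without about into onto over under
    between among through during before after above below up down out off
    and or but nor so yet if then than as because while when where
    not no also just very too there here
    """.split()
)


def stopword_list_hash(stopwords=DEFAULT_STOPWORDS) -> str:
    """SHA-1 of the sorted stop-word list; recorded in run manifests."""
    blob = "\n".join(sorted(stopwords)).encode("utf-8")
    return hashlib.sha1(blob).hexdigest()


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessSpec:
    """Tokenization conventions applied to a discourse text.

    ``truncate_after_last`` cuts the token list at the final occurrence of
    the given word (used to make a critical noun the last discourse token);
    ``neutral_prime_word`` is prepended to give the reservoir an initial,
    semantically bland input before the discourse proper.
    """

    stopword_list: frozenset = DEFAULT_STOPWORDS
    lowercase: bool = True
    strip_punctuation: bool = True
    neutral_prime_word: str | None = None
    truncate_after_last: str | None = None


@dataclass
class PreprocessReport:
    tokens: list[str]
    dropped_oov: list[str] = field(default_factory=list)
    dropped_stopwords: int = 0

    @property
    def n_dropped_oov(self) -> int:
        return len(self.dropped_oov)


_WORD_RE = re.compile(r"\w+(?:'\w+)?", re.UNICODE)


def preprocess(text: str, spec: PreprocessSpec, table: EmbeddingTable) -> PreprocessReport:
    """Turn a discourse text into a validated token list.

    Lowercases, strips punctuation, removes stop-words, drops (and logs)
    out-of-vocabulary tokens, then applies truncation and the neutral prime.
    Raises PreprocessingError if nothing survives.
    """
    if not text or not text.strip():
        raise PreprocessingError("empty discourse text")
    if spec.lowercase:
        text = text.lower()
    if spec.strip_punctuation:
        raw = _WORD_RE.findall(text)
    else:
        raw = text.split()
    tokens: list[str] = []
    dropped_oov: list[str] = []
    n_stop = 0
    for tok in raw:
        if tok in spec.stopword_list:
            n_stop += 1
            continue
        if tok not in table:
            dropped_oov.append(tok)
            continue
        tokens.append(tok)
    if dropped_oov:
        logger.warning("dropped %d out-of-vocabulary tokens: %s", len(dropped_oov), dropped_oov)
    if spec.truncate_after_last is not None:
        word = spec.truncate_after_last.lower()
        if word in tokens:
            cut = len(tokens) - 1 - tokens[::-1].index(word)
            tokens = tokens[: cut + 1]
        else:
            raise PreprocessingError(f"truncate_after_last word {word!r} not present in tokens")
    if spec.neutral_prime_word is not None:
        prime = spec.neutral_prime_word.lower()
        if prime not in table:
            raise PreprocessingError(f"neutral prime word {prime!r} is not in the embedding table")
        tokens = [prime] + tokens
    if not tokens:
        raise PreprocessingError("no tokens survived preprocessing")
    return PreprocessReport(tokens=tokens, dropped_oov=dropped_oov, dropped_stopwords=n_stop)


class Aggregator:
    """Stateful discourse-context accumulator.

    ``feed(v)`` integrates one word vector; ``current()`` returns the context
    vector, defined only once at least one vector has been fed; ``reset()``
    restores the initial state.
    """

    kind: str

    def __init__(self):
        self.fed_count = 0

    def reset(self) -> None:
        self.fed_count = 0

    def feed(self, v: np.ndarray) -> None:
        raise NotImplementedError

    def current(self) -> np.ndarray:
        raise NotImplementedError

    def _require_fed(self):
        if self.fed_count < 1:
            raise RuntimeError("current() is undefined before any vector has been fed")


class AverageAggregator(Aggregator):
    """Bag-of-words context: the arithmetic mean of all fed vectors."""

    kind = "average"

    def __init__(self, dim: int):
        super().__init__()
        self.dim = dim
        self._sum = np.zeros(dim)

    def reset(self) -> None:
        super().reset()
        self._sum = np.zeros(self.dim)

    def feed(self, v: np.ndarray) -> None:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.dim,):
            raise ValueError(f"vector has shape {v.shape}, expected ({self.dim},)")
        self._sum += v
        self.fed_count += 1

    def current(self) -> np.ndarray:
        self._require_fed()
        return self._sum / self.fed_count


class ReservoirAggregator(Aggregator):
    """Context from a trained Discourse Reservoir.

    feed() applies one leaky echo-state update; current() applies the trained
    readout to the present reservoir state.  Order-sensitive by nature.
    """

    kind = "reservoir"

    def __init__(self, results: DiscourseReservoirResults):
        super().__init__()
        if results.W_out is None:
            raise RuntimeError("reservoir aggregator requires a trained model")
        self.results = results
        self._state = results.model.initial_state()

    def reset(self) -> None:
        super().reset()
        self._state = self.results.model.initial_state()

    def feed(self, v: np.ndarray) -> None:
        self._state = self.results.model.step(self._state, v)
        self.fed_count += 1

    def current(self) -> np.ndarray:
        self._require_fed()
        return self.results.readout(self._state)


def trajectory(agg: Aggregator, tokens: list[str], table: EmbeddingTable) -> np.ndarray:
    """Context vector after each successive token (aggregator reset first).

    Returns an array of shape (len(tokens), dim): row k is the discourse
    context available when the (k+1)-th word has just been integrated.
    """
    agg.reset()
    rows = []
    for tok in tokens:
        agg.feed(table[tok])
        rows.append(np.asarray(agg.current(), dtype=float))
    return np.array(rows)
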