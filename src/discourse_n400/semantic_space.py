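"""Word vector spaces: loading, synthesis, and the cosine primitive.

A word's meaning is represented as a dense real vector; semantic relatedness
between two words is the cosine of the angle between their vectors.  Spaces
can be loaded from word2vec text files (e.g. a pretrained Wikipedia2Vec dump)
or generated synthetically with a controlled cluster structure, so that every
experiment in the package can run without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingTable",
    "SyntheticSpaceSpec",
    "TokenStream",
    "cosine",
    "load_embeddings",
    "save_embeddings",
    "generate_synthetic_space",
    "generate_training_stream",
]


class EmbeddingError(Exception):
    """Problem with an embedding table or one of its lookups."""


class OOVError(EmbeddingError, KeyError):
    """A word is absent from the table."""


class FormatError(EmbeddingError, ValueError):
    """A file does not conform to the word2vec text format."""


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Raises ``ValueError`` for zero vectors (the angle is undefined) or for
    mismatched lengths.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"cosine requires two vectors of equal length, got {u.shape} and {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine is undefined for the zero vector")
    return float(np.dot(u, v) / (nu * nv))


class EmbeddingTable:
    """Mapping from word (case-normalized to lowercase) to a d-dim vector.

    Invariants: every vector has length ``dim`` and none is all-zeros.
    Vectors are stored as handed in — no re-normalization — because cosine
    is scale-free; synthetic spaces are unit-norm by construction.
    """

    def __init__(self, dim: int):
        if dim < 1:
            raise ValueError("dim must be a positive integer")
        self.dim = int(dim)
        self._entries: dict[str, np.ndarray] = {}

    def add(self, word: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.dim,):
            raise ValueError(f"vector for {word!r} has shape {vector.shape}, expected ({self.dim},)")
        if not np.any(vector):
            raise ValueError(f"vector for {word!r} is all-zeros; cosine would be undefined")
        self._entries[word.lower()] = vector

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self._entries[word.lower()]
        except KeyError:
            raise OOVError(f"word {word!r} is not in the embedding table") from None

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def words(self) -> list[str]:
        return list(self._entries)

    def copy(self) -> "EmbeddingTable":
        """Independent copy (entry dict and vectors are duplicated)."""
        dup = EmbeddingTable(self.dim)
        for w, v in self._entries.items():
            dup._entries[w] = v.copy()
        return dup

    def vectors(self, words) -> np.ndarray:
        """Stack the vectors for ``words`` into an (n, dim) matrix."""
        return np.array([self[w] for w in words])

    def similarity(self, w1: str, w2: str) -> float:
        return cosine(self[w1], self[w2])


def load_embeddings(path, fmt: str = "word2vec-text") -> EmbeddingTable:
    """Read an embedding table from a word2vec text file.

    The format is a header line ``"<vocab_count> <dim>"`` followed by one
    ``"<word> <f1> ... <fdim>"`` line per word, space-separated, UTF-8.
    """
    if fmt != "word2vec-text":
        raise ValueError(f"unsupported embedding format {fmt!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: line 1: header must be '<vocab_count> <dim>'")
        try:
            vocab_count, dim = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}: line 1: header fields must be integers") from None
        table = EmbeddingTable(dim)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected a word and {dim} floats, got {len(parts)} fields"
                )
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric vector component") from None
            table.add(parts[0], vec)
    if len(table) != vocab_count:
        raise FormatError(
            f"{path}: header promised {vocab_count} words but {len(table)} distinct words were parsed"
        )
    return table


def save_embeddings(table: EmbeddingTable, path) -> None:
    """Write a table in word2vec text format (round-trips with load)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for word in table.words():
            comps = " ".join(repr(float(x)) for x in table[word])
            fh.write(f"{word} {comps}\n")


@dataclass(frozen=True)
class SyntheticSpaceSpec:
    """Recipe for a clustered synthetic semantic space.

    ``within_cluster_noise`` scales the expected *norm* of the isotropic
    perturbation added to a unit-norm cluster center before renormalization
    (per-component std = noise / sqrt(dim)), so a noise of 0.3 yields a
    within-cluster cosine around 1/(1 + 0.3**2) ~ 0.92 regardless of dim.
    """

    dim: int = 100
    n_clusters: int = 10
    words_per_cluster: int = 50
    within_cluster_noise: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1 or self.n_clusters < 1 or self.words_per_cluster < 1:
            raise ValueError("dim, n_clusters and words_per_cluster must be positive")
        if self.within_cluster_noise < 0:
            raise ValueError("within_cluster_noise must be non-negative")


def generate_synthetic_space(spec: SyntheticSpaceSpec) -> EmbeddingTable:
    """Deterministically build a clustered unit-norm embedding space.

    Words are named ``c<cluster>_w<index>`` so that downstream fixtures can
    select related (same cluster) and unrelated (different cluster) pairs by
    name alone.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.standard_normal((spec.n_clusters, spec.dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    table = EmbeddingTable(spec.dim)
    scale = spec.within_cluster_noise / math.sqrt(spec.dim)
    for c in range(spec.n_clusters):
        noise = scale * rng.standard_normal((spec.words_per_cluster, spec.dim))
        vecs = centers[c] + noise
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        for w in range(spec.words_per_cluster):
            table.add(f"c{c}_w{w}", vecs[w])
    return table


def cluster_of(word: str) -> int:
    """Cluster index encoded in a synthetic word name like ``c3_w17``."""
    if not word.startswith("c") or "_w" not in word:
        raise ValueError(f"{word!r} is not a synthetic cluster-labeled word")
    return int(word[1:].split("_w")[0])


@dataclass
class TokenStream:
    """An ordered collection of documents, each an ordered list of words.

    Document boundaries are explicit; no document is empty.  Used both as
    reservoir training material (documents play the role of articles) and as
    held-out evaluation material.
    """

    documents: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        for i, doc in enumerate(self.documents):
            if not doc:
                raise ValueError(f"document {i} is empty")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)

    def __iter__(self):
        return iter(self.documents)

    def validate(self, table: EmbeddingTable) -> None:
        for doc in self.documents:
            for tok in doc:
                if tok not in table:
                    raise OOVError(f"stream token {tok!r} is not in the embedding table")


def generate_training_stream(
    table: EmbeddingTable,
    n_docs: int,
    doc_len_range: tuple[int, int],
    topic_concentration: float = 9.0,
    seed: int = 0,
) -> TokenStream:
    """Sample a topically coherent token stream from a clustered space.

    Each document picks a primary cluster; every token comes from that
    cluster with probability ``topic_concentration / (topic_concentration+1)``
    and otherwise from the whole vocabulary, mimicking how an encyclopedia
    article stays mostly on one topic while mentioning others in passing.
    ``topic_concentration=inf`` yields perfectly single-topic documents.
    """
    if len(table) == 0:
        raise ValueError("embedding table is empty")
    lo, hi = doc_len_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid doc_len_range {doc_len_range!r}")
    if topic_concentration < 0:
        raise ValueError("topic_concentration must be non-negative")
    rng = np.random.default_rng(seed)
    words = np.array(table.words())
    clusters: dict[int, np.ndarray] = {}
    for idx, w in enumerate(words):
        try:
            c = cluster_of(w)
        except ValueError:
            c = 0
        clusters.setdefault(c, [])
        clusters[c].append(idx)
    cluster_ids = sorted(clusters)
    cluster_members = {c: np.array(v) for c, v in clusters.items()}
    if math.isinf(topic_concentration):
        p_topic = 1.0
    else:
        p_topic = topic_concentration / (topic_concentration + 1.0)
    docs = []
    for _ in range(n_docs):
        length = int(rng.integers(lo, hi + 1))
        primary = cluster_ids[rng.integers(len(cluster_ids))]
        members = cluster_members[primary]
        on_topic = rng.random(length) < p_topic
        tokens = np.where(
            on_topic,
            words[members[rng.integers(len(members), size=length)]],
            words[rng.integers(len(words), size=length)],
        )
        docs.append(list(tokens))
    return TokenStream(docs)
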