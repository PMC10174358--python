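"""The Discourse Reservoir: a leaky echo-state network trained to emit the
running average of its input word-embedding sequence.

The recurrent weights are fixed at initialization; only a linear readout is
learned, by ridge regression, against the running-average target
avg(w1), avg(w1,w2), ..., avg(w1..wN) computed per document.  The trained
readout turns the reservoir's fading-memory state into an online discourse
embedding that is updated word by word — the temporal-to-spatial integration
at the heart of the model.

Usage follows the model/results idiom::

    model = DiscourseReservoir(ReservoirConfig(seed=7), input_dim=100)
    res = model.fit(stream, table)        # -> DiscourseReservoirResults
    curve = res.tracking_curve(heldout_stream, table, max_position=10)
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass

import numpy as np

from .semantic_space import EmbeddingTable, TokenStream

__all__ = [
    "ReservoirConfig",
    "DiscourseReservoir",
    "DiscourseReservoirResults",
    "train_readout",
    "train_discourse_reservoir",
    "evaluate_average_tracking",
]


class NotTrainedError(RuntimeError):
    """An operation that needs a trained readout was called before fit()."""


@dataclass(frozen=True)
class ReservoirConfig:
    """Hyperparameters of the echo-state network.

    n_units : reservoir size (100, matching the embedding dimensionality).
    leak_rate : leaky-integration coefficient a in (0, 1]; the state moves a
        fraction ``a`` of the way toward the instantaneous activation at each
        word, so smaller values give longer memory (default 0.2).
    ridge_penalty : L2 penalty on the readout regression (default 1e-2).
    spectral_radius : largest |eigenvalue| of the recurrent matrix after
        rescaling; < 1 keeps the autonomous dynamics contractive.
    input_scaling, bias_scaling : multipliers on the uniform(-1, 1) input
        weights and unit biases.
    recurrent_density : fraction of nonzero recurrent weights.
    washout : number of initial tokens per document excluded from training.
    feedback : output-to-reservoir feedback; must remain False (the model
        has no readout feedback loop).
    """

    n_units: int = 100
    leak_rate: float = 0.2
    ridge_penalty: float = 1e-2
    spectral_radius: float = 0.95
    input_scaling: float = 1.0
    bias_scaling: float = 0.1
    recurrent_density: float = 1.0
    washout: int = 0
    seed: int = 0
    feedback: bool = False

    def __post_init__(self):
        if not (0 < self.leak_rate <= 1):
            raise ValueError("leak_rate must be in (0, 1]")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be positive")
        if not (0 < self.recurrent_density <= 1):
            raise ValueError("recurrent_density must be in (0, 1]")
        if self.washout < 0:
            raise ValueError("washout must be >= 0")
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.feedback:
            raise ValueError("output feedback is not supported (feedback must be False)")


def train_readout(states: np.ndarray, targets: np.ndarray, ridge_penalty: float) -> np.ndarray:
    """Closed-form ridge regression readout.

    Returns W of shape (output_dim, state_dim) minimizing
    ||S W^T - T||^2 + lambda ||W||^2.
    """
    S = np.asarray(states, dtype=float)
    T = np.asarray(targets, dtype=float)
    if S.ndim != 2 or T.ndim != 2 or S.shape[0] != T.shape[0]:
        raise ValueError(f"states {S.shape} and targets {T.shape} must share a positive row count")
    if S.shape[0] == 0:
        raise ValueError("cannot train a readout on zero rows")
    gram = S.T @ S + ridge_penalty * np.eye(S.shape[1])
    # solve (S'S + lam I) W' = S'T;  lstsq fallback covers lam = 0 on
    # rank-deficient designs
    try:
        Wt = np.linalg.solve(gram, S.T @ T)
    except np.linalg.LinAlgError:
        Wt = np.linalg.lstsq(gram, S.T @ T, rcond=None)[0]
    return Wt.T


class DiscourseReservoir:
    """Echo-state network model; weights are a pure function of (config, dims).

    The input and recurrent weights and the unit biases are drawn uniformly
    from [-1, 1] (then scaled / sparsified / rescaled to the configured
    spectral radius) using ``config.seed``, so the same config always builds
    bit-identical weights.
    """

    def __init__(self, config: ReservoirConfig, input_dim: int, output_dim: int | None = None):
        if input_dim < 1:
            raise ValueError("input_dim must be positive")
        self.config = config
        self.input_dim = int(input_dim)
        self.output_dim = int(output_dim) if output_dim is not None else self.input_dim
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")
        n = config.n_units
        rng = np.random.default_rng(config.seed)
        self.W_in = config.input_scaling * rng.uniform(-1.0, 1.0, size=(n, self.input_dim))
        W = rng.uniform(-1.0, 1.0, size=(n, n))
        if config.recurrent_density < 1.0:
            mask = rng.random((n, n)) < config.recurrent_density
            W = W * mask
        radius = float(np.max(np.abs(np.linalg.eigvals(W))))
        if radius == 0.0:
            raise ValueError("recurrent matrix has zero spectral radius; increase density")
        self.W_rec = W * (config.spectral_radius / radius)
        self.bias = config.bias_scaling * rng.uniform(-1.0, 1.0, size=n)

    def initial_state(self) -> np.ndarray:
        return np.zeros(self.config.n_units)

    def step(self, state: np.ndarray, u: np.ndarray) -> np.ndarray:
        """One leaky-integrator update:
        x' = (1 - a) x + a tanh(W_in u + W_rec x + b)."""
        u = np.asarray(u, dtype=float)
        state = np.asarray(state, dtype=float)
        if u.shape != (self.input_dim,):
            raise ValueError(f"input has shape {u.shape}, expected ({self.input_dim},)")
        if state.shape != (self.config.n_units,):
            raise ValueError(f"state has shape {state.shape}, expected ({self.config.n_units},)")
        a = self.config.leak_rate
        return (1.0 - a) * state + a * np.tanh(self.W_in @ u + self.W_rec @ state + self.bias)

    def collect_states(
        self, stream: TokenStream, table: EmbeddingTable
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the reservoir over a stream and pair states with running-average
        targets.

        The state and the running average are both reset to zero at every
        document boundary; the target row aligned with the k-th token of a
        document is the mean of that document's first k embeddings (current
        token included).  Rows within the washout window are excluded.
        """
        stream.validate(table)
        washout = self.config.washout
        state_rows: list[np.ndarray] = []
        target_rows: list[np.ndarray] = []
        for doc in stream:
            x = self.initial_state()
            running = np.zeros(table.dim)
            for k, tok in enumerate(doc, start=1):
                u = table[tok]
                x = self.step(x, u)
                running = running + (u - running) / k
                if k > washout:
                    state_rows.append(x)
                    target_rows.append(running.copy())
        if not state_rows:
            raise ValueError("stream produced no training rows (empty, or washout too long)")
        return np.array(state_rows), np.array(target_rows)

    def fit(self, stream: TokenStream, table: EmbeddingTable) -> "DiscourseReservoirResults":
        """Train the ridge readout on running-average targets over ``stream``."""
        if stream.n_documents == 0:
            raise ValueError("cannot fit on an empty stream")
        if table.dim != self.output_dim:
            raise ValueError(
                f"table dim {table.dim} does not match reservoir output_dim {self.output_dim}"
            )
        states, targets = self.collect_states(stream, table)
        W_out = train_readout(states, targets, self.config.ridge_penalty)
        mse = float(np.mean((states @ W_out.T - targets) ** 2))
        return DiscourseReservoirResults(
            model=self,
            W_out=W_out,
            train_mse=mse,
            n_train_tokens=states.shape[0],
            n_train_documents=stream.n_documents,
        )


class DiscourseReservoirResults:
    """A trained Discourse Reservoir: fixed dynamics plus learned readout."""

    def __init__(self, model, W_out, train_mse, n_train_tokens, n_train_documents):
        self.model = model
        self.W_out = np.asarray(W_out, dtype=float)
        self.train_mse = train_mse
        self.n_train_tokens = n_train_tokens
        self.n_train_documents = n_train_documents

    @property
    def config(self) -> ReservoirConfig:
        return self.model.config

    def readout(self, state: np.ndarray) -> np.ndarray:
        """Map a reservoir state (or a stack of states) through the readout."""
        return np.asarray(state) @ self.W_out.T

    def tracking_curve(
        self,
        stream: TokenStream,
        table: EmbeddingTable,
        max_position: int = 20,
        min_documents: int = 5,
    ):
        return evaluate_average_tracking(self, stream, table, max_position, min_documents)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Discourse Reservoir Results",
            "=" * 40,
            f"{'reservoir units':<24}{cfg.n_units}",
            f"{'input dim':<24}{self.model.input_dim}",
            f"{'output dim':<24}{self.model.output_dim}",
            f"{'leak rate':<24}{cfg.leak_rate}",
            f"{'spectral radius':<24}{cfg.spectral_radius}",
            f"{'ridge penalty':<24}{cfg.ridge_penalty}",
            f"{'seed':<24}{cfg.seed}",
            f"{'training documents':<24}{self.n_train_documents}",
            f"{'training tokens':<24}{self.n_train_tokens}",
            f"{'training MSE':<24}{self.train_mse:.6f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize config + dims + readout to one archive.

        The fixed weights are regenerated from (config, dims) on load, so the
        archive stays small and loading is bit-identical to the original.
        """
        meta = {
            "config": asdict(self.config),
            "input_dim": self.model.input_dim,
            "output_dim": self.model.output_dim,
            "train_mse": self.train_mse,
            "n_train_tokens": self.n_train_tokens,
            "n_train_documents": self.n_train_documents,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), W_out=self.W_out)

    @classmethod
    def load(cls, path) -> "DiscourseReservoirResults":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"]).decode())
            W_out = archive["W_out"]
        config = ReservoirConfig(**meta["config"])
        model = DiscourseReservoir(config, meta["input_dim"], meta["output_dim"])
        return cls(
            model=model,
            W_out=W_out,
            train_mse=meta["train_mse"],
            n_train_tokens=meta["n_train_tokens"],
            n_train_documents=meta["n_train_documents"],
        )


def train_discourse_reservoir(
    table: EmbeddingTable, stream: TokenStream, config: ReservoirConfig
) -> DiscourseReservoirResults:
    """Convenience wrapper: build the model for ``table.dim`` and fit it."""
    model = DiscourseReservoir(config, input_dim=table.dim, output_dim=table.dim)
    return model.fit(stream, table)


def evaluate_average_tracking(
    results: DiscourseReservoirResults,
    stream: TokenStream,
    table: EmbeddingTable,
    max_position: int = 20,
    min_documents: int = 5,
):
    """How well the trained readout tracks the true running average.

    For every document in ``stream`` and every within-document token position
    k <= max_position, computes the cosine between the readout output and the
    true mean of the document's first k embeddings, then averages over
    documents.  Positions supported by fewer than ``min_documents`` documents
    are omitted.

    Returns a list of (position, mean_cosine) pairs, positions 1-based.
    """
    from .semantic_space import cosine as _cosine

    if results.W_out is None:
        raise NotTrainedError("model has no trained readout")
    stream.validate(table)
    model = results.model
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for doc in stream:
        x = model.initial_state()
        running = np.zeros(table.dim)
        for k, tok in enumerate(doc, start=1):
            if k > max_position:
                break
            u = table[tok]
            x = model.step(x, u)
            running = running + (u - running) / k
            pred = results.readout(x)
            if np.any(pred):
                c = _cosine(pred, running)
            else:  # degenerate all-zero prediction counts as total miss
                c = 0.0
            sums[k] = sums.get(k, 0.0) + c
            counts[k] = counts.get(k, 0) + 1
    return [
        (k, sums[k] / counts[k])
        for k in sorted(sums)
        if counts[k] >= min_documents
    ]
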