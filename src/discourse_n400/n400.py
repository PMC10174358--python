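"""The linking hypothesis: predicted N400 = 1 - cosine(context, target).

As the semantic fit between the accumulated discourse context and the
incoming word decreases, the predicted N400 amplitude grows; identical
vectors give 0, orthogonal 1, antiparallel 2.  Values are reported raw —
no clamping or normalization — as a direct amplitude proxy.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .discourse import Aggregator, trajectory
from .semantic_space import EmbeddingTable, cosine

logger = logging.getLogger(__name__)

__all__ = [
    "predict_n400",
    "pairwise_priming_n400",
    "discourse_target_n400",
    "write_n400_table",
    "read_n400_table",
]

#: Column order of a long-format N400 table.
N400_COLUMNS = ["subject_id", "item_id", "condition", "position", "target", "value"]


def predict_n400(context: np.ndarray, target: np.ndarray) -> float:
    """1 - cosine(context, target), in [0, 2]."""
    return 1.0 - cosine(context, target)


def pairwise_priming_n400(table: EmbeddingTable, pairs, subject_id="model") -> pd.DataFrame:
    """Predicted N400 for the second word of each (prime, target, condition) pair.

    The context is the prime word's own vector — a one-word "discourse".
    Pairs with an out-of-vocabulary member are excluded and logged.
    """
    records = []
    skipped = []
    for i, (w1, w2, condition) in enumerate(pairs):
        if w1 not in table or w2 not in table:
            skipped.append((w1, w2))
            continue
        records.append(
            {
                "subject_id": subject_id,
                "item_id": f"pair{i}",
                "condition": condition,
                "position": 1,
                "target": w2,
                "value": predict_n400(table[w1], table[w2]),
            }
        )
    if skipped:
        logger.warning("excluded %d pairs with out-of-vocabulary members: %s", len(skipped), skipped)
    if not records:
        raise ValueError("no word pairs retained (all had out-of-vocabulary members)")
    return pd.DataFrame.from_records(records, columns=N400_COLUMNS)


def discourse_target_n400(
    agg: Aggregator, tokens: list[str], targets: list[str], table: EmbeddingTable
) -> pd.DataFrame:
    """Word-by-word predicted N400 trajectory for each target.

    After every token of the discourse, the N400 for each target word is
    1 - cosine of the aggregator's current context vector with the target's
    embedding.  Returns a long table with one row per (target, position),
    positions 1-based.
    """
    traj = trajectory(agg, tokens, table)
    records = []
    for tgt in targets:
        tv = table[tgt]
        for pos in range(traj.shape[0]):
            records.append(
                {
                    "target": tgt,
                    "position": pos + 1,
                    "token": tokens[pos],
                    "value": 1.0 - cosine(traj[pos], tv),
                }
            )
    return pd.DataFrame.from_records(records, columns=["target", "position", "token", "value"])


def write_n400_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_n400_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
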