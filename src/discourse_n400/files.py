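"""On-disk formats for stimuli, streams and run manifests.

Everything is plain text: word2vec text for embeddings (see
``semantic_space``), one document per line for token streams, TSV for word
pairs and all tabular results, JSON for scenario corpora, YAML for run
manifests.  A manifest records enough (config, seeds, package version,
stop-word list hash) to re-execute a run bit-identically.
"""

from __future__ import annotations

import json

import pandas as pd
import yaml

from . import __version__
from .discourse import stopword_list_hash
from .experiments import Scenario
from .semantic_space import TokenStream

__all__ = [
    "save_stream",
    "load_stream",
    "save_pairs",
    "load_pairs",
    "save_scenarios",
    "load_scenarios",
    "write_manifest",
    "read_manifest",
]


def save_stream(stream: TokenStream, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in stream:
            fh.write(" ".join(doc) + "\n")


def load_stream(path) -> TokenStream:
    with open(path, encoding="utf-8") as fh:
        docs = [line.split() for line in fh if line.strip()]
    return TokenStream(docs)


def save_pairs(pairs, path) -> None:
    pd.DataFrame(pairs, columns=["word1", "word2", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def load_pairs(path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("word1", "word2", "condition"):
        if col not in df.columns:
            raise ValueError(f"pair file {path} is missing column {col!r}")
    return list(df[["word1", "word2", "condition"]].itertuples(index=False, name=None))


def save_scenarios(scenarios: list[Scenario], path) -> None:
    payload = [
        {
            "item_id": sc.item_id,
            "context": list(sc.context_sentences),
            "sentence_stem": sc.final_sentence_stem,
            "expected": sc.expected,
            "related": sc.unexpected_related,
            "unrelated": sc.unexpected_unrelated,
        }
        for sc in scenarios
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_scenarios(path) -> list[Scenario]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        Scenario(
            item_id=item["item_id"],
            context_sentences=tuple(item["context"]),
            final_sentence_stem=item["sentence_stem"],
            expected=item["expected"],
            unexpected_related=item["related"],
            unexpected_unrelated=item["unrelated"],
        )
        for item in payload
    ]


def write_manifest(path, command: str, params: dict) -> None:
    manifest = {
        "command": command,
        "package_version": __version__,
        "stopword_list_sha1": stopword_list_hash(),
        "params": params,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
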