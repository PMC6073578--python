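"""Encoder registry: map config names to feature extractors and build
feature matrices for whole datasets."""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import baseline_features, ctd_features, pse_features
from .ctd_features import FeatureVector, concat
from .sequence_io import ProteinSequence

#: Named encoder configurations usable from the CLI (``--encoder``).
#: "188d+pse" is the default pipeline encoder: the 188-D CTD vector
#: concatenated with the default pseudo-composition profile.
REGISTRY: dict[str, Callable[[ProteinSequence], FeatureVector]] = {
    "188d": ctd_features.extract_188d,
    "pse": lambda s: pse_features.extract_pse_combined(s, pse_features.DEFAULT_PSE_CONFIG),
    "188d+pse": lambda s: concat(
        [
            ctd_features.extract_188d(s),
            pse_features.extract_pse_combined(s, pse_features.DEFAULT_PSE_CONFIG),
        ],
        "188d+pse",
    ),
    "ngram1": lambda s: baseline_features.ngram(s, 1),
    "skipgram400": baseline_features.skipgram_400,
    "kmer2": lambda s: pse_features.kmer(s, 2),
}


def get_encoder(name: str) -> Callable[[ProteinSequence], FeatureVector]:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; available: {sorted(REGISTRY)}") from None


def encode_dataset(
    seqs: Sequence[ProteinSequence],
    encoder: str | Callable[[ProteinSequence], FeatureVector] = "188d+pse",
) -> pd.DataFrame:
    """Feature matrix: one row per sequence (indexed by id), columns named
    per dimension."""
    fn = get_encoder(encoder) if isinstance(encoder, str) else encoder
    vectors = [fn(s) for s in seqs]
    if not vectors:
        return pd.DataFrame()
    names = vectors[0].names
    for s, v in zip(seqs, vectors):
        if v.names != names:
            raise ValueError(f"encoder produced inconsistent dimensions at {s.id!r}")
    return pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        index=[s.id for s in seqs],
        columns=list(names),
    )


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, index_label="id")


def read_feature_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col="id")
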