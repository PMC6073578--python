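"""Baseline comparison encoders: n-gram and the 400-D gapped dipeptide
(skip-gram) representation."""

from __future__ import annotations

import numpy as np

from .ctd_features import FeatureVector
from .pse_features import kmer
from .sequence_io import AMINO_ACIDS, ProteinSequence


def ngram(seq: ProteinSequence, n: int = 1) -> FeatureVector:
    """Alias for :func:`amylearn.pse_features.kmer`, kept so experiment
    configurations can use the n-gram naming."""
    vec = kmer(seq, n)
    return FeatureVector(vec.values, vec.names, f"ngram(n={n})")


def skipgram_400(seq: ProteinSequence, max_skip: int = 3) -> FeatureVector:
    """400-D gapped dipeptide frequencies.

    Counts ordered residue pairs (a, b) where b follows a with 0..max_skip
    residues skipped in between (gap 0 = adjacent), pools the counts over
    gaps with uniform weight, and normalizes by the total number of counted
    pairs; with max_skip = 0 this equals kmer(k=2).
    """
    if max_skip < 0:
        raise ValueError("max_skip must be >= 0")
    L = len(seq)
    if L < 2:
        raise ValueError("skipgram_400 requires length >= 2")
    counts = np.zeros(400)
    total = 0
    for gap in range(0, max_skip + 1):
        step = gap + 1
        if step >= L:
            break
        for i in range(L - step):
            a = AMINO_ACIDS.index(seq.residues[i])
            b = AMINO_ACIDS.index(seq.residues[i + step])
            counts[20 * a + b] += 1
            total += 1
    names = tuple(f"skip_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)
    return FeatureVector(counts / total, names, f"skipgram_400(max_skip={max_skip})")
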