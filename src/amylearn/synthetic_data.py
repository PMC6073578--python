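"""Synthetic labeled protein datasets with controlled class signal.

Negatives are drawn i.i.d. from a background residue distribution (uniform
by default, or a SwissProt-like table); positives from the same background
with a chosen residue set enriched by a multiplicative factor and the
distribution renormalized.  With factor 1 the two classes are statistically
identical (null case).  An optional order-1 Markov smoothing blends each
draw toward the previous residue's row of a mixing kernel so local
correlations exist without changing the marginal much.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence, write_fasta

#: Approximate SwissProt residue frequencies, renormalized over the 20
#: standard residues.
SWISSPROT_FREQUENCIES = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0394, "R": 0.0553,
    "S": 0.0661, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a two-class synthetic dataset."""

    n_pos: int = 165
    n_neg: int = 382
    length_range: tuple[int, int] = (50, 400)
    enriched_residues: str = "CLVIMFW"
    enrichment_factor: float = 5.0
    markov_order: int = 0
    background: str = "uniform"  # "uniform" | "swissprot"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 50:
            raise ValueError("minimum length must be >= 50 (dataset filter default)")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 or 1")
        if self.background not in ("uniform", "swissprot"):
            raise ValueError("background must be 'uniform' or 'swissprot'")
        bad = set(self.enriched_residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residues in enrichment set: {sorted(bad)}")


def background_frequencies(spec: GeneratorSpec) -> np.ndarray:
    if spec.background == "uniform":
        return np.full(20, 1 / 20)
    freqs = np.array([SWISSPROT_FREQUENCIES[a] for a in AMINO_ACIDS])
    return freqs / freqs.sum()


def positive_frequencies(spec: GeneratorSpec) -> np.ndarray:
    """Background with the chosen residue set multiplied by the enrichment
    factor, renormalized."""
    freqs = background_frequencies(spec).copy()
    for ch in spec.enriched_residues:
        freqs[AMINO_ACIDS.index(ch)] *= spec.enrichment_factor
    return freqs / freqs.sum()


def _draw_sequence(rng: np.random.Generator, freqs: np.ndarray, length: int, markov: bool) -> str:
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    if not markov:
        return rng.choice(alphabet, size=length, p=freqs).tobytes().decode()
    # order-1 smoothing: with prob 0.3 repeat-biased kernel favouring the
    # previous residue, else draw from the marginal
    chars = [rng.choice(20, p=freqs)]
    for _ in range(length - 1):
        if rng.random() < 0.3:
            chars.append(chars[-1])
        else:
            chars.append(rng.choice(20, p=freqs))
    return "".join(AMINO_ACIDS[i] for i in chars)


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a fully seeded labeled dataset from the spec."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    bg = background_frequencies(spec)
    pos_freqs = positive_frequencies(spec)
    markov = spec.markov_order == 1
    sequences, labels = [], []
    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        sequences.append(
            ProteinSequence(f"pos_{i+1:04d}", _draw_sequence(rng, pos_freqs, length, markov))
        )
        labels.append(1)
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        sequences.append(
            ProteinSequence(f"neg_{i+1:04d}", _draw_sequence(rng, bg, length, markov))
        )
        labels.append(0)
    return LabeledDataset(sequences, labels, name=f"synthetic-seed{spec.seed}")


def write_fixture(dataset: LabeledDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write positive/negative FASTA files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos_path = out_dir / "positive.fasta"
    neg_path = out_dir / "negative.fasta"
    pos = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 1]
    neg = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 0]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    if not pos or not neg:
        import logging

        logging.getLogger(__name__).warning(
            "write_fixture: wrote an empty class file (%d pos / %d neg)", len(pos), len(neg)
        )
    return pos_path, neg_path
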