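"""Composition/transition/distribution (CTD) protein descriptors.

The combined encoder produces a 188-dimensional vector: 20 amino-acid
composition features followed by, for each of 8 physicochemical properties,
21 features (3 class composition + 3 class transition + 15 class
distribution).  Residue-to-class partitions follow the canonical SVMProt/CTD
three-class tables; the feature ordering below is frozen so serialized
models remain stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import AMINO_ACIDS, AA_SET, ProteinSequence


@dataclass(frozen=True)
class PropertyPartition:
    """A named 3-class partition of the 20-letter alphabet.

    Class order is fixed per property and determines feature ordering.
    """

    name: str
    classes: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        c1, c2, c3 = self.classes
        if c1 & c2 or c1 & c3 or c2 & c3:
            raise ValueError(f"partition {self.name!r}: classes overlap")
        if c1 | c2 | c3 != AA_SET:
            raise ValueError(f"partition {self.name!r}: classes do not cover the alphabet")

    def class_of(self, residue: str) -> int:
        """0-based class index of a residue."""
        for i, cls in enumerate(self.classes):
            if residue in cls:
                return i
        raise KeyError(residue)


def _partition(name: str, c1: str, c2: str, c3: str) -> PropertyPartition:
    return PropertyPartition(name, (frozenset(c1), frozenset(c2), frozenset(c3)))


#: The 8 three-class partitions, in the frozen block order of the combined
#: encoder.  These are the standard SVMProt-style tables; they can be
#: overridden by passing a custom list to the extraction functions.
DEFAULT_PARTITIONS: tuple[PropertyPartition, ...] = (
    _partition("hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
    _partition("vdw_volume", "GASTPDC", "NVEQIL", "MHKFRYW"),
    _partition("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    _partition("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    _partition("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    _partition("surface_tension", "GQDNAHR", "KTSEC", "ILMFPWYV"),
    _partition("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    _partition("solvent_accessibility", "ALFCGIVW", "RKQEND", "MSPTHY"),
)

PARTITIONS_BY_NAME = {p.name: p for p in DEFAULT_PARTITIONS}


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric encoding with per-dimension names."""

    values: np.ndarray
    names: tuple[str, ...]
    encoder_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError(
                f"{self.encoder_id}: {self.values.shape} values vs {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.encoder_id}: non-finite feature values")

    def __len__(self) -> int:
        return len(self.values)


def concat(vectors: list[FeatureVector], encoder_id: str) -> FeatureVector:
    return FeatureVector(
        np.concatenate([v.values for v in vectors]),
        tuple(n for v in vectors for n in v.names),
        encoder_id,
    )


def aa_composition(seq: ProteinSequence) -> FeatureVector:
    """Frequency of each of the 20 residues (alphabetical order, sums to 1)."""
    counts = np.zeros(20)
    for ch in seq.residues:
        counts[AMINO_ACIDS.index(ch)] += 1
    return FeatureVector(
        counts / len(seq),
        tuple(f"comp_{a}" for a in AMINO_ACIDS),
        "aa_composition",
    )


def class_composition(seq: ProteinSequence, part: PropertyPartition) -> FeatureVector:
    """Fraction of residues in each of the 3 property classes."""
    counts = np.zeros(3)
    for ch in seq.residues:
        counts[part.class_of(ch)] += 1
    return FeatureVector(
        counts / len(seq),
        tuple(f"{part.name}_comp_c{i+1}" for i in range(3)),
        f"class_composition[{part.name}]",
    )


def class_transition(seq: ProteinSequence, part: PropertyPartition) -> FeatureVector:
    """Adjacent class-change frequencies for the unordered class pairs
    (1,2), (1,3), (2,3), normalized by L - 1."""
    L = len(seq)
    if L < 2:
        raise ValueError("class_transition undefined for length-1 sequences")
    counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
    prev = part.class_of(seq.residues[0])
    for ch in seq.residues[1:]:
        cur = part.class_of(ch)
        if cur != prev:
            counts[(min(prev, cur), max(prev, cur))] += 1
        prev = cur
    values = np.array([counts[(0, 1)], counts[(0, 2)], counts[(1, 2)]]) / (L - 1)
    return FeatureVector(
        values,
        tuple(f"{part.name}_trans_c{a+1}{b+1}" for a, b in ((0, 1), (0, 2), (1, 2))),
        f"class_transition[{part.name}]",
    )


_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)
_QLABELS = ("first", "q25", "q50", "q75", "last")


def class_distribution(seq: ProteinSequence, part: PropertyPartition) -> FeatureVector:
    """Positional quantiles of each class's occurrences (5 per class, 15 total).

    For a class with n occurrences, reports the 1-based sequence positions of
    the 1st, ceil(0.25 n)-th, ceil(0.50 n)-th, ceil(0.75 n)-th and n-th
    occurrence, each divided by L.  Absent classes contribute five zeros.
    """
    L = len(seq)
    positions: list[list[int]] = [[], [], []]
    for i, ch in enumerate(seq.residues, start=1):
        positions[part.class_of(ch)].append(i)
    values = []
    for cls_positions in positions:
        n = len(cls_positions)
        if n == 0:
            values.extend([0.0] * 5)
            continue
        for q in _QUANTILES:
            idx = max(1, math.ceil(q * n))  # 1-based rank
            values.append(cls_positions[idx - 1] / L)
    return FeatureVector(
        np.array(values),
        tuple(
            f"{part.name}_dist_c{c+1}_{lab}" for c in range(3) for lab in _QLABELS
        ),
        f"class_distribution[{part.name}]",
    )


def property_block(seq: ProteinSequence, part: PropertyPartition) -> FeatureVector:
    """The 21-feature CTD block for one property partition."""
    return concat(
        [
            class_composition(seq, part),
            class_transition(seq, part),
            class_distribution(seq, part),
        ],
        f"ctd[{part.name}]",
    )


def extract_188d(
    seq: ProteinSequence,
    partitions: tuple[PropertyPartition, ...] = DEFAULT_PARTITIONS,
) -> FeatureVector:
    """The combined 188-D encoder: 20 composition + 8 x 21 CTD features."""
    blocks = [aa_composition(seq)]
    blocks.extend(property_block(seq, p) for p in partitions)
    return concat(blocks, "188d")
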