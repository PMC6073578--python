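"""FASTA I/O, sequence validation and dataset-assembly filters.

Sequences are plain strings over the 20-letter amino-acid alphabet.  Labels
are attached at the dataset level (positive file vs. negative file), never
parsed out of FASTA headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetically ordered.  This ordering is frozen:
#: it fixes the dimension order of every composition-style feature block.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Characters that may appear in real-world FASTA but are not standard
#: residues, with their closest standard substitute (used by ``map-to-ALA``).
NONSTANDARD_MAP = {
    "U": "C",  # selenocysteine
    "B": "N",  # Asx
    "Z": "Q",  # Glx
    "X": "A",
    "J": "A",
    "O": "A",  # pyrrolysine
}

SANITIZE_POLICIES = ("reject", "strip", "map-to-ALA")


class SequenceError(ValueError):
    """Raised for invalid residue strings or malformed FASTA input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated amino-acid sequence with an identifier.

    Raises :class:`SequenceError` if ``residues`` is empty or contains any
    character outside the 20-letter alphabet.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - AA_SET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r}: non-standard residues {sorted(bad)}; "
                "run sanitize() first"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences plus binary labels (1 = positive / amyloid)."""

    sequences: list[ProteinSequence]
    labels: list[int]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0 or 1")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in {self.name!r}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
            name=name or self.name,
        )


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly line-wrapped) FASTA file into validated sequences.

    Headers are truncated at the first whitespace to form ids; residue lines
    are concatenated and uppercased.  An empty file yields an empty list with
    a warning.  Text before the first ``>`` header is a parse error.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        if first and first not in (">", ";"):
            raise SequenceError(f"{path}: line 1: sequence data before FASTA header")
        handle.seek(0)
        records = [
            ProteinSequence(id=header.split()[0] if header.split() else header,
                            residues=seq.upper())
            for header, seq in SimpleFastaParser(handle)
        ]
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapping residue lines at ``width``."""
    with open(path, "w") as handle:
        for s in seqs:
            handle.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                handle.write(s.residues[i : i + width] + "\n")


def sanitize(raw: str, policy: str = "strip", seq_id: str = "seq") -> ProteinSequence:
    """Normalize a raw residue string into a valid :class:`ProteinSequence`.

    Policies for characters outside the 20-letter alphabet:

    - ``reject``: raise, naming the first offending character and position.
    - ``strip``: drop them (default; raises if nothing remains).
    - ``map-to-ALA``: substitute via :data:`NONSTANDARD_MAP` (U→C, B→N, Z→Q,
      X/J/O→A); anything else is dropped.
    """
    if policy not in SANITIZE_POLICIES:
        raise ValueError(f"unknown sanitize policy {policy!r}; use one of {SANITIZE_POLICIES}")
    s = raw.upper().replace("*", "").replace("-", "") if policy != "reject" else raw.upper()
    if policy == "reject":
        for pos, ch in enumerate(s, start=1):
            if ch not in AA_SET:
                raise SequenceError(
                    f"sequence {seq_id!r}: non-standard residue {ch!r} at position {pos}"
                )
        cleaned = s
    elif policy == "strip":
        cleaned = "".join(ch for ch in s if ch in AA_SET)
    else:  # map-to-ALA
        cleaned = "".join(
            ch if ch in AA_SET else NONSTANDARD_MAP.get(ch, "")
            for ch in s
            if ch in AA_SET or ch in NONSTANDARD_MAP
        )
    if not cleaned:
        raise SequenceError(f"sequence {seq_id!r}: empty after sanitization")
    return ProteinSequence(id=seq_id, residues=cleaned)


def filter_min_length(
    seqs: Sequence[ProteinSequence], min_len: int = 50
) -> list[ProteinSequence]:
    """Keep sequences of length >= ``min_len`` (dataset-construction filter)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [s for s in seqs if len(s) >= min_len]
    removed = len(seqs) - len(kept)
    if removed:
        logger.info("filter_min_length: removed %d/%d sequences shorter than %d",
                    removed, len(seqs), min_len)
    return kept


def _kmer_set(residues: str, k: int) -> set[str]:
    return {residues[i : i + k] for i in range(len(residues) - k + 1)}


def pairwise_identity(a: ProteinSequence, b: ProteinSequence, k: int = 5) -> float:
    """Alignment-free identity proxy between two sequences.

    Equal-length pairs use exact positional identity; otherwise the Jaccard
    index of shared k-mers (k=5).  This is a cheap stand-in for a real
    clustering tool and is NOT equivalent to CD-HIT identities.
    """
    if a.residues == b.residues:
        return 1.0
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a.residues, b.residues))
        return matches / len(a)
    ka, kb = _kmer_set(a.residues, k), _kmer_set(b.residues, k)
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / len(ka | kb)


def greedy_identity_cluster(
    seqs: Sequence[ProteinSequence], identity_threshold: float = 0.9, k: int = 5
) -> list[ProteinSequence]:
    """Greedy longest-first redundancy reduction.

    Sequences are visited longest first; each joins the first existing
    representative with :func:`pairwise_identity` >= threshold, else becomes
    a new representative.  Returned representatives are pairwise below the
    threshold.  Fallback only — not a CD-HIT replacement.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    reps: list[ProteinSequence] = []
    for s in sorted(seqs, key=len, reverse=True):
        if not any(pairwise_identity(s, r, k=k) >= identity_threshold for r in reps):
            reps.append(s)
    # restore input order among representatives
    order = {s.id: i for i, s in enumerate(seqs)}
    reps.sort(key=lambda s: order[s.id])
    return reps


def load_labeled_fasta(
    positive: str | Path,
    negative: str | Path,
    *,
    min_len: int | None = None,
    sanitize_policy: str | None = None,
    name: str = "dataset",
) -> LabeledDataset:
    """Assemble a labeled dataset from a positive and a negative FASTA file."""
    def _load(path: str | Path) -> list[ProteinSequence]:
        seqs = read_fasta(path)
        if sanitize_policy is not None:
            seqs = [sanitize(s.residues, sanitize_policy, seq_id=s.id) for s in seqs]
        if min_len is not None:
            seqs = filter_min_length(seqs, min_len)
        return seqs

    pos, neg = _load(positive), _load(negative)
    return LabeledDataset(pos + neg, [1] * len(pos) + [0] * len(neg), name=name)
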