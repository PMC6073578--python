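"""Sequence-only pseudo-composition encoders.

Implements the sequence-derivable members of the five-group method catalog:
k-mer / distance-residue / distance-pair composition, physicochemical
autocorrelation (AC, CC, ACC, PDT), and pseudo amino-acid composition
(parallel- and series-correlation variants, plus their "General" forms that
accept user-supplied index tables).  Profile-based and predicted-structure
methods need PSSMs or structure predictors and are catalogued as
unsupported.

Layout conventions (frozen, pinned by oracle tests):

- ``kmer``: the 20**k k-mers in alphabetical order, normalized by L-k+1.
- ``distance_residue``: a 20-feature block for distance 0 (single-residue
  counts / L), then for each distance d = 1..d_max a 400-feature block of
  ordered residue pairs, normalized by L-d.
- ``distance_pair``: same distance-0 block, then per distance a 210-feature
  block of unordered residue pairs (i <= j lexicographically).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .ctd_features import FeatureVector, concat
from .sequence_io import AMINO_ACIDS, ProteinSequence


@dataclass(frozen=True)
class PhysChemIndex:
    """A per-residue physicochemical scale over the 20 standard residues."""

    name: str
    values: dict
    standardized: bool = False

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.values)
            raise ValueError(f"index {self.name!r}: missing residues {sorted(missing)}")

    def standardize(self) -> "PhysChemIndex":
        """Rescale to mean 0, population standard deviation 1 over the 20 residues."""
        vals = np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)
        std = vals.std()
        if std == 0:
            raise ValueError(f"index {self.name!r}: constant scale cannot be standardized")
        scaled = (vals - vals.mean()) / std
        return PhysChemIndex(
            self.name, dict(zip(AMINO_ACIDS, scaled)), standardized=True
        )

    def profile(self, seq: ProteinSequence) -> np.ndarray:
        return np.array([self.values[ch] for ch in seq.residues])


# Classical scales used by pseudo amino-acid composition: hydrophobicity
# (Tanford), hydrophilicity (Hopp-Woods), side-chain mass.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}

DEFAULT_INDICES: tuple[PhysChemIndex, ...] = (
    PhysChemIndex("hydrophobicity", _HYDROPHOBICITY).standardize(),
    PhysChemIndex("hydrophilicity", _HYDROPHILICITY).standardize(),
    PhysChemIndex("side_chain_mass", _SIDE_CHAIN_MASS).standardize(),
)


def load_index_tsv(path) -> PhysChemIndex:
    """Load a physicochemical index from a 20-row ``residue<TAB>value`` TSV."""
    import csv
    from pathlib import Path

    values = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            values[row[0].strip().upper()] = float(row[1])
    return PhysChemIndex(Path(path).stem, values)


# ---------------------------------------------------------------------------
# Group 1: composition


def kmer(seq: ProteinSequence, k: int = 2) -> FeatureVector:
    """Frequencies of all 20**k k-mers in alphabetical order (sums to 1)."""
    if not 1 <= k <= 3:
        raise ValueError("k must be in 1..3")
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} < k = {k}")
    words = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=k)]
    index = {w: i for i, w in enumerate(words)}
    counts = np.zeros(len(words))
    for i in range(L - k + 1):
        counts[index[seq.residues[i : i + k]]] += 1
    return FeatureVector(
        counts / (L - k + 1), tuple(f"kmer_{w}" for w in words), f"kmer(k={k})"
    )


def _distance_zero_block(seq: ProteinSequence) -> np.ndarray:
    counts = np.zeros(20)
    for ch in seq.residues:
        counts[AMINO_ACIDS.index(ch)] += 1
    return counts / len(seq)


def distance_residue(seq: ProteinSequence, d_max: int = 3) -> FeatureVector:
    """Ordered residue-pair frequencies by separation distance 0..d_max."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    L = len(seq)
    if L <= d_max:
        raise ValueError(f"sequence length {L} <= d_max = {d_max}")
    values = [_distance_zero_block(seq)]
    names = [f"dr_d0_{a}" for a in AMINO_ACIDS]
    for d in range(1, d_max + 1):
        counts = np.zeros(400)
        for i in range(L - d):
            a = AMINO_ACIDS.index(seq.residues[i])
            b = AMINO_ACIDS.index(seq.residues[i + d])
            counts[20 * a + b] += 1
        values.append(counts / (L - d))
        names.extend(f"dr_d{d}_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)
    return FeatureVector(np.concatenate(values), tuple(names), f"dr(d_max={d_max})")


def distance_pair(seq: ProteinSequence, d_max: int = 3) -> FeatureVector:
    """Unordered residue-pair frequencies by separation distance 0..d_max."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    L = len(seq)
    if L <= d_max:
        raise ValueError(f"sequence length {L} <= d_max = {d_max}")
    pairs = [a + b for a, b in itertools.combinations_with_replacement(AMINO_ACIDS, 2)]
    pair_index = {p: i for i, p in enumerate(pairs)}
    values = [_distance_zero_block(seq)]
    names = [f"dp_d0_{a}" for a in AMINO_ACIDS]
    for d in range(1, d_max + 1):
        counts = np.zeros(len(pairs))
        for i in range(L - d):
            key = "".join(sorted((seq.residues[i], seq.residues[i + d])))
            counts[pair_index[key]] += 1
        values.append(counts / (L - d))
        names.extend(f"dp_d{d}_{p}" for p in pairs)
    return FeatureVector(np.concatenate(values), tuple(names), f"distance_pair(d_max={d_max})")


# ---------------------------------------------------------------------------
# Group 2: autocorrelation


def _check_lag(seq: ProteinSequence, lag_max: int) -> None:
    if lag_max < 1:
        raise ValueError("lag_max must be >= 1")
    if lag_max >= len(seq):
        raise ValueError(f"lag_max = {lag_max} must be < sequence length {len(seq)}")


def _standardized(indices) -> list[PhysChemIndex]:
    return [u if u.standardized else u.standardize() for u in indices]


def autocorrelation_AC(
    seq: ProteinSequence,
    indices=DEFAULT_INDICES,
    lag_max: int = 2,
) -> FeatureVector:
    """Mean-centered auto-covariance of each index profile at lags 1..lag_max."""
    _check_lag(seq, lag_max)
    indices = _standardized(indices)
    L = len(seq)
    values, names = [], []
    for u in indices:
        p = u.profile(seq)
        m = p.mean()
        for g in range(1, lag_max + 1):
            values.append(np.mean((p[: L - g] - m) * (p[g:] - m)))
            names.append(f"ac_{u.name}_lag{g}")
    return FeatureVector(np.array(values), tuple(names), f"ac(lag_max={lag_max})")


def autocorrelation_CC(
    seq: ProteinSequence,
    indices=DEFAULT_INDICES,
    lag_max: int = 2,
) -> FeatureVector:
    """Cross-covariance between distinct index profiles at lags 1..lag_max."""
    if len(indices) < 2:
        raise ValueError("CC requires at least 2 physicochemical indices")
    _check_lag(seq, lag_max)
    indices = _standardized(indices)
    L = len(seq)
    values, names = [], []
    for u1, u2 in itertools.permutations(indices, 2):
        p1, p2 = u1.profile(seq), u2.profile(seq)
        m1, m2 = p1.mean(), p2.mean()
        for g in range(1, lag_max + 1):
            values.append(np.mean((p1[: L - g] - m1) * (p2[g:] - m2)))
            names.append(f"cc_{u1.name}_{u2.name}_lag{g}")
    return FeatureVector(np.array(values), tuple(names), f"cc(lag_max={lag_max})")


def autocorrelation_ACC(
    seq: ProteinSequence,
    indices=DEFAULT_INDICES,
    lag_max: int = 2,
) -> FeatureVector:
    """AC block followed by CC block."""
    return concat(
        [
            autocorrelation_AC(seq, indices, lag_max),
            autocorrelation_CC(seq, indices, lag_max),
        ],
        f"acc(lag_max={lag_max})",
    )


def pdt(seq: ProteinSequence, indices=DEFAULT_INDICES, lag_max: int = 2) -> FeatureVector:
    """Physicochemical distance transformation: lag-indexed mean squared
    differences of standardized profiles, halved."""
    _check_lag(seq, lag_max)
    indices = _standardized(indices)
    L = len(seq)
    values, names = [], []
    for u in indices:
        p = u.profile(seq)
        for g in range(1, lag_max + 1):
            values.append(np.mean((p[: L - g] - p[g:]) ** 2) / 2.0)
            names.append(f"pdt_{u.name}_lag{g}")
    return FeatureVector(np.array(values), tuple(names), f"pdt(lag_max={lag_max})")


# ---------------------------------------------------------------------------
# Group 3: pseudo amino-acid composition


def _theta_parallel(seq: ProteinSequence, indices, lam: int) -> np.ndarray:
    """theta_j = mean over positions of the mean squared index difference."""
    L = len(seq)
    profiles = [u.profile(seq) for u in indices]
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        corr = np.zeros(L - j)
        for p in profiles:
            corr += (p[: L - j] - p[j:]) ** 2
        thetas[j - 1] = np.mean(corr / len(profiles))
    return thetas


def pc_pseaac(
    seq: ProteinSequence,
    indices=DEFAULT_INDICES,
    lam: int = 2,
    w: float = 0.05,
) -> FeatureVector:
    """Parallel-correlation pseudo amino-acid composition (length 20 + lam).

    First 20 entries: residue frequencies; last lam entries: weighted
    sequence-order correlation factors.  The vector sums to 1.
    """
    if w <= 0:
        raise ValueError("w must be > 0")
    if lam < 1 or lam >= len(seq):
        raise ValueError(f"lam = {lam} must satisfy 1 <= lam < L = {len(seq)}")
    indices = _standardized(indices)
    freqs = np.zeros(20)
    for ch in seq.residues:
        freqs[AMINO_ACIDS.index(ch)] += 1
    freqs /= len(seq)
    thetas = _theta_parallel(seq, indices, lam)
    denom = freqs.sum() + w * thetas.sum()
    values = np.concatenate([freqs / denom, w * thetas / denom])
    names = tuple(f"pse_{a}" for a in AMINO_ACIDS) + tuple(
        f"pse_theta{j}" for j in range(1, lam + 1)
    )
    return FeatureVector(values, names, f"pc_pseaac(lam={lam},w={w})")


def sc_pseaac(
    seq: ProteinSequence,
    indices=DEFAULT_INDICES,
    lam: int = 2,
    w: float = 0.05,
) -> FeatureVector:
    """Series-correlation pseudo amino-acid composition (length 20 + |indices|*lam).

    Keeps a separate correlation factor per (lag, index) pair; with a single
    index it reduces exactly to :func:`pc_pseaac`.
    """
    if w <= 0:
        raise ValueError("w must be > 0")
    if lam < 1 or lam >= len(seq):
        raise ValueError(f"lam = {lam} must satisfy 1 <= lam < L = {len(seq)}")
    indices = _standardized(indices)
    L = len(seq)
    freqs = np.zeros(20)
    for ch in seq.residues:
        freqs[AMINO_ACIDS.index(ch)] += 1
    freqs /= L
    taus, tau_names = [], []
    for j in range(1, lam + 1):
        for u in indices:
            p = u.profile(seq)
            taus.append(np.mean((p[: L - j] - p[j:]) ** 2))
            tau_names.append(f"pse_tau{j}_{u.name}")
    taus = np.array(taus)
    denom = freqs.sum() + w * taus.sum()
    values = np.concatenate([freqs / denom, w * taus / denom])
    names = tuple(f"pse_{a}" for a in AMINO_ACIDS) + tuple(tau_names)
    return FeatureVector(values, names, f"sc_pseaac(lam={lam},w={w})")


def pc_pseaac_general(seq, indices, lam: int = 2, w: float = 0.05) -> FeatureVector:
    """PC-PseAAC with caller-supplied index tables (no defaults)."""
    if not indices:
        raise ValueError("pc_pseaac_general requires at least one index")
    return pc_pseaac(seq, indices, lam, w)


def sc_pseaac_general(seq, indices, lam: int = 2, w: float = 0.05) -> FeatureVector:
    """SC-PseAAC with caller-supplied index tables (no defaults)."""
    if not indices:
        raise ValueError("sc_pseaac_general requires at least one index")
    return sc_pseaac(seq, indices, lam, w)


# ---------------------------------------------------------------------------
# Method catalog


@dataclass(frozen=True)
class MethodCatalogEntry:
    name: str
    group: str
    supported: bool
    reason_unsupported: str | None = None


_GROUP_AAC = "amino acid composition"
_GROUP_AUTO = "autocorrelation"
_GROUP_PSE = "pseudo amino acid composition"
_GROUP_PROFILE = "profile-based"
_GROUP_STRUCT = "predicted structure"

_NEEDS_PSSM = "requires a PSSM profile (PSI-BLAST search against a sequence database)"
_NEEDS_STRUCT = "requires a structure predictor"

_CATALOG: tuple[MethodCatalogEntry, ...] = (
    MethodCatalogEntry("Kmer", _GROUP_AAC, True),
    MethodCatalogEntry("DR", _GROUP_AAC, True),
    MethodCatalogEntry("DP", _GROUP_AAC, True),
    MethodCatalogEntry("AC", _GROUP_AUTO, True),
    MethodCatalogEntry("CC", _GROUP_AUTO, True),
    MethodCatalogEntry("ACC", _GROUP_AUTO, True),
    MethodCatalogEntry("PDT", _GROUP_AUTO, True),
    MethodCatalogEntry("PC-PseAAC", _GROUP_PSE, True),
    MethodCatalogEntry("SC-PseAAC", _GROUP_PSE, True),
    MethodCatalogEntry("PC-PseAAC-General", _GROUP_PSE, True),
    MethodCatalogEntry("SC-PseAAC-General", _GROUP_PSE, True),
    MethodCatalogEntry("Top-n-gram", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("PDT-Profile", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("DT", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("AC-PSSM", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("CC-PSSM", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("ACC-PSSM", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("PSSM-DT", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("PSSM-RT", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("CS", _GROUP_PROFILE, False, _NEEDS_PSSM),
    MethodCatalogEntry("SS", _GROUP_STRUCT, False, _NEEDS_STRUCT),
    MethodCatalogEntry("SASA", _GROUP_STRUCT, False, _NEEDS_STRUCT),
)


def method_catalog() -> list[MethodCatalogEntry]:
    """The 22 named encoders in their 5 groups, with support flags."""
    return list(_CATALOG)


class UnsupportedMethodError(ValueError):
    """A catalogued method that cannot run from sequence alone was requested."""


_DISPATCH = {
    "Kmer": kmer,
    "DR": distance_residue,
    "DP": distance_pair,
    "AC": autocorrelation_AC,
    "CC": autocorrelation_CC,
    "ACC": autocorrelation_ACC,
    "PDT": pdt,
    "PC-PseAAC": pc_pseaac,
    "SC-PseAAC": sc_pseaac,
    "PC-PseAAC-General": pc_pseaac_general,
    "SC-PseAAC-General": sc_pseaac_general,
}


def extract_pse_combined(
    seq: ProteinSequence, config: list[tuple[str, dict]]
) -> FeatureVector:
    """Concatenate the selected supported encoders in config order.

    ``config`` is a list of ``(method_name, kwargs)`` pairs using catalog
    names.  Selecting a profile-based or predicted-structure method raises
    :class:`UnsupportedMethodError` naming the method and the missing input.
    """
    entries = {e.name: e for e in _CATALOG}
    vectors = []
    for name, kwargs in config:
        if name not in entries:
            raise ValueError(f"unknown method {name!r}; see method_catalog()")
        entry = entries[name]
        if not entry.supported:
            raise UnsupportedMethodError(f"method {name!r} is unsupported: {entry.reason_unsupported}")
        vec = _DISPATCH[name](seq, **kwargs)
        vectors.append(
            FeatureVector(vec.values, tuple(f"{name}:{n}" for n in vec.names), vec.encoder_id)
        )
    return concat(vectors, "pse_combined")


#: Default combined profile used by the "pse" encoder of the pipeline.
DEFAULT_PSE_CONFIG: list[tuple[str, dict]] = [
    ("Kmer", {"k": 2}),
    ("PC-PseAAC", {"lam": 2, "w": 0.05}),
]
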