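"""Pseudo-composition encoder tests with independent naive-loop oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amylearn.pse_features import (
    DEFAULT_INDICES,
    DEFAULT_PSE_CONFIG,
    PhysChemIndex,
    UnsupportedMethodError,
    autocorrelation_AC,
    autocorrelation_ACC,
    autocorrelation_CC,
    distance_pair,
    distance_residue,
    extract_pse_combined,
    kmer,
    method_catalog,
    pc_pseaac,
    pc_pseaac_general,
    pdt,
    sc_pseaac,
)
from amylearn.ctd_features import aa_composition
from amylearn.sequence_io import AMINO_ACIDS, ProteinSequence
from .conftest import random_protein

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=60).map(
    lambda s: ProteinSequence("h", s)
)


class TestPhysChemIndex:
    def test_standardized_mean_zero_sd_one(self):
        for idx in DEFAULT_INDICES:
            vals = np.array([idx.values[a] for a in AMINO_ACIDS])
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-9

    def test_missing_residue_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PhysChemIndex("partial", {"A": 1.0})

    def test_constant_scale_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            PhysChemIndex("flat", {a: 1.0 for a in AMINO_ACIDS}).standardize()


class TestKmer:
    def test_k1_equals_aa_composition(self, rng):
        seq = random_protein(rng, 50)
        assert np.allclose(kmer(seq, 1).values, aa_composition(seq).values)

    def test_homopolymer_k2(self):
        v = kmer(ProteinSequence("s", "AAA"), 2)
        assert v.values[0] == 1.0 and v.values[1:].sum() == 0.0

    def test_k_larger_than_length_errors(self):
        with pytest.raises(ValueError):
            kmer(ProteinSequence("s", "AC"), 3)

    def test_brute_force_dictionary_count(self, rng):
        seq = random_protein(rng, 40)
        counts = {}
        for i in range(39):
            w = seq.residues[i : i + 2]
            counts[w] = counts.get(w, 0) + 1
        v = kmer(seq, 2)
        for j, (a, b) in enumerate(itertools.product(AMINO_ACIDS, repeat=2)):
            assert v.values[j] == pytest.approx(counts.get(a + b, 0) / 39)

    @given(seq_strategy)
    @settings(max_examples=50, deadline=None)
    def test_normalized(self, seq):
        assert abs(kmer(seq, 2).values.sum() - 1.0) < 1e-12


class TestDistanceResidue:
    def test_d0_is_single_residue_counts(self, rng):
        seq = random_protein(rng, 30)
        v = distance_residue(seq, 0)
        assert len(v) == 20
        assert np.allclose(v.values, aa_composition(seq).values)

    def test_homopolymer_mass_on_AA(self):
        v = distance_residue(ProteinSequence("s", "AAAA"), 2)
        assert v.values[0] == 1.0  # d0 block, residue A
        # each d >= 1 block puts all mass on ordered pair (A, A)
        for d in (1, 2):
            block = v.values[20 + 400 * (d - 1) : 20 + 400 * d]
            assert block[0] == 1.0 and block[1:].sum() == 0.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            distance_residue(ProteinSequence("s", "ACD"), 3)

    def test_brute_force_pair_enumeration(self, rng):
        seq = random_protein(rng, 25)
        d_max = 3
        v = distance_residue(seq, d_max)
        assert len(v) == 20 + 400 * d_max
        for d in range(1, d_max + 1):
            counts = np.zeros(400)
            for i in range(25 - d):
                a = AMINO_ACIDS.index(seq.residues[i])
                b = AMINO_ACIDS.index(seq.residues[i + d])
                counts[20 * a + b] += 1
            block = v.values[20 + 400 * (d - 1) : 20 + 400 * d]
            assert np.allclose(block, counts / (25 - d))


class TestDistancePair:
    def test_layout_length(self, rng):
        v = distance_pair(random_protein(rng, 30), 2)
        assert len(v) == 20 + 210 * 2

    def test_brute_force_unordered(self, rng):
        seq = random_protein(rng, 25)
        v = distance_pair(seq, 3)
        pairs = [
            a + b for a, b in itertools.combinations_with_replacement(AMINO_ACIDS, 2)
        ]
        for d in range(1, 4):
            counts = dict.fromkeys(pairs, 0)
            for i in range(25 - d):
                key = "".join(sorted(seq.residues[i] + seq.residues[i + d]))
                counts[key] += 1
            block = v.values[20 + 210 * (d - 1) : 20 + 210 * d]
            assert np.allclose(block, [counts[p] / (25 - d) for p in pairs])


class TestAutocorrelation:
    def test_homopolymer_zero(self):
        seq = ProteinSequence("s", "A" * 20)
        assert np.allclose(autocorrelation_AC(seq, lag_max=3).values, 0.0)
        assert np.allclose(pdt(seq, lag_max=3).values, 0.0)

    def test_period_two_signs(self):
        # alternating A/R: lag-1 covariance negative, lag-2 positive for any
        # index that separates A from R
        seq = ProteinSequence("s", "AR" * 10)
        idx = [DEFAULT_INDICES[0]]  # hydrophobicity separates A and R
        v = autocorrelation_AC(seq, idx, lag_max=2).values
        assert v[0] < 0 < v[1]

    def test_period_two_closed_form(self):
        # even-length alternation: mean = (a + b)/2, every lag-1 product is
        # -((a-b)/2)^2 and every lag-2 product is +((a-b)/2)^2
        seq = ProteinSequence("s", "AR" * 10)
        idx = DEFAULT_INDICES[0]
        a, b = idx.values["A"], idx.values["R"]
        half_diff_sq = ((a - b) / 2) ** 2
        v = autocorrelation_AC(seq, [idx], lag_max=2).values
        assert v[0] == pytest.approx(-half_diff_sq, rel=1e-9)
        assert v[1] == pytest.approx(half_diff_sq, rel=1e-9)

    def test_ac_brute_force(self, rng):
        seq = random_protein(rng, 30)
        idx = DEFAULT_INDICES[0]
        v = autocorrelation_AC(seq, [idx], lag_max=4).values
        p = [idx.values[c] for c in seq.residues]
        m = sum(p) / 30
        for g in range(1, 5):
            expected = sum((p[i] - m) * (p[i + g] - m) for i in range(30 - g)) / (30 - g)
            assert v[g - 1] == pytest.approx(expected, abs=1e-12)

    def test_lag_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            autocorrelation_AC(random_protein(rng, 5), lag_max=5)

    def test_cc_requires_two_indices(self, rng):
        with pytest.raises(ValueError):
            autocorrelation_CC(random_protein(rng, 30), [DEFAULT_INDICES[0]], 2)

    def test_cc_excludes_self_pairs_by_length(self, rng):
        seq = random_protein(rng, 30)
        v = autocorrelation_CC(seq, DEFAULT_INDICES, lag_max=2)
        assert len(v) == 3 * 2 * 2  # |I| * (|I|-1) * lag_max

    def test_acc_is_ac_plus_cc(self, rng):
        seq = random_protein(rng, 30)
        ac = autocorrelation_AC(seq, DEFAULT_INDICES, 3)
        cc = autocorrelation_CC(seq, DEFAULT_INDICES, 3)
        acc = autocorrelation_ACC(seq, DEFAULT_INDICES, 3)
        assert len(acc) == len(ac) + len(cc)
        assert np.allclose(acc.values, np.concatenate([ac.values, cc.values]))

    def test_cc_brute_force(self, rng):
        seq = random_protein(rng, 30)
        u1, u2 = DEFAULT_INDICES[:2]
        v = autocorrelation_CC(seq, [u1, u2], lag_max=3).values
        p1 = [u1.values[c] for c in seq.residues]
        p2 = [u2.values[c] for c in seq.residues]
        m1, m2 = sum(p1) / 30, sum(p2) / 30
        expected = []
        for a, b, ma, mb in ((p1, p2, m1, m2), (p2, p1, m2, m1)):
            for g in range(1, 4):
                expected.append(
                    sum((a[i] - ma) * (b[i + g] - mb) for i in range(30 - g)) / (30 - g)
                )
        assert np.allclose(v, expected, atol=1e-12)

    def test_pdt_brute_force_and_nonnegative(self, rng):
        seq = random_protein(rng, 30)
        idx = DEFAULT_INDICES[1]
        v = pdt(seq, [idx], lag_max=3).values
        p = [idx.values[c] for c in seq.residues]
        for g in range(1, 4):
            expected = sum((p[i] - p[i + g]) ** 2 for i in range(30 - g)) / (30 - g) / 2
            assert v[g - 1] == pytest.approx(expected, abs=1e-12)
        assert np.all(v >= 0.0)


def oracle_pc_pseaac(seq, indices, lam, w):
    """Naive-loop parallel pseudo-AAC."""
    L = len(seq)
    profiles = [[u.values[c] for c in seq.residues] for u in indices]
    freqs = [seq.residues.count(a) / L for a in AMINO_ACIDS]
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            total += sum((p[i] - p[i + j]) ** 2 for p in profiles) / len(profiles)
        thetas.append(total / (L - j))
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


class TestPseaac:
    def test_output_length(self, rng):
        assert len(pc_pseaac(random_protein(rng, 40), lam=3)) == 23

    @given(seq_strategy)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, seq):
        assert abs(pc_pseaac(seq, lam=2).values.sum() - 1.0) < 1e-12

    def test_homopolymer_reduces_to_composition(self):
        seq = ProteinSequence("s", "A" * 30)
        v = pc_pseaac(seq, lam=3).values
        assert v[0] == pytest.approx(1.0)
        assert np.allclose(v[1:], 0.0)

    def test_lam_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            pc_pseaac(random_protein(rng, 5), lam=5)

    def test_naive_oracle(self, rng):
        seq = random_protein(rng, 30)
        expected = oracle_pc_pseaac(seq, DEFAULT_INDICES, lam=3, w=0.05)
        assert np.allclose(pc_pseaac(seq, lam=3, w=0.05).values, expected, atol=1e-12)

    def test_sc_output_length(self, rng):
        assert len(sc_pseaac(random_protein(rng, 40), lam=3)) == 20 + 3 * 3

    def test_sc_single_index_equals_pc(self, rng):
        seq = random_protein(rng, 35)
        idx = [DEFAULT_INDICES[0]]
        assert np.allclose(
            sc_pseaac(seq, idx, lam=4).values, pc_pseaac(seq, idx, lam=4).values
        )

    def test_sc_naive_oracle(self, rng):
        seq = random_protein(rng, 30)
        lam, w = 3, 0.05
        L = 30
        freqs = [seq.residues.count(a) / L for a in AMINO_ACIDS]
        taus = []
        for j in range(1, lam + 1):
            for u in DEFAULT_INDICES:
                p = [u.values[c] for c in seq.residues]
                taus.append(sum((p[i] - p[i + j]) ** 2 for i in range(L - j)) / (L - j))
        denom = sum(freqs) + w * sum(taus)
        expected = [f / denom for f in freqs] + [w * t / denom for t in taus]
        assert np.allclose(sc_pseaac(seq, lam=lam, w=w).values, expected, atol=1e-12)

    def test_general_requires_indices(self, rng):
        with pytest.raises(ValueError, match="at least one"):
            pc_pseaac_general(random_protein(rng, 30), [])


class TestMethodCatalog:
    def test_22_entries(self):
        assert len(method_catalog()) == 22

    def test_5_groups(self):
        assert len({e.group for e in method_catalog()}) == 5

    def test_names_unique(self):
        names = [e.name for e in method_catalog()]
        assert len(set(names)) == 22

    def test_profile_and_structure_unsupported(self):
        for e in method_catalog():
            if e.group in ("profile-based", "predicted structure"):
                assert not e.supported
                assert e.reason_unsupported

    def test_ss_and_sasa_unsupported(self):
        by_name = {e.name: e for e in method_catalog()}
        assert not by_name["SS"].supported
        assert not by_name["SASA"].supported

    def test_group_sizes(self):
        from collections import Counter

        sizes = Counter(e.group for e in method_catalog())
        assert sizes["amino acid composition"] == 3
        assert sizes["autocorrelation"] == 4
        assert sizes["pseudo amino acid composition"] == 4
        assert sizes["profile-based"] == 9
        assert sizes["predicted structure"] == 2


class TestExtractPseCombined:
    def test_single_kmer1(self, rng):
        v = extract_pse_combined(random_protein(rng, 30), [("Kmer", {"k": 1})])
        assert len(v) == 20

    def test_additive_lengths(self, rng):
        v = extract_pse_combined(
            random_protein(rng, 30), [("Kmer", {"k": 2}), ("PC-PseAAC", {"lam": 2})]
        )
        assert len(v) == 400 + 22

    def test_concatenation_order(self, rng):
        seq = random_protein(rng, 30)
        v = extract_pse_combined(seq, DEFAULT_PSE_CONFIG)
        parts = np.concatenate(
            [kmer(seq, 2).values, pc_pseaac(seq, lam=2, w=0.05).values]
        )
        assert np.array_equal(v.values, parts)
        assert v.names[0].startswith("Kmer:")
        assert v.names[-1].startswith("PC-PseAAC:")

    def test_unsupported_method_raises_with_reason(self, rng):
        with pytest.raises(UnsupportedMethodError, match="PSSM"):
            extract_pse_combined(random_protein(rng, 30), [("AC-PSSM", {})])

    def test_unknown_method_raises(self, rng):
        with pytest.raises(ValueError, match="unknown method"):
            extract_pse_combined(random_protein(rng, 30), [("Frobnicate", {})])
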