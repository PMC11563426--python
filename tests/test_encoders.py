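"""Encoder unit and property tests.

The short-sequence composition encoders (AAC/DPC/TPC/CKSAAP) are checked
against an exhaustive brute-force counter implemented here from scratch; the
pseudo-amino-acid encoders are checked against a direct hand evaluation of
the defining formulas using the bundled property tables.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepstack._property_tables import (
    CONJOINT_TRIAD_CLASSES,
    CTD_PROPERTIES,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    RAAC_SCHEMES,
    SIDE_CHAIN_MASS,
    standardized,
)
from pepstack.encoders import (
    EncoderSpec,
    EncodingError,
    encode_aac,
    encode_apaac,
    encode_cksaap,
    encode_ctdc,
    encode_ctriad,
    encode_dataset,
    encode_dpc,
    encode_moran,
    encode_paac,
    encode_peptide,
    encode_raacc,
    encode_tpc,
)
from pepstack.peptide_io import ALPHABET, LabeledDataset, PeptideSequence

from conftest import POSITIVE_EXAMPLE

peptides = st.text(alphabet=ALPHABET, min_size=4, max_size=30)

#: default-parameter vector lengths, one per encoder
EXPECTED_LENGTHS = {
    "AAC": 20,
    "APAAC": 24,
    "CKSAAP": 1600,
    "CTDC": 39,
    "CTriad": 343,
    "DPC": 400,
    "Moran": 2,
    "PAAC": 22,
    "RAACC": 4,
    "TPC": 8000,
}


@pytest.mark.parametrize("name,length", sorted(EXPECTED_LENGTHS.items()))
def test_default_vector_lengths(name, length):
    """Each descriptor emits its documented feature count on a real peptide."""
    spec = EncoderSpec(name)
    vec = encode_peptide(POSITIVE_EXAMPLE, spec)
    assert len(vec) == length == spec.vector_length
    assert list(vec.index) == spec.feature_names


# ---------------------------------------------------------------------------
# brute-force oracle for the plain composition encoders


def brute_kmer_freq(seq: str, k: int, gap: int = 0) -> dict[str, float]:
    """Independent counter: frequency of each residue k-mer (with an optional
    gap between the two residues of a pair), by explicit enumeration."""
    counts: dict[str, float] = {}
    if k == 1:
        positions = [seq[i] for i in range(len(seq))]
    elif k == 2:
        positions = [seq[i] + seq[i + gap + 1] for i in range(len(seq) - gap - 1)]
    elif k == 3:
        positions = [seq[i : i + 3] for i in range(len(seq) - 2)]
    else:
        raise AssertionError
    for kmer in positions:
        counts[kmer] = counts.get(kmer, 0) + 1
    return {k_: v / len(positions) for k_, v in counts.items()}


def all_sequences(alphabet: str, max_len: int, min_len: int = 1):
    for L in range(min_len, max_len + 1):
        for tup in itertools.product(alphabet, repeat=L):
            yield "".join(tup)


class TestCompositionOracle:
    """Exhaustive agreement with the brute-force counter on {A,C,D} words."""

    def test_aac_matches_brute_force(self):
        names = list(ALPHABET)
        for seq in all_sequences("ACD", 6):
            expected = brute_kmer_freq(seq, 1)
            vec = encode_aac(seq)
            for i, aa in enumerate(names):
                assert vec[i] == pytest.approx(expected.get(aa, 0.0), abs=1e-12)

    def test_dpc_matches_brute_force(self):
        pairs = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]
        for seq in all_sequences("ACD", 6, min_len=2):
            expected = brute_kmer_freq(seq, 2)
            vec = encode_dpc(seq)
            for i, pr in enumerate(pairs):
                assert vec[i] == pytest.approx(expected.get(pr, 0.0), abs=1e-12)

    def test_tpc_matches_brute_force(self):
        triples = ["".join(t) for t in itertools.product(ALPHABET, repeat=3)]
        for seq in all_sequences("ACD", 6, min_len=3):
            expected = brute_kmer_freq(seq, 3)
            vec = encode_tpc(seq)
            nz = {i for i in range(8000) if vec[i] != 0}
            for i in nz | {triples.index(t) for t in expected}:
                assert vec[i] == pytest.approx(expected.get(triples[i], 0.0), abs=1e-12)

    def test_cksaap_matches_brute_force(self):
        pairs = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]
        gap_max = 2
        for seq in all_sequences("ACD", 6, min_len=gap_max + 2):
            vec = encode_cksaap(seq, gap_max=gap_max)
            for g in range(gap_max + 1):
                expected = brute_kmer_freq(seq, 2, gap=g)
                block = vec[g * 400 : (g + 1) * 400]
                for i, pr in enumerate(pairs):
                    assert block[i] == pytest.approx(expected.get(pr, 0.0), abs=1e-12)


class TestHandDerivedExamples:
    def test_aac_of_published_positive_example(self):
        vec = encode_peptide(POSITIVE_EXAMPLE, EncoderSpec("AAC"))
        L = 13
        expected = {"R": 2, "P": 2, "F": 2, "S": 2, "D": 1, "E": 1, "I": 1, "N": 1, "V": 1}
        for aa in ALPHABET:
            assert vec[f"AAC.{aa}"] == pytest.approx(expected.get(aa, 0) / L)

    def test_dpc_of_published_positive_example(self):
        vec = encode_peptide(POSITIVE_EXAMPLE, EncoderSpec("DPC"))
        assert vec["DPC.PF"] == pytest.approx(2 / 12)
        assert vec["DPC.RP"] == pytest.approx(1 / 12)

    def test_dpc_homopolymer(self):
        vec = encode_peptide("AAAA", EncoderSpec("DPC"))
        assert vec["DPC.AA"] == 1.0 and vec.sum() == pytest.approx(1.0)

    def test_cksaap_acac_both_gaps(self):
        vec = encode_peptide("ACAC", EncoderSpec("CKSAAP", {"gap_max": 1}))
        assert vec["CKSAAP.g0.AC"] == pytest.approx(2 / 3)
        assert vec["CKSAAP.g0.CA"] == pytest.approx(1 / 3)
        assert vec["CKSAAP.g1.AA"] == pytest.approx(1 / 2)
        assert vec["CKSAAP.g1.CC"] == pytest.approx(1 / 2)

    def test_cksaap_homopolymer(self):
        vec = encode_cksaap("AAAA", gap_max=1)
        assert vec[0] == 1.0 and vec[400] == 1.0  # AA at g=0 and g=1


def _hand_paac(seq: str, lam: int, w: float) -> np.ndarray:
    """Direct evaluation of the pseudo-amino-acid composition definition."""
    h1 = standardized(HYDROPHOBICITY)
    h2 = standardized(HYDROPHILICITY)
    m = standardized(SIDE_CHAIN_MASS)
    L = len(seq)
    thetas = []
    for d in range(1, lam + 1):
        vals = []
        for i in range(L - d):
            a, b = seq[i], seq[i + d]
            vals.append(
                ((h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2) / 3
            )
        thetas.append(sum(vals) / (L - d))
    f = [seq.count(aa) / L for aa in ALPHABET]
    denom = 1.0 + w * sum(thetas)
    return np.array([x / denom for x in f] + [w * t / denom for t in thetas])


def _hand_apaac(seq: str, lam: int, w: float) -> np.ndarray:
    h1 = standardized(HYDROPHOBICITY)
    h2 = standardized(HYDROPHILICITY)
    L = len(seq)
    taus = []
    for d in range(1, lam + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + d]] for i in range(L - d)) / (L - d))
        taus.append(sum(h2[seq[i]] * h2[seq[i + d]] for i in range(L - d)) / (L - d))
    f = [seq.count(aa) / L for aa in ALPHABET]
    denom = 1.0 + w * sum(taus)
    return np.array([x / denom for x in f] + [w * t / denom for t in taus])


class TestPseudoComposition:
    def test_paac_golden_acd_lambda1(self):
        np.testing.assert_allclose(
            encode_paac("ACD", lam=1, w=0.05), _hand_paac("ACD", 1, 0.05), atol=1e-12
        )

    def test_paac_hand_agreement_on_longer_peptide(self):
        np.testing.assert_allclose(
            encode_paac(POSITIVE_EXAMPLE, lam=2, w=0.05),
            _hand_paac(POSITIVE_EXAMPLE, 2, 0.05),
            atol=1e-12,
        )

    def test_apaac_golden_acd_lambda1(self):
        vec = encode_apaac("ACD", lam=1, w=0.05)
        assert len(vec) == 22
        np.testing.assert_allclose(vec, _hand_apaac("ACD", 1, 0.05), atol=1e-12)

    @given(peptides)
    @settings(max_examples=50, derandomize=True)
    def test_lambda_zero_reduces_to_aac(self, seq):
        np.testing.assert_allclose(encode_paac(seq, lam=0), encode_aac(seq), atol=1e-12)
        np.testing.assert_allclose(encode_apaac(seq, lam=0), encode_aac(seq), atol=1e-12)

    @given(peptides)
    @settings(max_examples=50, derandomize=True)
    def test_paac_sums_to_one(self, seq):
        assert encode_paac(seq, lam=2).sum() == pytest.approx(1.0, abs=1e-9)

    def test_length_precondition(self):
        with pytest.raises(EncodingError):
            encode_paac("AC", lam=2)


class TestCtdc:
    def test_groupings_partition_alphabet(self):
        for prop, groups in CTD_PROPERTIES.items():
            joined = "".join(groups)
            assert sorted(joined) == sorted(ALPHABET), prop

    def test_homopolymer_concentrates_one_group(self):
        vec = encode_ctdc("AAAAA")
        for p in range(13):
            block = vec[3 * p : 3 * p + 3]
            assert sorted(block) == [0.0, 0.0, 1.0]

    @given(peptides)
    @settings(max_examples=50, derandomize=True)
    def test_property_blocks_sum_to_one(self, seq):
        vec = encode_ctdc(seq)
        for p in range(13):
            assert vec[3 * p : 3 * p + 3].sum() == pytest.approx(1.0, abs=1e-9)


class TestCtriad:
    def test_classes_partition_alphabet(self):
        assert sorted("".join(CONJOINT_TRIAD_CLASSES)) == sorted(ALPHABET)

    def test_aaa_single_nonzero_bin(self):
        vec = encode_ctriad("AAA")
        assert (vec != 0).sum() == 1

    @given(peptides)
    @settings(max_examples=50, derandomize=True)
    def test_raw_window_count_is_length_minus_two(self, seq):
        freq = encode_ctriad(seq, normalization="frequency")
        assert freq.sum() * (len(seq) - 2) == pytest.approx(len(seq) - 2)

    def test_minmax_range(self):
        vec = encode_ctriad(POSITIVE_EXAMPLE)
        assert vec.min() >= 0.0 and vec.max() <= 1.0


class TestMoran:
    def test_homopolymer_zero_by_convention(self):
        np.testing.assert_array_equal(encode_moran("AAAAAA", nlag=2), 0.0)

    def test_alternating_negative_lag1_matches_hand_formula(self):
        seq = "ARARAR"  # two residues of opposite hydrophobicity
        h = standardized(HYDROPHOBICITY)
        x = np.array([h[c] for c in seq])
        xbar = x.mean()
        var = ((x - xbar) ** 2).mean()
        expected_lag1 = ((x[:-1] - xbar) * (x[1:] - xbar)).mean() / var
        vec = encode_moran(seq, nlag=1)
        assert vec[0] == pytest.approx(expected_lag1)
        assert vec[0] < 0

    def test_too_short_is_error(self):
        with pytest.raises(EncodingError):
            encode_moran("AC", nlag=2)


class TestRaacc:
    def test_schemes_partition_alphabet(self):
        for scheme in RAAC_SCHEMES.values():
            assert sorted("".join(scheme)) == sorted(ALPHABET)

    def test_homopolymer(self):
        vec = encode_raacc("DDDD")
        assert sorted(vec) == [0.0, 0.0, 0.0, 1.0]

    @given(peptides)
    @settings(max_examples=50, derandomize=True)
    def test_sums_to_one(self, seq):
        assert encode_raacc(seq).sum() == pytest.approx(1.0, abs=1e-9)


@given(peptides)
@settings(max_examples=40, derandomize=True)
def test_composition_encoders_nonnegative_sum_to_one(seq):
    """AAC/DPC/TPC/RAACC and each CKSAAP gap-block are probability vectors."""
    for vec in (encode_aac(seq), encode_dpc(seq), encode_tpc(seq), encode_raacc(seq)):
        assert vec.min() >= 0
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
    ck = encode_cksaap(seq, gap_max=2)
    for g in range(3):
        assert ck[g * 400 : (g + 1) * 400].sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("name", sorted(EXPECTED_LENGTHS))
def test_determinism(name):
    spec = EncoderSpec(name)
    a = spec.encode(POSITIVE_EXAMPLE)
    b = spec.encode(POSITIVE_EXAMPLE)
    np.testing.assert_array_equal(a, b)


class TestEncodeDataset:
    def test_aac_matrix_shape(self, example_dataset):
        m = encode_dataset(example_dataset, [EncoderSpec("AAC")])
        assert m.shape == (2, 20)
        assert m.row_ids == ["pos1", "neg1"]

    def test_aac_dpc_concatenation(self, example_dataset):
        m = encode_dataset(example_dataset, [EncoderSpec("AAC"), EncoderSpec("DPC")])
        assert m.shape == (2, 420)
        assert m.col_names[0] == "AAC.A" and m.col_names[20] == "DPC.AA"

    def test_empty_spec_list_is_error(self, example_dataset):
        with pytest.raises(EncodingError):
            encode_dataset(example_dataset, [])

    def test_too_short_sequence_lists_offender(self):
        ds = LabeledDataset(
            [PeptideSequence("ok", "ACDEF"), PeptideSequence("tiny", "AC")],
            np.array([1, 0]),
        )
        with pytest.raises(EncodingError, match="tiny"):
            encode_dataset(ds, [EncoderSpec("CKSAAP")])

    def test_unknown_encoder_rejected(self):
        with pytest.raises(EncodingError, match="unknown encoder"):
            EncoderSpec("BLOSUM")
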