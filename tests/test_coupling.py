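import math

import numpy as np
import pytest

from profaln.coupling import (default_n_pairs, ec_traceback,
                              mutual_information_matrix, read_partner_map,
                              select_partners, write_partner_map)
from profaln.errors import ValidationError
from profaln.mac import MacMatrix, forward_backward, mac_align
from profaln.profile_model import MSA
from profaln.scoring import ScoringWeights
from profaln.synthetic import random_profile


class TestMutualInformation:
    def test_independent_columns_zero(self):
        # all four symbol combinations equally frequent -> independence
        msa = MSA(ids=list("abcd"), rows=["AA", "AC", "CA", "CC"])
        mi = mutual_information_matrix(msa, pseudocount=0.0)
        assert abs(mi[0, 1]) < 1e-12

    def test_perfect_covariation_ln2(self):
        msa = MSA(ids=list("abcd"), rows=["AA", "AA", "CC", "CC"])
        mi = mutual_information_matrix(msa, pseudocount=0.0)
        assert mi[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(0)
        from profaln.profile_model import AMINO_ACIDS
        alphabet = list(AMINO_ACIDS + "-")
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rows = ["".join(rng.choice(alphabet, size=7)) for _ in range(10)]
            msa = MSA(ids=[f"s{k}" for k in range(10)], rows=rows)
            mi = mutual_information_matrix(msa)
            np.testing.assert_allclose(mi, mi.T, atol=1e-12)
            assert mi.min() >= -1e-12

    def test_single_sequence_warns_and_zeroes(self, caplog):
        msa = MSA(ids=["a"], rows=["ACDEF"])
        with caplog.at_level("WARNING"):
            mi = mutual_information_matrix(msa)
        assert np.all(mi == 0.0)
        assert "single sequence" in caplog.text

    def test_gap_counts_as_symbol(self):
        # covariation carried entirely by the gap symbol
        msa = MSA(ids=list("abcd"), rows=["A-", "A-", "-A", "-A"])
        mi = mutual_information_matrix(msa, pseudocount=0.0)
        assert mi[0, 1] == pytest.approx(math.log(2), abs=1e-12)


class TestSelectPartners:
    def test_zero_pairs(self):
        mi = np.ones((10, 10))
        assert select_partners(mi, n_pairs=0) == {}

    def test_single_dominant_pair(self):
        mi = np.zeros((12, 12))
        mi[2, 8] = mi[8, 2] = 5.0  # columns 3 and 9, 1-based
        partners = select_partners(mi, n_pairs=1, min_separation=5)
        assert partners == {3: 9, 9: 3}

    def test_tie_breaks_lexicographically(self):
        mi = np.zeros((12, 12))
        mi[1, 7] = mi[7, 1] = 2.0
        mi[0, 6] = mi[6, 0] = 2.0
        partners = select_partners(mi, n_pairs=1, min_separation=5)
        assert partners == {1: 7, 7: 1}

    def test_min_separation_excludes_close_pairs(self):
        mi = np.zeros((10, 10))
        mi[0, 2] = mi[2, 0] = 9.0
        mi[0, 8] = mi[8, 0] = 1.0
        partners = select_partners(mi, n_pairs=1, min_separation=5)
        assert partners == {1: 9, 9: 1}

    def test_each_column_used_once(self):
        mi = np.zeros((20, 20))
        mi[0, 10] = mi[10, 0] = 3.0
        mi[0, 15] = mi[15, 0] = 2.0
        mi[5, 15] = mi[15, 5] = 1.0
        partners = select_partners(mi, n_pairs=3, min_separation=5)
        assert partners == {1: 11, 11: 1, 6: 16, 16: 6}

    def test_default_n_pairs(self):
        assert default_n_pairs(40) == 4
        assert default_n_pairs(41) == 5

    def test_asymmetric_rejected(self):
        mi = np.zeros((5, 5))
        mi[0, 4] = 1.0
        with pytest.raises(ValidationError):
            select_partners(mi, 1)

    def test_partner_map_roundtrip(self, tmp_path):
        partners = {3: 9, 9: 3, 1: 7, 7: 1}
        path = tmp_path / "partners.tsv"
        write_partner_map(partners, path)
        assert read_partner_map(path) == partners


def _hand_fixture():
    """AS / posterior fixture where the coupling bonus flips the move at
    (2, 2) from 'left' to 'diagonal'.

    Pass 1 path: (3,3) diag, (2,2) left (0.71 > 0.70), (2,1) diag ->
    pairs {(3,3), (2,1)}.  Partners k_q = k_t = {1: 3, 3: 1}; pass 1 aligns
    (3,3), so cell (1,1) earns a bonus of 2 * w_ec, lifting the diagonal
    candidate at (2,2) to 0.70 + 2 * w_ec > 0.71 for w_ec > 0.005.
    """
    AS = np.zeros((4, 4))
    AS[1, 1] = 0.4
    AS[1, 2] = 0.3
    AS[2, 1] = 0.81
    AS[2, 2] = 0.71
    AS[1, 3] = AS[3, 1] = 0.1
    AS[3, 2] = AS[2, 3] = 0.5
    AS[3, 3] = 1.31
    post = np.full((3, 3), 0.01)
    post[0, 0] = 0.6
    post[1, 0] = 0.9
    post[1, 1] = 0.5
    post[2, 2] = 0.8
    mac = MacMatrix(AS=AS, best_cell=(3, 3), mact=0.2)
    k = {1: 3, 3: 1}
    return mac, post, k


class TestEcTraceback:
    def test_reduction_with_zero_weight(self):
        mac, post, k = _hand_fixture()
        plain = ec_traceback(mac, post, {}, {}, 0.5)
        zero_w = ec_traceback(mac, post, k, k, 0.0)
        assert plain.columns == zero_w.columns
        assert plain.matched_pairs == [(2, 1), (3, 3)]

    def test_empty_partner_maps_reduce(self):
        mac, post, k = _hand_fixture()
        a = ec_traceback(mac, post, {}, {}, 0.1)
        b = ec_traceback(mac, post, k, k, 0.0)
        assert a.columns == b.columns

    def test_bonus_flips_one_decision(self):
        mac, post, k = _hand_fixture()
        before = ec_traceback(mac, post, k, k, 0.0)
        after = ec_traceback(mac, post, k, k, 0.1)
        assert (2, 2) not in before.matched_pairs
        assert (2, 2) in after.matched_pairs
        assert (2, 1) in before.matched_pairs
        assert (3, 3) in before.matched_pairs
        assert (3, 3) in after.matched_pairs

    def test_pipeline_reduction_bitwise(self):
        rng = np.random.default_rng(4)
        q = random_profile(rng, 10, "q")
        t = random_profile(rng, 10, "t")
        post = forward_backward(q, t, ScoringWeights())
        mat, plain = mac_align(post, 0.3501, "q", "t")
        k = {1: 8, 8: 1}
        again = ec_traceback(mat, post, k, k, 0.0, "q", "t")
        assert again.columns == plain.columns
        again = ec_traceback(mat, post, {}, {}, 0.1, "q", "t")
        assert again.columns == plain.columns

    def test_augmented_alignment_is_valid(self):
        rng = np.random.default_rng(5)
        q = random_profile(rng, 12, "q")
        t = random_profile(rng, 12, "t")
        post = forward_backward(q, t, ScoringWeights())
        mat, _ = mac_align(post, 0.3501)
        k_q = {1: 7, 7: 1, 2: 9, 9: 2}
        k_t = {3: 10, 10: 3}
        aln = ec_traceback(mat, post, k_q, k_t, 0.3)
        aln.validate()

    def test_planted_coupling_is_top_mi_pair(self):
        import profaln as pa
        pair = pa.generate_pair(pa.SyntheticParams(
            seed=3, length=30, n_sequences=64,
            coupling_strength=1.0, coupled_pairs=((4, 12),)))
        mi = mutual_information_matrix(pair.msa_q, pseudocount=0.0)
        i, j = np.unravel_index(np.argmax(mi), mi.shape)
        assert {int(i) + 1, int(j) + 1} == {4, 12}
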