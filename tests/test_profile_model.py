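import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from profaln.errors import DimensionError, ParseError, ValidationError
from profaln.profile_model import (AMINO_ACIDS, MSA, BackgroundModel,
                                   ProfileHMM, build_profile, read_msa,
                                   read_profile, write_msa, write_profile)
from profaln.synthetic import random_profile


# ---------------------------------------------------------------------- MSA

class TestReadMSA:
    def test_identical_records(self, tmp_path):
        path = tmp_path / "m.fasta"
        path.write_text(">a\nACD\n>b\nACD\n>c\nACD\n")
        msa = read_msa(path)
        assert msa.n_seqs == 3
        assert msa.n_cols == 3

    def test_a3m_lowercase_inserts_removed(self, tmp_path):
        path = tmp_path / "m.a3m"
        path.write_text(">a\nAcD\n>b\nAD\n")
        msa = read_msa(path, format="a3m")
        assert msa.n_cols == 2
        assert msa.rows == ["AD", "AD"]

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ParseError):
            read_msa(path)

    def test_garbage_before_header_names_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACDEF\n>a\nACD\n")
        with pytest.raises(ParseError, match=":1:"):
            read_msa(path)

    def test_ragged_fasta_is_dimension_error(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nACD\n>b\nAC\n")
        with pytest.raises(DimensionError):
            read_msa(path)

    def test_nonstandard_letters_become_unknown(self, tmp_path):
        path = tmp_path / "m.fasta"
        path.write_text(">a\nABZ\n")
        msa = read_msa(path)
        assert msa.rows == ["AXX"]

    def test_roundtrip(self, tmp_path):
        msa = MSA(ids=["a", "b"], rows=["AC-D", "A-CD"])
        path = tmp_path / "rt.fasta"
        write_msa(msa, path)
        again = read_msa(path)
        assert again.rows == msa.rows
        assert again.ids == msa.ids


# ------------------------------------------------------------- BackgroundModel

def test_background_default_valid():
    bg = BackgroundModel.default()
    assert bg.frequencies.shape == (20,)
    assert abs(bg.frequencies.sum() - 1.0) < 1e-9
    assert np.all(bg.frequencies > 0)


def test_background_rejects_nonpositive():
    f = np.full(20, 0.05)
    f[0] = 0.0
    f[1] = 0.1
    with pytest.raises(ValidationError):
        BackgroundModel(f)


# --------------------------------------------------------------- build_profile

class TestBuildProfile:
    def test_all_a_column_tau0(self, uniform_bg):
        msa = MSA(ids=["a", "b"], rows=["A", "A"])
        p = build_profile(msa, uniform_bg, pseudocount_admixture=0.0)
        a = AMINO_ACIDS.index("A")
        assert p.emissions[0, a] == pytest.approx(1.0, abs=1e-4)
        assert p.emissions[0, a] > 0.999

    def test_half_half_column(self, uniform_bg):
        msa = MSA(ids=list("abcd"), rows=["A", "A", "C", "C"])
        p = build_profile(msa, uniform_bg, pseudocount_admixture=0.0)
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert p.emissions[0, a] == pytest.approx(0.5, abs=1e-4)
        assert p.emissions[0, c] == pytest.approx(0.5, abs=1e-4)

    def test_admixture_hand_value(self, uniform_bg):
        # (1 - 0.5) * 1 + 0.5 * 0.05 = 0.525; no entry is floored here
        msa = MSA(ids=["a"], rows=["A"])
        p = build_profile(msa, uniform_bg, pseudocount_admixture=0.5)
        assert p.emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(0.525, abs=1e-12)

    def test_tau1_equals_background(self, default_bg):
        msa = MSA(ids=["a", "b"], rows=["AC", "CA"])
        p = build_profile(msa, default_bg, pseudocount_admixture=1.0)
        np.testing.assert_allclose(p.emissions, np.tile(default_bg.frequencies, (2, 1)),
                                   atol=1e-12)

    def test_all_gap_column_dropped(self, default_bg, caplog):
        msa = MSA(ids=["a", "b"], rows=["A-C", "A-C"])
        with caplog.at_level("WARNING"):
            p = build_profile(msa, default_bg)
        assert p.length == 2
        assert "all-gap" in caplog.text

    def test_gapped_msa_estimates_transitions(self, default_bg):
        msa = MSA(ids=list("abcd"), rows=["AC", "A-", "A-", "AC"])
        p = build_profile(msa, default_bg)
        # column 1: 2 M->M and 2 M->D observed (plus Laplace 1 each)
        from profaln.profile_model import T_MD, T_MM
        assert p.transitions[0, T_MD] > 0.2
        assert p.transitions[0, T_MM] + p.transitions[0, T_MD] == pytest.approx(0.985)

    def test_bad_tau(self, default_bg):
        msa = MSA(ids=["a"], rows=["A"])
        with pytest.raises(ValidationError):
            build_profile(msa, default_bg, pseudocount_admixture=1.5)

    @settings(max_examples=30, deadline=None)
    @given(
        nseq=st.integers(1, 6),
        ncol=st.integers(1, 8),
        tau=st.floats(0.0, 1.0),
        seed=st.integers(0, 10_000),
        weighting=st.sampled_from(["uniform", "position-based"]),
    )
    def test_output_always_valid(self, nseq, ncol, tau, seed, weighting):
        rng = np.random.default_rng(seed)
        alphabet = AMINO_ACIDS + "-"
        rows = ["".join(rng.choice(list(alphabet), size=ncol)) for _ in range(nseq)]
        if all(set(r) <= {"-"} for r in rows):
            rows[0] = "A" * ncol
        msa = MSA(ids=[f"s{k}" for k in range(nseq)], rows=rows)
        try:
            p = build_profile(msa, pseudocount_admixture=tau, weighting=weighting)
        except ValidationError:
            # only legal failure: nothing but gap columns
            assert all(all(ch == "-" for ch in col) for col in zip(*rows))
            return
        p.validate()
        assert np.all(p.emissions >= 1e-7)


# ----------------------------------------------------------------- profile I/O

class TestProfileIO:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        p = random_profile(rng, 9, "rt", with_annotation=False)
        path = tmp_path / "p.prof"
        write_profile(p, path)
        q, bg = read_profile(path)
        np.testing.assert_allclose(q.emissions, p.emissions, atol=1e-12, rtol=0)
        np.testing.assert_allclose(q.transitions, p.transitions, atol=1e-12, rtol=0)
        assert q.name == "rt"

    def test_bad_emission_row_rejected(self, tmp_path):
        rng = np.random.default_rng(8)
        p = random_profile(rng, 3, with_annotation=False)
        path = tmp_path / "p.prof"
        write_profile(p, path)
        lines = path.read_text().splitlines()
        # halve every emission in column 2's line
        fields = lines[-2].split("\t")
        fields[1:21] = [f"{float(v) / 2:.17g}" for v in fields[1:21]]
        lines[-2] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="row"):
            read_profile(path)

    def test_zero_length_rejected(self, tmp_path):
        path = tmp_path / "p.prof"
        path.write_text(
            "# profaln profile format 1\nname\tx\nlength\t0\n"
            "alphabet\t" + AMINO_ACIDS + "\n"
            "background\t" + "\t".join(["0.05"] * 20) + "\n"
        )
        with pytest.raises(ValidationError):
            read_profile(path)

    def test_not_a_profile_file(self, tmp_path):
        path = tmp_path / "p.prof"
        path.write_text("hello\n")
        with pytest.raises(ParseError):
            read_profile(path)


# ------------------------------------------------------------------ ProfileHMM

def test_profile_invariants_enforced():
    em = np.full((2, 20), 0.05)
    tr = np.tile(np.array([0.97, 0.015, 0.015, 0.5, 0.5, 0.5, 0.5]), (2, 1))
    ProfileHMM("ok", em, tr)  # fine
    bad = em.copy()
    bad[1, 0] = 0.5
    with pytest.raises(ValidationError):
        ProfileHMM("bad", bad, tr)
    bad_tr = tr.copy()
    bad_tr[0, 0] = 0.5
    with pytest.raises(ValidationError):
        ProfileHMM("bad", em, bad_tr)


def test_annotation_length_mismatch():
    from profaln.annotations import StructuralAnnotation
    em = np.full((3, 20), 0.05)
    tr = np.tile(np.array([0.97, 0.015, 0.015, 0.5, 0.5, 0.5, 0.5]), (3, 1))
    p = ProfileHMM("p", em, tr)
    with pytest.raises(DimensionError):
        p.attach_annotation(StructuralAnnotation.empty(4))
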