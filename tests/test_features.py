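"""Feature extractors against brute-force oracles and their normalization laws."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import recspot as rs
from recspot.errors import ParameterError, SequenceTooShortError
from recspot.features import all_kmers, default_property_table

dna = st.text(alphabet="ACGT", min_size=10, max_size=30)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the vectorized implementations)


def naive_gdc(seq: str, gap: int) -> dict[str, float]:
    windows = len(seq) - gap - 1
    out = {a + b: 0.0 for a in "ACGT" for b in "ACGT"}
    if windows <= 0:
        return out
    for i in range(windows):
        out[seq[i] + seq[i + gap + 1]] += 1
    return {k: v / windows for k, v in out.items()}


def naive_rcc(seq: str, k: int) -> dict[str, float]:
    out = {c: 0.0 for c in rs.canonical_classes(k)}
    for i in range(len(seq) - k + 1):
        out[min(seq[i : i + k], rs.reverse_complement(seq[i : i + k]))] += 1
    return {c: v / len(seq) for c, v in out.items()}


def naive_theta(seq: str, j: int, table: np.ndarray) -> float:
    tris = [seq[i : i + 3] for i in range(len(seq) - 2)]
    idx = {m: i for i, m in enumerate(all_kmers(3))}
    total = 0.0
    for i in range(len(tris) - j):
        diff = table[idx[tris[i]]] - table[idx[tris[i + j]]]
        total += float(np.mean(diff**2))
    return total / (len(tris) - j)


# ---------------------------------------------------------------------------
# GDC


class TestGdc:
    def test_homopolymer(self):
        v = rs.gdc_features(rs.DnaSequence("h", "AAAA"), rs.GdcParams(gaps=(0,)))
        assert v["GDC|AA|g0"] == 1.0 and v.values.sum() == 1.0

    @pytest.mark.parametrize("gap", [0, 1, 2])
    def test_matches_bruteforce_on_examples(self, gap):
        seq = "ACGTACGT"
        v = rs.gdc_features(rs.DnaSequence("x", seq), rs.GdcParams(gaps=(gap,)))
        expect = naive_gdc(seq, gap)
        for pair, val in expect.items():
            assert v[f"GDC|{pair}|g{gap}"] == pytest.approx(val)

    def test_spec_worked_values(self):
        v = rs.gdc_features(rs.DnaSequence("x", "ACGTACGT"))
        assert v["GDC|AC|g0"] == pytest.approx(2 / 7)
        assert v["GDC|TA|g0"] == pytest.approx(1 / 7)
        assert v["GDC|AG|g1"] == pytest.approx(2 / 6)
        assert v["GDC|GA|g1"] == pytest.approx(1 / 6)

    def test_default_dimension_is_128(self):
        v = rs.gdc_features(rs.DnaSequence("x", "ACGTACGTACGT"))
        assert len(v) == 128

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_per_gap_sums_to_one(self, s):
        params = rs.GdcParams(gaps=(0, 1, 2, 3))
        v = rs.gdc_features(rs.DnaSequence("x", s), params)
        for gi in range(4):
            block = v.values[gi * 16 : (gi + 1) * 16]
            assert block.sum() == pytest.approx(1.0, abs=1e-12)

    def test_short_sequence_zero_fills_large_gaps(self, caplog):
        v = rs.gdc_features(rs.DnaSequence("s", "ACGTA"), rs.GdcParams(gaps=(0, 7)))
        assert v.values[16:].sum() == 0.0 and v.values[:16].sum() == pytest.approx(1.0)

    def test_all_gaps_too_large_raises(self):
        with pytest.raises(SequenceTooShortError):
            rs.gdc_features(rs.DnaSequence("s", "ACG"), rs.GdcParams(gaps=(5,)))


# ---------------------------------------------------------------------------
# canonical k-mers and RCC


class TestCanonical:
    def test_examples(self):
        assert rs.canonical_kmer("CGT") == "ACG"
        assert rs.canonical_kmer("ACGT") == "ACGT"
        assert rs.canonical_kmer(rs.canonical_kmer("TTTT")) == rs.canonical_kmer("TTTT")

    def test_class_counts_by_enumeration(self):
        """32 / 136 / 512 canonical classes; 16 palindromic 4-mers."""
        for k, expected in ((3, 32), (4, 136), (5, 512)):
            images = {rs.canonical_kmer("".join(p))
                      for p in itertools.product("ACGT", repeat=k)}
            assert len(images) == expected
            assert images == set(rs.canonical_classes(k))
        pal4 = [m for m in all_kmers(4) if m == rs.reverse_complement(m)]
        assert len(pal4) == 16


class TestRcc:
    def test_single_window(self):
        v = rs.rcc_features(rs.DnaSequence("x", "ACG"), rs.RccParams(ks=(3,)))
        assert v["RCC|3|ACG"] == pytest.approx(1 / 3)
        assert v.values.sum() == pytest.approx(1 / 3)

    def test_default_dimension_is_680(self):
        v = rs.rcc_features(rs.DnaSequence("x", "ACGTACGTAC"))
        assert len(v) == 680

    def test_matches_bruteforce(self, random_sequences):
        for rec in random_sequences[:30]:
            v = rs.rcc_features(rec, rs.RccParams(ks=(3, 4)))
            expect = {**{f"RCC|3|{c}": x for c, x in naive_rcc(rec.residues, 3).items()},
                      **{f"RCC|4|{c}": x for c, x in naive_rcc(rec.residues, 4).items()}}
            np.testing.assert_allclose(v.values, [expect[n] for n in v.names], atol=1e-12)

    def test_strand_invariance(self, random_sequences):
        for rec in random_sequences[:50]:
            v1 = rs.rcc_features(rec)
            v2 = rs.rcc_features(rec.reverse_complement())
            np.testing.assert_allclose(v1.values, v2.values, atol=1e-12)

    def test_per_window_option(self):
        v = rs.rcc_features(
            rs.DnaSequence("x", "ACG"), rs.RccParams(ks=(3,), normalization="per-window")
        )
        assert v["RCC|3|ACG"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# TNC / PseTNC


class TestTnc:
    def test_homopolymer(self):
        v = rs.tnc_frequencies(rs.DnaSequence("x", "AAAA"))
        assert v["TNC|AAA"] == 1.0

    def test_three_windows(self):
        v = rs.tnc_frequencies(rs.DnaSequence("x", "ACGTA"))
        for m in ("ACG", "CGT", "GTA"):
            assert v[f"TNC|{m}"] == pytest.approx(1 / 3)

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_sums_to_one(self, s):
        assert rs.tnc_frequencies(rs.DnaSequence("x", s)).values.sum() == pytest.approx(
            1.0, abs=1e-12
        )


class TestTheta:
    def test_homopolymer_is_zero(self):
        for j in (1, 2, 3):
            assert rs.theta_correlation(rs.DnaSequence("x", "AAAAAA"), j) == 0.0

    def test_matches_bruteforce(self, random_sequences):
        table = default_property_table()
        for rec in random_sequences[:20]:
            got = rs.theta_correlation(rec, 1)
            assert got == pytest.approx(naive_theta(rec.residues, 1, table))
            assert got >= 0.0

    def test_tier_out_of_range(self):
        with pytest.raises(ParameterError):
            rs.theta_correlation(rs.DnaSequence("x", "ACGTA"), j=3)


class TestPsetnc:
    def test_default_dimension_is_66(self):
        v = rs.psetnc_features(rs.DnaSequence("x", "ACGTACGTAC"))
        assert len(v) == 66

    def test_lam_zero_reduces_to_tnc(self, random_sequences):
        for rec in random_sequences[:10]:
            p = rs.psetnc_features(rec, rs.PsetncParams(lam=0))
            t = rs.tnc_frequencies(rec)
            np.testing.assert_allclose(p.values, t.values, atol=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_sums_to_one_and_nonnegative(self, s):
        v = rs.psetnc_features(rs.DnaSequence("x", s))
        assert v.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert (v.values >= 0).all()

    def test_weight_monotonically_raises_tier_mass(self):
        rec = rs.DnaSequence("x", "ACGTTGCAACGTGGCA")
        masses = []
        for w in (0.05, 0.1, 0.5, 1.0):
            v = rs.psetnc_features(rec, rs.PsetncParams(lam=2, w=w))
            masses.append(v.values[64:].sum())
        assert all(a < b for a, b in zip(masses, masses[1:]))

    def test_too_short_for_lam(self):
        with pytest.raises(SequenceTooShortError):
            rs.psetnc_features(rs.DnaSequence("x", "ACGT"), rs.PsetncParams(lam=5))

    def test_custom_property_table_is_standardized(self):
        raw = np.arange(64 * 2, dtype=float).reshape(64, 2)
        params = rs.PsetncParams(lam=1, property_table=raw)
        assert params.table().mean(axis=0) == pytest.approx([0, 0], abs=1e-12)
        assert params.table().std(axis=0) == pytest.approx([1, 1], abs=1e-12)


# ---------------------------------------------------------------------------
# k-mer bank and dataset-level extraction


class TestBank:
    def test_default_dimension(self):
        v = rs.kmer_bank_features(rs.DnaSequence("x", "ACGTACGTAC"))
        assert len(v) == 4 + 16 + 64 + 256 + 1024 == 1364

    def test_homopolymer_support(self):
        v = rs.kmer_bank_features(rs.DnaSequence("x", "AAAAAA"))
        nz = {n for n, val in v.as_dict().items() if val > 0}
        assert nz == {f"KMER|{k}|{'A' * k}" for k in range(1, 6)}

    def test_per_k_sums(self, random_sequences):
        rec = random_sequences[0]
        v = rs.kmer_bank_features(rec)
        off = 0
        for k in range(1, 6):
            assert v.values[off : off + 4**k].sum() == pytest.approx(1.0, abs=1e-12)
            off += 4**k


class TestExtractBlock:
    @pytest.mark.parametrize(
        "method,dim", [("gdc", 128), ("rcc", 680), ("psetnc", 66), ("bank", 1364)]
    )
    def test_shapes_and_alignment(self, small_labeled_dataset, method, dim):
        m = rs.extract_block(small_labeled_dataset, method)
        assert m.shape == (len(small_labeled_dataset), dim)
        assert m.sample_ids == small_labeled_dataset.ids
        assert m.labels == [r.label for r in small_labeled_dataset]

    def test_block_tags(self, small_labeled_dataset):
        tags = {m: rs.extract_block(small_labeled_dataset, m).block_tag
                for m in ("gdc", "rcc", "psetnc", "bank")}
        assert tags == {"gdc": "G", "rcc": "R", "psetnc": "P", "bank": "H"}

    def test_tsv_roundtrip(self, small_labeled_dataset, tmp_path):
        m = rs.extract_block(small_labeled_dataset.subset(range(6)), "gdc")
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = rs.FeatureMatrix.from_tsv(p, block_tag="G")
        assert back.sample_ids == m.sample_ids
        assert back.feature_names == m.feature_names
        assert back.labels == m.labels
        np.testing.assert_allclose(back.values, m.values, rtol=1e-11)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ParameterError):
            rs.extract_block(rs.SequenceDataset([]), "gdc")
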