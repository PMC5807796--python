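"""BWT construction, RLE serialization and FM-index query tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrcorrect import (
    KmerQuery,
    RleBwt,
    build_fm_index,
    build_msbwt,
    load_rle,
    save_rle,
)
from lrcorrect._codec import decode, encode, revcomp

from .oracles import naive_count, naive_msbwt
from .conftest import random_reads

DNA = st.text(alphabet="ACGT", min_size=1, max_size=30)


def bwt_string(bwt: RleBwt) -> str:
    return decode(bwt.decode())


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildMsbwt:
    def test_single_read(self):
        assert bwt_string(build_msbwt(["ACGT"])) == "T$ACG"

    def test_empty_collection(self):
        bwt = build_msbwt([])
        assert len(bwt) == 0 and bwt.num_strings == 0

    def test_duplicate_reads_double_totals(self):
        one = build_msbwt(["ACGT"]).total_counts
        two = build_msbwt(["ACGT", "ACGT"]).total_counts
        assert np.array_equal(two, 2 * one)

    def test_length_invariant(self):
        reads = ["ACGT", "GGGTA", "N"]
        bwt = build_msbwt(reads)
        assert len(bwt) == sum(len(r) for r in reads) + len(reads)
        assert bwt.num_strings == len(reads) == bwt.total_counts[0]

    def test_lowercase_uppercased(self):
        assert build_msbwt(["acgt"]) == build_msbwt(["ACGT"])

    def test_illegal_character_names_read_index(self):
        with pytest.raises(ValueError, match="read 1"):
            build_msbwt(["ACGT", "ACXT"])

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError, match="read 2"):
            build_msbwt(["ACGT", "A", ""])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rotation_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = random_reads(rng, int(rng.integers(1, 10)), 1, 15)
        assert bwt_string(build_msbwt(reads)) == naive_msbwt(reads)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(DNA, min_size=1, max_size=6))
    def test_matches_rotation_sort_oracle_hypothesis(self, reads):
        assert bwt_string(build_msbwt(reads)) == naive_msbwt(reads)


# ---------------------------------------------------------------------------
# run-length serialization
# ---------------------------------------------------------------------------

class TestRleRoundTrip:
    def test_roundtrip_identity(self, tmp_path, random_read_set):
        bwt = random_read_set["bwt"]
        path = tmp_path / "set.rle"
        save_rle(bwt, path)
        assert load_rle(path) == bwt

    def test_long_runs_use_continuation_bytes(self, tmp_path):
        bwt = build_msbwt(["A" * 1000])
        path = tmp_path / "runs.rle"
        save_rle(bwt, path)
        assert load_rle(path) == bwt

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.rle"
        path.write_bytes(b"")
        bwt = load_rle(path)
        assert len(bwt) == 0 and bwt.num_strings == 0

    @pytest.mark.parametrize("code", [6, 7])
    def test_undecodable_symbol_rejected_with_offset(self, tmp_path, code):
        path = tmp_path / "bad.rle"
        path.write_bytes(bytes([(1 << 3) | 1, (1 << 3) | code]))
        with pytest.raises(ValueError, match="byte offset 1"):
            load_rle(path)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=0, max_size=200))
    def test_roundtrip_arbitrary_symbol_streams(self, symbols):
        import os
        import tempfile

        bwt = RleBwt.from_symbols(np.array(symbols, dtype=np.uint8))
        fd, path = tempfile.mkstemp(suffix=".rle")
        os.close(fd)
        try:
            save_rle(bwt, path)
            loaded = load_rle(path)
        finally:
            os.unlink(path)
        assert loaded == bwt
        assert np.array_equal(loaded.decode(), bwt.decode())

    def test_decode_reencode_identity(self, random_read_set):
        bwt = random_read_set["bwt"]
        assert RleBwt.from_symbols(bwt.decode()) == bwt


# ---------------------------------------------------------------------------
# rank queries
# ---------------------------------------------------------------------------

class TestRank:
    def test_example_rank(self):
        fm = build_fm_index(build_msbwt(["ACGT"]))
        assert bwt_string(build_msbwt(["ACGT"])) == "T$ACG"
        assert fm.rank(1, 5) == 1  # 'A' in "T$ACG"[:5]

    def test_rank_zero(self, random_read_set):
        for fm in (random_read_set["fm_bits"], random_read_set["fm_sampled"]):
            assert all(fm.rank(c, 0) == 0 for c in range(6))

    def test_rank_full_equals_totals(self, random_read_set):
        for fm in (random_read_set["fm_bits"], random_read_set["fm_sampled"]):
            for c in range(6):
                assert fm.rank(c, fm.length) == fm.total_counts[c]

    def test_rank_nondecreasing_and_matches_linear_scan(self):
        rng = np.random.default_rng(3)
        symbols = rng.integers(0, 6, size=1000).astype(np.uint8)
        bwt = RleBwt.from_symbols(symbols)
        fm_bits = build_fm_index(bwt, "bitarray")
        fm_samp = build_fm_index(bwt, "sampled", sample_rate=37)
        positions = np.sort(rng.integers(0, 1001, size=100))
        for c in range(6):
            prev = 0
            for p in positions:
                expected = int(np.sum(symbols[:p] == c))
                assert fm_bits.rank(c, int(p)) == expected
                assert fm_samp.rank(c, int(p)) == expected
                assert expected >= prev
                prev = expected

    def test_bad_sample_rate_rejected(self, random_read_set):
        with pytest.raises(ValueError):
            build_fm_index(random_read_set["bwt"], "sampled", sample_rate=0)

    def test_unknown_implementation_rejected(self, random_read_set):
        with pytest.raises(ValueError):
            build_fm_index(random_read_set["bwt"], "wavelet")


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

class TestCountKmer:
    def test_homopolymer(self):
        fm = build_fm_index(build_msbwt(["AAAA"]))
        assert fm.count_kmer("AAA") == 2  # forward 2, RC "TTT" 0

    def test_palindrome_counts_both_strands(self):
        fm = build_fm_index(build_msbwt(["ACGT"]))
        assert fm.count_kmer("ACGT") == 2

    def test_empty_index(self):
        fm = build_fm_index(build_msbwt([]))
        assert fm.count_kmer("ACGTT") == 0

    def test_kmer_longer_than_reads(self):
        fm = build_fm_index(build_msbwt(["ACGT"]))
        assert fm.count_kmer("ACGTA" * 3) == 0

    def test_invalid_kmer_rejected(self, random_read_set):
        fm = random_read_set["fm_bits"]
        with pytest.raises(ValueError):
            fm.count_kmer("ACGU")
        with pytest.raises(ValueError):
            fm.count_kmer("AC$")
        with pytest.raises(ValueError):
            KmerQuery("")

    def test_n_is_countable(self):
        fm = build_fm_index(build_msbwt(["ACNGT"]))
        assert fm.count_kmer("CNG") == naive_count(["ACNGT"], "CNG")

    def test_k1_conservation(self, random_read_set):
        reads, fm = random_read_set["reads"], random_read_set["fm_bits"]
        total = sum(fm.count_kmer(b) for b in "ACGT")
        bases = sum(len(r) for r in reads)  # random reads are ACGT-only
        assert total == 2 * bases

    def test_matches_oracle_both_implementations(self, random_read_set):
        rng = np.random.default_rng(7)
        reads = random_read_set["reads"]
        joined = "".join(reads)
        for _ in range(150):
            k = int(rng.integers(1, 32))
            if rng.random() < 0.7:  # mostly k-mers present in the set
                read = reads[int(rng.integers(0, len(reads)))]
                if len(read) < k:
                    continue
                i = int(rng.integers(0, len(read) - k + 1))
                kmer = read[i : i + k]
            else:
                i = int(rng.integers(0, len(joined) - k))
                kmer = joined[i : i + k]
            expected = naive_count(reads, kmer)
            assert random_read_set["fm_bits"].count_kmer(kmer) == expected
            assert random_read_set["fm_sampled"].count_kmer(kmer) == expected

    def test_monotonicity_under_extension(self, random_read_set):
        rng = np.random.default_rng(11)
        reads, fm = random_read_set["reads"], random_read_set["fm_bits"]
        for _ in range(50):
            read = reads[int(rng.integers(0, len(reads)))]
            k = int(rng.integers(1, 20))
            i = int(rng.integers(0, len(read) - k))
            kmer = read[i : i + k]
            parent = fm.count_kmer(kmer)
            for b in "ACGT":
                assert fm.count_kmer(kmer + b) <= parent
                assert fm.count_kmer(b + kmer) <= parent


class TestExtendKmer:
    def test_example(self):
        fm = build_fm_index(build_msbwt(["ACGTT"]))
        assert fm.extend_kmer("ACG", "right") == [("T", 2)]

    def test_absent_kmer(self, random_read_set):
        fm = random_read_set["fm_bits"]
        # a 40-mer absent from a 200-read random set with probability ~1
        assert fm.extend_kmer("AC" * 20, "right") == []

    def test_left_direction(self):
        fm = build_fm_index(build_msbwt(["ACGTT"]))
        out = fm.extend_kmer("CGT", "left")
        assert ("A", fm.count_kmer("ACG")) in out

    def test_extension_frequencies_match_counts(self, random_read_set):
        rng = np.random.default_rng(13)
        reads, fm = random_read_set["reads"], random_read_set["fm_bits"]
        for _ in range(30):
            read = reads[int(rng.integers(0, len(reads)))]
            k = int(rng.integers(2, 15))
            i = int(rng.integers(0, len(read) - k + 1))
            kmer = read[i : i + k]
            for b, freq in fm.extend_kmer(kmer, "right"):
                assert freq == fm.count_kmer(kmer[1:] + b) > 0
            for b, freq in fm.extend_kmer(kmer, "left"):
                assert freq == fm.count_kmer(b + kmer[:-1]) > 0


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(DNA, min_size=1, max_size=5), DNA)
def test_count_matches_oracle_hypothesis(reads, kmer):
    fm = build_fm_index(build_msbwt(reads))
    assert fm.count_kmer(kmer) == naive_count(reads, kmer)


def test_revcomp_helper():
    assert revcomp("ACGNT") == "ANCGT"
    assert encode("acgnt").tolist() == [1, 2, 3, 4, 5]
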