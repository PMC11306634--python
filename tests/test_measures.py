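import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molcomplexity.errors import UndefinedInputError
from molcomplexity.measures import (
    huffman_bits,
    huffman_decode,
    huffman_encode,
    lz77_decode,
    lz77_parse,
    lz78_decode,
    lz78_pairs,
    lz78_parse,
    lzw_compress,
    lzw_decompress,
    rle_decode,
    rle_encode,
    shannon_entropy,
)
from conftest import random_string
from oracles import min_prefix_code_bits

texts = st.text(alphabet=st.sampled_from("abcdefgh"), min_size=0, max_size=64)
nonempty_texts = st.text(alphabet=st.sampled_from("abcdefgh"), min_size=1, max_size=64)


class TestEntropy:
    def test_constant(self):
        assert shannon_entropy("0000", block=1) == 0.0

    def test_uniform_two_symbols(self):
        assert shannon_entropy("0101", block=1) == 1.0

    def test_blocks_of_two(self):
        # blocks 00,11,00,11: two equiprobable block values
        assert shannon_entropy("00110011", block=2) == 1.0

    def test_remainder_discarded(self):
        assert shannon_entropy("00110", block=2) == shannon_entropy("0011", block=2)

    def test_empty_raises(self):
        with pytest.raises(UndefinedInputError):
            shannon_entropy("", block=1)

    def test_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = random_string(rng, int(rng.integers(4, 50)), 4)
            h = shannon_entropy(s, block=1)
            assert 0.0 <= h <= math.log2(4) + 1e-12


class TestRLE:
    def test_basic(self):
        runs, encoded_length, run_count = rle_encode("AAAABBB")
        assert runs == [("A", 4), ("B", 3)]
        assert encoded_length == 4  # "A4B3"
        assert run_count == 2

    def test_alternating(self):
        runs, encoded_length, run_count = rle_encode("ABAB")
        assert run_count == 4
        assert encoded_length == 8  # "A1B1A1B1"

    def test_empty(self):
        assert rle_encode("") == ([], 0, 0)

    def test_multidigit_count(self):
        _, encoded_length, _ = rle_encode("A" * 12)
        assert encoded_length == 3  # "A12"

    @given(texts)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, s):
        runs, _, _ = rle_encode(s)
        assert rle_decode(runs) == s


class TestHuffman:
    def test_three_symbol_example(self):
        total, code = huffman_bits("AABC")
        assert total == 6
        assert len(code["A"]) == 1 and len(code["B"]) == 2 and len(code["C"]) == 2

    def test_single_symbol_convention(self):
        total, code = huffman_bits("AAAA")
        assert total == 4
        assert code == {"A": "0"}

    def test_four_symbols(self):
        assert huffman_bits("ABCD")[0] == 8

    def test_empty_raises(self):
        with pytest.raises(UndefinedInputError):
            huffman_bits("")

    def test_prefix_free(self):
        _, code = huffman_bits("AAABBC")
        words = sorted(code.values())
        for i, w in enumerate(words):
            for v in words[i + 1 :]:
                assert not v.startswith(w)

    @given(nonempty_texts)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, s):
        bits, code = huffman_encode(s)
        assert huffman_decode(bits, code) == s

    def test_optimal_vs_exhaustive_sample(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            s = random_string(rng, int(rng.integers(1, 11)), int(rng.integers(2, 5)))
            assert huffman_bits(s)[0] == min_prefix_code_bits(s)

    def test_entropy_bound(self):
        # n*H1 <= huffman bits < n*(H1+1) for non-constant strings
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = random_string(rng, int(rng.integers(2, 80)), int(rng.integers(2, 6)))
            if len(set(s)) < 2:
                continue
            n = len(s)
            h = shannon_entropy(s, block=1)
            bits = huffman_bits(s)[0]
            assert n * h <= bits + 1e-9
            assert bits < n * (h + 1)


class TestLZ78:
    def test_runs_of_one_symbol(self):
        assert lz78_parse("aaaaaa") == (["a", "aa", "aaa"], 3)

    def test_two_symbols(self):
        assert lz78_parse("abab") == (["a", "b", "ab"], 3)

    def test_single(self):
        assert lz78_parse("a") == (["a"], 1)

    def test_phrases_concatenate(self):
        s = "abracadabra"
        phrases, count = lz78_parse(s)
        assert "".join(phrases) == s
        assert len(phrases) == count
        assert len(set(phrases[:-1])) == count - 1  # distinct except maybe last

    @given(texts)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, s):
        assert lz78_decode(lz78_pairs(s)) == s

    def test_repetition_sublinear(self):
        for s in ("abcab", "a", "abcd", "aab"):
            ratios = [lz78_parse(s * k)[1] / k for k in (1, 2, 4, 8, 16)]
            assert all(b <= a + 1e-9 for a, b in zip(ratios, ratios[1:]))


class TestLZW:
    def test_two_symbol_example(self):
        codes, count, _ = lzw_compress("ABABAB")
        assert count == 4  # A, B, AB, AB

    def test_run(self):
        assert lzw_compress("AAAA")[1] == 3  # A, AA, A

    def test_single(self):
        assert lzw_compress("A")[1] == 1

    def test_empty_raises(self):
        with pytest.raises(UndefinedInputError):
            lzw_compress("")

    def test_code_count_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            s = random_string(rng, int(rng.integers(1, 100)), int(rng.integers(1, 5)))
            _, count, _ = lzw_compress(s)
            assert count <= len(s)

    @given(nonempty_texts)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, s):
        codes, _, _ = lzw_compress(s)
        assert lzw_decompress(codes, tuple(sorted(set(s)))) == s


class TestLZ77:
    def test_self_overlap(self):
        triples, count = lz77_parse("aaaa")
        assert triples == [(0, 0, "a"), (1, 3, None)]
        assert count == 2

    def test_no_repeats(self):
        triples, count = lz77_parse("abc")
        assert count == 3
        assert all(off == 0 and length == 0 for off, length, _ in triples)

    def test_random_vs_constant(self):
        rng = np.random.default_rng(11)
        s = random_string(rng, 64, 2)
        assert lz77_parse(s)[1] > lz77_parse("0" * 64)[1]

    def test_tie_smallest_offset(self):
        # "abab|ab": match "ab" available at offsets 2 and 4; smallest wins
        triples, _ = lz77_parse("ababab")
        offsets = [t[0] for t in triples if t[1] > 0]
        assert offsets and offsets[0] == 2

    @given(texts)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, s):
        triples, _ = lz77_parse(s)
        assert lz77_decode(triples) == s


def test_determinism_all_measures():
    rng = np.random.default_rng(13)
    s = random_string(rng, 40, 3)
    assert rle_encode(s) == rle_encode(s)
    assert huffman_bits(s) == huffman_bits(s)
    assert lz78_parse(s) == lz78_parse(s)
    assert lzw_compress(s) == lzw_compress(s)
    assert lz77_parse(s) == lz77_parse(s)
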