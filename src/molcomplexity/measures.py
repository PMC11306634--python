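"""Coding-based statistical complexity estimators.

Implements the classic dictionary/prefix family: block Shannon entropy,
run-length encoding, Huffman coding, LZ77/LZ78 parsing and LZW.  Every codec
comes with a decoder so losslessness is testable, and every measure exposes a
single scalar "size" proxy used by the statistics pipeline:

========  =======================
measure   scalar
========  =======================
entropy   bits per block
rle       encoded character length
huffman   total encoded bits
lz77      number of triples
lz78      number of phrases
lzw       number of output codes
========  =======================

No container or header overhead is added anywhere: these are complexity
indexes, not archivers.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Callable

from .encodings import Sequence, as_symbols
from .errors import UndefinedInputError

__all__ = [
    "ComplexityValue",
    "shannon_entropy",
    "rle_encode",
    "rle_decode",
    "huffman_bits",
    "huffman_encode",
    "huffman_decode",
    "lz78_parse",
    "lz78_pairs",
    "lz78_decode",
    "lzw_compress",
    "lzw_decompress",
    "lz77_parse",
    "lz77_decode",
    "SCALAR_MEASURES",
]


@dataclass(frozen=True)
class ComplexityValue:
    """A named scalar complexity value with its measure-specific payload."""

    measure_name: str
    value: float
    units: str
    details: object = None


# ---------------------------------------------------------------------------
# block Shannon entropy


def shannon_entropy(s: "Sequence | str", block: int = 1) -> float:
    """Empirical entropy (bits per block) over non-overlapping blocks.

    The trailing remainder shorter than ``block`` is discarded.
    """
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("entropy is undefined for the empty sequence")
    if block < 1:
        raise UndefinedInputError("block length must be >= 1")
    if len(sym) < block:
        raise UndefinedInputError("sequence shorter than one block")
    counts: dict[str, int] = {}
    n_blocks = len(sym) // block
    for k in range(n_blocks):
        b = sym[k * block : (k + 1) * block]
        counts[b] = counts.get(b, 0) + 1
    return -sum((c / n_blocks) * math.log2(c / n_blocks) for c in counts.values())


# ---------------------------------------------------------------------------
# run-length encoding


def rle_encode(s: "Sequence | str") -> tuple[list[tuple[str, int]], int, int]:
    """Maximal-run scan; returns ``(runs, encoded_length, run_count)``.

    The count is always written, including 1, so the encoded form
    ``symbol + decimal count`` is unambiguous; ``encoded_length`` is the total
    number of characters of that form.
    """
    sym = as_symbols(s)
    runs: list[tuple[str, int]] = []
    i = 0
    while i < len(sym):
        j = i
        while j < len(sym) and sym[j] == sym[i]:
            j += 1
        runs.append((sym[i], j - i))
        i = j
    encoded_length = sum(1 + len(str(c)) for _, c in runs)
    return runs, encoded_length, len(runs)


def rle_decode(runs: list[tuple[str, int]]) -> str:
    return "".join(ch * count for ch, count in runs)


# ---------------------------------------------------------------------------
# Huffman coding


def _huffman_code(freqs: dict[str, int]) -> dict[str, str]:
    # Single-symbol alphabets get a 1-bit code by convention.
    if len(freqs) == 1:
        (only,) = freqs
        return {only: "0"}
    # Tie-breaking: pop the node with smallest (weight, creation order); leaves
    # are created in sorted symbol order, merges afterwards.  This makes the
    # code, and hence total_bits, canonical.
    heap: list[tuple[int, int, dict[str, str]]] = [
        (f, order, {c: ""}) for order, (c, f) in enumerate(sorted(freqs.items()))
    ]
    heapq.heapify(heap)
    next_order = len(heap)
    while len(heap) > 1:
        w0, _, code0 = heapq.heappop(heap)
        w1, _, code1 = heapq.heappop(heap)
        merged = {c: "0" + bits for c, bits in code0.items()}
        merged.update({c: "1" + bits for c, bits in code1.items()})
        heapq.heappush(heap, (w0 + w1, next_order, merged))
        next_order += 1
    return heap[0][2]


def huffman_bits(s: "Sequence | str") -> tuple[int, dict[str, str]]:
    """Minimum-redundancy prefix code; returns ``(total_bits, code map)``."""
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("Huffman coding is undefined for the empty sequence")
    freqs: dict[str, int] = {}
    for c in sym:
        freqs[c] = freqs.get(c, 0) + 1
    code = _huffman_code(freqs)
    total = sum(freqs[c] * len(code[c]) for c in freqs)
    return total, code


def huffman_encode(s: "Sequence | str") -> tuple[str, dict[str, str]]:
    sym = as_symbols(s)
    total, code = huffman_bits(sym)
    return "".join(code[c] for c in sym), code


def huffman_decode(bits: str, code: dict[str, str]) -> str:
    rev = {v: k for k, v in code.items()}
    out: list[str] = []
    cur = ""
    for b in bits:
        cur += b
        if cur in rev:
            out.append(rev[cur])
            cur = ""
    if cur:
        raise UndefinedInputError("dangling bits: not a valid Huffman stream")
    return "".join(out)


# ---------------------------------------------------------------------------
# LZ78


def lz78_parse(s: "Sequence | str") -> tuple[list[str], int]:
    """Incremental parsing: each phrase = longest seen phrase + one symbol.

    Returns ``(phrases, phrase_count)``; phrases concatenate to the input and
    are all distinct except possibly the last.
    """
    sym = as_symbols(s)
    seen: set[str] = set()
    phrases: list[str] = []
    cur = ""
    for c in sym:
        cur += c
        if cur not in seen:
            seen.add(cur)
            phrases.append(cur)
            cur = ""
    if cur:
        phrases.append(cur)
    return phrases, len(phrases)


def lz78_pairs(s: "Sequence | str") -> list[tuple[int, str]]:
    """LZ78 as an actual code: ``(dictionary index, extension symbol)`` pairs.

    Index 0 means the empty phrase.  A trailing repeated phrase is emitted as
    ``(index, "")``.
    """
    sym = as_symbols(s)
    index: dict[str, int] = {}
    pairs: list[tuple[int, str]] = []
    cur = ""
    for c in sym:
        if cur + c in index:
            cur += c
            continue
        pairs.append((index.get(cur, 0), c))
        index[cur + c] = len(index) + 1
        cur = ""
    if cur:
        pairs.append((index[cur], ""))
    return pairs


def lz78_decode(pairs: list[tuple[int, str]]) -> str:
    phrases: list[str] = []
    out: list[str] = []
    for idx, ext in pairs:
        prefix = phrases[idx - 1] if idx else ""
        phrase = prefix + ext
        if ext:
            phrases.append(phrase)
        out.append(phrase)
    return "".join(out)


# ---------------------------------------------------------------------------
# LZW


def lzw_compress(s: "Sequence | str") -> tuple[list[int], int, int]:
    """LZW with the dictionary initialised to the sequence's sorted alphabet.

    Returns ``(codes, code_count, dict_size)``.
    """
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("LZW is undefined for the empty sequence")
    table: dict[str, int] = {c: i for i, c in enumerate(sorted(set(sym)))}
    codes: list[int] = []
    cur = ""
    for c in sym:
        if cur + c in table:
            cur += c
        else:
            codes.append(table[cur])
            table[cur + c] = len(table)
            cur = c
    codes.append(table[cur])
    return codes, len(codes), len(table)


def lzw_decompress(codes: list[int], alphabet: "tuple[str, ...] | list[str]") -> str:
    if not codes:
        raise UndefinedInputError("empty LZW code stream")
    table: dict[int, str] = {i: c for i, c in enumerate(sorted(alphabet))}
    prev = table[codes[0]]
    out = [prev]
    for code in codes[1:]:
        if code in table:
            entry = table[code]
        elif code == len(table):  # the KwKwK case
            entry = prev + prev[0]
        else:
            raise UndefinedInputError(f"invalid LZW code {code}")
        out.append(entry)
        table[len(table)] = prev + entry[0]
        prev = entry
    return "".join(out)


# ---------------------------------------------------------------------------
# LZ77


def lz77_parse(
    s: "Sequence | str", window: int | None = None
) -> tuple[list[tuple[int, int, "str | None"]], int]:
    """Greedy longest-match factorisation into ``(offset, length, next)`` triples.

    Self-overlapping matches (offset < length) are allowed and the window is
    unbounded by default.  At each position the longest available match is
    taken; among equally long matches the smallest offset wins.  A match that
    consumes the rest of the input carries ``next=None``.
    """
    sym = as_symbols(s)
    n = len(sym)
    triples: list[tuple[int, int, str | None]] = []
    pos = 0
    while pos < n:
        best_len = 0
        best_off = 0
        lo = 0 if window is None else max(0, pos - window)
        # scan nearest-first so ties resolve to the smallest offset
        for start in range(pos - 1, lo - 1, -1):
            # extend match allowing self-overlap
            length = 0
            while pos + length < n and sym[start + length] == sym[pos + length]:
                length += 1
            if length > best_len:
                best_len = length
                best_off = pos - start
        if best_len == 0:
            triples.append((0, 0, sym[pos]))
            pos += 1
        else:
            nxt = sym[pos + best_len] if pos + best_len < n else None
            triples.append((best_off, best_len, nxt))
            pos += best_len + (1 if nxt is not None else 0)
    return triples, len(triples)


def lz77_decode(triples: list[tuple[int, int, "str | None"]]) -> str:
    out: list[str] = []
    for off, length, nxt in triples:
        for _ in range(length):
            out.append(out[-off])
        if nxt is not None:
            out.append(nxt)
    return "".join(out)


# ---------------------------------------------------------------------------
# scalar registry (pipeline entry points)


def _scalar_entropy(s, block: int = 1) -> float:
    return shannon_entropy(s, block=block)


SCALAR_MEASURES: dict[str, Callable[..., float]] = {
    "entropy": _scalar_entropy,
    "rle": lambda s: rle_encode(s)[1],
    "huffman": lambda s: huffman_bits(s)[0],
    "lz77": lambda s: lz77_parse(s)[1],
    "lz78": lambda s: lz78_parse(s)[1],
    "lzw": lambda s: lzw_compress(s)[1],
}
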