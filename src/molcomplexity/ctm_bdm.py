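"""Coding Theorem Method (CTM) tables and the Block Decomposition Method (BDM).

CTM approximates the algorithmic complexity of short binary strings from the
output frequency of exhaustively enumerated small Turing machines:
``CTM(s) = -log2 D(s)`` where ``D(s)`` is the fraction of halting runs that
leave ``s`` on the tape.  BDM extends the table to longer sequences by summing
``CTM(block) + log2(multiplicity)`` over the distinct non-overlapping blocks.

Machine formalism (2 symbols, ``n`` work states, one extra halt state):
each of the ``2n`` (state, read-symbol) slots holds one of ``4n + 2``
instructions — ``(write, move left/right, next state)`` or ``(write, halt)`` —
so the machine space has exactly ``(4n + 2)^(2n)`` members.  Every machine is
run twice, once on an all-0 tape and once on an all-1 tape, which makes the
0/1-complement symmetry of the output distribution exact (left-right reversal
symmetry is exact already, via the move-swap bijection).  The output of a
halting run is the contiguous tape segment visited up to the halt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .encodings import Sequence, as_symbols
from .errors import InvalidArgumentError, ParseError, UndefinedInputError

__all__ = [
    "CTMMeta",
    "CTMTable",
    "BDMValue",
    "machine_space_size",
    "build_ctm_table",
    "save_ctm_table",
    "load_ctm_table",
    "default_ctm_table",
    "bdm",
]


@dataclass(frozen=True)
class CTMMeta:
    states: int
    symbols: int
    max_steps: int
    machines_total: int
    machines_halted: int  # halting runs (each machine contributes up to 2 runs)
    method: str  # exhaustive | sampled | loaded


@dataclass(frozen=True)
class CTMTable:
    entries: dict  # binary string -> complexity in bits
    meta: CTMMeta

    def __post_init__(self):
        if not self.entries:
            raise InvalidArgumentError("CTM table has no entries")
        for k, v in self.entries.items():
            if set(k) - {"0", "1"}:
                raise InvalidArgumentError(f"non-binary table key {k!r}")
            if v < 0:
                raise InvalidArgumentError(f"negative CTM value for {k!r}")

    def __contains__(self, s: str) -> bool:
        return s in self.entries

    def __getitem__(self, s: str) -> float:
        return self.entries[s]

    @property
    def max_block(self) -> int:
        return max(len(k) for k in self.entries)


@dataclass(frozen=True)
class BDMValue:
    value: float
    block_length: int
    boundary_policy: str
    missing_blocks: int


def machine_space_size(states: int) -> int:
    """``(4n + 2)^(2n)`` machines for ``n`` work states and 2 symbols."""
    return (4 * states + 2) ** (2 * states)


# instruction encoding: index d in [0, 4n+2)
#   d < 2            -> write d, halt
#   d >= 2           -> e = d - 2; write e % 2; move (-1 if (e//2) % 2 == 0 else +1);
#                       next state 1 + e // 4


def _decode_instruction(d: int):
    if d < 2:
        return d, 0, 0
    e = d - 2
    return e % 2, (-1 if (e // 2) % 2 == 0 else 1), 1 + e // 4


def _simulate(table: tuple, states: int, blank: int, max_steps: int):
    """Pure-Python single-machine run; returns the output string or None.

    ``table[(q-1)*2 + r]`` is the instruction index for state ``q`` reading
    ``r``.  Used by sampled mode and as a slow cross-check of the vectorised
    enumeration.
    """
    tape: dict[int, int] = {}
    pos = lo = hi = 0
    q = 1
    for _ in range(max_steps):
        r = tape.get(pos, blank)
        w, mv, nxt = _decode_instruction(table[(q - 1) * 2 + r])
        tape[pos] = w
        if nxt == 0:
            return "".join(str(tape.get(i, blank)) for i in range(lo, hi + 1))
        pos += mv
        lo = min(lo, pos)
        hi = max(hi, pos)
        q = nxt
    return None


def _enumerate_chunk(machine_ids: np.ndarray, states: int, blank: int, max_steps: int):
    """Vectorised simulation of one chunk of machines on a single blank tape.

    Returns a dict mapping output string -> count of halting runs.
    """
    n = states
    n_instr = 4 * n + 2
    m = machine_ids.shape[0]
    width = 2 * max_steps + 1
    centre = max_steps
    tape = np.full((m, width), blank, dtype=np.int8)
    pos = np.full(m, centre, dtype=np.int64)
    lo = pos.copy()
    hi = pos.copy()
    state = np.ones(m, dtype=np.int8)  # 1-based; 0 = halted
    active = np.ones(m, dtype=bool)
    halted_at_step = np.full(m, -1, dtype=np.int64)

    # per-instruction lookup tables
    instr = np.arange(n_instr)
    wr = np.where(instr < 2, instr, (instr - 2) % 2).astype(np.int8)
    mv = np.where(instr < 2, 0, np.where(((instr - 2) // 2) % 2 == 0, -1, 1)).astype(np.int8)
    nx = np.where(instr < 2, 0, 1 + (instr - 2) // 4).astype(np.int8)

    pow_n = n_instr ** np.arange(2 * n, dtype=np.int64)

    for step in range(max_steps):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        read = tape[idx, pos[idx]]
        slot = (state[idx].astype(np.int64) - 1) * 2 + read
        d = (machine_ids[idx] // pow_n[slot]) % n_instr
        tape[idx, pos[idx]] = wr[d]
        halting = nx[d] == 0
        hidx = idx[halting]
        halted_at_step[hidx] = step
        active[hidx] = False
        state[hidx] = 0
        ridx = idx[~halting]
        dm = d[~halting]
        pos[ridx] += mv[dm]
        np.minimum.at(lo, ridx, pos[ridx])
        np.maximum.at(hi, ridx, pos[ridx])
        state[ridx] = nx[dm]

    counts: dict[str, int] = {}
    for i in np.nonzero(halted_at_step >= 0)[0]:
        seg = tape[i, lo[i] : hi[i] + 1]
        out = "".join("1" if b else "0" for b in seg)
        counts[out] = counts.get(out, 0) + 1
    return counts


def build_ctm_table(
    states: int,
    max_steps: int = 107,
    mode: str = "exhaustive",
    sample_size: int | None = None,
    seed: int | None = None,
    chunk: int = 250_000,
) -> CTMTable:
    """Enumerate (or sample) the machine space and build a CTM table.

    Exhaustive mode is refused for ``states > 3`` (the (4,2) space already has
    more than 10^10 members); sampled mode requires a seed.
    """
    if states < 1:
        raise InvalidArgumentError("states must be >= 1")
    known_bb_steps = {1: 1, 2: 6, 3: 21}
    if mode == "exhaustive" and states in known_bb_steps and max_steps < known_bb_steps[states]:
        raise InvalidArgumentError(
            f"max_steps={max_steps} below the busy-beaver step bound "
            f"S({states})={known_bb_steps[states]}; the table would be incomplete"
        )
    total = machine_space_size(states)
    counts: dict[str, int] = {}
    if mode == "exhaustive":
        if states > 3:
            raise InvalidArgumentError(
                f"exhaustive enumeration refused for states={states} "
                f"({total} machines); use mode='sampled'"
            )
        for start in range(0, total, chunk):
            ids = np.arange(start, min(start + chunk, total), dtype=np.int64)
            for blank in (0, 1):
                for out, c in _enumerate_chunk(ids, states, blank, max_steps).items():
                    counts[out] = counts.get(out, 0) + c
    elif mode == "sampled":
        if seed is None:
            raise InvalidArgumentError("sampled mode requires a seed")
        if not sample_size or sample_size < 1:
            raise InvalidArgumentError("sampled mode requires a positive sample_size")
        rng = np.random.default_rng([seed, states])
        n_instr = 4 * states + 2
        for _ in range(sample_size):
            mid = int(rng.integers(0, total))
            digits = []
            for _slot in range(2 * states):
                digits.append(mid % n_instr)
                mid //= n_instr
            for blank in (0, 1):
                out = _simulate(tuple(digits), states, blank, max_steps)
                if out is not None:
                    counts[out] = counts.get(out, 0) + 1
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")

    halted = sum(counts.values())
    if halted == 0:
        raise InvalidArgumentError("no halting machine found; increase max_steps")
    entries = {s: -math.log2(c / halted) for s, c in sorted(counts.items())}
    meta = CTMMeta(states, 2, max_steps, total, halted, mode)
    return CTMTable(entries, meta)


# ---------------------------------------------------------------------------
# table I/O: CSV `string,ctm_bits` with a `#meta` header line


def save_ctm_table(table: CTMTable, path: "str | Path") -> None:
    m = table.meta
    lines = [
        f"#meta states={m.states} symbols={m.symbols} max_steps={m.max_steps} "
        f"machines_total={m.machines_total} machines_halted={m.machines_halted} "
        f"method={m.method}"
    ]
    for s, v in sorted(table.entries.items()):
        lines.append(f"{s},{v:.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_ctm_table(path: "str | Path") -> CTMTable:
    lines = Path(path).read_text().splitlines()
    meta_kv: dict[str, int] = {}
    entries: dict[str, float] = {}
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if raw.startswith("#meta"):
            for item in raw.split()[1:]:
                k, _, v = item.partition("=")
                meta_kv[k] = v
            continue
        if raw.startswith("#"):
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise ParseError(f"expected 'string,ctm_bits', got {raw!r}", line=ln)
        key, val = parts[0].strip(), parts[1].strip()
        if not key or set(key) - {"0", "1"}:
            raise ParseError(f"non-binary string {key!r}", line=ln)
        try:
            value = float(val)
        except ValueError:
            raise ParseError(f"malformed value {val!r}", line=ln) from None
        if value <= 0:
            raise ParseError(f"non-positive CTM value {value}", line=ln)
        if key in entries:
            raise ParseError(f"duplicate string {key!r}", line=ln)
        entries[key] = value
    meta = CTMMeta(
        states=int(meta_kv.get("states", 0)),
        symbols=int(meta_kv.get("symbols", 2)),
        max_steps=int(meta_kv.get("max_steps", 0)),
        machines_total=int(meta_kv.get("machines_total", 0)),
        machines_halted=int(meta_kv.get("machines_halted", 0)),
        method="loaded",
    )
    return CTMTable(entries, meta)


def default_ctm_table() -> CTMTable:
    """The packaged exhaustive (3,2) table (~7.5M machines, built once)."""
    ref = resources.files("molcomplexity").joinpath("data/ctm_3_2.csv")
    with resources.as_file(ref) as p:
        return load_ctm_table(p)


# ---------------------------------------------------------------------------
# BDM


def bdm(
    s: "Sequence | str",
    table: CTMTable,
    block_length: int = 8,
    boundary: str = "discard",
) -> BDMValue:
    """Block Decomposition: sum of ``CTM(block) + log2(multiplicity)``.

    Blocks are non-overlapping windows of ``block_length``; with the default
    ``discard`` policy a trailing remainder shorter than the block is dropped
    (matching the block-entropy convention).  Blocks absent from the table are
    scored ``block_length + 1`` bits — a near-maximal surrogate — and counted
    in ``missing_blocks`` so sparse-table coverage stays visible.
    """
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("BDM is undefined for the empty sequence")
    if set(sym) - {"0", "1"}:
        raise InvalidArgumentError("BDM requires a binary sequence")
    if block_length < 1:
        raise InvalidArgumentError("block_length must be >= 1")
    if block_length > table.max_block:
        raise InvalidArgumentError(
            f"block_length {block_length} exceeds table coverage ({table.max_block})"
        )
    if boundary != "discard":
        raise InvalidArgumentError(f"unknown boundary policy {boundary!r}")
    n_blocks = len(sym) // block_length
    if n_blocks == 0:
        raise UndefinedInputError("sequence shorter than one block")
    mult: dict[str, int] = {}
    for k in range(n_blocks):
        b = sym[k * block_length : (k + 1) * block_length]
        mult[b] = mult.get(b, 0) + 1
    missing = 0
    value = 0.0
    for b, m in mult.items():
        if b in table:
            ctm = table[b]
        else:
            ctm = block_length + 1
            missing += 1
        value += ctm + math.log2(m)
    return BDMValue(value, block_length, boundary, missing)
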