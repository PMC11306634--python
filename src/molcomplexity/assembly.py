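"""Assembly index for sequences.

The join model: an object is built by binary concatenation of previously
available objects, starting from the distinct symbols of the target (the basis,
free of charge).  Every intermediate product must be a contiguous substring of
the target, and each distinct product is paid for exactly once no matter how
often it is reused.  The assembly index of a string is the minimum number of
such join steps.

Three routes are provided:

* :func:`assembly_index_exact` — the global minimum, found by branch-and-bound
  over closed substring sets with iterative incumbent tightening;
* :func:`assembly_index_greedy` — repeatedly factor out the longest repeated
  substring (an upper bound, LZ-flavoured);
* :func:`assembly_bounds` — an analytic doubling lower bound together with a
  constructive upper bound read off the LZ78 parse.

Every constructive method returns a witness pathway that replays to the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .encodings import Sequence, as_symbols
from .errors import InvalidArgumentError, UndefinedInputError

__all__ = [
    "AssemblyPathway",
    "AssemblyResult",
    "assembly_index_exact",
    "assembly_index_greedy",
    "assembly_bounds",
    "lz78_bound_pathway",
    "replay_pathway",
    "DEFAULT_MAX_LEN",
]

DEFAULT_MAX_LEN = 20


@dataclass(frozen=True)
class AssemblyPathway:
    """An ordered list of join steps ``(left, right, product)``."""

    steps: tuple[tuple[str, str, str], ...]
    target: str


@dataclass(frozen=True)
class AssemblyResult:
    index: int
    pathway: AssemblyPathway
    method: str  # exact | greedy | lz78-bound
    is_exact: bool


def replay_pathway(pathway: AssemblyPathway) -> str:
    """Replay a pathway, enforcing every invariant of the join model.

    Returns the final product; raises :class:`InvalidArgumentError` on any
    violation (unavailable operand, non-substring product, wrong target).
    """
    target = pathway.target
    basis = set(target)
    available = set(basis)
    products: list[str] = []
    for left, right, product in pathway.steps:
        if left not in available:
            raise InvalidArgumentError(f"operand {left!r} not available")
        if right not in available:
            raise InvalidArgumentError(f"operand {right!r} not available")
        if left + right != product:
            raise InvalidArgumentError(f"{left!r}+{right!r} != {product!r}")
        if product not in target:
            raise InvalidArgumentError(f"product {product!r} is not a substring of the target")
        available.add(product)
        products.append(product)
    final = products[-1] if products else (target if len(target) <= 1 else None)
    if final != target:
        raise InvalidArgumentError("pathway does not terminate in the target")
    return final


# ---------------------------------------------------------------------------
# exact search
#
# A pathway of k steps is equivalent to a set S of k distinct multi-character
# substrings of the target with s in S and every t in S splitting as t = a+b
# where each of a, b is a single symbol or another member of S.  (Splits are
# strictly shorter, so any such set orders into a valid pathway by length.)
# The search is branch-and-bound over these closed sets: resolve the longest
# outstanding string, branch on its split point, bound with a count bound plus
# a doubling bound, and fold in "isolated" strings — whose multi-character
# substrings all occur exactly once in the target — at their closed-form cost
# of length-1, since nothing in their subtree can ever be shared.


def _substring_data(s: str):
    subs = {s[i: j] for i in range(len(s)) for j in range(i + 2, len(s) + 1)}
    occ: dict[str, int] = {}
    for t in subs:
        c = 0
        start = 0
        while True:
            k = s.find(t, start)
            if k < 0:
                break
            c += 1
            start = k + 1
        occ[t] = c
    isolated: dict[str, bool] = {}
    for t in sorted(subs, key=len):
        iso = occ[t] == 1
        if iso and len(t) > 2:
            iso = isolated[t[1:]] and isolated[t[:-1]]
        isolated[t] = iso
    return subs, isolated


def _prefix_chain_steps(t: str) -> list[tuple[str, str, str]]:
    return [(t[:k], t[k], t[: k + 1]) for k in range(1, len(t))]


def assembly_index_exact(
    s: "Sequence | str", max_len: int = DEFAULT_MAX_LEN
) -> AssemblyResult:
    """Exact minimal number of join steps, with a witness pathway.

    Refuses strings longer than ``max_len`` (the search is super-exponential);
    use :func:`assembly_index_greedy` or :func:`assembly_bounds` beyond it.
    """
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("assembly index is undefined for the empty sequence")
    if len(sym) > max_len:
        raise InvalidArgumentError(
            f"exact search refused for length {len(sym)} > max_len={max_len}; "
            "use assembly_index_greedy or assembly_bounds instead"
        )
    if len(sym) == 1:
        return AssemblyResult(0, AssemblyPathway((), sym), "exact", True)

    subs, isolated = _substring_data(sym)
    greedy = assembly_index_greedy(sym)
    best = greedy.index
    best_sol: tuple[frozenset, tuple] = None  # (resolved set w/ splits, isolated items)

    splits: dict[str, list[tuple[str, ...]]] = {}
    for t in subs:
        opts = []
        for i in range(1, len(t)):
            parts = tuple(p for p in (t[:i], t[i:]) if len(p) > 1)
            opts.append((i, parts))
        splits[t] = opts

    def lower_bound(n_s: int, chosen: dict, work: list) -> int:
        bound = n_s + len(work)
        for t in work:
            longest = 1
            for u in chosen:
                if longest < len(u) < len(t) and u in t:
                    longest = len(u)
            dbl = math.ceil(math.log2(len(t) / longest))
            extra = sum(1 for w in work if w is not t and w not in t)
            bound = max(bound, n_s + dbl + extra)
        return bound

    def dfs(n_s: int, chosen: dict, work: list, isolated_done: list):
        nonlocal best, best_sol
        pending = []
        iso_here = []
        for t in work:
            if isolated[t]:
                n_s += len(t) - 1
                iso_here.append(t)
            else:
                pending.append(t)
        work = pending
        iso_all = isolated_done + iso_here
        if not work:
            if n_s < best:
                best = n_s
                best_sol = (dict(chosen), tuple(iso_all))
            return
        if lower_bound(n_s, chosen, work) >= best:
            return
        work = sorted(work, key=lambda t: (-len(t), t))
        t = work[0]
        rest = work[1:]
        # try splits with the fewest new strings first: finds reuse early
        options = []
        for i, parts in splits[t]:
            new = sorted({p for p in parts if p not in chosen and p not in rest})
            options.append((len(new), i, parts, new))
        options.sort(key=lambda o: (o[0], o[1]))
        tried: set[frozenset] = set()
        for _, i, parts, new in options:
            key = frozenset(parts)
            if key in tried:
                continue
            tried.add(key)
            chosen[t] = i
            dfs(n_s + 1, chosen, rest + new, iso_all)
            del chosen[t]

    dfs(0, {}, [sym], [])

    # reconstruct a witness pathway from the winning closed set
    if best_sol is None:  # greedy incumbent was already optimal
        return AssemblyResult(
            best, greedy.pathway, "exact", True
        )
    chosen, iso_items = best_sol
    steps: list[tuple[str, str, str]] = []
    built: set[str] = set()
    for t in sorted(iso_items, key=lambda u: (len(u), u)):
        for step in _prefix_chain_steps(t):
            steps.append(step)
            built.add(step[2])
    for t in sorted(chosen, key=lambda u: (len(u), u)):
        i = chosen[t]
        steps.append((t[:i], t[i:], t))
        built.add(t)
    # order steps so operands always precede products (length order suffices)
    steps.sort(key=lambda st: (len(st[2]), st[2] != sym))
    pathway = AssemblyPathway(tuple(steps), sym)
    assert len(steps) == best, (len(steps), best)
    replay_pathway(pathway)
    return AssemblyResult(best, pathway, "exact", True)


# ---------------------------------------------------------------------------
# greedy upper bound


def _longest_disjoint_repeat(units: tuple[str, ...]):
    """Longest (by character length) sub-tuple occurring twice disjointly.

    Ties break to the leftmost start, then to the fewest units.  Returns
    ``(start, n_units)`` or ``None``.
    """
    n = len(units)
    best = None
    best_key = None
    for n_units in range(2, n):
        for i in range(0, n - n_units + 1):
            pat = units[i : i + n_units]
            if any(units[j : j + n_units] == pat for j in range(i + n_units, n - n_units + 1)):
                clen = sum(len(u) for u in pat)
                key = (clen, -i, -n_units)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (i, n_units)
    return best


def assembly_index_greedy(s: "Sequence | str") -> AssemblyResult:
    """Upper bound: factor out the longest repeated substring, reuse it, recurse."""
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("assembly index is undefined for the empty sequence")
    steps: list[tuple[str, str, str]] = []
    built: set[str] = set()

    def join_left_to_right(units: tuple[str, ...]) -> None:
        cur = units[0]
        for u in units[1:]:
            product = cur + u
            if product not in built and len(product) > 1:
                steps.append((cur, u, product))
                built.add(product)
            cur = product

    def build(units: tuple[str, ...]) -> None:
        if len(units) == 1:
            return
        rep = _longest_disjoint_repeat(units)
        if rep is None:
            join_left_to_right(units)
            return
        i, n_units = rep
        pat = units[i : i + n_units]
        pat_str = "".join(pat)
        if pat_str not in built and len(pat_str) > 1:
            build(pat)
        out: list[str] = []
        k = 0
        while k < len(units):
            if k <= len(units) - n_units and units[k : k + n_units] == pat:
                out.append(pat_str)
                k += n_units
            else:
                out.append(units[k])
                k += 1
        build(tuple(out))

    if len(sym) > 1:
        build(tuple(sym))
    pathway = AssemblyPathway(tuple(steps), sym)
    replay_pathway(pathway)
    return AssemblyResult(len(steps), pathway, "greedy", False)


# ---------------------------------------------------------------------------
# analytic bounds


def lz78_bound_pathway(s: "Sequence | str") -> AssemblyResult:
    """Constructive upper bound from the LZ78 parse.

    Each phrase extends its prefix phrase by one symbol (one join each, unless
    the phrase already exists), then phrases are joined left to right.
    """
    from .measures import lz78_parse

    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("bounds are undefined for the empty sequence")
    phrases, _ = lz78_parse(sym)
    steps: list[tuple[str, str, str]] = []
    built: set[str] = set()
    for ph in phrases:
        if len(ph) > 1 and ph not in built:
            steps.append((ph[:-1], ph[-1], ph))
            built.add(ph)
    cur = phrases[0]
    for ph in phrases[1:]:
        product = cur + ph
        if product not in built:
            steps.append((cur, ph, product))
            built.add(product)
        cur = product
    pathway = AssemblyPathway(tuple(steps), sym)
    replay_pathway(pathway)
    return AssemblyResult(len(steps), pathway, "lz78-bound", False)


def assembly_bounds(s: "Sequence | str") -> tuple[int, int]:
    """``(lower, lz78_upper)`` with lower = ceil(log2 n), the doubling limit."""
    sym = as_symbols(s)
    if not sym:
        raise UndefinedInputError("bounds are undefined for the empty sequence")
    lower = math.ceil(math.log2(len(sym)))
    upper = lz78_bound_pathway(sym).index
    return lower, upper
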