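"""Independent brute-force oracles.

Everything here is deliberately simple and shares no code with the package
implementations it checks.
"""

import itertools
import math
from collections import Counter


# ---------------------------------------------------------------------------
# assembly index: breadth-first search over sets of built substrings.
# No pruning beyond substring closure (any product must be a substring of the
# target).  States are bitmasks over the multi-character substring universe.


def assembly_index_bfs(s: str) -> int:
    if len(s) <= 1:
        return 0
    subs = sorted(
        {s[i:j] for i in range(len(s)) for j in range(i + 2, len(s) + 1)}
    )
    bit = {t: 1 << k for k, t in enumerate(subs)}
    objects = sorted(set(s)) + subs
    joins = []
    for a in objects:
        for b in objects:
            c = a + b
            if c in bit:
                joins.append((bit.get(a, 0), bit.get(b, 0), bit[c]))
    target_bit = bit[s]
    frontier = {0}
    seen = {0}
    depth = 0
    while frontier:
        depth += 1
        nxt = set()
        for mask in frontier:
            for need_a, need_b, product in joins:
                if (mask & need_a) == need_a and (mask & need_b) == need_b and not mask & product:
                    if product == target_bit:
                        return depth
                    m2 = mask | product
                    if m2 not in seen:
                        seen.add(m2)
                        nxt.add(m2)
        frontier = nxt
    raise RuntimeError(f"target unreachable: {s!r}")


# ---------------------------------------------------------------------------
# Huffman: exhaustive minimum over all prefix codes (full binary code trees)


def _all_depth_maps(symbols: tuple):
    if len(symbols) == 1:
        yield {symbols[0]: 0}
        return
    rest = symbols[1:]
    # split the remaining symbols between the two subtrees; the first symbol
    # is pinned to the left subtree to kill mirror duplicates
    for r in range(len(rest) + 1):
        for right_set in itertools.combinations(rest, r):
            left = (symbols[0],) + tuple(x for x in rest if x not in right_set)
            right = tuple(right_set)
            if not right:
                continue
            for dl in _all_depth_maps(left):
                for dr in _all_depth_maps(right):
                    yield {**{k: v + 1 for k, v in dl.items()}, **{k: v + 1 for k, v in dr.items()}}


def min_prefix_code_bits(s: str) -> int:
    """Minimum total bits over every full prefix-code tree (alphabet <= 4)."""
    freqs = Counter(s)
    symbols = tuple(sorted(freqs))
    if len(symbols) == 1:
        return len(s)  # 1-bit convention
    return min(
        sum(freqs[c] * depths[c] for c in symbols) for depths in _all_depth_maps(symbols)
    )


# ---------------------------------------------------------------------------
# CTM: plain dict-based enumeration of the (n,2) machine space


def ctm_counts_bruteforce(states: int, max_steps: int):
    n = states
    instrs = [(w, 0, 0) for w in (0, 1)]
    for w in (0, 1):
        for mv in (-1, 1):
            for nx in range(1, n + 1):
                instrs.append((w, mv, nx))
    keys = [(q, r) for q in range(1, n + 1) for r in (0, 1)]
    counts = Counter()
    total = 0
    for table in itertools.product(instrs, repeat=2 * n):
        total += 1
        tm = dict(zip(keys, table))
        for blank in (0, 1):
            tape = {}
            pos = lo = hi = 0
            q = 1
            for _ in range(max_steps):
                r = tape.get(pos, blank)
                w, mv, nx = tm[(q, r)]
                tape[pos] = w
                if nx == 0:
                    out = "".join(str(tape.get(i, blank)) for i in range(lo, hi + 1))
                    counts[out] += 1
                    break
                pos += mv
                lo = min(lo, pos)
                hi = max(hi, pos)
                q = nx
    return counts, total


# ---------------------------------------------------------------------------
# statistics


def pearson_closed_form(x, y) -> float:
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def auc_bruteforce(a, b) -> float:
    wins = 0.0
    for x in a:
        for y in b:
            if y > x:
                wins += 1.0
            elif y == x:
                wins += 0.5
    return wins / (len(a) * len(b))


def bfs_distances(n_atoms: int, edges) -> list:
    """All-pairs shortest paths by repeated BFS over an adjacency list."""
    adj = {i: [] for i in range(n_atoms)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    out = []
    for src in range(n_atoms):
        dist = {src: 0}
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        out.append([dist[i] for i in range(n_atoms)])
    return out
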