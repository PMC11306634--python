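"""Seeded synthetic corpora: strings, peak matrices and molecule graphs.

Two classes are emulated throughout: a modular/repetitive class built by
joining previously built pieces (so its members carry genuine statistical
redundancy) and an incompressible control class of i.i.d. random objects.
Paired objects are length/size matched so complexity differences are never an
artifact of size.

All randomness flows from a single integer seed per call through numpy's
splittable ``default_rng([seed, stream, ...])`` scheme: identical arguments
reproduce byte-identical output.
"""

from __future__ import annotations

import csv
import string as _string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encodings import MoleculeGraph, PeakMatrix, Sequence, write_matrix_csv, write_molfile, write_seq_file
from .errors import InvalidArgumentError

__all__ = [
    "GenSpec",
    "gen_random_string",
    "gen_modular_string",
    "gen_peak_matrix",
    "gen_molecule",
    "gen_string_corpus",
    "write_corpus",
    "DEFAULT_CORPUS",
]

_SYMBOLS = _string.ascii_lowercase

#: defaults behind ``gen_string_corpus`` — chosen so the modular class carries
#: strong, measurable redundancy at lengths 8-16
DEFAULT_CORPUS = dict(
    n_per_class=100,
    alphabet_size=4,
    reuse_bias=0.95,
    n_joins_range=(4, 7),
    length_range=(8, 16),
)


@dataclass(frozen=True)
class GenSpec:
    """A reproducible generation request."""

    kind: str  # strings | spectra | molecules
    n_per_class: int
    class_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("strings", "spectra", "molecules"):
            raise InvalidArgumentError(f"unknown kind {self.kind!r}")
        if self.n_per_class < 1:
            raise InvalidArgumentError("n_per_class must be >= 1")
        for key, val in self.class_params.items():
            if key in ("reuse_bias", "flip_noise", "density") and not (0.0 <= val <= 1.0):
                raise InvalidArgumentError(f"{key}={val} outside [0, 1]")


def _alphabet(alphabet_size: int) -> str:
    if alphabet_size < 1:
        raise InvalidArgumentError("alphabet_size must be >= 1")
    if alphabet_size > len(_SYMBOLS):
        raise InvalidArgumentError(f"alphabet_size must be <= {len(_SYMBOLS)}")
    return _SYMBOLS[:alphabet_size]


def gen_random_string(length: int, alphabet_size: int, seed: int) -> Sequence:
    """I.i.d. uniform symbols — the incompressible null model."""
    if length < 1:
        raise InvalidArgumentError("length must be >= 1")
    alpha = _alphabet(alphabet_size)
    rng = np.random.default_rng([seed, 0])
    draws = rng.integers(alphabet_size, size=length)
    return Sequence("".join(alpha[i] for i in draws), alphabet=tuple(alpha))


def gen_modular_string(
    n_joins: int,
    alphabet_size: int = 2,
    reuse_bias: float = 0.5,
    seed: int = 0,
) -> tuple[Sequence, int]:
    """Grow a string by an explicit pathway of concatenations.

    Start from the single symbols of the alphabet; at each of ``n_joins``
    steps pick two existing objects — each operand is the most recently built
    object with probability ``reuse_bias``, otherwise uniform over the pool —
    and append their concatenation.  Returns the last object built together
    with the pathway length (= ``n_joins``), which by construction upper
    bounds the string's exact assembly index.
    """
    if n_joins < 1:
        raise InvalidArgumentError("n_joins must be >= 1")
    if not (0.0 <= reuse_bias <= 1.0):
        raise InvalidArgumentError("reuse_bias must be in [0, 1]")
    alpha = _alphabet(alphabet_size)
    rng = np.random.default_rng([seed, 1])
    pool: list[str] = list(alpha)
    for _ in range(n_joins):
        operands = []
        for _side in range(2):
            if rng.random() < reuse_bias:
                operands.append(pool[-1])
            else:
                operands.append(pool[int(rng.integers(len(pool)))])
        pool.append(operands[0] + operands[1])
    return Sequence(pool[-1], alphabet=tuple(alpha)), n_joins


def gen_peak_matrix(
    rows: int,
    cols: int,
    class_label: str,
    n_templates: int = 2,
    flip_noise: float = 0.0,
    density: float = 0.5,
    seed: int = 0,
) -> PeakMatrix:
    """Binary peak matrix: i.i.d. Bernoulli rows, or noisy copies of templates.

    ``random``: every entry Bernoulli(density).  ``modular``: each row is one
    of ``n_templates`` Bernoulli(density) template rows with each bit flipped
    independently with probability ``flip_noise``.
    """
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("rows and cols must be >= 1")
    for name, p in (("flip_noise", flip_noise), ("density", density)):
        if not (0.0 <= p <= 1.0):
            raise InvalidArgumentError(f"{name}={p} outside [0, 1]")
    rng = np.random.default_rng([seed, 2])
    if class_label == "random":
        values = (rng.random((rows, cols)) < density).astype(int)
    elif class_label == "modular":
        if n_templates < 1 or n_templates > rows:
            raise InvalidArgumentError("need 1 <= n_templates <= rows")
        templates = (rng.random((n_templates, cols)) < density).astype(int)
        assignment = rng.integers(n_templates, size=rows)
        values = templates[assignment]
        flips = rng.random((rows, cols)) < flip_noise
        values = np.where(flips, 1 - values, values)
    else:
        raise InvalidArgumentError(f"unknown class_label {class_label!r}")
    return PeakMatrix(values, binary=True)


_ELEMENTS = ("C", "N", "O")


def gen_molecule(
    class_label: str,
    n_atoms: int,
    monomer_size: int | None = None,
    seed: int = 0,
) -> MoleculeGraph:
    """Connected molecule graphs for distance-matrix inputs.

    ``polymer``: one random ``monomer_size``-atom tree, repeated in a chain
    (consecutive copies bonded tail-to-head).  ``random_tree``: a uniform
    random labelled tree on ``n_atoms`` via its Pruefer sequence.
    """
    if n_atoms < 2:
        raise InvalidArgumentError("n_atoms must be >= 2")
    rng = np.random.default_rng([seed, 3])
    if class_label == "polymer":
        if monomer_size is None or monomer_size < 1:
            raise InvalidArgumentError("polymer requires a positive monomer_size")
        if n_atoms % monomer_size != 0:
            raise InvalidArgumentError("monomer_size must divide n_atoms")
        elements = tuple(_ELEMENTS[i] for i in rng.integers(len(_ELEMENTS), size=monomer_size))
        monomer_bonds = _random_tree_edges(monomer_size, rng) if monomer_size > 1 else []
        n_copies = n_atoms // monomer_size
        atoms: list[str] = []
        bonds: list[tuple[int, int, int]] = []
        for c in range(n_copies):
            off = c * monomer_size
            atoms.extend(elements)
            bonds.extend((i + off, j + off, 1) for i, j in monomer_bonds)
            if c > 0:  # chain link: last atom of previous copy to first of this one
                bonds.append((off - 1, off, 1))
        return MoleculeGraph(tuple(atoms), tuple(bonds))
    if class_label == "random_tree":
        atoms = tuple(_ELEMENTS[i] for i in rng.integers(len(_ELEMENTS), size=n_atoms))
        bonds = tuple((i, j, 1) for i, j in _random_tree_edges(n_atoms, rng))
        return MoleculeGraph(atoms, bonds)
    raise InvalidArgumentError(f"unknown class_label {class_label!r}")


def _random_tree_edges(n: int, rng) -> list[tuple[int, int]]:
    """Uniform labelled tree via a random Pruefer sequence (unbiased)."""
    if n == 1:
        return []
    if n == 2:
        return [(0, 1)]
    prufer = [int(x) for x in rng.integers(n, size=n - 2)]
    degree = [1] * n
    for v in prufer:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, v = sorted(leaves)
    edges.append((u, v))
    return edges


# ---------------------------------------------------------------------------
# the default paired string corpus


def gen_string_corpus(
    n_per_class: int = DEFAULT_CORPUS["n_per_class"],
    alphabet_size: int = DEFAULT_CORPUS["alphabet_size"],
    reuse_bias: float = DEFAULT_CORPUS["reuse_bias"],
    n_joins_range: tuple[int, int] = DEFAULT_CORPUS["n_joins_range"],
    length_range: tuple[int, int] = DEFAULT_CORPUS["length_range"],
    seed: int = 42,
) -> list[tuple[str, str, Sequence]]:
    """Length-matched modular/random string pairs.

    Modular strings are generated first (rejection-sampling the join count
    until the result lands inside ``length_range``); each is paired with an
    i.i.d. random control of identical length.  Returns tidy records
    ``(object_id, class_label, sequence)``.
    """
    lo, hi = length_range
    jlo, jhi = n_joins_range
    if lo < 2 or hi < lo:
        raise InvalidArgumentError("invalid length_range")
    records: list[tuple[str, str, Sequence]] = []
    count = 0
    stream = 0
    while count < n_per_class:
        stream += 1
        pick = np.random.default_rng([seed, stream, 0])
        n_joins = int(pick.integers(jlo, jhi + 1))
        seq, _ = gen_modular_string(n_joins, alphabet_size, reuse_bias, seed=hash_stream(seed, stream))
        if not (lo <= len(seq) <= hi):
            continue
        count += 1
        rand = gen_random_string(len(seq), alphabet_size, seed=hash_stream(seed, stream, 1))
        records.append((f"mod{count:04d}", "modular", seq))
        records.append((f"rnd{count:04d}", "random", rand))
    return records


def hash_stream(*parts: int) -> int:
    """Fold a (seed, stream, ...) tuple into one integer sub-seed."""
    h = 0
    for p in parts:
        h = (h * 1_000_003 + int(p)) % (2**63)
    return h


def write_corpus(spec: GenSpec, out_dir: "str | Path") -> Path:
    """Materialise a GenSpec as plain-text files plus a ``groups.csv`` manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(spec.class_params)
    rows: list[tuple[str, str]] = []
    if spec.kind == "strings":
        records = gen_string_corpus(n_per_class=spec.n_per_class, seed=spec.seed, **params)
        for object_id, label, seq in records:
            write_seq_file(seq, out / f"{object_id}.seq")
            rows.append((object_id, label))
    elif spec.kind == "spectra":
        shape = params.pop("shape", (32, 32))
        for k in range(spec.n_per_class):
            for label in ("modular", "random"):
                object_id = f"{label[:3]}{k + 1:04d}"
                pm = gen_peak_matrix(
                    shape[0], shape[1], label, seed=hash_stream(spec.seed, k, 0 if label == "modular" else 1), **params
                )
                write_matrix_csv(pm.values, out / f"{object_id}.csv")
                rows.append((object_id, label))
    elif spec.kind == "molecules":
        n_atoms = params.pop("n_atoms", 12)
        monomer_size = params.pop("monomer_size", 3)
        for k in range(spec.n_per_class):
            for label, cls in (("modular", "polymer"), ("random", "random_tree")):
                object_id = f"{label[:3]}{k + 1:04d}"
                mol = gen_molecule(
                    cls,
                    n_atoms,
                    monomer_size=monomer_size if cls == "polymer" else None,
                    seed=hash_stream(spec.seed, k, 0 if cls == "polymer" else 1),
                )
                write_molfile(mol, out / f"{object_id}.mol", title=object_id)
                rows.append((object_id, label))
    with open(out / "groups.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["object_id", "class_label"])
        writer.writerows(rows)
    return out
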