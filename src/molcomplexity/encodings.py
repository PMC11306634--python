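"""Data representations and their conversion into one-dimensional sequences.

Molecular inputs arrive in three shapes: opaque identifier text, connection
tables (MOL/SDF V2000) and peak matrices.  Every complexity measure in
:mod:`molcomplexity.measures` consumes a flat :class:`Sequence`, so this module
owns all conversions: 8-bit ASCII binarisation, bond (shortest-path) distance
matrices, and row-major matrix flattening.

Identifier strings are treated as opaque ASCII text; no chemical parsing of
InChI/SMILES layers is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np

from .errors import EncodingError, InvalidArgumentError, ParseError

__all__ = [
    "Sequence",
    "MoleculeGraph",
    "PeakMatrix",
    "ascii_to_bits",
    "bits_to_ascii",
    "bond_distance_matrix",
    "matrix_to_sequence",
    "read_molfile",
    "write_molfile",
    "read_seq_file",
    "write_seq_file",
    "read_matrix_csv",
    "write_matrix_csv",
]


@dataclass(frozen=True)
class Sequence:
    """A finite string over an explicit alphabet.

    ``symbols`` is stored as a plain ``str`` (one character per symbol);
    ``alphabet`` is the ordered tuple of distinct symbols that may occur.
    """

    symbols: str
    alphabet: tuple[str, ...] = field(default=())

    def __post_init__(self):
        alphabet = self.alphabet or tuple(sorted(set(self.symbols)))
        object.__setattr__(self, "alphabet", tuple(alphabet))
        extra = set(self.symbols) - set(self.alphabet)
        if extra:
            raise InvalidArgumentError(
                f"symbols {sorted(extra)} not in declared alphabet {self.alphabet}"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def __iter__(self):
        return iter(self.symbols)

    @property
    def is_binary(self) -> bool:
        return set(self.alphabet) <= {"0", "1"}


def as_symbols(s: "Sequence | str") -> str:
    """Accept either a raw string or a :class:`Sequence`; return the symbols."""
    return s.symbols if isinstance(s, Sequence) else s


@dataclass(frozen=True)
class MoleculeGraph:
    """Atoms plus bonds from a connection table.

    Bonds are ``(i, j, order)`` with 0-based atom indices.  The graph must be
    connected, self-bond free, and all indices in range; this is checked at
    construction so a distance matrix is always well defined.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "bonds", tuple(tuple(b) for b in self.bonds))
        n = len(self.atoms)
        if n < 1:
            raise InvalidArgumentError("molecule must have at least one atom")
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise InvalidArgumentError(f"bond ({i},{j}) references atom out of range")
            if i == j:
                raise InvalidArgumentError(f"self-bond on atom {i}")
        if n > 1 and not nx.is_connected(self.to_networkx()):
            raise InvalidArgumentError("molecule graph is disconnected")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g


@dataclass(frozen=True)
class PeakMatrix:
    """A rows x cols peak matrix; ``binary`` marks presence/absence calls."""

    values: np.ndarray
    binary: bool = True

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidArgumentError("peak matrix must be 2-D and non-empty")
        if self.binary and not np.isin(arr, (0, 1)).all():
            raise InvalidArgumentError("binary peak matrix has entries outside {0,1}")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# text <-> bits


def ascii_to_bits(text: str) -> Sequence:
    """Encode text as fixed 8-bit ASCII, one byte per character.

    Raises :class:`EncodingError` naming the index of the first non-ASCII
    character.
    """
    bits = []
    for i, ch in enumerate(text):
        code = ord(ch)
        if code > 127:
            raise EncodingError(f"non-ASCII character {ch!r}", index=i)
        bits.append(format(code, "08b"))
    return Sequence("".join(bits), alphabet=("0", "1"))


def bits_to_ascii(bits: "Sequence | str") -> str:
    """Inverse of :func:`ascii_to_bits`."""
    b = as_symbols(bits)
    if len(b) % 8 != 0:
        raise InvalidArgumentError("bit string length is not a multiple of 8")
    if set(b) - {"0", "1"}:
        raise InvalidArgumentError("input is not a binary sequence")
    return "".join(chr(int(b[i : i + 8], 2)) for i in range(0, len(b), 8))


# ---------------------------------------------------------------------------
# molecule graphs


def bond_distance_matrix(mol: MoleculeGraph) -> np.ndarray:
    """All-pairs shortest bond-path lengths, as a symmetric integer matrix."""
    n = mol.n_atoms
    g = mol.to_networkx()
    dist = np.zeros((n, n), dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def matrix_to_sequence(
    m: np.ndarray, mode: str = "digits", threshold: float | None = None
) -> Sequence:
    """Flatten a matrix row-major into a sequence.

    ``digits`` mode requires non-negative integer entries and caps each at 9 so
    every entry maps to exactly one symbol.  ``binary`` mode thresholds at
    ``threshold`` (entry >= t -> "1").
    """
    arr = np.asarray(m)
    flat = arr.ravel(order="C")
    if mode == "digits":
        if not np.issubdtype(flat.dtype, np.integer):
            if not np.allclose(flat, np.round(flat)):
                raise InvalidArgumentError("digits mode requires integer entries")
            flat = np.round(flat).astype(int)
        if (flat < 0).any():
            raise InvalidArgumentError("digits mode requires non-negative entries")
        capped = np.minimum(flat, 9)
        return Sequence("".join(str(int(v)) for v in capped))
    if mode == "binary":
        if threshold is None:
            raise InvalidArgumentError("binary mode requires a threshold")
        bits = (flat >= threshold).astype(int)
        return Sequence("".join(str(int(v)) for v in bits), alphabet=("0", "1"))
    raise InvalidArgumentError(f"unknown flattening mode {mode!r}")


# ---------------------------------------------------------------------------
# MOL/SDF V2000 I/O (topology only; coordinates are read and ignored)


def read_molfile(path: "str | Path") -> MoleculeGraph:
    """Read a single-structure MOL V2000 file into a :class:`MoleculeGraph`."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise ParseError("file too short for a V2000 connection table", line=len(lines))
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed counts line {counts!r}", line=4) from None
    if "V2000" not in counts:
        raise ParseError("counts line does not declare V2000", line=4)
    atoms: list[str] = []
    for k in range(n_atoms):
        ln = 4 + k
        if ln >= len(lines):
            raise ParseError("unexpected end of file in atom block", line=len(lines))
        fields = lines[ln].split()
        if len(fields) < 4:
            raise ParseError(f"malformed atom line {lines[ln]!r}", line=ln + 1)
        atoms.append(fields[3])
    bonds: list[tuple[int, int, int]] = []
    for k in range(n_bonds):
        ln = 4 + n_atoms + k
        if ln >= len(lines):
            raise ParseError("unexpected end of file in bond block", line=len(lines))
        raw = lines[ln]
        try:
            i = int(raw[0:3])
            j = int(raw[3:6])
            order = int(raw[6:9]) if raw[6:9].strip() else 1
        except ValueError:
            raise ParseError(f"malformed bond line {raw!r}", line=ln + 1) from None
        if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
            raise ParseError(f"bond references atom out of range: {i} {j}", line=ln + 1)
        bonds.append((i - 1, j - 1, order))  # V2000 is 1-based on disk
    try:
        return MoleculeGraph(tuple(atoms), tuple(bonds))
    except InvalidArgumentError as exc:
        raise ParseError(str(exc), line=4) from exc


def write_molfile(mol: MoleculeGraph, path: "str | Path", title: str = "") -> None:
    """Write a minimal MOL V2000 file (zero coordinates, topology only)."""
    out = [title, "  molcomplexity", ""]
    out.append(f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for element in mol.atoms:
        out.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in mol.bonds:
        out.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0  0  0  0")
    out.append("M  END")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# plain-text sequence and matrix files


def write_seq_file(seq: "Sequence | str", path: "str | Path") -> None:
    Path(path).write_text(as_symbols(seq) + "\n")


def read_seq_file(path: "str | Path") -> Sequence:
    return Sequence(Path(path).read_text().strip())


def write_matrix_csv(m: np.ndarray, path: "str | Path") -> None:
    np.savetxt(path, np.asarray(m), fmt="%g", delimiter=",")


def read_matrix_csv(path: "str | Path", header: bool = False) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1 if header else 0, ndmin=2)
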