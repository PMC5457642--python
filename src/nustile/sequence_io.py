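"""Sequence input/output and the base-pair bonding function.

RNA sequences are strings over the four-letter alphabet {A, C, G, U}.  The
bonding function :func:`delta` is the indicator used by base-pair
maximization: it returns 1 for the Watson-Crick pairs AU and GC and for the
GU wobble pair, provided the first index strictly precedes the second, and
0 otherwise.  Everything downstream (the dynamic program, the tiled
executors) consumes sequences through this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Unordered residue pairs that can bond: AU, GC and the GU wobble pair.
BONDING_PAIRS = frozenset(
    {frozenset(("A", "U")), frozenset(("G", "C")), frozenset(("G", "U"))}
)

_RESIDUE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# _BOND_CODE[a][b] == 1 iff residues with codes a, b can pair (symmetric).
_BOND_CODE = np.zeros((4, 4), dtype=np.int64)
for _x, _y in (("A", "U"), ("G", "C"), ("G", "U")):
    _BOND_CODE[_RESIDUE_CODE[_x], _RESIDUE_CODE[_y]] = 1
    _BOND_CODE[_RESIDUE_CODE[_y], _RESIDUE_CODE[_x]] = 1


class FastaError(ValueError):
    """Raised for files that are not parseable FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a record contains symbols outside {A, C, G, U}."""


@dataclass(frozen=True)
class RNASequence:
    """A validated RNA sequence.

    Parameters
    ----------
    id:
        Text label (FASTA header word).
    residues:
        Uppercase string over ``{A, C, G, U}``; length at least 1.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceValidationError(
                f"record {self.id!r}: empty sequence (N must be >= 1)"
            )
        for pos, ch in enumerate(self.residues):
            if ch not in RNA_ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: invalid symbol {ch!r} at position {pos}"
                )

    @property
    def n(self) -> int:
        """Sequence length N."""
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]

    def codes(self) -> np.ndarray:
        """Residues encoded as integers 0..3 (A, C, G, U)."""
        return np.fromiter(
            (_RESIDUE_CODE[c] for c in self.residues), dtype=np.int64, count=self.n
        )


def read_fasta(path: str | Path, dna_ok: bool = False) -> list[RNASequence]:
    """Read a (multi-record) FASTA file of RNA sequences.

    Residues are uppercased.  ``T`` is rejected unless ``dna_ok`` is set, in
    which case it is converted to ``U``.  Raises :class:`FastaError` naming
    the offending line for files that are not FASTA, and
    :class:`SequenceValidationError` naming record and position for invalid
    symbols.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise FastaError(
                f"{path}: line {lineno}: expected a '>' header before sequence data"
            )
        break
    else:
        raise FastaError(f"{path}: no FASTA records found")

    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            residues = str(rec.seq).upper()
            if dna_ok:
                residues = residues.replace("T", "U")
            records.append(RNASequence(id=rec.id, residues=residues))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def random_rna(n: int, seed: int) -> RNASequence:
    """A seeded random sequence with i.i.d. uniform residues over {A,C,G,U}.

    The same ``(n, seed)`` always yields the same sequence.
    """
    if n < 1:
        raise ValueError(f"sequence length must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACGU"))
    residues = "".join(rng.choice(letters, size=n))
    return RNASequence(id=f"random_n{n}_s{seed}", residues=residues)


def delta(seq: RNASequence, i: int, j: int, min_loop: int = 0) -> int:
    """Bonding indicator: 1 iff i < j and (seq[i], seq[j]) is AU, GC or GU.

    ``min_loop`` optionally requires ``j - i > min_loop`` (default 0, i.e.
    adjacent residues may pair).
    """
    n = seq.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"indices ({i}, {j}) out of range for N={n}")
    if j - i <= min_loop:
        return 0
    return 1 if frozenset((seq[i], seq[j])) in BONDING_PAIRS else 0


def bond_matrix(seq: RNASequence, min_loop: int = 0) -> np.ndarray:
    """N x N 0/1 matrix with ``delta(seq, i, j)`` at (i, j).

    Vectorized convenience for the executors; entries with ``j - i <=
    min_loop`` (in particular the lower triangle and diagonal) are 0.
    """
    codes = seq.codes()
    m = _BOND_CODE[codes[:, None], codes[None, :]]
    n = seq.n
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    m[(jj - ii) <= min_loop] = 0
    return m


# ---------------------------------------------------------------------------
# Dot-bracket structure serialization
# ---------------------------------------------------------------------------

class CrossingPairsError(ValueError):
    """Dot-bracket notation cannot express crossing pairs (pseudoknots)."""


def _check_pairs(pairs: Iterable[tuple[int, int]], n: int) -> list[tuple[int, int]]:
    plist = sorted(tuple(p) for p in pairs)
    seen: set[int] = set()
    for i, j in plist:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i}, {j}) out of range for N={n}")
        if i in seen or j in seen:
            raise ValueError(f"index reused by pair ({i}, {j})")
        seen.update((i, j))
    for a in range(len(plist)):
        i, j = plist[a]
        for k, l in plist[a + 1:]:
            if i < k < j < l:
                raise CrossingPairsError(
                    f"pairs ({i},{j}) and ({k},{l}) cross; refusing to serialize"
                )
    return plist


def dot_bracket(structure, n: int) -> str:
    """Render a non-crossing pair set as a dot-bracket string of length n."""
    pairs = _check_pairs(structure.pairs, n)
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def parse_dot_bracket(s: str) -> set[tuple[int, int]]:
    """Inverse of :func:`dot_bracket`: recover the pair set."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(s):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket symbol {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def write_structure(seq: RNASequence, structure, path: str | Path) -> None:
    """Write ``>id / residues / dot-bracket`` to ``path`` (appendable format).

    Refuses structures with crossing pairs.
    """
    text = f">{seq.id}\n{seq.residues}\n{dot_bracket(structure, seq.n)}\n"
    with open(path, "a") as fh:
        fh.write(text)


def read_structures(path: str | Path) -> list[tuple[RNASequence, set[tuple[int, int]]]]:
    """Read records written by :func:`write_structure`."""
    out = []
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    k = 0
    while k < len(lines):
        if not lines[k].startswith(">"):
            raise FastaError(f"{path}: expected header at line {k + 1}")
        seq = RNASequence(id=lines[k][1:].split()[0], residues=lines[k + 1].upper())
        pairs = parse_dot_bracket(lines[k + 2])
        out.append((seq, pairs))
        k += 3
    return out
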