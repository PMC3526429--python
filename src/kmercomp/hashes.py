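"""Position-wise nucleotide-projection hash functions.

A hash function in this family maps a k-mer to a k-bit integer by projecting
each nucleotide independently to a single bit, depending only on its letter.
There are exactly seven such functions up to global bit complement: three
*balanced* ones (two letters map to 0, two to 1) and four *unbalanced* ones
(one letter maps to 0, three to 1).  Balanced functions spread codes uniformly
over the 2^k values; unbalanced ones do not and therefore collide more often.

The family supports O(1) rolling evaluation along a read: the code of the
next k-mer is the previous code shifted left by one bit, truncated to k bits,
with the new nucleotide's bit appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterator

import numpy as np

__all__ = [
    "HashFunctionSpec",
    "AmbiguousBaseError",
    "enumerate_functions",
    "get_function",
    "parse_functions",
    "hash_kmer",
    "rolling_hashes",
    "reverse_complement",
]

_NUCLEOTIDES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a character outside A/C/G/T."""


@dataclass(frozen=True)
class HashFunctionSpec:
    """One member of the nucleotide-projection hash family.

    Parameters
    ----------
    id
        Function number, 1..7. Functions 1-3 are balanced, 4-7 unbalanced.
    zero_set
        The nucleotides that project to bit 0; all others project to 1.
    """

    id: int
    zero_set: frozenset[str]
    # per-letter 0/1 lookup, derived; excluded from equality
    bit_of: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.zero_set or len(self.zero_set) >= 4:
            raise ValueError("zero_set must be a non-empty proper subset of ACGT")
        table = {nt: (0 if nt in self.zero_set else 1) for nt in _NUCLEOTIDES}
        object.__setattr__(self, "bit_of", table)

    @property
    def balanced(self) -> bool:
        return len(self.zero_set) == 2

    @property
    def name(self) -> str:
        return f"f{self.id}"

    def bit_table(self) -> np.ndarray:
        """Bits for (A, C, G, T) in that order, as a uint64 array."""
        return np.array([self.bit_of[nt] for nt in _NUCLEOTIDES], dtype=np.uint64)


def _canonical_functions() -> tuple[HashFunctionSpec, ...]:
    specs = [
        HashFunctionSpec(1, frozenset("AC")),
        HashFunctionSpec(2, frozenset("AG")),
        HashFunctionSpec(3, frozenset("AT")),
        HashFunctionSpec(4, frozenset("A")),
        HashFunctionSpec(5, frozenset("C")),
        HashFunctionSpec(6, frozenset("G")),
        HashFunctionSpec(7, frozenset("T")),
    ]
    return tuple(specs)


_FUNCTIONS = _canonical_functions()
_BY_NAME = {f.name: f for f in _FUNCTIONS}
# aliases: b1..b3 for the balanced trio, u1..u4 for the unbalanced quartet
_BY_NAME.update({f"b{i}": _FUNCTIONS[i - 1] for i in (1, 2, 3)})
_BY_NAME.update({f"u{i}": _FUNCTIONS[i + 2] for i in (1, 2, 3, 4)})


def enumerate_functions() -> list[HashFunctionSpec]:
    """Return the seven distinct projection functions.

    Of the 16 possible nucleotide->bit labelings, the two constant ones hash
    every k-mer identically and are useless; the remaining 14 pair up under
    global bit complement (a labeling and its complement index the same
    partition of k-mer space), leaving 7 equivalence classes.  Each class is
    represented by the labeling whose zero_set is listed in its canonical
    form.
    """
    return list(_FUNCTIONS)


def enumerate_labelings_bruteforce() -> list[frozenset[str]]:
    """Independent enumeration of the function family from first principles.

    Walks all 2^4 binary labelings of {A,C,G,T}, discards the two constants,
    and merges each labeling with its complement, keeping the zero_set of
    whichever member of the pair is lexicographically smaller. Used as a
    cross-check of :func:`enumerate_functions`.
    """
    classes: set[frozenset[str]] = set()
    for bits in product((0, 1), repeat=4):
        zero = frozenset(nt for nt, b in zip(_NUCLEOTIDES, bits) if b == 0)
        if len(zero) in (0, 4):
            continue
        comp = frozenset(_NUCLEOTIDES) - zero
        # canonical representative: the smaller zero_set, ties broken
        # alphabetically (so balanced classes are named by their A-containing
        # member and unbalanced ones by their singleton)
        classes.add(min(zero, comp, key=lambda s: (len(s), sorted(s))))
    return sorted(classes, key=lambda s: (len(s) != 2, sorted(s)))


def get_function(name: str) -> HashFunctionSpec:
    """Look up a function by name: ``f1``..``f7``, ``b1``..``b3`` or ``u1``..``u4``."""
    try:
        return _BY_NAME[name.lower()]
    except KeyError:
        raise KeyError(f"unknown hash function {name!r}; use f1-f7, b1-b3 or u1-u4")


def parse_functions(spec: str) -> list[HashFunctionSpec]:
    """Parse a comma-separated list like ``"b1,b2,b3,u1"``."""
    funcs = [get_function(tok.strip()) for tok in spec.split(",") if tok.strip()]
    if not funcs:
        raise ValueError("empty function list")
    if len(set(f.id for f in funcs)) != len(funcs):
        raise ValueError(f"duplicate hash functions in {spec!r}")
    return funcs


def hash_kmer(f: HashFunctionSpec, kmer: str) -> int:
    """Hash a k-mer to its k-bit code under one projection function.

    The leftmost nucleotide occupies the most significant bit, so consecutive
    k-mer codes are related by ``(code << 1 | newbit) & (2**k - 1)``.

    Raises
    ------
    AmbiguousBaseError
        If the k-mer contains a character outside A/C/G/T (case-insensitive).
    """
    code = 0
    table = f.bit_of
    for ch in kmer.upper():
        try:
            code = (code << 1) | table[ch]
        except KeyError:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer {kmer!r}")
    return code


def rolling_hashes(
    f: HashFunctionSpec, sequence: str, k: int
) -> Iterator[tuple[int, int]]:
    """Yield ``(position, code)`` for every k-mer of ``sequence``.

    Codes are produced by the O(1) rolling update.  K-mers containing an
    ambiguous base are skipped and the rolling state restarts after the
    offending character.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    mask = (1 << k) - 1
    table = f.bit_of
    code = 0
    valid = 0  # length of the current run of unambiguous bases
    for i, ch in enumerate(seq):
        bit = table.get(ch)
        if bit is None:
            valid = 0
            code = 0
            continue
        code = ((code << 1) | bit) & mask
        valid += 1
        if valid >= k:
            yield i - k + 1, code


def sequence_codes(
    functions: list[HashFunctionSpec], sequence: str, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rolling hashes for several functions at once.

    Returns ``(positions, codes)`` where ``positions`` has shape (m,) and
    ``codes`` has shape (len(functions), m); column j holds the codes of the
    k-mer starting at ``positions[j]`` under each function.  K-mers spanning
    ambiguous bases are excluded.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < k:
        return np.empty(0, dtype=np.int64), np.empty((len(functions), 0), dtype=np.uint64)
    # map letters to 0..3, anything else to 4
    idx = np.full(L, 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for v, nt in enumerate(_NUCLEOTIDES):
        idx[arr == ord(nt)] = v
    ok = idx < 4
    # positions whose window [i, i+k) is all unambiguous
    win_ok = np.ones(L - k + 1, dtype=bool)
    bad = np.flatnonzero(~ok)
    for b in bad:
        lo = max(0, b - k + 1)
        hi = min(L - k, b)
        win_ok[lo : hi + 1] = False
    positions = np.flatnonzero(win_ok).astype(np.int64)
    if positions.size == 0:
        return positions, np.empty((len(functions), 0), dtype=np.uint64)
    safe_idx = np.where(ok, idx, 0).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(safe_idx, k)[positions]
    weights = (np.uint64(1) << np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(
        np.uint64
    )
    codes = np.empty((len(functions), positions.size), dtype=np.uint64)
    for fi, f in enumerate(functions):
        bits = f.bit_table()[windows]  # (m, k) of 0/1
        codes[fi] = bits @ weights
    return positions, codes


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    seq = sequence
    allowed = set("ACGTNacgtn")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]
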