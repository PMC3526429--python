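"""The Bloom Data Structure (BDS): a Bloom-filter variant for k-mer sets.

Unlike a classical Bloom filter, each hash function owns a *disjoint* 2^k-bit
array addressed directly by the function's k-bit code — there is no modular
reduction anywhere.  A k-mer is inserted by setting one bit per function and
is reported present iff every function's bit is set.  False negatives never
occur; the false-positive rate is governed by the closed-form model in
:mod:`kmercomp.fp_model`.
"""

from __future__ import annotations

import struct

import numpy as np

from .hashes import (
    AmbiguousBaseError,
    HashFunctionSpec,
    enumerate_functions,
    hash_kmer,
)

__all__ = ["BDSIndex", "bds_memory_bits", "default_functions", "MemoryBudgetError"]

_MAGIC = b"KMERBDS1"

#: Hard cap on the total bit-array allocation (bytes).  k=33 with 4 functions
#: needs 4 GiB; anything beyond that is almost certainly a mistake.
DEFAULT_MEMORY_BUDGET = 4 << 30

DEFAULT_K = 33


class MemoryBudgetError(MemoryError):
    """k too large for the configured memory budget."""


def default_functions() -> list[HashFunctionSpec]:
    """The production combination: the three balanced functions plus one
    unbalanced (f1, f2, f3, f4)."""
    return enumerate_functions()[:4]


def bds_memory_bits(k: int, n_functions: int) -> int:
    """Total size of the bit arrays: ``n_functions * 2**k`` bits, independent
    of how many k-mers are inserted."""
    return n_functions * (1 << k)


class BDSIndex:
    """Probabilistic k-mer membership index with per-function bit arrays.

    Parameters
    ----------
    k
        K-mer length; the arrays hold 2^k bits each.
    functions
        Hash functions to combine (default: f1-f3 balanced + f4 unbalanced).
    memory_budget_bytes
        Allocation guard; creation fails if the arrays would exceed it.

    Attributes
    ----------
    kmers_indexed
        Number of k-mer *occurrences* inserted since creation or the last
        :meth:`reset` (repeats count every time).
    """

    def __init__(
        self,
        k: int,
        functions: list[HashFunctionSpec] | None = None,
        memory_budget_bytes: int = DEFAULT_MEMORY_BUDGET,
    ) -> None:
        if not 1 <= k <= DEFAULT_K:
            raise ValueError(f"k must be in 1..{DEFAULT_K}, got {k}")
        functions = list(functions) if functions is not None else default_functions()
        if not functions:
            raise ValueError("at least one hash function required")
        if len({f.id for f in functions}) != len(functions):
            raise ValueError("duplicate hash functions")
        total_bits = bds_memory_bits(k, len(functions))
        if total_bits > 8 * memory_budget_bytes:
            raise MemoryBudgetError(
                f"BDS with k={k} and {len(functions)} functions needs "
                f"{total_bits // 8} bytes, exceeding the "
                f"{memory_budget_bytes}-byte memory budget"
            )
        self.k = k
        self.functions = functions
        words = max(1, (1 << k) >> 6)
        # one packed uint64 bitset per function
        self._arrays = [np.zeros(words, dtype=np.uint64) for _ in functions]
        self.kmers_indexed = 0

    # -- sizing ------------------------------------------------------------

    def memory_bits(self) -> int:
        return bds_memory_bits(self.k, len(self.functions))

    # -- core operations ---------------------------------------------------

    def insert(self, kmer: str) -> None:
        """Insert one k-mer; k-mers with ambiguous bases are skipped silently
        and do not advance :attr:`kmers_indexed`."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        try:
            codes = [hash_kmer(f, kmer) for f in self.functions]
        except AmbiguousBaseError:
            return
        for arr, code in zip(self._arrays, codes):
            arr[code >> 6] |= np.uint64(1) << np.uint64(code & 63)
        self.kmers_indexed += 1

    def contains(self, kmer: str) -> bool:
        """Membership query; may return a false positive, never a false
        negative. K-mers with ambiguous bases are never indexed, so False."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        try:
            codes = [hash_kmer(f, kmer) for f in self.functions]
        except AmbiguousBaseError:
            return False
        return all(
            bool((arr[code >> 6] >> np.uint64(code & 63)) & np.uint64(1))
            for arr, code in zip(self._arrays, codes)
        )

    def reset(self) -> None:
        """Zero all arrays and the occurrence counter; capacity retained."""
        for arr in self._arrays:
            arr.fill(0)
        self.kmers_indexed = 0

    # -- vectorised paths (used by the comparison engine & simulations) ----

    def insert_codes(self, codes: np.ndarray) -> None:
        """Insert pre-hashed k-mers; ``codes`` has shape (n_functions, m)."""
        if codes.shape[0] != len(self.functions):
            raise ValueError("code matrix row count must match function count")
        for arr, row in zip(self._arrays, codes):
            np.bitwise_or.at(
                arr, (row >> np.uint64(6)).astype(np.int64), np.uint64(1) << (row & np.uint64(63))
            )
        self.kmers_indexed += codes.shape[1]

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership over pre-hashed k-mers; returns bool (m,)."""
        if codes.shape[0] != len(self.functions):
            raise ValueError("code matrix row count must match function count")
        hit = np.ones(codes.shape[1], dtype=bool)
        for arr, row in zip(self._arrays, codes):
            word = arr[(row >> np.uint64(6)).astype(np.int64)]
            hit &= ((word >> (row & np.uint64(63))) & np.uint64(1)).astype(bool)
        return hit

    # -- serialization (debugging aid) -------------------------------------

    def dump(self, path) -> None:
        """Write the index: magic, k, function ids, then the raw arrays.
        A debugging format; not compatible with any other tool."""
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<BB", self.k, len(self.functions)))
            fh.write(bytes(f.id for f in self.functions))
            fh.write(struct.pack("<Q", self.kmers_indexed))
            for arr in self._arrays:
                fh.write(arr.tobytes())

    @classmethod
    def load(cls, path) -> "BDSIndex":
        from .hashes import get_function

        with open(path, "rb") as fh:
            if fh.read(8) != _MAGIC:
                raise ValueError("not a BDS index file")
            k, nf = struct.unpack("<BB", fh.read(2))
            ids = fh.read(nf)
            funcs = [get_function(f"f{i}") for i in ids]
            idx = cls(k, funcs)
            (idx.kmers_indexed,) = struct.unpack("<Q", fh.read(8))
            for arr in idx._arrays:
                buf = fh.read(arr.nbytes)
                arr[:] = np.frombuffer(buf, dtype=np.uint64)
        return idx
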