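"""Directional read-set intersection by shared k-mer content.

The fundamental operation finds the reads of a query set that share at least
``t`` non-overlapping k-mers with the k-mer content of a target set.  The
target is indexed in chunks of at most ``chunk_limit`` k-mer occurrences;
after each chunk every not-yet-matched query read is scanned, and the final
answer is the union over chunks — equivalent to indexing the whole target at
once.

Two membership backends are available: the probabilistic BDS index
(production) and an exact hash set (oracle, used in tests and for small
inputs).  The BDS can only add false positives, so its flag set always
contains the exact one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hashes import HashFunctionSpec, reverse_complement, sequence_codes
from .index import BDSIndex, DEFAULT_K, default_functions
from .read_io import ReadSet

__all__ = [
    "ComparisonParams",
    "DirectionalResult",
    "count_shared_nonoverlapping",
    "intersect_directional",
]


@dataclass
class ComparisonParams:
    """Tuning knobs of the intersection heuristic.

    Parameters
    ----------
    k
        K-mer length (default 33).
    t
        Minimum number of non-overlapping shared k-mers for a read to count
        as similar (default 2).
    chunk_limit
        Maximum k-mer occurrences indexed per target chunk (default 1e9).
    functions
        Hash combination for the BDS backend (default f1+f2+f3+f4).
    backend
        ``"bds"`` (probabilistic) or ``"exact"`` (hash-set oracle).
    reverse_complement
        Also scan each query read's reverse complement; a read qualifies if
        either orientation reaches ``t`` hits.  Off by default: similarity is
        defined on literal substrings.
    """

    k: int = DEFAULT_K
    t: int = 2
    chunk_limit: int = 10**9
    functions: list[HashFunctionSpec] = field(default_factory=default_functions)
    backend: str = "bds"
    reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.t < 1 or self.chunk_limit < 1:
            raise ValueError("k, t and chunk_limit must all be >= 1")
        if self.backend not in ("bds", "exact"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class DirectionalResult:
    """Outcome of one query-against-target pass."""

    query_sample: str
    target_sample: str
    member_flags: np.ndarray  # bool, one per query read
    matched_count: int
    chunks_used: int


# -- membership backends ---------------------------------------------------


class _ExactMembership:
    """Exact k-mer set; the oracle backend."""

    def __init__(self, k: int, functions) -> None:
        self.k = k
        self._kmers: set[str] = set()
        self.count = 0

    def add_sequence(self, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        for pos in _valid_positions(seq, k):
            self._kmers.add(seq[pos : pos + k])
            self.count += 1

    def hit_positions(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        k = self.k
        seq = seq.upper()
        positions = _valid_positions(seq, k)
        hits = np.fromiter(
            (seq[p : p + k] in self._kmers for p in positions),
            dtype=bool,
            count=positions.size,
        )
        return positions, hits

    def reset(self) -> None:
        self._kmers.clear()
        self.count = 0


class _BDSMembership:
    """Probabilistic backend over a :class:`BDSIndex`."""

    def __init__(self, k: int, functions) -> None:
        self.k = k
        self.functions = list(functions)
        self.index = BDSIndex(k, self.functions)
        self.count = 0

    def add_sequence(self, seq: str) -> None:
        positions, codes = sequence_codes(self.functions, seq, self.k)
        if positions.size:
            self.index.insert_codes(codes)
            self.count += positions.size

    def hit_positions(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        positions, codes = sequence_codes(self.functions, seq, self.k)
        if positions.size == 0:
            return positions, np.empty(0, dtype=bool)
        return positions, self.index.contains_codes(codes)

    def reset(self) -> None:
        self.index.reset()
        self.count = 0


def _valid_positions(seq: str, k: int) -> np.ndarray:
    """Start positions of k-mers free of ambiguous bases."""
    L = len(seq)
    if L < k:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    win_ok = np.ones(L - k + 1, dtype=bool)
    for b in np.flatnonzero(~ok):
        win_ok[max(0, b - k + 1) : min(L - k, b) + 1] = False
    return np.flatnonzero(win_ok).astype(np.int64)


def _countable_kmers(seq: str, k: int) -> int:
    return int(_valid_positions(seq.upper(), k).size)


def _greedy_scan(positions: np.ndarray, hits: np.ndarray, k: int, t: int) -> bool:
    """Left-to-right greedy selection of non-overlapping membership hits.

    On a hit at position p the scan resumes at p + k; returns True as soon as
    t hits are collected.  For equal-length intervals the greedy choice is
    optimal, so this maximises the count of non-overlapping shared k-mers.
    """
    count = 0
    next_ok = -1
    for p, h in zip(positions, hits):
        if p < next_ok or not h:
            continue
        count += 1
        if count >= t:
            return True
        next_ok = p + k
    return False


def count_shared_nonoverlapping(
    read: str, index, t: int, params: ComparisonParams
) -> bool:
    """Decide whether a read is similar to the indexed k-mer content.

    ``index`` may be a :class:`BDSIndex` or an exact membership backend.  If
    ``params.reverse_complement`` is set and the forward scan fails, the
    reverse complement is scanned as well.
    """
    backend = index
    if isinstance(index, BDSIndex):
        backend = _BDSMembership.__new__(_BDSMembership)
        backend.k = index.k
        backend.functions = index.functions
        backend.index = index
        backend.count = index.kmers_indexed
    if backend.k != params.k:
        raise ValueError(f"index k={backend.k} does not match params.k={params.k}")
    positions, hits = backend.hit_positions(read)
    if _greedy_scan(positions, hits, params.k, t):
        return True
    if params.reverse_complement:
        rc = reverse_complement(read)
        positions, hits = backend.hit_positions(rc)
        return _greedy_scan(positions, hits, params.k, t)
    return False


def intersect_directional(
    query: ReadSet,
    target: ReadSet,
    params: ComparisonParams,
    skip_flags=None,
) -> DirectionalResult:
    """Compute the directional intersection query->target.

    The target is streamed whole-read-wise into chunks of at most
    ``params.chunk_limit`` countable k-mer occurrences (a single read larger
    than the limit forms its own chunk); after each chunk the query reads not
    yet matched are scanned and the index is reset.  Reads with
    ``skip_flags`` set are never scanned and never flagged (used by the
    pipeline to restrict a pass to a previously selected subset).
    """
    n_query = len(query)
    flags = np.zeros(n_query, dtype=bool)
    if skip_flags is not None:
        skip = np.asarray(skip_flags, dtype=bool)
        if skip.shape != (n_query,):
            raise ValueError("skip_flags length must equal query read count")
    else:
        skip = np.zeros(n_query, dtype=bool)

    cls = _ExactMembership if params.backend == "exact" else _BDSMembership
    membership = cls(params.k, params.functions)
    chunks_used = 0

    def flush() -> None:
        nonlocal chunks_used
        chunks_used += 1
        for i, read in enumerate(query.reads):
            if flags[i] or skip[i]:
                continue
            if count_shared_nonoverlapping(read.sequence, membership, params.t, params):
                flags[i] = True
        membership.reset()

    for read in target.reads:
        c = _countable_kmers(read.sequence, params.k)
        if membership.count > 0 and membership.count + c > params.chunk_limit:
            flush()
        membership.add_sequence(read.sequence)

    if membership.count > 0 or (len(target) > 0 and chunks_used == 0):
        flush()

    return DirectionalResult(
        query_sample=query.sample_name,
        target_sample=target.sample_name,
        member_flags=flags,
        matched_count=int(flags.sum()),
        chunks_used=chunks_used,
    )
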