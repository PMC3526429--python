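"""Deterministic synthetic read sets with known shared content.

Reads are uniform i.i.d. A/C/G/T; similarity between samples is *planted* by
copying an identical block of length >= t*k into a chosen fraction of reads
of each sample, so the ground-truth similar reads are known exactly.  A
separate constructor builds the three decoy archetypes that exercise the
spread-k-mer false-positive behaviour of the symmetric pipeline.

The generator emulates sequence sharing only: no sequencing errors, no
abundance structure, no realistic read-length distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .read_io import Read, ReadSet

__all__ = ["SimSpec", "random_reads", "planted_pair", "grouped_samples", "decoy_pair"]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSpec:
    """Parameters of a synthetic dataset.

    ``planted_similarity`` is the fraction of reads of each sample that carry
    an identical block of length ``block_length`` (default t*k) copied into
    an otherwise-random read.
    """

    n_reads: int = 200
    read_length: int = 200
    n_samples: int = 2
    planted_similarity: float = 0.3
    k: int = 33
    t: int = 2
    block_length: int | None = None
    group_structure: list[list[int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_similarity <= 1.0:
            raise ValueError("planted_similarity must be in [0, 1]")
        if self.block_length is None:
            self.block_length = self.t * self.k

    @property
    def n_planted(self) -> int:
        return int(round(self.planted_similarity * self.n_reads))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def random_reads(spec: SimSpec, sample_index: int = 0, name: str | None = None) -> ReadSet:
    """One sample of uniform random reads; deterministic under (seed, index)."""
    rng = np.random.default_rng([spec.seed, sample_index])
    name = name or f"sample{sample_index}"
    reads = [
        Read(f"{name}_r{i}", _random_seq(rng, spec.read_length))
        for i in range(spec.n_reads)
    ]
    return ReadSet(sample_name=name, reads=reads)


def _plant(seq: str, block: str, rng: np.random.Generator) -> str:
    if len(block) > len(seq):
        raise ValueError(
            f"planted block ({len(block)} nt) longer than read ({len(seq)} nt)"
        )
    off = int(rng.integers(0, len(seq) - len(block) + 1))
    return seq[:off] + block + seq[off + len(block) :]


def planted_pair(spec: SimSpec) -> tuple[ReadSet, ReadSet, tuple[np.ndarray, np.ndarray]]:
    """Two samples with a planted identical block in a known subset of reads.

    Read i of A and read i of B, for i < n_planted, each carry a copy of the
    same random block (length >= t*k, random offset); all other sequence is
    independent.  Returns the two read sets and the ground-truth
    similar-read flags for each.
    """
    if spec.block_length > spec.read_length:
        raise ValueError(
            f"block_length {spec.block_length} exceeds read_length {spec.read_length}"
        )
    rng = np.random.default_rng([spec.seed, 941])
    A = random_reads(spec, 0, name="A")
    B = random_reads(spec, 1, name="B")
    n_p = spec.n_planted
    for i in range(n_p):
        block = _random_seq(rng, spec.block_length)
        A.reads[i] = Read(A.reads[i].id, _plant(A.reads[i].sequence, block, rng))
        B.reads[i] = Read(B.reads[i].id, _plant(B.reads[i].sequence, block, rng))
    flags = np.zeros(spec.n_reads, dtype=bool)
    flags[:n_p] = True
    return A, B, (flags, flags.copy())


def grouped_samples(spec: SimSpec) -> list[ReadSet]:
    """Samples partitioned into groups sharing a common planted block pool.

    Samples in the same group plant blocks drawn from a shared pool into
    ``planted_similarity`` of their reads, so within-group similarity is high
    and between-group similarity is near zero.  ``spec.group_structure``
    partitions sample indices; default: two halves.
    """
    groups = spec.group_structure
    if groups is None:
        half = spec.n_samples // 2
        groups = [list(range(half)), list(range(half, spec.n_samples))]
    rng = np.random.default_rng([spec.seed, 577])
    n_p = spec.n_planted
    pools = {
        gi: [_random_seq(rng, spec.block_length) for _ in range(n_p)]
        for gi in range(len(groups))
    }
    samples: list[ReadSet] = []
    for gi, members in enumerate(groups):
        for si in members:
            rs = random_reads(spec, si, name=f"g{gi}s{si}")
            for i in range(n_p):
                rs.reads[i] = Read(
                    rs.reads[i].id, _plant(rs.reads[i].sequence, pools[gi][i], rng)
                )
            samples.append(rs)
    return samples


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def decoy_pair(
    k: int = 15, t: int = 2, seed: int = 0
) -> tuple[ReadSet, ReadSet, dict[str, np.ndarray]]:
    """Two read sets realising the three decoy archetypes of the pipeline.

    With t = 2 the sets contain, besides background reads:

    * ``a1`` sharing two non-overlapping k-mers with the single read ``b1``
      (genuinely similar — retained by the pipeline);
    * ``a2`` sharing one k-mer each with ``b2`` and ``b3``, which share
      nothing else with A (a spread-k-mer decoy — removed at step 3, because
      b2 and b3 do not survive step 2);
    * ``a3`` sharing one k-mer each with ``b1`` and ``b4``, where ``b4`` is
      itself similar to ``a4`` (the residual false positive: both carriers
      survive step 2, so a3 is retained);
    * ``a4`` sharing two non-overlapping k-mers with ``b4`` (retained).

    The construction is rejection-sampled until the exact-k-mer sharing
    pattern between every pair of reads matches the intended design, so the
    expected outcome holds by construction.  Returns (A, B, expected) where
    ``expected`` has boolean vectors ``a_hat``, ``a_final`` and ``b_hat``.
    """
    read_len = 3 * k + 6
    for attempt in range(50):
        rng = np.random.default_rng([seed, 131, attempt])
        blocks = {nm: _random_seq(rng, k) for nm in ("X1", "X2", "Y1", "Y2", "Z1", "Z2", "W1", "W2")}

        # The character immediately flanking a planted block is pinned to a
        # set-specific letter ('A' in A-reads, 'C' in B-reads), so every
        # k-mer spanning a block junction differs between the two copies of
        # the block — only the blocks themselves can be shared.
        def make(pair: tuple[str | None, str | None], flank: str) -> str:
            seq = list(_random_seq(rng, read_len))
            left, right = pair
            if left is not None:
                seq[0:k] = blocks[left]
                seq[k] = flank
            if right is not None:
                seq[2 * k + 2] = flank
                seq[2 * k + 3 : 3 * k + 3] = blocks[right]
                seq[3 * k + 3] = flank
            return "".join(seq)

        a_reads = [
            make(("X1", "X2"), "A"),  # a1
            make(("Y1", "Y2"), "A"),  # a2
            make(("Z1", "Z2"), "A"),  # a3
            make(("W1", "W2"), "A"),  # a4
        ]
        b_reads = [
            make(("X1", "X2"), "C"),  # b1 — also carries Z1 below
            make(("Y1", None), "C"),  # b2
            make(("Y2", None), "C"),  # b3
            make(("W1", "W2"), "C"),  # b4 — also carries Z2 below
        ]
        # graft the single decoy k-mers of a3 onto b1 and b4 (middle slot)
        mid = k + 2
        for bi, block in ((0, "Z1"), (3, "Z2")):
            seq = list(b_reads[bi])
            seq[mid - 1] = "C"
            seq[mid : mid + k] = blocks[block]
            seq[mid + k] = "C"
            b_reads[bi] = "".join(seq)

        if _pattern_ok(a_reads, b_reads, blocks, k):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not realise the decoy k-mer sharing pattern")

    A = ReadSet("A", [Read(f"a{i+1}", s) for i, s in enumerate(a_reads)])
    B = ReadSet("B", [Read(f"b{i+1}", s) for i, s in enumerate(b_reads)])
    expected = {
        "a_hat": np.array([True, True, True, True]),
        "b_hat": np.array([True, False, False, True]),
        "a_final": np.array([True, False, True, True]),
    }
    return A, B, expected


def _pattern_ok(a_reads, b_reads, blocks, k) -> bool:
    """Exact check that the only shared k-mers are the intended blocks and
    that grafting did not clobber a planted block."""
    intended = {
        (0, 0): {blocks["X1"], blocks["X2"]},
        (1, 1): {blocks["Y1"]},
        (1, 2): {blocks["Y2"]},
        (2, 0): {blocks["Z1"]},
        (2, 3): {blocks["Z2"]},
        (3, 3): {blocks["W1"], blocks["W2"]},
    }
    for i, a in enumerate(a_reads):
        for j, b in enumerate(b_reads):
            shared = _kmers(a, k) & _kmers(b, k)
            if shared != intended.get((i, j), set()):
                return False
    # no accidental sharing inside either set beyond self
    for reads in (a_reads, b_reads):
        for i in range(len(reads)):
            for j in range(i + 1, len(reads)):
                if _kmers(reads[i], k) & _kmers(reads[j], k):
                    return False
    return True
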