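"""Closed-form and empirical false-positive analysis of the BDS index.

For a query k-mer drawn uniformly at random and n distinct indexed k-mers:

* a **balanced** function distributes codes uniformly over the 2^k cells, so
  the per-function false-positive probability is ``1 - (1 - 2^-k)^n``;
* an **unbalanced** function maps a k-mer with x "distinguished-letter"
  positions to a cell hit by any single insertion with probability
  ``a_x = (1/4)^x (3/4)^(k-x)``, giving
  ``sum_x C(k,x) a_x (1 - (1 - a_x)^n)``;
* a **combination** of functions is scored by multiplying the individual
  probabilities.  For the three balanced functions no two distinct k-mers
  collide on two functions at once, so the product is a true upper bound;
  for mixed combinations it is an independence approximation that simulation
  shows to be accurate.

Classical Bloom-filter reference formulas are included for comparison only;
the production index never uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .hashes import HashFunctionSpec
from .index import BDSIndex, default_functions

__all__ = [
    "FPQuery",
    "p_fp_balanced",
    "p_fp_unbalanced",
    "p_fp_function",
    "p_fp_combo",
    "bloom_fp_asymptotic",
    "bloom_memory_bits",
    "simulate_fp",
]


@dataclass
class FPQuery:
    """Parameters of a false-positive-rate evaluation."""

    k: int
    n: int
    combo: list[HashFunctionSpec] = field(default_factory=default_functions)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not self.combo:
            raise ValueError("combo must be non-empty")


def p_fp_balanced(k: int, n: float) -> float:
    """FP probability of one balanced function: ``1 - (1 - 2^-k)^n``.

    Evaluated as ``-expm1(n * log1p(-2^-k))`` so it stays accurate when
    ``(1 - 2^-k)^n`` underflows or is close to 1.
    """
    if n == 0:
        return 0.0
    return float(-np.expm1(n * np.log1p(-(2.0 ** -k))))


def p_fp_unbalanced(k: int, n: float) -> float:
    """FP probability of one unbalanced function.

    ``sum_{x=0}^{k} C(k,x) a_x (1 - (1-a_x)^n)`` with
    ``a_x = (1/4)^x (3/4)^(k-x)``; x counts the positions of the query k-mer
    holding the single letter the function maps to 0 (by symmetry the value
    is the same for all four unbalanced functions).
    """
    if n == 0:
        return 0.0
    x = np.arange(k + 1, dtype=np.float64)
    log_a = x * np.log(0.25) + (k - x) * np.log(0.75)
    a = np.exp(log_a)
    log_binom = gammaln(k + 1) - gammaln(x + 1) - gammaln(k - x + 1)
    weight = np.exp(log_binom + log_a)  # C(k,x) * a_x = P(query has x such positions)
    hit = -np.expm1(n * np.log1p(-a))
    return float(np.sum(weight * hit))


def p_fp_function(f: HashFunctionSpec, k: int, n: float) -> float:
    """Dispatch on the function type."""
    return p_fp_balanced(k, n) if f.balanced else p_fp_unbalanced(k, n)


def p_fp_combo(query: FPQuery) -> float:
    """FP probability of a combination: product of the per-function rates.

    Exact upper bound for all-balanced combinations; independence
    approximation otherwise.
    """
    p = 1.0
    for f in query.combo:
        p *= p_fp_function(f, query.k, query.n)
    return p


def bloom_fp_asymptotic(m_bits: float, n: float) -> float:
    """Classical Bloom filter FP rate ``0.6185^(m/n)`` at the optimal
    hash-function count."""
    if m_bits < 1 or n < 1:
        raise ValueError("m_bits and n must be >= 1")
    return float(0.6185 ** (m_bits / n))


def bloom_memory_bits(n: float, epsilon: float) -> float:
    """Bits a classical Bloom filter needs for n elements at FP rate eps:
    ``n * log2(e) * log2(1/eps)``."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(n * np.log2(np.e) * np.log2(1.0 / epsilon))


def _random_distinct_kmer_codes(
    rng: np.random.Generator, k: int, count: int, exclude: set[int] | None = None
) -> np.ndarray:
    """Draw ``count`` distinct k-mers (as 2-bit packed integers in [0, 4^k)),
    optionally disjoint from ``exclude``."""
    space = 4 ** k
    exclude = exclude or set()
    if space - len(exclude) < count:
        raise ValueError(
            f"cannot draw {count} distinct {k}-mers: 4^{k} = {space} is too small"
        )
    chosen: set[int] = set()
    # rejection sampling; fine while count << 4^k
    while len(chosen) < count:
        need = count - len(chosen)
        draw = rng.integers(0, space, size=max(need * 2, 16), dtype=np.uint64)
        for v in draw:
            v = int(v)
            if v not in exclude and v not in chosen:
                chosen.add(v)
                if len(chosen) == count:
                    break
    return np.fromiter(chosen, dtype=np.uint64, count=count)


def _codes_for_functions(
    packed: np.ndarray, k: int, functions: list[HashFunctionSpec]
) -> np.ndarray:
    """Hash 2-bit packed k-mers under each function; returns (n_func, m)."""
    shifts = (2 * np.arange(k - 1, -1, -1)).astype(np.uint64)
    letters = ((packed[None, :] >> shifts[:, None]) & np.uint64(3)).astype(np.int64)
    weights = (np.uint64(1) << np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(
        np.uint64
    )
    out = np.empty((len(functions), packed.size), dtype=np.uint64)
    for fi, f in enumerate(functions):
        bits = f.bit_table()[letters]  # (k, m)
        out[fi] = weights @ bits
    return out


def simulate_fp(
    k: int,
    n: int,
    n_queries: int,
    combo: list[HashFunctionSpec] | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical FP rate of a BDS: index ``n`` random distinct k-mers, query
    ``n_queries`` distinct k-mers outside the indexed set.

    Returns ``(fp_fraction, binomial_standard_error)``; deterministic for a
    given seed.
    """
    combo = list(combo) if combo is not None else default_functions()
    rng = np.random.default_rng(seed)
    indexed = _random_distinct_kmer_codes(rng, k, n)
    queries = _random_distinct_kmer_codes(
        rng, k, n_queries, exclude=set(int(v) for v in indexed)
    )
    index = BDSIndex(k, combo)
    if n > 0:
        index.insert_codes(_codes_for_functions(indexed, k, combo))
    hits = index.contains_codes(_codes_for_functions(queries, k, combo))
    frac = float(np.mean(hits)) if n_queries else 0.0
    se = float(np.sqrt(max(frac * (1 - frac), 1.0 / n_queries) / n_queries))
    return frac, se
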