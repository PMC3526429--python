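"""Symmetric read-set comparison, all-pairs matrices and clustering.

A single directional pass A->B is asymmetric and, because the target is
indexed as a bag of k-mers, may keep query reads whose t shared k-mers are
spread over several target reads.  The symmetric pipeline reduces this
effect with three passes:

1. ``A_hat  = A -> B``       (candidate similar reads of A)
2. ``B_hat  = B -> A_hat``   (similar reads of B, against the candidates)
3. ``A_fin  = A_hat -> B_hat`` (candidates re-checked against B_hat only)

Step 3 restricted to A_hat gives the same result as re-scanning all of A but
touches fewer reads.  The similarity between the two samples is the
percentage of reads retained:

    similarity = 100 * (|A_fin| + |B_hat|) / (|A| + |B|)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .core_compare import ComparisonParams, intersect_directional
from .read_io import ReadSet

__all__ = ["SymmetricResult", "SimilarityMatrix", "symmetric_compare", "all_pairs", "cluster_dendrogram"]


@dataclass
class SymmetricResult:
    """Outputs of the three-pass symmetric comparison of samples A and B."""

    a_hat: np.ndarray  # flags over A after step 1
    b_hat: np.ndarray  # flags over B after step 2
    a_final: np.ndarray  # flags over A after step 3 (subset of a_hat)
    similarity: float  # percentage, 0..100
    params: ComparisonParams


@dataclass
class SimilarityMatrix:
    sample_names: list[str]
    values: np.ndarray  # square, percentages; NaN where not computed
    include_self: bool
    n_comparisons: int = 0


def _subset(readset: ReadSet, flags: np.ndarray, suffix: str) -> ReadSet:
    reads = [r for r, keep in zip(readset.reads, flags) if keep]
    return ReadSet(
        sample_name=f"{readset.sample_name}{suffix}",
        reads=reads,
        source_format=readset.source_format,
    )


def symmetric_compare(
    A: ReadSet, B: ReadSet, params: ComparisonParams | None = None
) -> SymmetricResult:
    """Run the three-pass pipeline on two read sets."""
    params = params or ComparisonParams()
    step1 = intersect_directional(A, B, params)
    a_hat = step1.member_flags
    step2 = intersect_directional(B, _subset(A, a_hat, "^"), params)
    b_hat = step2.member_flags
    step3 = intersect_directional(
        A, _subset(B, b_hat, "^"), params, skip_flags=~a_hat
    )
    a_final = step3.member_flags
    denom = len(A) + len(B)
    similarity = (
        100.0 * (int(a_final.sum()) + int(b_hat.sum())) / denom if denom else 0.0
    )
    return SymmetricResult(
        a_hat=a_hat, b_hat=b_hat, a_final=a_final, similarity=similarity, params=params
    )


def all_pairs(
    samples: list[ReadSet],
    params: ComparisonParams | None = None,
    include_self: bool = True,
) -> SimilarityMatrix:
    """Similarity matrix over every unordered pair of samples.

    With ``include_self`` each sample is also compared against itself
    (n(n+1)/2 comparisons in total, n(n-1)/2 without); each pair is computed
    once and mirrored.
    """
    if not samples:
        raise ValueError("at least one sample required")
    names = [s.sample_name for s in samples]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate sample names: {names}")
    params = params or ComparisonParams()
    n = len(samples)
    values = np.full((n, n), np.nan)
    count = 0
    for i in range(n):
        start = i if include_self else i + 1
        for j in range(start, n):
            res = symmetric_compare(samples[i], samples[j], params)
            values[i, j] = values[j, i] = res.similarity
            count += 1
    return SimilarityMatrix(
        sample_names=names, values=values, include_self=include_self, n_comparisons=count
    )


def cluster_dendrogram(matrix: SimilarityMatrix) -> TreeNode:
    """Average-linkage hierarchical clustering on distance = 100 - similarity.

    Returns a tree with branch lengths, leaves labelled by sample name,
    ready for Newick export.
    """
    n = len(matrix.sample_names)
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    vals = matrix.values
    off_diag = vals[~np.eye(n, dtype=bool)]
    if not np.all(np.isfinite(off_diag)):
        raise ValueError("similarity matrix has undefined off-diagonal cells")
    dist = 100.0 - vals
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    tree = TreeNode.from_linkage_matrix(Z, matrix.sample_names)
    return tree
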