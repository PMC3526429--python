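# Methods

## Model

`kmercomp` compares read sets through a single primitive: two sequences are
*similar* when they share at least *t* non-overlapping k-mers as literal
substrings. The directional operation `A→∩B` relaxes this from read-to-read to
read-to-dataset: it keeps the reads of A with ≥ *t* non-overlapping k-mers
found anywhere in B's k-mer content. This is a deliberate heuristic — it is
what makes a single streaming index sufficient — and it over-approximates the
read-to-read definition in two ways, each with its own mitigation:

1. **Spread k-mers.** The *t* k-mers of a kept read may come from different
   reads of B. The symmetric pipeline (Â = A→∩B, B̂ = B→∩Â, final = Â→∩B̂)
   removes the cases where the carrying reads of B do not themselves survive;
   a residual false-positive class remains (t k-mers spread over ≥ 2 target
   reads that are each genuinely similar to A), and the decoy generator in
   `simdata` constructs it on purpose so tests pin down both behaviours.
   Running step 3 on Â instead of all of A is an optimisation only; a test
   asserts it equals the full rescan.
2. **Index false positives.** The BDS is probabilistic (below); false
   positives only ever *add* reads, never remove them, so the exact-backend
   result is always a subset of the BDS result.

## The index and its false-positive model

The BDS gives each hash function a disjoint 2^k-bit array addressed directly
by the function's k-bit code; there is no modular reduction. The hash family
is the set of position-wise nucleotide→bit projections: 16 labelings of
{A,C,G,T}, minus 2 constants, identified under complement (a labeling and its
complement induce the same partition of k-mer space) — 7 functions, 3 balanced
and 4 unbalanced. Balanced functions are uniform over codes, so one function's
FP rate after n distinct insertions is `1 − (1 − 2^−k)^n`. An unbalanced
function maps a k-mer with x copies of its distinguished letter to a cell
whose per-insertion hit probability is `a_x = (1/4)^x (3/4)^(k−x)`; averaging
over the query composition gives `Σ C(k,x) a_x (1 − (1 − a_x)^n)`. Both are
evaluated with `log1p`/`expm1` so they remain accurate at n = 10^9 and beyond.

No two distinct k-mers agree on two balanced functions at once (the pair of
codes determines, per position, the nucleotide), so the product of balanced
rates is a true bound; for mixed combinations the product is an independence
approximation, checked against `simulate_fp` (Monte-Carlo over uniformly drawn
distinct k-mers, reported with a binomial standard error) at a 3–4 SE
tolerance. The production combination is the three balanced functions plus
f4 (zero on A): the three balanced ones do almost all the discriminating work,
any one unbalanced function adds the same expected improvement by symmetry,
and f4 is simply the first listed. At k = 33, n = 10^9 the closed forms give
0.13 % (balanced triple) and 0.11 % (production quad) — the quantities
`scripts/acceptance.py` recomputes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 33 | k-mer length (nt); arrays are 2^k bits per function |
| t | 2 | min non-overlapping shared k-mers per similar read |
| chunk_limit | 10^9 | k-mer occurrences indexed per target chunk |
| functions | f1–f4 | hash combination (`b1,b2,b3,u1` in the CLI) |
| backend | bds | `bds` (probabilistic) or `exact` (hash set) |
| reverse_complement | off | scan the query's reverse complement as fallback |

k = 33 with 4 functions costs 4 GiB and supports ~10^9 indexed k-mers at
≈ 0.1 % FP; k = 30 supports 3·10^8 below 2 %. Larger k is more stringent
biologically as well as cheaper statistically. `chunk_limit` counts k-mer
*occurrences* scanned, not distinct k-mers — counting distinct ones would
itself require an exact set. Chunk boundaries fall on whole reads: a chunk is
closed when the next read would push it past the limit (a single read larger
than the limit forms its own chunk), so each chunk holds at most
`chunk_limit` occurrences and results are unioned across chunks; with exact
membership this is provably identical to a single pass, and a test sweeps
chunk sizes to confirm it.

## Numerical and procedural choices

- **Bit order.** Leftmost nucleotide = most significant bit, so the rolling
  update is a left shift, mask to k bits, append the new bit. Only the shift
  direction is forced by the O(1) update; the MSB convention realises it
  literally and is asserted by tests against per-position recomputation.
- **Greedy non-overlap.** On a hit at position i the scan resumes at i + k.
  For intervals of equal length the greedy choice maximises the number of
  disjoint intervals, so given exact per-k-mer membership the greedy count
  equals the true maximum; early exit at t hits changes nothing.
- **Ambiguous bases.** Any k-mer containing a non-ACGT character is skipped
  everywhere — not indexed, not queried, not counted toward chunk volume.
  Input is case-insensitive.
- **Similarity denominator** counts *all* reads, including those too short or
  too ambiguous to ever match; an empty pair of sets scores 0.
- **Self-comparisons** are included in all-pairs runs by default (15 samples
  → 120 comparisons), and each unordered pair is computed once and mirrored.
- **Clustering** is average-linkage on distance = 100 − similarity via scipy,
  exported as Newick through scikit-bio; scipy's deterministic tie-breaking
  makes the tree reproducible.
- **Reverse complements** are not scanned by default: the similarity
  definition is literal substring sharing. `--rc` enables a
  forward-then-reverse fallback per read.

## Synthetic data

The generator produces uniform i.i.d. A/C/G/T reads and plants similarity by
copying an identical random block (length t·k by default) into a chosen
fraction of reads of each sample at random offsets, so ground truth is exact:
with the exact backend the pipeline must recover precisely the planted reads,
and tests assert this across 20 seeds. Group-structured samples share a block
pool within groups, giving high within-group and near-zero between-group
similarity for clustering tests. The decoy constructor builds the three
archetypes discussed above, pinning the characters that flank each planted
block to set-specific letters so junction-spanning k-mers cannot be shared by
accident, and verifying the realised sharing pattern exhaustively.

What this emulates is sequence sharing only. Real metagenomes add sequencing
error, non-uniform base composition, abundance structure and read-length
variation, none of which the generator models; passing tests demonstrate the
correctness of the algorithmics and the FP model's calibration on unbiased
k-mers, not performance on biased real data (the FP formulas themselves
assume unbiased composition).

## Test and simulation scales

Unit and property tests run at k ≤ 25 with hundreds of reads so the whole
suite finishes in seconds; the FP-calibration checks use k = 18–20 with
10^5 indexed/queried k-mers, where the binomial standard error is small
enough to resolve the predicted rates. The headline k = 33, n = 10^9 figures
are closed-form and therefore computed exactly at full scale. The 4 GiB
production index is never allocated in tests; its size is checked through the
sizing arithmetic, which is content-independent.

## Known limitations

- The spread-k-mer residual false-positive class is inherent to the
  read-to-dataset relaxation; its magnitude on real data is not bounded here.
- The BDS cannot delete, count, or resize; `reset` is the only mutation
  besides insertion.
- No paired-end awareness: mates are independent reads.
- The index serialization format is a debugging aid, not an interchange
  format.
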