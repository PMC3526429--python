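# kmercomp

Alignment-free comparison of metagenomic read sets by shared k-mer content.

Comparative metagenomics often has to answer a simple question at an awkward
scale: *which reads of sample A look like anything in sample B, and how much
sequence content do two samples share overall?* Alignment (e.g. BLAST) answers
it precisely but is far too slow for all-pairs comparisons of modern datasets.
`kmercomp` answers it heuristically: two reads are **similar** when they share
at least *t* non-overlapping k-mers (exact substrings of length *k*). For two
read sets it returns the reads of each set similar to the other set and a
similarity percentage; for many samples it builds an all-pairs similarity
matrix and an average-linkage dendrogram, which is usually enough to recover
the ecological structure of the samples.

## Method

The directional operation `A→∩B` indexes every k-mer of B and scans each read
of A left to right, greedily counting non-overlapping k-mers found in the
index; a read with ≥ *t* hits is kept. The index is a **BDS** (Bloom Data
Structure): a Bloom-filter variant where each hash function owns a disjoint
2^k-bit array addressed directly by the function's k-bit code. The hash
functions project each nucleotide independently to one bit — there are exactly
7 such functions up to complement, 3 *balanced* (two letters → 0) and 4
*unbalanced* — and they roll along a read in O(1) per position
(`code' = (code << 1 | bit) & (2^k − 1)`).

For a balanced function the false-positive probability after indexing *n*
distinct k-mers is

    P_fp = 1 − (1 − 2^(−k))^n

and for an unbalanced one

    P_fp = Σ_{x=0..k} C(k,x) · a_x · (1 − (1 − a_x)^n),   a_x = (1/4)^x (3/4)^(k−x).

Combinations multiply the individual rates (an exact bound for the balanced
triple, an empirically validated independence approximation otherwise). With
the default combination (3 balanced + 1 unbalanced), k = 33 and n = 10^9
indexed k-mers, the index costs 4 GiB and the FP rate is ≈ 0.11 %. Targets
larger than the chunk limit *n* are indexed in successive chunks and the
per-chunk results are unioned — exactly equivalent to one big index.

Because the index holds a *bag* of k-mers, a read can be kept when its *t*
shared k-mers are spread over several target reads. The symmetric pipeline
reduces this: step 1 computes `Â = A→∩B`, step 2 `B̂ = B→∩Â`, step 3 re-checks
`Â` against `B̂` only. The similarity between the samples is

    sim(A, B) = 100 · (|Â→∩B̂| + |B̂|) / (|A| + |B|).

## Worked example

```sh
kmercomp simulate -o sim --n-reads 40 --read-length 120 -k 21 --planted-similarity 0.3 --seed 7
kmercomp compare sim.A.fasta sim.B.fasta -k 21 -t 2 --exact -o out
```

prints

```
sim.A	sim.B	12	12	30.00
```

i.e. 12 of the 40 reads of each sample are similar to the other sample —
exactly the 30 % of reads the simulator planted a shared 2·21-nt block into —
and the similarity is 100·(12+12)/(40+40) = 30.00 %. The retained reads are
written to `out.sim.A.similar.fasta` and `out.sim.B.similar.fasta`.

```sh
kmercomp matrix sim.A.fasta sim.B.fasta -k 21 --exact -o mat
cat mat.matrix.tsv
```

```
sample	sim.A	sim.B
sim.A	100.00	30.00
sim.B	30.00	100.00
```

(the diagonal is each sample against itself; `mat.nwk` holds the Newick
dendrogram `(sim.A:35.0,sim.B:35.0);`). `kmercomp fp-model -k 33 -n 1e9` prints the theoretical
false-positive table used to pick parameters, and every command accepts
`--exact` to swap the probabilistic index for an exact k-mer set.

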