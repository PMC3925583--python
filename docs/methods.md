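# Methods

## Model and definitions

The input is a binary matrix **B⁰** (N₀ transactions × n items); entry
(t, i) = 1 iff item i occurs in transaction t. For an itemset J, the support
σ(J) is the number of rows containing every item of J. J is *frequent* when
σ(J) ≥ `minsupp` and *closed* when additionally no proper superset has equal
support. A *bicluster* is a (row set, column set) pair whose submatrix is all
ones; it is *inclusion-maximal* when no row or column can be added. With a
minimum row count of `minsupp`, closed frequent itemsets and inclusion-maximal
biclusters are the same objects: map J to (all rows containing J, J).
Row-maximality is automatic because the row set is *all* supporting rows;
column-maximality is precisely closedness. Both directions are asserted
independently in the test suite.

## The mining procedure

Level-wise (Apriori) search, with every counting step expressed as integer
linear algebra on occurrence columns:

1. **Level 1.** Column sums of B⁰ are the singleton supports (bᵀb for a 0/1
   column is its count of ones). Columns below `minsupp` are erased; rows
   whose sum over the surviving columns is zero are deleted, with original
   row identities kept in `row_ids`. The index table L¹ records each
   surviving column's original item index.
2. **Join.** Two frequent (k−1)-itemsets are joinable when their
   lexicographically ordered first k−2 items agree and their last items
   differ. Because Lᵏ⁻¹ is kept lexicographically sorted, joinable pairs
   live in contiguous *blocks* sharing a (k−2)-prefix, so enumeration is
   block-local. Candidates with any infrequent (k−1)-subset are discarded
   (downward closure); this filter is a pure optimization — anti-monotonicity
   means such candidates could never be frequent — and a toggle
   (`MiningConfig.use_subset_filter`) lets tests assert output invariance.
3. **Support and prune.** The pairwise-support matrix Sᵏ = (Bᵏ⁻¹)ᵀBᵏ⁻¹ gives
   the support of every joined candidate as one entry: the inner product of
   two parent columns counts the rows where both are 1, which is exactly the
   support of the merged k-itemset. Candidates with Sᵏᵢⱼ ≥ `minsupp` have
   their occurrence columns materialized as Hadamard products bᵢ∘bⱼ, forming
   Bᵏ; all-zero rows are again deleted. Mining stops at the first empty
   level or at `max_level`.
4. **Closed extraction.** A frequent k-itemset with support s is non-closed
   iff some immediate (k+1)-superset has support s: support is anti-monotone,
   so any equal-support proper superset implies an equal-support immediate
   one, and equal support ≥ `minsupp` guarantees that superset was itself
   mined. One linear pass over each level k therefore marks, for every
   k-itemset, its equal-support (k−1)-subsets as non-closed via a hash of the
   level below. The brute-force oracle instead checks *all* proper supersets
   literally; the suite asserts the two notions coincide on every instance,
   which validates the anti-monotonicity argument.

`mine_frequent` fuses steps 2–3: supports are read off Sᵏ *before* any
candidate column is allocated, so only frequent candidates are ever
materialized. The explicit two-phase path (`join_candidates` → `prune`,
columns first, filtering second) is kept as a public API and tested equal to
the fused path level by level. The fused order matters at scale: a
1000-column level has ~5·10⁵ joinable pairs, and materializing all of their
1000-row columns (5·10⁸ cells) before pruning would dwarf the 10⁶-cell S
matrix that replaces it.

Supports are integer counts throughout; the only floating-point step is the
BLAS matrix product used for Sᵏ, whose entries (≤ N₀ ≤ 2⁵³) are exactly
representable and are rounded back to integers.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `minsupp` | minimum number of supporting transactions (absolute count; the CLI also accepts a fraction in (0,1), converted by ⌈fraction·N₀⌉) | required |
| `min_items` | smallest itemset size reported by closed extraction | 1 (most inclusive; pattern counts in the literature do not always state whether 1-itemsets are counted, so both conventions are reachable) |
| `max_level` | cap on itemset size | none |
| `use_subset_filter` | downward-closure filter at join time | on |
| `delete_zero_rows` | drop rows that support no surviving itemset | on (never changes supports; tested) |
| `cell_cap` | maximum cells of any matrix a level may allocate (Sᵏ: n², Bᵏ: nₖ·N) | 5·10⁶ — fails fast with `MemoryGuardError` rather than exhausting memory; the dense-column representation is the method's stated trade-off |

Binarization (`binarize`): `cutoff` (fold change, default 2), `mode`
(`up`: value ≥ cutoff; `abs`: also value ≤ 1/cutoff, i.e. down-regulation
counts), `scale` (`ratio` or `log2`, where the threshold becomes
log₂ cutoff). Defaults are up-regulation on the ratio scale at twofold
change; whether "twofold change" should include down-regulation is a genuine
convention choice, so it is surfaced as a flag rather than decided silently.
Missing values map to 0 (no evidence of expression) with a logged count.

## Degenerate inputs, ties, determinism

* Items are densely re-indexed 0..m−1 in first-appearance order at input;
  the join rule only needs a total order, and the original labels are
  restored on output.
* Duplicate transactions add support; duplicate item columns are legal (the
  closed set reports one itemset containing both labels); an all-zero column
  is simply infrequent; an empty table yields an empty result.
* Index tables and output are kept in (size ascending, lexicographic) order
  at every step, so two runs on the same input are byte-identical —
  including the result files, which is asserted in the suite.
* If `max_level` truncates mining, closedness is relative to the mined
  universe (a cap-level itemset has no mined supersets to absorb it);
  uncapped runs are unaffected.
* Synthetic generation uses numpy's PCG64 (`default_rng(seed)`), so a seed
  pins the matrix bitwise across platforms.

## What the synthetic generator does and does not emulate

`random_binary` produces i.i.d. Bernoulli(density) matrices — the standard
unstructured instance for scalability and correctness experiments — and
`implant_blocks` overlays all-ones rectangles, optionally degraded by noise
(each block cell reverts to the background with probability `noise`), giving
recovery tests a known answer. Real expression data are not i.i.d.: genes
are co-regulated (correlated columns), density varies per sample, and
single-cell data add dropout. Passing tests therefore demonstrate
*combinatorial correctness* — the miner returns exactly the closed
itemsets/maximal biclusters of whatever binary matrix it is given — not that
a twofold-change binarization of a particular data set yields biologically
meaningful patterns, which depends on upstream normalization and threshold
choice.

## Verification strategy and problem sizes

Correctness is established against deliberately naive oracles
(`bitclose.oracle`): support of every one of the 2^m−1 subsets by direct row
scan (rows packed as bitmasks), closedness against **all** proper supersets
via a subset-lattice max sweep, and maximal biclusters by scanning all
column subsets with explicit maximality checks. The oracles cap m at 24
items; the equivalence suites run 300 seeded instances with 5–25 rows, 4–15
items, density 0.05–0.6 and minsupp 1–5 — small enough to enumerate
exhaustively, large enough to exercise multi-level joins, block boundaries
and row deletion — and finish in seconds. The qualitative scale run
(1000 × 1000 at density 0.10, minsupp 20, roughly a third of a second)
checks that the fused path stays inside the memory guard and spot-checks 50
outputs with the independent closedness verifier. Counts on random matrices
are realization-dependent and are never asserted against published figures.

## Known limitations

* Dense int8 columns, no compressed bitset arithmetic or out-of-core tables;
  the `cell_cap` guard makes the trade-off explicit instead of thrashing.
* Exact, noise-free patterns only: a single flipped 0 splits a bicluster.
  Noise-tolerant bicluster definitions are out of scope.
* Closed (not maximal) itemsets; no FP-tree/prefix-tree storage, no
  parallelism.
* Binarization assumes values already on a ratio or log2 fold-change scale;
  normalization and per-gene adaptive thresholds are upstream concerns.
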