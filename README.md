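# bitclose

Frequent **closed itemset** mining and binary **biclustering** for
high-dimensional 0/1 matrices, with all support counting done by matrix and
vector products on bit-tables.

## The problem

A binary matrix **B⁰** with transactions as rows and items as columns (market
baskets, or a binarized gene-expression matrix with genes as rows and
conditions as columns) hides two equivalent families of patterns:

* **Frequent closed itemsets** — item sets *J* contained in at least
  `minsupp` transactions, σ(J) ≥ minsupp, such that no proper superset
  *J′ ⊃ J* has the same support σ(J′) = σ(J). They are a lossless
  compression of *all* frequent itemsets.
* **Inclusion-maximal biclusters** — pairs (rows, columns) whose submatrix is
  all ones and to which no row or column can be added. With a minimum row
  count equal to `minsupp`, the two families are in bijection: a closed
  itemset's columns plus *all* rows containing them form a maximal bicluster.

`bitclose` mines both at once, level-wise (Apriori), but replaces every
database scan by integer linear algebra:

* support of one column: σ = **b**ᵀ**b**;
* supports of all candidate pairs at level k: **Sᵏ = (Bᵏ⁻¹)ᵀ Bᵏ⁻¹**, where
  column *j* of **Bᵏ⁻¹** is the occurrence vector of the *j*-th frequent
  (k−1)-itemset;
* the occurrence column of a joined candidate: the Hadamard (element-wise)
  product **bᵢ ∘ bⱼ** of its two parents.

Two (k−1)-itemsets join when their lexicographically ordered first k−2 items
agree; infrequent columns are erased and all-zero rows deleted as levels
advance, so the tables shrink as the patterns grow. Candidate columns are
materialized only after their support — read directly off **Sᵏ** — clears
`minsupp`, which is what makes 10⁶-cell inputs practical. Closed itemsets are
then extracted by eliminating every frequent itemset that has an
immediate superset of equal support.

Audience: anyone mining co-occurrence structure in binary data — binarized
bulk or single-cell expression, presence/absence calls, market baskets.

## Worked example

Four transactions over items 0,1,2 (rows `111`, `110`, `101`, `011`):

```bash
printf '1,1,1\n1,1,0\n1,0,1\n0,1,1\n' > toy.csv
bitclose mine --input toy.csv --minsupp 2 --emit-rows --output toy_closed.tsv
# 6 closed itemsets -> toy_closed.tsv
cat toy_closed.tsv
```

```
0	3	0 1 2
1	3	0 1 3
2	3	0 2 3
0 1	2	0 1
0 2	2	0 2
1 2	2	0 3
```

Each line is `items <TAB> support <TAB> supporting rows`: every single item
appears in 3 transactions, every pair in 2; the triple {0,1,2} has support 1,
below the threshold, so no size-3 pattern is reported. Read as biclusters:
line 4 says rows {0,1} × columns {0,1} is an all-ones submatrix that cannot
be extended. A JSON sidecar `toy_closed.tsv.meta.json` records the input
hash and thresholds of the run.

The same library call is:

```python
from bitclose import BitTable, MiningConfig, mine_closed
B = BitTable.from_dense([[1,1,1],[1,1,0],[1,0,1],[0,1,1]])
for it in mine_closed(B, MiningConfig(minsupp=2)):
    print(it.items, it.support, sorted(it.rows))
```

Real-valued expression tables are binarized first (default: twofold change,
up-regulation only — see `bitclose binarize --help` for the `abs` mode and
log2 inputs):

```bash
bitclose binarize --input expr.csv --cutoff 2 --output expr_binary.csv
bitclose mine --input expr_binary.csv --minsupp 50 --min-items 2 --output patterns.tsv
```

Other entry points: `bitclose synth` (seeded random matrices, optional
planted biclusters), `bitclose oracle` (brute-force reference on small
inputs), FIMI transaction files and MatrixMarket sparse input via
`--format`.

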