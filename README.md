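# lbcc — essential-protein ranking in PPI networks

Essential proteins are those whose single deletion is lethal to the
organism. Because experimental essentiality screens are slow and expensive,
a long line of work ranks the proteins of a protein–protein interaction
(PPI) network by topological scores and treats the top of the ranking as
predicted-essential. This package implements the **LBCC** score, which
combines local neighborhood density, global betweenness, and protein-complex
membership, together with six classical baseline centralities and the full
evaluation protocol used to compare such rankings.

## The score

For a node *v* of an undirected simple PPI graph *G*:

- **Den1(v)** — edge density of the subgraph induced by the closed
  neighborhood *N_v ∪ {v}*: `2|E(H)| / (|V(H)|(|V(H)|−1))`.
- **Den2(v)** — the same density over the closed ball of radius 2
  (v, its neighbors, and their neighbors).
- **BC(v)** — unnormalized shortest-path betweenness (Brandes; unordered
  pairs, endpoints excluded).
- **IDC(v)** — sum over the protein complexes containing *v* of *v*'s PPI
  degree restricted to each complex's members; proteins in no complex get
  the floor value 0.001.

These are combined as

```
LBCC(v) = a·log Den1(v) + b·log Den2(v) + c·log IDC(v) + d·log BC(v)
```

with default weights `(a, b, c, d) = (1, 4, 3, 1)`. Every factor is floored
at 0.001 before the logarithm so leaves (BC = 0) and isolated nodes keep
finite scores; the ranking is invariant to the log base. Baselines provided
for comparison: degree (DC), betweenness (BC), subgraph (SC), eigenvector
(EC), local average connectivity (LAC), edge-clustering network centrality
(NC), and the local clustering coefficient (LCC).

Evaluation of a ranking against a known-essential list: true-essential
counts in the top k, the confusion matrix at a top-20% cutoff with the six
derived statistics (SN, SP, PPV, NPV, F, ACC), precision–recall and
jackknife (cumulative true positive) curves, and a set-difference
comparison of two methods' top-k predictions.

## Worked example

Everything runs on a built-in synthetic benchmark: a planted-partition
graph (five dense 12-node modules over a sparse 30-node background) with
essentiality concentrated in the modules and complexes planted inside them.

```python
import lbcc

net, ess, cplx = lbcc.generate(lbcc.FixtureSpec(seed=7))
scores = lbcc.lbcc(lbcc.den1(net), lbcc.den2(net), lbcc.idc(net, cplx),
                   lbcc.betweenness_centrality(net))
pred = lbcc.rank(scores)
print("top 5:", list(pred.ordering[:5]))
print("true essentials in top 10/20/40:",
      lbcc.top_k_true(pred, ess, [10, 20, 40]))
s = lbcc.statistics(lbcc.confusion_at_fraction(pred, ess, 0.2))
print(f"top-20% SN={s.sn:.3f} SP={s.sp:.3f} PPV={s.ppv:.3f} "
      f"NPV={s.npv:.3f} F={s.f:.3f} ACC={s.acc:.3f}")
```

prints

```
top 5: ['P0035', 'P0024', 'P0030', 'P0012', 'P0008']
true essentials in top 10/20/40: {10: 7, 20: 12, 40: 25}
top-20% SN=0.250 SP=0.848 PPV=0.611 NPV=0.542 F=0.355 ACC=0.556
```

The 90-node benchmark has 44 essential proteins; 7 of the top 10 ranked
proteins are truly essential, and at the top-20% cutoff (18 proteins
called essential) precision (PPV) is 0.611 against a base rate of 0.49.

The same pipeline is available from the shell:

```
lbcc synth --seed 7 --out-prefix demo/data
lbcc score --network demo/data/network.tsv --measure LBCC --measure BC \
     --complexes demo/data/complexes.tsv --out demo/scores.tsv
lbcc evaluate --scores demo/scores.tsv --measure LBCC \
     --essentials demo/data/essentials.tsv --top-ks 10,20,40 --out-dir demo/eval
lbcc compare --a demo/scores.tsv --measure-a LBCC --b demo/scores.tsv \
     --measure-b BC --essentials demo/data/essentials.tsv --k 20 --out demo/diff.tsv
lbcc reproduce --network demo/data/network.tsv \
     --essentials demo/data/essentials.tsv \
     --complexes demo/data/complexes.tsv --out-dir demo/reports
```

`reproduce` scores all eleven measures and writes `scores.tsv`, `topk.tsv`,
`statistics.tsv`, `differences.tsv` and per-measure PR/jackknife curve
tables, each with a provenance header (tool version, parameters, input
checksums).

## Running on the published yeast data

The yeast datasets (YMIPS, YMBD, YHQ, YDIP edge lists; the essential-gene
list; the 745-complex catalog) are not redistributed here. To run the
reproduction, export them as plain text into `data/`:

- `data/YMIPS.txt`, `data/YMBD.txt`, … — two tab-separated ORF names per
  interaction;
- `data/essentials.txt` — one ORF per line (or `ORF essential|nonessential`);
- `data/complexes.txt` — one complex per line: complex id then member ORFs
  (a two-column `complex_id member` long format is also accepted via
  `load_complexes(..., long_format=True)`).

Then `lbcc reproduce --network data/YMIPS.txt --essentials
data/essentials.txt --complexes data/complexes.txt --out-dir reports/ymips`
produces the score, top-k, statistics and difference tables, and the
acceptance test above will verify the published numbers.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the seeded synthetic benchmark, runs the complete scoring and
evaluation chain on it (all measures, all reports), and writes the result
JSON to `--out`.
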