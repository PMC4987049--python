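# Methods

## Model

The package ranks the proteins of an undirected simple PPI graph by the
combined score

LBCC(v) = a·log Den1(v) + b·log Den2(v) + c·log IDC(v) + d·log BC(v)

and evaluates rankings against a binary essentiality annotation. The score
encodes three premises: essential proteins sit in densely connected
neighborhoods (Den1, Den2), they occupy globally central positions (BC),
and they concentrate inside annotated protein complexes (IDC). The log
transform puts the four factors — which differ by orders of magnitude
(densities in [0, 1], betweenness in the tens of thousands on yeast-scale
networks, complex in-degrees typically 10–100) — on comparable additive
scales.

## Parameters

| parameter | default | meaning |
|---|---|---|
| a, b, c, d | 1, 4, 3, 1 | weights of the four log terms; validated to [0, 10] |
| floor_value | 0.001 | value substituted for any factor ≤ floor before the log |
| log_base | e | base of the logarithm; rankings are base-invariant |
| top-k levels | 100…600 | ranks at which true-essential counts are reported |
| cutoff fraction | 0.2 | top fraction called "predicted essential"; cutoff k = floor(0.2·|V|) |

The default weights are the empirically tuned values for yeast networks;
no weight optimization is shipped (a grid can be swept through the CLI).

## Conventions and numerical choices

- **Betweenness** is unnormalized, over unordered pairs, endpoints
  excluded, with fractional credit among tied shortest paths (Brandes
  accumulation via networkx). Large published BC values are integers under
  this convention; tools that count ordered pairs report exactly double,
  so `ordered_pairs=True` is exposed for that comparison.
- **Subgraph centrality** is computed spectrally per connected component
  (dense `eigh`, SC(v) = Σ_j u_j[v]² e^{λ_j}); an isolated node scores 1.
  At yeast scale λ_max stays far below overflow range.
- **Eigenvector centrality** uses a dense symmetric eigensolve up to 3000
  nodes and power iteration (tol 1e-12, ≤10000 iterations) above; the
  vector is taken entrywise non-negative and L2-normalized. It is rejected
  on edgeless graphs, where the principal eigenvector is degenerate.
- **NC** has no universally printed formula in the application literature;
  this package uses the edge-clustering-coefficient sum
  ECC(u,v) = z(u,v)/min(deg u −1, deg v −1), with 0/0 → 0, which vanishes
  on triangle-free graphs.
- **Degenerate densities**: an isolated node has 0/0 density and is
  assigned 0 (it can then never rank as essential by density); a leaf has
  Den1 = 1 (its closed neighborhood is a single edge). LCC is 0 for degree
  ≤ 1. Den1 relates to LCC by Den1 = ((deg−1)·LCC + 2)/(deg+1) for degree
  ≥ 2, which the tests verify to 1e-12.
- **Flooring**: the published rule floors only IDC (at 0.001, for proteins
  in no complex). log(0) also arises for BC of leaves, for densities of
  isolated nodes, and for complex members with zero in-complex degree.
  The same 0.001 floor is applied uniformly to every factor before the
  logarithm — an explicit design substitute, configurable, not an
  inference of original intent.
- **Ranking ties** are broken by ascending protein identifier, making
  every ordering a deterministic total order.
- **Top-20% cutoff** uses floor(fraction·|V|); the integer cutoff is
  echoed in report headers so rounding discrepancies are diagnosable.
  Proteins without essentiality annotation count as nonessential (the
  binary framing admits no third class).
- **Break-even point** of a PR curve is reported as the recall at the
  largest rank with precision ≥ recall.

## Synthetic benchmark

`FixtureSpec`/`generate` build a planted-partition world: `n_modules`
dense modules (within-module edge probability `p_in`, between-module
`p_out`), plus `n_background` nodes wired by a sparse Erdős–Rényi layer so
that leaves and zero-betweenness nodes exist and the flooring path is
exercised. Module nodes are labelled essential with probability
`essential_fraction_in_modules`, background nodes at a low base rate;
complexes are sampled as subsets of single modules. Defaults — five
modules of 12 at p_in 0.9 / p_out 0.02, 30 background nodes at 0.02,
module essential rate 0.6 against background 0.05, eight complexes of 3–6
members — were fixed once as a realistic small-world benchmark in which
density, complex membership and essentiality are genuinely correlated, and
are not tuned against test outcomes. One seeded NumPy generator drives all
sampling in a fixed order (module/background edges in lexicographic node
order, then labels, then complexes), so outputs are byte-identical across
platforms for a given seed.

The generator emulates modular essentiality structure only. It does not
reproduce yeast degree distributions, false-positive interaction noise, or
overlapping complexes spanning modules; a green synthetic test therefore
establishes algorithmic correctness and the expected qualitative ordering
(module nodes out-rank background nodes), not field performance on real
interactomes. Real-data claims are covered by the separate reproduction
test, which requires the original yeast datasets on disk.

## Known limitations

- No approximate betweenness: networks much beyond ~10⁴ nodes will be slow.
- IDC treats complex membership as certain; no weighting by complex
  confidence or size.
- The evaluation assumes a single binary annotation; condition-dependent
  essentiality is out of scope.
- The human (HDIP/CORUM) case study is runnable through the generic
  readers but no human data ships with the package.
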