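# scdnet

Differential gene co-expression network analysis for sparse single-cell
RNA-seq data.

## The problem

Single-cell RNA-seq matrices are dominated by exact zeros (dropouts:
transcripts present in the cell but not captured), which breaks the usual
recipe for comparing gene regulatory wiring between two groups of cells —
compute a correlation per group, compare.  Every gene pair effectively has
its own sample size (the cells where *both* genes were observed), so raw
correlation coefficients from different pairs and different groups are not
comparable.

`scdnet` addresses this for two-state designs (e.g. drug-resistant vs naïve
tumor cells, 2-cell vs 8-cell embryos).  For each state *n* ∈ {0, 1} and
gene pair (*i*, *j*) it computes, on the pair's dropout-free **support**
*x*<sub>i,j</sub> = {cells where both genes are non-zero}:

- **C<sup>n</sup>(i, j)** — Pearson correlation over *x*<sub>i,j</sub>,
- **S<sup>n</sup>(i, j)** = |*x*<sub>i,j</sub>| — the pair's own sample size,
- **I<sup>n</sup>(i, j)** = √(S − 3) · atanh(C) — the Fisher-transformed,
  sample-size-adjusted *interaction score*, standard normal under the
  no-correlation null.

Because the interaction scores live in a sample-size-free domain, the change
between states, **ΔI = |I¹| − |I⁰|**, can be tested exactly: under the null
ΔI is distributed as |X| − |Y| with X, Y independent standard normals, whose
CDF has the closed form

    F(d) = 1/2 + erf(d/2) − 1/2 · sgn(d) · erf(d/2)²

so p-values need no permutation or simulation.  Pairs significant after
Bonferroni control are merged into a **differential network**; node degree
ranks hub genes whose regulatory partnerships rewired between states.

## Worked example

Generate a small synthetic dataset with one planted differential pair
(genes `g0000`/`g0001`: uncorrelated in state A, ρ = 0.95 in state B, 25%
zeros), then run the pipeline:

```bash
scdnet fixture --genes 12 --cells0 50 --cells1 50 --sparsity 0.25 \
       --seed 3 --plant "0,1,0.0,0.95" --out demo/fx
scdnet run --matrix demo/fx/matrix.tsv --labels demo/fx/labels.tsv --out demo/net
# tested 66 pairs, 1 differential edges on 2 genes -> demo/net
```

`demo/net/edges.tsv` then contains exactly the planted pair:

```
gene_i  gene_j  I0        I1       S0  S1  delta    p          p_adj      specific_state
g0000   g0001   -0.765    9.755    23  30  8.990    4.22e-20   2.79e-18   1
```

Reading: in state A the pair's 23-cell support gave a near-zero interaction
score (I⁰ = −0.77); in state B the 30-cell support gave I¹ = 9.76; the gain
ΔI = 8.99 has two-sided p = 4.2 × 10⁻²⁰ under the exact |X|−|Y| null,
surviving Bonferroni over the 66 testable pairs (p_adj = 2.8 × 10⁻¹⁸), and
the edge is specific to state 1 (`B`).  The run log echoes the full
configuration plus diagnostics (input sparsity 0.274, 12 genes retained by
the CV ≥ 0.25 filter).  `network.sif`/`network.graphml` are Cytoscape-ready;
`hubs.tsv` ranks genes by differential degree.

The simulation study is exposed the same way:

```bash
scdnet simulate --theta 1.0 --epsilon 0.05 --cells 50 --tau 0.25 \
       --pairs 10000 --seed 1 --out demo/sim.tsv
# accuracy=0.9999 sensitivity=1.0 specificity=0.999875
```

i.e. with 10,000 pairs (20% correlated at covariance 1.0), noise at 5% of
signal power, 50 cells and a quarter of observations eliminated, the strict
Bonferroni rule recovers every correlated pair at near-perfect specificity.
`scdnet simulate --calibration` sweeps per-test thresholds instead and
reports the full sensitivity/specificity operating curve; `--grid grid.yaml`
runs parameter sweeps (K × τ tables mark support-starved cells with "-").

Real datasets enter through `scdnet run --matrix M.tsv --labels L.tsv`
(dense TSV/CSV or MatrixMarket `--mtx` with `genes.txt`/`cells.txt`), with
`--normalize` for median-of-ratios size factors when counts are raw.

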