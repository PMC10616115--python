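# pure-regulators

Causal upstream-regulator analysis for gene-expression experiments:
given a differential-expression (DE) profile and a signed chemical–gene
knowledge base, **PURE** (Predicting Upstream REgulators) tests, for every
chemical, drug, or toxicant (CDT), two directional hypotheses:

* **H1** — the CDT's level is *elevated* in the phenotype (its known
  activation targets should be up-regulated and its inhibition targets
  down-regulated);
* **H2** — the CDT is *lacking or absent* (its known effects should be
  reversed — the signature-reversal reading used in drug repurposing).

It is aimed at toxicologists, pharmacologists, and bioinformaticians who
have a DE table (e.g. from limma/DESeq2 on a GEO series) and a
CTD-style interaction table, and want a ranked, significance-flagged list
of candidate upstream CDTs.

## The statistic

Let `G` be the DE genes that also appear in the knowledge base and `E`
the knowledge-base edges pointing into `G`. Each edge `e(c,g)` carries a
sign `s(e)` (+1 activation, −1 inhibition) and each DE gene a sign `s(g)`
(+1 up, −1 down). An edge **supports H1** iff `s(e) = s(g)`, otherwise it
supports H2 — the two sets partition `E`. For a focal CDT `c` a 2×2
contingency table over *edges* is built:

|                  | supporting H1 | against H1 |
|------------------|---------------|------------|
| related to `c`   | *l*           | *k*        |
| not related to `c` | *m*         | *n*        |

and the one-sided Fisher exact p-value is the upper tail
`P[X ≥ l]` of the hypergeometric law

```
P(table) = C(l+k, l) · C(m+n, m) / C(‖E‖, l+m),   ‖E‖ = l+k+m+n.
```

The H2 p-value is the same test on the column-swapped table `(k, l, n, m)`.
P-values are Benjamini–Hochberg corrected per hypothesis family and CDTs
are ranked on the adjusted values with the average-rank tie convention.
Counting *edges* rather than genes keeps the test informative when the DE
list is small relative to the genome.

The package also ships faithful reference implementations of the five
comparator methods used to benchmark this statistic — hypergeometric ORA,
two-sample Kolmogorov–Smirnov, Wilcoxon rank-sum, classic pre-ranked
permutation GSEA, and IPA-style causal scoring (gene-level overlap
p-value plus the activation z-score
`z = Σ w·s_R·s_D / √Σw²`, called activated at `z ≥ 2`, inhibited at
`z ≤ −2`) — together with the benchmarking conventions (rank of the true
CDT, imputed rank `n_significant + 1` when a method misses it, false-
positive counts, cross-method Wilcoxon comparisons) and a synthetic-data
generator that emulates the H1/H2 generative story.

## Worked example

Simulate one noiseless experiment (50 candidate CDTs, 200 genes; one CDT
truly perturbed) and analyze it:

```sh
$ pure simulate --out-dir demo --seed 7
wrote 1 replicate(s) under demo
$ pure run --kb demo/kb.tsv --de demo/de.tsv --out demo/results.tsv
tested 50 CDTs, 1 significant (alpha=0.05); wrote demo/results.tsv
```

`demo/truth.json` records that `CDT010` was perturbed under H1. The top
of `demo/results.tsv`:

```
cdt_id     cdt_name  n_edges  l  k   m   n         p_h1       fdr_h1  rank_h1     p_h2   fdr_h2  rank_h2    call
CDT010 compound-010       35 35  0 192 210 2.823140e-11 1.411570e-09      1.0 1.000000 1.000000     32.0 present
CDT028 compound-028       10  1  9 226 201 9.994140e-01 1.000000e+00     29.0 0.007205 0.360226      1.0    none
CDT004 compound-004       11  2  9 225 201 9.962980e-01 1.000000e+00     29.0 0.022968 0.416563      2.5    none
```

All 35 of the true CDT's edges into DE genes support H1 (`l=35, k=0`),
giving p ≈ 2.8e−11 and the call `present` — it is the single significant
CDT, i.e. zero false positives. Every other CDT sits near the chance
expectation and is not called.

The same machinery runs on real inputs: a CTD
`CTD_chem_gene_ixns.tsv(.gz)` download (only `increases^expression` /
`decreases^expression` actions are used) and any DE table with
`gene_id`, `log_fc`, `p_value` columns, with DE genes selected at
|log FC| > 0.6 and p < 0.05 by default:

```sh
pure run --kb CTD_chem_gene_ixns.tsv.gz --de my_contrast.tsv \
         --organism "Homo sapiens" --out results.tsv
```

`pure benchmark --manifest bench.yaml --out-dir out` evaluates any subset
of the seven methods over a list of experiments with known true CDTs.

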