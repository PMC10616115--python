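# Methods

## The model

PURE treats upstream-regulator inference as a series of per-regulator
hypothesis tests over *edges* of a signed chemical–gene network. The
knowledge base contributes edges `e(c,g)` with sign +1 ("c increases the
expression of g") or −1 ("c decreases it"); the experiment contributes a
DE sign `s(g)` per selected gene. Restricting the network to DE genes
gives the overlap sets `G` (genes), `C` (CDTs with ≥ 1 edge into `G`),
and `E` (those edges). Each edge supports exactly one of two directional
hypotheses about its CDT — H1 (level elevated: `s(e) = s(g)`) or H2
(level lacking: `s(e) ≠ s(g)`) — so the H1/H2 label sets partition `E`.

For a focal CDT the 2×2 table (l, k | m, n) counts its supporting/
opposing edges against everyone else's, and the H1 p-value is the
one-sided upper tail of the Fisher exact test, `P[X ≥ l]` at fixed
margins. The H2 p-value is the identical test on the column-swapped
table — an exact involution, which is why negating every DE sign swaps
the two p-values for every CDT (a property the tests assert).

Implicit assumptions worth stating: edges are treated as exchangeable
units under the null (no per-edge reliability weighting — the weight
field exists but CTD supplies none, so all weights are 1); a CDT's
evidence is only its *direct* edges (no gene–gene propagation); and
conflicting curation (a CDT that both increases and decreases the same
gene) legitimately contributes one edge to each hypothesis tally.

## Decisions where the design was open

* **Inclusive tail.** The upper tail includes the observed table
  (`P[X ≥ l]`). An exclusive tail (`> l`) would assign p = 0 to maximal
  tables and is not a valid p-value; an exclusive mode remains available
  (`strict_tail`) for sensitivity checks only.
* **FDR family.** Benjamini–Hochberg is applied separately within the H1
  family and the H2 family (one test family per research hypothesis); a
  pooled mode is configurable. Adjusted values are used for ranking.
* **Ranking and ties.** CDTs are ranked on the FDR-adjusted p-value;
  tied values receive the mean of the positions they occupy (four tied
  at the top → each ranked 2.5). A flag (`tiebreak_raw_p`) lets raw
  p-values break adjusted-value ties before averaging.
* **Calls.** `present` iff `fdr_h1 ≤ α`, `absent` iff `fdr_h2 ≤ α`
  (α = 0.05, inclusive). A CDT significant both ways is reported as
  `both` rather than suppressed — hard to interpret biologically, but
  suppressing it would hide a real property of the data.
* **No minimum-edge filter by default**: every CDT with at least one
  overlap edge is tested; `min_edges` exists for users who want one.
* **Overlap-p tail limit.** The gene-level overlap p-value sums table
  probabilities for first cells `a..a+min(b,c)`. The commonly quoted
  limit `min(c,d)` coincides with this whenever the non-regulated DE
  genes (b) and the unannotated background (d) dwarf the regulated set
  (c) — i.e. every realistic regulator table — but truncates the tail on
  degenerate tables, where it would no longer be a valid p-value; the
  complete tail is used so the statistic equals the one-sided Fisher
  test exactly (asserted against enumeration).
* **Deterministic output**: results are ordered by (call priority, best
  adjusted p, cdt_id) and floats printed at 6 significant digits, so
  repeated runs are byte-identical.

## Input conventions

DE genes are selected with strict inequalities, |log FC| > 0.6 and
p < 0.05 (both configurable); boundary values are excluded because the
selection rule is printed with strict operators. The log base of the
fold-change column is the caller's responsibility, as is whether the
p-values are raw or adjusted (recorded as metadata, not interpreted).
Duplicate gene rows are collapsed by smallest p, then largest |log FC| —
a conventional best-probe rule, documented rather than asserted as
universal. CTD parsing keeps only `increases^expression` /
`decreases^expression` action tokens; directionless `affects^expression`
rows are excluded and counted in the parse stats. Organism matching is
exact and case-insensitive, and rows with a blank organism are dropped
when a filter is set (CTD leaves organism blank for inferred rows).
Gene identity is the numeric GeneID; symbols are carried for display.

## Numerical choices

For overlap networks with ‖E‖ ≤ 1000 the hypergeometric tail is summed
in exact integer arithmetic (correctly rounded big-integer division;
error ≤ 1 ulp), and scipy's log-space survival function is used above
that. The acceptance machinery checks every 2×2 table with total ≤ 60
(≈ 6.4 × 10⁵ tables) against integer enumeration at 1e−12. The same
dual-path policy applies to the ORA hypergeometric tail. GSEA uses the
classic pre-ranked form: weight exponent 1, gene-label permutation null
(nperm = 10⁴, minSize = 15 by default), p = (1 + #{|ES*| ≥ |ES|}) /
(nperm + 1), fully seeded; sets below minSize are recorded as "not
tested" rather than scored. The cross-method Wilcoxon comparison offers
both variants: unpaired rank-sum (complete permutation enumeration with
midranks when both groups have ≤ 8 values, else normal approximation
with tie correction) and paired signed-rank (p = 1 when all differences
vanish).

## The synthetic generator

`SimulationConfig` describes one experiment: `n_cdts` = 50 candidate
regulators over `n_genes` = 200 genes, each CDT receiving
`edges_per_cdt` = 20–60 edges (targets sampled without replacement,
activation with probability 0.5) — edge counts in the range typical of
curated chemicals, with a floor high enough that a noiseless
perturbation is decisively detectable: even if ~75% of unrelated overlap
edges supported H1 by chance, a 20-edge true CDT's raw p stays below
0.005, so its adjusted value cannot saturate into a field-wide tie. One
true CDT is perturbed: each target becomes DE with the edge-implied sign
(H1) or its opposite (H2), independently contradicted with probability
`agreement_noise` (default 0); unrelated genes become DE at
`background_de_rate` = 0.02 with a random sign. DE magnitudes are the
threshold plus a log-normal excess (location −0.5, scale 0.6 — median
|log FC| ≈ 1.2) with Beta(0.5, 3)-scaled p-values below 0.05; non-DE
genes get uniform sub-threshold magnitudes and p ≥ 0.05, so the
selection filter recovers the intended DE set exactly, every time. A
single seed derives per-replicate substreams by counter, making any
replicate reproducible in isolation.

What the generator does *not* emulate: correlated expression between
genes, hub-biased network topology (popular chemicals having far more
annotations), annotation errors in the knowledge base itself, multiple
simultaneous perturbations, and p-values that co-vary with effect size.
Passing recovery tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance
on real tissue data.

## Evaluation conventions

A method's report is a ranked CDT list with a significance flag (BH-FDR
≤ 0.05 for p-value methods, |z| ≥ 2 for the z-score method). The rank of
the true CDT uses the average-rank convention; when a method's report
omits the true CDT entirely its rank is imputed as the number of
significant CDTs reported plus one. False positives are significant CDTs
other than the true one. Summaries are mean ± sample sd (sd reported as
0 and flagged for a single experiment), displayed at one decimal with
half-up rounding. The package ships the per-experiment reference values
from PURE's original 16-experiment evaluation (14 H1, 2 H2) and always
recomputes summaries from them; comparator columns from that evaluation
are not shipped.

## Problem sizes

The test suite and the acceptance script run recovery at the generator
defaults with 50 replicates per condition (noise grid 0–0.5), the
exhaustive table check at total ≤ 60, and GSEA unit tests at reduced
permutation counts (the 10⁴ default is exercised through the
seeded-reproducibility contract); together they complete in well under
two minutes on one CPU.

## Known limitations

Only direct CDT→gene expression edges are scored; regulators acting
through unannotated intermediaries are invisible. Annotation-volume bias
(well-studied chemicals have more edges, hence more power) is inherited
from the knowledge base. A CDT can in principle be called `both`; the
package reports it honestly instead of resolving it. The IPA-style
comparator reproduces the published scoring formulas on the same public
knowledge base — not the proprietary content or regulator taxonomy of
the commercial tool — so `ipa_cdt_like` differs from `ipa_like` only in
its report label here, where the candidate universe is already
all-chemical.
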