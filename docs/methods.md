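# Methods

## The testing problem

Given log-expression of p genes in n cell lines split into two phenotypes A
and B, and a collection of gene sets ("subnetworks"), decide for each gene
set whether its *regulatory* behavior differs between the phenotypes. The
package's premise is that differential regulation shows up in three partly
independent ways: shifted expression levels, changed regulatory effect
sizes, and rewired network neighborhoods. Each axis gets its own
dissimilarity statistic and the axes are combined on a common scale.

## Statistics

**SAM-GS (expression).** For gene j, `s_j = sqrt(a·[Σ_A (x_ij − x̄_Aj)² +
Σ_B (x_kj − x̄_Bj)²])` with `a = (1/n_A + 1/n_B)/(n_A + n_B − 2)`, and
`D = Σ_{j∈V} (x̄_Aj − x̄_Bj)²/(s_j + s0)`. The square root makes `s_j` a
standard-deviation-scale quantity, dimensionally consistent with dividing a
squared mean difference; a literal no-square-root variant is available as
`samgs_scatter="raw"`. The stabilizer `s0` defaults to the median of `s_j`
over the full gene universe — the usual SAM-family choice; it is scale-free
and recomputed on every permutation replicate along with everything else.

**GSCA (co-expression).** Mean over unordered gene pairs of the squared
difference of Pearson correlations between phenotypes. A gene that is
constant within a phenotype contributes correlation 0 (with a warning)
rather than NaN.

**Regulatory effects (Γ).** Per phenotype, the network is estimated by a
per-target lasso: each gene is regressed on all other genes of the scored
universe. Gene j's effect vector stacks `β̂_ℓj·x̄_j` over targets ℓ
(j acting as regulator, scaled by the regulator's phenotype mean) and
`β̂_jk·x̄_k` over regulators k (k acting on j). `γ_j` is the squared
Euclidean distance between the phenotype A and B vectors divided by their
length, and `Γ` is the subnetwork mean. Scaling coefficients by the
regulator's mean expression makes the entries effect sizes on the
expression scale rather than bare slopes.

**Neighborhood rewiring (Λ).** Gene k is a neighbor of j when either
directed coefficient magnitude exceeds `edge_threshold` (default 0 in
simulation settings: any surviving lasso coefficient is an edge; analyses
of noisy real panels should raise it, e.g. to 0.7). `λ_j` is the Jaccard
distance between j's neighborhoods in the two networks; two empty
neighborhoods count as identical (λ = 0) — an identically disconnected gene
is no evidence of rewiring. `Λ` is the subnetwork mean, and
`Γ_Λ = mean(γ_j(1 + λ_j))` lets rewiring amplify effect-size changes.

**Combination and testing.** T label permutations re-run the entire
estimation pipeline (network re-estimation included) on resampled phenotype
assignments of sizes n_A/n_B. For each subnetwork and each statistic the
(T+1)-vector of observed-plus-permuted values is z-scored (population SD;
a constant vector maps to zeros so a degenerate statistic contributes
nothing), and the combined scores are `CIdrgn.1 = Γ_Λ + D` and
`CIdrgn.2 = Γ + Λ + D` on those normalized scales. All three addends are
normalized — including D — since the combination is only meaningful on a
common scale. The p-value is the fraction of permutation replicates whose
combined score reaches the observed one, with denominator T (so p = 0 is
attainable; `pvalue_rule="add-one"` switches to (count+1)/(T+1)).
Subnetworks with p < κ are called responsive; κ defaults to 0.05 and no
multiplicity correction is applied (matching the benchmark design; a BH
step can be applied downstream if needed). All four tests (SAM-GS, GSCA,
CIdrgn.1, CIdrgn.2) share the same permutation draws within a fit, so
method comparisons are paired.

## Network estimation

Expression columns are standardized within the estimation subset before the
lasso (penalty fairness across genes); coefficients are reported back on
the original scale. The penalty rule for the standalone estimator defaults
to per-target 5-fold cross-validation with the 1-SE rule. Inside the
permutation pipeline the default is the closed-form universal penalty
`α = sqrt(2·log(p̃)/n)` on the standardized scale: cross-validating every
target of every subnetwork in each of the 2(T+1) re-estimations buys
little and costs two orders of magnitude; the same rule is applied to
observed and permuted networks so the pipeline remains exchangeable. The
permutation loop solves all targets of a subnetwork by coordinate descent
on one (weighted) correlation matrix — a unit test pins this solver to
sklearn's Lasso at 1e-8.

Estimation is restricted per subnetwork to the scored genes. The statistics
only involve coefficients among scored genes, the normalization by vector
length cancels in the permutation z-scoring, and the restriction makes the
permutation re-estimation loop tractable; estimation over any larger
universe is available through `estimate_network(gene_universe=...)`.

## Sample-specific mode

With a scalar modulator m per cell line (a cell-line characteristic such as
drug response), the varying-coefficient model `y_ℓ = Σ_j β_ℓj(m)·x_j + ε`
is estimated per cell line: cell i gets Gaussian kernel weight
`K((m_i − m_α)/h)` in cell α's fit. Networks for a phenotype side are
estimated from that side's cell lines only — the sample-specific analogue
of per-phenotype bulk estimation — and are re-estimated on every
permutation's partition. Gene j's phenotype-level effect entries are
medians over the side's cell lines of `β̂_ℓj(m_α)·x_αj` (each cell line's
own expression), and neighborhoods are unions over the side's per-cell-line
networks before the Jaccard distance. D_SAM-GS is computed from expression
exactly as in bulk mode.

**Bandwidth.** Silverman's rule on the modulator (`0.9·min(sd, IQR/1.34)·
n^{−1/5}`) is the standalone estimator's default, but for n ≈ 50 it leaves
a kernel effective sample size near 14 and the per-cell-line networks are
then variance-dominated. The pipeline therefore selects h once per fit by
leave-one-out prediction error over a grid from Silverman's value up to the
modulator range (each cell line predicted from the others' kernel fit at
its modulator value, pooled over subnetworks and phenotypes, median of the
per-block winners), and reuses that h for every permutation — the same
discipline as the penalty rule. When coefficients vary strongly in m the CV
picks small bandwidths; on the benchmark's gently varying edge strengths it
picks heavy smoothing. A degenerate modulator (all values equal) falls back
to unweighted estimation with a warning. The weighted universal penalty
uses the Kish effective sample size `(Σw)²/Σw²` in place of n.

## Synthetic benchmark design

The generator reproduces the study conditions of the Monte Carlo benchmark:

* p = 1000 genes (restricted runs use the subnetwork genes plus a 100-gene
  background), n_A = n_B = 50 cell lines;
* 10 disjoint subnetworks of 10 (or 50) genes: 4 **common** (one generating
  distribution for all cell lines) and 6 **responsive** (phenotype A and
  phenotype B use different graphs, and B genes get a mean shift μ = 0.3);
* graph structures per scenario — scenario 1 random (edge probability 0.3
  at size 10, 0.1 at size 50), 2 cluster (two equal groups, within-group
  edge probability 0.6), 3 scale-free (preferential-attachment tree),
  4 hub (⌈size/10⌉ star groups); common and A-side graphs use the
  scenario's structure, B-side graphs are always width-1 band;
* precision matrices: 0.5 on every edge, constant diagonal
  `|λ_min(0.5A)| + 0.1 + 0.2` — the construction of the conventional
  graphical-model generator with added diagonal u = 0.2, giving spectral
  margin 0.3. Sampling uses the inverse precision standardized to unit
  marginal variances (again the conventional generator's behavior), so μ is
  in marginal-SD units and every gene has variance 1;
* background genes are i.i.d. standard normal.

The sample-specific variant draws m_α ~ U(−1, 1), maps it to
δ_α = (m_α + 1)/2, and scales each responsive precision matrix's
**off-diagonal** entries by (0.5 + 0.5·δ_α) with the diagonal held fixed,
then samples each cell line from its own standardized inverse. Scaling the
whole matrix instead (available as `interpolation="full"`) would rescale
variances while leaving every conditional regression coefficient untouched
— no modulator signal would reach the networks — so edge-only scaling is
the default: conditional edge strengths grow monotonically with the
modulator, which is the phenomenon the sample-specific estimator is meant
to recover.

What the generator does *not* emulate: library-size/technical noise,
heavy-tailed or zero-inflated expression, overlapping pathways, more than
two phenotypes, and modulator-phenotype confounding. Passing benchmarks
therefore demonstrate correctness and power under clean Gaussian
conditions, not robustness to real-panel artifacts.

## Evaluation

Responsive subnetworks are the positive class (6 per replicate), common the
negative (4 per replicate). Counts are pooled across replicates before
ratios (micro-average), matching the granularity of the reference tables;
recall, precision, TNR, F-measure and accuracy are reported per scenario ×
method. The benchmark defaults to 50 replicates with T = 100 and κ = 0.05.
The acceptance tests run the expensive full-pipeline scenarios at 15–25
replicates and the cheap comparator-only scenarios at 100–200 (comparator
statistics cost almost nothing, and the larger pools halve the Monte Carlo
noise of the pooled ratios); the acceptance script uses 50 replicates
throughout.

## Numerical choices and edge cases

* All randomness flows from one seed through spawned `SeedSequence`
  streams; fits, scenarios, reports and CLI outputs are bit-reproducible.
* Coordinate descent: tolerance 1e-8 on coefficient updates, 1000 sweeps
  max; constant gene columns get zero coefficient rows/columns and a
  warning.
* Z-scoring guard: a vector whose SD is ≤ 1e-12 of its magnitude is
  treated as constant.
* Jaccard 0/0 = similarity 1 (λ = 0); single-gene sets are allowed for Γ/Λ
  but GSCA requires ≥ 2 genes.
* Decisions use strict `p < κ`.

## Known limitations

* The permutation test assumes exchangeable cell lines under the null;
  batch structure or covariate imbalance between phenotypes violates this.
* In sample-specific mode the modulator is assumed comparable across
  phenotypes; strong modulator-phenotype association makes the kernel fits
  asymmetric.
* The lasso's universal penalty is conservative for very small phenotypes
  (n < 20); use the CV rule there.
* Combined scores can be dominated by a single axis when the other axes
  are degenerate across all permutations (all-zero networks); the
  constant-vector guard keeps such axes silent rather than undefined.
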