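# Methods

`txaging` implements the analytical machinery of a comparative
transcriptome-aging analysis — per-gene aging effects, cell-type signature
profiling, motif-density screens, and cross-dataset meta statistics —
together with synthetic-data generators that plant recoverable ground
truth for every stage. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data does and does
not establish.

## Per-gene aging effects

**Continuous-age designs.** Expression is modeled on the log2 scale as
linear in age, y_g = a_g + b_g·t + ε. Coefficients are estimated by
iteratively reweighted least squares with the Huber loss: the fit is
initialized at ordinary least squares with all weights equal, then each
iteration re-estimates the residual scale s as the normalized median
absolute deviation (MAD × 1.4826) and assigns weight
w_i = min(1, c·s/|r_i|) with tuning constant c = 1.345 — the value at
which the Huber estimator retains 95% Gaussian efficiency. Iteration stops
when the largest coefficient update falls below 1e-8 or after 50
iterations; residuals at rounding level (scale < 1e-10) terminate
immediately with all weights 1. All genes are iterated simultaneously in
vectorized form; `statsmodels`' RLM reproduces the coefficients to ~1e-8
and serves as an independent cross-check in the tests, never as the
implementation.

Standard errors use the Huber asymptotic covariance
(ψ-based sandwich with the small-sample correction factor
1 + (p/n)·Var(ψ′)/E(ψ′)², as in MASS's `summary.rlm`), which reduces
exactly to the OLS covariance when no residual is downweighted. A naive
weighted-RSS variance was measurably anti-conservative (empirical type-I
rate 0.078 instead of 0.05 at n = 60); the sandwich holds the level at
~0.052. p-values use a t reference with n − 2 degrees of freedom.
Constant-expression genes get slope 0 and p = 1 by convention.

**Lack of fit.** Adequacy of the linear model is checked per gene by an F
test of the linear model against linear + quadratic, BH-adjusted across
genes. Designs with fewer than five distinct ages are flagged degenerate
(p = 1).

**Two-group designs.** Young-vs-old contrasts use a pooled-variance t
test. Optional empirical-Bayes moderation shrinks per-gene variances
toward a global prior whose degrees of freedom and location are estimated
by moments on the log variances (inverting the trigamma function); the t
degrees of freedom become prior df + residual df. Moderation is off by
default — the plain t is exact under the generator's Gaussian noise.

**Interval fold change.** Fold changes are summarized over a fixed span —
40 years for year-scaled studies, 24 months for month-scaled ones — on the
*absolute* scale: values are exponentiated, a straight line is fit to
absolute expression vs age, and fc = (ŷ(t₀) + b·Δ)/ŷ(t₀) with t₀ the
youngest sampled age (continuous designs) or the young-group age
(two-group designs, where b is the group-mean difference over the age
gap). The evaluation age t₀ is a deterministic choice; under a linear
absolute-scale trajectory the ratio depends on it, and the youngest
sampled age makes the statistic reproducible from the data alone.
Non-positive baselines leave the fold change undefined (flagged).

**Detectability.** Since probe-level presence calls are out of scope,
genes are filtered by a quantile rule: keep genes exceeding the study-wide
0.25 expression quantile in strictly more than half the samples.

## Inflammation profiling

Each cell population is represented by its signature transcripts: the top
N = 500 transcripts ranked by two-sample t statistic of population
replicates against a heterogeneous reference panel, restricted to
positive effects. In an aging profile, n₁ counts members with fold change
above 1 and n₂ those below 1 (no significance filter by default; members
at exactly 1 count in neither; a p < 0.05 filter is available since either
reading of the counting rule is defensible). The canonical internal
quantity is the proportion p̂ = n₁/(n₁+n₂) (ratio > 1 ⇔ p̂ > 0.5).

Shared markers are handled by exclusion: population i's adjusted counts
(n₁*, n₂*) drop any member that is also a signature transcript of a
population with a *strictly* larger raw ratio (ties leave both sets
intact, so the top-ratio population is never altered). Significance
requires bias in both the raw and the adjusted counts: one-sided Fisher
tests of [[n₁, n₂], [U−n₁, D−n₂]] against the up/down split (U, D) of all
analyzed transcripts, run as two one-sided families (increase, decrease),
BH-adjusted across populations within each family; a population is called
only when raw and adjusted q are both below 0.05 on the same side. The
transcriptome-wide background makes the test one of *bias relative to the
global split* rather than absolute counts — important because a genuine
infiltration signal slightly tilts the global split itself. This also
means the background must dwarf any single signature; see the generator
notes below.

Category display follows the charting rule: within a category, show the
maximum p̂ when the median across populations exceeds 0.5, otherwise the
minimum, with a marker only if the displayed population is significant.
Age trajectories report the median and interquartile range, across
members, of each age group's absolute-scale mean expression relative to
the youngest group.

## Motif-density screens

**Scanning.** A PWM of length L is converted to per-position
log2(posterior/prior) scores against the background base frequencies
(probabilities floored at 1e-4 and renormalized so log-odds stay finite).
Every window on the forward strand and on the reverse complement is
scored by summing positional scores; a window is a hit when its score
strictly exceeds 90% of the PWM's maximum attainable score. Windows
containing N are skipped. Overlapping hits from either strand are
collapsed greedily left-to-right into non-overlapping matches, each
counted once. Window coordinates are 0-based half-open; the default gene
window spans 2000 bp upstream through 200 bp downstream of the TSS, taken
5′→3′ of the gene so minus-strand genes mirror plus-strand ones. The
vectorized scanner is property-tested against a per-window Python
enumeration oracle.

**Threshold series.** For each motif, nested gene sets x_t collect genes
with at least t matches (t = 1…max). Each set's up/down membership split
(u_t, d_t) is compared with the direction totals of all analyzed genes by
a two-sided Fisher test, BH-adjusted across all sets of all motifs in a
run. Motifs are ranked by the most extreme proportion (distance from 0.5)
among sets holding at least 100 genes — small sets are too unstable to
rank by.

**Family-wise calibration.** Because the nested sets are strongly
dependent, multiplicity is handled by simulation: each of 2000 trials
permutes the direction labels over genes (equivalent, under
exchangeability, to randomly re-assigning genes to sets, and preserving
both set sizes and direction totals), recomputes every set's Fisher p,
and records the minimum; P* is the empirical 0.05 quantile of that
null distribution, and observed sets with p < P* pass. Trials are
evaluated in closed form: for fixed margins the two-sided Fisher p is a
function of the set's up-count alone, so a per-set-size lookup table
(verified against `scipy.stats.fisher_exact`) reduces each trial to a
matrix multiply. The family defaults to all sets of all motifs in one run.

**Length adjustment.** For variable-length region sets (intergenic,
intronic, conserved-upstream), raw counts correlate with length; the
length-free density score is the Pearson residual (y − μ̂)/√μ̂ from a
log-link Poisson regression of counts on ln(length) (deviance residuals
by flag). Foreground/background contrasts sweep the foreground size k
over the p-ranked directional genes and flag k's where the
normal-approximation 95% confidence intervals of the foreground and
background mean scores are disjoint — a deliberately conservative rule.

## Meta-profiles

Profiles (interval fold changes over a shared gene universe) are
standardized by dividing each row by its own standard deviation (ddof 1);
constant rows are flagged and excluded. Clustering uses
1 − Pearson correlation distance with average linkage and label-sorted
ordering for deterministic ties. Support-ranked gene lists count
same-direction significant calls across profiles, breaking ties by mean
standardized fold-change magnitude, then gene id.

Cross-species agreement over 1:1 ortholog pairs is assessed three ways:

- a 3×3 direction contingency ({up, ns, down} × {up, ns, down}) with
  adjusted residuals (O−E)/√(E(1−r/n)(1−c/n)), approximately standard
  normal under independence, |residual| > 3 flagging a cell;
- a rank statistic: with one species' orthologs ranked by the other's
  aging p, U sums background items below each foreground item and
  z = (U − m(N−m)/2)/√(m(N−m)(N+1)/12) refers to the standard normal
  (tie-free lists are required; ties are broken by gene id upstream);
- a running-sum enrichment score (+1/m at hits, −1/(N−m) at misses,
  computed in exact integer arithmetic so a top-loaded foreground yields
  ES = 1.0 precisely), with a null from re-drawing m random foreground
  positions per trial (default 1000) and p = (1 + #null ≥ obs)/(trials+1).

Ortholog fold-change correlation is Pearson's r with a t-based p;
central-region flags mark the ⌈0.5n⌉ and ⌈0.8n⌉ points closest to the
coordinate-wise median by Mahalanobis distance under the sample
covariance (pseudo-inverse, so degenerate clouds do not error).

## Ontology enrichment

Terms form a DAG (child → parent edges, `networkx`); gene annotations
propagate to ancestors. Overrepresentation is tested children-first with
one-sided Fisher tests; once a child is significant (uncorrected
p < 0.05, as is conventional for this conditional procedure — a BH option
exists but is off by default), its genes are excluded from every
ancestor's table, decorrelating the reported terms. Directional calls per
term combine a one-sample t test, an exact binomial sign test and a
Wilcoxon signed-rank test of member fold changes against the no-change
point fc = 1.0 (a background-mean center is available by flag); a
direction is reported only when all three agree at p < 0.05. Terms are
clustered by 1 − Jaccard similarity of their ancestor sets (term included
in its own set; a raw shared-count similarity is available by flag).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a configuration and a seed, and each
returns a truth table sufficient to score recovery downstream. Defaults
are the study conditions the analyses target:

| parameter | default | role |
|---|---|---|
| `n_genes` | 10,000 | transcriptome size; large enough that one 500-gene signature is a small fraction of the whole, as on expression arrays — with a tiny transcriptome a planted shift would distort the global up/down background |
| `n_samples` / `age_range` | 60 over 18–75 y | continuous human-like cohort |
| `n_per_group`, ages | 5 + 5 at 5 / 30 mo | two-group mouse-like design |
| `effect_fraction`, `slope_sd` | 0.2, 0.02 log2/unit | planted age effects |
| `noise_sd` | 0.2 log2 | residual spread typical of array data |
| `signature_size`, `signature_delta` | 500, 2.0 log2 | population signatures |
| `mixing_shift` | +0.30 | planted abundance change in old samples |
| `lambda_up/down/bg` | 3 / 1 / 1 | motif occurrences per window by gene direction |
| `window_up/down` | 2000 / 200 bp | TSS scan window |
| `n_decoys` | 20 | decoy motifs per run |
| `shared_core_fraction`, `discordant_fraction` | 0.10, 0.05 | cross-species structure |

Mixture shifts are applied multiplicatively on the absolute scale to the
target population's signature genes only — simpler than full convex
mixing but sufficient to create the directional bias the screen detects.
Promoter backgrounds are i.i.d. sequences regenerated by rejection until
free of chance consensus matches on either strand, so planted occurrence
counts are exact; planted and decoy motifs are sharp (near-consensus)
probability models so that only exact matches clear the 90% threshold.

Consequently, passing tests demonstrate that the statistics recover what
they are designed to recover under their own assumptions. They do not
show robustness to features of real data the generators omit: probe-level
noise and batch structure, correlated genes, soft (information-content
rich but degenerate) motifs, compositional coupling between cell
populations, or non-linear age trajectories. The robustness tests cover
gross outliers, not heavy-tailed noise generally.

## Numerical choices and degenerate inputs

- BH adjustment delegates to `statsmodels.multipletests` and is
  oracle-tested against the literal step-up formula.
- Fisher tests delegate to `scipy.stats.fisher_exact`; the calibration
  lookup matches its two-sided convention (probabilities ≤ observed with
  a 1+1e-7 tie guard) and is tested against exhaustive enumeration for
  all small tables.
- Degenerate cases are conventions, not errors, wherever the pipeline
  must continue: constant genes (slope 0, p 1), all-tied fold changes
  (undefined p̂, flagged), empty signature candidates (empty set,
  flagged), zero contingency margins (NaN residuals, flagged), empty
  sweep backgrounds (degenerate flag, never significant).
- Every stochastic routine takes a seed or `numpy` Generator; the CLI
  threads one `--seed` through all stages (default 20120307).

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the distributional claims are stable: type-I
calibration at 10,000 genes; the min-p correction at 500 genes × 20 sets
over 200 null runs with the full 2000 trials each; abundance-shift
recovery over 50 seeds at default conditions; motif recovery at 2000
genes with 20 decoys over 10 seeds; the end-to-end pipeline on the
default configuration.
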