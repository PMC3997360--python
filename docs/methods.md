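# Methods

## Quantification model

Expression is measured on the quantification-cycle (Cq) scale and reported
as the relative copy number RCN = 2^(−ΔCq) × 100, where
ΔCq = Cq(target) − Cq(reference) and the per-subject reference is the
median Cq of the housekeeping genes (≥ 1 required; the default panel
carries B2M, GAPDH and RPL13, and the median of three is robust to one
aberrant control). RCN = 100 means "at housekeeping level"; the −log2
round trip recovers ΔCq to 1e−12. Amplification-efficiency correction,
standard curves and technical-duplicate handling beyond a mean-collapse of
input wells are out of scope. Missing target Cq values propagate as NaN
and pairwise statistics use pairwise-complete subjects; a missing
*reference* Cq is an error naming the subject, since the whole subject
column would be uninterpretable.

Standardization (z-scores) uses the sample SD (ddof = 1): the cohorts this
package targets are small (tens of subjects), and the sample convention
matches the statistics packages practitioners compare against. A
zero-variance gene is an error listing the offending genes.

## Co-expression statistics

Pearson r with two-sided p-values from t = r·√((n−2)/(1−r²)), exactly
collinear pairs reported as p = 0. The Bonferroni correction multiplies by
all G(G−1)/2 pairwise tests — one global family, not per-row. Pearson is
affine-invariant, so RCN and z-scored inputs give identical r; note that
correlations are computed on the *linear* RCN scale, so strongly lognormal
genes attenuate r relative to the log2 scale (see the generator notes
below).

Hierarchical clustering is complete linkage on Euclidean distances between
z-scored gene profiles. With standardized rows the squared Euclidean
distance is 2(n−1)(1−r), monotone in 1 − r, so the dendrogram ordering
matches a correlation-distance clustering; `metric="correlation"` is
provided for the literal 1 − r variant. The merge tree serializes to
Newick (scipy merge tree walked directly; round-trip validated against
scikit-bio in tests).

## Module mining

The co-expression graph joins two genes iff |r| > τ, strictly; the
default τ = 0.7, with τ = 0.8 a common display convention for the same
kind of network. Maximal cliques come from Bron–Kerbosch with greedy
pivoting (pivot = candidate maximizing |P ∩ N(u)|), which keeps the
worst case manageable at panel scale (≤ ~50 nodes); output order is
canonical (size descending, then lexicographic on sorted members) so every
downstream step is deterministic. Isolated nodes are returned as singleton
cliques (mathematically maximal) and dropped from module output by the
minimum-size rule (|members| ≥ 2).

Merging is greedy agglomeration over subnetworks with overlapping
membership, candidate pairs processed in order of union size (descending,
lexicographic tie-break — the published merge procedures leave this order
open, so determinism is a package choice). A pair merges iff the union's
edge density ≥ γ **and** the union's mean |r| over *all* member pairs
≥ α_corr (defaults 0.8 / 0.8). Density alone cannot guarantee an average
correlation at an edge threshold of 0.7, so the average-correlation
guarantee is enforced as an explicit second floor; the two floors are also
applied to the returned set, so a raw clique whose mean |r| falls in
(τ, α_corr) is filtered out rather than reported in violation of the
contract. Fully contained subnetworks are absorbed. Modules may overlap in
boundary genes; no disjoint partition is attempted.

Connectivity diagnostics use the module-induced subgraph: degree k and
C(k) = 2·triangles/(k(k−1)), with C ≡ 0 for k < 2. The hierarchical-
modularity signature is the least-squares slope of log C(k) on log k,
excluding C = 0 points (log undefined); fewer than two distinct k values
⇒ undefined (`None`). A hub is a member adjacent to every other member of
its module and to ≥ 1 node of a different module.

## Functional filter, metagene, internal consistency

Gene–phenotype associations are Pearson r with two-sided p per gene ×
variable; BMI is evaluated within the female stratum (sex-specific
adiposity coupling), all other variables on the full cohort. The filter
keeps genes with **unadjusted** p < 0.05 for *every* requested variable —
deliberately liberal (per-gene screening, no multiplicity correction),
flagged as such; the all-variables conjunction is the real gatekeeper.

The modular index is the plain mean of z-scored RCNs over member genes —
equal weights, so duplicated items genuinely re-weight the metagene (this
is asserted, not hidden). The standardizing population defaults to the
analyzed cohort; for cross-cohort comparison patients can be standardized
against the control cohort's per-gene mean/SD (`reference=`), and radial
percent-of-median profiles likewise default to the control medians when
profiling patients. Metagene–phenotype effect sizes are reported both as r
and as signed_r2 = sign(r)·r², an explicit signed convention (a literal
R² is non-negative).

Cronbach's α comes in raw (variance-ratio) and standardized
(Spearman–Brown, α = K·r̄/(1+(K−1)·r̄)) modes; they coincide for
equal-variance items (asserted to 1e−9 in tests). Standardized is the
default for z-scored metagenes. α > 0.95 is read as item redundancy
(saturation). For saturation analyses items are taken on the log2 scale,
where qPCR noise is approximately normal — the assumption behind the
inter-item Pearson correlations that α summarizes.

## Cohort comparison

Percent reduction per gene is 100·(median_CT − median_HT)/median_CT,
median-based because RCN distributions are right-skewed; the default test
is two-sided Mann–Whitney on RCN (a rank test is the defensible default
under skew), with Welch's t on log2 RCN as the parametric variant.
Module-level reduction is mean ± sample SD of per-gene reductions over the
cardiovascular module's genes (the default gene set; the choice of gene
set and median- vs mean-based reductions are exposed because the aggregate
is not uniquely pinned down by convention). The structure contrast reports
per-cohort module counts, within-module degree ranges over module nodes
(leukocyte genes excludable), and a fusion flag that is true iff some
patient module contains genes *exclusive* to two different control
modules — shared boundary genes alone cannot trigger fusion.

## Synthetic cohorts: what is emulated, and what is not

The generator works on the log2 (Cq) scale, where qPCR noise is additive:
a module gene's log2 expression is loading·f + ε with a module-specific
latent factor f and N(0, noise_sd²) noise, so the planted pairwise
correlation between module genes is loading²/(loading²+noise_sd²) — 0.9 at
the defaults (loading 0.5, noise 0.167 cycles). The moderate amplitude
(total log2 SD ≈ 0.53 cycles) keeps Pearson on the linear RCN scale within
~2 % of the planted log-scale value; large-amplitude lognormal genes would
attenuate RCN-scale correlations noticeably. Housekeeping noise is 0.1
cycles — precise endogenous controls are the premise of ΔCq normalization,
and the per-subject reference median is a small common-mode component
shared by every gene.

Coupled phenotypes are generated as *children* of the cardiovascular
factor: z_v = w_v·f1 + √(1−w_v²)·ε_v with w_v = coupling/attenuation, so
the per-gene gene–phenotype correlation equals the requested coupling
(defaults: age −0.85, AIx −0.85, AoPP −0.85, BMI +0.90 in females; the
female BMI coupling sits at the top of its observed per-gene range because
the female stratum is small, n = 14 of 26). This construction is the only
one that supports several strong couplings simultaneously — if the
phenotypes were mutually independent, the sum of squared correlations with
one latent factor could not exceed 1 — and its price is stated openly: the
coupled phenotypes are mutually correlated (≈ product of their latent
weights). Phenotype marginals are uniform over the printed cohort ranges
via a Gaussian copula; sex composition is fixed (14 F / 12 M control,
6 F / 14 M patient). Patient AIx/AoPP ranges are not printed for the
reference cohorts, so mildly elevated uniform ranges (AIx 5–50,
AoPP 25–60) are package choices.

The hypertensive cohort applies per-gene percent reductions drawn from a
Beta distribution on (0, 100) % with mean 72 and SD 22 (clipped at 95 %) —
a bounded law carrying the target mean ± SD exactly, where a truncated
normal would shift the realized mean by ~6 points — implemented as an
upward Cq shift of −log2(1 − pct/100); a loading multiplier
(`coupling_tightening`, default 1.6) and a raised inter-factor correlation
(0.95 vs 0.1 in controls) produce the tightened, fused patient network and
the compacted degree range. Hub bridging (two designated module-1 genes
with a cross-loading on the second factor) is an option, off by default:
at n = 26 the "adjacent to every member" hub property does not
concentrate, so hub-recovery tests run it at n = 200.

Not emulated: plate and batch effects, amplification-efficiency variation,
technical duplicates, dissociation-curve artifacts, single-cell structure,
heavy-tailed per-gene outliers, and any dependence of phenotypes on
treatment. Passing tests therefore demonstrate that the *pipeline*
recovers planted structure of the assumed form at study-scale n — not that
real PBMC data satisfy these assumptions.

## Problem sizes, seeds, tolerances

Test and reproduction runs use the study-scale conditions: 45 assay genes,
n = 26 control / n = 20 patient subjects. Monte-Carlo characterizations in
the test suite use 20–300 seeded cohorts depending on the concentration of
the statistic (20 seed pairs for reduction recovery; 300 cohorts for the
saturation expectation and for the type-I rate, whose confidence interval
is computed cluster-robust over cohorts because tests within a cohort
share subject draws). Exact identities are asserted at 1e−12 (RCN formula,
correlation vs sum-formula oracle, C(k) vs triangle counting), moment
contracts at 1e−9 (z-score mean/SD, raw-vs-standardized α), recovery
statements at their Monte-Carlo tolerances (planted pairwise r ± 0.1;
module membership up to ≤ 2 boundary genes; reduction mean ± 5 percentage
points). The saturation scenario plants pairwise r = 0.81 so that the
*expected empirical* mean inter-item correlation at n = 26 is 0.800: the
sample mean pairwise correlation of a factor model is attenuated at small
n because the factor's sample variance enters every pair.

## Known limitations

* The functional filter's all-variables conjunction is sensitive to the
  smallest stratum (females, n = 14); in repeated simulation at the
  default couplings it returns exactly the planted 15 genes in most seeds
  and 14–16 in ~94 % — single-seed runs can deviate by a gene or two.
* Merging is greedy; a different (also defensible) candidate order can
  yield different overlapping covers on borderline graphs. The canonical
  order makes results reproducible, not "the" unique answer.
* RCN-scale Pearson underestimates log-scale coupling for high-variance
  genes; the package follows the field's RCN-scale convention rather than
  silently switching scales.
* No age adjustment or multivariable modelling of gene–phenotype
  associations is attempted; associations are bivariate by design.
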