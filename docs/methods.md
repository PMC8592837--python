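# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic-data tests do and do not demonstrate about real data.

## Immune topography classification

Patients are characterized by two scalars computed from H&E cell tables:
the intratumoral lymphocyte proportion `p_IT` (lymphocyte count / total
cell count among IT cells) and the analogous `p_PT`, with
`delta = p_PT − p_IT`. Labels are assigned by a two-phase unsupervised
procedure:

1. Agglomerative hierarchical clustering (Ward.D2 linkage, Euclidean
   distance) of the 1-D `p_IT` values, cut into two clusters; the cluster
   with the higher mean is **hot**.
2. The same clustering of `delta` restricted to non-hot patients; the
   higher-mean cluster is **excluded**, the other **cold**.

scipy's `linkage(..., method="ward")` on raw distances implements the same
update rule as R's `ward.D2`, which is what the two-phase procedure
expects. On 1-D data with a gap larger than the within-cluster spread the
two-cluster Ward cut coincides with the partition minimizing total
within-cluster sum of squares; the test suite verifies this against a
brute-force all-splits minimizer.

Design choices where the procedure itself is underdetermined:

* Correlation distance is undefined on 1-D features, so Euclidean distance
  is used for both phases (correlation-distance clustering is reserved for
  the multi-feature heatmaps).
* Cluster → label mapping is by cluster means; an exact tie of means, or
  all-equal inputs, is degenerate and raises by default
  (`on_degenerate="cold"` falls back to the conservative class).
* The assignment is invariant to row permutation and to adding a constant
  to all `p_IT` values; it is **not** invariant to rescaling, since Ward
  merge costs scale with squared distances.

## Mutation–topography association

For each gene, patients with a topography label and a non-missing call
form the 2×2 table `[[class ∩ mutated, class ∩ wild-type], [rest ∩
mutated, rest ∩ wild-type]]`. Genes mutated in fewer than 5% of callable
patients are skipped (configurable), and missing calls are dropped
per gene (pairwise), so per-gene denominators may differ. The dispatch
rule: chi-square with Yates continuity correction when every observed cell
count exceeds 5, else the two-sided Fisher exact test. The continuity
correction is part of the method definition here; the test suite pins both
branches to independent textbook oracles (the corrected χ² formula and an
exact-rational hypergeometric enumeration) at 1e-10. Because the dispatch
boundary is a convention, every result carries `test_used` and an override
parameter forces either branch. Benjamini–Hochberg adjustment is applied
across genes.

## Gating and phenotyping

A cell is positive for a marker when its intensity is **at or above** the
threshold (boundary positive — the convention must be fixed somewhere, and
ties at the threshold are vanishingly rare for continuous intensities).
Automatic thresholds fit a two-component Gaussian mixture to log
intensities and use the geometric midpoint of the component means. The
mixture uses a tied covariance and extreme-quantile initialization so the
fit stays bimodal when positives are rare (~1% of cells); if the fitted
means are separated by less than two pooled standard deviations the
distribution is treated as unimodal and the midpoint of the intensity
range is used, with a warning.

Cell classes are conjunctions over positivity calls (T = CD3+, helper T =
CD3+CD4+, cytotoxic T = CD3+CD8+, NK = CD2+CD3−, CD16+ myeloid). Classes
overlap, so membership is stored as a boolean cell × class matrix rather
than an exclusive assignment; subset consistency (`#Tc ≤ #T` in every
patient × region) is asserted in the invariant tests. Phenotype
proportions use either all cells or a parent class as denominator;
parent-class denominators below 10 cells (configurable) yield missing
values rather than unstable ratios.

Heatmap normalization is per feature (column): subtract the median across
rows, divide by the maximum absolute centered value; constant features map
to zero. The output obeys max |value| ≤ 1; the transform is not
idempotent in general and is treated as display-only. Heatmap clustering
uses 1 − Spearman correlation with Ward.D2; Euclidean distance between
correlation profiles is available as an option. Profiles with zero
variance have undefined correlations and are appended unclustered.

## Interaction index

With the threshold `d ≤ 100 px` (22 µm at 0.22 µm/px, inclusive at the
boundary), the interacting-pair count i_ab sums over all (j, k)
combinations of types a and b. Conventions the double-sum notation leaves
open:

* Same-type pairs are unordered with self-pairs excluded (a cell is not
  adjacent to itself).
* Because classes overlap, one physical cell can appear under both type
  labels; pairs formed by the same cell under two labels are excluded by
  cell id.
* Pairs never span region or core boundaries; multi-core patients are
  aggregated by summing i_ab, m, n, c across cores before normalizing.

The index is `I_ab = i_ab · c / √(m·n)`: the count divided by the
geometric-mean pair proportion `√(mn)/c`, so samples are comparable across
differing cell-type abundances. The normalization is read this way because
the alternative (`√(m+n)/c`) does not represent a pair proportion; it is
nevertheless implemented behind `index_variant="sum"`. KD-tree counting is
exactly equivalent to the O(mn) double loop (property-tested on random
instances), so no tolerance is involved.

Interaction-conditioned fold-changes compare marker-positive proportions
between interacting and non-interacting focal cells. Medians and the
paired test are taken **across patients** (each patient contributes one
p_int/p_non pair, both groups ≥ 10 cells) rather than pooling cells, so a
single cell-rich patient cannot dominate; `FC = log10(median p_int /
median p_non)` with a two-sided Wilcoxon signed-rank p, BH-adjusted within
the panel.

## Group comparisons and survival

Unpaired two-group comparisons use the two-sided Mann–Whitney rank-sum
test, three or more groups Kruskal–Wallis; the signed-rank test is
reserved for genuinely paired contrasts (interacting vs non-interacting
within patient). Fold-changes are log10 ratios of group medians, missing
when a median is zero. Clinical features are median-dichotomized with ties
assigned to the low class (documented, configurable); an all-constant
feature is a degenerate split and raises.

Survival screens are univariate Cox proportional-hazards fits on overall
survival. Dichotomized (or already binary) features report the log-rank p
between groups plus the Wald 95% CI of the hazard ratio; continuous
features report the Wald p. Fits require ≥10 patients and ≥3 events;
non-convergence is flagged rather than raised. Kaplan–Meier coordinates
are attached for plotting.

## Synthetic cohort generator

The generator emulates the study design at the cell-table level: 64
patients by default, one 2 mm core each with disjoint IT and PT regions,
0.22 µm/px coordinates, topography weights equal to the observed cluster
sizes (14/38/12 of 64). Per patient:

* The topography label is drawn from the weights; per-region lymphocyte
  fractions are beta-distributed with topography-specific means (hot IT
  0.25 / PT 0.15; cold IT 0.03 / PT 0.05; excluded IT 0.04 / PT 0.20;
  concentration 120). The means are deliberately well separated so that
  recovery tests are decisive; only overall medians are known from real
  cohorts, so these are illustrative, not calibrated.
* Cell positions follow a Thomas-type cluster process (Poisson parents,
  Poisson(25) offspring, 30 px Gaussian dispersion, 50% uniform
  background) or a homogeneous Poisson process. Expected counts are 2600
  (IT) and 1700 (PT) cells per region, comfortably above the 1500-cell
  core filter.
* Lymphocytes split into helper T / cytotoxic T / NK at 40/35/25%; 6% of
  non-lymphocytes are CD16+ myeloid. Lineage-marker truth is deterministic
  given the class; functional-marker positivity is Bernoulli with
  class-specific probabilities. CD45RO positivity is enriched 3× among
  cells placed by the clustered component, encoding the association
  between spatial interaction and memory phenotype that the
  interaction-FC analysis is designed to detect.
* Intensities are two-mode log-normals (log-means 0 and 2.3, log-sd 0.35
  — about 6.5 sd of separation, i.e. "well-separated modes").
* Mutations are Bernoulli with per-gene prevalence and per-topography odds
  ratios (e.g. PBRM1 0.43 prevalence, OR 2.5 in cold tumors). Survival is
  exponential proportional hazards (baseline median ~4 years) with
  independent exponential censoring at an expected 30% rate; the default
  log-hazard −log 5 on the excluded indicator encodes the protective
  excluded topography.

Randomness is hierarchical: each patient consumes a child stream of the
cohort seed keyed by patient index, so identical configs reproduce
byte-identical tables and adding patients never perturbs earlier ones.

**What the synthetic tests show — and don't.** Passing recovery tests
demonstrates that the implementation correctly inverts its own generative
assumptions at realistic sample sizes (≥95% topography label agreement
across 50 cohorts of 64; ≥99% gating accuracy; Cox HR recovery; ≥90%
detection of a 3× interaction-linked enrichment at 40 patients). Real
tissue violates these assumptions in known ways: lymphocyte fractions are
not beta with shared dispersion, segmentation errors correlate spatially,
marker intensities drift across staining batches and are not cleanly
bimodal, region annotation is manual, and censoring is not independent of
prognosis. Results on real cohorts therefore need the usual external
validation; the tests certify the arithmetic, not the biology.

## Problem sizes in the checked runs

The shipped acceptance analyses use 50 cohorts of 64 patients for
topography recovery, one 8-patient full-panel cohort (~35k cells) for
gating, n=500 for Cox recovery, and 10–20 cohorts of 40 patients for the
interaction fold-change power check — sizes at which each recovery
check is statistically decisive for the generator's effect sizes.

## Known limitations

* The topography procedure has no reject option: every patient with both
  regions receives a label, however weak the separation; inspect the
  dendrogram heights for borderline cohorts.
* Auto-gating assumes a shared log-scale spread for the negative and
  positive modes; markers with strongly asymmetric modes should be gated
  with fixed thresholds.
* The interaction index is undefined (missing) when either type is absent
  from a sample, and grows linearly with total cellularity c by
  construction; compare indexes only within comparable cellularity ranges
  or rely on the per-patient paired contrasts.
* Cox fits are univariate by design; no multivariable adjustment or model
  selection is provided.
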