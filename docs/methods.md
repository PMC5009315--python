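# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions at the edges.

## Differential expression

Per study, each gene is tested between two sample groups with the
two-sided Mann–Whitney rank-sum test and gated on the linear-scale fold
change of group means: a gene is called iff p < 0.001 and
FC ≥ 1.5 or FC ≤ 1/1.5. Both thresholds are configurable; the defaults
are the conventional microarray re-analysis settings for this kind of
meta-comparison. Points worth making explicit:

- **No multiple-testing correction.** Calls are gated on the raw
  p-value. The replication filter in this design is the downstream
  cross-study intersection: a false positive must recur, with the same
  direction, in every member study of a meta-profile to survive. Users
  applying `differential_genes` outside that context should be aware the
  per-study call sets are not FDR-controlled.
- **p-value computation.** The test statistic U is the smaller of the two
  one-sided U's. For untied samples with ≤ 8 per group the p-value is
  exact (full enumeration, via `scipy.stats.mannwhitneyu`); otherwise the
  normal approximation with tie correction and continuity correction is
  used. The genome-wide path is a vectorized implementation of the same
  asymptotic formula, verified row-by-row against the scalar routine; for
  small studies (both groups ≤ 8) untied genes are re-routed through the
  exact path so that a small study gets exact p-values genome-wide.
  A fully degenerate gene (every pooled value identical) gets p = 1.
- **Fold change** is the ratio of linear-scale group means. Mean (not
  median) aggregation is used and no log-scale variant is offered, to
  keep a single semantics. A ratio of exactly 1 carries the inert label
  "up" (it can never pass the gate).
- The auxiliary `student_t_test` (viability readouts) is the equal-variance
  two-sided t-test; zero pooled variance returns p = 1 for equal means and
  p = 0 otherwise — the limit for perfectly reproducible measurements.

Sample sizes matter here: the exact two-sided Mann–Whitney floor at
n = 3 vs 3 is p = 0.1, so a 0.001 gate is unreachable below roughly n = 7
per group. The synthetic preset therefore uses n = 9 per group (see
below).

## Harmonization and the annotation mask

Cross-platform comparison goes through a probe→gene map ("annotation
mask") that defines the shared gene universe; any user-supplied mask is
treated as authoritative. Probes absent from the mask are dropped.
Multi-probe genes collapse by **max_mean** — the probe row with the
highest mean intensity over all samples, ties to the earliest probe — the
common microarray convention; a per-sample **median** rule is available.
Intensities are assumed background-corrected and normalized upstream
(vendor-processed chips): this package performs no normalization, by
design. Gene identity is the whitespace-trimmed, case-sensitive symbol
string.

## Meta-profiles, decomposition, maintenance, specificity

"Similarly altered" is implemented as *membership with the same direction
of dysregulation* everywhere (a `require_direction_match=False` flag
relaxes this to bare membership); pure membership would count
opposite-direction genes as similar, which contradicts the way up/down
panels are read.

- **Meta-profile rule.** Default `all_concordant`: a gene is kept iff
  every member study calls it with one common direction. The
  `majority_concordant` alternative (strict majority, no dissent) is a
  sensitivity check, and the strict profile is always a subset of the
  majority one.
- **Decomposition** partitions a disease profile into reference-like and
  non-reference parts; the reported percentage is 100·|reference-like|/
  |profile|, rounded to one decimal with halves away from zero (so
  768/989 prints as 77.7).
- **Maintenance** builds the 2×2 component × maintained/lost table and
  tests association with the Pearson chi-square, df = 1, upper-tail p,
  *without* Yates correction by default — the tables this package reports
  have large cells; the correction is available as a flag. A zero row
  margin (an empty component) leaves the statistic undefined and is
  reported as absent; a zero column margin with both components populated
  means observed equals expected everywhere and is reported as
  chi2 = 0, p = 1 (no association).
- **Specificity** of a signature in an unrelated condition's profile is
  the direction-concordant overlap percentage; when a comparator split is
  supplied (typically the profile the signature was defined against) the
  two in/out splits are compared with the same chi-square.

## Clustering and separation

Samples (or genes) are clustered agglomeratively on a gene subset.
Defaults: Pearson correlation distance (1 − r) with average linkage —
the classic expression heat-map convention — with Euclidean distance and
complete/single linkage available. Correlation distance makes the result
invariant to per-item positive-affine intensity transforms. An item with
zero variance has no defined correlation and is rejected by id. An
optional `center_rows` switch subtracts each gene's median across samples
before clustering (display-style midpoint normalization).

Merge order for tied distances follows `scipy.cluster.hierarchy.linkage`,
which is deterministic for a fixed input ordering; that determinism (not
a particular tie-break convention) is the contract, and the average-
linkage heights are verified against a naive O(n³) re-agglomeration in
the test suite.

The **separation score** cuts the tree at the k − 1 highest merges
(k = 2 by default) and reports purity: the weighted mean majority-label
fraction over clusters. Purity 1 means label-perfect clusters; on
label-shuffled exchangeable data it sits near the majority-class
baseline (0.5 for balanced two-class labels), slightly above it for
finite samples because maxima are taken per cluster.

Dendrograms export to Newick with branch lengths equal to parent−child
merge-height differences (leaf-to-root distance then equals the root
height); matrices export as TSV reordered by leaf order.

## ΔΔCt quantification

Technical replicates are averaged per (sample, gene); then
ΔCt = C̄t(target) − C̄t(reference gene), ΔΔCt = ΔCt − mean ΔCt of the
control group, FC = 2^(−ΔΔCt). Conventions:

- **Non-detects.** Ct above the ceiling (default 40 cycles) is clamped to
  the ceiling and the sample flagged, so "not expressed" enters the
  arithmetic as the detection limit rather than vanishing; a drop policy
  is available by flag.
- **Group summary.** Arithmetic mean of per-sample fold changes by
  default; the geometric option equals 2^(−mean ΔΔCt) and makes the
  control group's own summary exactly 1.
- **Group testing** uses the Mann–Whitney test on per-sample relative
  quantities 2^(−ΔCt). The test is rank-based, so this choice is
  equivalent to ranking −ΔCt; the quantity scale is used for reporting
  consistency.
- A per-sample loading offset added to every gene of a sample cancels in
  ΔCt by construction.
- No amplification-efficiency correction or standard-curve fitting is
  performed: the model is plain ΔΔCt (perfect doubling per cycle).

## Median-effect fitting and combination index

Single-agent dose–response points (D, fa) with fa strictly inside (0, 1)
are fitted by least squares on the linearized median-effect equation,
log10(fa/fu) = m·log10 D − m·log10 Dm; r is the correlation of that fit.
Viability readouts convert as fa = 1 − treated/control, clipped into
[ε, 1 − ε] with ε = 10⁻⁴ so the log-linearization stays defined; clipped
points are flagged and excluded from fits by default. A fit with m ≤ 0
(effect not increasing with dose) is returned flagged and refuses
inversion.

The combination index is the two-term, mutually-exclusive form
CI = d₁/Dx₁(fa) + d₂/Dx₂(fa) with Dx = Dm·(fa/fu)^(1/m), scored
independently at every combination point (non-constant-ratio design).
The classification band is ±0.1 around 1, reported alongside the raw
value. The mutually-nonexclusive third term is deliberately not
implemented (the two-term form is the standard default), and no
dose-reduction index, Bliss or HSA model is offered. CI is invariant to
rescaling one agent's dose units consistently across its fit and doses.
Isobologram export gives the additivity-line intercepts (Dx₁, 0)–(0, Dx₂)
per effect level plus combination points in normalized coordinates,
whose coordinate sum is the CI.

## Synthetic data

The generators are pure functions of (config, seed) and attach the full
answer key to their output.

**Multi-study expression.** Intensities are log-normal:
value = 2^(b_g + effect + N(0, σ)) with per-gene baselines b_g ~ N(7, 1)
drawn once and shared across studies, σ = 0.25 by default. A directional
signature (default 2861 genes, signed log2 effect 2.0) is planted in both
intestinal tissues of a three-tissue normal study; the early-disease
profile (989 genes: 769 drawn from the signature with inherited
directions plus 220 outside it) is planted in every early study; each
reference-like gene is retained at the late stage independently with
probability 0.85 (gene-wise Bernoulli — the minimal mechanism matching a
set-level maintenance fraction), the non-reference component at 45/220,
plus 381 late-novel genes. Disease platforms cover planted genes always
and background genes with probability 0.9; a fifth of genes get a second,
dimmer probe to exercise the collapse rule. Default sample sizes are
n = 9 per group: within the 3–17 per-group range of the emulated study
designs and above the Mann–Whitney floor discussed earlier, which a
p < 0.001 gate makes a hard requirement (at n = 3 the pipeline would,
correctly, return empty call sets).

What passing on this generator shows — and what it does not: the model
has clean group structure, independent genes, no batch effects, no
probe-level hybridization physics, and noise that is homoscedastic on
the log scale. Recovery results on it validate the *inference chain*
(thresholding, intersection, decomposition, counting, chi-square), not
robustness to the artefacts of real array compendia.

**Ct tables.** Ct = base + shift(group, gene) + N(0, σ_rep) per technical
replicate (default 3 replicates, σ_rep = 0.3 cycles), reference gene
shift 0, optional per-sample loading offset applied to all genes. A −2
cycle shift with σ = 0 forces FC = 4 exactly.

**Dose–response.** Single-agent fa follows the median-effect equation
with Gaussian noise on log10(fa/fu). Combination points are constructed
under Loewe additivity with the dose requirement scaled by an interaction
factor s: the effect assigned to (d₁, d₂) solves
d₁/Dx₁(fa) + d₂/Dx₂(fa) = s (monotone in fa; solved by Brent's method to
machine tolerance), so the planted CI is exactly s. Default doses span
1–100 in units where the two Dm sit mid-range (20 and 30), echoing an
siRNA nM titration.

## Numerical conventions and edge cases

- Reported percentages round to one decimal, halves away from zero.
- TSV writers emit shortest round-trip float representations, so
  write-then-read is bit-exact and reruns are byte-identical.
- Correlation distances are clipped at 0 against microscopic negative
  floating-point values before linkage.
- The pipeline's config hash covers the scientific configuration but not
  the output directory, so identical analyses in different locations
  report the same hash.

## Known limitations

- No GEO/CEL ingestion or normalization: inputs are pre-normalized
  matrices in the documented TSV dialects.
- Per-study DE is uncorrected for multiplicity (see above); the package
  is built around cross-study intersection as the replication filter.
- The separation score depends on the cut, not on the full tree; two
  dendrograms with equal purity can differ in structure.
- Chou–Talalay scoring assumes both agents have invertible (m > 0)
  median-effect fits; flat or non-monotone response data is flagged
  rather than scored.
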