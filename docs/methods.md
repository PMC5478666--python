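# Methods

This note documents the models and procedures implemented in `endomethyl`,
the choices made where the design was genuinely open, and what the synthetic
testbed does and does not establish about real data.

## Signal model

Illumina-style arrays report a methylated (*m*) and unmethylated (*u*)
intensity per CpG and sample. Two derived scales are used:

- **β = m / (m + u + 100)** — the conventional methylation proportion. The
  +100 offset stabilizes the ratio at low total intensity and introduces a
  small downward bias of factor T/(T+100) at total intensity T; the
  synthetic intensities are drawn at realistic totals (log-normal, median
  e⁸ ≈ 3,000) so this bias is exercised and visible in round-trip tests.
- **M = log2((m + 1) / (u + 1))** — the log-ratio scale on which all
  hypothesis tests run, since β is heteroscedastic near its boundaries. M
  uses its own +1 offset rather than inheriting β's +100, so the log-ratio
  is not contaminated by the large offset; for intensities well above the
  offsets, M ≈ logit2(β), and a property test asserts this agreement.

**Filtering** is staged and first-hit accounted: stage 1 removes probes
flagged for SNP overlap or cross-reactivity and probes whose detection
failed in more than `max_fail_frac` (default 0.05) of samples; stage 2
removes sex-chromosome (manifest `chrX`/`chrY`) and non-CpG-context probes
(probe ids not starting with `cg`). A probe is counted once, at the first
rule that removes it, so the report always balances exactly. The
detection-failure threshold replaces iterative matrix-trimming heuristics
used by array-QC suites: a fixed thresholded rule is deterministic,
order-stable and idempotent, and the threshold is exposed in configuration.

**Scaling normalization** multiplies each sample's intensities by one scalar
so its mean total intensity equals the grand mean. Control-probe-based
scaling is not applicable (the synthetic arrays carry no control probes);
the contract that matters downstream — one scalar per sample, within-sample
m:u ratios untouched, hence M unchanged up to offsets — is the same. β is
computed from the normalized intensities; computing Δβ before normalization
is the untested alternative, and with per-sample scalars this close to 1 the
difference is far below the effect sizes of interest.

## Paired differential methylation

The design pairs one pre-receptive (LH+2) and one receptive (LH+8) sample
per subject, so inference works on per-subject differences
d = M(LH+8) − M(LH+2), with the sign convention receptive minus
pre-receptive. Pairing absorbs all subject-constant effects — including
age — which creates a tension with adjusting for age: a subject-level
covariate cannot enter a model that already eliminates subject effects. The
resolution implemented here regresses d on centered age and tests the
intercept: the intercept is the mean phase effect at the cohort's mean age,
and the age slope absorbs any age-dependent *difference* in the phase
effect. The Wilcoxon arm admits no covariate and is therefore unadjusted;
this is a documented divergence between the arms.

**Moderated t.** Per probe, OLS of d on [1, age_c] gives the intercept b₀
and residual variance s² on d = n − k df. Variances are pooled with a
scaled inverse-chi-square prior (d₀, s₀²) estimated by moment matching on
z = log s²: E[z] and Var[z] are digamma/trigamma expressions in the residual
and prior df, inverted with a Newton solve of trigamma(x) = y. When the
observed spread of z does not exceed its sampling floor, d₀ = ∞ and all
probes share s₀². The moderated statistic t̃ = b₀ / √(s̃²·c₀₀) is referenced
to d₀ + d df. Limits are exact: d₀ = 0 reproduces the ordinary t-test to
machine precision, d₀ = ∞ the fully pooled test; the pooled estimates are
cross-checked against an independent Bioconductor implementation in the test
suite.

**Wilcoxon signed-rank.** Zeros are dropped (the original convention), ties
in |d| get midranks. With no ties/zeros and n ≤ 25 the exact two-sided p is
computed from the null distribution of W built by the subset-sum generating
polynomial ∏ᵣ(1 + xʳ), as p = 2·min(P(W ≤ w), P(W ≥ w)) capped at 1;
otherwise the normal approximation with tie and continuity corrections is
used. The exact path is verified against full 2ⁿ sign enumeration.

**Segment test.** Tested CpGs are partitioned into segments positionally:
a new segment starts at a chromosome change or when the gap to the previous
tested CpG exceeds `max_gap` (default 500 bp). Per-subject segment means of
d are tested with the unmoderated intercept model and the segment p is
assigned to each member. Segmentation is deliberately data-independent: an
earlier variant also broke segments where the sign of the probe-mean
difference flipped, but conditioning the segment composition on the observed
signs biases the segment mean away from zero under the null (a segment of k
same-sign probes acquires noncentrality ≈ 0.8√k) and destroys type-I error
calibration. The sign-splitting variant remains available as
`split_on_sign=True` for users who prefer the stricter within-segment
homogeneity and accept the anti-conservative site-level p-values.

**Multiplicity and consensus.** Benjamini–Hochberg runs per arm — across
sites for the moderated and Wilcoxon arms, across segments for the segment
arm (the segment q is then propagated to members). The consensus set is the
intersection of the three FDR < α calls (α default 0.05). Intersecting
methods with different operating characteristics trades sensitivity for a
much lower realized false-discovery proportion, which the recovery tests
quantify against planted truth.

## DMR calling

Significant CpGs (consensus by default, any single arm's q configurable) are
scanned per chromosome in position order. A run extends while the next
significant CpG is ≤ `max_gap` bp from the previous one *and* shares its
direction; runs of ≥ `min_cpgs` (default 3) become DMRs. "Within a 500 bp
window" is thus read as an adjacent-gap rule, which makes maximal runs of
any length well defined; the total-span reading is implemented behind
`window_rule="span"`. Direction homogeneity is required because regions are
reported as increased or decreased, never mixed. Intervening non-significant
CpGs are invisible to the scan — gaps are measured between significant CpGs.
The scanner is verified against brute-force enumeration of all maximal valid
windows on random instances. Region p-values reuse the intercept model on
per-subject region-mean differences; region q is BH across emitted DMRs.
BED6 export converts the 1-based inclusive CpG span to 0-based half-open
coordinates and scores regions as −10·log₁₀(q), capped at 1000.

## Methylation–expression correlation

Candidate pairs are consensus CpGs with |Δβ| > 0.1 (configurable) carrying
at least one gene annotation — open-sea CpGs drop out here, having none —
paired with every annotated gene present in the expression matrix (a CpG
annotated to k genes yields k pairs). Expression is CPM with library size =
per-sample total counts. Correlation is Spearman's ρ (Pearson on midranks)
between β and CPM over the samples present in both matrices, both phases
pooled (14 samples under the default design: 7 subjects × 2 phases).

Significance is permutational: the expression vector is permuted across all
samples jointly, B = 10,000 by default, and p = (1 + #{|ρ_b| ≥ |ρ|})/(B+1);
when n! ≤ B all n! orderings are enumerated instead and p is the exact
fraction. The add-one estimator keeps p ≥ 1/(B+1) and is mildly conservative
because the discrete rank statistic ties with its permuted replicates. The
free permutation scheme breaks the subject pairing; a pairing-preserving
scheme (within-subject swaps, 2ᵏ arrangements) is available as
`scheme="paired"`. Constant vectors yield ρ undefined, flagged with p = 1.
Each pair gets an independent child RNG spawned from the config seed, so
results do not depend on evaluation order.

Significant correlations are aggregated to per-(gene, region) medians (a
gene with CpGs in two regions gets two medians; singletons pass through),
and the regional summary counts tested/correlated/positive/negative per
subregion and per super-group (TSS1500, TSS200, 5′UTR, 1st exon → "5′
region"; Body, 3′UTR → gene body), with percentages printed to one decimal.

## Descriptive profiling

A CpG is consistently hypermethylated if its phase-mean β exceeds 0.8 in
both phases, hypomethylated below 0.2 in both; "consistently" is
operationalized as the phase mean over subjects (the every-sample-unanimity
reading is stricter and was not adopted). Category distributions pool CpGs
with multiple distinct subregion annotations into 'Others' and unannotated
CpGs into 'Unknown'. Two-sample Kolmogorov–Smirnov compares category
distributions; χ² goodness-of-fit compares the consensus set's category
counts against proportions of the full tested set (raising an error rather
than silently collapsing when a non-empty observed category has zero
expectation). Sample clustering is agglomerative with Euclidean distance and
average linkage over β at a probe subset — the metric/linkage are
conventional defaults, exposed as parameters — and the two-branch cut is
reported with its per-phase agreement.

## The synthetic study generator

The generator is the testbed that defines the study conditions; its defaults
are fixed once:

| parameter | default | rationale |
|---|---|---|
| subjects | 17, ages 24–35 | the paired cohort size the design emulates |
| probes | 20,000 | desk-scale stand-in for a 485k array |
| landscape weights (hypo/mid/hyper) | 0.33 / 0.48 / 0.19 | matches the observed hypo/hyper fractions at β thresholds 0.2 / 0.8 |
| frac_dmc | 0.05 | ~5% of sites truly differential |
| frac_increase | 0.845 | ~85% of true effects gain methylation in the receptive phase |
| &#124;Δβ&#124; effects | uniform 0.05–0.25 | small shifts, the regime the design targets |
| σ_m (within-subject, M scale) | 0.3 | no per-probe variance estimates are published; chosen so paired effects of Δβ ≈ 0.15 are clearly but not trivially detectable at n = 17; exposed in config |
| subject SD (M scale) | 0.3 | between-subject heterogeneity; cancels in pairing |
| DMR blocks | 30 | planted contiguous same-sign runs of 3–5 CpGs within 500 bp |
| expression sub-cohort | 7 subjects (14 samples) | the correlation set size the design emulates |
| coupling strength | Spearman 0.9 | strong planted coupling, detectable at n = 14 |
| coupling sign P(positive) | gene body 0.565, 5′ region 0.444 | region-dependent sign mix, positive couplings more common in gene bodies |

Generation is on the M scale: baseline M per probe from the tri-modal
landscape (truncated normals at ±3.5 for the hypo/hyper modes, uniform
(−1.8, 1.8) for intermediate), with mode assignment tilted by CpG-island
relation (islands preferentially hypomethylated, open sea hypermethylated)
while keeping the marginal mode fractions exactly at the configured weights.
Planted effects are specified as β-shifts and converted to M-shifts at the
probe's baseline; baselines are re-drawn into the feasible range when a
shift would leave (0, 1). Per-sample M adds a subject random effect and
Gaussian noise; intensities are emitted by splitting a log-normal total, so
the downstream β/M recomputation — including the +100 offset bias — is part
of what the tests exercise. Expression counts are Poisson around
library-scaled rates; coupled genes receive log-expression
a + sign·(M − M̄) + noise with the noise tuned via r = 2·sin(πρₛ/6) to hit
the target Spearman magnitude. A deterministic count mode (`count_noise =
False`, fixed library and rate denominator) exists so that the noise-free
strength-1 construction is exactly monotone — Poisson draws would break
exact monotonicity at any depth.

**What the generator does not emulate:** Infinium I/II probe-chemistry
differences, batch and chip effects, control probes, cell-type composition
shifts between phases (real endometrium changes stromal/epithelial/immune
proportions across the cycle, which can mimic or mask methylation change),
genomic enrichment of true effects (planted DMCs are uniform over eligible
probes, so the χ² enrichment machinery is exercised but near-null), and
realistic RNA-seq overdispersion (counts are Poisson, not negative
binomial). Passing recovery tests therefore demonstrates the correctness and
calibration of the inference pipeline under its stated model, not robustness
to these real-data complications.

## Numerical choices

- Paired-difference tests with a constant-age cohort drop the degenerate age
  column rather than failing on a singular design.
- s² = 0 probes (identical differences) are floored at 10⁻³⁰⁰ for the
  log-moment fit; moderation guarantees s̃² > 0 whenever d₀s₀² > 0.
- Permutation hit-counting uses |ρ_b| ≥ |ρ| − 10⁻¹², so exact ties in the
  discrete rank statistic count as hits (conservative, and required for the
  exhaustive mode to reproduce enumeration exactly).
- BH is statsmodels' step-up implementation; inputs are validated to [0, 1]
  and order is preserved.
- Problem sizes in the analysis drivers and validation runs (20,000 probes,
  B ≤ 10,000 permutations) were chosen as the package's desk-scale study
  conditions; all stages are vectorized across probes, so a full run
  completes in seconds.

## Known limitations

- The moderated arm assumes exchangeable variances across probes on the M
  scale; strong variance heterogeneity structured by methylation level is
  only partially absorbed by the prior.
- The segment arm's positional segmentation can dilute an isolated true
  effect inside a large segment of nulls, costing consensus sensitivity for
  singleton DMCs in dense clusters.
- Permutation p-values are exchangeability-based; the default free scheme
  ignores the paired sample structure (the paired scheme is provided but has
  coarse resolution at 7 subjects: 2⁷ = 128 arrangements).
- The β offset bias means recomputed Δβ underestimates planted Δβ by ~3% at
  the default intensity scale; truth-recovery correlations account for this
  but absolute Δβ comparisons to the planted values should not expect
  equality.
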