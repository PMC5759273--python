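# Methods

This note records the models, conventions and design choices behind
`lungbiota`, and what the synthetic validation does and does not establish.

## Data model and table preparation

An OTU table is a taxa-by-samples matrix of non-negative integer read counts
with optional greengenes-style lineages (`k__…;p__…;…;g__…`); a field that is
empty or consists only of its rank prefix counts as unclassified at that rank.
Sample metadata carries subject, anatomic site (oral / nasal / bronchial /
lung / control) and sequencing batch; controls have an empty subject id.

**Depth summaries.** Per-sample column sums; the median of an even number of
samples is the midpoint of the two central order statistics, and displayed
means/medians are rounded half away from zero while full precision is kept
internally. The bundled reference fixture (a published nine-subject COPD
airway cohort's per-sample yields) illustrates two internal inconsistencies of
published tables that the code intentionally does **not** paper over: the 36
subject rows sum to 12,667,006 although the source table's footer prints
12,667,009, and the narrative swaps the control samples' mean (~226.3) and
median (113). The column-derived values are the ones any correct computation
reproduces.

**Contaminant filtering.** A taxon is removed iff (a) it has a positive count
in at least one negative control and (b) its *pooled* relative abundance
across all subject samples exceeds the threshold (default 1%). The pooled
reading — rather than a per-sample maximum — is deterministic and matches the
reference cohort's outcome of exactly one removed taxon. The rule is
idempotent, and with no controls present it is a no-op.

**Rarefaction.** One vector hypergeometric draw per sample, without
replacement, to exactly the target depth (default 563); samples below the
depth are dropped and reported. The random stream is keyed by
`(seed, sample_id)`, so results are independent of column order and of which
other samples are present. A single rarefied data set is produced, not an
average over repeats, because downstream analyses consume one table.

**Rank aggregation.** OTUs unclassified at the requested rank are dropped and
counted; the remainder are summed by identical lineage prefix through that
rank. Reads are conserved up to the dropped taxa.

## Diversity and batch correction

Shannon entropy uses base e by default (configurable); the inverse Simpson
index is 1/Σpᵢ². Bray-Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on whatever values the
caller provides (counts or proportions). PCoA is classical scaling: Gower
double-centering of −D²/2, eigendecomposition, coordinates scaled by
√eigenvalue; negative-eigenvalue axes are dropped without Lingoes/Cailliez
correction, variance explained is relative to the sum of positive eigenvalues,
and each axis is oriented so its first non-negligible loading is positive.
PERMANOVA uses the usual within/between sum-of-squares decomposition of
squared distances and the "+1" convention (the observed statistic counts
among the permutations), so p ≥ 1/(n_permutations+1); label permutations come
from a seeded generator.

Batch correction operates on relative abundances: per taxon, a least-squares
fit of proportion ~ intercept + batch indicators (equivalently batch group
means); the corrected value is the residual plus the taxon grand mean,
clipped at zero, with columns renormalized to sum 1. **Limitation:** this
additive correction removes a batch shift that is common across samples, and
it demonstrably lowers the overall mean between-batch Bray-Curtis distance on
simulated cohorts; but a batch bias that is *multiplicative* in composition
is site-dependent in proportion space (a site-by-batch interaction), which a
single batch term cannot remove and may even redistribute across sites. This
is one reason the bronchus–lung similarity test below stratifies by batch
rather than relying on the correction.

Post-hoc site comparisons of per-sample alpha diversity use paired two-sided
*t* tests over subjects present at both sites, with Holm step-down adjustment
across all site pairs; pairs with fewer than two complete subjects are
reported as not testable, and identically-zero paired differences report
p = 1.

## Batch-stratified permutation test

For subjects having both sites, `cross[s, t]` is the Bray-Curtis distance
between subject s's bronchial sample and subject t's lung sample; the
statistic is the diagonal mean (within-subject distances). Null statistics
come from permuting subjects *within* each sequencing batch independently;
with batch sizes 3 and 5 the composite group has 720 elements and is
enumerated exhaustively (the identity included exactly once). Because small
distances mean similarity, the p-value is the left-tail fraction
#{T(σ) ≤ T(identity)}/K, ties counting toward the numerator; the identity
guarantees p ≥ 1/K, and p attains 1/K exactly when the identity strictly
minimizes the statistic. Above a configurable group-size cap the test samples
permutations uniformly (Monte-Carlo mode) with the identity forced into the
sample. Observed and permuted statistics are accumulated through the same
per-batch partial sums, so the identity permutation ties the observed value
bit-for-bit and the tie-counting convention is exact in floating point.

## Neutral-model immigration fit

Under the neutral model, a taxon with relative abundance p in the source
community has equilibrium lung relative abundance x ~ Beta(Nmp, Nm(1−p)),
with N the average lung read total and m the immigration probability. Its
predicted detection probability is P(x > d) = 1 − I_d(Nmp, Nm(1−p)) with
d = 1/N the detection limit and I the regularized incomplete beta function
(boundary conventions: p = 0 → 0, p = 1 → 1). Inputs are p̂ᵢ = the
across-sample mean of within-sample relative abundance at the source site and
fᵢ = the fraction of lung samples detecting the taxon. m̂ minimizes
Σᵢ (Pᵢ(m) − fᵢ)² over m ∈ (0, 1], by a 2000-point grid followed by bounded
scalar refinement between the best point's grid neighbours (tolerance 1e-6);
grid ties resolve toward smaller m because the SSE can be flat when detection
frequencies are coarse (n = 8–9 subjects). Taxa absent from the source are
excluded from the objective (their contribution is constant in m) and
reported as `absent_in_source`.

Classification bands are the central `confidence` (default 95%) interval of
Binomial(n, Pᵢ(m̂)) scaled by 1/n — exact binomial quantiles by default, with
a Wilson score option since the literature rarely states its construction.
Frequencies inside the band (inclusive) are `consistent`, otherwise `above`
or `below`. No confidence interval is attempted for m̂ itself; at these
cohort sizes it is not reliably estimable. The fit runs per source site
independently (oral, nasal, bronchial → lung), at OTU granularity by default
with a genus-aggregation option.

The pipeline fits on the rarefied table by default (a `filtered` option uses
the unrarefied filtered table); the report records which was used.

## Synthetic cohorts

The generator emulates the study design: n_subjects (default 9) × four sites,
six contaminant-only controls, sequencing batches of 3 and 6 subjects, and
log-normal site depths ordered oral (~8×10⁵ reads) ≈ nasal (~3.5×10⁵) ≫
bronchial ≈ lung (~1.5×10³ = `reads_N`). Subject depths are floored at 600
reads — every retained specimen in the reference cohort exceeded ~580 — except
one designated lung specimen (subject 8 by default) drawn at 20–100 reads so
that rarefaction reproducibly drops it, leaving 8 paired subjects and a
720-element permutation group. Taxa form guilds (oral 160, nasal 140, shared
40, lung-resident 140, contaminant 20 by default; 500 total). Oral and nasal
communities are subject-level Dirichlet draws around shared guild profiles
with a log-normal rank-abundance curve; the bronchial community is the
mixture w_oral·oral + w_nasal·nasal + w_unknown·unknown with weights
0.21/0.09/0.70 (jittered per subject), where "unknown" is a subject-specific
Dirichlet draw over the lung-resident guild — a concrete generative stand-in
for the large source fraction that source-attribution methods leave
unexplained. The first contaminant-guild taxon is carried into every subject
sample at 2%, so the contaminant filter has exactly one taxon to remove. A
measurement-stage batch bias multiplies a random 10% of taxa by e^0.25 in
batch-2 samples.

**Lung generation and discretization.** The lung community is drawn from the
subject's bronchial profile: one Beta(Nmp, Nm(1−p)) draw per source-present
taxon, renormalized (independent marginal betas do not jointly sum to 1;
renormalization preserves each taxon's marginal mean), then discretized to
integer counts by flooring N·x and assigning the remainder reads among
already-detected taxa. In the Wright-Fisher diffusion the beta is the
stationary law of the community fraction itself, so counts are N·x rounded —
*not* an additional multinomial read-sampling layer, which would double-count
sampling noise: read-based detection E[1−(1−x)ᴺ] then systematically exceeds
the estimator's threshold model P(x > 1/N) and inflates m̂ by +0.2 or more at
realistic N. The floor-based discretization makes detection (count ≥ 1)
coincide exactly with the estimator's detection limit.

**Calibration of heterogeneity.** The Dirichlet concentration (default
15,000) and mixing-weight jitter (sd 0.015) were fixed from a
pre-implementation sensitivity analysis so that the pooled-source moment fit
is approximately unbiased, as the estimator assumes near-common source
profiles across subjects. Three sensitivities of the estimator, measured
during that analysis and worth knowing when applying it to real data:

1. *Depth heterogeneity.* Fitting with a single N when lung depths vary
   log-normally (sd ≈ 0.5) biases m̂ downward by 0.15–0.27; the recovery
   harness therefore holds lung depth at `reads_N`, matching the method's
   single-N assumption.
2. *Rarefaction before fitting.* Hypergeometric subsampling to a common
   depth smooths the detection threshold and biased m̂ upward by ≈ +0.4 in
   simulation; recovery is validated on the unrarefied equal-depth lung
   table. (The pipeline still follows the conventional rarefied route for
   its default report; its m̂ values inherit this caveat.)
3. *Source heterogeneity.* Strong between-subject source variation
   (Dirichlet concentration ≲ 1000 at these richness levels) biases m̂
   downward, because many subjects then carry effectively zero source
   abundance for rare taxa. Real cohorts have larger inter-subject
   variability than the generator's default, so real-data m̂ values should
   be read as lower bounds in this respect.

Consequently, passing recovery tests establish that the estimator and its
implementation are correct *under the model's own assumptions* at the studied
sizes; they do not certify accuracy under strong depth or source
heterogeneity, which the list above quantifies.

## Validation problem sizes

Parameter recovery uses 50-subject, 500-taxon cohorts (median |m̂ − m| ≤ 0.05
over seeded replicates at m ∈ {0.3, 0.6, 0.9}; ≤ 0.1 at the study's n = 9).
Type-I error of the stratified test is measured over 200 null cohorts (lung
samples permuted across subjects within batch before testing), with the
rejection rate at α = 0.05 required to sit inside the binomial 95% band.
Detection probabilities are checked against adaptive quadrature of the beta
density at 100 random parameter settings to 1e-8. PCoA must reproduce planar
configurations' distances to 1e-9, and Bray-Curtis must match a double-loop
evaluation to 1e-12.

## Pipeline conventions

Stage order: load/simulate → depth summaries → contaminant removal →
rarefaction (controls leave the analysis here — they exist to drive the
filter) → alpha diversity + Holm pairwise → Bray-Curtis → batch correction →
PCoA + PERMANOVA (site, then subject on the same corrected matrix) →
stratified bronchus–lung permutation test → neutral fits per source.
Per-stage seeds derive deterministically from the configured seed and are
recorded in the stage log; a report serialized without timings is
byte-identical across reruns of the same configuration. The report validates
against the JSON schema shipped at `src/lungbiota/schemas/`. A failing stage
aborts with its name while preserving artifacts already written.
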