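# Methods

`exochip` models the data flow of a large jointly-called exome genotyping
array project: two-channel intensities for a few hundred thousand mostly
rare coding variants are pooled across all samples, clustered per variant,
called with a quality score, filtered by a fixed catalogue of SNP- and
sample-level criteria, and finally evaluated against sequencing-derived
genotypes with contingency-table statistics. This note records the models,
the defaults, and the choices made where the design was genuinely open.

## Polar intensity model

A genotyping assay reports two channel intensities (x, y) per sample and
variant, one per allele. All clustering happens in polar coordinates

    theta = (2/pi) * arctan2(y, x)   in [0, 1],     R = x + y,

where theta approximates the allelic ratio (0 = pure A signal, 1 = pure B)
and R the total signal. The transform is undefined at the origin; a cell
with x = y = 0 is a failed assay and is treated as an intrinsic no-call
(score 0) that never enters cluster fitting.

## Cluster model and calling

Per variant, genotype clusters are a 1-D Gaussian mixture on theta with at
most `expected_clusters` components: 3 for diploid variants, 2 for
hemizygous systems (Y, mitochondrial), matching the practice of setting the
expected cluster number to 2 for those chips' Y and MT assays. Fitting is a
deterministic EM (no random initialisation): starts are data quantiles, the
canonical cluster positions 0.05 / 0.50 / 0.95, and wide (±sigma) and tight
(±sigma/2) splits of the broadest component of the (k−1)-component fit; the
best likelihood wins. Component standard deviations are floored at 0.01 so
single-member clusters (a lone rare heterozygote) remain well-posed.

The component count is selected by BIC with two modifications, both aimed
at the rare-variant regime that motivates joint calling:

* **Island floor and coverage.** Occupied theta regions separated by an
  empty gap wider than 0.15 are conclusive evidence of distinct clusters
  (genotype clusters sit ≥ ~0.4 apart; within-cluster spread is a few
  hundredths). The number of such islands is a hard lower bound on k, and
  a candidate fit whose component means leave any island empty loses to
  the best island-covering fit of the same k. Without these rules, a
  penalized likelihood absorbs a single far-away rare-genotype point into
  a broad component — or spends a forced component on shape quirks of the
  dominant cluster while two separated carrier islands share one — and the
  carriers are miscalled, exactly the failure joint calling exists to
  prevent. Island centroids also serve as an additional EM start.
* **Doubled penalty beyond the islands.** An extra component *within* one
  occupied region must clear twice the BIC penalty. Genuine sub-clusters
  (a narrow cluster on the flank of a wide one) gain hundreds of
  log-likelihood units and pass easily; mild skew from boundary compression
  of theta gains ~10–20 and is rejected. This keeps monomorphic variants
  from being spuriously split into two classes.

Components map to genotype classes AA < AB < BB by theta order when the fit
is full; degenerate fits (fewer clusters than expected) take the class
subset whose canonical centers 0.05 / 0.50 / 0.95 are nearest, ties broken
toward the more common class (AA).

Each call's quality score combines a posterior ratio with a distance decay:

    s     = 1 − posterior(second-best class) / posterior(best class)
    d     = min over classes of |theta − theta_mean| / theta_dev
    score = s                     if d ≤ 3
          = s · exp(−(d − 3))     otherwise

A call is missing (XX) exactly when score < the no-call threshold (default
0.15) or when the variant's cluster record is zeroed. The score is an
analogue of a vendor call-quality score: the threshold semantics carry
over, the score *values* are not claimed comparable to any proprietary
score.

Joint calling is two-pass: pass 1 fits on all samples and computes
provisional per-sample call rates; pass 2 refits each variant on samples
with provisional call rate > 0.99 (falling back to all samples if the
restricted set is too small) and calls everyone from the refit models. The
two-pass structure resolves the circularity in "samples with call rates
above 99% define the clusters" — a call rate requires prior calls. Females
contribute nothing to, and receive no calls for, Y variants.

Cluster parameters serialize to a versioned TSV (`repr`-precision decimals)
whose write/read round trip reproduces calls bit-identically; QC zeroes out
failing variants in this file so re-applied calling forces them missing.

## No-call rescue (zCall-style)

The rescue stage re-examines no-calls in channel space. Per variant,
thresholds sit z standard deviations (default z = 7) above the homozygote
clusters' noise channels — t_y from the AA cluster's y signal, t_x from the
BB cluster's x signal — estimated from called homozygotes, with
cross-variant linear regression imputing the statistics of a homozygote
class that has no calls. An XX call is reassigned by quadrant (high-x/low-y
→ AA, high/high → AB, low/high → BB); points below both thresholds stay
missing and existing calls are never touched, so missingness can only fall
and discordance can only rise or stay — the directional signature a rescue
stage shows against a sequence comparator. This is a simplified
reimplementation of the published zCall idea, used as a comparator stage,
not a faithful port.

## SNP and sample statistics

Statistics are computed from called genotypes; for Y variants, females are
excluded from every denominator. Allele counts respect ploidy (one allele
per male on X, one per sample on Y/MT). Conventions fixed by test vectors:

* per-class theta mean/dev are the member points' mean and population
  standard deviation;
* `cluster_sep` = min over adjacent called classes of
  gap / (gap + dev1 + dev2), 1.0 when fewer than two classes are called;
* `het_excess` = (AB frequency − e)/e with e = 2p(1−p) from the called
  allele frequency; 0 when e = 0 without heterozygotes, capped at 10 when
  e = 0 with heterozygotes. For haploid classes (Y, MT) the Hardy–Weinberg
  expectation is meaningless and the statistic is reported absent —
  computing it literally would auto-exclude every clean MT variant via the
  het-deficit rule;
* `p10gc` is the lower 10th-percentile order statistic of a sample's
  per-call scores, no-calls included (100 scores with the lowest ten at
  0.10 give exactly 0.10);
* minor allele count rounds 2·n_called·maf to the nearest integer to
  absorb floating error (diploid variants; sex-aware counts are used
  directly elsewhere).

Replicate errors count pairs with two unequal non-missing calls (a missing
call is not discordance). Mendelian checks are autosomal only: the
parent–parent–child test requires both parents called; with one informative
parent only opposite homozygotes are impossible.

## QC criteria

The review tier flags variants for inspection (all X/Y/XY/MT variants,
call frequency in [0.95, 0.99], cluster separation < 0.4, AB frequency
> 0.6, AB R mean < 0.2, het excess > 0.1 or < −0.9, class theta means in
suspicious bands, homozygote theta deviations > 0.025, AB theta deviation
≥ 0.07, structural combinations such as AB frequency = 0 with MAF > 0,
replicate/Mendelian inconsistencies, and user-supplied cautious-site and
removed-in-v1.1 lists) and never excludes by itself. The exclusion tier
removes variants outright: call frequency < 0.95 (waived for Y), cluster
separation < 0.4, AB frequency > 0.6, AB R mean < 0.2, het excess > 0.1 or
< −0.9, AA theta mean > 0.3, BB theta mean < 0.7, AB theta mean < 0.2 or
> 0.8, homozygote theta deviations > 0.06, AB theta deviation ≥ 0.07
(inclusive, unlike the strict homozygote bounds), and batch effects.
Samples are excluded when p10GC < 0.38 or call rate < 0.97, both strict.

"Obvious batch effects" is a visual judgement in laboratory practice; here
it is operationalized as chi-square tests of no-call counts and of allele
counts across batches, the per-variant p-value Bonferroni-combined over the
two tests and Bonferroni-screened across variants at a configurable
family-wise level (default 0.05). Manual recluster review is out of scope;
the flag export supports external review instead.

## Concordance evaluation

Calls and a truth set are cross-tabulated into a 4×4 table over
AA/AB/BB/XX (rows = truth, columns = test), optionally after per-variant
allele orientation (flipped variants swap AA↔BB; unresolvable variants are
dropped with a logged reason). The summary decomposition counts a pair as
*missing* if either side is XX (the XX/XX cell once), *concordant* if equal
and non-missing, *discordant* otherwise; the three percentages sum to 100
exactly. Reporting rounds half-up to two decimals.

Because rare-variant panels are dominated by the common homozygote,
percent concordance is nearly saturated by construction; the uncertainty
coefficient (Theil's U) measures association on the entropy scale instead.
With I the table's mutual information, U(X|Y) = I/H(X). Natural logarithms
are used internally; the value is base-invariant. Direction and
missing-class handling are exposed as parameters because no single
convention reproduces the three published reference values exactly from
the printed tables; the closest (within ~0.004) is U(chip|truth) with the
missing class included, which is the default. Under that default — and the
symmetric form — the three shipped reference matrices order vendor-file <
rescue < joint calling; conventions that drop the XX class (or condition
the other way) hide the vendor file's missingness and do not rank the
strategies, so the package reports all conventions side by side.

Per-MAC-bin concordance restricts to variants with a given truth minor
allele count (singletons, doubletons, tripletons by default) and uses
non-missing pairs in the denominator; empty bins are reported absent, not
zero.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes —
not any particular instrument. Defaults:

* **MAF spectrum**: monomorphic 4.5%, (0, 0.001] 58.8%, (0.001, 0.005]
  15.3%, (0.005, 0.01] 4.3%, (0.01, 0.05] 5.7%, (0.05, 0.1] 1.8%,
  (0.1, 0.2] 2.4%, (0.2, 0.5] 7.3% — the published all-race spectrum of an
  exome array, normalized to sum to exactly 1 (the printed percentages
  carry 0.1% rounding error). A bin is chosen per variant by its
  proportion, then the MAF uniformly within the bin.
* **Cluster geometry**: theta centers 0.05 / 0.50 / 0.95 with ±0.01
  per-variant jitter, theta deviation 0.02, R means 1.0 / 1.1 / 1.0 with
  deviation 0.1 — clean variants pass every exclusion criterion with wide
  margin. Theta is reflected at the [0, 1] boundaries (channel intensities
  are non-negative, so boundary clusters compress rather than pile up a
  point mass).
* **Genotypes**: Hardy–Weinberg draws at the generating MAF (B minor);
  trio children by Mendelian transmission; replicate samples copy their
  source's truth but receive independent intensity draws; X males are
  hemizygous (intensities at the homozygote clusters), Y and MT are
  two-cluster systems, female Y truth is missing and female Y intensities
  are background noise.
* **Low-quality samples**: theta and R deviations multiplied by 4 (the
  noise multiplier is configurable; 4 places such samples' p10GC and call
  rate far below the 0.38 / 0.97 sample bounds while leaving clean samples
  untouched).
* **Batches**: samples are assigned to 4 batches; only the batch archetype
  shifts theta (+0.25) in batch 0. The magnitude is not taken from any
  publication — real batch review was visual — and is set so the planted
  effect produces differential calls/missingness the chi-square screen
  detects with ≥95% power at 1,000 samples.
* **Sequence comparator**: truth with independent missingness (default
  0.001, the order of the sequence-side XX margin in the published
  comparison) and independent adjacent-class errors (default 0.0005, half
  the published 0.09% discordance, reflecting the observation that
  mismatches split roughly evenly between chip and sequence):
  heterozygotes err to the common homozygote — the dominant real
  misclassification — and homozygotes err to the heterozygote.

**Failing-SNP archetypes** plant one construction per exclusion criterion;
each is built so its *matched* statistic violates its bound (verified
criterion-by-criterion on clean 1,000-sample simulations, ≥95% of instances
per archetype; exclusion by *some* criterion is 100% in all tested seeds).
Archetype MAFs are fixed at common values (0.30–0.45) so every genotype
class is populated. Two constructions deserve comment:

* *low call frequency*: a 10% sample fraction yields no signal (x = y = 0,
  a failed assay). A diffuse-noise construction cannot trip this criterion
  under a theta-only score: the mixture fit absorbs diffuse points into a
  widened component whose 3-sigma window then covers them.
* *compressed clusters*: a wide heterozygote cluster (deviation 0.20) with
  the BB cluster on its flank (centers 0.05 / 0.52 / 0.60, MAF 0.45).
  Symmetric equal-variance compression cannot push the member-point
  separation statistic below 0.4 — hard assignment truncates each class's
  spread, flooring the statistic near 0.55 — while the wide-flank geometry
  lands it at ~0.3.

What the generator does **not** emulate: linkage disequilibrium, population
structure or race strata, vendor normalization from raw image data, probe
sequence effects, and genuine cluster-shape pathology beyond the archetype
catalogue. Passing tests therefore demonstrate that the pipeline's logic is
correct under its stated model, not that thresholds are optimal for any
particular real instrument or cohort.

## Problem sizes and determinism

The test suite and the acceptance script use 500 samples × 5,000 variants
for clean calling accuracy and 1,000 × 5,000 with 2% of variants per
archetype for QC power — sizes at which every acceptance-grade quantity is
stable to well inside its tolerance while a full run stays within a few
minutes on one CPU. All randomness flows from a single integer seed through
`numpy.random.default_rng`; fitting is deterministic by construction, so
identical seeds give bit-identical artifacts.

## Known limitations

* The caller is an open analogue, not a reimplementation, of proprietary
  vendor clustering; thresholds retained from published practice (0.15 no
  call, 0.38 p10GC) are applied to the analogue score and shown adequate on
  simulation only.
* The 1-D theta mixture ignores R in scoring (R enters only the AB-R-mean
  statistic and the rescue stage); dim-but-well-separated clusters
  therefore call with high scores.
* Mendelian checks cover autosomes only; X-specific inheritance rules are
  not implemented.
* The uncertainty-coefficient convention used by the original reports is
  not recoverable from the printed tables; all conventions are reported and
  the default is the closest match, ~0.003–0.004 off.
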