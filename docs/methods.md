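# Methods

## Model

Genotypes are allele counts g_ij ∈ {0, 1, 2} of a fixed counted allele,
with an explicit missing marker. A sample is a point on the K-simplex of
temporal components and its genotypes follow the binomial admixture model
g_ij ~ Binomial(2, f_ij), f_ij = Σ_k q_ik p_kj. The log-likelihood sums
g·ln f + (2−g)·ln(1−f) over non-missing cells only: missing data are
dropped from every sum, never imputed. Pseudo-haploid calls ({0, 2}) are
accepted as given without special casing.

Both fitting modes use EM. The responsibilities split each observed allele
between components in proportion to q_ik·p_kj (counted allele) and
q_ik·(1−p_kj) (other allele); Q and P updates both derive from the same
responsibilities, so the likelihood is non-decreasing on every step — the
property the tests assert directly, and the reason EM was chosen over a
faster quasi-Newton scheme. P is clamped to [1e-6, 1−1e-6]; without the
clamp a genotype sampled outside a component's support sends the
likelihood to −∞. Unsupervised runs initialise Q from a seeded flat
Dirichlet and P from per-SNP observed frequencies with uniform jitter.
Supervised runs pin labelled reference rows to unit vectors and initialise
P from their empirical frequencies; unlabelled rows start at the uniform
profile 1/K. That symmetric start matters: given (near-)fixed P the
per-sample subproblem is concave, so supervised projections are exactly
equivariant under component-label permutation and invariant to SNP and
sample order. By default the P update in supervised mode uses labelled and
unlabelled responsibilities (full EM); a frequencies-from-labels-only mode
is available and near-identical with 15 references per component.
Convergence: relative log-likelihood change below 1e-6, capped at 500
(unsupervised) / 300 (supervised) iterations; non-convergence returns the
best state flagged, not an exception.

## Component curation

The paper-style selection of temporal components is visual; here it is a
scored, auditable procedure:

1. Unsupervised EM with K = 8 on a seeded random subsample (default 300
   ancient + 250 modern samples — discovery does not need the full
   cohort and the subsample keeps runtime linear).
2. Each Q column is classed modern/ancient by ranking its enrichment in
   modern samples (mean loading in modern over mean loading in modern +
   ancient); the top-3 enriched columns are the modern candidates. A
   weighted-mean-date threshold proved unreliable because modern
   components also load on the youngest ancient samples.
3. Each column gets a temporality score: |Spearman ρ| between
   per-500-year-bin mean fraction and bin index (bins with ≥ 5 samples,
   ≥ 3 bins required), plus a geography diagnostic — the between-country
   share of the component's variance inside its peak bin. Defaults:
   ρ ≥ 0.5 passes, geography ratio ≤ 0.5 passes. Near-duplicate columns
   (|correlation| > 0.95) drop the lower-scoring member. A manual-override
   list of column indices exists for curations that stay judgement-based.
4. 15 synthetic reference genomes per selected component are drawn
   Binomial(2, p_kj), no missingness.
5. The whole cohort is projected against the references (supervised EM);
   the refined P of that fit is the component frequency matrix used
   downstream.
6. Ancient components receive epochs: the weighted [5th, 95th] percentile
   interval of sample dates, weights being the samples' component
   fractions, snapped outward to 500-year bin edges. The 0.90 mass makes
   epochs robust to stray weights; it is configurable. Components are
   then ordered ancient-oldest → youngest → modern; "first ancient
   component" downstream always means the oldest. Modern components carry
   the nominal epoch [500, 0].

All weighted and unweighted percentiles in the package (epochs, family
rule, noise band) use linear interpolation, for cross-implementation
reproducibility.

## Time-informative markers

Per SNP, a 21-point series on bin centers 10,000 … 0 BP (step 500): each
bin's value is the mean p_kj over ancient components whose epoch covers
the bin center (overlaps average); uncovered bins carry the nearest
covered value and are flagged. The series is smoothed by a centered moving
average (window 3, truncating at the edges; window 1 is the identity).
Classification finds, per direction, the longest run of consecutive steps
non-decreasing (or non-increasing) within tolerance 1e-3. A run qualifies
if it spans ≥ 6 steps (3,000 years) and its endpoint amplitude is
≥ 0.05; a qualifying run covering all 20 steps is global_increasing /
global_decreasing, otherwise local; everything else is none. Ties between
directions break by larger amplitude, then earlier start.

The 3,000-year span is the method's defining rule. The amplitude floor and
smoothing window are this package's choices (the source procedure states
neither): without an amplitude floor, numerically flat monotone drifts
flood the TIM set. Sign-flip equivariance (classifying 1−series swaps the
directions) holds exactly and is property-tested. A seeded equal-sized
non-TIM sample provides the null marker panel.

## Dating model

**Preprocessing.** Three filters with a removal ledger naming each rule:
(i) ancient samples older than 10,000 BP; (ii) ancient samples whose
dating method is neither direct radiocarbon nor archaeological context
(configurable map; unmappable method strings become "other" at parse time
and are removed here, not at parsing); (iii) features z-scored over the
remaining *ancient* samples (population variance; zero-variance features
score z = 0) and samples with any |z| ≥ 3 AND date SD > 400 years removed.
The conjunction is the default reading; a disjunction flag exists. Modern
samples are never z-filtered — their feature distribution would distort
the statistics, and the paper-scale removals are ancient-only. Skewness of
the ancient date distribution is reported before/after as a curation
audit. Note the z-filter is inert below ~11 ancient samples: with
population variance, max attainable |z| is (n−1)/√n.

**Features.** Ten, fixed order: [c1', c2..c5, m1..m3, f_mean, f_dev] with
f_mean the mean of the five ancient fractions, f_dev = |μ̂(c1) − c1|, and
c1' = c1 + 3·f_dev replacing c1. μ̂(c1) is computed once in fit mode
(training cohort) and reused verbatim in apply mode; the reading that the
ten features are the eight components with c1 substituted plus the two
derived columns is fixed here. The pipeline fits μ̂ on the training split
only, so perturbing held-out samples cannot change any training artifact
(property-tested); the z-filter in preprocessing runs on the pre-split
cohort, as a curation step rather than a model parameter.

**Split.** Ancient samples stratify by (500-year date bin × country),
modern by country; single-sample strata go to training only. Unseen
fractions are allocated across strata by largest remainder, so the
realised unseen count matches round(0.15·n) instead of accumulating
per-stratum rounding error; ancient and modern unseen sets are drawn
separately and merged. Validation (10% of the 85%) is drawn from the
multi-sample remainder, and training is reshuffled, seeded.

**Training.** 10-fold cross-validation fits ten replicas of a random
forest (≤ 20 trees; other hyperparameters follow scikit-learn defaults,
pinned through config) and retains each replica's held-fold median
absolute error. The final model is a seeded-random replica — mirroring the
method's stated choice — with best_validation available because picking at
random is statistically odd. Forest predictions average leaf means, so
they cannot leave the training date range; dates are YBP floats
throughout, no calendar conversion.

**Uncertainty.** Per unseen sample: resample 90% of the training set
without replacement, retrain, date — 10 times; report mean, SD (ddof 1),
SEM = SD/√10, normal 95% CI. All repeat seeds derive from one master seed.

## Evaluation and robustness

Accuracy per sample is |predicted − mean published date| in years;
reports carry the median, 75th percentile, fraction over 1,000 years, and
a 500-year-bin breakdown.

**Families.** For families larger than two, predictions outside the
family's [30th, 70th] percentile band move to the family median. The
one-pass rule is not idempotent (e.g. [0, 4, 10, 20] changes again on a
second pass because the percentile band tightens around the inserted
medians), so the implementation iterates the rule to its fixed point —
converging in at most family-size passes, usually one. This makes the
operation idempotent, as the contract requires, and replacements only move
inward, so the within-family spread never grows. The band is taken over
the family's own predictions; the alternative reading (percentiles of the
whole-cohort median) is self-contradictory.

**Noise injection.** Within a seeded fraction of samples, cells inside the
central 90% band of their component's distribution (5th–95th percentile;
"below the 90th" switchable) are eligible; exactly round(level ×
n_eligible) cells per sample shift by ±U[0, 1], clipped to [0, 1] by
default, never renormalised — the model consumes raw features.

**Leave-window-out / leave-geo-cluster-out.** Each 500-year (or
1,000-year) age window is dropped from training and its samples dated;
empty windows are skipped with a warning. Geographic holdout K-means
clusters (lat, lon) under seven published (clusters, folds)
configurations, dates each held-out cluster from the rest, then groups
samples by coordinates rounded to one decimal; the median of group mean
accuracies is reported. The fixed published group count is dataset
specific, so the rounded grid makes the group count emergent while keeping
the procedure identical.

**Controls.** The random-matrix control runs uniform [0, 100] features
through the identical train/predict cycle — the no-signal floor. The PCA
control mean-imputes missing genotypes from the modern panel, takes the
top 10 modern-defined PCs by SVD, and projects ancient samples with the
modern centering; its output records the known leakage caveat of
sample-derived axes. MAF trajectories report per-bin minor-allele
frequency with binomial SE, a NaN-aware centered moving average (empty
bins stay gaps), and a count-weighted combined curve.

## Synthetic cohorts

The generator plants exactly the structure the method exploits and
nothing else. Defaults are the study conditions used throughout the tests
and the acceptance script: 800 samples × 3,000 SNPs, 5 ancient components
on 2,000-year epochs tiling [10,000, 0] BP plus 3 modern components, 25%
modern samples fixed at 10 BP, ancient dates uniform on [200, 9,800] with
a 2% tail beyond 10,000 BP (so the age filter has work), 30% ancient
genotype missingness, 10 families of 2–5 members, 8 countries with
coordinate centers, narrow/wide date-SD mixture (20–100 vs 300–900 years,
20% wide — giving the SD > 400 filter genuine outliers), 5% unusable
dating-method labels, seed 1.

Trend SNPs (default 20%) get frequencies linear in the component's epoch
midpoint with amplitude U[0.1, 0.4] and random direction, so the
oldest-vs-youngest difference equals the drawn amplitude; non-trend SNPs
share a base frequency U[0.05, 0.95] across components plus ±0.02 jitter;
all clipped to [0.01, 0.99]. Samples mix components with a Gaussian
kernel on |date − epoch midpoint| (bandwidth 1,500 years) so profiles
turn over smoothly in time rather than switching at epoch boundaries;
modern components dominate below ~500 BP. Families share the founder's
date and mixing weights with genotypes independently resampled —
relatedness is temporal, not duplicated data — and a copy mode duplicates
the founder row for the biased-duplicate robustness analysis. Country is
drawn independently of date, so geography is not confounded with time by
construction, and the geographic holdout measures reliance on neighbours
rather than a planted signal.

What the generator does **not** model: linkage disequilibrium, coalescent
genealogies, selection dynamics, ascertainment bias, damage patterns, or
any real-data frequency spectrum. Passing tests therefore demonstrate
that the pipeline recovers the frequency-over-time structure it assumes;
they do not certify accuracy on real ancient-DNA panels, where the
temporal signal may be weaker, confounded with ancestry, or absent.

## Problem sizes and numerical choices

Discovery subsamples 550 samples; the full pipeline on the default cohort
runs in about two minutes on one CPU, and the tests reuse one calibrated
pipeline across the end-to-end checks. Tolerances: EM 1e-6 relative;
simplex validation 1e-5; trend tolerance 1e-3; profile sums asserted to
1e-6. Degenerate inputs are contracts, not crashes: all-missing samples
are named in errors, empty survivor sets and uncovered time axes raise,
empty windows skip with a warning, and an empty dating input returns an
empty table.

## Known limitations

The date range is bounded by the training span — forests cannot
extrapolate, which is also why held-out extreme time windows date worst.
Component discovery is stochastic; a different seed can find a different
(rotated) component basis, though downstream dating is insensitive to
this. The temporality score replaces an irreducibly manual curation with
one reasonable formalisation; its thresholds (0.5/0.5) are defaults, not
dogma. Binary PLINK, VCF ingestion, and functional TIM annotation are out
of scope.
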