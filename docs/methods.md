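# Methods

This note documents the models, parameter choices and numerical
conventions behind `gutqs`, and what its synthetic validation does and
does not demonstrate.

## Diversity on rarefied profiles

Taxonomic profiles arrive as percent relative abundances per lineage
(MetaPhlAn dialect). Species-level percentages are converted to
approximate absolute counts by multiplying with the sample's total
read count, rounding half-away-from-zero. Samples are then rarefied —
uniform subsampling without replacement, implemented exactly via the
multivariate hypergeometric distribution — to a common depth, 50,000
reads by default; samples below the depth are dropped with a logged
warning rather than an error, mirroring common practice.

Alpha diversity is observed species (count of non-zero species) and
Shannon entropy. The Shannon log base is 2 by default and
configurable; the convention follows the QIIME-style toolchain the
profiles come from. Beta diversity is Bray–Curtis on rarefied counts.
PCoA applies Gower double-centering (B = −½ J D² J) followed by a
symmetric eigendecomposition; axes are ordered by eigenvalue, negative
eigenvalues are reported but excluded from the explained-fraction
denominator, and no Cailliez correction is applied by default.

One-way PERMANOVA uses Anderson's pseudo-F from distance-based sums of
squares. The permutation p-value includes the observed labelling in
both numerator and denominator, p = (1 + #{F\* ≥ F}) / (1 + N), so
p ≥ 1/(N+1) and is never zero. With N permutations the p-value is
discrete on multiples of 1/(N+1); the size-α decision rule is p ≤ α
(with N = 99 and α = 0.05 this has exact size 0.05, where the strict
inequality would give 0.04). Default N = 9,999.

## Biomarker discovery (LDA effect size)

Two stages, following the LEfSe design restricted to plain class
labels (the subclass Wilcoxon stage is omitted because only
IBD vs non-IBD labels exist here):

1. Per-feature Kruskal–Wallis with tie correction; keep p < α
   (default 0.05). A feature constant across all samples is assigned
   p = 1.
2. Samples are scaled to sum 10⁶. For each of 30 bootstraps (a 2/3
   subsample per class, resampled if a class would drop below 2), a
   one-dimensional Fisher discriminant w is fitted on the candidate
   features with a ridge-regularised pooled covariance
   (λ = 10⁻⁶ · mean diagonal), w normalised to unit length. The
   per-feature effect is ½(|w_j Δ_j| + |Δ_j|), with Δ_j the class-mean
   difference of feature j in the bootstrap; the reported score is
   log₁₀(max(mean effect, 1)).

Species with score > 2 are discriminating, sorted by descending score
with lexicographic tie-break. The bootstrap subsampling is made
order-invariant by canonicalising samples to sorted-id order before
drawing. The exact internals of the reference implementation are
under-documented, so this formula is fixed and validated by planted-
marker recovery simulations rather than by numeric identity to the
reference tool.

A property of this scale-plus-threshold convention worth knowing: the
score measures the *absolute* abundance shift on the 10⁶ scale, so an
abundant species that squeaks past the screen by chance will usually
also clear score 2, while a rare species never can. Control of false
discoveries therefore rests on the screen for abundant species and on
the score threshold for rare ones.

## Dysbiosis classifier

The top four discriminating species (by score) form the marker panel.
A marker enriched in the IBD class is "dysbiosis-enriched", otherwise
"dysbiosis-depleted". Each marker's relative-abundance threshold is
chosen from a ROC curve of its abundance against the IBD / non-IBD
phenotype labels — the only labels available before dysbiosis is
defined; the resulting calls then legitimately cut across phenotype.
Candidate thresholds are midpoints between consecutive unique scores
plus ±∞ sentinels; AUC is the trapezoid over (1 − specificity,
sensitivity) with ties resolved by ascending-TPR ordering. The default
threshold policy maximises Youden's J = sensitivity + specificity − 1,
breaking ties toward higher specificity and then higher sensitivity; a
`max_specificity` policy (maximise specificity among positive-J
points) is offered because "most specific" admits either reading.

A sample meets an enriched criterion when its abundance exceeds the
threshold and a depleted criterion when it falls below; a sample with
≥ `min_markers` (default 3) criteria met is dysbiotic. "Meeting a
criterion" is threshold-exceedance, not mere detection: presence or
absence of common gut species carries no information. A marker species
absent from a profile counts as abundance zero (logged). Outlier
exclusion — explicit sample ids or per-species abundance caps such as
(species, 70%) — runs before marker discovery and classification and
is config-driven, never hardcoded to sample names.

If fewer than four discriminating species exist the panel shrinks and
`min_markers` is clamped to size − 1 (floor 1) with a warning.

## Gene abundance and expression

BLAST tabular (outfmt-6, 12 columns) hits are filtered per gene with
strict inequalities: e-value < cut-off and, when an identity floor is
set, %identity > floor. The read-search cut-off is 10⁻³⁰ and the
assembly-search (presence/absence) cut-off 10⁻²⁰. The *luxR2–4
B. fragilis* queries carry no identity floor because those genes are
unique to *B. fragilis*; *luxR1 B. fragilis* uses > 80% and *luxR1
B. dorei* > 97% to stay species-specific. Gene reads are counted as
distinct read ids — multiple HSPs on one read count once. A read may
count toward every gene whose filters it passes; no best-hit
assignment is attempted, and the default catalogue's gene queries are
disjoint enough that this does not arise in practice.

Relative abundance is gene reads over total reads in the sample.
Expression is the MTX relative abundance divided by the MGX relative
abundance; samples with zero MGX gene reads have undefined expression
and are excluded from expression comparisons (reported with an
`excluded` flag). The ratio is invariant to common rescaling of MTX
counts and totals. Note that the arithmetic mean of a ratio of Poisson
counts is biased upward by roughly 1/λ at low coverage; group
comparisons therefore use rank tests, and fold-change summaries use
geometric means over samples with positive expression.

BLAST itself is never executed: the pipeline consumes tabular outputs
(real or simulated), which keeps it self-contained and testable.

## AHL identification from MRM peaks

An AHL candidate, designated by its precursor [M+H]⁺ m/z M, is
confirmed when two diagnostic product-ion peaks co-elute: one within
`mz_tol` of M − 101.048 (neutral loss of the homoserine-lactone
moiety) and one within `mz_tol` of 102.055 (protonated lactone
fragment), their retention times within `rt_tol` of each other. When a
precursor trace row is recorded it must co-elute too, but its absence
does not veto a call — in MRM the precursor is implicit in every
transition. The conjunctive two-ion rule is the default; a
`require_both_products=False` switch gives the permissive
either-ion reading. Defaults: `mz_tol` = 0.3 Da (unit-resolution
quadrupole), `rt_tol` = 0.1 min; instruments report neither, so these
are chosen to match common triple-quadrupole practice.

The neutral-loss transition (the more structure-specific ion) is the
quantifier; its area divided by the internal-standard (C6-d3-HSL) area
gives the relative concentration. The internal standard is identified
by its own configured transition, and a sample whose internal-standard
peak is missing is dropped from the profile matrix with a warning.
Profile-matrix columns exist only for AHLs confirmed in at least one
sample; group richness is the number of such columns confirmed within
the group.

## Synthetic-data generator

The generator emulates the structure of a paired MGX/MTX IBD cohort:
three phenotype groups (defaults 26 non-IBD, 50 CD, 27 UC),
per-phenotype dysbiosis probabilities (defaults 4/26, 24/50, 17/27 —
the observed dysbiotic counts per phenotype), species profiles,
per-gene read counts and MRM peak tables, all driven by one seed that
fans out to per-sample substreams (adding samples never perturbs
earlier ones; identical seed and config give byte-identical outputs).

Communities: species baseline means are log-normal (σ = 3.5 between
species — a steep, dominance-heavy rank-abundance curve), with
per-sample log-normal noise (σ = 0.002 within groups), closure to
relative abundances, and multinomial read sampling at a log-normal
total (mean 4 × 10⁶, σ = 0.25). Marker species are planted at fixed
community shares (0.45, 0.28, 0.16, 0.10 %) rather than drawn, with
folds 10×, 12×, 15× depletion and 9.1× enrichment; the enriched fold
is chosen so the mass gained by the bloom offsets the mass lost by the
depleted markers. Two of these choices deserve emphasis:

- *Mass balance.* Because relative abundances are compositional, any
  net mass the planted markers move is mirrored, with opposite sign,
  in every other species — a correlated, entirely artificial group
  difference. Balancing the panel keeps non-marker species
  exchangeable between groups, which is what "null species" must mean
  for recovery experiments to be interpretable.
- *Dispersion.* The within-group σ is far below the dispersion of real
  stool microbiomes. It is deliberately chosen so that counting noise,
  not biological variability, dominates: the validation suite then
  measures the algorithmic behaviour of the pipeline (screen
  calibration, threshold behaviour, recovery) rather than the power
  available at a particular biological noise level. Passing these
  tests shows the machinery is correct; it does not show that four
  markers would be recoverable at real-data dispersion, where the
  published analysis itself operated at the edge of significance.

Gene hits: MGX reads ~ Poisson(total × abundance), MTX reads ~
Poisson(total × abundance × fold) in dysbiotic samples, with a shared
per-sample log-normal jitter (σ = 0.5) on the gene's abundance that
cancels in the expression ratio. The default catalogue plants a 3-fold
dysbiosis over-expression on *luxR4 B. fragilis* and fold 1 elsewhere.

BLAST emission: one outfmt-6 table per sample and sequencing type in
which true hits are drawn strictly inside the gene's cut-offs (≥ 1
identity point above any floor, ≥ 10× below the e-value ceiling),
decoys strictly outside, and ~10% of true reads carry a second HSP
row; the unique-read count surviving the filters equals the planted
hit count by construction.

MRM: 13 true AHL precursors (C4 through C16:1 [M+H]⁺ values); non-IBD
samples draw from all 13, IBD samples from the first 7, with the first
sample of each group carrying its full repertoire so group richness
equals the planted (13, 7) structure. Decoy precursors always violate
the rule — missing one product ion, or both ions present but separated
by 3 × `rt_tol`. The internal standard appears in every sample. The
generator does not simulate raw reads or chromatograms, strain-level
variation, or longitudinal sampling.

## Validation experiments and problem sizes

The experiments in `gutqs.validation` (run by the test suite and
`scripts/acceptance.py`) use these sizes, chosen to give stable
statistics at desk scale:

- cohort percentages: the printed activity-category counts (50 CD,
  27 UC, 26 non-IBD);
- null calibration: 500 replicates each for PERMANOVA (10 + 10
  samples, 50 species, 99 permutations) and the expression comparison
  (20 + 20 samples, fold 1);
- marker recovery: 50 runs of 25 + 25 samples, 200 species, feeding
  the biomarker stage the relative-abundance profiles directly (the
  analysis pipeline on cohort-shaped data rarefies first; inside the
  recovery experiment rarefaction only re-injects counting noise on
  top of an identical method path);
- classifier accuracy: 3 runs of 50 + 50 samples with dysbiosis in
  half the cohort overall, phenotype-linked (0.2 non-IBD / 0.8 IBD) —
  a uniform 0.5 rate in both phenotypes would leave the phenotype
  labels, from which the panel thresholds are derived, with no marker
  signal at all;
- expression recovery: 50 runs of 50 + 50 samples, planted fold 3;
- AHL identification: the default 12-sample MRM cohort with decoys;
- determinism: two complete pipeline runs (15/15/10 samples, 499
  permutations) compared by artifact checksum.

## Known limitations

- The LEfSe stage is a documented re-formulation, not a numeric clone
  of the reference implementation.
- Within-group dispersion and marker mass-balance in the generator are
  validation-power choices, not estimates from data (see above).
- Expression ratios at very low coverage are noisy and biased; the
  pipeline excludes zero-MGX samples but applies no shrinkage.
- The dysbiosis score is a hard ≥3-of-4 rule; no probabilistic score
  or longitudinal modelling is attempted.
- UniFrac and other phylogeny-aware metrics, multi-factor PERMANOVA,
  best-hit read assignment and absolute AHL quantification are out of
  scope.
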