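# Methods

This note records the models, conventions and numerical choices behind
`microstab`, and what the simulation-based checks do and do not show.

## Study design and data model

The analysis targets a paired cold-chain design: each subject
contributes one sample per storage condition (C1 fresh, C2 −80 °C,
C3 −20 °C then −80 °C), measured as (a) a phylotype proportion vector
from 16S amplicon sequencing and (b) a 1D ¹H NMR spectrum of the
aqueous swab extract. Profiles enter the package as relative-abundance
tables; the upstream read processing (quality filtering, chimera
removal, taxonomic assignment) and NMR acquisition/phasing are out of
scope. Trees for weighted UniFrac enter as Newick with branch lengths.

The packaged fixtures carry the study's printed tables: 23 taxon
profiles (subject S01 lacks C2 — its amplicon failed) and 24
metabolite records. Printed percentages cover only the top 20 taxa, so
an explicit "Other" remainder taxon closes each composition; negative
remainders from rounding (sums slightly above 100 %) are clipped to
zero with a warning. This matters because JSD and Bray–Curtis assume
full compositions.

## Dissimilarity measures

JSD is computed in natural log; its upper bound is ln 2 and `0 log 0`
is taken as 0. The relative-entropy ("kl") and log-Euclidean metrics
are undefined at zeros, so both use a small additive pseudocount,
default 1e-6; the single-pair `kl` call is the directed divergence
(first argument is the reference), and matrix/equivalence code
symmetrizes it as [KL(p,q)+KL(q,p)]/2 because a dissimilarity is
required. Rarefaction subsamples counts without replacement
(multivariate hypergeometric) and is available but off by default in
the equivalence pipeline, which operates on full-depth proportions.

## Equivalence testing

For a condition pair, the test sample holds one within-subject
distance per subject possessing both conditions; the null sample pools
all within-subject pairwise distances among technical replicate
triplets (a triplet contributes three). The two-sided two-sample KS
test compares the two samples; the p-value is exact while
C(n+m, n) ≤ 1e5 and otherwise uses the asymptotic Kolmogorov
distribution with effective size nm/(n+m). ECDFs are right-continuous
and evaluated at all pooled points.

Two statistical caveats are properties of the procedure itself, not of
this implementation:

* the three distances of one triplet share both samples and the
  triplet's underlying composition, so the 48 pooled null values are
  positively correlated within triplets. Under heterogeneous cohorts
  (distinct community state types) this understates the null ECDF's
  sampling noise and inflates the test's size somewhat above nominal —
  simulations here put it near 0.07 at α = 0.05 with 8 test and 16×3
  null distances. It remains inside the calibration band the checks
  use, and the package reports n_test/n_null so users can judge;
* with ≤ 8 test distances the KS test has limited resolution, so
  "equivalence" means "no detectable difference at this n", not proof
  of identity.

The cross-metric sensitivity check asks, for each alternative metric,
whether its reject/accept decision matches the JSD decision for the
same condition pair — the form of agreement the original analysis
reports.

## Community state typing

CSTs are assigned by Ward-linkage hierarchical clustering of the JSD
matrix (treated as a plain dissimilarity, no square-root correction —
a documented convention, since the clustering recipe behind the
published labels is not restated there), cut into k = 4 clusters
(this cohort exhibits four states; k is exposed). Cluster labels come
from the centroid: if total *Lactobacillus* (iners, crispatus,
gasseri, jensenii) is below 0.5 the cluster is the diverse anaerobic
state IV; otherwise the strongest of crispatus/gasseri/iners decides
(I/II/III), ties broken lexicographically. Rows are sorted by sample
id before linkage so assignments are independent of input order. On
the packaged fixture this recipe reproduces all 23 printed labels.

## Synthetic studies

The generator defines the simulated study conditions:

* 8 subjects × 3 conditions; 16 replicate triplets for the null;
* four CST templates (crispatus-, gasseri-, iners-dominated, and a
  17-taxon anaerobic mixture) drawn uniformly per subject;
* subject base ~ Dirichlet(50 · template): substantial between-subject
  variation within a CST, as the real cohort shows;
* storage perturbation ~ Dirichlet(κ · base) per condition. The
  default κ = 5·10⁴ keeps the perturbation below multinomial
  sequencing noise at the default depth of 7000 reads — the regime the
  study's findings support; κ = ∞ disables it exactly, and small κ
  (e.g. 20) plants a strong artifact for power studies;
* reads ~ Multinomial(7000, composition), converted to proportions.

All randomness descends from one integer seed through numpy
`SeedSequence` spawning, so every artifact is reproducible.

Synthetic spectra are sums of Lorentzian lines (half-width γ = 0.004
ppm) on a 16384-point grid over δ = 0.30–8.50 ppm: a lactate CH₃
doublet at 1.33 ppm and CH quartet at 4.11 ppm (areas 3:1), acetate,
succinate, butyrate/propionate lines growing with the anaerobe
fraction, ~20 fixed background resonances, small additive Gaussian
noise, and a per-sample log-normal factor (σ = 0.05) on the lactate
level. The lactate area is calibrated so its normalized CH₃ integral
is ≈ 0.045 + 0.18·f_lacto, placing fully *Lactobacillus*-dominated
samples at ~18–27 % and diverse anaerobic samples at ~3–12 % lactic
acid, the ranges the fixture data show. The generator does not emulate
peak-position drift, baseline/phasing artifacts, J-coupling fine
structure beyond fixed line positions, or inter-metabolite
correlations beyond the community composition, so passing tests speak
to the statistical pipeline, not to robustness against those
real-data effects.

## NMR processing

Bucketing is valley-seeking adaptive binning — an open reimplementation
of the "intelligent bucketing" idea, not a clone of any vendor
algorithm: buckets start as an equal-width grid over δ = 0.50–8.30
minus the water window 4.70–5.00 (allocated proportionally to
sub-region width), each interior boundary snaps to the lowest point of
the cohort mean spectrum within half a spacing (ties resolved toward
the original position, so a flat spectrum stays equal-width),
boundaries violating the minimum width (0.01 ppm) are merged away, any
interval wider than 0.30 ppm is split evenly, and the widest buckets
are split at interior valleys until the count is within n_target − 5.
Integration is trapezoidal with interpolated interval endpoints, so
adjacent buckets tile the region exactly. Total-sum normalization
divides by the total over included buckets only, i.e. the water region
is excluded *before* the normalizing total is computed (the ordering
is our call; the source analysis does not state it). Metabolite
quantification sums normalized integrals over buckets whose centers
fall within ±0.05 ppm of the resonance (window width our choice; only
peak centers are given), × 100.

## Per-bucket statistics

The condition comparison is a paired Wilcoxon signed-rank test,
pairing by subject — the within-woman design makes the paired form the
natural reading of "Wilcoxon test". Zero differences are dropped
(Wilcoxon's original treatment); the exact two-sided p comes from the
null distribution of the rank sum computed by subset-sum dynamic
programming over doubled ranks (identical to enumerating all 2ⁿ sign
vectors, including under ties) for n ≤ 25, and a normal approximation
with tie and continuity corrections above. FDR control is
Benjamini–Hochberg across buckets within each condition pair (not
pooled across pairs). Because total-sum normalization couples the
buckets, an all-same-sign event (probability 2·2⁻⁸ per pair at n = 8)
produces a correlated block of small p-values across much of the
spectrum; the null-simulation check therefore expects a near-zero but
not exactly zero discovery rate. Ward clustering of bucket tables uses
Euclidean distances on the normalized integrals and scipy's
deterministic merge order; dendrograms can be exported as Newick.

## Ordination

Weighted UniFrac accumulates b·|A−B| over a post-order traversal;
multifurcations are allowed, zero-length or unlengthed branches
contribute nothing, and the normalized form divides by Σ b·(A+B).
Taxa with positive mass must be tree leaves; zero-mass taxa (such as
an all-zero "Other" remainder) need none. PCoA eigendecomposes the
symmetrized double-centered −½D²; eigenvalues below a relative
tolerance of 1e-10 are treated as zero, negative eigenvalues are
discarded from coordinates and the explained-variation denominator
(no Cailliez correction), and their total magnitude is retained for
inspection. The module accepts any distance matrix, so the pipeline
runs end-to-end on JSD when no tree is available — the published axis
percentages from the study's own tree are not reproducible without
its raw reads. The subject clustering score is the fraction of
within-subject pairs falling below the median between-subject
distance (~0.5 under no subject structure, 1 under perfect
separation).

## Problem sizes of the checks

The simulation checks use 600 no-effect replicates × 3 condition pairs
for the KS size estimate (Monte-Carlo SE ≈ 0.006), 200 replicates for
power against κ_C3 = 20, 200 replicates for cross-metric agreement,
and 100 replicates of the full spectrum-to-FDR pipeline for planted
lactate recovery (lactate scaled ×1.3 in C3). These sizes give the
estimates comfortable precision relative to the bands they are judged
against while keeping the whole suite fast on a single CPU.

## Known limitations

* The equivalence null requires technical replicates; with none, the
  test cannot separate storage effects from handling noise.
* The KS size inflation under pooled triplet nulls (above) is inherent
  to treating the 48 pooled distances as independent.
* CST labeling is centroid-based; clusters mixing two *Lactobacillus*
  species are labeled by the stronger one.
* Bucket boundaries derive from the cohort mean spectrum; cohorts with
  strongly shifted peaks would need re-bucketing per cohort.
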