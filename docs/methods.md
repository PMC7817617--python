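# Methods

## Signal model and estimator

A DNA bulk hybridised to a two-colour SNP array yields, per SNP, normalized
channel intensities x (allele A) and y (allele B). The quantitative
measurement is the fluorescence intensity ratio FIR = y/(x+y), in [0, 1];
a record with no signal (x + y = 0) or an absent channel is missing.
Internally all matrices are SNP-major; missingness is NaN (never 0, which
is a legal intensity and a legal frequency), and `NA` on disk.

The estimator is deliberately two-step:

1. **Fixation test.** For each SNP, a reference panel of inbred
   (fully homozygous) lines provides FIR clusters for AA and BB genotypes,
   summarised as mean, sample sd (n−1 denominator) and count. The bulk's
   FIR is tested against each cluster with a two-sided single-observation
   Student test in prediction-interval form,
   t = (obs − mu)/(sd·sqrt(1 + 1/N)), df = N−1, at nominal level 0.05.
   The sqrt(1 + 1/N) inflation accounts for the estimation error of the
   cluster mean; with it, the statistic is exactly t-distributed when the
   bulk truly belongs to the cluster, so the nominal level is exact — the
   unit tests verify the 5% rejection rate empirically. A cluster absent
   from the panel is replaced by its theoretical homozygote (mean 0 for
   AA, 1 for BB) with the observed cluster's spread and df; a
   single-member cluster has no spread estimate and degenerates to an
   exact-match rule. Membership of exactly one cluster gives a frequency
   of exactly 0 or 1; membership of both (possible only for overlapping
   clusters, which the wd filter makes rare) is reported as AMBIGUOUS and
   treated as missing downstream — fabricating a call would defeat the
   protection against false allele detection that motivates the test.

2. **Logistic calibration.** Bulks rejected by both membership tests are
   polymorphic and get a frequency from a single calibration curve
   logit(f_B) = alpha + beta·FIR shared by all SNPs. Per-SNP curves would
   require every SNP to be polymorphic in the controlled pools and would
   be badly determined for SNPs with a narrow covered range; one common
   curve, fitted to a class-balanced SNP sample, trades a small
   differential-hybridization bias for robustness and freedom from that
   ascertainment. A per-SNP extension hook exists in principle (fit any
   subset and predict with its own fit) but is not a default.

Because the logistic maps to the open interval (0, 1), an exact 0 or 1 in
the output can only come from the fixation test. Per-cell provenance
(FIXED_BY_TEST / LOGISTIC / AMBIGUOUS / MISSING) is mandatory output.

## SNP quality score

wd = |mu_AA − mu_BB| / sqrt((N_AA·sd_AA² + N_BB·sd_BB²)/(N_AA+N_BB)).

Conventions chosen where the formula leaves room: sds are sample sds
(n−1); a cluster with fewer than two members contributes N·sd² = 0; a
zero pooled variance with distinct means scores +inf (passes any
threshold); no usable cluster at all scores NaN (fails every threshold).
"Above 50" is implemented strictly (wd > threshold); the threshold is a
parameter. SNPs heterozygous in any controlled-pool parent are removed
regardless of wd because their expected pool frequencies are undefined.

## Controlled pools and the calibration sample

Nine standard pools mix three parental lines L1/L2/L3 in mass proportions
(0.01, 0.495, 0.495) … (1/3, 1/3, 1/3); L2 and L3 always share a
proportion. The expected allele-B frequency of a pool is the
proportion-weighted sum of parental allele-B dosages; over the eight
dosage triples this spans 0–100%, with the four polymorphic configuration
classes R1 (B,A,A: 1–33%), R2 (A,A,B / A,B,A: 33–50%), R3 (B,A,B / B,B,A:
51–67%) and R4 (A,B,B: 67–99%). Whole-percent values are rounded half
away from zero after snapping to 9 decimals (0.575 → 58%, immune to
binary representation error).

The calibration sample takes 250 SNPs per class (seeded, uniform without
replacement from lexicographically sorted ids). A SNP showing different
classes in the two parental series is assigned once, by the priority
R1, R4, R2, R3 — extreme-range classes first, which maximises the
frequency span the curve is trained on. The calibration design includes
the 18 pools and the 6 parental lines (24 samples); a
`polymorphic_only` switch restricts to unsaturated cells.

`fit_logistic` is an in-package IRLS for the quasi-binomial logit model
with fractional responses and unit weights: initial mean clip(y, 0.005,
0.995); convergence when the deviance change is below 1e-10 relative (or
the deviance is numerically zero), at most 50 iterations; means are
clipped to [1e-12, 1−1e-12] against overflow; non-convergence or
separation is reported, not raised. The implementation is cross-checked
in the tests against statsmodels' GLM (independent IRLS) to 1e-6 on
noisy data and against the two-point closed form exactly.

## Accuracy machinery

MAE is the mean |predicted − expected| over pairwise-complete cells, with
a breakdown over 21 equal expected-frequency bins (the bin width is a
reporting choice; nothing downstream depends on it). Two cross-validation
schemes probe the calibration: SNP k-fold (default 800 train / 200 test,
5 repeats) and sample removal (k of the 18 pool samples removed at
random, refit on the rest plus parents, predict the removed pools;
default 1000 repeats, any 1 ≤ k ≤ 17 accepted). Held-out cells are
predicted with the logistic equation alone, so expected cells at exactly
0/1 bound the attainable MAE away from zero — the same structural floor
the published version of this scheme has. Mean MAE grows with k because
removing pools shrinks the covered frequency range; the tests assert the
trend, not specific values, which depend on the data.

Replicate concordance: two bulks of the same population drawn
independently differ by gamete sampling alone; with pooled estimate
m = (f1+f2)/2 and n individuals per bulk, d = f1 − f2 is approximately
Normal(0, 2·m(1−m)/(2n)) and the reported fraction counts pairs inside
the two-sided 95% band. The normal approximation on the 2n-gamete lattice
is slightly conservative near fixation; fixed loci (m ∈ {0,1}) are
concordant only on exact agreement. The construction of the published
confidence ellipse this mirrors was not specified; the difference-based
band is recorded as this package's choice.

## Sampling error

A bulk of n diploid individuals carries 2n gametes; with r biological
replicates pooled, the binomial size is 2nr. Bounds are exact
Clopper–Pearson: lower = BetaInv((1−c)/2; x, n−x+1) (0 at x=0), upper =
BetaInv(1−(1−c)/2; x+1, n−x) (1 at x=n), with x = round(freq·n) half away
from zero. Coverage is ≥ nominal by construction (verified by simulation
in the tests). Two replicates are modelled as pooling gametes — the
interval at the same frequency is nested inside the one-replicate
interval.

## Genetic distance

MRD(p, q) = sqrt((1/2m)·Σ_loci Σ_alleles (p_a − q_a)²), which for
biallelic loci equals sqrt((1/m)·Σ(p_B − q_B)²); the two normalisations
coincide exactly for biallelic data (asserted against an explicit
allele-wise oracle). MRD is Euclidean up to scaling, hence a metric, with
range [0, 1]. Pre-processing order: replicate columns averaged per
population (pairwise-complete, so a cell missing in one replicate passes
the other through), excluded samples dropped first; then per-SNP mean
imputation across populations (all-missing SNPs dropped with a logged
count); SNP subsetting (seeded) happens after imputation. Provenance
codes are not carried past imputation — an imputed cell has no honest
code in the closed source domain.

## Synthetic data generator

The generator emulates the study design end to end from a single seed:
a reference panel of inbred lines, two series of nine controlled pools
plus their six parents, and landrace bulks of n individuals.

Forward signal model: a bulk with allele-B frequency 0 < f < 1 produces
FIR = (logit(f) − alpha0)/beta0 + Normal(0, noise_sd), clipped to [0, 1];
a fixed bulk (f exactly 0 or 1) produces the corresponding homozygote
cluster mean plus the same noise, because a fixed pool is physically a
homozygote. Defaults: cluster means 0.08/0.92, cluster sds 0.02, per-SNP
cluster-mean jitter 0.01 (creates a wd spectrum), alpha0 = −5,
beta0 = 10, noise_sd = 0.02. Under these defaults the curve crosses the
AA anchor at f ≈ 0.015, below both the smallest controlled pool (1%) and
the smallest realisable 15-plant bulk frequency (1/30), so the piecewise
definition introduces no discontinuity at study scales.

Panel: per SNP, lines are BB with probability drawn from the minor-allele
distribution (default Uniform(0.05, 0.5); configurable), no
heterozygotes; FIR per cluster is Gaussian, clipped to [0, 1] (clipping
in place of resampling biases nothing at >4 sd from the boundary).
Bulks: the realised bulk frequency is Binomial(2n, f)/2n per SNP (gamete
sampling), and the FIR observation applies the forward model to that
realised frequency; the realised frequencies are kept as ground truth.
Population truth: each SNP × population is fixed with probability 0.5
(allele fair), otherwise Beta(2, 2) — roughly half the loci fixed per
population matches pooled genotyping of landraces, and the mound-shaped
spectrum reflects array SNPs ascertained for intermediate diversity.

What the generator does not emulate: linkage disequilibrium between
SNPs, per-SNP differential hybridization (the forward curve is common to
all SNPs, so the common-curve calibration is exactly well-specified
here — real arrays are not this kind), batch/laboratory effects, and
genotype-calling error in the reference panel. Passing tests therefore
demonstrate the estimator's correctness under its own assumptions and
its error decomposition (measurement vs sampling), not its accuracy on
any particular array.

## Study conditions used in tests

- *Noise-free identity*: noise_sd = 0, jitter = 0, panel maf = 0.5 (all
  clusters well populated). The calibration is fitted on polymorphic pool
  cells only: saturated 0/1 cells sit off-curve by construction (the
  logistic never reaches 0/1) and at zero noise would add a
  deterministic pull on the fitted curve. Under these conditions the
  estimated matrix equals the realised bulk frequencies to machine
  precision and every fixation call is correct.
- *Noisy end-to-end*: cluster sds 0.015. With the default 0.02 and
  cluster separation 0.84 the wd score centres near 42 and the wd > 50
  filter removes nearly everything; at 0.015 (wd ≈ 56) the filter keeps
  ~95%, matching the kept fraction seen on well-behaved real arrays.
  End-to-end MAE is ~2%, well below the 15-plant sampling error scale.
- *Type-I calibration*: each simulated fixed bulk is paired with its own
  freshly simulated panel, so the Monte-Carlo estimate targets the
  unconditional rejection rate — the quantity the nominal level controls
  exactly. Conditioning on one panel realisation would make the rate a
  random variable with sd ≈ 1.3 percentage points across panels.
- Problem sizes (SNP counts 300–3000, 60–200 panel lines, repeats
  60–200) are chosen so the full suite runs in well under a minute while
  keeping Monte-Carlo error far from every asserted tolerance.

## Known limitations

- The AMBIGUOUS state is never resolved or imputed; downstream analyses
  see it as missing.
- The common calibration curve absorbs differential hybridization into
  residual error; per-SNP calibration would need additional controlled
  pools polymorphic at every SNP.
- The replicate-concordance band is a normal approximation; exact
  binomial-difference regions would be tighter near fixation.
- `sample_removal_cv` and `snp_kfold_cv` validate the calibration curve
  only, not the fixation step (held-out cells are predicted logistically).
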