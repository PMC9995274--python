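# Methods

This note documents the statistical models implemented in `gmrate`,
their assumptions, the design choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## DNM calling and the callable genome

A candidate de novo mutation is a site where both parents are
homozygous reference and the offspring heterozygous, surviving five
filter stages. Thresholds live in `FilterConfig`; the defaults are the
hard filters commonly used with GATK joint genotyping of trios:

| filter | default | acts on |
|---|---|---|
| QD (qual by depth) | ≥ 2.0 | site |
| FS (Fisher strand) | ≤ 20.0 | site |
| MQ (RMS mapping quality) | ≥ 40.0 | site |
| MQRankSum | in [−2, 4] | site |
| ReadPosRankSum | in [−3, 3] | site |
| SOR (strand odds ratio) | ≤ 3.0 | site |
| Mendelian pattern | HomRef × HomRef → Het | trio |
| allelic balance | 0.30 ≤ AB ≤ 0.70 (closed) | offspring |
| depth | 0.5·m̄ < DP < 2·m̄ (open) | each individual |
| genotype quality | GQ ≥ 60 | each individual |

Decisions worth recording:

* **Missing annotations pass their sub-filter.** GATK omits RankSum
  annotations where they cannot be computed; failing such sites would
  silently shrink the callable genome.
* **AB bounds are inclusive, DP bounds strict.** "30–70%" is read as a
  closed interval; the depth window is written with strict
  inequalities and implemented that way.
* **m̄ (mean trio depth) is the mean of the three per-individual mean
  depths over the analysed sites** (a per-genome mean, not per-site).
* **Multi-allelic sites are skipped** with a counted reason in the
  audit table; only bi-allelic point mutations are analysed.
* **Cross-caller verification is out of scope**; `call_dnms` accepts an
  external exclusion list of positions in its place.

The callable genome C counts sites where both parents are HomRef and
all three individuals pass the depth and GQ filters. Site annotations
are *not* applied to callable counting — they exist only at polymorphic
sites — which is exactly why an FNR correction is needed.

## False-negative rate

The FNR is the probability that a true DNM at a callable site is lost
to the filters not included in the callable definition:

* `f_site`, analytic: the annotations with a known null at true
  variants. MQRankSum and ReadPosRankSum are standard normal, so their
  loss is the two-tailed mass outside the thresholds (0.02278 and
  0.00270 at the defaults); FS behaves as a phred-scaled uniform
  p-value, so P(FS > 20) = 10^(−2) = 0.01. QD, MQ and SOR have no
  clean parametric null and are treated as lossless at true DNMs.
* `f_ab`, empirical: the fraction of transmitted heterozygote sites
  (one parent HomRef, the other HomAlt, offspring necessarily Het)
  whose offspring allele balance falls outside the AB window. These
  sites are guaranteed true hets, so their AB distribution is the
  correct null for the AB filter.

The components combine multiplicatively, `FNR = 1 − (1−f_site)(1−f_ab)`,
assuming the site filters and the AB filter act independently on a true
DNM. Both the distributional choices and the combination rule are
configurable; they are stated here because the choice of null is a
modelling decision, not a measurement.

Rates are `mu = m/((1−FNR)·2·C)`. CIs are Wilson score intervals on
(m, 2C) divided by (1 − FNR); this treats the FNR as known, which
understates uncertainty slightly when f_ab is estimated from few
transmitted hets. Species-level rates average trio rates, with a CI
from the pooled (Σm, Σ2C).

## Phasing and α

A read (or read pair) spanning a DNM and a nearby heterozygous site
reveals which allele of that site shares the DNM haplotype; a read
without the DNM allele reveals the complementary haplotype. If the
shared allele is carried by exactly one parent, the DNM is assigned to
that parent. The conflict rule is strict: any observation pointing at
the other parent, any allele carried by both parents or by neither,
leaves the DNM unphased. A false phase biases α directly, whereas a
lost observation only widens the CI, so the asymmetric rule is the
conservative one. A single consistent observation suffices.

α = n_pat/n_mat. The CI maps the Wilson interval (L, U) on the paternal
fraction p through the strictly increasing transform p/(1−p); groups
with fewer than 30 phased mutations are flagged low-confidence but
still computed. When n_mat = 0, α = +∞ with a finite lower bound.

Sibling sharing: a DNM instance counts as shared when the identical
(chrom, pos, alt) occurs in ≥ 2 offspring of the same parent pair. The
denominator is every DNM instance in families with at least two
sequenced siblings, and the standard error is the per-mutation binomial
√(f(1−f)/n); a per-species basis is available as an option.

## The parental-age model

Counts per trio follow an identity-link Poisson model,

    m_i ~ Poisson( E_i · d_s(i) · (a + b·τ_i) ),   E_i = (1−FNR_i)·2·C_i,

with τ the paternal-fraction-weighted parental age in years, `a` ≥ 0 the
mutation load present at parental age zero (per site per generation),
`b` the accrual per year, and d_s > 0 a per-species multiplicative
deviation. The identity link is deliberate: the biology is additive —
a baseline contribution at birth plus age-proportional accumulation —
and a log link would make the intercept uninterpretable.

Fitting is two-stage maximum likelihood. Stage 1 fits (a, b) globally
with all d_s = 1 by bounded quasi-Newton on the Poisson likelihood
(optimized in units of the moment estimates so the problem is
well-scaled; a ≥ 0 enforced). Stage 2 fits each d_s in closed form,
d_s = Σm_i/Σμ̂_i over the species' trios, which is the per-species ML
solution with (a, b) fixed and therefore weakly increases the total
likelihood. No shrinkage is applied by default; single-trio species
simply get noisy d_s, surfaced through wide bootstrap CIs. Standard
errors for (a, b) come from the analytic observed information
H = Σ m_i x_i x_iᵀ/λ_i².

Trios without recorded parental ages are excluded from fitting but
still receive predictions (at the species generation time) and
modelled rates. Goodness of fit is reported as r² between predicted
and observed *counts* (1 − SSres/SStot).

Modelled rates evaluate the fit at the species generation time G:
`mu_generation_modelled = d_s(a + bG)`, `mu_yearly_modelled` divides by
G (an exact identity, tested as such). CIs are parametric bootstrap:
counts resampled from the fitted Poisson means, both stages refitted,
percentile intervals taken; 200 replicates by default (reducible),
seeded.

## Spectrum statistics

Point mutations collapse to six classes (A>C, A>G, A>T, C>A, C>G, C>T)
by complementing G>* and T>* so the reference base is A or C; the
classification is invariant under reverse complement (tested
exhaustively). CpG status is read from the trinucleotide context in the
original orientation — C followed by G, or G preceded by C — and
mutations without context are excluded from CpG proportions with a
logged count rather than guessed. The strong→weak flag marks the
C:G > T:A transition. Ts/Tv and proportion CIs are Wilson intervals
(the Ts/Tv CI via the same p/(1−p) transform as α). Homogeneity across
vertebrate groups uses Pearson χ² without continuity correction (counts
are large; Yates would be anticonservative here), with per-class 2×k
contrasts available; cross-class comparison of species-level mean rates
is a one-way ANOVA.

## Comparative analyses

PGLS fits y ~ x by generalized least squares with covariance
proportional to shared branch length under Brownian motion on a
time-calibrated ultrametric tree. Pagel's λ is fixed at 1 by default;
ML estimation of λ ∈ [0, 1] is available but off, since the default
should be the plain Brownian model rather than a silently optimized
transformation. On a star phylogeny the covariance is diagonal and the
fit reduces exactly to OLS (tested to machine precision); estimates are
invariant to global rescaling of branch lengths. Regressions are on the
raw scale by default with adjusted r² = 1 − (1−r²)(n−1)/(n−k−1) and a
two-sided t-test on the slope; fewer than four species are refused.
Ultrametricity is checked with a relative tolerance of 1e-6 and warned
about, not enforced, since empirical chronograms carry rounding error.

Harmonic-mean Ne over a window [t0, t1] of a piecewise-constant
trajectory is (∫dt)/(∫dt/Ne(t)) with partial segments clipped to the
window; windows that miss the trajectory support entirely are refused.
Ne = π/4μ is provided as the neutral-theory cross-check.

## The synthetic cohort generator

The generator plants known truth at the level the pipeline consumes —
genotypes, depths, qualities, annotations — not reads:

* DNM count ~ Binomial(2·n_sites, mu_true); parent of origin
  Bernoulli(paternal_fraction_true); offspring alt reads
  Binomial(DP, 0.5), optionally beta-binomially overdispersed
  (`ab_noise`).
* Depths are Poisson(mean_depth = 67); GQ is normal (mean 85, sd 12,
  clipped to [0, 99]), so a realistic few percent of sites fail the GQ
  and DP windows and the callable genome is genuinely smaller than
  n_sites.
* Annotations at variant sites are drawn from the FNR model's nulls
  (RankSums standard normal, FS phred-uniform, QD/MQ/SOR safely inside
  thresholds), so planted DNMs are lost at exactly the rate the FNR
  correction predicts — the property the end-to-end coverage tests
  verify.
* Error sites are candidate lookalikes violating one randomly chosen
  filter (an out-of-threshold annotation, an extreme allele balance, or
  a non-Mendelian genotype); transmitted-het sites (rate
  `het_site_rate`) feed the empirical f_ab.
* Planted alts follow a realistic spectrum: transitions with
  probability 0.7 (Ts/Tv ≈ 2.3) and CpG contexts for 42% of C:G > T:A
  mutations.
* Phasing evidence is simulated as consistent linkage observations
  pointing at the true parent for ~48% of DNMs; sibling sharing
  duplicates a DNM into a sibling of the same family with probability
  `sibling_share_prob`.
* Cohort metadata: correlated parental ages (r ≈ 0.8) around each
  species' typical reproductive age, generation times, life-history
  traits and domestication flags; a random ultrametric tree built by
  sequential pair joins at increasing node ages; piecewise-constant
  lognormal Ne histories over the last 2 Myr.
* A counts mode draws per-trio DNM totals directly from the Poisson
  age model (a_true = 0.6e−8, b_true = 0.4e−9 by default) for
  parameter-recovery work without site tables.

Everything is deterministic given the config seed (per-trio streams are
derived from the seed and a CRC of the trio id, so results do not
depend on generation order).

**Problem sizes.** A real study has callable genomes of ~2×10⁹ sites;
the generator's default is n_sites = 200,000 per trio, and the test and
reproducibility runs use 20,000–500,000 sites, 50-trio cohorts and
200-trio counts-mode cohorts. At the study's per-generation rate
(~1.2×10⁻⁸) such tables yield mostly zero-count trios, so coverage is
exercised at those conditions while parameter-recovery checks run at a
scaled-up rate (10⁻⁵ over 10⁶ sites, or genome-scale exposures in
counts mode) where estimates are sharp.

**What the generator does not emulate** — and therefore what passing
tests do not demonstrate about real data: read-level artefacts
(alignment error, duplicates, index hopping), correlated filter
failures, mutation clustering and mosaicism, indels, sex chromosomes,
reference bias, and annotation distributions deviating from the assumed
nulls. The FNR recovery results in particular hold *because* the
simulator draws annotations from the same nulls the estimator assumes;
on real data that agreement is an approximation.

## Known limitations

* The FNR enters CIs as a known constant; uncertainty in f_ab is not
  propagated.
* The species deviation d_s is fitted without shrinkage; species with
  one trio have unstable deviations (flagged, wide bootstrap CIs).
* PGLS assumes the supplied chronogram is correct; λ is not optimized
  by default, so residual phylogenetic signal misspecification shows up
  in p-values.
* The phasing module consumes linkage observations, not BAMs;
  extracting observations from alignments is upstream of this package,
  as are read mapping, variant calling and PSMC inference.
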