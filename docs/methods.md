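# Methods

## Estimation model

All two-locus estimation is built on the 3×3 table of unphased genotype
classes for a marker pair, tabulated over the animals called at both
markers (pairwise-complete deletion; the per-pair `n` used in every
statistic is this complete-case count). Individuals are treated as a
multinomial sample from the population genotype distribution. Because the
saturated model has as many parameters as degrees of freedom, maximum
likelihood reduces to plugging observed proportions into the defining
identities; every estimator in `zygld.core` is such a plug-in. Biases are
of order 1/n (e.g. `E(p̂²) − p² = [p(1−p) + D_A]/2n`, which the test suite
verifies by simulation) and are ignored at the sample sizes the package
targets (hundreds to thousands of diploids).

The components and their identities:

* single-locus: `p_A = (2n₂ + n₁)/2n`, `P_AA = n₂/n`, `D_A = P_AA − p_A²`,
  `f_A = D_A/(p_A p_a)`, HWD chi-square `n f_A²` (1 df).
* composite digenic `Δ_AB = E[XY]/2 − 2 p_A p_B` — half the covariance of
  the dosage variables, estimable without any equilibrium assumption; it
  equals the sum of the gametic and nongametic digenic disequilibria.
* trigenic `D_AAB = P_AAB − p_A² p_B − p_B D_A − p_A Δ_AB` with
  `P_AAB = Σ_y y·P[2, y]/2` (the frequency of the gene triple A, A, B in
  one individual), and symmetrically `D_ABB`. These are the composite
  (arrangement-summed) trigenic measures: with unphased data the gametic
  and nongametic arrangements of a gene triple are not separable, so the
  residual is defined after removing allele products, HWD and the
  *composite* digenic term.
* quadrigenic `Δ_AABB`, defined by exact inversion of the zygotic
  identity `ω = 2p_A D_ABB + 2p_B D_AAB + 2p_A p_B Δ_AB + Δ_AB² + Δ_AABB`
  with `ω = P_AABB − P_AA P_BB`. Inversion makes the decomposition
  self-consistent by construction — reconstruction of `P_AABB` from the
  estimated parts is exact to rounding for any table, which the suite
  checks on random tables.
* gametic `D_AB` by the standard two-locus EM over the four haplotype
  frequencies, treating only the central (double-heterozygote) cell as
  phase-ambiguous. Initialisation is at linkage equilibrium; convergence
  when the largest haplotype-frequency change drops below 1e-10 (default;
  1000-iteration cap, non-convergence flagged and the last iterate
  returned). The all-double-heterozygote table leaves the likelihood flat
  in phase; the equilibrium start is then a stationary point and the
  package reports D = 0 with a `flat_likelihood` flag rather than picking
  a phase arbitrarily. Allele frequencies are invariants of the EM map, so
  `r²_GLD = D̂²/(p_A p_a p_B p_b)` uses the genotype-based frequencies.
  The EM was cross-checked against direct numerical maximisation of the
  multinomial likelihood.

Every estimator also accepts an exact 9-cell probability table (`n → ∞`
mode); simulated-population truths are computed through this mode by the
same code path, so generator and estimator cannot drift apart silently.

## Inference

Tests are 1-df chi-squares against zero disequilibrium, with α = 0.05 and
critical value 3.84 throughout. The gametic and zygotic statistics arise
from 2×2 collapses (haplotype table; AA-vs-rest × BB-vs-rest), so
`X² = n r²` and `φ² = X²/n = r²` exactly. The composite test uses
`X² = nΔ̂²/[(π̂_A + D̂_A)(π̂_B + D̂_B)]`, algebraically `n` times the squared
dosage correlation, so it shares this property. `n` counts animals, not
gametes, for all three (a 2n-gamete variant of the gametic test is exposed
as an option). The trigenic and quadrigenic statistics use
`X² = D̂²/Var(D̂)`.

Variances come from a generic multinomial delta method: the statistic is
differentiated in the nine cell proportions by central differences
(step 1e-6) and contracted with the multinomial covariance
`Σ_kl = (δ_kl p_k − p_k p_l)/n`. The engine is validated against the exact
`Var(p̂)` formula and against empirical sampling variances (10% relative
tolerance at n = 1023). As a quadratic form it is non-negative, so
delta-method φ² values are never below zero; published closed-form
variance expressions for these estimators can be negative in finite
samples, and the `variance_fn` hook lets a user supply them, in which case
φ² < 0 occurs and is tallied by the out-of-bound filter. φ² > 1 does occur
with the default engine — the quadrigenic variance degenerates toward zero
at boundary tables — and the filter removes such pairs from all strength
and power summaries, reporting both tallies separately per component.

"Power" is used in the calibration sense: the empirical rejection rate
computed when the hypothesis under test may in fact be true, so that a
true null yields the significance level. Rejection rates are computed over
defined, in-bound tests only, with exclusion counts reported.

## Marker QC

Markers are removed in a fixed order, each counted once: (i) monomorphic,
(ii) unmapped, (iii) sex chromosome, (iv) MAF ≤ 0.02 (inclusive removal),
(v) HWD chi-square `n f̂²` > 600. The thresholds are the package defaults
for a 50K-style cattle panel and are all configurable. The designated A
allele is oriented to the minor allele once at QC time and never
re-derived, keeping the signs of all D estimates stable across a run.

## Genome scans

Pair enumeration is within-chromosome (optionally distance-capped) or
between-chromosome, with seeded uniform subsampling for dense panels; a
full all-pairs scan of a 43K-marker panel (~36M syntenic pairs) is beyond
desk scale, which is why capping and subsampling are first-class. The scan
is vectorised over blocks of pairs (counts by a single flat bincount, all
estimators and the EM batched); a few hundred thousand pairs take well
under a minute on one core. Summaries: distance bins (default: the nine
half-open sub-5 Mb intervals, `[lo, hi)`), per-chromosome power split at
≤50 Mb vs >50 Mb under the 1 cM = 1 Mb equivalence (chromosomes with no
pair beyond the cutoff report an absent cell), MAF classes `[0.02, 0.1)`,
`[0.1, 0.3)`, `[0.3, 0.5]` (boundary 0.3 belongs to the upper class) with
per-chromosome(-pair) mean/min/max power, and binned power-vs-distance
series. All summaries are exact functions of the persisted pair table and
reproduce bit-identically from the TSV.

## Synthetic populations

The generators provide known-truth inputs at every level of control:

* **Random union of gametes** (`simulate_rug`): 2n gametes i.i.d. from
  given haplotype frequencies, paired at random. All nongametic and
  higher-order parameters are zero and `Δ_AB = D_AB` — the canonical null
  and reduction fixture.
* **Saturated sampling** (`simulate_cell_probs`): multinomial draws from
  an arbitrary 9-cell table, for estimator sampling distributions.
* **Explicit admixture** (`simulate_admixture`): founders drawn from
  breed-specific HWE populations (loci independent within breed), then g
  generations of random union of recombinant gametes, crossover
  probability `min(0.5, d_bp × 1e-8)` per marker interval. The exact truth
  per pair is tracked analytically: generation 0 is the Wahlund mixture
  (HWD, admixture LD, nonzero trigenic/quadrigenic residuals); every later
  generation is a random-union population whose gametic LD decays by
  (1 − r) per generation while all nongametic terms are zero. The
  two-locus recombination fraction through intermediate markers uses the
  exact odd-number-of-crossovers probability.
* **Ancestry-mosaic genome** (`simulate_genome`): emulates a composite
  beef population at genome scale. Each individual carries an admixture
  proportion `q ~ Dirichlet(ν·w)` shared by both haplotypes; variation in
  q produces Wahlund-type HWD and admixture LD that spans chromosomes, as
  in a herd under continued crossbreeding. Along a chromosome each
  haplotype is a mosaic of breed-ancestry blocks: the ancestry state is
  redrawn from q between adjacent markers with probability
  `1 − exp(−u·d/s)`, where the per-haplotype multiplier `u ~ Exp(1)`
  represents haplotypes of different effective pedigree depths. Averaging
  over u integrates the per-haplotype exponential decay into a long-tailed
  `1/(1 + d/s)`-shaped ancestry correlation — the Sved-like decay seen in
  livestock panels — rather than a single exponential. Defaults: two
  founder breeds with mirrored per-marker allele frequencies drawn from
  (0.8, 0.95) (an ancestry-informative panel; strong differentiation is
  what makes admixture LD visible), weights (0.8, 0.2), concentration
  ν = 3 and block scale s = 100 kb. The pronounced weight asymmetry gives
  the admixture distribution the skew that generates trigenic residuals
  clearly exceeding the quadrigenic ones; the concentration sets the
  long-range LD floor relative to the short-range peak. With these
  defaults a two-chromosome panel reproduces the qualitative genome-wide
  structure the method is designed to reveal: mean φ² of composite LD
  declining monotonically across the nine sub-5 Mb bins from ≈0.25–0.30,
  component ordering digenic > trigenic > quadrigenic, and — at a cohort
  size (~150) where the long-range composite signal sits near the
  detection threshold — a composite-LD power curve that decays sharply
  with distance while the trigenic/quadrigenic curves stay comparatively
  flat.

What the generators deliberately do **not** model: within-breed founder
LD, selection, mutation, pedigree structure and genotyping error. Passing
tests on these populations therefore demonstrate correctness and
calibration of the estimators and the expected structural signatures of
admixture, not quantitative agreement with any real cattle panel. In
particular the empirical dependence of test power on MAF class observed in
real composite populations (composite-LD power rising, zygotic-LD power
falling with MAF) is a property of a real genome's joint frequency/LD
structure: under controlled constant-Fst admixture the zygotic test on the
minor-homozygote collapse shows the opposite trend, and in the mosaic
panel MAF is confounded with breed divergence. The MAF-class summary is
therefore validated structurally (assignment, per-cell power), not against
that empirical contrast.

## Numerical and design choices

* Zygotic LD is computed for the double homozygote of the designated
  (minor, after QC) alleles; which 2×2 collapse to use is a genuinely open
  convention, and the major-allele alternative is available by
  re-orienting dosages.
* The EM is the standard one and does not impose HWE on the zygote
  distribution beyond what random pairing of haplotypes implies; the
  composite-LD estimator is the fully assumption-free route.
* Degenerate pairs (monomorphic in complete cases, empty homozygote
  margins, zero variances) yield flagged NaN statistics; a scan never
  aborts on a bad pair.
* Missing genotypes: all statistics use pairwise-complete observations.
  How the original SAS-based analyses handled missing calls is not
  documented; pairwise deletion is this package's choice.
* Test problem sizes (e.g. 2,000 null pairs at n = 1023; 200 recovery
  replicates at n = 10,000; a 1,600-marker, 150-animal genome scan) were
  chosen to give stable Monte-Carlo margins at interactive runtimes and
  are stated in each test.

## Known limitations

* Biallelic loci only; three-locus and phased analyses are out of scope.
* The delta-method variance cannot reproduce the negative-variance
  behaviour of the closed-form trigenic variance expressions (it is
  non-negative by construction); the plug-in hook exists for users who
  want the closed forms, which are not re-derived here.
* φ² for the trigenic/quadrigenic tests has no exact r² interpretation;
  its [0, 1] screening is a pragmatic outlier rule, not a distributional
  statement.
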