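# zygld — zygotic linkage disequilibrium and its genic components

`zygld` estimates and tests **every non-allelic association between a pair of
unphased biallelic SNPs** in a diploid population: the usual digenic linkage
disequilibrium, and the higher-order three- and four-gene disequilibria that
appear when a population — for example a composite livestock population built
by repeated crossbreeding — is not in Hardy–Weinberg equilibrium. It is aimed
at population and quantitative geneticists who have a genome-wide unphased
genotype panel and want to know how much of the multilocus structure is
carried by ordinary gametic LD and how much by everything else.

## The model

Write `P[x, y]` for the frequency of the unphased two-locus genotype with
dosage `x` of allele A and `y` of allele B (the two double-heterozygote
phases share the central cell). From this 3×3 table the package estimates,
by direct plug-in (which is also maximum likelihood for the saturated
multinomial model):

| quantity | definition | meaning |
|---|---|---|
| `D_A` | `P_AA − p_A²` | Hardy–Weinberg disequilibrium at one locus; `f_A = D_A/(p_A p_a)` |
| `Δ_AB` | `E[XY]/2 − 2 p_A p_B` | composite (Burrows) digenic LD = gametic + nongametic digenic LD |
| `D_AB` | `P_AB − p_A p_B` | gametic LD, via the standard two-locus EM over haplotype frequencies |
| `D_AAB`, `D_ABB` | residual gene-triple association | composite trigenic disequilibria |
| `Δ_AABB` | residual four-gene association | composite quadrigenic disequilibrium |
| `ω_AABB` | `P_AABB − P_AA P_BB` | zygotic LD (double-homozygote deviation) |

These satisfy the exact decomposition

```
ω_AABB = 2 p_A D_ABB + 2 p_B D_AAB + 2 p_A p_B Δ_AB + Δ_AB² + Δ_AABB
```

and the quadrigenic estimator is defined by inverting this identity, so the
reconstruction holds to machine precision for any genotype table.

Each component is tested against zero with a 1-df chi-square: `X² = n·r²`
for the gametic, composite and zygotic statistics, and `X² = D̂²/Var(D̂)`
with a multinomial delta-method variance for the trigenic and quadrigenic
ones. Strength is reported as the generalized squared correlation
`φ² = X²/n`, which equals `r²` exactly for the 2×2-table statistics; φ²
values outside `[0, 1]` (possible for the higher-order tests) are filtered
and tallied. Genome scans aggregate pair results into distance bins, a
50 Mb linked/unlinked split (1 cM = 1 Mb), MAF classes and
power-vs-distance curves.

Because no suitable public genotype panel accompanies the method, the
package ships first-class synthetic generators — random union of gametes,
saturated 9-cell sampling, explicit multi-breed admixture with random
mating, and an ancestry-mosaic whole-genome model — all with exact known
truths computed by the package's own estimators in their
exact-population mode.

## A worked example

`python examples/worked_pair.py` analyses the fixture of 50 AABB + 50 aabb
animals and prints:

```
composite LD       Delta_AB  = 0.5
gametic LD (EM)    D_AB      = 0.25
trigenic           D_AAB     = 0.0
trigenic           D_ABB     = 0.0
quadrigenic        Delta_AABB= -0.25
zygotic LD         omega     = 0.25

component tests (X2 on 1 df, phi2 = X2/n):
  GLD     X2 =          100   phi2 =        1   significant = True
  ZLD     X2 =          100   phi2 =        1   significant = True
  CLD     X2 =          100   phi2 =        1   significant = True
  D_AAB   X2 =            0   phi2 =        0   significant = False
  D_ABB   X2 =            0   phi2 =        0   significant = False
```

The pair is perfectly associated (`φ² = 1` for the digenic and zygotic
tests, the maximum of the generalized squared correlation), and the
higher-order residuals are exactly zero: the association is entirely
digenic. `Δ_AABB = −0.25` is the value needed for the zygotic
decomposition above to reproduce `P_AABB = 0.5` exactly.

The other examples show the admixture signature with exact truths
(`examples/admixture_truths.py`), test calibration under the null
(`examples/null_calibration.py`) and the full QC → scan → summary pipeline
on a simulated composite genome (`examples/genome_scan.py`).

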