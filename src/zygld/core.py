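"""Single-locus and two-locus disequilibrium estimators for unphased biallelic SNPs.

All two-locus structure between a pair of unphased SNPs is contained in the
3x3 table of joint dosage classes (0, 1, 2 copies of the designated A allele
at locus A crossed with the same at locus B); the two double-heterozygote
phases are indistinguishable and occupy the single central cell.  Every
estimator here is the plug-in (method-of-moments) estimator: the defining
population identity evaluated on observed proportions.  Because the saturated
multinomial model has as many free parameters as degrees of freedom, these
plug-in estimates are also the maximum-likelihood estimates.

The decomposition estimated for a pair of loci:

* ``D_A = P_AA - p_A**2`` — Hardy-Weinberg disequilibrium at one locus,
  with fixation index ``f_A = D_A / (p_A * p_a)``.
* ``Delta_AB`` — composite (Burrows) digenic LD, the sum of the gametic and
  nongametic digenic disequilibria; equals half the dosage covariance.
* ``D_AAB``, ``D_ABB`` — composite trigenic disequilibria: residual
  association of a gene triple (two genes at one locus, one at the other)
  after removing allele-frequency products, HWD and digenic LD.
* ``Delta_AABB`` — composite quadrigenic disequilibrium: residual four-gene
  association, absorbing the product of gametic and nongametic digenic LD.
* ``omega_AABB`` — zygotic LD, the deviation of the double-homozygote
  frequency from the product of single-locus homozygote frequencies.  It
  decomposes exactly as

  ``omega = 2*p_A*D_ABB + 2*p_B*D_AAB + 2*p_A*p_B*Delta_AB + Delta_AB**2
  + Delta_AABB``

  and the quadrigenic estimator is defined by inverting this identity, so
  the reconstruction holds to machine precision for any table.
* gametic LD ``D_AB`` — estimated separately by EM over the four haplotype
  frequencies (:func:`em_gametic_ld`), the only estimator here that needs
  iteration because of the phase-ambiguous central cell.

Functions accept either observed counts (`TwoLocusCounts`) or an exact
9-cell probability table (n -> infinity mode), so simulated population
truths can be computed by the very same code path as the data estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1
"""Dosage code for a missing genotype call."""

_DOSE = np.arange(3.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSummary:
    """Single-locus allele-frequency and Hardy-Weinberg summaries.

    Attributes
    ----------
    p_A : frequency of the designated A allele.
    maf : minor allele frequency, ``min(p_A, 1 - p_A)``.
    P_AA : frequency of the AA homozygote.
    D_A : HWD measure, ``P_AA - p_A**2``.
    f_A : fixation index ``D_A / (p_A * (1 - p_A))``; ``nan`` at monomorphism.
    pi_A : heterozygosity term ``p_A * (1 - p_A)``.
    hwd_chisq : 1-df HWD chi-square ``n * f_A**2``; ``nan`` at monomorphism.
    n_called : number of animals with a non-missing call.
    """

    p_A: float
    maf: float
    P_AA: float
    D_A: float
    f_A: float
    pi_A: float
    hwd_chisq: float
    n_called: int

    @property
    def monomorphic(self) -> bool:
        return self.p_A in (0.0, 1.0)


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 joint unphased genotype counts for one marker pair.

    ``counts[x, y]`` is the number of animals with dosage ``x`` at locus A
    and dosage ``y`` at locus B, over animals called at both loci.  The two
    double-heterozygote phases are merged in ``counts[1, 1]``.  ``n`` may be
    the float 1.0 when the table holds exact population probabilities
    (n -> infinity mode).
    """

    counts: np.ndarray
    n: float

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (3, 3):
            raise ValueError(f"expected a 3x3 table, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_probs(cls, probs) -> "TwoLocusCounts":
        """Exact-population mode: a 9-cell probability table with n = 1."""
        p = np.asarray(probs, dtype=float).reshape(3, 3)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities sum to {p.sum()}, not 1")
        return cls(counts=p, n=1.0)

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.n


@dataclass
class PairDisequilibria:
    """All disequilibrium estimates for one marker pair (one scan row)."""

    delta_AB: float
    d_gametic: float
    d_AAB: float
    d_ABB: float
    delta_AABB: float
    omega_AABB: float
    r2_gld: float
    r2_cld: float
    r2_zld: float
    n: float
    haplotype_freqs: np.ndarray | None = None
    em_converged: bool = True
    em_flat: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# single locus
# ---------------------------------------------------------------------------

def genotype_counts(dosages) -> np.ndarray:
    """Counts of dosage classes 0, 1, 2 ignoring missing codes."""
    d = np.asarray(dosages)
    d = d[d != MISSING]
    return np.bincount(d.astype(np.intp), minlength=3)[:3]


def locus_summary(dosages) -> LocusSummary:
    """Plug-in single-locus summary from a dosage column (missing allowed).

    ``p_A = (2 n_2 + n_1) / 2n``, ``P_AA = n_2 / n``, ``D_A = P_AA - p_A**2``,
    ``f_A = D_A / (p_A p_a)`` and ``hwd_chisq = n f_A**2`` (the standard 1-df
    HWD chi-square).
    """
    counts = genotype_counts(dosages)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("all genotypes missing at this locus")
    p = (2 * counts[2] + counts[1]) / (2 * n)
    P_AA = counts[2] / n
    D = P_AA - p * p
    pi = p * (1 - p)
    if pi > 0:
        f = D / pi
        hwd = n * f * f
    else:
        f = float("nan")
        hwd = float("nan")
    return LocusSummary(
        p_A=float(p), maf=float(min(p, 1 - p)), P_AA=float(P_AA),
        D_A=float(D), f_A=float(f), pi_A=float(pi),
        hwd_chisq=float(hwd), n_called=n,
    )


def two_locus_counts(gm, i: int, j: int) -> TwoLocusCounts:
    """Cross-tabulate the 9 unphased classes for markers ``i`` and ``j``.

    Animals missing at either marker are excluded (pairwise-complete rule).
    ``gm`` is a :class:`~zygld.io.GenotypeMatrix` or a plain dosage array.
    """
    if i == j:
        raise ValueError("a pair requires two distinct markers")
    dosages = getattr(gm, "dosages", gm)
    a = np.asarray(dosages)[:, i]
    b = np.asarray(dosages)[:, j]
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no animal called at both markers {i} and {j}")
    idx = a[ok].astype(np.intp) * 3 + b[ok].astype(np.intp)
    counts = np.bincount(idx, minlength=9).reshape(3, 3)
    return TwoLocusCounts(counts=counts.astype(float), n=n)


# ---------------------------------------------------------------------------
# vectorised plug-in machinery (tables of shape (..., 3, 3))
# ---------------------------------------------------------------------------

def table_statistics(P) -> dict[str, np.ndarray]:
    """Every plug-in disequilibrium statistic from 9-cell proportion tables.

    Vectorised over leading dimensions: ``P`` has shape ``(..., 3, 3)`` with
    each trailing table summing to 1.  Returns a dict of arrays of shape
    ``(...)``.  This single function backs the scalar per-pair API, the
    genome scan, the delta-method variance engine (which differentiates it
    numerically) and the exact-population truth computations.
    """
    P = np.asarray(P, dtype=float)
    PA = P.sum(axis=-1)          # (..., 3) marginal at locus A
    PB = P.sum(axis=-2)
    pA = PA[..., 2] + 0.5 * PA[..., 1]
    pB = PB[..., 2] + 0.5 * PB[..., 1]
    P_AA = PA[..., 2]
    P_BB = PB[..., 2]
    D_A = P_AA - pA * pA
    D_B = P_BB - pB * pB
    pi_A = pA * (1 - pA)
    pi_B = pB * (1 - pB)

    # composite digenic LD: E[XY]/2 - 2 pA pB  (= half the dosage covariance)
    exy = np.einsum("...xy,x,y->...", P, _DOSE, _DOSE)
    delta_AB = exy / 2 - 2 * pA * pB

    # trigenic gene-triple frequencies and residual trigenic disequilibria
    P_AAB = np.einsum("...y,y->...", P[..., 2, :], _DOSE) / 2
    P_ABB = np.einsum("...x,x->...", P[..., :, 2], _DOSE) / 2
    d_AAB = P_AAB - pA * pA * pB - pB * D_A - pA * delta_AB
    d_ABB = P_ABB - pA * pB * pB - pA * D_B - pB * delta_AB

    # quadrigenic by exact inversion of the AABB zygotic identity
    P_AABB = P[..., 2, 2]
    omega = P_AABB - P_AA * P_BB
    delta_AABB = (omega - 2 * pA * d_ABB - 2 * pB * d_AAB
                  - 2 * pA * pB * delta_AB - delta_AB ** 2)

    return {
        "p_A": pA, "p_B": pB, "P_AA": P_AA, "P_BB": P_BB,
        "D_A": D_A, "D_B": D_B, "pi_A": pi_A, "pi_B": pi_B,
        "delta_AB": delta_AB, "d_AAB": d_AAB, "d_ABB": d_ABB,
        "delta_AABB": delta_AABB, "omega_AABB": omega,
        "P_AAB": P_AAB, "P_ABB": P_ABB, "P_AABB": P_AABB,
    }


def reconstruct_P_AABB(stats: dict[str, np.ndarray]) -> np.ndarray:
    """Rebuild the AABB cell from the estimated components.

    ``P_AABB = P_AA P_BB + 2 pA D_ABB + 2 pB D_AAB + 2 pA pB Delta_AB
    + Delta_AB**2 + Delta_AABB`` — the forward direction of the identity the
    quadrigenic estimator inverts; used as an algebraic self-check.
    """
    s = stats
    return (s["P_AA"] * s["P_BB"] + 2 * s["p_A"] * s["d_ABB"]
            + 2 * s["p_B"] * s["d_AAB"] + 2 * s["p_A"] * s["p_B"] * s["delta_AB"]
            + s["delta_AB"] ** 2 + s["delta_AABB"])


# ---------------------------------------------------------------------------
# scalar per-pair API
# ---------------------------------------------------------------------------

def composite_ld(c: TwoLocusCounts,
                 locusA: LocusSummary | None = None,
                 locusB: LocusSummary | None = None) -> float:
    """Composite digenic LD Delta_AB = sum x*y*n[x,y] / 2n - 2 pA pB."""
    s = table_statistics(c.probs)
    _require_polymorphic(s)
    return float(s["delta_AB"])


def trigenic_disequilibria(c: TwoLocusCounts,
                           locusA: LocusSummary | None = None,
                           locusB: LocusSummary | None = None,
                           delta_AB: float | None = None) -> tuple[float, float]:
    """Composite trigenic disequilibria (D_AAB, D_ABB)."""
    s = table_statistics(c.probs)
    _require_polymorphic(s)
    return float(s["d_AAB"]), float(s["d_ABB"])


def quadrigenic_disequilibrium(c: TwoLocusCounts, parts=None) -> float:
    """Composite quadrigenic disequilibrium Delta_AABB."""
    s = table_statistics(c.probs)
    _require_polymorphic(s)
    return float(s["delta_AABB"])


def zygotic_ld(c: TwoLocusCounts) -> tuple[float, float]:
    """Zygotic LD omega_AABB and its 2x2 squared correlation r2_ZLD.

    ``omega = P_AABB - P_AA P_BB``; ``r2_ZLD`` is the squared correlation of
    the AA-vs-rest x BB-vs-rest indicator table,
    ``omega**2 / [P_AA (1-P_AA) P_BB (1-P_BB)]``.
    """
    s = table_statistics(c.probs)
    varA = s["P_AA"] * (1 - s["P_AA"])
    varB = s["P_BB"] * (1 - s["P_BB"])
    if varA <= 0 or varB <= 0:
        raise ValueError("degenerate homozygote margin: r2_ZLD undefined")
    return float(s["omega_AABB"]), float(s["omega_AABB"] ** 2 / (varA * varB))


def r2_cld(c: TwoLocusCounts) -> float:
    """Squared dosage correlation Delta**2 / [(pi_A + D_A)(pi_B + D_B)]."""
    s = table_statistics(c.probs)
    denom = (s["pi_A"] + s["D_A"]) * (s["pi_B"] + s["D_B"])
    if denom <= 0:
        raise ValueError("degenerate dosage variance: r2_CLD undefined")
    return float(s["delta_AB"] ** 2 / denom)


def _require_polymorphic(s) -> None:
    if s["pi_A"] == 0 or s["pi_B"] == 0:
        raise ValueError("monomorphic locus: pair disequilibria undefined")


# ---------------------------------------------------------------------------
# EM for gametic LD
# ---------------------------------------------------------------------------

def em_gametic_ld(c: TwoLocusCounts, tol: float = 1e-10, max_iter: int = 1000):
    """EM estimate of the gametic LD D_AB from unphased counts.

    Only the double-heterozygote cell is phase-ambiguous; the EM iterates the
    four haplotype frequencies (AB, Ab, aB, ab), initialised at linkage
    equilibrium (products of the observed allele frequencies), assigning the
    central cell to the coupling phase with posterior weight
    ``h_AB h_ab / (h_AB h_ab + h_Ab h_aB)``.  Convergence: max absolute
    haplotype-frequency change < ``tol``.

    Returns ``(haplotype_freqs, D_AB, r2_GLD, info)`` with
    ``haplotype_freqs = [h_AB, h_Ab, h_aB, h_ab]`` and ``info`` carrying
    ``converged``, ``flat`` (all-double-heterozygote input, where the
    likelihood is flat in phase and the equilibrium start is stationary:
    D is reported as 0) and ``n_iter``.

    The allele frequencies are invariants of the iteration, so
    ``D_AB = h_AB - p_A p_B`` and ``r2_GLD = D_AB**2 / (p_A p_a p_B p_b)``.
    """
    h, D, r2, conv, flat, it = em_gametic_ld_batch(
        c.probs[None, :, :], tol=tol, max_iter=max_iter)
    info = {"converged": bool(conv[0]), "flat": bool(flat[0]),
            "n_iter": int(it)}
    if flat[0]:
        D[0] = 0.0
        r2[0] = 0.0
    return h[0], float(D[0]), float(r2[0]), info


def em_gametic_ld_batch(P, tol: float = 1e-10, max_iter: int = 1000):
    """Vectorised two-locus EM over a batch of proportion tables.

    ``P`` has shape ``(k, 3, 3)``; returns haplotype frequencies ``(k, 4)``
    in order (AB, Ab, aB, ab), D_AB, r2_GLD, a convergence mask, a
    flat-likelihood mask and the number of iterations run.
    """
    P = np.asarray(P, dtype=float)
    s = table_statistics(P)
    pA, pB = s["p_A"], s["p_B"]
    # fixed haplotype contributions from the eight unambiguous cells, as
    # proportions of the 2 gametes per individual
    fAB = (2 * P[:, 2, 2] + P[:, 2, 1] + P[:, 1, 2]) / 2
    fAb = (2 * P[:, 2, 0] + P[:, 2, 1] + P[:, 1, 0]) / 2
    faB = (2 * P[:, 0, 2] + P[:, 0, 1] + P[:, 1, 2]) / 2
    fab = (2 * P[:, 0, 0] + P[:, 0, 1] + P[:, 1, 0]) / 2
    # a double heterozygote carries one coupling pair (AB + ab) or one
    # repulsion pair (Ab + aB): each phase contributes one gamete of each
    # type, i.e. half the cell's gamete share per haplotype class
    dh = P[:, 1, 1] / 2

    h = np.stack([pA * pB, pA * (1 - pB), (1 - pA) * pB,
                  (1 - pA) * (1 - pB)], axis=1)
    converged = np.zeros(len(P), dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        coup = h[:, 0] * h[:, 3]
        rep = h[:, 1] * h[:, 2]
        tot = coup + rep
        w = np.where(tot > 0, coup / np.where(tot > 0, tot, 1.0), 0.5)
        new = np.stack([fAB + dh * w, fAb + dh * (1 - w),
                        faB + dh * (1 - w), fab + dh * w], axis=1)
        delta = np.abs(new - h).max(axis=1)
        h = new
        converged |= delta < tol
        if converged.all():
            break
    flat = (P[:, 1, 1] > 0) & np.isclose(P[:, 1, 1], P.sum(axis=(1, 2)))
    D = h[:, 0] - pA * pB
    denom = s["pi_A"] * s["pi_B"]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, D * D / np.where(denom > 0, denom, 1.0),
                      np.nan)
    return h, D, r2, converged, flat, it


# ---------------------------------------------------------------------------
# one-call pair estimation
# ---------------------------------------------------------------------------

def pair_disequilibria(c: TwoLocusCounts, tol: float = 1e-10,
                       max_iter: int = 1000) -> PairDisequilibria:
    """All disequilibrium estimates (composite, trigenic, quadrigenic,
    zygotic, EM-gametic) for one counts table."""
    s = table_statistics(c.probs)
    _require_polymorphic(s)
    h, d_gam, r2g, info = em_gametic_ld(c, tol=tol, max_iter=max_iter)
    varA = s["P_AA"] * (1 - s["P_AA"])
    varB = s["P_BB"] * (1 - s["P_BB"])
    r2z = float(s["omega_AABB"] ** 2 / (varA * varB)) if varA > 0 and varB > 0 else float("nan")
    denom = (s["pi_A"] + s["D_A"]) * (s["pi_B"] + s["D_B"])
    r2c = float(s["delta_AB"] ** 2 / denom) if denom > 0 else float("nan")
    flags = []
    if not info["converged"]:
        flags.append("em_nonconvergence")
    if info["flat"]:
        flags.append("flat_likelihood")
    return PairDisequilibria(
        delta_AB=float(s["delta_AB"]), d_gametic=d_gam,
        d_AAB=float(s["d_AAB"]), d_ABB=float(s["d_ABB"]),
        delta_AABB=float(s["delta_AABB"]), omega_AABB=float(s["omega_AABB"]),
        r2_gld=r2g, r2_cld=r2c, r2_zld=r2z, n=c.n,
        haplotype_freqs=h, em_converged=info["converged"],
        em_flat=info["flat"], flags=flags,
    )
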