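"""Synthetic genotype panels with known disequilibrium structure.

Four generators, from controlled to realistic:

* :func:`simulate_rug` — one marker pair under random union of gametes from
  given haplotype frequencies.  All nongametic, trigenic and quadrigenic
  terms are exactly zero in the population, and the composite LD equals the
  gametic LD: the canonical null / reduction fixture.
* :func:`simulate_cell_probs` — multinomial sampling from an arbitrary
  9-cell genotype table (saturated model), for estimator sampling tests.
* :func:`simulate_admixture` — a Wahlund-type composite population: founders
  drawn from breed-specific Hardy-Weinberg populations, then a given number
  of generations of random mating with recombination at
  ``min(0.5, distance_bp * 1e-8)`` (the 1 cM = 1 Mb equivalence).  The exact
  population truth per pair is tracked analytically through the generations.
* :func:`simulate_genome` — a whole-genome panel emulating a composite beef
  population: per-individual admixture proportions (Wahlund HWD and
  chromosome-spanning admixture LD) and ancestry blocks along chromosomes
  whose length scale varies between haplotypes, producing gametic LD that
  decays smoothly with physical distance like the classic
  ``1 / (1 + d/s)``-shaped curves seen in livestock panels.

Every truth value is computed by the package's own estimators applied to
exact population frequencies (the plug-in identity), never by separate
formulas, so generator and estimator can never drift apart silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import MISSING, table_statistics
from .io import GenotypeMatrix

RECOMB_PER_BP = 1e-8  # 1 cM / Mb


@dataclass(frozen=True)
class SimulationSpec:
    """Reproducible description of one generator run."""

    mode: str
    n_animals: int
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


@dataclass(frozen=True)
class PopulationTruth:
    """Exact parameter values for one simulated marker pair."""

    p_A: float
    p_B: float
    D_A: float
    D_B: float
    delta_AB: float
    d_gametic: float
    d_AAB: float
    d_ABB: float
    delta_AABB: float
    omega_AABB: float

    @classmethod
    def from_probs(cls, probs, d_gametic: float) -> "PopulationTruth":
        s = table_statistics(np.asarray(probs, dtype=float))
        return cls(p_A=float(s["p_A"]), p_B=float(s["p_B"]),
                   D_A=float(s["D_A"]), D_B=float(s["D_B"]),
                   delta_AB=float(s["delta_AB"]), d_gametic=float(d_gametic),
                   d_AAB=float(s["d_AAB"]), d_ABB=float(s["d_ABB"]),
                   delta_AABB=float(s["delta_AABB"]),
                   omega_AABB=float(s["omega_AABB"]))


def _check_probs(p, k):
    p = np.asarray(p, dtype=float).ravel()
    if p.size != k or (p < 0).any() or abs(p.sum() - 1) > 1e-12:
        raise ValueError(f"need {k} non-negative probabilities summing to 1")
    return p


def rug_genotype_probs(haplotype_freqs) -> np.ndarray:
    """Exact 9-cell genotype table under random union of gametes.

    ``haplotype_freqs`` ordered (AB, Ab, aB, ab).
    """
    h = _check_probs(haplotype_freqs, 4)
    a = np.array([1, 1, 0, 0])  # A-allele indicator per haplotype
    b = np.array([1, 0, 1, 0])
    P = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            P[a[i] + a[j], b[i] + b[j]] += h[i] * h[j]
    return P


def simulate_rug(haplotype_freqs, n: int, seed=None, rng=None):
    """Random union of gametes for one marker pair.

    2n gametes are drawn i.i.d. from the four haplotype frequencies
    (AB, Ab, aB, ab), shuffled and paired into n zygotes.  Returns
    ``(GenotypeMatrix, PopulationTruth)``; the truth has all nongametic and
    higher-order terms zero and ``delta_AB = D_gametic``.
    """
    h = _check_probs(haplotype_freqs, 4)
    rng = np.random.default_rng(seed) if rng is None else rng
    gametes = rng.choice(4, size=2 * n, p=h)
    rng.shuffle(gametes)
    g1, g2 = gametes[:n], gametes[n:]
    a = np.array([1, 1, 0, 0], dtype=np.int8)
    b = np.array([1, 0, 1, 0], dtype=np.int8)
    dosages = np.stack([a[g1] + a[g2], b[g1] + b[g2]], axis=1)
    gm = GenotypeMatrix([f"ind{i}" for i in range(n)], ["M1", "M2"], dosages)
    pA = h[0] + h[1]
    pB = h[0] + h[2]
    truth = PopulationTruth.from_probs(rug_genotype_probs(h),
                                       d_gametic=h[0] - pA * pB)
    return gm, truth


def simulate_cell_probs(cell_probs, n: int, seed=None, rng=None):
    """Multinomial sample of n animals from a 9-cell genotype table."""
    p = _check_probs(cell_probs, 9)
    rng = np.random.default_rng(seed) if rng is None else rng
    counts = rng.multinomial(n, p)
    classes = np.repeat(np.arange(9), counts)
    rng.shuffle(classes)
    dosages = np.stack([classes // 3, classes % 3], axis=1).astype(np.int8)
    gm = GenotypeMatrix([f"ind{i}" for i in range(n)], ["M1", "M2"], dosages)
    P = p.reshape(3, 3)
    # gametic LD is not identified from a genotype table without phase
    # information, so the gametic slot of the truth is left undefined
    truth = PopulationTruth.from_probs(P, d_gametic=float("nan"))
    return gm, truth


def sample_cell_tables(cell_probs, n: int, n_reps: int, seed=None, rng=None):
    """Vectorised multinomial replicate tables: shape (n_reps, 3, 3)."""
    p = _check_probs(cell_probs, 9)
    rng = np.random.default_rng(seed) if rng is None else rng
    return rng.multinomial(n, p, size=n_reps).reshape(n_reps, 3, 3).astype(float)


# ---------------------------------------------------------------------------
# explicit admixture with random mating
# ---------------------------------------------------------------------------

def admixture_genotype_probs(freqs_A, freqs_B, weights) -> np.ndarray:
    """Exact generation-0 9-cell table for a mixture of HWE breeds.

    ``freqs_A[k]``, ``freqs_B[k]`` are breed k's A-allele frequencies at the
    two loci (loci independent within breed); ``weights`` the breed mixing
    proportions.
    """
    fa = np.asarray(freqs_A, float)
    fb = np.asarray(freqs_B, float)
    w = _check_probs(weights, len(fa))
    x = np.arange(3)
    binA = np.stack([(1 - fa) ** 2, 2 * fa * (1 - fa), fa ** 2], axis=1)
    binB = np.stack([(1 - fb) ** 2, 2 * fb * (1 - fb), fb ** 2], axis=1)
    return np.einsum("k,kx,ky->xy", w, binA, binB)


def admixture_pair_truth(freqs_A, freqs_B, weights, generations: int,
                         recomb: float) -> PopulationTruth:
    """Exact truth for one pair after g generations of random mating.

    Generation 0 is the breed mixture (Wahlund HWD, nonzero trigenic and
    quadrigenic terms).  Founder gametes have haplotype frequencies
    ``sum_k w_k p_kA p_kB`` (loci independent within breed, so recombination
    in founders changes nothing); every later generation is a random union
    of gametes, whose gametic LD decays by (1 - r) per generation while all
    nongametic terms are zero.
    """
    fa = np.asarray(freqs_A, float)
    fb = np.asarray(freqs_B, float)
    w = _check_probs(weights, len(fa))
    if generations == 0:
        P = admixture_genotype_probs(fa, fb, w)
        # unphased founders: gametic share of the composite LD equals the
        # between-breed allele covariance (within-breed haplotypes are
        # independent, both of an individual's haplotypes come from its breed)
        pA, pB = w @ fa, w @ fb
        d_gam = float(w @ (fa * fb) - pA * pB)
        return PopulationTruth.from_probs(P, d_gametic=d_gam)
    pA, pB = w @ fa, w @ fb
    d1 = float(w @ (fa * fb) - pA * pB)
    d = d1 * (1 - recomb) ** (generations - 1)
    h = np.array([pA * pB + d, pA * (1 - pB) - d,
                  (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d])
    return PopulationTruth.from_probs(rug_genotype_probs(h), d_gametic=d)


def simulate_admixture(breed_profiles, weights, generations: int, n: int,
                       seed=None, rng=None, marker_map: pd.DataFrame | None = None):
    """Individual-based composite population for a set of markers.

    ``breed_profiles`` is a (n_breeds, n_markers) array of A-allele
    frequencies.  Generation 0: each founder's breed is drawn from
    ``weights`` and both haplotypes sampled from that breed's HWE
    frequencies (loci independent within breed).  Each later generation is
    formed by random union of gametes from random parents, with
    recombination between adjacent syntenic markers at
    ``min(0.5, distance_bp * 1e-8)``; markers on different chromosomes (or
    with no map) recombine freely.

    Returns ``(GenotypeMatrix, marker_map, truths)`` where ``truths`` maps
    each marker index pair to its exact :class:`PopulationTruth`.
    """
    profiles = np.atleast_2d(np.asarray(breed_profiles, dtype=float))
    n_breeds, m = profiles.shape
    if n_breeds < 2:
        raise ValueError("need at least two breeds")
    w = _check_probs(weights, n_breeds)
    rng = np.random.default_rng(seed) if rng is None else rng

    if marker_map is None:
        marker_map = pd.DataFrame({
            "marker_id": [f"M{j + 1}" for j in range(m)],
            "chromosome": [str(j + 1) for j in range(m)],
            "position_bp": np.zeros(m, dtype=np.int64),
        })
    if len(marker_map) != m:
        raise ValueError("marker_map length does not match breed profiles")

    # per-interval recombination fractions in map order
    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    r = np.full(m, 0.5)
    r[0] = 0.5
    same = chrom[1:] == chrom[:-1]
    r[1:][same] = np.minimum(0.5, np.abs(pos[1:] - pos[:-1])[same] * RECOMB_PER_BP)

    breed = rng.choice(n_breeds, size=n, p=w)
    hap = rng.random((n, 2, m)) < profiles[breed][:, None, :]
    for _ in range(generations):
        hap = _random_mating(hap, r, rng)
    dosages = hap.sum(axis=1).astype(np.int8)
    gm = GenotypeMatrix([f"ind{i}" for i in range(n)],
                        marker_map["marker_id"].tolist(), dosages)

    truths = {}
    for i in range(m):
        for j in range(i + 1, m):
            if chrom[i] != chrom[j]:
                rij = 0.5
            else:
                # exact two-locus recombination fraction of the per-interval
                # crossover process: P(odd number of switches)
                rij = (1 - np.prod(1 - 2 * r[i + 1:j + 1])) / 2
            truths[(i, j)] = admixture_pair_truth(
                profiles[:, i], profiles[:, j], w, generations, rij)
    return gm, marker_map, truths


def _random_mating(hap, r, rng):
    """One generation of random union of recombinant gametes.

    ``hap``: (n, 2, m) boolean haplotypes; ``r``: per-marker switch
    probability from the previous marker (0.5 at chromosome starts).
    """
    n, _, m = hap.shape
    out = np.empty_like(hap)
    for gamete in range(2):
        parents = rng.integers(n, size=n)
        switch = rng.random((n, m)) < r
        switch[:, 0] = rng.random(n) < 0.5
        source = (np.cumsum(switch, axis=1) % 2).astype(np.intp)
        out[:, gamete, :] = np.take_along_axis(
            hap[parents], source[:, None, :], axis=1)[:, 0, :]
    return out


# ---------------------------------------------------------------------------
# whole-genome composite-population panel
# ---------------------------------------------------------------------------

def simulate_genome(chromosome_lengths_bp, markers_per_chrom, n: int,
                    decay_scale_bp: float = 100_000.0,
                    weights=(0.8, 0.2), admixture_concentration: float = 3.0,
                    breed_freq_range=(0.8, 0.95),
                    missing_rate: float = 0.0,
                    seed=None, rng=None):
    """Genome-scale panel from an ancestry-mosaic composite population.

    Model: two (or more) founder breeds; the first two are strongly
    differentiated, with the first breed's A-allele frequency drawn per
    marker from ``breed_freq_range`` and the second's mirrored (1 minus it),
    as for an ancestry-informative marker set; further breeds draw
    independently.  Each individual carries an admixture proportion
    ``q_i ~ Dirichlet(concentration * weights)`` shared by both of its
    haplotypes — between-individual variation in q produces Wahlund-type
    HWD and admixture LD that spans chromosomes, as expected in a
    population under continued crossbreeding.  Along each chromosome a
    haplotype is a mosaic of breed-ancestry blocks: the ancestry state is
    redrawn from ``q_i`` between adjacent markers with probability
    ``1 - exp(-u * d / decay_scale_bp)`` where ``u ~ Exponential(1)`` per
    haplotype.  The exponential mixing over block scales ``u`` represents
    haplotypes of different effective pedigree depths and integrates to a
    long-tailed, Sved-like LD decay in distance rather than a single
    exponential.

    Returns ``(GenotypeMatrix, marker_map)``.  Marker positions are uniform
    per chromosome; ``missing_rate`` masks calls at random.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    lengths = list(chromosome_lengths_bp)
    if np.isscalar(markers_per_chrom):
        markers_per_chrom = [int(markers_per_chrom)] * len(lengths)
    w = _check_probs(weights, len(weights))
    k = len(w)

    q = rng.dirichlet(admixture_concentration * w, size=n)  # (n, k)
    lo, hi = breed_freq_range

    marker_rows = []
    dosage_cols = []
    for c, (length, m) in enumerate(zip(lengths, markers_per_chrom), start=1):
        pos = np.sort(rng.integers(0, length, size=m))
        freqs = rng.uniform(1 - hi, hi, size=(k, m))
        freqs[0] = rng.uniform(lo, hi, size=m)
        if k > 1:
            freqs[1] = 1 - freqs[0]
        d = np.diff(pos, prepend=pos[0]).astype(float)

        hap_dosage = np.zeros((n, m), dtype=np.int8)
        for _ in range(2):
            u = rng.standard_exponential(n)          # per-haplotype block scale
            switch_p = 1 - np.exp(-np.outer(u, d) / decay_scale_bp)
            switch_p[:, 0] = 1.0                     # fresh draw at chrom start
            cum_q = np.cumsum(q, axis=1)
            state = np.zeros(n, dtype=np.intp)
            alleles = np.empty((n, m), dtype=bool)
            for jm in range(m):
                redraw = rng.random(n) < switch_p[:, jm]
                if redraw.any():
                    draw = (rng.random(n)[:, None] < cum_q).argmax(axis=1)
                    state = np.where(redraw, draw, state)
                alleles[:, jm] = rng.random(n) < freqs[state, jm]
            hap_dosage += alleles
        if missing_rate > 0:
            mask = rng.random((n, m)) < missing_rate
            hap_dosage[mask] = MISSING
        dosage_cols.append(hap_dosage)
        for jm in range(m):
            marker_rows.append((f"c{c}m{jm + 1}", str(c), int(pos[jm])))

    dosages = np.concatenate(dosage_cols, axis=1)
    marker_map = pd.DataFrame(marker_rows, columns=["marker_id", "chromosome",
                                                    "position_bp"])
    gm = GenotypeMatrix([f"ind{i}" for i in range(n)],
                        marker_map["marker_id"].tolist(), dosages)
    return gm, marker_map
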