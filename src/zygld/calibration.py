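"""Null calibration of the pair tests: rejection rates when no LD exists.

Under a true null hypothesis the "power" of a test is its significance
level, so the empirical rejection rate of each component test over many
independent marker pairs simulated with zero disequilibrium should sit at
alpha.  The null populations here are formed by random union of gametes
from linkage-equilibrium haplotype frequencies — Hardy-Weinberg and linkage
equilibrium hold exactly, so every disequilibrium parameter is zero.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .core import table_statistics, two_locus_counts
from .simulate import simulate_rug


def rug_null_rejection_rates(n_pairs: int = 2000, n: int = 1023,
                             maf_range=(0.05, 0.5), alpha: float = 0.05,
                             seed=None, rng=None) -> dict:
    """Empirical rejection rates of the CLD and ZLD tests under the null.

    For each pair, allele frequencies are drawn uniformly from
    ``maf_range`` at both loci, 2n gametes are drawn from the
    linkage-equilibrium haplotype frequencies and paired at random, and the
    composite-LD statistic ``n * r2_CLD`` and zygotic-LD statistic
    ``n * r2_ZLD`` (2x2 double-homozygote collapse) are referred to the
    1-df chi-square critical value.

    Returns a dict with per-component rejection rates, the numbers of
    defined tests, and the binomial standard error at alpha.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    crit = float(sps.chi2.ppf(1 - alpha, df=1))
    rejections = {"CLD": 0, "ZLD": 0}
    defined = {"CLD": 0, "ZLD": 0}
    for _ in range(n_pairs):
        pA, pB = rng.uniform(*maf_range, size=2)
        h = [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
        gm, _ = simulate_rug(h, n, rng=rng)
        c = two_locus_counts(gm, 0, 1)
        s = table_statistics(c.probs)
        denom_c = (s["pi_A"] + s["D_A"]) * (s["pi_B"] + s["D_B"])
        if denom_c > 0:
            defined["CLD"] += 1
            if c.n * s["delta_AB"] ** 2 / denom_c > crit:
                rejections["CLD"] += 1
        denom_z = (s["P_AA"] * (1 - s["P_AA"]) * s["P_BB"] * (1 - s["P_BB"]))
        if denom_z > 0:
            defined["ZLD"] += 1
            if c.n * s["omega_AABB"] ** 2 / denom_z > crit:
                rejections["ZLD"] += 1
    out = {
        "alpha": alpha,
        "n_pairs": n_pairs,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_pairs)),
    }
    for comp in ("CLD", "ZLD"):
        out[f"rate_{comp}"] = rejections[comp] / defined[comp]
        out[f"n_defined_{comp}"] = defined[comp]
    return out
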