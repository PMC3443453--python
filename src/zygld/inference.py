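"""Hypothesis tests for disequilibria: variances, chi-square, phi2, power.

Each disequilibrium estimate ``D`` is tested against H0: D = 0 with
``X2 = D**2 / Var(D)``, referred to a 1-df chi-square.  For the three
measures with a natural squared correlation (gametic, composite and zygotic
LD) the equivalent form ``X2 = n * r2`` is used directly.  Strength is
expressed as the generalized squared correlation ``phi2 = X2 / n``, which
equals r2 exactly only for the 2x2-table statistics (GLD, ZLD); for the
composite test the identity ``n Delta**2 / [(pi_A + D_A)(pi_B + D_B)] =
n r2_CLD`` makes the two routes coincide as well.  phi2 for the trigenic and
quadrigenic tests has no exact r2 interpretation and can fall outside
[0, 1]; such pairs are tallied and removed by :func:`oob_filter` before any
strength or power summary.

Sampling variances default to the generic multinomial delta method: for a
statistic ``T`` that is a smooth function of the 9 cell proportions,
``Var(T) ~= g' Sigma g`` with ``g`` the gradient of ``T`` in the cell
proportions (central differences) and ``Sigma`` the multinomial covariance
``Sigma_kl = (delta_kl p_k - p_k p_l) / n``.  This quadratic form is
non-negative, so delta-method phi2 values are never below zero; closed-form
variance expressions can be supplied through the ``variance_fn`` hook and,
if negative, propagate to phi2 < 0 where they are counted by the
out-of-bound filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import TwoLocusCounts, table_statistics, em_gametic_ld_batch

#: 95th percentile of the 1-df chi-square; the scan-wide critical value.
CHI2_CRIT_95: float = float(sps.chi2.ppf(0.95, df=1))

#: Components tested for every marker pair.
COMPONENTS = ("GLD", "CLD", "ZLD", "D_AAB", "D_ABB", "D_AABB")

# statistics differentiable by the delta-method engine, as keys into
# table_statistics output
_STAT_KEYS = {
    "delta_AB": "delta_AB",
    "d_AAB": "d_AAB",
    "d_ABB": "d_ABB",
    "delta_AABB": "delta_AABB",
    "omega_AABB": "omega_AABB",
    "p_A": "p_A",
    "p_B": "p_B",
    "D_A": "D_A",
    "D_B": "D_B",
}


@dataclass
class TestResult:
    """One component's test for one marker pair."""

    __test__ = False  # not a pytest class, despite the name

    component: str
    estimate: float
    variance: float
    chisq: float
    phi2: float
    significant: bool
    oob_status: str  # "in-range" | "below-zero" | "above-one"


@dataclass
class PowerResult:
    """Empirical rejection rate over a set of defined, in-bound tests."""

    power: float
    n_used: int
    n_excluded: int


def _oob_status(phi2: float) -> str:
    if np.isnan(phi2):
        return "undefined"
    if phi2 < 0:
        return "below-zero"
    if phi2 > 1:
        return "above-one"
    return "in-range"


# ---------------------------------------------------------------------------
# delta-method variance engine
# ---------------------------------------------------------------------------

def delta_variance(statistic, c: TwoLocusCounts, step: float = 1e-6) -> float:
    """Large-sample variance of a statistic of the 9 cell proportions.

    ``statistic`` is a key of :func:`~zygld.core.table_statistics` (e.g.
    ``"delta_AB"``, ``"d_AAB"``, ``"delta_AABB"``, ``"p_A"``) or any callable
    mapping a (..., 3, 3) proportion table to a scalar per table.
    """
    if c.n < 2:
        raise ValueError("delta-method variance needs n >= 2")
    P = c.probs
    if callable(statistic):
        fn = statistic
    else:
        key = _STAT_KEYS[statistic]
        fn = lambda tbl: table_statistics(tbl)[key]  # noqa: E731
    g = _gradient(fn, P, step)
    return float(_quadratic_form(g[None, :], P.reshape(1, 9), c.n)[0])


def delta_variance_batch(P, n, names=("delta_AB", "d_AAB", "d_ABB", "delta_AABB"),
                         step: float = 1e-6) -> dict[str, np.ndarray]:
    """Delta-method variances for several statistics over a batch of tables.

    ``P`` has shape (k, 3, 3); ``n`` is scalar or shape (k,).  One pass of
    18 perturbed evaluations of :func:`table_statistics` yields the
    gradients of all requested statistics simultaneously.
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    pert = np.tile(P, (9, 2, 1, 1, 1))      # (9, 2, k, 3, 3)
    eye = np.eye(9).reshape(9, 3, 3) * step
    pert[:, 0] += eye[:, None]
    pert[:, 1] -= eye[:, None]
    stats = table_statistics(pert)          # each value: (9, 2, k)
    flat = P.reshape(k, 9)
    out = {}
    for name in names:
        key = _STAT_KEYS[name]
        v = stats[key]
        g = ((v[:, 0] - v[:, 1]) / (2 * step)).T   # (k, 9)
        out[name] = _quadratic_form(g, flat, n)
    return out


def _gradient(fn, P, step):
    pert = np.tile(P, (9, 2, 1, 1))         # (9, 2, 3, 3)
    eye = np.eye(9).reshape(9, 3, 3) * step
    pert[:, 0] += eye
    pert[:, 1] -= eye
    v = np.asarray(fn(pert), dtype=float)   # (9, 2)
    return (v[:, 0] - v[:, 1]) / (2 * step)


def _quadratic_form(g, p_flat, n):
    """g' Sigma g with multinomial Sigma_kl = (delta_kl p_k - p_k p_l)/n."""
    gp = (g * p_flat).sum(axis=1)
    return ((g * g * p_flat).sum(axis=1) - gp * gp) / np.asarray(n, float)


# ---------------------------------------------------------------------------
# chi-square tests
# ---------------------------------------------------------------------------

def component_chisq(pair, c: TwoLocusCounts, method: str = "r2",
                    alpha: float = 0.05, gld_n: str = "animals",
                    variance_fn=None) -> dict[str, TestResult]:
    """1-df chi-square tests for every disequilibrium component of a pair.

    GLD and ZLD use ``X2 = n r2`` (their statistics arise from 2x2 tables);
    CLD uses ``X2 = n Delta**2 / [(pi_A + D_A)(pi_B + D_B)]`` which equals
    ``n r2_CLD``; trigenic and quadrigenic use ``X2 = D**2 / Var(D)`` with
    the delta-method variance.  ``method="variance"`` routes the CLD test
    through the variance engine instead (the two agree to the large-sample
    approximation).  ``gld_n="gametes"`` counts 2n gametes rather than n
    animals in the GLD statistic.  ``variance_fn(name, counts) -> float``
    overrides the variance engine (closed-form plug-in slot); negative
    values are kept and surface as phi2 < 0.

    ``pair`` is a :class:`~zygld.core.PairDisequilibria`.
    """
    n = c.n
    crit = float(sps.chi2.ppf(1 - alpha, df=1))
    res: dict[str, TestResult] = {}

    n_gld = 2 * n if gld_n == "gametes" else n
    for comp, est, r2, n_eff in (("GLD", pair.d_gametic, pair.r2_gld, n_gld),
                                 ("ZLD", pair.omega_AABB, pair.r2_zld, n)):
        chisq = n_eff * r2 if not np.isnan(r2) else float("nan")
        phi2 = chisq / n if not np.isnan(chisq) else float("nan")
        res[comp] = TestResult(comp, est, float("nan"), chisq, phi2,
                               bool(chisq > crit), _oob_status(phi2))

    def _var(name):
        if variance_fn is not None:
            return float(variance_fn(name, c))
        return delta_variance(name, c)

    if method == "variance":
        var = _var("delta_AB")
        chisq = pair.delta_AB ** 2 / var if var > 0 else float("nan")
    else:
        var = float("nan")
        chisq = n * pair.r2_cld if not np.isnan(pair.r2_cld) else float("nan")
    phi2 = chisq / n if not np.isnan(chisq) else float("nan")
    res["CLD"] = TestResult("CLD", pair.delta_AB, var, chisq, phi2,
                            bool(chisq > crit), _oob_status(phi2))

    for comp, name, est in (("D_AAB", "d_AAB", pair.d_AAB),
                            ("D_ABB", "d_ABB", pair.d_ABB),
                            ("D_AABB", "delta_AABB", pair.delta_AABB)):
        var = _var(name)
        chisq = est * est / var if var != 0 else float("nan")
        phi2 = chisq / n if not np.isnan(chisq) else float("nan")
        res[comp] = TestResult(comp, est, var, chisq, phi2,
                               bool(chisq > crit), _oob_status(phi2))
    return res


# ---------------------------------------------------------------------------
# out-of-bound filtering and power
# ---------------------------------------------------------------------------

def oob_filter(results):
    """Retain tests with 0 <= phi2 <= 1; tally the two out-of-bound classes.

    Accepts a sequence of :class:`TestResult` or a numeric phi2 array.
    Returns ``(retained, counts)`` with ``counts = {"below_zero": ...,
    "above_one": ...}``.
    """
    if len(results) and isinstance(results[0], TestResult):
        phi2 = np.array([r.phi2 for r in results], dtype=float)
        keep = (phi2 >= 0) & (phi2 <= 1)
        retained = [r for r, k in zip(results, keep) if k]
    else:
        phi2 = np.asarray(results, dtype=float)
        keep = (phi2 >= 0) & (phi2 <= 1)
        retained = phi2[keep]
    counts = {"below_zero": int((phi2 < 0).sum()),
              "above_one": int((phi2 > 1).sum())}
    return retained, counts


def power_estimate(results, alpha: float = 0.05) -> PowerResult:
    """Fraction of defined, in-bound tests exceeding the 1-df critical value.

    Under a true null this estimates the significance level itself (the
    convention used throughout: "power" of a true hypothesis = alpha).
    Undefined and out-of-bound tests are excluded from the denominator and
    counted in ``n_excluded``.
    """
    if len(results) == 0:
        raise ValueError("no tests supplied")
    if isinstance(results[0], TestResult):
        retained, _ = oob_filter(list(results))
        chisq = np.array([r.chisq for r in retained], dtype=float)
        total = len(results)
    else:
        chisq = np.asarray(results, dtype=float)
        total = chisq.size
        chisq = chisq[~np.isnan(chisq)]
    crit = float(sps.chi2.ppf(1 - alpha, df=1))
    n_used = chisq.size
    if n_used == 0:
        return PowerResult(float("nan"), 0, total)
    return PowerResult(float((chisq > crit).mean()), n_used, total - n_used)
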