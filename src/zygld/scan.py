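"""Pairwise genome scans and the summary tables built from them.

A scan row holds, for one marker pair, every disequilibrium estimate
(composite, EM-gametic, trigenic, quadrigenic, zygotic), the delta-method
variances for the non-r2 statistics, the component chi-squares, phi2 values
and flags, plus pair metadata (chromosomes, physical distance, per-pair n
under pairwise-complete deletion).

The summaries mirror the standard presentation of genome-wide LD surveys:
mean/SD of phi2 and the fraction above a strength threshold across physical
distance bins; per-chromosome empirical power split at the 50 Mb
linked/unlinked convention (1 cM = 1 Mb); power across minor-allele-
frequency classes; and power-vs-distance series.  Pairs whose phi2 falls
outside [0, 1] (possible for the trigenic and quadrigenic tests) are
excluded from strength and power denominators and counted separately.

The estimation loop is vectorised over blocks of pairs, so a scan of a few
hundred thousand pairs runs in seconds to minutes on one core.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .core import MISSING, table_statistics, em_gametic_ld_batch
from .inference import CHI2_CRIT_95, delta_variance_batch
from scipy import stats as sps

#: distance bin edges (bp) for the nine sub-5 Mb intervals
TABLE1_EDGES_BP = (0, 25_000, 50_000, 75_000, 100_000,
                   200_000, 500_000, 1_500_000, 3_000_000, 5_000_000)

#: 50 Mb: pairs at most this far apart are "linked", beyond it "unlinked"
LINKED_CUTOFF_BP = 50_000_000

#: MAF class edges; interval convention [0.02, 0.1), [0.1, 0.3), [0.3, 0.5]
MAF_CLASS_EDGES = (0.1, 0.3)
MAF_CLASS_LABELS = ("<0.1", "0.1-0.3", "0.3-0.5")

#: components carried through every scan row / summary
SCAN_COMPONENTS = ("GLD", "CLD", "ZLD", "D_AAB", "D_ABB", "D_AABB")

_EST_COLUMN = {"GLD": "d_gametic", "CLD": "delta_AB", "ZLD": "omega_AABB",
               "D_AAB": "d_AAB", "D_ABB": "d_ABB", "D_AABB": "delta_AABB"}


class PairKey(NamedTuple):
    """Identity and location of one marker pair."""

    marker_i: str
    marker_j: str
    chromosome_i: str
    chromosome_j: str
    distance_bp: float  # nan when non-syntenic
    syntenic: bool


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

def pair_table(marker_map: pd.DataFrame, mode: str = "syntenic",
               max_distance_bp: float | None = None,
               subsample: int | None = None, seed=None) -> pd.DataFrame:
    """Enumerate marker pairs as a DataFrame (one row per pair).

    ``mode`` is "syntenic" (within-chromosome, optionally distance-capped)
    or "nonsyntenic" (between-chromosome).  ``subsample`` draws that many
    pairs uniformly without replacement with the recorded ``seed``, for
    tractability on dense panels.  Row indices ``i``/``j`` refer to
    positions in ``marker_map`` order (= genotype columns after alignment).
    """
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    chrom = marker_map["chromosome"].to_numpy(dtype=object)
    pos = marker_map["position_bp"].to_numpy()
    ids = marker_map["marker_id"].to_numpy(dtype=object)
    m = len(ids)
    iu, ju = np.triu_indices(m, k=1)
    same = chrom[iu] == chrom[ju]
    if mode == "syntenic":
        keep = same
    elif mode == "nonsyntenic":
        keep = ~same
    else:
        raise ValueError(f"unknown mode {mode!r}")
    iu, ju = iu[keep], ju[keep]
    dist = np.where(chrom[iu] == chrom[ju],
                    np.abs(pos[iu] - pos[ju]).astype(float), np.nan)
    if mode == "syntenic" and max_distance_bp is not None:
        keep = dist <= max_distance_bp
        iu, ju, dist = iu[keep], ju[keep], dist[keep]
    if subsample is not None and subsample < len(iu):
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(iu), size=subsample, replace=False)
        sel.sort()
        iu, ju, dist = iu[sel], ju[sel], dist[sel]
    return pd.DataFrame({
        "i": iu, "j": ju,
        "marker_i": ids[iu], "marker_j": ids[ju],
        "chrom_i": chrom[iu], "chrom_j": chrom[ju],
        "distance_bp": dist,
        "syntenic": chrom[iu] == chrom[ju],
    })


def enumerate_pairs(marker_map: pd.DataFrame, mode: str = "syntenic",
                    max_distance_bp: float | None = None,
                    subsample: int | None = None,
                    seed=None) -> Iterator[PairKey]:
    """Stream :class:`PairKey` records (see :func:`pair_table`)."""
    tbl = pair_table(marker_map, mode, max_distance_bp, subsample, seed)
    for row in tbl.itertuples(index=False):
        yield PairKey(row.marker_i, row.marker_j, str(row.chrom_i),
                      str(row.chrom_j), row.distance_bp, bool(row.syntenic))


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def scan(gm, marker_map: pd.DataFrame, mode: str = "syntenic",
         max_distance_bp: float | None = None,
         subsample: int | None = None, seed=None,
         gld_n: str = "animals",
         em_tol: float = 1e-10, em_max_iter: int = 1000,
         chunk_size: int = 20_000) -> pd.DataFrame:
    """Estimate and test every enumerated pair; one row per pair.

    Markers are taken in ``marker_map`` order; ``gm`` must contain every
    mapped marker.  Per-pair failures (monomorphic in the pairwise-complete
    subset, degenerate margins) yield NaN statistics and a flag, never an
    aborted scan.  Deterministic for a given map, genotypes and ``seed``.
    """
    col_of = {mid: k for k, mid in enumerate(gm.marker_ids)}
    order = np.array([col_of[mid] for mid in marker_map["marker_id"]])
    X = gm.dosages[:, order]
    X4 = np.where(X == MISSING, 3, X).astype(np.int64)

    pairs = pair_table(marker_map, mode, max_distance_bp, subsample, seed)
    out_chunks = []
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs.iloc[start:start + chunk_size]
        out_chunks.append(_scan_chunk(X4, chunk, gld_n, em_tol, em_max_iter))
    if not out_chunks:
        return _scan_chunk(X4, pairs, gld_n, em_tol, em_max_iter)
    return pd.concat(out_chunks, ignore_index=True)


def _scan_chunk(X4, pairs: pd.DataFrame, gld_n: str,
                em_tol: float, em_max_iter: int) -> pd.DataFrame:
    k = len(pairs)
    i = pairs["i"].to_numpy()
    j = pairs["j"].to_numpy()
    # 4x4 cross-tab per pair via one flat bincount (code 3 = missing)
    cells = X4[:, i] * 4 + X4[:, j]                      # (n_animals, k)
    flat = cells + 16 * np.arange(k)[None, :]
    counts16 = np.bincount(flat.ravel(), minlength=16 * k)
    counts = counts16.reshape(k, 4, 4)[:, :3, :3].astype(float)
    n = counts.sum(axis=(1, 2))

    with np.errstate(divide="ignore", invalid="ignore"):
        P = counts / np.where(n > 0, n, 1.0)[:, None, None]
        s = table_statistics(P)
        poly = (s["pi_A"] > 0) & (s["pi_B"] > 0) & (n > 0)

        h, d_gam, r2_gld, conv, flat_lik, _ = em_gametic_ld_batch(
            P, tol=em_tol, max_iter=em_max_iter)
        d_gam = np.where(flat_lik, 0.0, d_gam)
        r2_gld = np.where(flat_lik, 0.0, r2_gld)

        denom_c = (s["pi_A"] + s["D_A"]) * (s["pi_B"] + s["D_B"])
        r2_cld = np.where(denom_c > 0, s["delta_AB"] ** 2 / denom_c, np.nan)
        varA = s["P_AA"] * (1 - s["P_AA"])
        varB = s["P_BB"] * (1 - s["P_BB"])
        denom_z = varA * varB
        r2_zld = np.where(denom_z > 0, s["omega_AABB"] ** 2 / denom_z, np.nan)

        variances = delta_variance_batch(P, n)
        n_gld = 2 * n if gld_n == "gametes" else n
        x2 = {
            "GLD": n_gld * r2_gld,
            "CLD": n * r2_cld,
            "ZLD": n * r2_zld,
            "D_AAB": s["d_AAB"] ** 2 / variances["d_AAB"],
            "D_ABB": s["d_ABB"] ** 2 / variances["d_ABB"],
            "D_AABB": s["delta_AABB"] ** 2 / variances["delta_AABB"],
        }

    out = pairs.drop(columns=["i", "j"]).reset_index(drop=True)
    out["n"] = n
    out["maf_A"] = np.minimum(s["p_A"], 1 - s["p_A"])
    out["maf_B"] = np.minimum(s["p_B"], 1 - s["p_B"])
    out["delta_AB"] = s["delta_AB"]
    out["d_gametic"] = d_gam
    out["d_AAB"] = s["d_AAB"]
    out["d_ABB"] = s["d_ABB"]
    out["delta_AABB"] = s["delta_AABB"]
    out["omega_AABB"] = s["omega_AABB"]
    out["r2_gld"] = r2_gld
    out["r2_cld"] = r2_cld
    out["r2_zld"] = r2_zld
    for name in ("delta_AB", "d_AAB", "d_ABB", "delta_AABB"):
        out[f"var_{name}"] = variances[name]
    for comp in SCAN_COMPONENTS:
        v = np.where(poly, x2[comp], np.nan)
        out[f"x2_{comp}"] = v
        out[f"phi2_{comp}"] = v / np.where(n > 0, n, np.nan)
    out["em_converged"] = conv
    out["em_flat"] = flat_lik
    out["defined"] = poly
    # blank the estimate columns of degenerate pairs
    est_cols = ["delta_AB", "d_gametic", "d_AAB", "d_ABB", "delta_AABB",
                "omega_AABB", "r2_gld", "r2_cld", "r2_zld"]
    out.loc[~poly, est_cols] = np.nan
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _component_power(rows: pd.DataFrame, comp: str, alpha: float):
    """(n_used, power, mean_phi2, sd_phi2, n_excluded) for one component.

    Uses only pairs with a defined phi2 inside [0, 1]; everything else is
    excluded from the denominator and counted.
    """
    phi2 = rows[f"phi2_{comp}"].to_numpy(dtype=float)
    x2 = rows[f"x2_{comp}"].to_numpy(dtype=float)
    ok = np.isfinite(phi2) & (phi2 >= 0) & (phi2 <= 1)
    n_used = int(ok.sum())
    if n_used == 0:
        return 0, np.nan, np.nan, np.nan, int(len(rows))
    crit = float(sps.chi2.ppf(1 - alpha, df=1))
    power = float((x2[ok] > crit).mean())
    mean = float(phi2[ok].mean())
    sd = float(phi2[ok].std(ddof=1)) if n_used > 1 else np.nan
    return n_used, power, mean, sd, int(len(rows) - n_used)


def bin_by_distance(rows: pd.DataFrame, edges=TABLE1_EDGES_BP,
                    threshold: float = 0.25,
                    components=("GLD", "CLD", "ZLD"),
                    alpha: float = 0.05) -> pd.DataFrame:
    """Strength and power of syntenic pairs across distance bins.

    Half-open bins [lo, hi) from ``edges`` (default: the nine sub-5 Mb
    intervals).  Per bin and component: retained pair count, mean and SD of
    phi2, the fraction of phi2 values at or above ``threshold``, and power.
    """
    syn = rows[rows["syntenic"] & rows["distance_bp"].notna()]
    edges = np.asarray(edges, dtype=float)
    labels = [_bin_label(lo, hi, edges) for lo, hi in zip(edges[:-1], edges[1:])]
    which = pd.cut(syn["distance_bp"], bins=edges, right=False, labels=labels)
    recs = []
    for lab in labels:
        sub = syn[which == lab]
        for comp in components:
            if len(sub) == 0:
                recs.append((lab, comp, 0, np.nan, np.nan, np.nan, np.nan, 0))
                continue
            n_used, power, mean, sd, n_exc = _component_power(sub, comp, alpha)
            phi2 = sub[f"phi2_{comp}"].to_numpy(dtype=float)
            ok = np.isfinite(phi2) & (phi2 >= 0) & (phi2 <= 1)
            frac = float((phi2[ok] >= threshold).mean()) if ok.any() else np.nan
            recs.append((lab, comp, n_used, mean, sd, frac, power, n_exc))
    return pd.DataFrame(recs, columns=["bin", "component", "n_pairs",
                                       "mean_phi2", "sd_phi2",
                                       f"frac_ge_{threshold}", "power",
                                       "n_excluded"])


def _bin_label(lo, hi, edges):
    lo_mb, hi_mb = lo / 1e6, hi / 1e6
    if lo == edges[0]:
        return f"<{hi_mb:g}"
    return f"{lo_mb:g}-{hi_mb:g}"


def linked_unlinked_summary(rows: pd.DataFrame,
                            cutoff_bp: float = LINKED_CUTOFF_BP,
                            components=SCAN_COMPONENTS,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-chromosome power for pairs <= cutoff ("linked") and > cutoff.

    Chromosomes with no pairs beyond the cutoff (shorter than 50 Mb) report
    NaN power and zero pairs for the unlinked group — the absent cell.
    """
    syn = rows[rows["syntenic"] & rows["distance_bp"].notna()]
    recs = []
    for chrom, sub in syn.groupby("chrom_i", sort=True):
        for group, grp in (("linked", sub[sub["distance_bp"] <= cutoff_bp]),
                           ("unlinked", sub[sub["distance_bp"] > cutoff_bp])):
            for comp in components:
                if len(grp) == 0:
                    recs.append((chrom, group, comp, 0, np.nan, 0))
                    continue
                n_used, power, _, _, n_exc = _component_power(grp, comp, alpha)
                recs.append((chrom, group, comp, n_used, power, n_exc))
    return pd.DataFrame(recs, columns=["chromosome", "group", "component",
                                       "n_pairs", "power", "n_excluded"])


def maf_class(maf) -> np.ndarray:
    """Class index 0/1/2 for MAF intervals [*, 0.1), [0.1, 0.3), [0.3, 0.5]."""
    return np.digitize(np.asarray(maf, dtype=float), MAF_CLASS_EDGES)


def maf_class_summary(rows: pd.DataFrame, components=SCAN_COMPONENTS,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Power over the 3x3 MAF classes, syntenic and non-syntenic separately.

    Within each (MAF_A class, MAF_B class) cell, power is computed per
    chromosome (syntenic pairs) or per chromosome pair (non-syntenic) and
    its mean, minimum and maximum across those groups reported — plus the
    pooled power over all pairs in the cell.
    """
    rows = rows.copy()
    rows["maf_class_A"] = maf_class(rows["maf_A"].fillna(-1))
    rows["maf_class_B"] = maf_class(rows["maf_B"].fillna(-1))
    recs = []
    for syntenic, sub in rows.groupby("syntenic"):
        group_key = "chrom_i" if syntenic else None
        if not syntenic:
            sub = sub.assign(_cp=[f"{a}|{b}" for a, b in
                                  zip(sub["chrom_i"], sub["chrom_j"])])
            group_key = "_cp"
        for (ca, cb), cell in sub.groupby(["maf_class_A", "maf_class_B"]):
            for comp in components:
                powers = []
                for _, grp in cell.groupby(group_key):
                    _, p, _, _, _ = _component_power(grp, comp, alpha)
                    if np.isfinite(p):
                        powers.append(p)
                n_used, pooled, _, _, n_exc = _component_power(cell, comp, alpha)
                recs.append((bool(syntenic), MAF_CLASS_LABELS[ca],
                             MAF_CLASS_LABELS[cb], comp, n_used,
                             pooled,
                             float(np.mean(powers)) if powers else np.nan,
                             float(np.min(powers)) if powers else np.nan,
                             float(np.max(powers)) if powers else np.nan,
                             n_exc))
    return pd.DataFrame(recs, columns=["syntenic", "maf_class_A", "maf_class_B",
                                       "component", "n_pairs", "power",
                                       "power_mean", "power_min", "power_max",
                                       "n_excluded"])


def power_vs_distance_curve(rows: pd.DataFrame, window_bp: float,
                            max_bp: float = LINKED_CUTOFF_BP,
                            components=SCAN_COMPONENTS,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Binned power series in distance: windows [k*w, (k+1)*w) up to max_bp."""
    syn = rows[rows["syntenic"] & rows["distance_bp"].notna()]
    syn = syn[syn["distance_bp"] < max_bp]
    edges = np.arange(0, max_bp + window_bp, window_bp)
    idx = np.digitize(syn["distance_bp"].to_numpy(dtype=float), edges) - 1
    recs = []
    for k in range(len(edges) - 1):
        sub = syn[idx == k]
        mid = (edges[k] + edges[k + 1]) / 2
        for comp in components:
            if len(sub) == 0:
                recs.append((mid, comp, 0, np.nan, 0))
                continue
            n_used, power, _, _, n_exc = _component_power(sub, comp, alpha)
            recs.append((mid, comp, n_used, power, n_exc))
    return pd.DataFrame(recs, columns=["distance_mid_bp", "component",
                                       "n_pairs", "power", "n_excluded"])


def oob_summary(rows: pd.DataFrame,
                components=("D_AAB", "D_ABB", "D_AABB")) -> pd.DataFrame:
    """Out-of-bound phi2 proportions per component (below 0 / above 1)."""
    recs = []
    for comp in components:
        phi2 = rows[f"phi2_{comp}"].to_numpy(dtype=float)
        defined = np.isfinite(phi2)
        nd = int(defined.sum())
        below = float((phi2[defined] < 0).mean()) if nd else np.nan
        above = float((phi2[defined] > 1).mean()) if nd else np.nan
        recs.append((comp, nd, below, above))
    return pd.DataFrame(recs, columns=["component", "n_defined",
                                       "frac_below_zero", "frac_above_one"])


def write_pairs_tsv(rows: pd.DataFrame, path) -> None:
    """Persist a scan table; floats round-trip exactly through repr."""
    rows.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip",
                       dtype={"chrom_i": str, "chrom_j": str,
                              "marker_i": str, "marker_j": str})
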