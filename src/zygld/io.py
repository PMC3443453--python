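"""Genotype matrices, marker maps, text-format readers/writers and marker QC.

Two text dialects are supported: a tab-delimited dosage table (header row of
marker ids, first column the animal id, entries 0/1/2 or a missing token)
with a companion marker map (marker_id / chromosome / position_bp), and the
PLINK .ped/.map text dialect (six leading .ped columns, two allele columns
per marker, "0" = missing allele).

QC follows the standard panel-cleaning sequence for a SNP-chip dataset:
markers are removed, each by the first matching rule, in the order
(i) monomorphic, (ii) unmapped, (iii) sex chromosome, (iv) MAF <= 2%,
(v) HWD chi-square > 600, with the per-rule tallies reported so the
retained count reconciles exactly with the input count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, locus_summary

#: chromosome labels treated as sex chromosomes by default
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "x", "y"})

#: chromosome label given to markers absent from the map
UNKNOWN_CHROMOSOME = "unknown"

MAP_COLUMNS = ["marker_id", "chromosome", "position_bp"]


@dataclass
class GenotypeMatrix:
    """Unphased dosage matrix: rows = animals, columns = markers.

    ``dosages[i, j]`` is the number of copies of the designated A allele of
    marker ``j`` carried by animal ``i`` (0, 1, 2) or :data:`~zygld.core.MISSING`.
    ``a_alleles`` optionally records which allele label was designated A at
    load time (PLINK reader: the lexicographically smaller observed allele;
    QC re-orients to the minor allele and records the flips).
    """

    animal_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    a_alleles: dict[str, str] | None = None

    def __post_init__(self):
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if d.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers")
        bad = ~np.isin(d, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"non-dosage entries at {np.argwhere(bad)[:5]}")
        self.dosages = d.astype(np.int8)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        ids = [self.marker_ids[k] for k in np.flatnonzero(keep)] \
            if keep.dtype == bool else [self.marker_ids[k] for k in keep]
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        alle = None
        if self.a_alleles is not None:
            alle = {m: self.a_alleles[m] for m in ids if m in self.a_alleles}
        return GenotypeMatrix(self.animal_ids, ids,
                              self.dosages[:, idx], alle)


@dataclass(frozen=True)
class QCReport:
    """Per-rule marker removal tallies; categories are mutually exclusive."""

    n_input: int
    n_removed_monomorphic: int
    n_removed_unmapped: int
    n_removed_sex_chromosome: int
    n_removed_maf: int
    n_removed_hwd: int
    n_retained: int

    def __post_init__(self):
        removed = (self.n_removed_monomorphic + self.n_removed_unmapped
                   + self.n_removed_sex_chromosome + self.n_removed_maf
                   + self.n_removed_hwd)
        if self.n_retained != self.n_input - removed:
            raise ValueError("QC tallies do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosage-table dialect
# ---------------------------------------------------------------------------

def read_dosage_table(path, map_path=None, missing_code: str = "NA"):
    """Read a tab-delimited dosage table (and optional marker map).

    Returns ``(GenotypeMatrix, MarkerMap DataFrame)``.  Markers absent from
    the map are kept with chromosome label ``"unknown"`` and position -1 so
    the QC unmapped rule can pick them up.  Unknown tokens are an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    marker_ids = header[1:]
    if len(set(marker_ids)) != len(marker_ids):
        counts = pd.Series(marker_ids).value_counts()
        raise ValueError(f"duplicate marker id: {counts.index[0]!r}")
    df = pd.read_csv(path, sep="\t", dtype=str,
                     keep_default_na=False, na_values=[])
    if df.shape[1] != len(header):
        raise ValueError("malformed table: ragged rows")
    animal_ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = np.empty(raw.shape, dtype=np.int8)
    mapping = {"0": 0, "1": 1, "2": 2, missing_code: MISSING}
    for token, code in mapping.items():
        dosages[raw == token] = code
    known = np.isin(raw, list(mapping))
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise ValueError(
            f"unknown genotype token {raw[i, j]!r} for animal "
            f"{animal_ids[i]!r}, marker {marker_ids[j]!r}")
    gm = GenotypeMatrix(animal_ids, marker_ids, dosages)
    if map_path is None:
        mm = pd.DataFrame({"marker_id": marker_ids,
                           "chromosome": UNKNOWN_CHROMOSOME,
                           "position_bp": -1})
    else:
        mm = read_marker_map(map_path)
        mm = align_map(mm, marker_ids)
    return gm, mm


def write_dosage_table(gm: GenotypeMatrix, path, missing_code: str = "NA") -> None:
    """Write a GenotypeMatrix in the dosage-table dialect (round-trippable)."""
    codes = gm.dosages.astype(object)
    codes[gm.dosages == MISSING] = missing_code
    df = pd.DataFrame(codes, columns=gm.marker_ids)
    df.insert(0, "animal_id", gm.animal_ids)
    df.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    """Read a tab-delimited marker map; positions sorted within chromosome."""
    mm = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    missing = [c for c in MAP_COLUMNS if c not in mm.columns]
    if missing:
        raise ValueError(f"marker map lacks columns {missing}")
    if mm["marker_id"].duplicated().any():
        dup = mm.loc[mm["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker id in map: {dup!r}")
    mm["position_bp"] = mm["position_bp"].astype(np.int64)
    return mm.sort_values(["chromosome", "position_bp"], kind="stable",
                          ignore_index=True)


def write_marker_map(mm: pd.DataFrame, path) -> None:
    mm[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def align_map(mm: pd.DataFrame, marker_ids) -> pd.DataFrame:
    """Reindex a map to a marker list; absent markers flagged unmapped."""
    mm = mm.set_index("marker_id")
    out = []
    for m in marker_ids:
        if m in mm.index:
            row = mm.loc[m]
            out.append((m, row["chromosome"], int(row["position_bp"])))
        else:
            out.append((m, UNKNOWN_CHROMOSOME, -1))
    return pd.DataFrame(out, columns=MAP_COLUMNS)


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path):
    """Read PLINK .ped/.map text files into a GenotypeMatrix + marker map.

    Per marker the A allele is the lexicographically smaller observed allele
    label (recorded in ``a_alleles``); the dosage is the count of A; a pair
    with either allele "0" is missing.  More than two observed alleles at a
    marker is an error naming the marker.
    """
    mm = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chromosome", "marker_id", "cm", "position_bp"],
                     dtype={"chromosome": str, "marker_id": str})
    marker_ids = mm["marker_id"].tolist()
    n_markers = len(marker_ids)

    animal_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            alleles = parts[6:]
            if len(alleles) != 2 * n_markers:
                raise ValueError(
                    f"{ped_path} line {line_no}: expected "
                    f"{2 * n_markers} allele columns, got {len(alleles)}")
            animal_ids.append(parts[1])
            allele_rows.append(alleles)

    arr = np.array(allele_rows, dtype=object).reshape(len(animal_ids), n_markers, 2)
    dosages = np.full((len(animal_ids), n_markers), MISSING, dtype=np.int8)
    a_alleles: dict[str, str] = {}
    for j, marker in enumerate(marker_ids):
        col = arr[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(
                f"marker {marker!r} has more than two alleles: {observed}")
        a = observed[0] if observed else "0"
        a_alleles[marker] = a
        called = (col != "0").all(axis=1)
        dosages[called, j] = (col[called] == a).sum(axis=1)
    gm = GenotypeMatrix(animal_ids, marker_ids, dosages, a_alleles)
    mm = mm[["marker_id", "chromosome", "position_bp"]].copy()
    mm["position_bp"] = mm["position_bp"].astype(np.int64)
    mm = mm.sort_values(["chromosome", "position_bp"], kind="stable",
                        ignore_index=True)
    return gm, mm


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------

def orient_to_minor_allele(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Recode dosages so the designated A allele is the minor allele.

    Fixing the orientation once keeps the signs of all D estimates stable
    across downstream modules.
    """
    dosages = gm.dosages.copy()
    for j in range(gm.n_markers):
        col = dosages[:, j]
        called = col != MISSING
        if not called.any():
            continue
        p = col[called].mean() / 2
        if p > 0.5:
            col[called] = 2 - col[called]
    return GenotypeMatrix(gm.animal_ids, gm.marker_ids, dosages, gm.a_alleles)


def qc_filter(gm: GenotypeMatrix, marker_map: pd.DataFrame,
              maf_min: float = 0.02, hwd_chisq_max: float = 600.0,
              drop_sex: bool = True,
              sex_labels=SEX_CHROMOSOMES):
    """Apply the marker QC rules; returns (matrix, map, QCReport).

    Removal rules, applied in order with each marker counted once:
    (i) monomorphic, (ii) unmapped (chromosome "unknown" or position < 0),
    (iii) sex chromosome, (iv) MAF <= ``maf_min`` (strict: MAF exactly at
    the threshold is removed), (v) HWD chi-square ``n f**2`` >
    ``hwd_chisq_max``.
    """
    mm = align_map(marker_map, gm.marker_ids) \
        if list(marker_map["marker_id"]) != gm.marker_ids else marker_map
    by_id = mm.set_index("marker_id")
    summaries = [locus_summary(gm.dosages[:, j]) if (gm.dosages[:, j] != MISSING).any()
                 else None for j in range(gm.n_markers)]

    reasons = np.zeros(gm.n_markers, dtype=int)  # 0 = keep
    for j, s in enumerate(summaries):
        chrom = str(by_id.loc[gm.marker_ids[j], "chromosome"])
        pos = int(by_id.loc[gm.marker_ids[j], "position_bp"])
        if s is None or s.monomorphic:
            reasons[j] = 1
        elif chrom == UNKNOWN_CHROMOSOME or pos < 0:
            reasons[j] = 2
        elif drop_sex and chrom in sex_labels:
            reasons[j] = 3
        elif s.maf <= maf_min:
            reasons[j] = 4
        elif s.hwd_chisq > hwd_chisq_max:
            reasons[j] = 5

    keep = reasons == 0
    report = QCReport(
        n_input=gm.n_markers,
        n_removed_monomorphic=int((reasons == 1).sum()),
        n_removed_unmapped=int((reasons == 2).sum()),
        n_removed_sex_chromosome=int((reasons == 3).sum()),
        n_removed_maf=int((reasons == 4).sum()),
        n_removed_hwd=int((reasons == 5).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("QC removed every marker")
    kept_ids = [m for m, k in zip(gm.marker_ids, keep) if k]
    mm_out = mm[mm["marker_id"].isin(kept_ids)].reset_index(drop=True)
    return gm.subset_markers(keep), mm_out, report
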