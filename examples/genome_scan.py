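"""Full pipeline on a simulated composite-population genome.

Simulates a small two-chromosome panel from the ancestry-mosaic admixture
model, applies the marker QC rules, scans every syntenic pair and prints
the genome-wide summary tables: LD strength by distance bin, power in the
linked (<= 50 Mb) and unlinked (> 50 Mb) groups, power by minor-allele-
frequency class, and the out-of-bound tallies for the higher-order tests.
"""

import numpy as np

from zygld import (
    bin_by_distance,
    linked_unlinked_summary,
    maf_class_summary,
    qc_filter,
    scan,
    simulate_genome,
)
from zygld.scan import oob_summary

gm, mm = simulate_genome([60_000_000, 60_000_000], 300, n=200, seed=99)
gm, mm, report = qc_filter(gm, mm)
print("QC:", report.n_input, "markers in,", report.n_retained, "retained",
      f"({report.n_removed_maf} removed at MAF <= 2%,",
      f"{report.n_removed_hwd} at HWD X2 > 600)")

rows = scan(gm, mm, mode="syntenic")
print(f"\nscanned {len(rows)} syntenic pairs "
      f"({int(rows['defined'].sum())} with defined statistics)\n")

tbl = bin_by_distance(rows)
cld = tbl[tbl["component"] == "CLD"]
print("composite-LD strength by distance (phi2 = X2/n):")
print(cld[["bin", "n_pairs", "mean_phi2", "sd_phi2", "frac_ge_0.25"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

lu = linked_unlinked_summary(rows)
pooled = (lu.groupby(["group", "component"], sort=False)["power"]
          .mean().unstack("group"))
print("\nmean per-chromosome power, linked (<=50 Mb) vs unlinked (>50 Mb):")
print(pooled.to_string(float_format=lambda v: f"{v:.3f}"))

maf = maf_class_summary(rows, components=("CLD", "ZLD"))
syn = maf[maf["syntenic"]]
print("\nsyntenic power by MAF class (CLD / ZLD):")
for (_, row) in syn[syn["component"] == "CLD"].iterrows():
    zrow = syn[(syn["component"] == "ZLD")
               & (syn["maf_class_A"] == row["maf_class_A"])
               & (syn["maf_class_B"] == row["maf_class_B"])].iloc[0]
    print(f"  MAF_A {row['maf_class_A']:>7s}  MAF_B {row['maf_class_B']:>7s}"
          f"   CLD {row['power']:.3f}   ZLD {zrow['power']:.3f}"
          f"   ({row['n_pairs']} pairs)")

print("\nout-of-bound phi2 tallies for the higher-order tests:")
print(oob_summary(rows).to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))

print("\nExpected picture: composite LD decays with physical distance and "
      "is stronger for linked pairs, yet admixture keeps power well above "
      "alpha even for unlinked pairs.  In this panel power falls with MAF "
      "for both tests because the most breed-divergent markers are also "
      "the lowest-MAF ones — with real data the MAF profile of power "
      "instead reflects each test's frequency-dependent sensitivity.")
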