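"""Group the catalog's 11 identified ions into CF2 homologous series.

Single-linkage grouping on Kendrick mass defect (tolerance 0.002 Da) with an
explicit CF2-spacing requirement recovers the class structure: three series
with two or more members (sulfonic acids, sulfonamides, 1H-perfluoroalkanes)
and the fluorotelomer sulfonate as a singleton.  Retention times within each
series must increase with mass; violations would flag false positives.
"""

from pfas_screen import SeriesPoint, check_rt_trend, group_series
from pfas_screen.catalog import COMPOUNDS

points = [
    SeriesPoint(label=c.name, mz=c.theoretical_mz, rt=c.rt, class_label=c.pfas_class)
    for c in COMPOUNDS
]

for series in group_series(points):
    series = check_rt_trend(series)
    members = " -> ".join(f"{m.label} ({m.mz:.4f}, {m.rt} min)" for m in series.members)
    print(f"series KMD {series.shared_kmd:+.5f}  class={series.class_label}  "
          f"rt_trend_ok={series.rt_trend_ok}")
    print(f"  {members}")

n_multi = sum(len(s) >= 2 for s in group_series(points))
print(f"\n{n_multi} series with >= 2 members; singletons are legal series of one.")
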