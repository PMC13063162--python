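"""CF2 homologous-series detection via Kendrick mass defects.

Members of a homologous series differ by whole CF2 units, so after CF2
normalisation they share a Kendrick mass defect and align horizontally on an
m/z-vs-KMD plot.  Series are found by single-linkage grouping: two ions link
when their KMDs agree within ``kmd_tol`` *and* their mass difference is an
integer multiple (>= 1) of the exact CF2 mass within ``spacing_ppm``.  The
spacing requirement makes explicit what a reader of the plot checks visually
— that a shared mass defect is not an accidental coincidence between classes.

Within a series, retention time should increase with chain length on a
reversed-phase gradient; members that break strict monotonicity are flagged
as suspected false positives but never deleted, leaving the exclusion as a
reviewed decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .chem import CF2_EXACT, kendrick_mass_defect

__all__ = [
    "SeriesPoint",
    "HomologSeries",
    "group_series",
    "check_rt_trend",
    "kmd_table",
    "plot_kmd",
]


@dataclass(frozen=True)
class SeriesPoint:
    """An identified ion to be placed on the KMD plot."""

    label: str
    mz: float
    rt: Optional[float] = None
    class_label: Optional[str] = None

    @property
    def kmd(self) -> float:
        return kendrick_mass_defect(self.mz).kmd


@dataclass
class HomologSeries:
    members: List[SeriesPoint]  # sorted by m/z
    shared_kmd: float
    class_label: Optional[str] = None
    rt_trend_ok: Optional[bool] = None
    flagged_members: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def group_series(
    points: Sequence[SeriesPoint],
    kmd_tol: float = 0.002,
    spacing_ppm: float = 5.0,
) -> List[HomologSeries]:
    """Single-linkage grouping of ions into CF2 homologous series.

    Singletons are legal series of one.  Grouping is invariant to input
    order; output series are sorted by their lowest member m/z.
    """
    pts = list(points)
    n = len(pts)
    if n == 0:
        return []
    kmds = np.array([p.kmd for p in pts])
    mzs = np.array([p.mz for p in pts])
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(kmds[i] - kmds[j]) > kmd_tol:
                continue
            dmz = abs(mzs[i] - mzs[j])
            k = round(dmz / CF2_EXACT)
            if k < 1:
                continue
            if abs(dmz - k * CF2_EXACT) <= spacing_ppm * 1e-6 * max(mzs[i], mzs[j]):
                rows.append(i)
                cols.append(j)
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    series: List[HomologSeries] = []
    for comp in range(n_comp):
        members = sorted(
            (pts[i] for i in range(n) if labels[i] == comp), key=lambda p: p.mz
        )
        classes = {m.class_label for m in members if m.class_label}
        series.append(
            HomologSeries(
                members=members,
                shared_kmd=float(np.mean([m.kmd for m in members])),
                class_label=classes.pop() if len(classes) == 1 else None,
            )
        )
    series.sort(key=lambda s: s.members[0].mz)
    return series


def check_rt_trend(series: HomologSeries) -> HomologSeries:
    """Validate that RT strictly increases with mass within the series.

    Members that fail strict monotonicity (including ties) are recorded in
    ``flagged_members`` as suspected false positives.  Members without RT
    make the trend unassessable (``rt_trend_ok`` stays None).
    """
    if any(m.rt is None for m in series.members):
        return replace(series, rt_trend_ok=None, flagged_members=[])
    flagged: List[str] = []
    running_max = -np.inf
    for m in series.members:  # already sorted by m/z
        if m.rt <= running_max:
            flagged.append(m.label)
        else:
            running_max = m.rt
    return replace(series, rt_trend_ok=not flagged, flagged_members=flagged)


def kmd_table(
    points: Iterable[SeriesPoint],
    kmd_tol: float = 0.002,
    spacing_ppm: float = 5.0,
) -> pd.DataFrame:
    """Plot-ready table: one row per ion with its KMD and series id.

    Rows are deduplicated by label (an ion identified in several samples
    appears once) and ordered by m/z.
    """
    unique: dict = {}
    for p in points:
        unique.setdefault(p.label, p)
    pts = sorted(unique.values(), key=lambda p: p.mz)
    series = group_series(pts, kmd_tol, spacing_ppm)
    series_of = {
        m.label: idx for idx, s in enumerate(series, start=1) for m in s.members
    }
    return pd.DataFrame(
        [
            {
                "compound": p.label,
                "mz": p.mz,
                "kmd": p.kmd,
                "series_id": series_of[p.label],
                "class": p.class_label,
            }
            for p in pts
        ],
        columns=["compound", "mz", "kmd", "series_id", "class"],
    )


def plot_kmd(table: pd.DataFrame, path=None):
    """Render the m/z-vs-KMD plot with one colour per series.

    Horizontal bands are homologous series; returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, grp in table.groupby("series_id"):
        label = grp["class"].dropna().unique()
        ax.scatter(
            grp["mz"],
            grp["kmd"],
            label=label[0] if len(label) == 1 else f"series {sid}",
        )
        if len(grp) > 1:
            ax.plot(grp["mz"], grp["kmd"], linestyle="--", linewidth=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("Kendrick mass defect (CF$_2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
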