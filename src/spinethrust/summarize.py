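"""Group-level descriptive statistics for spine-thrust measurements.

For each (species, strain, temperature) group: n, mean, standard error,
median, quartiles (linear interpolation between order statistics) and the
half-width of the notch estimating the 95% confidence interval of the
median, 1.58 * IQR / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .errors import SpineThrustError

__all__ = ["GroupSummary", "summarize_group", "summarize_measurements", "plot_groups"]


@dataclass(frozen=True)
class GroupSummary:
    """Descriptives of one group's ST values (micrometers).

    ``se`` and ``notch`` are NaN for n == 1, where they are undefined.
    """

    key: Hashable
    n: int
    mean: float
    se: float
    median: float
    q1: float
    q3: float
    notch: float


def summarize_group(values: Sequence[float], key: Hashable = None) -> GroupSummary:
    """Mean, SE, median, quartiles and median-CI notch of one group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise SpineThrustError(f"empty group: {key!r}")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    n = v.size
    if n >= 2:
        se = float(v.std(ddof=1) / math.sqrt(n))
        notch = float(1.58 * (q3 - q1) / math.sqrt(n))
    else:
        se = math.nan
        notch = math.nan
    return GroupSummary(
        key=key,
        n=int(n),
        mean=float(v.mean()),
        se=se,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        notch=notch,
    )


GROUP_KEYS = ["species", "strain", "temperature_C"]


def summarize_measurements(
    measurements: pd.DataFrame, value_column: str = "ST_um"
) -> pd.DataFrame:
    """One summary row per (species, strain, temperature) group.

    Rows without a measured value (excluded specimens) are ignored.
    """
    df = measurements.dropna(subset=[value_column])
    rows = []
    for key, grp in df.groupby(GROUP_KEYS, sort=True):
        s = summarize_group(grp[value_column].to_numpy(), key=key)
        rows.append(
            {
                **dict(zip(GROUP_KEYS, key)),
                "n": s.n,
                "mean": s.mean,
                "se": s.se,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "notch": s.notch,
            }
        )
    return pd.DataFrame(rows)


def plot_groups(summary: pd.DataFrame, measurements: pd.DataFrame, path=None):
    """Notched-box style overview: individual points, mean +/- SE per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(summary) + 2, 4))
    labels = []
    for i, row in summary.reset_index(drop=True).iterrows():
        sel = measurements
        for k in GROUP_KEYS:
            sel = sel[sel[k] == row[k]]
        vals = sel["ST_um"].dropna()
        ax.scatter(np.full(len(vals), i), vals, s=8, color="0.6", zorder=1)
        ax.errorbar(i, row["mean"], yerr=row["se"], fmt="o", color="C0", zorder=3)
        ax.hlines(row["median"], i - 0.25, i + 0.25, color="k", lw=2, zorder=2)
        ax.vlines(i, row["q1"], row["q3"], color="C0", lw=6, alpha=0.3, zorder=0)
        labels.append(f"{row['species']}\n{row['strain']}\n{row['temperature_C']:g}C")
    ax.set_xticks(range(len(summary)), labels, fontsize=8)
    ax.set_ylabel("spine thrust (um)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
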